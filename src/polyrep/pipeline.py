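"""Pipeline orchestration: config, staged execution, reports and figures.

Runs simulate (optional) -> prep -> cluster -> filter -> additivity -> bias
from a single flat YAML config, writing TSV/JSON outputs, figures, and a run
manifest. A single global seed is split into per-stage seeds through
``numpy.random.SeedSequence`` in a fixed stage order, so any stage can be
reproduced in isolation. Identical config + seed gives byte-identical
TSV/JSON outputs (figures are excluded from the byte-identity promise: PNG
encoders embed library metadata).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import __version__
from .additivity import (
    DeviationCurve,
    cumulative_curve,
    deviation_table,
    genome_size_deviation,
)
from .bias import fit_joint_plane, fit_parent_regression, slope_equality_test
from .cluster import cluster_reads, pool_readsets
from .filtering import CrossDesign, apply_filters, flag_contaminants
from .prep import preprocess_reads, read_fastq, subsample_reads, tag_species, write_fastq
from .simulate import (
    InheritanceModel,
    apply_inheritance,
    generate_reads,
    simulate_parents,
    write_truth_tsv,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "prep", "cluster", "filter", "additivity", "bias")

# reads are simulated at this multiple of the target proportion so the
# subsampling stage operates on a genuine surplus
SIMULATE_OVERSAMPLE = 3.0


class PipelineError(RuntimeError):
    def __init__(self, stage: str, reason: Exception):
        super().__init__(f"stage {stage!r} failed: {reason}")
        self.stage = stage
        self.reason = reason


@dataclass
class PipelineConfig:
    """Flat configuration for a full pipeline run."""

    outdir: str
    seed: int = 1
    # roles
    maternal_code: str = "MATER"
    paternal_code: str = "PATER"
    tetraploid_code: str = "TETRA"
    # genome sizes (bp); for simulate mode the tetraploid size is derived
    maternal_c_value_bp: int = 500_000
    paternal_c_value_bp: int = 500_000
    tetraploid_c_value_bp: int | None = None
    # input mode
    simulate: bool = True
    maternal_fastq: str | None = None
    paternal_fastq: str | None = None
    tetraploid_fastq: str | None = None
    # simulation scenario
    n_families: int = 8
    abundance_exponent: float = 1.8
    min_copies: int = 1
    divergence: float = 0.02
    per_copy_divergence: float = 0.02
    unit_length: int = 300
    copy_jitter_sd: float = 0.3
    error_rate: float = 0.005
    inheritance_mode: str = "additive"
    bias_rho: float = 1.0
    bias_parent: str = "paternal"
    size_threshold: int = 0
    size_factor: float = 1.0
    # prep
    min_phred: int = 10
    max_n: int = 3
    read_length: int = 91
    proportion: float = 0.02
    # clustering
    k: int = 17
    min_identity: float = 0.90
    min_coverage: float = 0.55
    split_min_size: int = 100
    # filtering
    contaminants: str | None = None
    min_reads: int = 10
    require_all_species: bool = False

    def __post_init__(self) -> None:
        self.design  # validates role codes are distinct
        if not self.simulate:
            missing = [
                name
                for name, p in (
                    ("maternal_fastq", self.maternal_fastq),
                    ("paternal_fastq", self.paternal_fastq),
                    ("tetraploid_fastq", self.tetraploid_fastq),
                )
                if p is None
            ]
            if missing:
                raise ValueError(f"simulate=false requires FASTQ paths: {missing}")
        if not 0 < self.proportion <= 1:
            raise ValueError("proportion must be in (0, 1]")

    @property
    def design(self) -> CrossDesign:
        return CrossDesign(
            maternal_code=self.maternal_code,
            paternal_code=self.paternal_code,
            tetraploid_code=self.tetraploid_code,
        )

    @property
    def inheritance(self) -> InheritanceModel:
        return InheritanceModel(
            mode=self.inheritance_mode,
            bias_rho=self.bias_rho,
            bias_parent=self.bias_parent,
            size_threshold=self.size_threshold,
            size_factor=self.size_factor,
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def stage_seeds(seed: int) -> dict[str, int]:
    """Split the global seed into one sub-2^31 integer seed per stage."""
    state = np.random.SeedSequence(seed).generate_state(len(STAGES), dtype=np.uint32)
    return {stage: int(s & 0x7FFFFFFF) for stage, s in zip(STAGES, state)}


def demo_config(outdir, seed: int = 1) -> PipelineConfig:
    """The packaged additive demo scenario (small, runs in seconds)."""
    return PipelineConfig(
        outdir=str(outdir),
        seed=seed,
        simulate=True,
        n_families=8,
        maternal_c_value_bp=400_000,
        paternal_c_value_bp=400_000,
        abundance_exponent=2.5,
        min_copies=200,
        # satellite-like families whose monomer equals the read length:
        # every same-family read pair is globally alignable, so the demo's
        # cluster recovery does not depend on chained partial overlaps
        unit_length=91,
        divergence=0.02,
        per_copy_divergence=0.02,
        copy_jitter_sd=0.3,
        error_rate=0.005,
        proportion=0.06,
        inheritance_mode="additive",
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    design = config.design
    manifest: dict = {
        "polyrep_version": __version__,
        "config": config.to_dict(),
        "stage_seeds": seeds,
        "stages": {},
    }
    results: dict = {}

    def run_stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            (outdir / "FAILED").write_text(f"{name}: {exc}\n")
            raise PipelineError(name, exc) from exc

    # ---- simulate -------------------------------------------------------
    def _simulate():
        if not config.simulate:
            return None
        mat, pat = simulate_parents(
            n_families=config.n_families,
            abundance_exponent=config.abundance_exponent,
            divergence=config.divergence,
            c_value_bp=config.maternal_c_value_bp,
            seed=seeds["simulate"],
            unit_length=config.unit_length,
            copy_jitter_sd=config.copy_jitter_sd,
            per_copy_divergence=config.per_copy_divergence,
            min_copies=config.min_copies,
            species_codes=(config.maternal_code, config.paternal_code),
        )
        tet = apply_inheritance(
            mat, pat, config.inheritance, species_code=config.tetraploid_code
        )
        sim_proportion = min(1.0, config.proportion * SIMULATE_OVERSAMPLE)
        raws = {}
        for i, genome in enumerate((mat, pat, tet)):
            rs = generate_reads(
                genome,
                proportion=sim_proportion,
                read_length=config.read_length,
                error_rate=config.error_rate,
                seed=seeds["simulate"] + i + 1,
            )
            write_fastq(rs, outdir / f"{genome.species_code}.sim.fastq")
            write_truth_tsv(rs, outdir / f"{genome.species_code}.truth.tsv")
            raws[genome.species_code] = rs
        manifest["stages"]["simulate"] = {
            "n_reads": {code: len(rs) for code, rs in raws.items()},
            "tetraploid_c_value_bp": tet.c_value_bp,
        }
        results["genomes"] = {"maternal": mat, "paternal": pat, "tetraploid": tet}
        return raws

    raws = run_stage("simulate", _simulate)

    # ---- prep -----------------------------------------------------------
    def _prep():
        if config.simulate:
            inputs = {
                "maternal": raws[config.maternal_code],
                "paternal": raws[config.paternal_code],
                "tetraploid": raws[config.tetraploid_code],
            }
            c_values = {
                role: g.c_value_bp for role, g in results["genomes"].items()
            }
        else:
            inputs = {
                "maternal": read_fastq(config.maternal_fastq),
                "paternal": read_fastq(config.paternal_fastq),
                "tetraploid": read_fastq(config.tetraploid_fastq),
            }
            c_values = {
                "maternal": config.maternal_c_value_bp,
                "paternal": config.paternal_c_value_bp,
                "tetraploid": config.tetraploid_c_value_bp
                or (config.maternal_c_value_bp + config.paternal_c_value_bp),
            }
        codes = {
            "maternal": config.maternal_code,
            "paternal": config.paternal_code,
            "tetraploid": config.tetraploid_code,
        }
        prepped = {}
        counts = {}
        for i, (role, rs) in enumerate(inputs.items()):
            pp = preprocess_reads(
                rs,
                min_phred=config.min_phred,
                max_n=config.max_n,
                target_length=config.read_length,
            )
            sub = subsample_reads(
                pp,
                c_value_bp=c_values[role],
                proportion=config.proportion,
                seed=seeds["prep"] + i,
            )
            tagged = tag_species(sub, codes[role])
            write_fastq(tagged, outdir / f"{codes[role]}.prepped.fastq")
            prepped[role] = tagged
            counts[codes[role]] = {
                "raw": len(rs),
                "filtered": len(pp),
                "subsampled": len(sub),
            }
        manifest["stages"]["prep"] = counts
        results["c_values"] = c_values
        return prepped

    prepped = run_stage("prep", _prep)

    # ---- cluster --------------------------------------------------------
    def _cluster():
        pooled = pool_readsets(*prepped.values())
        table = cluster_reads(
            pooled,
            species_codes=design.codes,
            seed=seeds["cluster"],
            k=config.k,
            min_identity=config.min_identity,
            min_coverage=config.min_coverage,
            split_min_size=config.split_min_size,
        )
        table.write_tsv(outdir / "clusters.tsv")
        table.write_membership_tsv(outdir / "membership.tsv")
        manifest["stages"]["cluster"] = {
            "n_reads_pooled": len(pooled),
            "n_clusters": len(table),
            "n_clustered_reads": sum(c.total for c in table),
        }
        results["pooled"] = pooled
        return table

    table = run_stage("cluster", _cluster)

    # ---- filter ---------------------------------------------------------
    def _filter():
        flagged = flag_contaminants(
            table, results["pooled"], contaminant_refs=config.contaminants, k=config.k
        )
        fr = apply_filters(
            flagged,
            design,
            min_reads=config.min_reads,
            require_all_species=config.require_all_species,
        )
        fr.retained.write_tsv(outdir / "clusters.filtered.tsv")
        manifest["stages"]["filter"] = {
            "n_retained": len(fr.retained),
            "n_curve": len(fr.curve),
            "removed": {cid: reason for cid, reason in fr.removed},
        }
        return fr

    fr = run_stage("filter", _filter)

    # ---- additivity -----------------------------------------------------
    def _additivity():
        records = deviation_table(fr.curve, design)
        curve = cumulative_curve(records) if records else None
        if curve is not None:
            curve.write_tsv(outdir / "deviation.tsv")
        gsd = None
        if "c_values" in results:
            cv = results["c_values"]
            expected = cv["maternal"] + cv["paternal"]
            gsd = genome_size_deviation(cv["tetraploid"], expected)
        manifest["stages"]["additivity"] = {
            "n_records": len(records),
            "total_expected": int(sum(r.E for r in records)),
            "total_deviation": int(sum(r.D for r in records)),
            "genome_size_deviation_pct": gsd,
        }
        results["curve"] = curve
        results["records"] = records
        return records

    records = run_stage("additivity", _additivity)

    # ---- bias -----------------------------------------------------------
    def _bias():
        regression_records = deviation_table(fr.retained, design)
        report: dict = {
            "n_clusters_curve": len(records),
            "n_clusters_regression": len(regression_records),
            "error_pooling": "stacked model (pooled residual variance)",
        }
        for parent in ("maternal", "paternal"):
            try:
                fit = fit_parent_regression(
                    regression_records, parent, min_count=config.min_reads
                )
                report[f"{parent}_fit"] = fit.to_dict()
            except ValueError as exc:
                logger.warning("%s regression skipped: %s", parent, exc)
                report[f"{parent}_fit"] = {"error": str(exc)}
        try:
            st = slope_equality_test(
                regression_records, design, min_count=config.min_reads
            )
            report["slope_test"] = st.to_dict()
        except ValueError as exc:
            logger.warning("slope test skipped: %s", exc)
            report["slope_test"] = {"error": str(exc)}
        try:
            plane = fit_joint_plane(regression_records, min_count=config.min_reads)
            report["plane_fit"] = plane.to_dict()
        except ValueError as exc:
            logger.warning("plane fit skipped: %s", exc)
            report["plane_fit"] = {"error": str(exc)}
        n_usable = sum(
            1
            for r in regression_records
            if min(r.m, r.p, r.t) >= config.min_reads
        )
        report["excluded_from_slope_test"] = len(regression_records) - n_usable
        report["genome_size_deviation_pct"] = manifest["stages"]["additivity"][
            "genome_size_deviation_pct"
        ]
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        manifest["stages"]["bias"] = {
            "slope_test_p": report["slope_test"].get("p_value"),
            "n_usable": n_usable,
        }
        results["report"] = report
        results["regression_records"] = regression_records
        return report

    report = run_stage("bias", _bias)

    write_figures(results, outdir)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# figures
# ---------------------------------------------------------------------------


def write_figures(results: dict, outdir) -> list[str]:
    """Write the three standard figures; skip (with a warning) what lacks data."""
    outdir = Path(outdir)
    written = []
    curve: DeviationCurve | None = results.get("curve")
    if curve is not None and len(curve.records) > 0:
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(curve.ln_cum_E, curve.cum_D, marker="o", ms=3, label="signed")
        ax.plot(
            curve.ln_cum_E, curve.abs_cum_D, ls="--", alpha=0.6, label="absolute"
        )
        ax.axhline(0, color="grey", lw=0.5)
        ax.set_xlabel("ln cumulative expected cluster size")
        ax.set_ylabel("cumulative deviation from expectation (reads)")
        ax.legend(frameon=False)
        fig.tight_layout()
        fig.savefig(outdir / "fig2_deviation.png", dpi=150)
        plt.close(fig)
        written.append("fig2_deviation.png")
    else:
        logger.warning("no deviation curve: skipping fig2")

    recs = results.get("regression_records") or []
    report = results.get("report") or {}
    usable = [r for r in recs if min(r.m, r.p, r.t) >= 1]
    if (
        usable
        and "slope" in report.get("maternal_fit", {})
        and "slope" in report.get("paternal_fit", {})
    ):
        fig, ax = plt.subplots(figsize=(6, 4))
        for parent, color in (("maternal", "tab:blue"), ("paternal", "tab:red")):
            xs = np.log(
                [r.m if parent == "maternal" else r.p for r in usable if (r.m if parent == "maternal" else r.p) > 0 and r.t > 0]
            )
            ys = np.log(
                [r.t for r in usable if (r.m if parent == "maternal" else r.p) > 0 and r.t > 0]
            )
            ax.scatter(xs, ys, s=12, alpha=0.6, color=color, label=parent)
            f = report[f"{parent}_fit"]
            grid = np.linspace(xs.min(), xs.max(), 20)
            ax.plot(grid, f["intercept"] + f["slope"] * grid, color=color)
        ax.set_xlabel("ln parental cluster size (reads)")
        ax.set_ylabel("ln tetraploid cluster size (reads)")
        ax.legend(frameon=False)
        fig.tight_layout()
        fig.savefig(outdir / "fig3_regressions.png", dpi=150)
        plt.close(fig)
        written.append("fig3_regressions.png")
    else:
        logger.warning("no usable regressions: skipping fig3")

    if usable and "slope_maternal" in report.get("plane_fit", {}):
        pf = report["plane_fit"]
        pts = [r for r in usable if min(r.m, r.p, r.t) > 0]
        lm = np.log([r.m for r in pts])
        lp = np.log([r.p for r in pts])
        lt = np.log([r.t for r in pts])
        fig = plt.figure(figsize=(6, 5))
        ax = fig.add_subplot(111, projection="3d")
        ax.scatter(lm, lp, lt, c=lt, cmap="coolwarm", s=15)
        gm, gp = np.meshgrid(
            np.linspace(lm.min(), lm.max(), 8), np.linspace(lp.min(), lp.max(), 8)
        )
        ax.plot_surface(
            gm,
            gp,
            pf["intercept"] + pf["slope_maternal"] * gm + pf["slope_paternal"] * gp,
            alpha=0.25,
            color="grey",
        )
        ax.set_xlabel("ln maternal")
        ax.set_ylabel("ln paternal")
        ax.set_zlabel("ln tetraploid")
        fig.tight_layout()
        fig.savefig(outdir / "fig4_plane.png", dpi=150)
        plt.close(fig)
        written.append("fig4_plane.png")
    else:
        logger.warning("no plane fit: skipping fig4")
    return written
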