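"""Synthetic repeatomes and reads with known ground truth.

Emulates the study system: two diploid progenitor relatives (maternal and
paternal) whose genomes are composed of shared repeat families with
heavy-tailed copy-number distributions plus single-copy background, and an
allotetraploid whose per-family abundance follows a configurable inheritance
model:

* ``additive`` — the strict null: the tetraploid carries the sum of the two
  parental copy numbers for every family (a young, faithfully additive
  polyploid);
* ``parent_bias`` — one parent's contribution is multiplied by ``bias_rho``
  (the nuclear-cytoplasmic-interaction expectation of paternal degradation
  corresponds to ``bias_rho < 1`` on the paternal side);
* ``size_dependent`` — families above a combined copy-number threshold are
  amplified or deleted by ``size_factor`` (genome upsizing for factor > 1,
  downsizing for factor < 1), emulating the preferential turnover of
  high-copy repeats in older polyploids.

Two tiers of generator are provided. ``generate_reads`` produces actual
uniform-length reads (FASTQ plus a truth table mapping read to source
family), exercising the whole pipeline including graph clustering.
``simulate_cluster_counts`` skips the sequence layer and draws per-family
read counts multinomially, which is what the statistical properties of the
deviation curves and regressions depend on; it makes thousand-replicate
experiments cheap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .prep import Read, ReadSet, SPECIES_CODE_RE, round_half_away

logger = logging.getLogger(__name__)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_UNIT_LENGTH = 300
DEFAULT_COPY_JITTER_SD = 0.3
DEFAULT_QUALITY = 35  # placeholder Phred for simulated bases


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class RepeatFamily:
    """One repeat family: a consensus monomer and its genomic copy number.

    ``per_copy_divergence`` is the per-base substitution probability of an
    individual genomic copy relative to the consensus; it models the
    intragenomic heterogeneity of a repeat family.
    """

    family_id: str
    consensus: str
    copies_per_1C: int
    per_copy_divergence: float = 0.0

    def __post_init__(self) -> None:
        if set(self.consensus) - set("ACGT"):
            raise ValueError(f"family {self.family_id}: consensus must be A/C/G/T")
        if self.copies_per_1C < 0:
            raise ValueError(f"family {self.family_id}: negative copy number")
        if not 0.0 <= self.per_copy_divergence <= 0.3:
            raise ValueError(
                f"family {self.family_id}: per_copy_divergence outside [0, 0.3]"
            )

    @property
    def unit_length(self) -> int:
        return len(self.consensus)

    @property
    def genomic_bp(self) -> int:
        return self.copies_per_1C * self.unit_length


@dataclass
class GenomeSpec:
    """A simulated 1C genome: repeat families plus single-copy background."""

    species_code: str
    c_value_bp: int
    families: list[RepeatFamily] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not SPECIES_CODE_RE.match(self.species_code):
            raise ValueError(
                f"species code must be exactly 5 letters, got {self.species_code!r}"
            )
        if self.c_value_bp <= 0:
            raise ValueError("c_value_bp must be positive")
        if self.repeat_bp > self.c_value_bp:
            raise ValueError(
                f"{self.species_code}: repeat content {self.repeat_bp} bp exceeds "
                f"1C size {self.c_value_bp} bp"
            )

    @property
    def repeat_bp(self) -> int:
        return sum(f.genomic_bp for f in self.families)

    @property
    def single_copy_fraction(self) -> float:
        return 1.0 - self.repeat_bp / self.c_value_bp

    def family(self, family_id: str) -> RepeatFamily:
        for f in self.families:
            if f.family_id == family_id:
                return f
        raise KeyError(family_id)


@dataclass
class InheritanceModel:
    """How per-family abundance passes from the parents to the tetraploid."""

    mode: str = "additive"  # additive | parent_bias | size_dependent
    bias_rho: float = 1.0
    bias_parent: str = "paternal"  # which parent the multiplier applies to
    size_threshold: int = 0
    size_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in {"additive", "parent_bias", "size_dependent"}:
            raise ValueError(f"unknown inheritance mode {self.mode!r}")
        if self.bias_rho < 0 or self.size_factor < 0:
            raise ValueError("inheritance multipliers must be non-negative")
        if self.bias_parent not in {"maternal", "paternal"}:
            raise ValueError("bias_parent must be 'maternal' or 'paternal'")

    def combine(self, m: int, p: int) -> int:
        """Tetraploid copy number for one family with parental copies (m, p)."""
        if self.mode == "additive":
            return m + p
        if self.mode == "parent_bias":
            if self.bias_parent == "paternal":
                return round_half_away(m + self.bias_rho * p)
            return round_half_away(self.bias_rho * m + p)
        # size_dependent: amplify/delete only above the combined-size cutoff
        total = m + p
        if total >= self.size_threshold:
            return round_half_away(self.size_factor * total)
        return total


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------


def random_dna(rng: np.random.Generator, length: int) -> str:
    return BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each base independently with probability ``rate``."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    if hits.size:
        # replace with one of the three other bases, uniformly
        offsets = rng.integers(1, 4, size=hits.size)
        idx = np.searchsorted(BASES, arr[hits])
        arr[hits] = BASES[(idx + offsets) % 4]
    return arr.tobytes().decode()


def bounded_powerlaw(
    rng: np.random.Generator, n: int, exponent: float, k_max: int, k_min: int = 1
) -> np.ndarray:
    """Draw integer copy numbers from a power law on [k_min, k_max].

    Continuous inverse-CDF sampling of density ∝ x^(-exponent) on
    [k_min, k_max + 1), floored to integers; avoids materializing the
    support. A ``k_min`` above 1 restricts the simulation to families in
    the detectable abundance range.
    """
    if exponent <= 1:
        raise ValueError("abundance_exponent must be > 1")
    if not 1 <= k_min <= k_max:
        raise ValueError("need 1 <= k_min <= k_max")
    u = rng.random(n)
    b = 1.0 - exponent
    lo = float(k_min) ** b
    hi = float(k_max + 1) ** b
    x = (lo + u * (hi - lo)) ** (1.0 / b)
    return np.minimum(np.floor(x).astype(int), k_max)


def discrete_powerlaw(
    rng: np.random.Generator, n: int, exponent: float, k_max: int
) -> np.ndarray:
    """Draw from the exact discrete power law P(k) ∝ k^(-exponent) on [1, k_max].

    Materializes the normalized pmf, so it is meant for moderate supports
    (the count-level scenarios); :func:`bounded_powerlaw` is the
    constant-memory approximation used for genome-scale supports.
    """
    if exponent <= 1:
        raise ValueError("abundance_exponent must be > 1")
    ks = np.arange(1, k_max + 1, dtype=float)
    pmf = ks ** (-exponent)
    pmf /= pmf.sum()
    return rng.choice(np.arange(1, k_max + 1), size=n, p=pmf)


# ---------------------------------------------------------------------------
# genome simulation
# ---------------------------------------------------------------------------


def simulate_parents(
    n_families: int,
    abundance_exponent: float,
    divergence: float,
    c_value_bp: int,
    seed: int,
    unit_length: int = DEFAULT_UNIT_LENGTH,
    copy_jitter_sd: float = DEFAULT_COPY_JITTER_SD,
    per_copy_divergence: float = 0.02,
    min_copies: int = 1,
    species_codes: tuple[str, str] = ("MATER", "PATER"),
) -> tuple[GenomeSpec, GenomeSpec]:
    """Simulate the two diploid progenitor genomes.

    Copy numbers per family are drawn once from a bounded power law (support
    [1, c_value_bp // unit_length]) and then perturbed independently per
    parent with lognormal noise of sd ``copy_jitter_sd``, modelling repeat
    turnover along the two lineages since their split. Consensus sequences
    are mutated at ``divergence / 2`` per lineage so that the expected
    pairwise divergence between homologous family consensi is ``divergence``.
    With ``copy_jitter_sd=0`` and ``divergence=0`` the parents are identical.

    If the drawn repeat content would exceed the 1C size, copy numbers are
    rescaled proportionally (logged), never silently overflowed.
    """
    if not 0.0 <= divergence <= 0.3:
        raise ValueError("divergence must be in [0, 0.3]")
    rng = np.random.default_rng(seed)
    k_max = max(1, c_value_bp // unit_length)
    base = (
        bounded_powerlaw(rng, n_families, abundance_exponent, k_max, k_min=min_copies)
        if n_families
        else np.array([], dtype=int)
    )
    ancestral = [random_dna(rng, unit_length) for _ in range(n_families)]

    genomes = []
    for code in species_codes:
        if copy_jitter_sd > 0:
            jitter = np.exp(rng.normal(0.0, copy_jitter_sd, size=n_families))
        else:
            jitter = np.ones(n_families)
        copies = np.maximum(1, np.vectorize(round_half_away)(base * jitter)) if n_families else base
        total_bp = int(copies.sum()) * unit_length if n_families else 0
        if total_bp > c_value_bp:
            scale = c_value_bp / total_bp
            logger.warning(
                "%s: repeat content %d bp exceeds 1C %d bp; rescaling copy "
                "numbers by %.3f",
                code,
                total_bp,
                c_value_bp,
                scale,
            )
            copies = np.maximum(1, np.floor(copies * scale).astype(int))
        families = [
            RepeatFamily(
                family_id=f"fam{i:03d}",
                consensus=mutate(ancestral[i], divergence / 2.0, rng),
                copies_per_1C=int(copies[i]),
                per_copy_divergence=per_copy_divergence,
            )
            for i in range(n_families)
        ]
        genomes.append(GenomeSpec(species_code=code, c_value_bp=c_value_bp, families=families))
    return genomes[0], genomes[1]


def planted_genomes(
    copy_numbers: dict[str, int],
    c_value_bp: int,
    seed: int,
    unit_length: int = DEFAULT_UNIT_LENGTH,
    within_family_divergence: float = 0.05,
    between_parent_divergence: float = 0.02,
    species_codes: tuple[str, str] = ("MATER", "PATER"),
) -> tuple[GenomeSpec, GenomeSpec]:
    """Build a pair of parental genomes with explicitly planted families.

    Family consensi are independent random sequences, so between-family
    divergence is ~75% while two copies of the same family differ by only
    ``within_family_divergence`` pairwise (each copy is mutated at half that
    rate relative to the consensus) — the separation cluster-recovery tests
    rely on. ``between_parent_divergence`` is likewise the pairwise rate
    between the two parents' homologous consensi. With the default
    ``unit_length`` of 300 bp, reads are random windows of the monomer and
    same-family reads connect through chains of near-offset neighbours; for
    unambiguous single-clique families use ``unit_length`` equal to the read
    length.
    """
    rng = np.random.default_rng(seed)
    ancestral = {fid: random_dna(rng, unit_length) for fid in copy_numbers}
    out = []
    for code in species_codes:
        families = [
            RepeatFamily(
                family_id=fid,
                consensus=mutate(ancestral[fid], between_parent_divergence / 2.0, rng),
                copies_per_1C=copies,
                per_copy_divergence=within_family_divergence / 2.0,
            )
            for fid, copies in copy_numbers.items()
        ]
        out.append(GenomeSpec(species_code=code, c_value_bp=c_value_bp, families=families))
    return out[0], out[1]


def apply_inheritance(
    maternal: GenomeSpec,
    paternal: GenomeSpec,
    model: InheritanceModel,
    species_code: str = "TETRA",
) -> GenomeSpec:
    """Derive the allotetraploid genome from the two parents.

    Family namespaces are unioned; a family absent from one parent
    contributes 0 copies. The tetraploid 1C value is recomputed as the sum
    of the parental 1C values adjusted by the net repeat-content change, so
    that amplification/deletion moves genome size the way it moves repeat
    abundance. The merged family keeps the maternal consensus where the
    family exists in the maternal parent (the two parental variants lie
    within the per-copy divergence envelope).
    """
    mat = {f.family_id: f for f in maternal.families}
    pat = {f.family_id: f for f in paternal.families}
    all_ids = sorted(set(mat) | set(pat))
    families = []
    additive_bp = 0
    actual_bp = 0
    for fid in all_ids:
        fm, fp = mat.get(fid), pat.get(fid)
        if fm is not None and fp is not None and fm.unit_length != fp.unit_length:
            raise ValueError(
                f"family {fid}: unit length differs between parents "
                f"({fm.unit_length} vs {fp.unit_length})"
            )
        ref = fm if fm is not None else fp
        m = fm.copies_per_1C if fm is not None else 0
        p = fp.copies_per_1C if fp is not None else 0
        t = model.combine(m, p)
        additive_bp += (m + p) * ref.unit_length
        actual_bp += t * ref.unit_length
        families.append(
            RepeatFamily(
                family_id=fid,
                consensus=ref.consensus,
                copies_per_1C=t,
                per_copy_divergence=ref.per_copy_divergence,
            )
        )
    c_value = maternal.c_value_bp + paternal.c_value_bp + (actual_bp - additive_bp)
    return GenomeSpec(species_code=species_code, c_value_bp=c_value, families=families)


# ---------------------------------------------------------------------------
# read generation
# ---------------------------------------------------------------------------


def generate_reads(
    genome: GenomeSpec,
    proportion: float,
    read_length: int,
    error_rate: float,
    seed: int,
    quality: int = DEFAULT_QUALITY,
) -> ReadSet:
    """Sample uniform-length reads from a simulated genome.

    The read number is ``round(proportion * c_value_bp / read_length)``.
    Each read is drawn from a repeat family with probability proportional to
    the family's genomic bp, or from single-copy background for the
    remainder. A family read is a window of the consensus, first mutated at
    the family's per-copy divergence (sampling a diverged genomic copy) and
    then at the sequencing ``error_rate``; reads never span copy junctions.
    Background reads are unique random sequence. True source families are
    recorded in ``ReadSet.provenance`` (None for background).
    """
    if not 0.0 < proportion <= 1.0:
        raise ValueError("proportion must be in (0, 1]")
    n = round_half_away(proportion * genome.c_value_bp / read_length)
    if n < 1:
        raise ValueError(
            f"proportion {proportion} of {genome.c_value_bp} bp yields less than "
            f"one {read_length} bp read"
        )
    for f in genome.families:
        if f.unit_length < read_length:
            raise ValueError(
                f"family {f.family_id}: unit length {f.unit_length} shorter than "
                f"read length {read_length}"
            )
    rng = np.random.default_rng(seed)
    weights = np.array([f.genomic_bp for f in genome.families] + [0.0], dtype=float)
    weights[-1] = genome.c_value_bp - genome.repeat_bp  # background
    probs = weights / weights.sum()
    sources = rng.choice(len(weights), size=n, p=probs)

    sequences: list[str | None] = [None] * n
    for s_idx in range(len(weights)):
        positions = np.nonzero(sources == s_idx)[0]
        if positions.size == 0:
            continue
        if s_idx < len(genome.families):
            fam = genome.families[s_idx]
            cons = np.frombuffer(fam.consensus.encode(), dtype=np.uint8)
            starts = rng.integers(0, fam.unit_length - read_length + 1, size=positions.size)
            windows = cons[starts[:, None] + np.arange(read_length)[None, :]].copy()
            total_rate = fam.per_copy_divergence + error_rate
            if total_rate > 0:
                hits = rng.random(windows.shape) < total_rate
                offsets = rng.integers(1, 4, size=windows.shape)
                idx = np.searchsorted(BASES, windows)
                windows = np.where(hits, BASES[(idx + offsets) % 4], windows)
        else:
            windows = BASES[rng.integers(0, 4, size=(positions.size, read_length))]
        for row, pos in enumerate(positions):
            sequences[pos] = windows[row].tobytes().decode()

    quals = tuple([quality] * read_length)
    reads = []
    provenance: dict[str, str | None] = {}
    for i in range(n):
        rid = f"r{i:06d}"
        reads.append(Read(read_id=rid, sequence=sequences[i], qualities=quals))
        src = sources[i]
        provenance[rid] = (
            genome.families[src].family_id if src < len(genome.families) else None
        )
    return ReadSet(
        reads=reads,
        species_code=genome.species_code,
        read_length=read_length,
        provenance=provenance,
    )


def write_truth_tsv(rs: ReadSet, path) -> None:
    """Write the read → source-family truth table (TSV)."""
    df = pd.DataFrame(
        {
            "read_id": [r.read_id for r in rs.reads],
            "species_code": rs.species_code,
            "family_id": [
                rs.provenance.get(r.read_id) or "background" for r in rs.reads
            ],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# count-level scenarios (cluster tables without the sequence layer)
# ---------------------------------------------------------------------------


def simulate_cluster_counts(
    n_clusters: int,
    seed: int,
    reads_per_parent: int = 20_000,
    abundance_exponent: float = 1.8,
    max_copies: int = 5_000,
    divergence_sd: float = DEFAULT_COPY_JITTER_SD,
    shared_base: bool = True,
    inheritance: InheritanceModel | None = None,
) -> pd.DataFrame:
    """Simulate a per-cluster read-count table directly.

    True family abundances are power-law distributed; with
    ``shared_base=True`` the two parents perturb one shared draw with
    lognormal noise of sd ``divergence_sd`` (closely related progenitors),
    otherwise each parent draws independently (long-diverged progenitors).
    The tetraploid's true abundance follows ``inheritance`` (additive by
    default). Observed counts are multinomial at fixed genome proportion:
    ``reads_per_parent`` reads for each diploid, and proportionally more for
    the tetraploid in line with its larger genome.

    Returns a DataFrame with columns m, p, t (observed counts) and the true
    abundances m_true, p_true, t_true.
    """
    inheritance = inheritance or InheritanceModel(mode="additive")
    rng = np.random.default_rng(seed)
    if shared_base:
        base = discrete_powerlaw(rng, n_clusters, abundance_exponent, max_copies).astype(float)
        m = base * np.exp(rng.normal(0.0, divergence_sd, n_clusters))
        p = base * np.exp(rng.normal(0.0, divergence_sd, n_clusters))
    else:
        m = discrete_powerlaw(rng, n_clusters, abundance_exponent, max_copies).astype(float)
        p = discrete_powerlaw(rng, n_clusters, abundance_exponent, max_copies).astype(float)
    t = np.array(
        [float(inheritance.combine(mi, pi)) for mi, pi in zip(m, p)]
    )
    cm = rng.multinomial(reads_per_parent, m / m.sum())
    cp = rng.multinomial(reads_per_parent, p / p.sum())
    # same genome proportion => reads scale with genome (here: repeat) size
    n_t = int(round(reads_per_parent * t.sum() / ((m.sum() + p.sum()) / 2.0)))
    ct = rng.multinomial(n_t, t / t.sum())
    return pd.DataFrame(
        {"m": cm, "p": cp, "t": ct, "m_true": m, "p_true": p, "t_true": t}
    )


def additive_null_scenario(seed: int, n_clusters: int = 100) -> pd.DataFrame:
    """Standard additive scenario: a young polyploid of closely related parents.

    Shared power-law base (exponent 1.8, support [1, 5000]), lineage
    divergence sd 0.3, 20,000 reads per diploid.
    """
    return simulate_cluster_counts(
        n_clusters=n_clusters,
        seed=seed,
        reads_per_parent=20_000,
        abundance_exponent=1.8,
        divergence_sd=0.3,
        shared_base=True,
        inheritance=InheritanceModel(mode="additive"),
    )


def biased_scenario(
    seed: int, bias_rho: float = 0.5, n_clusters: int = 200
) -> pd.DataFrame:
    """Standard parental-bias scenario: long-diverged parents, paternal bias.

    Independent parental abundances (exponent 2.0), 50,000 reads per
    diploid. With weakly correlated parents a multiplicative bias bends the
    two parental regression slopes apart (with strongly correlated parents
    it only shifts the intercept and is invisible to a slope test).
    """
    return simulate_cluster_counts(
        n_clusters=n_clusters,
        seed=seed,
        reads_per_parent=50_000,
        abundance_exponent=2.0,
        shared_base=False,
        inheritance=InheritanceModel(mode="parent_bias", bias_rho=bias_rho),
    )
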