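"""Synthetic repeatome and read generator: formulas, determinism, sampling."""

import numpy as np
import pytest
from scipy import stats

from polyrep import (
    GenomeSpec,
    InheritanceModel,
    RepeatFamily,
    apply_inheritance,
    bounded_powerlaw,
    generate_reads,
    planted_genomes,
    simulate_parents,
)
from polyrep.prep import read_fastq, write_fastq


def _genome(copy_numbers, c_value_bp, code="MATER", unit=300, div=0.0, seed=0):
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    fams = [
        RepeatFamily(
            family_id=f"fam{i:03d}",
            consensus="".join(rng.choice(bases, unit)),
            copies_per_1C=c,
            per_copy_divergence=div,
        )
        for i, c in enumerate(copy_numbers)
    ]
    return GenomeSpec(species_code=code, c_value_bp=c_value_bp, families=fams)


class TestInheritance:
    @pytest.mark.parametrize(
        "model,m,p,expected",
        [
            (InheritanceModel("additive"), 100, 50, 150),
            (InheritanceModel("parent_bias", bias_rho=0.5), 100, 50, 125),
            (InheritanceModel("parent_bias", bias_rho=0.5, bias_parent="maternal"), 100, 50, 100),
            (InheritanceModel("parent_bias", bias_rho=0.0), 100, 50, 100),
            (InheritanceModel("size_dependent", size_threshold=1000, size_factor=2.0), 100, 50, 150),
            (InheritanceModel("size_dependent", size_threshold=100, size_factor=2.0), 100, 50, 300),
        ],
    )
    def test_combine_formulas(self, model, m, p, expected):
        assert model.combine(m, p) == expected

    def test_size_dependent_matches_per_family_hand_rule(self):
        """Brute-force re-application of the size rule on a 5-family genome."""
        m_copies = [1500, 800, 400, 90, 10]
        p_copies = [700, 900, 300, 30, 5]
        mat = _genome(m_copies, 10_000_000, "MATER")
        pat = _genome(p_copies, 10_000_000, "PATER")
        # paternal genome must share consensi with maternal for merging
        pat = GenomeSpec(
            "PATER",
            10_000_000,
            [
                RepeatFamily(f.family_id, f.consensus, c, f.per_copy_divergence)
                for f, c in zip(mat.families, p_copies)
            ],
        )
        model = InheritanceModel("size_dependent", size_threshold=1000, size_factor=2.0)
        tet = apply_inheritance(mat, pat, model)
        got = {f.family_id: f.copies_per_1C for f in tet.families}
        for f, m, p in zip(mat.families, m_copies, p_copies):
            total = m + p
            expected = int(np.floor(2.0 * total + 0.5)) if total >= 1000 else total
            assert got[f.family_id] == expected

    def test_additive_is_elementwise_sum_for_any_seed(self):
        for seed in (1, 2, 17):
            mat, pat = simulate_parents(12, 1.8, 0.05, 2_000_000, seed=seed)
            tet = apply_inheritance(mat, pat, InheritanceModel("additive"))
            for fm, fp, ft in zip(mat.families, pat.families, tet.families):
                assert ft.copies_per_1C == fm.copies_per_1C + fp.copies_per_1C
            assert tet.c_value_bp == mat.c_value_bp + pat.c_value_bp

    def test_mismatched_unit_length_rejected(self):
        mat = _genome([10], 100_000, "MATER", unit=300)
        pat = _genome([10], 100_000, "PATER", unit=200)
        with pytest.raises(ValueError, match="unit length"):
            apply_inheritance(mat, pat, InheritanceModel("additive"))


class TestSimulateParents:
    def test_no_divergence_no_jitter_gives_identical_parents(self):
        mat, pat = simulate_parents(
            8, 1.8, 0.0, 1_000_000, seed=5, copy_jitter_sd=0.0
        )
        for fm, fp in zip(mat.families, pat.families):
            assert fm.copies_per_1C == fp.copies_per_1C
            assert fm.consensus == fp.consensus

    def test_zero_families_gives_background_only_genome(self):
        mat, pat = simulate_parents(0, 1.8, 0.0, 1_000_000, seed=1)
        assert mat.families == [] and pat.families == []
        assert mat.single_copy_fraction == 1.0

    def test_repeat_content_never_exceeds_1C(self):
        """Direct summation over families, incl. a forced-rescale regime."""
        for seed in range(5):
            for c_value in (50_000, 2_000_000):
                mat, pat = simulate_parents(20, 1.2, 0.05, c_value, seed=seed)
                for g in (mat, pat):
                    total = sum(f.copies_per_1C * len(f.consensus) for f in g.families)
                    assert total <= g.c_value_bp

    def test_deterministic_for_fixed_seed(self):
        a = simulate_parents(6, 1.8, 0.05, 500_000, seed=9)
        b = simulate_parents(6, 1.8, 0.05, 500_000, seed=9)
        assert [f.consensus for f in a[0].families] == [f.consensus for f in b[0].families]
        assert [f.copies_per_1C for f in a[1].families] == [f.copies_per_1C for f in b[1].families]


class TestBoundedPowerlaw:
    def test_support_bounds(self, rng):
        draws = bounded_powerlaw(rng, 5000, 1.8, 123)
        assert draws.min() >= 1 and draws.max() <= 123

    def test_invalid_exponent(self, rng):
        with pytest.raises(ValueError):
            bounded_powerlaw(rng, 10, 1.0, 100)


class TestGenerateReads:
    def test_read_count_formula(self):
        g = _genome([100], 1_000_000)
        rs = generate_reads(g, proportion=0.02, read_length=91, error_rate=0.0, seed=1)
        assert len(rs) == 220  # round(0.02 * 1e6 / 91) = round(219.78)

    def test_error_free_family_reads_are_consensus_substrings(self):
        g = _genome([50, 30], 100_000, div=0.0)
        rs = generate_reads(g, proportion=0.2, read_length=91, error_rate=0.0, seed=3)
        consensi = {f.family_id: f.consensus for f in g.families}
        n_family_reads = 0
        for r in rs.reads:
            fam = rs.provenance[r.read_id]
            if fam is not None:
                assert r.sequence in consensi[fam]
                n_family_reads += 1
        assert n_family_reads > 0

    def test_fastq_round_trip_and_seed_determinism(self, tmp_path):
        g = _genome([40], 200_000)
        rs = generate_reads(g, proportion=0.05, read_length=91, error_rate=0.01, seed=7)
        f1, f2 = tmp_path / "a.fastq", tmp_path / "b.fastq"
        write_fastq(rs, f1)
        rs2 = generate_reads(g, proportion=0.05, read_length=91, error_rate=0.01, seed=7)
        write_fastq(rs2, f2)
        assert f1.read_bytes() == f2.read_bytes()
        back = read_fastq(f1)
        assert len(back) == len(rs)
        assert [r.sequence for r in back.reads] == [r.sequence for r in rs.reads]

    def test_too_small_proportion_rejected(self):
        g = _genome([10], 10_000)
        with pytest.raises(ValueError, match="less than"):
            generate_reads(g, proportion=0.001, read_length=91, error_rate=0.0, seed=1)

    def test_family_read_counts_are_multinomial(self):
        """Chi-square goodness of fit to expected source proportions.

        At alpha = 0.01 the test should fail to reject in >= 95 of 100 seeds.
        """
        g = _genome([2000, 1000, 500, 250], 1_500_000, div=0.0)
        sources = [f.family_id for f in g.families] + [None]
        expected_p = np.array(
            [f.genomic_bp for f in g.families] + [g.c_value_bp - g.repeat_bp],
            dtype=float,
        )
        expected_p /= expected_p.sum()
        n_reads = round(0.607 * g.c_value_bp / 91)
        assert n_reads >= 10_000
        ok = 0
        for seed in range(100):
            rs = generate_reads(g, proportion=0.607, read_length=91, error_rate=0.0, seed=seed)
            counts = {s: 0 for s in sources}
            for fam in rs.provenance.values():
                counts[fam] += 1
            obs = np.array([counts[s] for s in sources], dtype=float)
            _, p = stats.chisquare(obs, f_exp=expected_p * obs.sum())
            ok += p >= 0.01
        assert ok >= 95


class TestPlantedGenomes:
    def test_within_vs_between_family_divergence(self):
        mat, _ = planted_genomes(
            {"famA": 100, "famB": 100}, 200_000, seed=1, within_family_divergence=0.05
        )
        a, b = mat.families
        frac_diff = np.mean([x != y for x, y in zip(a.consensus, b.consensus)])
        assert frac_diff > 0.5  # unrelated random sequences
        # 5% pairwise divergence between copies = 2.5% of each copy vs consensus
        assert a.per_copy_divergence == 0.025
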