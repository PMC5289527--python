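"""Statistical kernels: Mann-Whitney, Fisher-Freeman-Halton, chi-square, and
the genotype-stratified clinical summary."""

import subprocess

import numpy as np
import pytest
from scipy import stats

from kdprio import (
    SimulationSpec,
    chi_square,
    fisher_freeman_halton,
    genotype_summary,
    mann_whitney,
    simulate_clinical,
)
from kdprio.clinical_assoc import enumerate_table_probabilities


class TestMannWhitney:
    def test_exact_small_sample_enumeration(self):
        """x={1,2}, y={3,4}: U=0 and two-sided p = 1/3 (2 of the 6 equally
        likely rank arrangements are as extreme)."""
        u, p = mann_whitney([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1 / 3)

    def test_identical_samples(self):
        u, p = mann_whitney([1, 2], [1, 2])
        assert u == 2.0  # n1*n2/2
        assert p == 1.0

    def test_asymptotic_regime_matches_hand_rolled_normal_approximation(self):
        """Tie-corrected normal approximation with continuity correction,
        written out from the textbook formula."""
        rng = np.random.default_rng(12)
        for _ in range(100):
            n1, n2 = rng.integers(13, 40, size=2)
            x = np.round(rng.normal(size=n1), 1)  # rounding induces ties
            y = np.round(rng.normal(size=n2), 1)
            u, p = mann_whitney(x, y)
            pooled = np.concatenate([x, y])
            ranks = stats.rankdata(pooled)
            u_hand = ranks[:n1].sum() - n1 * (n1 + 1) / 2
            assert u == pytest.approx(u_hand)
            n = n1 + n2
            mu = n1 * n2 / 2
            _, tie_counts = np.unique(pooled, return_counts=True)
            tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
            sd = np.sqrt(n1 * n2 / 12 * (n + 1 - tie_term))
            z = (abs(u_hand - mu) - 0.5) / sd
            p_hand = min(1.0, 2 * stats.norm.sf(z))
            assert abs(p - p_hand) < 1e-8

    def test_symmetry_and_monotone_invariance(self):
        rng = np.random.default_rng(13)
        x, y = rng.normal(size=9), rng.normal(size=7)
        _, p = mann_whitney(x, y)
        _, p_swap = mann_whitney(y, x)
        assert p == pytest.approx(p_swap)
        _, p_exp = mann_whitney(np.exp(x), np.exp(y))
        assert p == pytest.approx(p_exp)

    def test_empty_sample_fatal(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestFisherFreemanHalton:
    def test_printed_ethnicity_table(self, tables):
        p = fisher_freeman_halton(tables.ethnicity_table)
        assert round(p, 3) == 0.002

    def test_homogeneous_2x2(self):
        assert fisher_freeman_halton([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_reduces_to_classical_fisher_on_random_2x2(self):
        rng = np.random.default_rng(14)
        for _ in range(50):
            t = rng.integers(0, 15, size=(2, 2))
            if t.sum() == 0:
                continue
            ours = fisher_freeman_halton(t)
            _, ref = stats.fisher_exact(t, alternative="two-sided")
            assert ours == pytest.approx(ref, rel=1e-9)

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(15)
        for shape in ((2, 3), (3, 3), (3, 2)):
            t = rng.integers(0, 8, size=shape)
            t[0, 0] += 1  # ensure positive total
            assert sum(enumerate_table_probabilities(t)) == pytest.approx(1.0, abs=1e-9)

    def test_matches_r_fisher_test_on_rxc_table(self, tables):
        """Independent oracle: R's fisher.test on the 3x2 ethnicity table."""
        flat = ",".join(str(v) for row in tables.ethnicity_table for v in row)
        try:
            out = subprocess.run(
                ["Rscript", "-e",
                 f"cat(fisher.test(matrix(c({flat}), nrow=3, byrow=TRUE))$p.value)"],
                capture_output=True, text=True, timeout=120, check=True,
            )
        except (FileNotFoundError, subprocess.SubprocessError):
            pytest.skip("Rscript unavailable")
        p_r = float(out.stdout.strip())
        assert fisher_freeman_halton(tables.ethnicity_table) == pytest.approx(p_r, rel=1e-6)


class TestChiSquare:
    def test_observed_equals_expected(self):
        stat, df, p = chi_square([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0)
        assert df == 1
        assert p == pytest.approx(1.0)

    def test_random_tables_match_formula(self):
        rng = np.random.default_rng(16)
        for _ in range(30):
            t = rng.integers(1, 20, size=(3, 2))
            stat, df, p = chi_square(t)
            total = t.sum()
            expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / total
            assert stat == pytest.approx(((t - expected) ** 2 / expected).sum())
            assert df == (t.shape[0] - 1) * (t.shape[1] - 1)
            assert p == pytest.approx(stats.chi2.sf(stat, df))

    def test_zero_margin_fatal(self):
        with pytest.raises(ValueError):
            chi_square([[0, 0], [3, 4]])


class TestGenotypeSummary:
    CONTINUOUS = ["age_years", "esr", "crp"]
    CATEGORICAL = ["sex", "ethnicity"]

    def test_planted_esr_shift_recovered(self):
        """+20 mm/h ESR in hom-risk subjects: medians ordered and rank-test
        p < 0.05 in >=90% of seeded cohorts of 161."""
        n_rep, hits = 20, 0
        for seed in range(n_rep):
            df = simulate_clinical(SimulationSpec(seed=seed))
            rep = genotype_summary(df, self.CONTINUOUS, self.CATEGORICAL)
            ok_order = (
                rep["groups"]["hom_risk"]["esr"]["median"]
                > rep["groups"]["hom_nonrisk"]["esr"]["median"]
            )
            if ok_order and rep["tests"]["esr"]["p"] < 0.05:
                hits += 1
        assert hits >= 0.9 * n_rep

    def test_report_structure_and_ethnicity_test(self):
        df = simulate_clinical(SimulationSpec(seed=99))
        rep = genotype_summary(df, self.CONTINUOUS, self.CATEGORICAL)
        assert set(rep["groups"]) == {"hom_nonrisk", "het", "hom_risk"}
        for g in rep["groups"].values():
            assert "median" in g["esr"] and "iqr" in g["esr"]
        assert rep["tests"]["ethnicity:Asian_vs_other"]["test"] == "fisher_freeman_halton"
        assert 0 < rep["tests"]["ethnicity:Asian_vs_other"]["p"] <= 1

    def test_single_genotype_cohort_runs_no_tests(self):
        df = simulate_clinical(SimulationSpec(seed=1))
        df = df[df["genotype"] == 1]
        rep = genotype_summary(df, self.CONTINUOUS, self.CATEGORICAL)
        assert list(rep["groups"]) == ["het"]
        assert rep["tests"] == {}

    def test_constant_covariate_p_is_one(self):
        df = simulate_clinical(SimulationSpec(seed=2))
        df["crp"] = 5.0
        rep = genotype_summary(df, ["crp"], [])
        assert rep["tests"]["crp"]["p"] == 1.0
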