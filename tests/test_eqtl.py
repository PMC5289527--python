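"""Paired differential expression and the genotype-stratified eQTL scan."""

import math
from itertools import product

import numpy as np
import pandas as pd
import pytest

from kdprio import (
    ExpressionMatrix,
    SimulationSpec,
    eqtl_scan,
    paired_differential_expression,
    simulate_cohort_genotypes,
    simulate_expression,
)


def tiny_matrix(acute, conv, gene="G1"):
    """One-probe matrix from per-subject acute/convalescent abundances."""
    subjects = [f"S{i}" for i in range(len(acute))]
    cols, phases, subj = [], {}, {}
    data = []
    for i, s in enumerate(subjects):
        for phase, val in (("acute", acute[i]), ("convalescent", conv[i])):
            sid = f"{s}.{phase[0]}"
            cols.append(sid)
            phases[sid] = phase
            subj[sid] = s
            data.append(val)
    values = pd.DataFrame([data], index=["P1"], columns=cols)
    return ExpressionMatrix(values, {"P1": gene}, phases, subj)


class TestPairedDE:
    def test_no_change_gives_unit_fold_change_and_p_one(self):
        expr = tiny_matrix([4.0, 5.0, 6.0], [4.0, 5.0, 6.0])
        res = paired_differential_expression(expr)
        assert res.loc["G1", "fold_change"] == pytest.approx(1.0)
        assert res.loc["G1", "raw_p"] == 1.0

    def test_two_pair_signed_rank_matches_enumeration(self):
        """With two pairs, the exact signed-rank p equals enumeration over
        all 2^2 equally-likely sign assignments."""
        acute, conv = [8.0, 9.0], [2.0, 1.0]
        expr = tiny_matrix(acute, conv)
        res = paired_differential_expression(expr)
        diffs = [math.log2(a) - math.log2(c) for a, c in zip(acute, conv)]
        ranks = np.argsort(np.argsort(np.abs(diffs))) + 1
        w_obs = sum(r for d, r in zip(diffs, ranks) if d > 0)
        n = len(diffs)
        ws = [
            sum(r for s, r in zip(signs, ranks) if s > 0)
            for signs in product((-1, 1), repeat=n)
        ]
        total = sum(ranks)
        # two-sided: as or more extreme in either direction
        p_exact = sum(1 for w in ws if min(w, total - w) <= min(w_obs, total - w_obs)) / len(ws)
        assert res.loc["G1", "raw_p"] == pytest.approx(p_exact)

    def test_zero_abundance_fatal(self):
        expr = tiny_matrix([4.0, 0.0], [4.0, 1.0])
        with pytest.raises(ValueError, match="> 0"):
            paired_differential_expression(expr)

    def test_adjusted_p_dominates_raw(self):
        spec = SimulationSpec(seed=3, n_subjects=20, n_paired_subjects=20,
                              n_tf_target_genes=30, n_probes=30, eqtl_effect_sd=0.0)
        res = paired_differential_expression(simulate_expression(spec))
        assert (res["adj_p"] >= res["raw_p"] - 1e-12).all()
        order = res.sort_values("raw_p")
        assert order["adj_p"].is_monotonic_increasing

    def test_planted_shift_recovered(self):
        """A 1.5x acute shift (50 pairs, log2 noise sd 0.1) is recovered with
        fold change near 1.5 and significant adjusted p in >=95% of replicates."""
        n_rep = 60
        hits = 0
        for seed in range(n_rep):
            spec = SimulationSpec(
                seed=seed, n_subjects=50, n_paired_subjects=50,
                n_tf_target_genes=10, n_probes=10, noise_sd=0.1,
                eqtl_effect_sd=0.0, de_log2_shift={"IL6": math.log2(1.5)},
            )
            res = paired_differential_expression(simulate_expression(spec))
            fc = res.loc["IL6", "fold_change"]
            if 1.4 <= fc <= 1.6 and res.loc["IL6", "adj_p"] < 0.05:
                hits += 1
        assert hits >= 0.95 * n_rep


class TestEqtlScan:
    def test_constant_gene_not_flagged(self):
        spec = SimulationSpec(seed=4, n_subjects=30, n_paired_subjects=0,
                              n_tf_target_genes=3, n_probes=3, noise_sd=0.5)
        geno = simulate_cohort_genotypes(spec)
        expr = simulate_expression(spec, geno)
        expr.values.iloc[0, :] = 5.0  # constant probe
        gene = expr.probe_to_gene[expr.values.index[0]]
        res = eqtl_scan(expr, geno, expr.genes(), alpha=0.001)
        row = res.loc[gene]
        assert all(row[c] == 1.0 for c in res.columns if c.startswith("p_"))
        assert not row["significant"]

    def test_planted_dose_effect_detected_and_ranks_first(self):
        """One gene with a 1-sd-per-allele additive effect is flagged and
        attains the minimum p of the whole scan in >=95% of replicates."""
        n_rep, hits = 30, 0
        for seed in range(n_rep):
            spec = SimulationSpec(seed=seed, n_tf_target_genes=120, n_probes=120,
                                  n_paired_subjects=0, eqtl_effect_sd=1.0)
            geno = simulate_cohort_genotypes(spec)
            expr = simulate_expression(spec, geno)
            res = eqtl_scan(expr, geno, expr.genes(), alpha=0.001)
            if res["significant"].loc["IL6"] and res.index[0] == "IL6":
                hits += 1
        assert hits >= 0.95 * n_rep

    def test_rank_invariance_under_monotone_transform(self):
        spec = SimulationSpec(seed=5, n_subjects=40, n_paired_subjects=0,
                              n_tf_target_genes=8, n_probes=8)
        geno = simulate_cohort_genotypes(spec)
        expr = simulate_expression(spec, geno)
        res1 = eqtl_scan(expr, geno, expr.genes())
        cubed = ExpressionMatrix(expr.values ** 3, expr.probe_to_gene,
                                 expr.sample_phase, expr.sample_subject)
        res2 = eqtl_scan(cubed, geno, expr.genes())
        pd.testing.assert_frame_equal(res1, res2)

    def test_joint_subject_relabeling_leaves_scan_unchanged(self):
        """Permuting subject identities jointly in genotypes and expression
        columns is a pure relabeling: every p-value is preserved."""
        spec = SimulationSpec(seed=6, n_subjects=30, n_paired_subjects=0,
                              n_tf_target_genes=6, n_probes=6)
        geno = simulate_cohort_genotypes(spec)
        expr = simulate_expression(spec, geno)
        rng = np.random.default_rng(0)
        subjects = list(geno)
        perm = dict(zip(subjects, rng.permutation(subjects)))
        geno2 = {perm[s]: d for s, d in geno.items()}
        subj2 = {sid: perm[s] for sid, s in expr.sample_subject.items()}
        expr2 = ExpressionMatrix(expr.values, expr.probe_to_gene, expr.sample_phase, subj2)
        res1 = eqtl_scan(expr, geno, expr.genes()).sort_index()
        res2 = eqtl_scan(expr2, geno2, expr.genes()).sort_index()
        pd.testing.assert_frame_equal(res1, res2)

    def test_single_genotype_group_fatal(self):
        spec = SimulationSpec(seed=7, n_subjects=10, n_paired_subjects=0,
                              n_tf_target_genes=3, n_probes=3)
        geno = {s: 1 for s in simulate_cohort_genotypes(spec)}
        expr = simulate_expression(spec, geno)
        with pytest.raises(ValueError, match="genotype groups"):
            eqtl_scan(expr, geno, expr.genes())

    def test_kruskal_mode_agrees_on_strong_signal(self):
        spec = SimulationSpec(seed=8, n_paired_subjects=0, n_tf_target_genes=20,
                              n_probes=20, eqtl_effect_sd=1.5)
        geno = simulate_cohort_genotypes(spec)
        expr = simulate_expression(spec, geno)
        mw = eqtl_scan(expr, geno, expr.genes(), method="mannwhitney")
        kw = eqtl_scan(expr, geno, expr.genes(), method="kruskal")
        assert mw.index[0] == kw.index[0] == "IL6"
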