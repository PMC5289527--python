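"""Expression analyses: paired acute/convalescent differential expression
(which feeds the transcriptome filter) and the genotype-stratified eQTL scan
over a transcription-factor target gene set.

Expression values are positive microarray-style abundances on an arbitrary
scale; all modeling is on log2.  Differential expression uses the Wilcoxon
matched-pairs signed-rank test on within-subject log2(acute) -
log2(convalescent) differences, with Benjamini-Hochberg adjustment across
genes.  The eQTL scan compares acute-phase expression between genotype
groups with two-sided rank-sum tests for each genotype pair (0v1, 0v2, 1v2);
a gene is flagged when its minimum pairwise p over all its probes falls
below a nominal alpha (no multiplicity correction inside the scan — an
anti-conservative, nominal-p convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .clinical_assoc import mann_whitney

__all__ = ["ExpressionMatrix", "paired_differential_expression", "eqtl_scan",
           "read_expression_tsv", "write_expression_tsv"]

_PHASES = ("acute", "convalescent")


@dataclass
class ExpressionMatrix:
    """Probe x sample abundance matrix with phase and subject metadata.

    ``values``: DataFrame indexed by probe id, one column per sample.
    ``probe_to_gene``: each probe maps to exactly one gene (several probes
    may share a gene — they measure different transcripts and are never
    averaged).  ``sample_phase`` maps sample -> "acute"/"convalescent";
    ``sample_subject`` pairs the two phases of one subject.
    """

    values: pd.DataFrame
    probe_to_gene: dict[str, str]
    sample_phase: dict[str, str]
    sample_subject: dict[str, str]

    def __post_init__(self) -> None:
        for s in self.values.columns:
            if s not in self.sample_phase or s not in self.sample_subject:
                raise ValueError(f"sample {s!r} lacks phase/subject metadata")
            if self.sample_phase[s] not in _PHASES:
                raise ValueError(f"unknown phase {self.sample_phase[s]!r} for sample {s!r}")
        for probe in self.values.index:
            if probe not in self.probe_to_gene:
                raise ValueError(f"probe {probe!r} has no gene mapping")

    def samples_in_phase(self, phase: str) -> list[str]:
        return [s for s in self.values.columns if self.sample_phase[s] == phase]

    def paired_subjects(self) -> list[str]:
        """Subjects with exactly one sample in each phase, in column order."""
        by_subject: dict[str, set[str]] = {}
        for s in self.values.columns:
            by_subject.setdefault(self.sample_subject[s], set()).add(self.sample_phase[s])
        seen: list[str] = []
        for s in self.values.columns:
            subj = self.sample_subject[s]
            if by_subject[subj] == set(_PHASES) and subj not in seen:
                seen.append(subj)
        return seen

    def genes(self) -> set[str]:
        return set(self.probe_to_gene[p] for p in self.values.index)


def paired_differential_expression(expr: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene acute-vs-convalescent fold change and paired signed-rank p.

    Fold change is 2**(mean over subjects of log2(acute) - log2(convalescent));
    the raw two-sided p comes from the Wilcoxon matched-pairs signed-rank
    test on the per-subject log2 differences, BH-adjusted across genes.  For
    genes with several probes the probe with the smallest raw p represents
    the gene.  Zero or negative abundances are fatal (log undefined).

    Returns a DataFrame indexed by gene with columns ``probe``,
    ``fold_change``, ``raw_p``, ``adj_p``.
    """
    subjects = expr.paired_subjects()
    if len(subjects) < 2:
        raise ValueError("paired analysis needs >=2 subjects with both phases")
    sample_of: dict[tuple[str, str], str] = {}
    for s in expr.values.columns:
        sample_of[(expr.sample_subject[s], expr.sample_phase[s])] = s
    acute_cols = [sample_of[(subj, "acute")] for subj in subjects]
    conv_cols = [sample_of[(subj, "convalescent")] for subj in subjects]

    vals = expr.values.to_numpy(dtype=float)
    if (vals <= 0).any():
        raise ValueError("expression abundances must be > 0 (log2 undefined)")
    log2 = pd.DataFrame(np.log2(vals), index=expr.values.index, columns=expr.values.columns)
    diffs = log2[acute_cols].to_numpy() - log2[conv_cols].to_numpy()

    rows = []
    for i, probe in enumerate(expr.values.index):
        d = diffs[i]
        fc = float(2.0 ** d.mean())
        if np.allclose(d, 0.0):
            p = 1.0  # no within-pair change anywhere
        else:
            p = float(stats.wilcoxon(d, alternative="two-sided", zero_method="wilcox").pvalue)
        rows.append((probe, expr.probe_to_gene[probe], fc, p))
    probe_table = pd.DataFrame(rows, columns=["probe", "gene", "fold_change", "raw_p"])
    best = probe_table.loc[probe_table.groupby("gene")["raw_p"].idxmin()].set_index("gene")

    from statsmodels.stats.multitest import multipletests

    best = best.sort_index()
    best["adj_p"] = multipletests(best["raw_p"].to_numpy(), method="fdr_bh")[1]
    return best[["probe", "fold_change", "raw_p", "adj_p"]]


def _pairwise_p(groups: Mapping[int, np.ndarray]) -> dict[str, float]:
    """Two-sided rank-sum p for each genotype-dose pair present."""
    out: dict[str, float] = {}
    for a, b in combinations(sorted(groups), 2):
        x, y = groups[a], groups[b]
        pooled = np.concatenate([x, y])
        if np.all(pooled == pooled[0]):
            p = 1.0  # constant expression: no evidence either way
        else:
            _, p = mann_whitney(x, y)
        out[f"p_{a}v{b}"] = p
    return out


def eqtl_scan(
    expr: ExpressionMatrix,
    genotypes: Mapping[str, int],
    gene_set: Iterable[str],
    alpha: float = 0.001,
    phase: str = "acute",
    method: str = "mannwhitney",
) -> pd.DataFrame:
    """Scan a gene set for genotype-dependent expression in one phase.

    ``genotypes`` maps subject -> allele dose at the query SNV.  For each
    probe of each gene in ``gene_set``, expression in the chosen phase is
    compared between genotype groups: pairwise two-sided rank-sum tests
    (``method="mannwhitney"``, the default) or a single Kruskal-Wallis test
    across all groups (``method="kruskal"``).  Probes aggregate to genes by
    minimum p; ``significant`` flags min p < alpha.

    Returns a DataFrame indexed by gene, sorted by ``min_p``, with the
    pairwise p columns, ``min_p`` and ``significant``.
    """
    if method not in ("mannwhitney", "kruskal"):
        raise ValueError("method must be 'mannwhitney' or 'kruskal'")
    samples = [
        s
        for s in expr.samples_in_phase(phase)
        if expr.sample_subject[s] in genotypes
    ]
    doses = np.array([genotypes[expr.sample_subject[s]] for s in samples])
    present = sorted(set(doses.tolist()))
    if len(present) < 2:
        raise ValueError("eQTL scan needs >=2 genotype groups with samples")
    wanted = set(gene_set)
    probes = [p for p in expr.values.index if expr.probe_to_gene[p] in wanted]
    if not probes:
        raise ValueError("gene_set shares no genes with the expression matrix")

    mat = expr.values.loc[probes, samples].to_numpy(dtype=float)
    masks = {d: doses == d for d in present}

    if method == "kruskal":
        rows = []
        for i, probe in enumerate(probes):
            row = mat[i]
            groups = [row[masks[d]] for d in present]
            if np.all(row == row[0]):
                ps = {"p_kruskal": 1.0}
            else:
                ps = {"p_kruskal": float(stats.kruskal(*groups).pvalue)}
            rows.append(
                {"probe": probe, "gene": expr.probe_to_gene[probe], **ps,
                 "min_p": min(ps.values())}
            )
        probe_table = pd.DataFrame(rows)
    else:
        min_group = min(int(masks[d].sum()) for d in present)
        pcols: dict[str, np.ndarray] = {}
        for a, b in combinations(present, 2):
            A, B = mat[:, masks[a]], mat[:, masks[b]]
            pooled = np.concatenate([A, B], axis=1)
            constant = (pooled == pooled[:, :1]).all(axis=1)
            if min_group > 12:
                # large groups: tie-corrected normal approximation, vectorized
                with np.errstate(invalid="ignore", divide="ignore"):
                    p = stats.mannwhitneyu(
                        A, B, alternative="two-sided", method="asymptotic", axis=1
                    ).pvalue
            else:
                p = np.array([_pairwise_p({a: A[i], b: B[i]})[f"p_{a}v{b}"]
                              for i in range(mat.shape[0])])
            p = np.where(constant, 1.0, p)
            pcols[f"p_{a}v{b}"] = np.minimum(p, 1.0)
        probe_table = pd.DataFrame(
            {"probe": probes, "gene": [expr.probe_to_gene[p] for p in probes], **pcols}
        )
        probe_table["min_p"] = probe_table[list(pcols)].min(axis=1)
    best = probe_table.loc[probe_table.groupby("gene")["min_p"].idxmin()].set_index("gene")
    # per-pair minimum over probes (reported alongside the best probe's id)
    p_cols = [c for c in probe_table.columns if c.startswith("p_")]
    agg = probe_table.groupby("gene")[p_cols + ["min_p"]].min()
    agg["probe"] = best["probe"]
    agg["significant"] = agg["min_p"] < alpha
    return agg.sort_values("min_p")


def write_expression_tsv(expr: ExpressionMatrix, path) -> None:
    """Probes x samples TSV with a two-row header (phase, subject) and a
    leading gene column."""
    cols = list(expr.values.columns)
    with open(path, "w") as fh:
        fh.write("#phase\t\t" + "\t".join(expr.sample_phase[s] for s in cols) + "\n")
        fh.write("#subject\t\t" + "\t".join(expr.sample_subject[s] for s in cols) + "\n")
        fh.write("probe\tgene\t" + "\t".join(cols) + "\n")
        for probe in expr.values.index:
            vals = "\t".join(f"{v:.6g}" for v in expr.values.loc[probe])
            fh.write(f"{probe}\t{expr.probe_to_gene[probe]}\t{vals}\n")


def read_expression_tsv(path) -> ExpressionMatrix:
    with open(path) as fh:
        phase_row = fh.readline().rstrip("\n").split("\t")
        subject_row = fh.readline().rstrip("\n").split("\t")
        header = fh.readline().rstrip("\n").split("\t")
        if phase_row[0] != "#phase" or subject_row[0] != "#subject":
            raise ValueError("expression TSV must start with #phase and #subject rows")
        samples = header[2:]
        sample_phase = dict(zip(samples, phase_row[2:]))
        sample_subject = dict(zip(samples, subject_row[2:]))
        probes, genes, data = [], {}, []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            probes.append(parts[0])
            genes[parts[0]] = parts[1]
            data.append([float(x) for x in parts[2:]])
    values = pd.DataFrame(data, index=probes, columns=samples)
    return ExpressionMatrix(values, genes, sample_phase, sample_subject)
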