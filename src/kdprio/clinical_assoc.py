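"""Genotype-stratified clinical association: rank tests, chi-square, a
from-scratch Fisher-Freeman-Halton exact test for r x c contingency tables,
and the per-genotype clinical summary table.

The Fisher-Freeman-Halton test generalizes Fisher's 2x2 exact test: under
fixed margins the table counts follow the multivariate hypergeometric
distribution

    P(T) = (prod_i r_i!) (prod_j c_j!) / (N! prod_ij n_ij!),

and the two-sided p is the total probability of all margin-preserving
tables no more probable than the observed one (the probability-ordering
rule; probabilities are compared with a small relative tolerance so float
noise does not split exact ties).  Enumeration is depth-first over the free
cells with margin pruning, in log space.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp, lgamma, log
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable",
    "mann_whitney",
    "fisher_freeman_halton",
    "enumerate_table_probabilities",
    "chi_square",
    "genotype_summary",
]

#: cap on enumerated candidate tables for the exact test
_MAX_TABLES = 10_000_000
_TIE_RTOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """Non-negative integer r x c counts with optional axis labels."""

    counts: tuple[tuple[int, ...], ...]
    row_labels: Optional[tuple[str, ...]] = None
    col_labels: Optional[tuple[str, ...]] = None

    @classmethod
    def from_array(cls, arr, row_labels=None, col_labels=None) -> "ContingencyTable":
        a = np.asarray(arr, dtype=int)
        if a.ndim != 2:
            raise ValueError("contingency table must be 2-D")
        if (a < 0).any():
            raise ValueError("counts must be non-negative")
        if a.sum() < 1:
            raise ValueError("grand total must be >= 1")
        return cls(
            counts=tuple(tuple(int(x) for x in row) for row in a),
            row_labels=tuple(row_labels) if row_labels is not None else None,
            col_labels=tuple(col_labels) if col_labels is not None else None,
        )

    def to_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=int)


def _as_array(table) -> np.ndarray:
    if isinstance(table, ContingencyTable):
        return table.to_array()
    return ContingencyTable.from_array(table).to_array()


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of the first sample, p).

    U is computed from midranks.  The exact null distribution is used when
    both samples have <= 12 observations and the pooled data carry no ties;
    otherwise the tie-corrected normal approximation with continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney requires non-empty samples")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size <= 12 and y.size <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def _log_table_prob_const(rows: np.ndarray, cols: np.ndarray) -> float:
    n = rows.sum()
    return (
        sum(lgamma(r + 1) for r in rows)
        + sum(lgamma(c + 1) for c in cols)
        - lgamma(n + 1)
    )


def enumerate_table_probabilities(table) -> list[float]:
    """Probabilities of every margin-preserving table (sums to 1).

    Exposed for verification; :func:`fisher_freeman_halton` uses the same
    enumeration without materializing the list.
    """
    probs: list[float] = []
    _enumerate(_as_array(table), lambda lp: probs.append(exp(lp)))
    return probs


def _enumerate(observed: np.ndarray, visit) -> None:
    """Depth-first enumeration of all tables with the observed margins.

    ``visit`` receives the log-probability of each table.
    """
    rows = observed.sum(axis=1)
    cols = observed.sum(axis=0)
    const = _log_table_prob_const(rows, cols)
    r, c = observed.shape
    counter = {"n": 0}

    def recurse(i: int, j: int, row_left: np.ndarray, col_left: np.ndarray, log_fact: float):
        if i == r:
            counter["n"] += 1
            if counter["n"] > _MAX_TABLES:
                raise RuntimeError(
                    "Fisher-Freeman-Halton enumeration exceeds the "
                    f"{_MAX_TABLES} table guard; use a Monte-Carlo approach"
                )
            visit(const - log_fact)
            return
        if j == c - 1:
            # last cell of the row is forced by the row margin
            v = row_left[i]
            if v > col_left[j]:
                return
            col_left[j] -= v
            recurse(i + 1, 0, row_left, col_left, log_fact + lgamma(v + 1))
            col_left[j] += v
            return
        remaining_cols = col_left[j + 1 :].sum()
        lo = max(0, row_left[i] - remaining_cols)
        hi = min(row_left[i], col_left[j])
        for v in range(lo, hi + 1):
            row_left[i] -= v
            col_left[j] -= v
            recurse(i, j + 1, row_left, col_left, log_fact + lgamma(v + 1))
            row_left[i] += v
            col_left[j] += v

    recurse(0, 0, rows.copy(), cols.copy(), 0.0)


def fisher_freeman_halton(table) -> float:
    """Exact two-sided p for an r x c contingency table.

    Sums the multivariate-hypergeometric probabilities of all tables with
    the observed margins whose probability does not exceed the observed
    table's (within relative tolerance 1e-7 for floating-point ties).
    """
    observed = _as_array(table)
    rows = observed.sum(axis=1)
    cols = observed.sum(axis=0)
    const = _log_table_prob_const(rows, cols)
    log_p_obs = const - sum(lgamma(v + 1) for v in observed.ravel())
    cutoff = log_p_obs + log(1.0 + _TIE_RTOL)

    acc = {"p": 0.0}

    def visit(lp: float) -> None:
        if lp <= cutoff:
            acc["p"] += exp(lp)

    _enumerate(observed, visit)
    return min(acc["p"], 1.0)


def chi_square(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence: (statistic, df, upper-tail p)."""
    observed = _as_array(table)
    if (observed.sum(axis=1) == 0).any() or (observed.sum(axis=0) == 0).any():
        raise ValueError("chi_square requires positive row and column margins")
    res = stats.chi2_contingency(observed, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


_GENOTYPE_LABELS = {0: "hom_nonrisk", 1: "het", 2: "hom_risk"}


def genotype_summary(
    clinical: pd.DataFrame,
    continuous: Sequence[str],
    categorical: Sequence[str] = (),
    genotype_col: str = "genotype",
    risk_ethnicity: Optional[str] = "Asian",
    ethnicity_col: str = "ethnicity",
) -> dict:
    """Per-genotype clinical characteristics with the tests used in cohort
    genotype-stratification tables.

    Continuous covariates: median and IQR per genotype group, with the
    two-sided Mann-Whitney p comparing the extreme homozygotes (dose 2 vs
    dose 0) — not a 3-group trend test.  Categorical covariates: counts and
    percentages, chi-square across genotype groups.  Ethnicity (when
    present) additionally gets the Fisher-Freeman-Halton exact p for the
    risk ethnicity versus all others combined, by genotype.

    Returns a dict with ``groups`` (per-genotype summaries) and ``tests``
    (covariate -> test name and p-value).  With a single genotype group no
    tests are run; a covariate constant everywhere reports p = 1.
    """
    doses = sorted(clinical[genotype_col].unique())
    groups: dict[str, dict] = {}
    for d in doses:
        sub = clinical[clinical[genotype_col] == d]
        summary: dict = {"n": int(len(sub))}
        for cov in continuous:
            vals = sub[cov].dropna()
            summary[cov] = {
                "median": float(vals.median()),
                "iqr": (float(vals.quantile(0.25)), float(vals.quantile(0.75))),
            }
        for cov in categorical:
            counts = sub[cov].value_counts()
            summary[cov] = {
                str(k): {"n": int(v), "pct": round(100.0 * v / len(sub))}
                for k, v in counts.items()
            }
        groups[_GENOTYPE_LABELS.get(d, str(d))] = summary

    tests: dict[str, dict] = {}
    if len(doses) >= 2:
        lo, hi = min(doses), max(doses)
        x = clinical.loc[clinical[genotype_col] == hi]
        y = clinical.loc[clinical[genotype_col] == lo]
        for cov in continuous:
            xv = x[cov].dropna().to_numpy()
            yv = y[cov].dropna().to_numpy()
            if np.unique(np.concatenate([xv, yv])).size == 1:
                tests[cov] = {"test": "mann_whitney", "p": 1.0}
                continue
            _, p = mann_whitney(xv, yv)
            tests[cov] = {"test": "mann_whitney", "p": p}
        for cov in categorical:
            ct = pd.crosstab(clinical[genotype_col], clinical[cov]).to_numpy()
            if ct.shape[1] < 2:
                tests[cov] = {"test": "chi_square", "p": 1.0}
                continue
            stat, df, p = chi_square(ct)
            tests[cov] = {"test": "chi_square", "p": p, "statistic": stat, "df": df}
        if risk_ethnicity is not None and ethnicity_col in clinical.columns:
            is_risk = clinical[ethnicity_col] == risk_ethnicity
            ct = pd.crosstab(clinical[genotype_col], is_risk)
            # columns ordered (risk, other) for readability
            arr = np.column_stack(
                [
                    ct[True].to_numpy() if True in ct.columns else np.zeros(len(ct), int),
                    ct[False].to_numpy() if False in ct.columns else np.zeros(len(ct), int),
                ]
            )
            tests[f"{ethnicity_col}:{risk_ethnicity}_vs_other"] = {
                "test": "fisher_freeman_halton",
                "p": fisher_freeman_halton(arr),
            }
    return {"groups": groups, "tests": tests}
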