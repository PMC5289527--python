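"""Pairwise linkage disequilibrium (r-squared, D') from phased haplotypes,
and greedy grouping of SNVs into LD blocks with a positional representative.

Inputs are phased binary haplotypes: one row per haplotype, one 0/1 column
per site.  With p_A, p_B the allele-1 frequencies at two sites and p_11 the
frequency of the 1-1 haplotype,

    D  = p_11 - p_A * p_B
    r2 = D^2 / (p_A (1-p_A) p_B (1-p_B))
    D' = |D| / D_max,   D_max = min(p_A (1-p_B), (1-p_A) p_B)      if D > 0
                         D_max = min(p_A p_B, (1-p_A)(1-p_B))       if D < 0

Both statistics are undefined when either site is monomorphic.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = ["ld_r2", "ld_dprime", "ld_matrix", "tag_representative", "MonomorphicSiteError"]


class MonomorphicSiteError(ValueError):
    """LD is undefined when a site carries only one allele."""


def _freqs(site_a, site_b) -> tuple[float, float, float]:
    a = np.asarray(site_a, dtype=float)
    b = np.asarray(site_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("sites must be equal-length 1-D haplotype vectors")
    if not (np.isin(a, (0, 1)).all() and np.isin(b, (0, 1)).all()):
        raise ValueError("haplotype alleles must be 0/1")
    pa = a.mean()
    pb = b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise MonomorphicSiteError("both sites must be polymorphic in the sample")
    p11 = float(np.mean(a * b))
    return pa, pb, p11


def ld_r2(site_a: Sequence[int], site_b: Sequence[int]) -> float:
    """Squared allele-frequency correlation between two sites, in [0, 1]."""
    pa, pb, p11 = _freqs(site_a, site_b)
    d = p11 - pa * pb
    return float(d * d / (pa * (1 - pa) * pb * (1 - pb)))


def ld_dprime(site_a: Sequence[int], site_b: Sequence[int]) -> float:
    """Lewontin's D': |D| normalized by its maximum given the allele
    frequencies, in [0, 1]."""
    pa, pb, p11 = _freqs(site_a, site_b)
    d = p11 - pa * pb
    if d == 0.0:
        return 0.0
    if d > 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    return float(abs(d) / dmax)


def ld_matrix(haplotypes, statistic: str = "r2") -> np.ndarray:
    """Pairwise LD over all site columns of a (n_haplotypes, n_sites) matrix."""
    H = np.asarray(haplotypes)
    fn = {"r2": ld_r2, "dprime": ld_dprime}[statistic]
    n = H.shape[1]
    out = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = fn(H[:, i], H[:, j])
    return out


def tag_representative(
    positions: Sequence[int],
    haplotypes,
    r2_threshold: float = 0.8,
) -> list[dict]:
    """Greedily group sites into LD blocks and pick one representative each.

    Sites are visited in ascending chromosome position; a site joins the
    earliest-started group whose seed site has r2 >= threshold with it
    (inclusive at the threshold), otherwise it seeds a new group.  The
    representative is the group's smallest position — the convention used to
    pick one tag SNV per block for downstream analyses.

    Returns a list of dicts with keys ``members`` (site indices, position
    order) and ``representative`` (site index).
    """
    H = np.asarray(haplotypes)
    if H.shape[1] != len(positions):
        raise ValueError("one haplotype column per position required")
    order = sorted(range(len(positions)), key=lambda i: positions[i])
    groups: list[dict] = []
    for i in order:
        placed = False
        for g in groups:
            seed = g["representative"]
            if ld_r2(H[:, seed], H[:, i]) >= r2_threshold:
                g["members"].append(i)
                placed = True
                break
        if not placed:
            groups.append({"members": [i], "representative": i})
    return groups
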