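"""Region/consequence-based deleteriousness and population-rarity filters."""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

from .model import AnnotationError, VariantRecord

__all__ = ["deleterious_filter", "rare_filter", "is_rare"]

#: region classes treated as potentially deleterious
DELETERIOUS_REGIONS = frozenset({"exon", "promoter", "splice_site", "utr3"})
#: loss-of-function/ACMG-style consequence classes
DELETERIOUS_CONSEQUENCES = frozenset(
    {"frameshift", "inframe_indel", "start_stop_change", "missense", "splice_loss"}
)


def deleterious_filter(
    records: Sequence[VariantRecord], mode: str = "region"
) -> list[VariantRecord]:
    """Keep variants predicted deleterious.

    ``mode="region"`` keeps exonic, promoter, splice-site and 3'UTR variants;
    ``mode="consequence"`` keeps frameshift, in-frame indel, start/stop
    change, missense and splice-loss variants.  Unannotated records are a
    fatal error (annotation is a precondition of this stage).
    """
    if mode == "region":
        keep = lambda ann: ann.region_class in DELETERIOUS_REGIONS
    elif mode == "consequence":
        keep = lambda ann: ann.consequence_class in DELETERIOUS_CONSEQUENCES
    else:
        raise ValueError(f"mode must be 'region' or 'consequence', got {mode!r}")
    out = []
    for rec in records:
        if rec.annotation is None:
            raise AnnotationError(f"deleterious_filter: unannotated record {rec.label()}")
        if keep(rec.annotation):
            out.append(rec)
    return out


def is_rare(
    rec: VariantRecord, threshold: float, populations: Optional[Iterable[str]] = None
) -> bool:
    """True when the allele frequency is < threshold in every queried
    population with data, or wholly unknown ("not available" counts as rare)."""
    if rec.annotation is None:
        raise AnnotationError(f"rare filter: unannotated record {rec.label()}")
    freqs = rec.annotation.allele_frequencies
    if populations is not None:
        freqs = {p: f for p, f in freqs.items() if p in set(populations)}
    if not freqs:
        return True
    return all(f < threshold for f in freqs.values())


def rare_filter(
    records: Sequence[VariantRecord],
    threshold: float,
    populations: Optional[Iterable[str]] = None,
) -> list[VariantRecord]:
    """Keep variants rare (strictly below ``threshold``) in all queried
    populations, or with no frequency data at all.

    A single population at or above the threshold disqualifies the variant;
    ``populations=None`` queries every population carrying data.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0,1), got {threshold}")
    pops = None if populations is None else set(populations)
    return [rec for rec in records if is_rare(rec, threshold, pops)]
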