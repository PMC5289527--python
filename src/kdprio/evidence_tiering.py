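"""Evidence integration: pathway, GWAS and transcriptome filters, and the
two-tier assignment of inheritance-consistent variants.

Tier 1 collects rare inheritance-consistent variants in disease-pathway,
differentially-expressed genes: the recessive-homozygous branch additionally
requires predicted deleteriousness and allele frequency < 1%, the
compound-het branch allele frequency < 3%.  Tier 2 collects common
recessive-homozygous deleterious variants with nominal GWAS support
(p < 0.05) and differential expression — deliberately with NO rarity cap
(the observed Tier 2 risk-allele frequencies run up to 83%).  A variant
qualifying for both tiers is labeled Tier 1 (the rarity + pathway evidence
is the stronger claim).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

from .annotation_filters import deleterious_filter, is_rare
from .inheritance import compound_heterozygous_filter, recessive_homozygous_filter
from .model import (
    AnnotationError,
    FilterConfig,
    GeneEvidence,
    Pedigree,
    REJECTED,
    TIER1,
    TIER2,
    TierAssignment,
    VariantRecord,
)
from .variant_io import confidence_filter

__all__ = [
    "pathway_filter",
    "gwas_filter",
    "transcriptome_filter",
    "de_passes",
    "assign_tiers",
    "write_tier_table",
]


def pathway_filter(
    records: Sequence[VariantRecord], pathway_genes: Iterable[str]
) -> list[VariantRecord]:
    """Keep variants whose gene belongs to the disease-pathway gene set."""
    genes = set(pathway_genes)
    if not genes:
        import warnings

        warnings.warn("empty pathway gene set: pathway_filter returns nothing")
        return []
    out = []
    for rec in records:
        if rec.gene is None:
            raise AnnotationError(f"pathway_filter: unannotated record {rec.label()}")
        if rec.gene in genes:
            out.append(rec)
    return out


def gwas_filter(records: Sequence[VariantRecord], alpha: float = 0.05) -> list[VariantRecord]:
    """Keep variants with nominal association p strictly below ``alpha``;
    variants never tested (unknown p) are excluded."""
    out = []
    for rec in records:
        if rec.annotation is None:
            raise AnnotationError(f"gwas_filter: unannotated record {rec.label()}")
        p = rec.annotation.gwas_p
        if p is not None and p < alpha:
            out.append(rec)
    return out


def de_passes(ev: Optional[GeneEvidence], config: FilterConfig) -> bool:
    """Differential-expression gate: fold-change magnitude >= 1.2 (either
    direction) and BH-adjusted p < 0.05, under the default config."""
    if ev is None:
        return False
    magnitude = max(ev.de_fold_change, 1.0 / ev.de_fold_change)
    return magnitude >= config.de_fold_change and ev.de_adj_p < config.de_adj_alpha


def transcriptome_filter(
    records: Sequence[VariantRecord],
    evidence: Mapping[str, GeneEvidence],
    config: FilterConfig | None = None,
) -> list[VariantRecord]:
    """Keep variants in differentially expressed genes (|FC| >= cutoff and
    adjusted p < alpha); genes without evidence are excluded."""
    if config is None:
        config = FilterConfig()
    out = []
    for rec in records:
        if rec.gene is None:
            raise AnnotationError(f"transcriptome_filter: unannotated record {rec.label()}")
        if de_passes(evidence.get(rec.gene), config):
            out.append(rec)
    return out


def assign_tiers(
    records: Sequence[VariantRecord],
    pedigree: Pedigree,
    evidence: Mapping[str, GeneEvidence],
    config: FilterConfig | None = None,
    pathway_genes: Optional[Iterable[str]] = None,
) -> list[TierAssignment]:
    """Run the full prioritization funnel and label every input variant.

    Stages: confidence -> inheritance model (HR or CH) -> branch filters:

    * HR Tier 1: deleterious, AF < 1%, pathway, differential expression
    * HR Tier 2: deleterious, GWAS nominal p < 0.05, differential expression
    * CH Tier 1: AF < 3%, pathway, differential expression

    Every variant receives exactly one assignment with the ordered trail of
    evaluated stages; Tier 1 wins when both tiers qualify.  ``pathway_genes``
    defaults to the genes flagged ``in_kd_pathway`` in ``evidence``.
    """
    if config is None:
        config = FilterConfig()
    if pathway_genes is None:
        pathway = {g for g, ev in evidence.items() if ev.in_kd_pathway}
    else:
        pathway = set(pathway_genes)

    survivors = confidence_filter(records, config)
    conf_ok = {id(r) for r in survivors}
    hr_ok = {
        id(r)
        for r in recessive_homozygous_filter(survivors, pedigree, config.missing_policy)
    }
    pairs = compound_heterozygous_filter(
        survivors, pedigree, missing_policy=config.missing_policy
    )
    ch_ok = {id(p.maternal_variant) for p in pairs} | {id(p.paternal_variant) for p in pairs}

    deleterious = {id(r) for r in deleterious_filter(survivors, config.deleterious_mode)} if survivors else set()

    assignments: list[TierAssignment] = []
    for rec in records:
        trail: list[tuple[str, bool]] = [("confidence", id(rec) in conf_ok)]
        if id(rec) not in conf_ok:
            assignments.append(TierAssignment(rec, REJECTED, None, trail))
            continue
        if id(rec) in hr_ok:
            mode = "HR"
        elif id(rec) in ch_ok:
            mode = "CH"
        else:
            trail.append(("inheritance", False))
            assignments.append(TierAssignment(rec, REJECTED, None, trail))
            continue
        trail.append(("inheritance", True))
        ev = evidence.get(rec.gene) if rec.gene is not None else None
        de_ok = de_passes(ev, config)
        in_pathway = rec.gene in pathway

        if mode == "HR":
            del_ok = id(rec) in deleterious
            rare1 = is_rare(rec, config.rare_af_homozygous, config.rare_populations)
            gp = rec.annotation.gwas_p if rec.annotation else None
            gwas_ok = gp is not None and gp < config.gwas_alpha
            trail += [
                ("deleterious", del_ok),
                ("rare_af_lt_1pct", rare1),
                ("pathway", in_pathway),
                ("gwas", gwas_ok),
                ("transcriptome", de_ok),
            ]
            if del_ok and rare1 and in_pathway and de_ok:
                tier = TIER1
            elif del_ok and gwas_ok and de_ok:
                tier = TIER2
            else:
                tier = REJECTED
        else:  # CH
            rare3 = is_rare(rec, config.rare_af_compound_het, config.rare_populations)
            trail += [
                ("rare_af_lt_3pct", rare3),
                ("pathway", in_pathway),
                ("transcriptome", de_ok),
            ]
            tier = TIER1 if (rare3 and in_pathway and de_ok) else REJECTED
        assignments.append(TierAssignment(rec, tier, mode, trail))
    return assignments


def write_tier_table(assignments: Sequence[TierAssignment], path) -> None:
    """Emit the tier table as TSV: rs_id, gene, tier, inheritance mode and
    the semicolon-joined stage:flag trail."""
    with open(path, "w") as fh:
        fh.write("rs_id\tchrom\tpos\tgene\ttier\tinheritance_mode\ttrail\n")
        for a in assignments:
            trail = ";".join(f"{name}:{'pass' if ok else 'fail'}" for name, ok in a.trail)
            fh.write(
                "\t".join(
                    [
                        a.variant.rs_id or ".",
                        a.variant.chrom,
                        str(a.variant.pos),
                        a.variant.gene or ".",
                        a.tier,
                        a.inheritance_mode or ".",
                        trail,
                    ]
                )
                + "\n"
            )
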