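"""Inheritance-model filters for a multiplex nuclear family.

Two models are implemented, matching the discovery workflow for a family
with affected and unaffected children of one unaffected parent couple:

* **Recessive homozygous** — the alternate allele is homozygous in every
  affected member and non-homozygous in every unaffected member.
* **Compound heterozygous** — per variant, three rules: (1) heterozygous in
  every affected child; (2) not homozygous in any unaffected member; (3)
  heterozygous in exactly one of the two parents.  Rule 3 fixes the parent
  of origin without phasing, so a reported pair combines one maternally and
  one paternally inherited eligible variant in the same gene (trans
  configuration).  Genes with eligible variants from only one parent yield
  no pairs; if several eligible variants share an origin, all maternal x
  paternal combinations are reported.

Missing genotypes: under the default strict policy any missing call
disqualifies a variant; the lenient policy tolerates missing calls in
unaffected siblings (not in affected children or parents).
"""

from __future__ import annotations

from itertools import product
from typing import Callable, Iterable, Mapping, Optional, Sequence

from .model import CompoundHetPair, Pedigree, PedigreeError, VariantRecord

__all__ = [
    "recessive_homozygous_filter",
    "compound_heterozygous_filter",
    "compound_het_eligibility",
    "mendelian_error_scan",
]


def _check_missing(
    rec: VariantRecord,
    pedigree: Pedigree,
    critical_ids: Sequence[str],
    missing_policy: str,
) -> bool:
    """True when the record's missing calls do not disqualify it."""
    for m in pedigree:
        call = rec.calls.get(m.sample_id)
        if call is None or call.is_missing:
            if missing_policy == "strict":
                return False
            if m.sample_id in critical_ids:
                return False
    return True


def recessive_homozygous_filter(
    records: Sequence[VariantRecord],
    pedigree: Pedigree,
    missing_policy: str = "strict",
) -> list[VariantRecord]:
    """Variants homozygous-alt in all affected and non-hom in all unaffected."""
    affected = pedigree.affected_ids
    unaffected = pedigree.unaffected_ids
    if not affected:
        raise PedigreeError("recessive-homozygous filter needs >=1 affected member")
    out = []
    for rec in records:
        # affected members and parents are always critical; unaffected sibs
        # only under the strict policy
        if not _check_missing(rec, pedigree, affected, missing_policy):
            continue
        if any(rec.calls[s].allele_dose != 2 for s in affected):
            continue
        bad = False
        for s in unaffected:
            dose = rec.calls[s].allele_dose
            if dose == 2:
                bad = True
                break
        if not bad:
            out.append(rec)
    return out


def compound_het_eligibility(
    rec: VariantRecord,
    pedigree: Pedigree,
    missing_policy: str = "strict",
) -> Optional[str]:
    """Apply the three compound-het rules to a single variant.

    Returns ``"maternal"``/``"paternal"`` (the parent carrying the variant)
    when all three rules hold, else ``None``.
    """
    affected = pedigree.affected_ids
    if not affected:
        raise PedigreeError("compound-het filter needs >=1 affected member")
    father, mother = pedigree.founder_parents_of_affected()
    critical = list(affected) + [father, mother]
    if not _check_missing(rec, pedigree, critical, missing_policy):
        return None
    # rule 1: heterozygous in every affected child
    if any(rec.calls[s].allele_dose != 1 for s in affected):
        return None
    # rule 2: not homozygous in any unaffected member
    for s in pedigree.unaffected_ids:
        if rec.calls[s].allele_dose == 2:
            return None
    # rule 3: heterozygous in exactly one parent
    father_het = rec.calls[father].allele_dose == 1
    mother_het = rec.calls[mother].allele_dose == 1
    if father_het == mother_het:
        return None
    return "paternal" if father_het else "maternal"


def compound_heterozygous_filter(
    records: Sequence[VariantRecord],
    pedigree: Pedigree,
    gene_map: Mapping | Callable[[VariantRecord], Optional[str]] | None = None,
    missing_policy: str = "strict",
) -> list[CompoundHetPair]:
    """All trans-configured pairs of rule-satisfying variants, per gene.

    ``gene_map`` maps a record (or its ``(chrom,pos,ref,alt)`` key) to a gene
    symbol; by default the record's own annotation supplies the gene.
    """

    def gene_of(rec: VariantRecord) -> Optional[str]:
        if gene_map is None:
            return rec.gene
        if callable(gene_map):
            return gene_map(rec)
        return gene_map.get(rec.key(), gene_map.get(rec.rs_id))

    by_gene: dict[str, dict[str, list[VariantRecord]]] = {}
    for rec in records:
        origin = compound_het_eligibility(rec, pedigree, missing_policy)
        if origin is None:
            continue
        gene = gene_of(rec)
        if gene is None:
            raise ValueError(f"no gene mapping for eligible variant {rec.label()}")
        by_gene.setdefault(gene, {"maternal": [], "paternal": []})[origin].append(rec)

    pairs: list[CompoundHetPair] = []
    for gene in sorted(by_gene):
        sides = by_gene[gene]
        for mat, pat in product(sides["maternal"], sides["paternal"]):
            pairs.append(CompoundHetPair(gene=gene, maternal_variant=mat, paternal_variant=pat))
    return pairs


_TRANSMISSIBLE = {0: {0}, 1: {0, 1}, 2: {1}}


def mendelian_error_scan(
    records: Iterable[VariantRecord], pedigree: Pedigree
) -> list[tuple[VariantRecord, str, str]]:
    """Flag child genotypes impossible under Mendelian transmission.

    For every member with both parents in the pedigree, the child dose must
    decompose into one transmissible allele from each parent.  Missing calls
    in child or either parent are skipped.
    """
    children = [m for m in pedigree if m.father_id is not None and m.mother_id is not None]
    flags: list[tuple[VariantRecord, str, str]] = []
    for rec in records:
        for child in children:
            c = rec.calls[child.sample_id].allele_dose
            f = rec.calls[child.father_id].allele_dose
            m = rec.calls[child.mother_id].allele_dose
            if c is None or f is None or m is None:
                continue
            possible = {a + b for a in _TRANSMISSIBLE[f] for b in _TRANSMISSIBLE[m]}
            if c not in possible:
                flags.append(
                    (rec, child.sample_id, f"child dose {c} impossible from parents ({f},{m})")
                )
    return flags
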