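"""Readers/writers for the pipeline's file formats and the confidence filter.

Formats handled here: multi-sample VCF v4.x (via cyvcf2; FORMAT fields GT,
GQ, DP), 6-column PED pedigrees, the tab-delimited annotation table, gene
lists (one symbol per line) and the per-gene evidence table.  Multi-allelic
VCF sites are split into one biallelic :class:`~kdprio.model.VariantRecord`
per alternate allele; the allele dose of each split record counts only that
alternate allele, so doses across the split records sum to the genotype's
total alternate content.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Optional, Sequence

from .model import (
    AnnotationError,
    FilterConfig,
    GeneEvidence,
    GenotypeCall,
    Pedigree,
    PedigreeError,
    PedigreeMember,
    VariantAnnotation,
    VariantRecord,
)

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_ped",
    "write_ped",
    "read_annotations",
    "write_annotations",
    "attach_annotations",
    "read_gene_list",
    "read_evidence",
    "write_evidence",
    "confidence_filter",
]


def read_vcf(path: str | os.PathLike, pedigree: Pedigree) -> list[VariantRecord]:
    """Read a multi-sample VCF into variant records, one per (site, alt allele).

    Diploid GT fields are mapped to alternate-allele doses; per-sample GQ and
    DP populate ``call_quality``/``read_depth``.  Any pedigree sample missing
    from the VCF header is a fatal configuration error.
    """
    from cyvcf2 import VCF

    vcf = VCF(os.fspath(path))
    vcf_samples = list(vcf.samples)
    missing = [s for s in pedigree.sample_ids if s not in vcf_samples]
    if missing:
        raise PedigreeError(f"pedigree samples absent from VCF header: {missing}")
    col = {s: vcf_samples.index(s) for s in pedigree.sample_ids}

    records: list[VariantRecord] = []
    for v in vcf:
        genotypes = v.genotypes  # [[a, b, phased], ...]
        gqs = v.gt_quals  # -1 when absent
        try:
            dps = v.format("DP")
        except Exception:  # pragma: no cover - format lookup quirks
            dps = None
        for alt_index, alt in enumerate(v.ALT):
            allele_code = alt_index + 1
            calls: dict[str, GenotypeCall] = {}
            for sid, j in col.items():
                gt = genotypes[j]
                alleles = [a for a in gt[:-1] if a is not None]
                if not alleles or any(a < 0 for a in alleles):
                    calls[sid] = GenotypeCall(sid, None)
                    continue
                if len(alleles) != 2:
                    raise ValueError(
                        f"non-diploid genotype for sample {sid} at "
                        f"{v.CHROM}:{v.POS} (line with ID {v.ID!r})"
                    )
                dose = sum(1 for a in alleles if a == allele_code)
                gq = float(gqs[j]) if gqs is not None and gqs[j] >= 0 else None
                dp = None
                if dps is not None:
                    d = dps[j]
                    try:
                        d = int(d[0]) if hasattr(d, "__len__") else int(d)
                        dp = d if d >= 0 else None
                    except (TypeError, ValueError):
                        dp = None
                calls[sid] = GenotypeCall(sid, dose, call_quality=gq, read_depth=dp)
            records.append(
                VariantRecord(
                    chrom=v.CHROM,
                    pos=v.POS,
                    ref_allele=v.REF,
                    alt_allele=alt,
                    rs_id=v.ID if v.ID not in (None, ".") else None,
                    calls=calls,
                    site_quality=float(v.QUAL) if v.QUAL is not None else None,
                )
            )
    return records


def write_vcf(
    records: Sequence[VariantRecord],
    path: str | os.PathLike,
    sample_ids: Optional[Sequence[str]] = None,
) -> None:
    """Write biallelic records as VCF v4.2 with GT:GQ:DP per sample.

    Records split from a multi-allelic site are written as separate biallelic
    lines (the split is not re-merged).
    """
    if sample_ids is None:
        seen: list[str] = []
        for rec in records:
            for sid in rec.calls:
                if sid not in seen:
                    seen.append(sid)
        sample_ids = seen
    contigs: list[str] = []
    for rec in records:
        if rec.chrom not in contigs:
            contigs.append(rec.chrom)

    gt_of = {0: "0/0", 1: "0/1", 2: "1/1", None: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=kdprio\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for rec in records:
            qual = "." if rec.site_quality is None else f"{rec.site_quality:g}"
            cols = [
                rec.chrom,
                str(rec.pos),
                rec.rs_id or ".",
                rec.ref_allele,
                rec.alt_allele,
                qual,
                "PASS",
                ".",
                "GT:GQ:DP",
            ]
            for sid in sample_ids:
                call = rec.calls.get(sid)
                if call is None:
                    cols.append("./.:.:.")
                    continue
                gq = "." if call.call_quality is None else str(int(round(call.call_quality)))
                dp = "." if call.read_depth is None else str(int(call.read_depth))
                cols.append(f"{gt_of[call.allele_dose]}:{gq}:{dp}")
            fh.write("\t".join(cols) + "\n")


_PHENOTYPE_CODES = {"2": True, "1": False, "0": None, "-9": None}


def read_ped(path: str | os.PathLike) -> Pedigree:
    """Parse a 6-column whitespace-delimited PED file.

    Phenotype codes: 2 = affected, 1 = unaffected, 0/-9 = unknown.  A "0"
    parent entry marks a founder; a parent id with no own row is fatal.
    """
    members: list[PedigreeMember] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 PED columns, got {len(fields)}")
            _fam, sid, father, mother, sex, pheno = fields[:6]
            if pheno not in _PHENOTYPE_CODES:
                raise ValueError(
                    f"{path}:{lineno}: unknown phenotype code {pheno!r} "
                    "(expected 2/1/0/-9)"
                )
            members.append(
                PedigreeMember(
                    sample_id=sid,
                    father_id=None if father == "0" else father,
                    mother_id=None if mother == "0" else mother,
                    sex=int(sex) if sex in ("0", "1", "2") else 0,
                    affected=_PHENOTYPE_CODES[pheno],
                )
            )
    return Pedigree(members)  # dangling-parent check lives in Pedigree


def write_ped(pedigree: Pedigree, path: str | os.PathLike, family_id: str = "FAM1") -> None:
    code = {True: "2", False: "1", None: "0"}
    with open(path, "w") as fh:
        for m in pedigree:
            fh.write(
                "\t".join(
                    [
                        family_id,
                        m.sample_id,
                        m.father_id or "0",
                        m.mother_id or "0",
                        str(m.sex),
                        code[m.affected],
                    ]
                )
                + "\n"
            )


def read_annotations(path: str | os.PathLike) -> dict[tuple, VariantAnnotation]:
    """Read the annotation TSV into a map keyed by (chrom, pos, ref, alt).

    Expected header: rs_id, chrom, pos, ref, alt, gene, region_class,
    consequence_class, any number of af_<POP> columns, gwas_p.  Empty cells
    mean "unknown".
    """
    import csv

    out: dict[tuple, VariantAnnotation] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"chrom", "pos", "ref", "alt", "gene", "region_class"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"annotation table {path} lacks required columns {sorted(required)}")
        af_cols = [c for c in reader.fieldnames if c.startswith("af_")]
        for row in reader:
            freqs = {}
            for c in af_cols:
                cell = (row.get(c) or "").strip()
                if cell:
                    freqs[c[3:]] = float(cell)
            gwas_cell = (row.get("gwas_p") or "").strip()
            ann = VariantAnnotation(
                gene=row["gene"],
                region_class=row["region_class"],
                consequence_class=(row.get("consequence_class") or "noncoding").strip()
                or "noncoding",
                allele_frequencies=freqs,
                gwas_p=float(gwas_cell) if gwas_cell else None,
            )
            out[(row["chrom"], int(row["pos"]), row["ref"], row["alt"])] = ann
    return out


def write_annotations(
    records: Sequence[VariantRecord], path: str | os.PathLike, populations: Sequence[str] = ("ALL",)
) -> None:
    with open(path, "w") as fh:
        af_cols = [f"af_{p}" for p in populations]
        fh.write(
            "\t".join(
                ["rs_id", "chrom", "pos", "ref", "alt", "gene", "region_class",
                 "consequence_class", *af_cols, "gwas_p"]
            )
            + "\n"
        )
        for rec in records:
            ann = rec.annotation
            if ann is None:
                raise AnnotationError(f"record {rec.label()} has no annotation to write")
            afs = [
                f"{ann.allele_frequencies[p]:g}" if p in ann.allele_frequencies else ""
                for p in populations
            ]
            fh.write(
                "\t".join(
                    [
                        rec.rs_id or "",
                        rec.chrom,
                        str(rec.pos),
                        rec.ref_allele,
                        rec.alt_allele,
                        ann.gene,
                        ann.region_class,
                        ann.consequence_class,
                        *afs,
                        "" if ann.gwas_p is None else f"{ann.gwas_p:g}",
                    ]
                )
                + "\n"
            )


def attach_annotations(
    records: Iterable[VariantRecord],
    annotations: Mapping[tuple, VariantAnnotation],
    strict: bool = False,
) -> list[VariantRecord]:
    """Return records with annotations attached by (chrom, pos, ref, alt) key."""
    out = []
    for rec in records:
        ann = annotations.get(rec.key())
        if ann is None and strict:
            raise AnnotationError(f"no annotation for {rec.label()}")
        out.append(rec.with_annotation(ann) if ann is not None else rec)
    return out


def read_gene_list(path: str | os.PathLike) -> set[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    genes: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.add(line)
    return genes


def read_evidence(path: str | os.PathLike) -> dict[str, GeneEvidence]:
    """Per-gene evidence TSV: gene, in_kd_pathway (0/1), de_fold_change, de_adj_p."""
    import csv

    out: dict[str, GeneEvidence] = {}
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out[row["gene"]] = GeneEvidence(
                gene=row["gene"],
                in_kd_pathway=row["in_kd_pathway"].strip() in ("1", "true", "True"),
                de_fold_change=float(row["de_fold_change"]),
                de_adj_p=float(row["de_adj_p"]),
            )
    return out


def write_evidence(evidence: Mapping[str, GeneEvidence], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tin_kd_pathway\tde_fold_change\tde_adj_p\n")
        for ev in evidence.values():
            fh.write(
                f"{ev.gene}\t{int(ev.in_kd_pathway)}\t{ev.de_fold_change:g}\t{ev.de_adj_p:g}\n"
            )


def confidence_filter(
    records: Sequence[VariantRecord], config: FilterConfig | None = None
) -> list[VariantRecord]:
    """Keep records whose every non-missing call meets the quality/depth bars.

    With ``quality_scope="sample"`` (default) the phred genotype quality of
    each call must be >= ``min_call_quality``; with ``"site"`` the VCF QUAL
    of the record is used instead.  Read depth is always judged per sample.
    Missing calls impose no requirement here (the inheritance filters handle
    them).  Records whose annotated gene is blacklisted (the "most exonically
    variable genes" exclusion) are dropped.  Order is preserved.
    """
    if config is None:
        config = FilterConfig()
    out: list[VariantRecord] = []
    for rec in records:
        if rec.gene is not None and rec.gene in config.blacklist_genes:
            continue
        ok = True
        if config.quality_scope == "site":
            if rec.site_quality is not None and rec.site_quality < config.min_call_quality:
                ok = False
        for call in rec.calls.values():
            if call.is_missing:
                continue
            if config.quality_scope == "sample":
                if call.call_quality is not None and call.call_quality < config.min_call_quality:
                    ok = False
                    break
            if call.read_depth is not None and call.read_depth < config.min_read_depth:
                ok = False
                break
        if ok:
            out.append(rec)
    return out
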