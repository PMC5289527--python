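"""Core data model for the family-based variant prioritization pipeline.

The unit flowing through every filter is a :class:`VariantRecord`: one
biallelic site with a :class:`GenotypeCall` per pedigree member and an
optional :class:`VariantAnnotation`.  Multi-allelic VCF sites are split into
one record per alternate allele on ingest, so ``allele_dose`` always counts
copies of a single alternate allele.

Coordinates follow the VCF convention (1-based, fully closed).  A missing
genotype is represented by ``allele_dose is None``; missing calls carry no
quality/depth requirement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "GenotypeCall",
    "VariantAnnotation",
    "VariantRecord",
    "PedigreeMember",
    "Pedigree",
    "FilterConfig",
    "GeneEvidence",
    "CompoundHetPair",
    "TierAssignment",
    "TIER1",
    "TIER2",
    "REJECTED",
    "REGION_CLASSES",
    "CONSEQUENCE_CLASSES",
    "CODING_CONSEQUENCES",
    "PedigreeError",
    "AnnotationError",
]

FOUNDER = None  # parent slot of a pedigree founder

TIER1 = "TIER1"
TIER2 = "TIER2"
REJECTED = "REJECTED"

REGION_CLASSES = frozenset(
    {"exon", "promoter", "splice_site", "utr3", "utr5", "intron", "intergenic"}
)
CONSEQUENCE_CLASSES = frozenset(
    {
        "frameshift",
        "inframe_indel",
        "start_stop_change",
        "missense",
        "splice_loss",
        "synonymous",
        "noncoding",
    }
)
#: consequence classes that can only occur in exonic/splice-site sequence
CODING_CONSEQUENCES = frozenset(
    {"frameshift", "inframe_indel", "start_stop_change", "missense", "splice_loss", "synonymous"}
)


class PedigreeError(ValueError):
    """Raised when a pedigree is structurally unusable for a filter."""


class AnnotationError(ValueError):
    """Raised when a record lacks the annotation a filter requires."""


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's diploid genotype at one biallelic site.

    ``allele_dose`` is the count of alternate alleles (0, 1 or 2), or ``None``
    for a missing call.  ``call_quality`` is the phred-scaled genotype quality
    (GQ) and ``read_depth`` the per-sample depth (DP); either may be ``None``
    when the VCF omits the field.
    """

    sample_id: str
    allele_dose: Optional[int]
    call_quality: Optional[float] = None
    read_depth: Optional[int] = None

    def __post_init__(self) -> None:
        if self.allele_dose is not None and self.allele_dose not in (0, 1, 2):
            raise ValueError(f"allele_dose must be 0/1/2 or None, got {self.allele_dose!r}")
        if self.call_quality is not None and self.call_quality < 0:
            raise ValueError("call_quality must be >= 0")
        if self.read_depth is not None and self.read_depth < 0:
            raise ValueError("read_depth must be >= 0")

    @property
    def is_missing(self) -> bool:
        return self.allele_dose is None


@dataclass(frozen=True)
class VariantAnnotation:
    """Functional annotation of one variant allele.

    ``allele_frequencies`` maps population label -> alternate-allele frequency
    in [0, 1]; an absent population means "frequency unknown there".  ``gwas_p``
    is the nominal case-control association p-value, ``None`` when the variant
    was not typed/imputed in the association study.
    """

    gene: str
    region_class: str
    consequence_class: str = "noncoding"
    allele_frequencies: Mapping[str, float] = field(default_factory=dict)
    gwas_p: Optional[float] = None

    def __post_init__(self) -> None:
        if self.region_class not in REGION_CLASSES:
            raise ValueError(f"unknown region_class {self.region_class!r}")
        if self.consequence_class not in CONSEQUENCE_CLASSES:
            raise ValueError(f"unknown consequence_class {self.consequence_class!r}")
        if self.consequence_class in CODING_CONSEQUENCES and self.region_class not in (
            "exon",
            "splice_site",
        ):
            raise ValueError(
                f"coding consequence {self.consequence_class!r} requires exon/splice_site "
                f"region, got {self.region_class!r}"
            )
        for pop, f in self.allele_frequencies.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"allele frequency for {pop} out of [0,1]: {f}")
        if self.gwas_p is not None and not 0.0 < self.gwas_p <= 1.0:
            raise ValueError(f"gwas_p must be in (0,1], got {self.gwas_p}")


@dataclass
class VariantRecord:
    """One biallelic variant with per-sample genotype calls."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    rs_id: Optional[str] = None
    calls: dict[str, GenotypeCall] = field(default_factory=dict)
    annotation: Optional[VariantAnnotation] = None
    site_quality: Optional[float] = None

    @property
    def gene(self) -> Optional[str]:
        return self.annotation.gene if self.annotation is not None else None

    def dose(self, sample_id: str) -> Optional[int]:
        return self.calls[sample_id].allele_dose

    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)

    def label(self) -> str:
        return self.rs_id or f"{self.chrom}:{self.pos}:{self.ref_allele}>{self.alt_allele}"

    def with_annotation(self, annotation: VariantAnnotation) -> "VariantRecord":
        return replace(self, annotation=annotation)


@dataclass(frozen=True)
class PedigreeMember:
    sample_id: str
    father_id: Optional[str]  # None = founder
    mother_id: Optional[str]
    sex: int  # 1 male, 2 female, 0 unknown
    affected: Optional[bool]  # None = unknown phenotype


@dataclass
class Pedigree:
    """Sample relationships and affection status driving the inheritance filters."""

    members: list[PedigreeMember]

    def __post_init__(self) -> None:
        ids = [m.sample_id for m in self.members]
        if len(set(ids)) != len(ids):
            raise PedigreeError("duplicate sample ids in pedigree")
        known = set(ids)
        for m in self.members:
            for parent in (m.father_id, m.mother_id):
                if parent is not None and parent not in known:
                    raise PedigreeError(
                        f"member {m.sample_id!r} references unknown parent {parent!r}"
                    )

    def __iter__(self):
        return iter(self.members)

    def __len__(self) -> int:
        return len(self.members)

    @property
    def sample_ids(self) -> list[str]:
        return [m.sample_id for m in self.members]

    @property
    def affected_ids(self) -> list[str]:
        return [m.sample_id for m in self.members if m.affected is True]

    @property
    def unaffected_ids(self) -> list[str]:
        return [m.sample_id for m in self.members if m.affected is False]

    def member(self, sample_id: str) -> PedigreeMember:
        for m in self.members:
            if m.sample_id == sample_id:
                return m
        raise KeyError(sample_id)

    def founder_parents_of_affected(self) -> tuple[str, str]:
        """The (father_id, mother_id) couple shared by all affected members.

        The compound-het rules reason about "the" two parents; they are only
        defined when every affected member has the same two genotyped parents.
        """
        couples = {
            (m.father_id, m.mother_id) for m in self.members if m.affected is True
        }
        if len(couples) != 1:
            raise PedigreeError("affected members do not share a single parent couple")
        father, mother = couples.pop()
        if father is None or mother is None:
            raise PedigreeError("affected members must have both parents in the pedigree")
        return father, mother


@dataclass
class FilterConfig:
    """Every numeric threshold of the prioritization workflow, with the
    study defaults: genotype quality >= 20, depth >= 10, rare means allele
    frequency < 1% (recessive-homozygous branch) or < 3% (compound-het
    branch), GWAS nominal p < 0.05, differential expression |fold change|
    >= 1.2 with BH-adjusted p < 0.05, eQTL nominal alpha 0.001.
    """

    min_call_quality: float = 20.0
    min_read_depth: int = 10
    rare_af_homozygous: float = 0.01
    rare_af_compound_het: float = 0.03
    gwas_alpha: float = 0.05
    de_fold_change: float = 1.2
    de_adj_alpha: float = 0.05
    eqtl_alpha: float = 0.001
    blacklist_genes: frozenset[str] = frozenset()
    quality_scope: str = "sample"  # "sample" (per-genotype GQ) or "site" (VCF QUAL)
    deleterious_mode: str = "region"  # "region" or "consequence"
    missing_policy: str = "strict"  # "strict" or "lenient" (inheritance filters)
    rare_populations: Optional[frozenset[str]] = None  # None = all with data

    def __post_init__(self) -> None:
        for name in ("min_call_quality", "min_read_depth", "rare_af_homozygous",
                     "rare_af_compound_het", "de_fold_change"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("gwas_alpha", "de_adj_alpha", "eqtl_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0,1)")
        if self.quality_scope not in ("sample", "site"):
            raise ValueError("quality_scope must be 'sample' or 'site'")
        if self.deleterious_mode not in ("region", "consequence"):
            raise ValueError("deleterious_mode must be 'region' or 'consequence'")
        if self.missing_policy not in ("strict", "lenient"):
            raise ValueError("missing_policy must be 'strict' or 'lenient'")
        if isinstance(self.blacklist_genes, (list, set, tuple)):
            object.__setattr__(self, "blacklist_genes", frozenset(self.blacklist_genes))

    @classmethod
    def from_yaml(cls, path) -> "FilterConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        return cls(**raw)


@dataclass(frozen=True)
class GeneEvidence:
    """Per-gene pathway membership and acute-vs-convalescent differential
    expression summary.  ``de_fold_change`` is the acute/convalescent ratio
    (>0, <1 means lower in acute); ``de_adj_p`` the BH-adjusted paired-test p.
    """

    gene: str
    in_kd_pathway: bool
    de_fold_change: float
    de_adj_p: float

    def __post_init__(self) -> None:
        if self.de_fold_change <= 0:
            raise ValueError("de_fold_change must be > 0")
        if not 0.0 < self.de_adj_p <= 1.0:
            raise ValueError("de_adj_p must be in (0,1]")


@dataclass(frozen=True)
class CompoundHetPair:
    """Two variants in the same gene, one inherited from each parent, jointly
    knocking out both copies in the affected children (trans configuration)."""

    gene: str
    maternal_variant: VariantRecord
    paternal_variant: VariantRecord


@dataclass
class TierAssignment:
    """Final label for one variant, with the ordered trail of every filter
    stage evaluated (stage name, passed)."""

    variant: VariantRecord
    tier: str  # TIER1 / TIER2 / REJECTED
    inheritance_mode: Optional[str]  # "HR", "CH" or None
    trail: list[tuple[str, bool]] = field(default_factory=list)

    def failed_stages(self) -> list[str]:
        return [name for name, ok in self.trail if not ok]
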