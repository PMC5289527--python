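import pytest

from kdprio import (
    GenotypeCall,
    VariantAnnotation,
    VariantRecord,
    default_family_pedigree,
    fixtures_tables,
)

SAMPLE_ORDER = ("KD1", "KD2", "NK1", "NK2", "MO", "FA")


def make_record(doses, gene="GENE1", pos=100, rs_id=None, gq=99.0, dp=30,
                region="exon", consequence="missense", freqs=None, gwas_p=None):
    """Record with doses given in (KD1, KD2, NK1, NK2, MO, FA) order."""
    calls = {
        sid: GenotypeCall(sid, dose, call_quality=gq, read_depth=dp)
        for sid, dose in zip(SAMPLE_ORDER, doses)
    }
    return VariantRecord(
        chrom="1",
        pos=pos,
        ref_allele="A",
        alt_allele="G",
        rs_id=rs_id,
        calls=calls,
        site_quality=100.0,
        annotation=VariantAnnotation(
            gene=gene,
            region_class=region,
            consequence_class=consequence,
            allele_frequencies=freqs or {},
            gwas_p=gwas_p,
        ),
    )


@pytest.fixture(scope="session")
def family():
    return default_family_pedigree()


@pytest.fixture(scope="session")
def tables():
    return fixtures_tables()
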