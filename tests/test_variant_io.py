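"""VCF/PED ingestion and the genotype-confidence filter."""

import dataclasses

import numpy as np
import pytest

from kdprio import (
    FilterConfig,
    PedigreeError,
    SimulationSpec,
    confidence_filter,
    read_ped,
    read_vcf,
    simulate_family,
    write_ped,
    write_vcf,
)
from conftest import SAMPLE_ORDER, make_record

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=1>\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
    '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="q">\n'
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
    "KD1\tKD2\tNK1\tNK2\tMO\tFA\n"
)

PED_TEXT = (
    "FAM1 FA 0 0 1 1\n"
    "FAM1 MO 0 0 2 1\n"
    "FAM1 KD1 FA MO 1 2\n"
    "FAM1 KD2 FA MO 1 2\n"
    "FAM1 NK1 FA MO 1 1\n"
    "FAM1 NK2 FA MO 2 1\n"
)


def write_text(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return str(path)


def test_read_vcf_maps_genotypes_to_doses(tmp_path, family):
    gts = ["0/1", "0/1", "0/0", "0/0", "0/1", "0/1"]
    line = "1\t100\trs1\tA\tG\t50\tPASS\t.\tGT:GQ:DP\t" + "\t".join(
        f"{g}:40:22" for g in gts
    )
    vcf = write_text(tmp_path, "a.vcf", VCF_HEADER + line + "\n")
    records = read_vcf(vcf, family)
    assert len(records) == 1
    rec = records[0]
    assert [rec.dose(s) for s in SAMPLE_ORDER] == [1, 1, 0, 0, 1, 1]
    assert rec.calls["KD1"].call_quality == 40
    assert rec.calls["KD1"].read_depth == 22
    assert rec.rs_id == "rs1"


def test_multiallelic_site_splits_and_conserves_alt_content(tmp_path, family):
    # genotypes mix both alts; split records count each alt separately
    gts = ["1/2", "0/1", "2/2", "0/0", "0/2", "1/1"]
    line = "1\t200\t.\tA\tC,G\t50\tPASS\t.\tGT\t" + "\t".join(gts)
    vcf = write_text(tmp_path, "m.vcf", VCF_HEADER + line + "\n")
    records = read_vcf(vcf, family)
    assert len(records) == 2
    assert {r.alt_allele for r in records} == {"C", "G"}
    by_alt = {r.alt_allele: r for r in records}
    assert [by_alt["C"].dose(s) for s in SAMPLE_ORDER] == [1, 1, 0, 0, 0, 2]
    assert [by_alt["G"].dose(s) for s in SAMPLE_ORDER] == [1, 0, 2, 0, 1, 0]
    # total alt content per sample is conserved across the split
    for sid, gt in zip(SAMPLE_ORDER, gts):
        expected = sum(a != "0" for a in gt.split("/"))
        assert by_alt["C"].dose(sid) + by_alt["G"].dose(sid) == expected


def test_missing_genotype_and_absent_sample(tmp_path, family):
    line = "1\t300\t.\tA\tG\t50\tPASS\t.\tGT\t./.\t0/1\t0/0\t0/0\t0/1\t0/0"
    vcf = write_text(tmp_path, "x.vcf", VCF_HEADER + line + "\n")
    rec = read_vcf(vcf, family)[0]
    assert rec.calls["KD1"].is_missing
    bad_header = VCF_HEADER.replace("\tFA\n", "\tZZ\n")
    vcf2 = write_text(tmp_path, "bad.vcf", bad_header + line + "\n")
    with pytest.raises(PedigreeError):
        read_vcf(vcf2, family)


def test_vcf_round_trip_preserves_simulated_doses(tmp_path):
    spec = SimulationSpec(seed=11, n_variants=100)
    records, ped = simulate_family(spec)
    path = tmp_path / "sim.vcf"
    write_vcf(records, path, sample_ids=ped.sample_ids)
    back = read_vcf(str(path), ped)
    assert len(back) == len(records)
    for a, b in zip(records, back):
        assert a.key() == b.key()
        for sid in ped.sample_ids:
            assert a.dose(sid) == b.dose(sid)
            assert a.calls[sid].call_quality == b.calls[sid].call_quality
            assert a.calls[sid].read_depth == b.calls[sid].read_depth


def test_read_ped_study_family(tmp_path):
    ped = read_ped(write_text(tmp_path, "fam.ped", PED_TEXT))
    assert len(ped) == 6
    assert set(ped.affected_ids) == {"KD1", "KD2"}
    assert len(ped.unaffected_ids) == 4
    assert ped.member("FA").father_id is None  # founder
    assert ped.founder_parents_of_affected() == ("FA", "MO")


def test_ped_round_trip(tmp_path, family):
    path = tmp_path / "rt.ped"
    write_ped(family, path)
    back = read_ped(str(path))
    assert back.members == family.members


@pytest.mark.parametrize(
    "text,match",
    [
        ("FAM1 A 0 0 1 5\n", "phenotype"),
        ("FAM1 A F9 0 1 1\n", "F9"),
    ],
)
def test_read_ped_fatal_errors(tmp_path, text, match):
    with pytest.raises((ValueError, PedigreeError), match=match):
        read_ped(write_text(tmp_path, "bad.ped", text))


def test_single_founder_pedigree(tmp_path):
    ped = read_ped(write_text(tmp_path, "one.ped", "F X 0 0 2 1\n"))
    assert len(ped) == 1 and ped.unaffected_ids == ["X"]


class TestConfidenceFilter:
    def test_boundaries_are_inclusive(self):
        at = make_record([1, 1, 0, 0, 1, 1], gq=20.0, dp=10)
        below_gq = make_record([1, 1, 0, 0, 1, 1], gq=19.0, dp=30)
        below_dp = make_record([1, 1, 0, 0, 1, 1], gq=99.0, dp=9)
        out = confidence_filter([at, below_gq, below_dp])
        assert out == [at]

    def test_one_bad_sample_removes_record(self):
        rec = make_record([1, 1, 0, 0, 1, 1])
        rec.calls["FA"] = dataclasses.replace(rec.calls["FA"], call_quality=19.0)
        assert confidence_filter([rec]) == []

    def test_missing_calls_pass_and_blacklist_drops(self):
        rec = make_record([1, 1, 0, 0, 1, None], gene="MUC4")
        assert confidence_filter([rec]) == [rec]
        cfg = FilterConfig(blacklist_genes=frozenset({"MUC4"}))
        assert confidence_filter([rec], cfg) == []

    def test_site_quality_scope(self):
        rec = make_record([1, 1, 0, 0, 1, 1], gq=5.0)  # bad GQ, good site QUAL
        cfg = FilterConfig(quality_scope="site")
        assert confidence_filter([rec], cfg) == [rec]
        assert confidence_filter([rec]) == []

    def test_survivor_count_matches_brute_force_recount(self):
        rng = np.random.default_rng(3)
        records = []
        for i in range(500):
            gq = rng.integers(0, 60, size=6).astype(float)
            dp = rng.integers(0, 30, size=6)
            calls = [
                (int(d), float(q), int(p))
                for d, q, p in zip(rng.integers(0, 3, size=6), gq, dp)
            ]
            rec = make_record([c[0] for c in calls], pos=i + 1)
            for sid, (_, q, p) in zip(SAMPLE_ORDER, calls):
                rec.calls[sid] = dataclasses.replace(
                    rec.calls[sid], call_quality=q, read_depth=p
                )
            records.append(rec)
        survivors = confidence_filter(records)
        # independent per-record recount
        expected = sum(
            all(c.call_quality >= 20 and c.read_depth >= 10 for c in r.calls.values())
            for r in records
        )
        assert len(survivors) == expected

    def test_idempotent_and_monotone_in_quality_threshold(self):
        rng = np.random.default_rng(4)
        records = []
        for i in range(200):
            rec = make_record(rng.integers(0, 3, size=6).tolist(), pos=i + 1,
                              gq=float(rng.integers(0, 60)), dp=int(rng.integers(0, 40)))
            records.append(rec)
        out = confidence_filter(records)
        assert confidence_filter(out) == out
        counts = [
            len(confidence_filter(records, FilterConfig(min_call_quality=q)))
            for q in (1, 10, 20, 40, 60)
        ]
        assert counts == sorted(counts, reverse=True)
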