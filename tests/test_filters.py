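"""Frequency/recurrence filters and inheritance classification."""

import copy

import pandas as pd
import pytest

from dosecnv import (
    CnvCall,
    CommonCnvDb,
    CommonCnvRecord,
    PedigreeTable,
    SnpGenotypeTable,
    classify_inheritance,
    filter_common,
    filter_recurrent,
    infer_denovo_deletion,
    overlap_fraction,
    reciprocal_overlap,
)


def make_call(sample="P1", chrom="chr1", start=0, end=1000, type="del", score=None):
    return CnvCall(
        sample=sample, chrom=chrom, start=start, end=end, type=type,
        n_probes=3, mean_score=score if score is not None else (-2.5 if type == "del" else 2.5),
    )


# ---------------------------------------------------------------- overlap


@pytest.mark.parametrize(
    "a, b, expected",
    [
        (("chr1", 0, 100), ("chr1", 0, 100), (1.0, 1.0)),
        (("chr1", 0, 100), ("chr1", 200, 300), (0.0, 0.0)),
        (("chr1", 0, 100), ("chr1", 50, 150), (0.5, 0.5)),
        (("chr1", 0, 100), ("chr2", 0, 100), (0.0, 0.0)),
        (("chr1", 0, 400), ("chr1", 100, 200), (0.25, 1.0)),
    ],
)
def test_overlap_fraction_cases(a, b, expected):
    assert overlap_fraction(a, b) == pytest.approx(expected)
    # swapping roles swaps the fractions
    assert overlap_fraction(b, a) == pytest.approx(expected[::-1])


from hypothesis import given, settings, strategies as st


@settings(derandomize=True, max_examples=200)
@given(st.integers(0, 10_000), st.integers(1, 5_000),
       st.integers(0, 10_000), st.integers(1, 5_000))
def test_overlap_fraction_bounds_and_swap_symmetry(sa, la, sb, lb):
    a, b = ("chr1", sa, sa + la), ("chr1", sb, sb + lb)
    fa, fb = overlap_fraction(a, b)
    assert 0.0 <= fa <= 1.0 and 0.0 <= fb <= 1.0
    assert overlap_fraction(b, a) == (fb, fa)
    # intersection length is shared: fa*|a| == fb*|b|
    assert fa * la == pytest.approx(fb * lb)


def test_overlap_fraction_rejects_zero_length():
    with pytest.raises(ValueError):
        overlap_fraction(("chr1", 5, 5), ("chr1", 0, 10))


def test_reciprocal_overlap_is_min_of_fractions():
    assert reciprocal_overlap(("chr1", 0, 400), ("chr1", 100, 200)) == 0.25


# ---------------------------------------------------------------- common filter


def db_with(maf=0.02, study_n=100, start=0, end=10_000):
    return CommonCnvDb([CommonCnvRecord("chr1", start, end, maf, study_n)])


def test_filter_common_marks_call_inside_frequent_record():
    calls = [make_call(start=1000, end=2000)]
    filter_common(calls, db_with(maf=0.02, study_n=100))
    assert calls[0].filter_status == "common"


@pytest.mark.parametrize(
    "kwargs, status",
    [
        ({"maf": 0.005}, "pass"),           # below the MAF threshold
        ({"maf": 0.01}, "common"),          # MAF boundary is inclusive
        ({"study_n": 40}, "pass"),          # study size must exceed 40
        ({"study_n": 41}, "common"),
    ],
)
def test_filter_common_frequency_boundaries(kwargs, status):
    calls = [make_call(start=1000, end=2000)]
    filter_common(calls, db_with(**kwargs))
    assert calls[0].filter_status == status


def test_filter_common_overlap_boundary():
    # db record covers exactly 79% vs 80% of the call
    calls = [make_call(start=0, end=1000)]
    filter_common(calls, db_with(start=210, end=10_000))  # covers 790/1000
    assert calls[0].filter_status == "pass"
    calls = [make_call(start=0, end=1000)]
    filter_common(calls, db_with(start=200, end=10_000))  # covers 800/1000
    assert calls[0].filter_status == "common"


def test_filter_common_one_way_vs_reciprocal():
    # small call engulfed by a huge common CNV: flagged one-way, not reciprocal
    calls = [make_call(start=1000, end=2000)]
    big = db_with(start=0, end=100_000)
    filter_common(calls, big, reciprocal=True)
    assert calls[0].filter_status == "pass"
    filter_common(calls, big)
    assert calls[0].filter_status == "common"


# ---------------------------------------------------------------- recurrence


def test_filter_recurrent_more_than_ten_individuals():
    eleven = [make_call(sample=f"S{i}") for i in range(11)]
    filter_recurrent(eleven)
    assert all(c.filter_status == "recurrent" for c in eleven)

    ten = [make_call(sample=f"S{i}") for i in range(10)]
    filter_recurrent(ten)
    assert all(c.filter_status == "pass" for c in ten)


def test_filter_recurrent_counts_individuals_not_events():
    # 12 events from 6 individuals (two loci each merging by overlap)
    calls = [make_call(sample=f"S{i % 6}") for i in range(12)]
    filter_recurrent(calls)
    assert all(c.filter_status == "pass" for c in calls)


def test_filter_recurrent_requires_same_type_and_overlap():
    dels = [make_call(sample=f"S{i}", type="del") for i in range(6)]
    dups = [make_call(sample=f"D{i}", type="dup") for i in range(6)]
    filter_recurrent(dels + dups)  # 12 carriers but two type-strata of 6
    assert all(c.filter_status == "pass" for c in dels + dups)


def test_filters_commute_on_status_outcomes():
    def fresh():
        common_and_recurrent = [
            make_call(sample=f"S{i}", start=1000, end=2000) for i in range(11)
        ]
        unique = [make_call(sample="U", chrom="chr2")]
        return common_and_recurrent + unique

    db = db_with()
    a = fresh()
    filter_common(a, db)
    filter_recurrent(a)
    b = fresh()
    filter_recurrent(b)
    filter_common(b, db)
    assert [c.filter_status for c in a] == [c.filter_status for c in b]
    # idempotent
    again = [c.filter_status for c in a]
    filter_common(a, db)
    filter_recurrent(a)
    assert [c.filter_status for c in a] == again


def test_filters_never_mutate_intervals(called_cohort):
    _, _, calls = called_cohort
    calls = copy.deepcopy(calls)
    before = [(c.sample, c.chrom, c.start, c.end, c.type) for c in calls]
    filter_recurrent(calls)
    assert [(c.sample, c.chrom, c.start, c.end, c.type) for c in calls] == before
    assert len(calls) == len(before)


# ---------------------------------------------------------------- inheritance


def trio_pedigree():
    return PedigreeTable(
        pd.DataFrame(
            {
                "proband": ["P1", "P2", "P3"],
                "mother": ["M1", "", "M3"],
                "father": ["F1", "F2", ""],
                "sex": ["F", "M", "F"],
            }
        )
    )


def test_classify_inheritance_parental_match_and_de_novo():
    ped = trio_pedigree()
    proband = make_call("P1", start=0, end=5000)
    maternal = make_call("M1", start=0, end=5000)
    assert classify_inheritance(proband, ped, [proband, maternal]) == "maternal"
    assert classify_inheritance(proband, ped, [proband]) == "de_novo"


def test_classify_inheritance_double_match_prefers_mother():
    ped = trio_pedigree()
    proband = make_call("P1")
    both = [proband, make_call("M1"), make_call("F1")]
    assert classify_inheritance(proband, ped, both) == "maternal"


def test_classify_inheritance_incomplete_families():
    ped = trio_pedigree()
    # duo with father only, no parental match -> unknown (not de novo)
    duo_call = make_call("P2")
    assert classify_inheritance(duo_call, ped, [duo_call]) == "unknown"
    # matching call in the present father
    assert classify_inheritance(duo_call, ped, [duo_call, make_call("F2")]) == "paternal"


def test_classify_inheritance_requires_overlap_threshold():
    ped = trio_pedigree()
    proband = make_call("P1", start=0, end=1000)
    shifted = make_call("M1", start=600, end=1600)  # reciprocal overlap 0.4
    assert classify_inheritance(proband, ped, [proband, shifted]) == "de_novo"


def test_classify_inheritance_rejects_non_proband():
    ped = trio_pedigree()
    with pytest.raises(KeyError):
        classify_inheritance(make_call("M1"), ped, [])


# ---------------------------------------------------------------- duo inference


def genotype_table(rows):
    return SnpGenotypeTable(
        pd.DataFrame(rows, columns=["sample", "chrom", "pos", "alleles"])
    )


def test_infer_denovo_from_incompatible_haplotype():
    # parent homozygous G/G, proband's remaining allele A at two sites:
    # the surviving haplotype cannot come from the genotyped parent
    gt = genotype_table(
        [("P1", "chr1", 100, "A"), ("P1", "chr1", 200, "A"),
         ("M1", "chr1", 100, "G/G"), ("M1", "chr1", 200, "G/G")]
    )
    call = make_call("P1", start=0, end=1000, type="del")
    assert infer_denovo_deletion(call, "M1", gt) == "de_novo_inferred"


def test_heterozygous_parent_sites_are_uninformative():
    gt = genotype_table(
        [("P1", "chr1", 100, "A"), ("P1", "chr1", 200, "C"),
         ("M1", "chr1", 100, "A/G"), ("M1", "chr1", 200, "C/T")]
    )
    call = make_call("P1", start=0, end=1000, type="del")
    assert infer_denovo_deletion(call, "M1", gt) == "ambiguous"


def test_compatible_haplotype_points_to_missing_parent():
    gt = genotype_table(
        [("P1", "chr1", p, "A") for p in (100, 200, 300)]
        + [("M1", "chr1", p, "A/A") for p in (100, 200, 300)]
    )
    call = make_call("P1", start=0, end=1000, type="del")
    assert infer_denovo_deletion(call, "M1", gt) == "on_missing_parent_haplotype"


def test_single_incompatible_site_is_ambiguous():
    gt = genotype_table(
        [("P1", "chr1", 100, "A"), ("M1", "chr1", 100, "G/G")]
    )
    call = make_call("P1", start=0, end=1000, type="del")
    assert infer_denovo_deletion(call, "M1", gt, min_informative=2) == "ambiguous"


def test_no_genotyped_sites_warns_and_is_ambiguous():
    gt = genotype_table([("P1", "chr2", 100, "A"), ("M1", "chr2", 100, "A/A")])
    call = make_call("P1", start=0, end=1000, type="del")
    with pytest.warns(RuntimeWarning, match="no genotyped sites"):
        assert infer_denovo_deletion(call, "M1", gt) == "ambiguous"


def test_infer_denovo_rejects_duplications():
    with pytest.raises(ValueError):
        infer_denovo_deletion(make_call(type="dup"), "M1", genotype_table([]))
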