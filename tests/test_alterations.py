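"""Damaging-alteration classification, CNV calling and molecular profiles."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from syssvm.alterations import (
    Consequence,
    CopyNumberSegment,
    DamagingCategory,
    DialectError,
    GeneInterval,
    SmallVariant,
    StructuralVariant,
    SVType,
    UnannotatedVariantError,
    assign_gene_cn,
    build_molecular_profiles,
    call_copy_number,
    classify_small_variant,
    cnv_damage,
    filter_variants,
)


def make_variant(consequence, func=0, cons=0, splice=0, vaf=0.5, indel=0, gof=False):
    return SmallVariant(
        sample_id="S1",
        gene_id="G1",
        consequence=consequence,
        vaf=vaf,
        indel_length=indel,
        functional_calls=tuple(i < func for i in range(7)),
        conservation_calls=tuple(i < cons for i in range(3)),
        splicing_calls=tuple(i < splice for i in range(2)),
        gof_flag=gof,
    )


def oracle_classification(consequence, func_votes, cons_votes, splice_votes):
    """Brute-force restatement of the damaging rules."""
    if consequence in (Consequence.STOPGAIN, Consequence.STOPLOSS, Consequence.FRAMESHIFT):
        return DamagingCategory.TRUNCATING
    if consequence is Consequence.SILENT:
        return None
    if consequence in (Consequence.NONSYNONYMOUS, Consequence.NONFRAMESHIFT):
        if func_votes >= 5 or cons_votes >= 2:
            return DamagingCategory.NON_TRUNCATING
        return None
    if consequence is Consequence.SPLICING:
        return DamagingCategory.SPLICING if splice_votes >= 1 else None
    raise AssertionError


def test_classification_matches_rule_oracle_on_all_vote_patterns():
    """Every consequence x 2^12 predictor-vote pattern agrees with the oracle."""
    for consequence in Consequence:
        for func in itertools.product([False, True], repeat=7):
            for cons in itertools.product([False, True], repeat=3):
                for splice in itertools.product([False, True], repeat=2):
                    v = SmallVariant(
                        "S", "G", consequence, vaf=0.5,
                        functional_calls=func, conservation_calls=cons,
                        splicing_calls=splice,
                    )
                    expected = oracle_classification(
                        consequence, sum(func), sum(cons), sum(splice)
                    )
                    assert classify_small_variant(v) == expected


@pytest.mark.parametrize(
    "consequence,func,cons,splice,expected",
    [
        (Consequence.STOPGAIN, 0, 0, 0, DamagingCategory.TRUNCATING),
        (Consequence.NONSYNONYMOUS, 4, 1, 0, None),
        (Consequence.NONSYNONYMOUS, 5, 0, 0, DamagingCategory.NON_TRUNCATING),
        (Consequence.NONFRAMESHIFT, 0, 2, 0, DamagingCategory.NON_TRUNCATING),
        (Consequence.SPLICING, 0, 0, 1, DamagingCategory.SPLICING),
        (Consequence.SPLICING, 0, 0, 0, None),
        (Consequence.SILENT, 7, 3, 2, None),
    ],
)
def test_classification_examples(consequence, func, cons, splice, expected):
    assert classify_small_variant(make_variant(consequence, func, cons, splice)) == expected


def test_missing_predictor_calls_raise_not_default():
    missense = SmallVariant("S", "G", Consequence.NONSYNONYMOUS, vaf=0.5)
    with pytest.raises(UnannotatedVariantError):
        classify_small_variant(missense)
    splicing = SmallVariant("S", "G", Consequence.SPLICING, vaf=0.5)
    with pytest.raises(UnannotatedVariantError):
        classify_small_variant(splicing)


def test_filter_variants_thresholds_and_order():
    batch = [
        make_variant(Consequence.SILENT, vaf=0.05),
        make_variant(Consequence.SILENT, vaf=0.12),
        make_variant(Consequence.FRAMESHIFT, vaf=0.3, indel=5),
        make_variant(Consequence.FRAMESHIFT, vaf=0.4, indel=6),
        make_variant(Consequence.SILENT, vaf=0.5),
    ]
    kept = filter_variants(batch)
    assert kept == [batch[1], batch[2], batch[4]]
    assert len(batch) == 5  # input untouched


def seg(mean=None, cn=None, start=0, end=1000, sample="S1", chrom="chr1", ploidy=2.0):
    return CopyNumberSegment(sample, chrom, start, end, segment_mean=mean,
                             absolute_cn=cn, sample_ploidy=ploidy)


def test_copy_number_conversion_examples():
    cn, state = call_copy_number(seg(mean=0.0))
    assert cn == 2.0 and state == "neutral"
    cn, state = call_copy_number(seg(mean=2.0))
    assert cn == pytest.approx(2 * 2**1.5) and state == "amplified"
    cn, state = call_copy_number(seg(mean=-0.5))
    assert cn == pytest.approx(2 * 2**-0.5) and state == "deleted"


def test_copy_number_monotone_in_segment_mean():
    means = [i / 100 - 3 for i in range(601)]
    cns = [call_copy_number(seg(mean=m))[0] for m in means]
    assert all(b >= a for a, b in zip(cns, cns[1:]))


def test_copy_number_rejects_absolute_dialect():
    with pytest.raises(DialectError):
        call_copy_number(seg(cn=4.0))


GENE = GeneInterval("G1", "chr1", 1000, 2000)


def test_gene_cn_below_overlap_threshold_stays_neutral():
    # 240/1000 bp = 24% overlap: below the 25% rule
    cn, state = assign_gene_cn(GENE, [seg(mean=1.0, start=0, end=1240)])
    assert (cn, state) == (2.0, "neutral")
    cn, state = assign_gene_cn(GENE, [seg(mean=1.0, start=0, end=1250)])
    assert state == "amplified"


def test_gene_cn_tie_rule_largest_overlap_wins():
    a = seg(cn=6.0, start=900, end=1300)   # 300 bp overlap
    b = seg(cn=1.0, start=1740, end=2500)  # 260 bp overlap
    cn, _ = assign_gene_cn(GENE, [a, b])
    assert cn == 6.0
    cn, _ = assign_gene_cn(GENE, [b, a])
    assert cn == 6.0


def test_gene_cn_fully_contained_takes_segment_cn():
    cn, state = assign_gene_cn(GENE, [seg(mean=1.0, start=0, end=10_000)])
    assert cn == pytest.approx(4.0)
    assert state == "amplified"


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.permutations(range(4)), st.data())
def test_gene_cn_permutation_invariant(perm, data):
    segs = []
    for i in range(4):
        start = data.draw(st.integers(min_value=0, max_value=1900))
        length = data.draw(st.integers(min_value=100, max_value=1500))
        mean = data.draw(st.floats(min_value=-2, max_value=2, allow_nan=False))
        segs.append(seg(mean=round(mean, 3), start=start, end=start + length))
    baseline = assign_gene_cn(GENE, segs)
    shuffled = [segs[i] for i in perm]
    assert assign_gene_cn(GENE, shuffled) == baseline


def test_ploidy_corrected_gain_and_homozygous_loss():
    assert cnv_damage(5.0, sample_ploidy=4.0) == "gain"
    assert cnv_damage(4.0, sample_ploidy=4.0) is None  # at ploidy: no gain
    assert cnv_damage(3.0, sample_ploidy=2.0) == "gain"
    assert cnv_damage(0.0, sample_ploidy=2.0) == "loss"
    assert cnv_damage(1.0, sample_ploidy=2.0) is None  # hemizygous: not damaging
    assert cnv_damage(0.4, sample_ploidy=2.0, hom_loss_max=0.5) == "loss"


def test_profile_from_single_stopgain():
    profiles = build_molecular_profiles([make_variant(Consequence.STOPGAIN)])
    assert len(profiles) == 1
    p = profiles[0]
    assert p.truncating == 1 and p.total_exonic_mutations == 1
    assert p.n_damaging == 1


def test_profile_counts_silent_in_burden_only():
    events = [
        make_variant(Consequence.STOPGAIN),
        make_variant(Consequence.NONSYNONYMOUS, func=6),
        make_variant(Consequence.SPLICING, splice=1),
        make_variant(Consequence.SILENT),
        make_variant(Consequence.SILENT),
    ]
    (p,) = build_molecular_profiles(events)
    assert p.total_exonic_mutations == 5
    assert p.truncating == 1
    assert p.non_truncating_damaging == 2  # splicing counts as non-truncating damaging
    assert p.n_damaging == 3


def test_profile_gof_recorded_in_addition():
    (p,) = build_molecular_profiles([make_variant(Consequence.STOPGAIN, gof=True)])
    assert p.truncating == 1 and p.gof == 1


def test_profiles_include_sv_and_cnv_and_drop_undamaged():
    variants = [make_variant(Consequence.SILENT)]  # damages nothing
    svs = [StructuralVariant("S1", "G2", SVType.TRANSLOCATION)]
    segments = [seg(cn=6.0, start=0, end=5000)]
    genes = [GENE, GeneInterval("G3", "chr2", 0, 100)]
    profiles = build_molecular_profiles(variants, segments, svs, genes)
    by_gene = {p.gene_id: p for p in profiles}
    assert set(by_gene) == {"G1", "G2"}  # silent-only G1 rescued by the gain
    assert by_gene["G1"].gain == 1 and by_gene["G1"].copy_number == 6.0
    assert by_gene["G1"].total_exonic_mutations == 1
    assert by_gene["G2"].translocation == 1


def test_cohort_profiles_bounded_by_event_counts(worked_cohort):
    """Damaging counts never exceed the events supplied for that pair."""
    c = worked_cohort
    profiles = build_molecular_profiles(
        c.variants, c.segments, c.svs, c.gene_intervals
    )
    events = {}
    for v in c.variants:
        events[(v.sample_id, v.gene_id)] = events.get((v.sample_id, v.gene_id), 0) + 2
    for s in c.svs:
        events[(s.sample_id, s.gene_id)] = events.get((s.sample_id, s.gene_id), 0) + 1
    for p in profiles:
        supplied = events.get((p.sample_id, p.gene_id), 0) + 1  # +1 possible CNV
        assert p.n_damaging <= supplied
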