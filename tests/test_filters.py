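"""Retention-filter cascade: decisions, ordering, and invariances."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from carrierscreen import (
    AnnotatedVariant,
    FilterConfig,
    ValidationError,
    apply_filters,
    flag_local_common,
    parse_evidence,
)


def make_variant(
    variant_id="GENE:c.100G>A",
    filter_status="PASS",
    depth=50,
    af=None,
    af_source="1000G",
    chgvs="c.100G>A",
    phgvs="p.Gly34Ser",
    **kwargs,
):
    pop_af = {} if af is None else {af_source: af}
    return AnnotatedVariant(
        variant_id=variant_id,
        gene="GENE",
        transcript="T",
        chgvs=chgvs,
        phgvs=phgvs,
        filter_status=filter_status,
        depth=depth,
        pop_af=pop_af,
        evidence=parse_evidence(""),
        **kwargs,
    )


class TestDecisions:
    def test_clean_rare_missense_passes(self):
        [d] = apply_filters([make_variant(af=0.005)])
        assert d.passed and d.reason == "none"

    @pytest.mark.parametrize(
        "variant, reason",
        [
            (make_variant(filter_status="LowQual"), "quality"),
            (make_variant(af=0.06), "maf"),
            (make_variant(af=0.05), "maf"),  # strict: retained iff AF < threshold
            (make_variant(chgvs="garbage", phgvs=None), "consequence"),
            (make_variant(chgvs="c.100-9G>A", phgvs=None), "consequence"),  # offset 9 > 8
            (make_variant(depth=10), "depth"),  # strict > 10
        ],
    )
    def test_single_failures(self, variant, reason):
        [d] = apply_filters([variant])
        assert not d.passed and d.reason == reason

    def test_depth_just_above_floor_passes(self):
        [d] = apply_filters([make_variant(depth=11)])
        assert d.passed

    def test_splice_region_within_offset_passes(self):
        [d] = apply_filters([make_variant(chgvs="c.100-6G>A", phgvs=None)])
        assert d.passed

    def test_first_failing_reason_in_fixed_order(self):
        # fails quality AND maf AND depth -> attributed to quality
        v = make_variant(filter_status="LowQual", af=0.5, depth=1)
        [d] = apply_filters([v])
        assert d.reason == "quality"

    def test_missing_af_treated_as_rare(self):
        [d] = apply_filters([make_variant(af=None)])
        assert d.passed

    def test_unconsulted_sources_ignored(self):
        # high AF in a source the config does not consult must not fail MAF
        [d] = apply_filters([make_variant(af=0.3, af_source="gnomAD_SAS")])
        assert d.passed

    def test_curated_exclusion_despite_passing_numeric_filters(self):
        # the population-polymorphism case: AF 0.5% passes every numeric
        # filter and is removed only by the curated exclusion list
        v = make_variant(variant_id="CFTR:c.3854C>T", af=0.005)
        config = FilterConfig(exclusion_list=frozenset({"CFTR:c.3854C>T"}))
        [d] = apply_filters([v], config)
        assert not d.passed and d.reason == "curation_exclusion"
        [d] = apply_filters([v])
        assert d.passed

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            FilterConfig(maf_threshold=0.0)
        with pytest.raises(ValidationError):
            FilterConfig(max_intronic_offset=1)


class TestLocalCommonFlag:
    def test_at_threshold_flags(self):
        assert flag_local_common(make_variant(af=0.005, af_source="gnomAD_SAS"))

    def test_below_threshold_does_not(self):
        assert not flag_local_common(make_variant(af=0.0049, af_source="local"))

    def test_absent_local_evidence_does_not(self):
        assert not flag_local_common(make_variant(af=0.5, af_source="1000G"))

    def test_flag_never_drops(self):
        v = make_variant(af=0.01, af_source="local")
        assert flag_local_common(v)
        [d] = apply_filters([v])
        assert d.passed


_variants = st.builds(
    make_variant,
    variant_id=st.sampled_from([f"G:c.{i}G>A" for i in range(8)]),
    filter_status=st.sampled_from(["PASS", "LowQual", "q10"]),
    depth=st.integers(0, 60),
    af=st.one_of(st.none(), st.floats(0, 1, allow_nan=False)),
    chgvs=st.sampled_from(["c.100G>A", "c.100-3G>A", "c.100-7G>A", "c.100+12G>A", "junk"]),
    phgvs=st.sampled_from([None, "p.Gly34Ser", "p.Gly34Ter", "p.Gly34del"]),
)


@settings(derandomize=True, max_examples=150)
@given(
    variants=st.lists(_variants, max_size=8, unique_by=lambda v: v.variant_id),
    seed=st.randoms(use_true_random=False),
)
def test_permutation_invariance(variants, seed):
    """A variant's decision does not depend on catalogue order."""
    decisions = {d.variant_id: d for d in apply_filters(variants)}
    shuffled = list(variants)
    seed.shuffle(shuffled)
    for d in apply_filters(shuffled):
        assert decisions[d.variant_id] == d


@settings(derandomize=True, max_examples=200)
@given(
    variant=_variants,
    maf=st.floats(0.001, 0.05),
    depth_floor=st.integers(10, 40),
    offset=st.integers(2, 8),
    exclude=st.booleans(),
)
def test_tightening_is_monotone(variant, maf, depth_floor, offset, exclude):
    """Tightening any threshold never converts a failed variant to passed."""
    loose = FilterConfig()
    tight = FilterConfig(
        maf_threshold=maf,
        min_depth_exclusive=depth_floor,
        max_intronic_offset=offset,
        exclusion_list=frozenset({variant.variant_id}) if exclude else frozenset(),
    )
    [d_loose] = apply_filters([variant], loose)
    [d_tight] = apply_filters([variant], tight)
    if not d_loose.passed:
        assert not d_tight.passed


def test_all_reference_variants_pass_default_filters(catalogue):
    """Every catalogued (reported) variant survives the default cascade —
    including the -6 splice-region variant, which needs the splice window
    wider than the canonical +/-2 sites."""
    decisions = apply_filters(catalogue)
    failures = [d for d in decisions if not d.passed]
    assert failures == []
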