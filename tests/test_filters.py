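import random

import pytest
from hypothesis import given, settings, strategies as st

from genoquery import (
    FunctionalAnnotation,
    GenotypeCall,
    GenotypeRun,
    GroupFilter,
    Query,
    ValidationError,
    VariantLevelFilter,
    VariantRecord,
    evaluate_discrimination,
    evaluate_group_filter,
    evaluate_variant_level,
    group_stats,
    mask_by_thresholds,
)
from oracle import _group_decision


def calls(mapping):
    return {k: GenotypeCall(v) for k, v in mapping.items()}


class TestGroupStats:
    def test_mixed_group_tallies(self):
        group = ["i1", "i2", "i3", "i4", "i5"]
        masked = calls({"i1": (0, 0), "i2": (0, 0), "i3": (0, 1), "i4": (1, 1)})
        s = group_stats(masked, group)
        assert s.n_selected == 5 and s.n_called == 4
        assert s.missing_ratio == pytest.approx(0.2)
        assert s.allele_counts == {0: 5, 1: 3}
        assert s.maf == pytest.approx(0.375)
        assert s.major_genotype == (0, 0)
        assert s.major_ratio == pytest.approx(0.5)

    def test_monomorphic_group(self):
        group = [f"i{k}" for k in range(10)]
        s = group_stats(calls({g: (0, 0) for g in group}), group)
        assert s.maf == 0.0 and s.major_ratio == 1.0 and s.missing_ratio == 0.0

    def test_empty_group_stats_are_degenerate_not_errors(self):
        s = group_stats({}, ["i1", "i2"])
        assert s.n_called == 0 and s.missing_ratio == 1.0
        assert s.maf is None and s.major_genotype is None

    def test_major_tie_breaks_to_smallest_multiset(self):
        s = group_stats(calls({"a": (0, 0), "b": (1, 1)}), ["a", "b"])
        assert s.major_genotype == (0, 0)

    def test_matches_brute_force_tally_on_random_groups(self):
        rng = random.Random(17)
        for _ in range(100):
            group = [f"i{k}" for k in range(rng.randint(1, 12))]
            masked = {}
            for g in group:
                if rng.random() < 0.8:
                    masked[g] = GenotypeCall(
                        tuple(rng.choices(range(3), k=rng.choice([1, 2])))
                    )
            s = group_stats(masked, group)
            # direct tallies
            from collections import Counter

            geno = Counter(c.allele_indices for c in masked.values())
            alle = Counter(a for c in masked.values() for a in c.allele_indices)
            assert s.n_called == len(masked)
            assert s.genotype_counts == dict(geno)
            assert s.allele_counts == dict(alle)
            if alle:
                freqs = sorted(alle.values(), reverse=True)
                expected_maf = freqs[1] / sum(freqs) if len(freqs) > 1 else 0.0
                assert s.maf == pytest.approx(expected_maf)


class TestMasking:
    def run(self):
        return GenotypeRun(
            "v",
            calls({"a": (0, 1), "b": (0, 0), "c": (1, 1)}),
            {"a": {"DP": 12}, "b": {"DP": 3}},  # c has no DP value
        )

    def test_threshold_masks_low_and_absent_values(self):
        masked = mask_by_thresholds(self.run(), {"DP": 10}, ["a", "b", "c"], {"DP"})
        assert set(masked) == {"a"}  # b below threshold, c has no value

    def test_boundary_value_is_retained(self):
        masked = mask_by_thresholds(self.run(), {"DP": 12}, ["a", "b"], {"DP"})
        assert set(masked) == {"a"}

    def test_empty_thresholds_is_identity(self):
        masked = mask_by_thresholds(self.run(), {}, ["a", "b", "c"])
        assert masked == self.run().calls

    def test_unknown_field_rejected_with_detected_list(self):
        with pytest.raises(ValidationError, match="DP"):
            mask_by_thresholds(self.run(), {"XX": 1}, ["a"], {"DP", "GQ"})


class TestGroupFilterEvaluation:
    def stats_9_of_10(self):
        group = [f"i{k}" for k in range(10)]
        m = {g: GenotypeCall((0, 0)) for g in group[:9]}
        m["i9"] = GenotypeCall((0, 1))
        return group_stats(m, group)

    def test_similarity_boundary_is_inclusive(self):
        s = self.stats_9_of_10()
        gf_pass = GroupFilter(tuple(f"i{k}" for k in range(10)), "ALL_OR_MOSTLY_SAME", 0.9)
        gf_fail = GroupFilter(tuple(f"i{k}" for k in range(10)), "ALL_OR_MOSTLY_SAME", 0.91)
        assert evaluate_group_filter(s, gf_pass)[0] is True
        assert evaluate_group_filter(s, gf_fail)[0] is False

    def test_maf_outside_range_fails(self):
        group = ["i1", "i2", "i3", "i4", "i5"]
        masked = calls({"i1": (0, 0), "i2": (0, 0), "i3": (0, 1), "i4": (1, 1)})
        s = group_stats(masked, group)  # maf 0.375
        gf = GroupFilter(tuple(group), maf_min=0.10, maf_max=0.30)
        assert evaluate_group_filter(s, gf)[0] is False
        gf2 = GroupFilter(tuple(group), maf_min=0.10, maf_max=0.375)  # inclusive upper bound
        assert evaluate_group_filter(s, gf2)[0] is True

    def test_no_calls_fails_pattern_and_maf(self):
        s = group_stats({}, ["i1"])
        assert evaluate_group_filter(s, GroupFilter(("i1",), "ALL_OR_MOSTLY_SAME", 0.5))[0] is False
        assert evaluate_group_filter(s, GroupFilter(("i1",), maf_min=0.0))[0] is False

    def test_decisions_match_independent_rule_evaluation(self):
        rng = random.Random(23)
        inds = [f"i{k}" for k in range(10)]
        for _ in range(200):
            run = GenotypeRun("v", {}, {})
            for g in inds:
                if rng.random() < 0.75:
                    run.calls[g] = GenotypeCall(tuple(rng.choices(range(3), k=2)))
                run.numeric_values[g] = {"DP": rng.randint(0, 50)}
            kwargs = {"individuals": tuple(rng.sample(inds, rng.randint(1, 10)))}
            if rng.random() < 0.5:
                kwargs["pattern"] = "ALL_OR_MOSTLY_SAME"
                kwargs["similarity_ratio"] = rng.random()
            if rng.random() < 0.5:
                kwargs["maf_min"] = round(rng.uniform(0, 0.25), 3)
                kwargs["maf_max"] = round(rng.uniform(kwargs["maf_min"], 0.5), 3)
            if rng.random() < 0.5:
                kwargs["max_missing_ratio"] = rng.random()
            if rng.random() < 0.5:
                kwargs["numeric_thresholds"] = {"DP": rng.randint(0, 50)}
            gf = GroupFilter(**kwargs)
            masked = mask_by_thresholds(run, gf.numeric_thresholds, gf.individuals, {"DP"})
            got = evaluate_group_filter(group_stats(masked, gf.individuals), gf)
            assert got == _group_decision(run, gf)


class TestDiscrimination:
    def test_distinct_majors_both_passing(self):
        assert evaluate_discrimination((True, (0, 0)), (True, (1, 1))) is True

    def test_equal_majors_after_unphased_normalisation(self):
        g1 = group_stats(calls({"a": (0, 1)}), ["a"])
        g2 = group_stats({"b": GenotypeCall((1, 0), phased=True)}, ["b"])
        assert g1.major_genotype == g2.major_genotype == (0, 1)
        assert evaluate_discrimination((True, g1.major_genotype), (True, g2.major_genotype)) is False

    def test_failing_group_blocks_discrimination(self):
        assert evaluate_discrimination((True, (0, 0)), (False, (1, 1))) is False
        assert evaluate_discrimination((True, (0, 0)), (True, None)) is False


class TestVariantLevel:
    REC = VariantRecord("v", "chr10", 28_000_000, ("A", "T"))

    def test_sequence_and_position_window(self):
        vf = VariantLevelFilter(
            sequences=frozenset(["chr10"]), position_min=27_530_000, position_max=29_520_000
        )
        assert evaluate_variant_level(self.REC, [], vf) is True
        vf2 = VariantLevelFilter(sequences=frozenset(["chr9"]))
        assert evaluate_variant_level(self.REC, [], vf2) is False

    def test_effect_filter_requires_matching_annotation(self):
        vf = VariantLevelFilter(effects=frozenset(["missense_variant"]))
        intron = [FunctionalAnnotation("T", "intron_variant")]
        missense = [FunctionalAnnotation("T", "missense_variant")]
        assert evaluate_variant_level(self.REC, intron, vf) is False
        assert evaluate_variant_level(self.REC, missense, vf) is True

    def test_empty_filter_matches_everything(self):
        assert evaluate_variant_level(self.REC, [], VariantLevelFilter()) is True

    def test_position_bounds_are_inclusive(self):
        vf = VariantLevelFilter(position_min=28_000_000, position_max=28_000_000)
        assert evaluate_variant_level(self.REC, [], vf) is True


def test_query_invariants():
    g = GroupFilter(("a",), "ALL_OR_MOSTLY_SAME", 0.9)
    with pytest.raises(ValidationError):
        Query(group1=g, discriminate=True)  # both groups required
    with pytest.raises(ValidationError):
        Query(group1=g, group2=GroupFilter(("b",), "ANY"), discriminate=True)
    Query(group1=g, group2=GroupFilter(("b",), "ALL_OR_MOSTLY_SAME", 0.9), discriminate=True)
    with pytest.raises(ValidationError):
        GroupFilter(())
    with pytest.raises(ValidationError):
        GroupFilter(("a",), maf_min=0.4, maf_max=0.1)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    genotypes=st.lists(
        st.one_of(st.none(), st.tuples(st.integers(0, 2), st.integers(0, 2))),
        min_size=1,
        max_size=15,
    ),
    ratio=st.floats(0, 1),
)
def test_similarity_ratio_monotone_in_threshold(genotypes, ratio):
    """Raising the ratio can only turn a passing pattern into a failing one."""
    group = [f"i{k}" for k in range(len(genotypes))]
    masked = {g: GenotypeCall(gt) for g, gt in zip(group, genotypes) if gt is not None}
    s = group_stats(masked, group)
    lo = GroupFilter(tuple(group), "ALL_OR_MOSTLY_SAME", similarity_ratio=ratio)
    hi_ratio = min(1.0, ratio + 0.1)
    hi = GroupFilter(tuple(group), "ALL_OR_MOSTLY_SAME", similarity_ratio=hi_ratio)
    if evaluate_group_filter(s, hi)[0]:
        assert evaluate_group_filter(s, lo)[0]
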