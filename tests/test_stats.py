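import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import tractprofiles as tp
from tractprofiles.stats import NodeRange

import oracles
from conftest import make_dataset, random_small_dataset


class TestBinning:
    def test_quantile_matches_sort_and_split_oracle(self):
        ages = [8.0, 9.0, 10.0, 11.0, 20.0, 21.0, 22.0, 30.0, 31.0]
        subs = [f"s{i}" for i in range(9)]
        ds = make_dataset(
            {("fa", "t"): {s: [0.5] for s in subs}}, metadata={"age": ages}
        )
        ga = tp.bin_subjects(ds, "age", 3, "quantile")
        expected = oracles.quantile_bins(list(zip(subs, ages)), 3)
        assert {s: g for s, g in ga.assignment.items()} == expected
        assert sorted(ga.members(0)) == ["s0", "s1", "s2"]
        assert sorted(ga.members(1)) == ["s3", "s4", "s5"]
        assert sorted(ga.members(2)) == ["s6", "s7", "s8"]

    def test_explicit_edges_reproduce_age_bins(self):
        # the canonical development split: 8-15, 15-30, 30-50
        ages = [8.0, 12.0, 15.0, 20.0, 29.0, 30.0, 40.0, 50.0]
        subs = [f"s{i}" for i in range(8)]
        ds = make_dataset(
            {("fa", "t"): {s: [0.5] for s in subs}}, metadata={"age": ages}
        )
        ga = tp.bin_subjects(ds, "age", method="explicit_edges", edges=[8, 15, 30, 50])
        assert ga.labels == ["8–15", "15–30", "30–50"]
        # half-open intervals, last closed: 15 -> group 1, 30 -> group 2, 50 -> group 2
        assert ga.assignment["s2"] == 1
        assert ga.assignment["s5"] == 2
        assert ga.assignment["s7"] == 2

    def test_single_group_collects_everyone(self, trio_ds):
        ga = tp.bin_subjects(trio_ds, "age", 1, "quantile")
        assert ga.group_sizes() == [3]

    def test_categorical_one_group_per_level(self):
        ds = make_dataset(
            {("fa", "t"): {"s1": [0.1], "s2": [0.2], "s3": [0.3]}},
            metadata={"dx": ["pat", "ctl", "pat"]},
        )
        ga = tp.bin_subjects(ds, "dx", method="categorical")
        assert ga.labels == ["ctl", "pat"]
        assert ga.members(0) == ["s2"]
        assert sorted(ga.members(1)) == ["s1", "s3"]

    def test_missing_values_are_unassigned(self):
        ds = make_dataset(
            {("fa", "t"): {"s1": [0.1], "s2": [0.2], "s3": [0.3]}},
            metadata={"age": [10.0, np.nan, 30.0]},
        )
        ga = tp.bin_subjects(ds, "age", 2, "quantile")
        assert ga.unassigned == ["s2"]
        assert sum(ga.group_sizes()) == 2

    def test_errors(self, trio_ds):
        with pytest.raises(KeyError):
            tp.bin_subjects(trio_ds, "nope", 2)
        with pytest.raises(ValueError, match="exceeds"):
            tp.bin_subjects(trio_ds, "age", 5, "quantile")
        ds = make_dataset(
            {("fa", "t"): {"s1": [0.1]}}, metadata={"dx": ["x"]}
        )
        with pytest.raises(TypeError):
            tp.bin_subjects(ds, "dx", 2, "quantile")

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        values=st.lists(st.floats(-100, 100, allow_nan=False), min_size=2, max_size=20),
        k=st.integers(1, 5),
    )
    def test_quantile_partition_property(self, values, k):
        """Every assigned subject lands in exactly one group; sizes differ by <= 1."""
        k = min(k, len(values))
        subs = [f"s{i:02d}" for i in range(len(values))]
        ds = make_dataset(
            {("fa", "t"): {s: [0.5] for s in subs}},
            metadata={"age": values},
        )
        ga = tp.bin_subjects(ds, "age", k, "quantile")
        sizes = ga.group_sizes()
        assert sum(sizes) == len(values)
        assert max(sizes) - min(sizes) <= 1
        seen = [s for g in range(k) for s in ga.members(g)]
        assert sorted(seen) == sorted(subs)
        # group index non-decreasing in value
        by_val = sorted(zip(values, subs))
        indices = [ga.assignment[s] for _, s in by_val]
        assert indices == sorted(indices)


class TestGroupProfile:
    def test_matches_hand_example(self, trio_ds):
        summ = tp.group_profile(trio_ds, "tract1", "fa", ["s1", "s2", "s3"])
        np.testing.assert_allclose(summ.mean, [0.5, 0.6, 0.7, 0.6], atol=1e-12)
        np.testing.assert_allclose(summ.sd, [0.1] * 4, atol=1e-12)
        np.testing.assert_allclose(summ.se, [0.1 / math.sqrt(3)] * 4, atol=1e-12)
        assert summ.n.tolist() == [3, 3, 3, 3]

    def test_single_member_has_no_spread(self, trio_ds):
        summ = tp.group_profile(trio_ds, "tract1", "fa", ["s1"])
        np.testing.assert_allclose(summ.mean, [0.4, 0.5, 0.6, 0.5])
        assert np.isnan(summ.sd).all() and np.isnan(summ.se).all()

    def test_missing_cell_drops_from_n(self, trio_ds):
        trio_ds.values[("fa", "tract1")][1, 2] = np.nan  # s2, node 2
        summ = tp.group_profile(trio_ds, "tract1", "fa", ["s1", "s2", "s3"])
        assert summ.n.tolist() == [3, 3, 2, 3]
        exp = oracles.summary_at_node([0.6, 0.8])
        assert summ.mean[2] == pytest.approx(exp[1], abs=1e-12)

    def test_empty_members_rejected(self, trio_ds):
        with pytest.raises(ValueError):
            tp.group_profile(trio_ds, "tract1", "fa", [])
        with pytest.raises(KeyError):
            tp.group_profile(trio_ds, "no-such-tract", "fa", ["s1"])


class TestZScores:
    def test_hand_example(self, trio_ds):
        ds = trio_ds
        mat = np.vstack([ds.values[("fa", "tract1")], [[0.5, 0.6, 1.0, 0.6]]])
        ds4 = make_dataset(
            {("fa", "tract1"): {s: mat[i] for i, s in enumerate(["s1", "s2", "s3", "s4"])}}
        )
        zp = tp.subject_zscores(ds4, "s4", "tract1", "fa", ["s1", "s2", "s3"])
        np.testing.assert_allclose(zp.z, [0, 0, 3, 0], atol=1e-12)

    def test_subject_at_reference_mean_is_zero(self, trio_ds):
        zp = tp.subject_zscores(
            trio_ds, "s2", "tract1", "fa", ["s1", "s3"], exclude_self=False
        )
        # s2's profile is exactly the mean of s1 and s3
        np.testing.assert_allclose(zp.z, 0, atol=1e-12)

    def test_self_excluded_from_reference_by_default(self, trio_ds):
        zp = tp.subject_zscores(trio_ds, "s1", "tract1", "fa", ["s1", "s2", "s3"])
        assert zp.reference_n.tolist() == [2, 2, 2, 2]

    def test_zero_reference_sd_gives_missing_with_warning(self):
        ds = make_dataset(
            {("fa", "t"): {"s1": [0.5, 0.5], "s2": [0.5, 0.6], "x": [0.7, 0.7]}}
        )
        with pytest.warns(UserWarning, match="zero reference SD"):
            zp = tp.subject_zscores(ds, "x", "t", "fa", ["s1", "s2"])
        assert np.isnan(zp.z[0])
        assert np.isfinite(zp.z[1])

    def test_reference_empty_after_self_exclusion(self, trio_ds):
        with pytest.raises(ValueError, match="self-exclusion"):
            tp.subject_zscores(trio_ds, "s1", "tract1", "fa", ["s1"])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        a=st.floats(0.1, 50, allow_nan=False),
        b=st.floats(-10, 10, allow_nan=False),
        seed=st.integers(0, 2**20),
    )
    def test_affine_invariance(self, a, b, seed):
        """z-profiles are invariant under x -> a*x + b applied to everyone."""
        rng = np.random.default_rng(seed)
        ds = random_small_dataset(rng, missing_rate=0.0)
        tract, metric = ds.tract_names[0], ds.metric_names[0]
        ds2 = ds.copy()
        ds2.values[(metric, tract)] = a * ds2.values[(metric, tract)] + b
        ref = ds.subject_ids[1:]
        z1 = tp.subject_zscores(ds, ds.subject_ids[0], tract, metric, ref).z
        z2 = tp.subject_zscores(ds2, ds.subject_ids[0], tract, metric, ref).z
        np.testing.assert_allclose(z1, z2, atol=1e-10, equal_nan=True)

    def test_leave_self_out_z_mean_is_zero_without_exclusion(self, small_synth_ds):
        """With self-exclusion disabled, reference members' z-scores sum to 0."""
        ds = small_synth_ds
        ref = ds.subject_ids
        zs = [
            tp.subject_zscores(ds, s, "Left Arcuate", "fa", ref, exclude_self=False).z
            for s in ref
        ]
        np.testing.assert_allclose(np.mean(zs, axis=0), 0, atol=1e-10)


class TestSummarizeZ:
    def test_peak_picks_max_magnitude_signed(self):
        zp = tp.ZProfile("s", "t", "fa", "ref", np.array([3] * 4), np.array([0.0, 0, 3, 0]))
        assert tp.summarize_z(zp) == (3.0, 2)
        zp2 = tp.ZProfile("s", "t", "fa", "ref", np.array([3] * 3), np.array([-4.0, 1, 2]))
        assert tp.summarize_z(zp2) == (-4.0, 0)

    def test_tie_breaks_to_lowest_node(self):
        zp = tp.ZProfile("s", "t", "fa", "ref", np.array([3] * 3), np.array([2.0, -2.0, 1.0]))
        value, node = tp.summarize_z(zp)
        assert (value, node) == (2.0, 0)

    def test_mean_of_constant_is_constant(self):
        zp = tp.ZProfile("s", "t", "fa", "ref", np.array([3] * 4), np.full(4, 1.3))
        value, node = tp.summarize_z(zp, how="mean")
        assert value == pytest.approx(1.3)
        assert node is None

    def test_range_restriction(self):
        zp = tp.ZProfile("s", "t", "fa", "ref", np.array([3] * 4), np.array([9.0, 0.5, 1.0, 0.2]))
        value, node = tp.summarize_z(zp, NodeRange(1, 3))
        assert (value, node) == (1.0, 2)

    def test_all_missing_range_rejected(self):
        zp = tp.ZProfile("s", "t", "fa", "ref", np.array([3] * 2), np.array([np.nan, np.nan]))
        with pytest.raises(ValueError, match="missing"):
            tp.summarize_z(zp)


class TestFractionDeviant:
    def _cohort(self):
        # 4 patients, 3 of whom spike beyond |z|>1 inside nodes 1-2
        ctrl = {f"c{i}": [0.5 + 0.01 * i, 0.5 + 0.01 * i, 0.5 + 0.01 * i] for i in range(6)}
        pats = {
            "p0": [0.5, 0.9, 0.5],
            "p1": [0.5, 0.5, 0.9],
            "p2": [0.1, 0.5, 0.5],  # deviates only at node 0
            "p3": [0.51, 0.52, 0.53],  # unremarkable
        }
        return make_dataset({("fa", "t"): {**ctrl, **pats}}), list(ctrl), list(pats)

    def test_three_of_four_in_window(self):
        ds, ctrl, pats = self._cohort()
        frac = tp.fraction_deviant(ds, pats, ctrl, "t", "fa", 1.0, NodeRange(1, 2))
        assert frac == pytest.approx(0.75)
        # matches the brute-force oracle
        ctrl_rows = [ds.profile(s, "t", "fa").tolist() for s in ctrl]
        pat_rows = {s: ds.profile(s, "t", "fa").tolist() for s in pats}
        assert frac == pytest.approx(
            oracles.fraction_deviant(pat_rows, ctrl_rows, 1.0, 1, 2)
        )

    def test_zero_threshold_catches_everyone(self):
        ds, ctrl, pats = self._cohort()
        assert tp.fraction_deviant(ds, pats, ctrl, "t", "fa", 0.0) == 1.0

    def test_one_sided_direction(self):
        ds, ctrl, pats = self._cohort()
        # p2's only deviation is negative at node 0
        frac = tp.fraction_deviant(
            ds, ["p2"], ctrl, "t", "fa", 1.0, NodeRange(0, 0), direction="positive"
        )
        assert frac == 0.0
        frac = tp.fraction_deviant(
            ds, ["p2"], ctrl, "t", "fa", 1.0, NodeRange(0, 0), direction="negative"
        )
        assert frac == 1.0

    def test_overlap_rejected(self):
        ds, ctrl, pats = self._cohort()
        with pytest.raises(ValueError, match="overlap"):
            tp.fraction_deviant(ds, pats, ctrl + [pats[0]], "t", "fa", 1.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 2**20))
    def test_monotone_nonincreasing_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        ds = random_small_dataset(rng, max_subjects=6, missing_rate=0.0)
        if ds.n_subjects < 4:
            return
        pats = ds.subject_ids[:2]
        ctrl = ds.subject_ids[2:]
        tract, metric = ds.tract_names[0], ds.metric_names[0]
        fracs = [
            tp.fraction_deviant(ds, pats, ctrl, tract, metric, thr)
            for thr in [0.0, 0.5, 1.0, 2.0, 5.0]
        ]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))


class TestCompareGroups:
    def test_single_bin_equals_group_profile(self, small_synth_ds):
        ds = small_synth_ds
        ga = tp.bin_subjects(ds, "age", 1, "quantile")
        [summ] = tp.compare_groups(ds, ga, "Left Arcuate", "fa")
        direct = tp.group_profile(ds, "Left Arcuate", "fa", ga.members(0))
        np.testing.assert_allclose(summ.mean, direct.mean, equal_nan=True)

    def test_injected_group_effect_recovered(self):
        from tractprofiles.synth import GroupEffect, MetadataColumn, SyntheticSpec

        delta = 0.3
        spec = SyntheticSpec(
            n_subjects=400,
            tract_names=["t"],
            metric_names=["fa"],
            n_nodes=80,
            seed=11,
            metadata_columns=[
                MetadataColumn("dx", "categorical", levels=("ctl", "pat"), probs=(0.5, 0.5))
            ],
            group_effects=[GroupEffect("dx", "pat", "fa", "t", NodeRange(40, 60), delta)],
        )
        ds = tp.generate(spec)
        ga = tp.bin_subjects(ds, "dx", method="categorical")
        ctl, pat = tp.compare_groups(ds, ga, "t", "fa")
        diff = pat.mean - ctl.mean
        se = np.sqrt(pat.se**2 + ctl.se**2)
        inside = slice(40, 61)
        assert np.all(np.abs(diff[inside] - delta) < 3 * se[inside])
        outside = np.r_[0:40, 61:80]
        assert np.all(np.abs(diff[outside]) < 3 * se[outside])

    def test_empty_group_yields_all_missing_summary(self):
        ds = make_dataset(
            {("fa", "t"): {"s1": [0.1], "s2": [0.2]}}, metadata={"age": [10.0, 11.0]}
        )
        ga = tp.bin_subjects(ds, "age", method="explicit_edges", edges=[0, 5, 20])
        summs = tp.compare_groups(ds, ga, "t", "fa")
        assert summs[0].n.tolist() == [0]
        assert np.isnan(summs[0].mean).all()
        assert summs[1].n.tolist() == [2]


class TestBrushMask:
    def test_inclusive_window_node_count(self):
        mask = tp.brush_mask(100, [NodeRange(50, 80)])
        assert mask.sum() == 31
        assert mask[50] and mask[80] and not mask[49] and not mask[81]

    def test_empty_ranges_all_false(self):
        assert not tp.brush_mask(10, []).any()

    def test_overlapping_ranges_union(self):
        mask = tp.brush_mask(20, [NodeRange(0, 5), NodeRange(3, 9)])
        assert mask.tolist() == oracles.union_mask(20, [(0, 5), (3, 9)])
        assert mask.sum() == 10

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            tp.brush_mask(10, [NodeRange(5, 10)])


def test_long_format_serialization(small_synth_ds):
    ds = small_synth_ds
    ga = tp.bin_subjects(ds, "age", 2, "quantile")
    from tractprofiles.stats import summaries_to_frame

    frame = summaries_to_frame(tp.compare_groups(ds, ga, "Left Arcuate", "fa"))
    assert list(frame.columns) == [
        "tractID", "metric", "group", "nodeID", "n", "mean", "sd", "se",
    ]
    assert len(frame) == 2 * ds.n_nodes
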