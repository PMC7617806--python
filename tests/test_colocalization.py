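"""Manders coefficients: oracle equality, algebraic properties, summaries."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from colocq import (
    ChannelPair,
    SegmentationMask,
    SyntheticSceneSpec,
    VoxelGrid,
    analyze_pair,
    generate_scene,
    manders_pair,
    summarize_groups,
)
from conftest import random_grid, random_mask


def manders_loop_oracle(raw_a, raw_b, mask_a, mask_b):
    """Brute-force triple-loop Manders computation (independent oracle).

    Membership of every voxel is decided by explicit loops; the collected
    values are reduced with np.sum in the same C order as the vectorized
    path, so agreement is exact (bit-for-bit), not merely approximate.
    """
    num_a, num_b, den_a, den_b = [], [], [], []
    nz, ny, nx = raw_a.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                both = mask_a[z, y, x] and mask_b[z, y, x]
                if mask_a[z, y, x]:
                    den_a.append(raw_a[z, y, x])
                if mask_b[z, y, x]:
                    den_b.append(raw_b[z, y, x])
                if both:
                    num_a.append(raw_a[z, y, x])
                    num_b.append(raw_b[z, y, x])

    def ratio(num, den):
        den_sum = float(np.sum(np.array(den))) if den else 0.0
        if den_sum == 0.0:
            return None
        return float(np.sum(np.array(num))) / den_sum if num else 0.0

    return ratio(num_a, den_a), ratio(num_b, den_b)


def toy_1d(values):
    return VoxelGrid(np.array(values, dtype=float).reshape(1, 1, -1))


def toy_mask(flags):
    return SegmentationMask(np.array(flags, dtype=bool).reshape(1, 1, -1))


class TestMandersPair:
    def test_identical_channels_and_masks_give_one(self, rng):
        grid = random_grid(rng, (3, 5, 5), lo=1.0)
        mask = random_mask(rng, (3, 5, 5), p=0.5)
        res = manders_pair(grid, grid, mask, mask)
        assert res.m_a == 1.0 and res.m_b == 1.0
        assert res.n_intersection == mask.n_true

    def test_disjoint_masks_give_zero(self):
        a = toy_1d([2, 2, 0, 0])
        b = toy_1d([0, 0, 3, 3])
        res = manders_pair(a, b, toy_mask([1, 1, 0, 0]), toy_mask([0, 0, 1, 1]))
        assert res.m_a == 0.0 and res.m_b == 0.0
        assert res.n_intersection == 0

    def test_hand_computed_overlap(self):
        # I_a=[2,2,0,0] on {v0,v1}; I_b=[0,3,3,0] on {v1,v2}; intersection {v1}
        res = manders_pair(
            toy_1d([2, 2, 0, 0]),
            toy_1d([0, 3, 3, 0]),
            toy_mask([1, 1, 0, 0]),
            toy_mask([0, 1, 1, 0]),
        )
        assert res.m_a == pytest.approx(0.5)
        assert res.m_b == pytest.approx(0.5)

    def test_matches_triple_loop_oracle_exactly(self, rng):
        for _ in range(10):
            shape = (8, 8, 8)
            a, b = random_grid(rng, shape), random_grid(rng, shape)
            ma, mb = random_mask(rng, shape), random_mask(rng, shape)
            res = manders_pair(a, b, ma, mb)
            o_a, o_b = manders_loop_oracle(a.data, b.data, ma.data, mb.data)
            assert res.m_a == o_a and res.m_b == o_b  # exact, same float sums

    def test_zero_denominator_flagged_not_zero(self, rng):
        grid = random_grid(rng, (2, 4, 4), lo=1.0)
        empty = SegmentationMask(np.zeros((2, 4, 4), dtype=bool))
        res = manders_pair(grid, grid, empty, random_mask(rng, (2, 4, 4)))
        assert res.m_a is None
        assert any("undefined_m_a" in f for f in res.flags)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="shape"):
            manders_pair(
                random_grid(rng, (2, 4, 4)),
                random_grid(rng, (2, 4, 4)),
                random_mask(rng, (2, 4, 4)),
                random_mask(rng, (2, 4, 5)),
            )

    def test_negative_intensity_rejected(self, rng):
        bad = VoxelGrid(np.full((2, 4, 4), -1.0))
        with pytest.raises(ValueError, match="non-negative"):
            manders_pair(bad, bad, random_mask(rng, (2, 4, 4)), random_mask(rng, (2, 4, 4)))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 2**20))
    def test_range_symmetry_nesting(self, seed):
        rng = np.random.default_rng(seed)
        shape = (4, 6, 6)
        a = VoxelGrid(rng.uniform(0, 10, shape))
        b = VoxelGrid(rng.uniform(0, 10, shape))
        ma = SegmentationMask(rng.random(shape) < 0.4)
        mb_arr = rng.random(shape) < 0.4
        mb = SegmentationMask(mb_arr)
        res = manders_pair(a, b, ma, mb)
        for m in (res.m_a, res.m_b):
            if m is not None:
                assert 0.0 <= m <= 1.0
        assert res.n_intersection <= min(res.n_mask_a, res.n_mask_b)
        # role symmetry
        swapped = manders_pair(b, a, mb, ma)
        assert swapped.m_a == res.m_b and swapped.m_b == res.m_a
        # nesting: mask_a ⊆ mask_b forces m_a = 1
        nested = SegmentationMask(ma.data & mb_arr)
        res_nested = manders_pair(a, b, nested, mb)
        if res_nested.m_a is not None:
            assert res_nested.m_a == 1.0


class TestAnalyzePair:
    def test_full_colocalization_recovered(self):
        spec = SyntheticSceneSpec(
            shape=(12, 128, 128),
            n_puncta_a=15,
            n_puncta_b=15,
            coloc_fraction=1.0,
            jitter_sd=0.0,
            noise_sd=0.0,
            seed=4,
        )
        res = analyze_pair(generate_scene(spec)[0])
        assert res.m_a >= 0.95 and res.m_b >= 0.95

    def test_zero_colocalization_well_separated(self):
        spec = SyntheticSceneSpec(
            shape=(12, 192, 192),
            n_puncta_a=12,
            n_puncta_b=12,
            coloc_fraction=0.0,
            noise_sd=0.0,
            min_separation=12.0,  # 8·punctum_sigma
            seed=4,
        )
        res = analyze_pair(generate_scene(spec)[0])
        assert res.m_a <= 0.05 and res.m_b <= 0.05

    def test_background_only_scene_flagged(self):
        spec = SyntheticSceneSpec(
            shape=(8, 64, 64), n_puncta_a=0, n_puncta_b=0, background=10.0, noise_sd=0.0
        )
        res = analyze_pair(generate_scene(spec)[0])
        # constant channels give empty masks -> undefined coefficients
        assert res.m_a is None and res.m_b is None
        assert res.flags

    def test_per_channel_scale_invariance(self):
        spec = SyntheticSceneSpec(shape=(8, 96, 96), n_puncta_a=10, n_puncta_b=10, seed=6)
        pair, _ = generate_scene(spec)
        res = analyze_pair(pair)
        scaled = ChannelPair(
            VoxelGrid(7.5 * pair.channel_a.data),
            pair.channel_b,
            pair_id=pair.pair_id,
        )
        res_scaled = analyze_pair(scaled)
        assert res_scaled.m_a == pytest.approx(res.m_a, rel=1e-12)
        assert res_scaled.n_mask_a == res.n_mask_a


class TestSummarizeGroups:
    def _result(self, group, m_a, m_b=0.5):
        from colocq import ColocalizationResult

        return ColocalizationResult(
            m_a=m_a, m_b=m_b, n_mask_a=1, n_mask_b=1, n_intersection=1, group=group
        )

    def test_two_value_group_stats(self):
        summaries = summarize_groups([self._result("g", 0.4), self._result("g", 0.6)])
        st_a = summaries[0].stats["m_a"]
        assert st_a["mean"] == pytest.approx(0.5)
        assert st_a["sem"] == pytest.approx(0.1)

    def test_identical_values_zero_spread(self):
        summaries = summarize_groups([self._result("g", 0.3)] * 5)
        st_a = summaries[0].stats["m_a"]
        assert st_a["sd"] == 0.0 and st_a["sem"] == 0.0

    def test_undefined_excluded_and_counted(self):
        results = [self._result("g", 0.4), self._result("g", None)]
        summaries = summarize_groups(results)
        assert summaries[0].n_undefined["m_a"] == 1
        assert summaries[0].stats["m_a"]["n"] == 1

    def test_stable_group_ordering_and_empty_input(self):
        assert summarize_groups([]) == []
        summaries = summarize_groups(
            [self._result("zeta", 0.1), self._result("alpha", 0.2)]
        )
        assert [s.group for s in summaries] == ["alpha", "zeta"]

    def test_n10_batch_summary(self):
        """A batch of 10 results per condition mirrors the study design."""
        results = [self._result("wt", 0.8 + 0.01 * i) for i in range(10)] + [
            self._result("mut", 0.1 + 0.01 * i) for i in range(10)
        ]
        summaries = summarize_groups(results)
        assert all(int(s.stats["m_a"]["n"]) == 10 for s in summaries)
        by = {s.group: s.stats["m_a"] for s in summaries}
        expected_sem = np.std([0.8 + 0.01 * i for i in range(10)], ddof=1) / math.sqrt(10)
        assert by["wt"]["sem"] == pytest.approx(expected_sem)
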