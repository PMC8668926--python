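import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pitx1tools.contacts import (
    ContactMatrix,
    ContactPairs,
    bin_pairs,
    kr_balance,
    subdiagonal_scale,
    subtract,
    truncate_percentile,
)
from pitx1tools.regions import GenomicInterval

REGION = GenomicInterval("chr1", 1, 100)  # 10 bins of 10 bp


def normalized_matrix(m, mask=None):
    m = np.asarray(m, dtype=float)
    n = m.shape[0]
    region = GenomicInterval("chr1", 1, n * 10)
    return ContactMatrix(
        region=region, bin_size=10, matrix=m, mask=mask,
        normalized=True, bias=np.ones(n),
    )


class TestBinPairs:
    def test_empty_pairs_give_zero_matrix(self):
        pairs = ContactPairs(REGION, np.array([], int), np.array([], int))
        m = bin_pairs(pairs, 10)
        assert m.matrix.sum() == 0
        assert not m.mask.any()

    def test_hand_placed_pairs(self):
        # bins: pos 1-10 -> 0, 11-20 -> 1, ...
        pairs = ContactPairs(
            REGION, np.array([1, 5, 15]), np.array([15, 8, 18])
        )
        m = bin_pairs(pairs, 10)
        assert m.matrix[0, 1] == 1 and m.matrix[1, 0] == 1  # pair (1, 15)
        assert m.matrix[0, 0] == 1  # pair (5, 8), same bin counted once
        assert m.matrix[1, 1] == 1  # pair (15, 18)
        assert m.matrix.sum() == 4

    def test_upper_triangle_mass_equals_pair_count(self, rng):
        pos_a = rng.integers(1, 101, 500)
        pos_b = rng.integers(1, 101, 500)
        m = bin_pairs(ContactPairs(REGION, pos_a, pos_b), 10)
        assert np.triu(m.matrix).sum() == 500

    def test_out_of_region_position_rejected_with_index(self):
        with pytest.raises(ValueError, match=r"pos_b\[1\]"):
            ContactPairs(REGION, np.array([1, 2]), np.array([50, 101]))


class TestSubdiagonalScale:
    def test_identical_maps_unchanged(self, rng):
        a = rng.uniform(1, 2, (6, 6))
        a = (a + a.T) / 2
        ma, mb = normalized_matrix(a), normalized_matrix(a.copy())
        sa, sb, flagged = subdiagonal_scale(ma, mb)
        np.testing.assert_allclose(sa.matrix, a, rtol=1e-12)
        np.testing.assert_allclose(sb.matrix, a, rtol=1e-12)
        assert flagged == []

    def test_per_offset_means_equal_after_scaling(self, rng):
        a = rng.uniform(0.5, 3, (8, 8))
        b = rng.uniform(0.5, 3, (8, 8))
        a, b = (a + a.T) / 2, (b + b.T) / 2
        sa, sb, flagged = subdiagonal_scale(normalized_matrix(a), normalized_matrix(b))
        for d in range(8):
            if d in flagged:
                continue
            i = np.arange(8 - d)
            assert sa.matrix[i, i + d].mean() == pytest.approx(
                sb.matrix[i, i + d].mean(), rel=1e-12
            )

    def test_doubled_map_meets_halfway(self, rng):
        b = rng.uniform(1, 2, (5, 5))
        b = (b + b.T) / 2
        a = 2 * b
        sa, sb, _ = subdiagonal_scale(normalized_matrix(a), normalized_matrix(b))
        np.testing.assert_allclose(sa.matrix, 1.5 * b, rtol=1e-12)
        np.testing.assert_allclose(sb.matrix, 1.5 * b, rtol=1e-12)

    def test_symmetry_preserved(self, rng):
        a = rng.uniform(0.5, 3, (7, 7))
        b = rng.uniform(0.5, 3, (7, 7))
        sa, sb, _ = subdiagonal_scale(
            normalized_matrix((a + a.T) / 2), normalized_matrix((b + b.T) / 2)
        )
        np.testing.assert_allclose(sa.matrix, sa.matrix.T, atol=1e-12)
        np.testing.assert_allclose(sb.matrix, sb.matrix.T, atol=1e-12)

    def test_zero_offset_flagged_not_scaled(self):
        a = np.diag([0.0, 0.0, 0.0]) + np.ones((3, 3)) - np.eye(3)
        b = a * 2
        sa, sb, flagged = subdiagonal_scale(normalized_matrix(a), normalized_matrix(b))
        assert 0 in flagged  # empty diagonal left alone
        np.testing.assert_array_equal(np.diag(sa.matrix), 0)

    def test_unnormalized_maps_rejected(self, rng):
        a = np.ones((4, 4))
        region = GenomicInterval("chr1", 1, 40)
        raw = ContactMatrix(region=region, bin_size=10, matrix=a)
        with pytest.raises(ValueError, match="normalized"):
            subdiagonal_scale(raw, raw)

    def test_mismatched_geometry_rejected(self, rng):
        with pytest.raises(ValueError, match="share"):
            subdiagonal_scale(
                normalized_matrix(np.ones((4, 4))), normalized_matrix(np.ones((5, 5)))
            )


class TestSubtract:
    def _scaled(self, m):
        out = normalized_matrix(m)
        out.subdiag_scaled = True
        return out

    def test_self_subtraction_is_zero(self, rng):
        a = rng.uniform(1, 2, (5, 5))
        a = (a + a.T) / 2
        diff = subtract(self._scaled(a), self._scaled(a.copy()))
        np.testing.assert_array_equal(diff.matrix, 0)
        assert diff.signed

    def test_antisymmetry_under_swap(self, rng):
        a = (lambda x: (x + x.T) / 2)(rng.uniform(1, 2, (5, 5)))
        b = (lambda x: (x + x.T) / 2)(rng.uniform(1, 2, (5, 5)))
        d1 = subtract(self._scaled(a), self._scaled(b))
        d2 = subtract(self._scaled(b), self._scaled(a))
        np.testing.assert_allclose(d1.matrix, -d2.matrix, atol=1e-12)

    def test_hand_example(self):
        a = np.array([[2.0, 1, 0], [1, 3, 1], [0, 1, 4]])
        b = np.array([[1.0, 1, 1], [1, 1, 1], [1, 1, 1]])
        diff = subtract(self._scaled(a), self._scaled(b))
        np.testing.assert_array_equal(diff.matrix, a - b)

    def test_unscaled_maps_rejected_unless_overridden(self, rng):
        a = (lambda x: (x + x.T) / 2)(rng.uniform(1, 2, (4, 4)))
        ma, mb = normalized_matrix(a), normalized_matrix(a.copy())
        with pytest.raises(ValueError, match="scaled together"):
            subtract(ma, mb)
        diff = subtract(ma, mb, require_scaled=False)
        np.testing.assert_array_equal(diff.matrix, 0)


def percentile_by_hand(values, q):
    """Linear-interpolation quantile from sorted order statistics."""
    v = np.sort(np.asarray(values, float))
    pos = q / 100 * (len(v) - 1)
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    return v[lo] + (pos - lo) * (v[hi] - v[lo])


class TestTruncatePercentile:
    def test_constant_matrix_unchanged(self):
        m = normalized_matrix(np.full((5, 5), 2.0))
        out = truncate_percentile(m, q=99)
        np.testing.assert_array_equal(out.matrix, m.matrix)

    def test_only_top_entries_clipped_to_hand_computed_cap(self, rng):
        a = rng.uniform(0, 10, (10, 10))
        a = (a + a.T) / 2
        m = normalized_matrix(a)
        out = truncate_percentile(m, q=99)
        cap = percentile_by_hand(a.ravel(), 99)
        assert out.matrix.max() == pytest.approx(cap, rel=1e-12)
        below = a <= cap
        np.testing.assert_array_equal(out.matrix[below], a[below])

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(1, 99))
    def test_clipping_is_monotone(self, seed, q):
        gen = np.random.default_rng(seed)
        a = gen.uniform(0, 5, (6, 6))
        a = (a + a.T) / 2
        out = truncate_percentile(normalized_matrix(a), q=q)
        assert out.matrix.max() <= a.max() + 1e-12
        assert (out.matrix <= np.percentile(a, q) + 1e-12).all()

    def test_all_masked_rejected(self):
        m = normalized_matrix(np.zeros((3, 3)), mask=np.zeros(3, bool))
        with pytest.raises(ValueError, match="unmasked"):
            truncate_percentile(m)

    def test_invalid_percentile_rejected(self, rng):
        with pytest.raises(ValueError):
            truncate_percentile(normalized_matrix(np.ones((3, 3))), q=100)


class TestFullSubtractionPipeline:
    def test_extra_loop_surfaces_at_anchor_after_balance_scale_subtract(self):
        from pitx1tools.simulate import default_contact_config, gen_contacts

        pa, truth = gen_contacts(default_contact_config(seed=21, n_pairs=100_000))
        pb, _ = gen_contacts(
            default_contact_config(seed=22, n_pairs=100_000, with_loop=False)
        )
        ma, mb = bin_pairs(pa, 5000), bin_pairs(pb, 5000)
        ba, _ = kr_balance(ma)
        bb, _ = kr_balance(mb)
        sa, sb, _ = subdiagonal_scale(ba, bb)
        diff = subtract(sa, sb)
        valid = np.outer(diff.mask, diff.mask)
        i, j = np.unravel_index(
            np.argmax(np.where(valid, diff.matrix, -np.inf)), diff.matrix.shape
        )
        loop = truth.loops[0]
        region = diff.region
        anchor_bins_a = {
            region.bin_index(loop.anchor_a.start, 5000),
            region.bin_index(loop.anchor_a.end, 5000),
        }
        anchor_bins_b = {
            region.bin_index(loop.anchor_b.start, 5000),
            region.bin_index(loop.anchor_b.end, 5000),
        }
        assert (i in anchor_bins_a and j in anchor_bins_b) or (
            i in anchor_bins_b and j in anchor_bins_a
        )
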