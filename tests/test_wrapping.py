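import numpy as np
import pytest
from hypothesis import given, strategies as st

import axonwrap as aw
from axonwrap.io import ValidationError
from axonwrap.segmentation import AxonRegion
from axonwrap.wrapping import categorize, CATEGORY_LABELS


def _pixels(mask):
    return np.nonzero(np.asarray(mask, dtype=bool))


def brute_force_wrap_fraction(outline_pixels, myelin):
    """Independent per-pixel oracle: walk every outline pixel and count."""
    rows, cols = outline_pixels
    hits = 0
    for r, c in zip(rows, cols):
        if myelin[r, c]:
            hits += 1
    return hits / len(rows)


# ---------------------------------------------------------------- outline


def test_outline_of_3x3_square_is_its_8_perimeter_pixels():
    mask = np.zeros((7, 7), dtype=bool)
    mask[2:5, 2:5] = True
    rr, cc = aw.outline(_pixels(mask), mask.shape)
    got = set(zip(rr.tolist(), cc.tolist()))
    expected = {(r, c) for r in range(2, 5) for c in range(2, 5)} - {(3, 3)}
    assert got == expected


def test_outline_of_single_pixel_is_itself():
    mask = np.zeros((5, 5), dtype=bool)
    mask[2, 3] = True
    rr, cc = aw.outline(_pixels(mask), mask.shape)
    assert list(zip(rr, cc)) == [(2, 3)]


def test_disc_outline_is_inner_boundary():
    yy, xx = np.mgrid[0:20, 0:20]
    disc = (yy - 10) ** 2 + (xx - 10) ** 2 <= 36
    rr, cc = aw.outline(_pixels(disc), disc.shape)
    assert len(rr) > 0
    for r, c in zip(rr, cc):
        assert disc[r, c]
        neighbourhood = disc[max(0, r - 1) : r + 2, max(0, c - 1) : c + 2]
        assert not neighbourhood.all()  # every outline pixel touches background


def test_outline_of_empty_region_is_an_error():
    with pytest.raises(ValidationError):
        aw.outline((np.array([], int), np.array([], int)), (5, 5))


# ---------------------------------------------------------- overlap mask


def test_overlap_mask_encodes_255_and_0():
    mask = np.zeros((9, 9), dtype=bool)
    mask[2:7, 2:7] = True
    ring = aw.outline(_pixels(mask), mask.shape)
    full = aw.overlap_mask(ring, np.ones((9, 9), dtype=bool))
    assert set(full[ring].tolist()) == {255}
    empty = aw.overlap_mask(ring, np.zeros((9, 9), dtype=bool))
    assert set(empty[ring].tolist()) == {0}
    assert empty.sum() == 0 and full.dtype == np.uint8


def test_overlap_mask_half_plane_covers_half_the_disc_outline():
    yy, xx = np.mgrid[0:32, 0:32]
    disc = (yy - 16) ** 2 + (xx - 16) ** 2 <= 64
    ring = aw.outline(_pixels(disc), disc.shape)
    half = xx >= 16
    overlap = aw.overlap_mask(ring, half)
    frac = (overlap[ring] == 255).mean()
    assert abs(frac - 0.5) <= 0.05


# --------------------------------------------------------- wrap fraction


def test_wrap_fraction_direct_ratio():
    rows = np.zeros(100, dtype=int)
    cols = np.arange(100)
    myelin = np.zeros((1, 100), dtype=bool)
    myelin[0, :80] = True
    assert aw.wrap_fraction((rows, cols), myelin) == pytest.approx(0.80)
    assert aw.wrap_fraction((rows, cols), np.ones((1, 100), bool)) == 1.0


def test_wrap_fraction_equals_brute_force_oracle_on_random_masks(rng):
    for _ in range(300):
        mask = rng.random((12, 12)) > 0.6
        if not mask.any():
            continue
        # take one connected region's pixels
        from skimage.measure import label

        lbl = label(mask, connectivity=2)
        pix = np.nonzero(lbl == 1)
        ring = aw.outline(pix, mask.shape)
        myelin = rng.random((12, 12)) > 0.5
        assert aw.wrap_fraction(ring, myelin) == brute_force_wrap_fraction(ring, myelin)
        # and equals the overlap-mask 255-count over outline size
        overlap = aw.overlap_mask(ring, myelin)
        assert aw.wrap_fraction(ring, myelin) == (overlap == 255).sum() / len(ring[0])


@given(st.integers(0, 2**31 - 1))
def test_wrap_fraction_monotone_under_added_myelin(seed):
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:16, 0:16]
    disc = (yy - 8) ** 2 + (xx - 8) ** 2 <= 25
    ring = aw.outline(_pixels(disc), disc.shape)
    base = rng.random((16, 16)) > 0.7
    extra = base | (rng.random((16, 16)) > 0.7)
    f_base = aw.wrap_fraction(ring, base)
    assert aw.wrap_fraction(ring, extra) >= f_base
    # myelin pixels off the outline never change the fraction
    ring_mask = np.zeros_like(base)
    ring_mask[ring] = True
    assert aw.wrap_fraction(ring, base | ~ring_mask) == f_base
    assert aw.wrap_fraction(ring, base & ring_mask) == f_base


# -------------------------------------------------------------- profiles


def _region_with_fractions(fractions, n_px=20):
    """A 1 x n_px line region per slice plus myelin masks hitting the
    requested fraction of its pixels (the line is its own outline)."""
    nz = len(fractions)
    myelin = np.zeros((nz, 5, n_px + 4), dtype=bool)
    slice_pixels = {}
    for z, f in enumerate(fractions):
        if f is None:
            continue
        slice_pixels[z] = (np.full(n_px, 2), np.arange(2, 2 + n_px))
        myelin[z, 2, 2 : 2 + int(round(f * n_px))] = True
    region = AxonRegion(axon_id=0, slice_pixels=slice_pixels, centroid=(2.0, 6.0))
    return region, myelin


@pytest.mark.parametrize(
    "fractions, n_segments, max_len, fully",
    [
        ([0.9, 0.9, 0.9], 1, 6.0, True),  # 3 slices x 2 um = 6 um qualifies
        ([0.9, 0.7, 0.9], 2, 2.0, False),  # broken run
        ([0.85] * 5, 1, 10.0, True),  # 5 slices -> 10 um
        ([0.9, 0.9, None, 0.9, 0.9], 2, 4.0, False),  # absent slice breaks run
        ([0.8, 0.8, 0.8], 0, 0.0, False),  # threshold is strict: 0.8 not > 0.8
    ],
)
def test_segment_aggregation_rules(fractions, n_segments, max_len, fully):
    region, myelin = _region_with_fractions(fractions)
    profile = aw.build_profile(region, myelin, z_step=2.0)
    assert len(profile.segments) == n_segments
    assert profile.max_segment_length() == pytest.approx(max_len)
    assert profile.fully_wrapped is fully
    for s in profile.segments:
        assert s.length_um == s.n_slices * 2.0


def test_category_bin_edges():
    assert categorize(0.0) == "0-20%"
    assert categorize(0.2) == "0-20%"
    assert categorize(0.5) == "20-50%"
    assert categorize(0.8) == "50-80%"
    assert categorize(0.80001) == "80-100%"
    assert categorize(1.0) == "80-100%"


# ---------------------------------------------------------- field metrics


def _profile(fully=False, max_fraction=0.9, border=False, axon_id=0):
    segs = [aw.Segment(0, 3, 6.0)] if fully else []
    return aw.AxonWrapProfile(
        axon_id=axon_id,
        wrap_fractions={0: max_fraction},
        segments=segs,
        max_fraction=max_fraction,
        category=categorize(max_fraction),
        fully_wrapped=fully,
        border_touching=border,
    )


def test_wrapping_index_is_full_wraps_over_nuclei():
    profiles = [_profile(fully=True, axon_id=i) for i in range(5)]
    m = aw.field_metrics(profiles, n_nuclei=20)
    assert m.wrapping_index == pytest.approx(0.25)
    assert aw.field_metrics([], n_nuclei=20).wrapping_index == 0.0


def test_zero_nuclei_field_is_flagged_invalid():
    m = aw.field_metrics([_profile()], n_nuclei=0)
    assert not m.valid and np.isnan(m.wrapping_index)


def test_border_touching_axons_are_excluded():
    profiles = [_profile(fully=True), _profile(fully=True, border=True, axon_id=1)]
    m = aw.field_metrics(profiles, n_nuclei=10)
    assert m.n_axons == 1 and m.n_fully_wrapped == 1


def test_fully_wrapped_implies_highest_category(noiseless_field):
    stack, _, _ = noiseless_field
    profiles, metrics = aw.quantify_stack(stack)
    for p in profiles:
        if p.fully_wrapped:
            assert p.category == "80-100%"
    assert metrics.n_fully_wrapped <= metrics.category_counts["80-100%"]
    engaged = sum(1 for p in profiles if not p.border_touching and p.max_fraction > 0)
    assert sum(metrics.category_counts.values()) == engaged


def test_wrapping_index_scales_inversely_with_nuclei():
    from fractions import Fraction

    profiles = [_profile(fully=True, axon_id=i) for i in range(7)]
    m1 = aw.field_metrics(profiles, n_nuclei=12)
    m2 = aw.field_metrics(profiles, n_nuclei=24)
    assert Fraction(m1.n_fully_wrapped, m1.n_nuclei) == 2 * Fraction(
        m2.n_fully_wrapped, m2.n_nuclei
    )
    assert m1.wrapping_index == pytest.approx(2 * m2.wrapping_index)


def test_noiseless_field_recovers_truth_exactly(noiseless_field):
    stack, truths, n_nuclei = noiseless_field
    profiles, metrics = aw.quantify_stack(stack)
    assert metrics.n_fully_wrapped == sum(t.true_fully_wrapped for t in truths)
    assert metrics.n_nuclei == n_nuclei
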