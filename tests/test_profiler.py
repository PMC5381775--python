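"""Ring-profiler unit, oracle and property tests."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import stainmap as sm
from stainmap.classes import CLASS_CODES, StainClass
from stainmap.errors import ConfigurationError, ContractError, DetectionError
from stainmap.profiler import OUTSIDE


def geometry(cx, cy, radius_px, px_um=1.0):
    return sm.ConfinementGeometry(cx, cy, radius_px, px_um)


def brute_force_rings(geom, shape, dr_um):
    """Exhaustive per-pixel ring assignment, the independent oracle."""
    n = math.ceil(geom.radius_um / dr_um - 1e-9)
    idx = np.full(shape, OUTSIDE, dtype=int)
    for r in range(shape[0]):
        for c in range(shape[1]):
            d = math.hypot(c - geom.center_x, r - geom.center_y) * geom.pixel_size_um
            if d < geom.radius_um:
                idx[r, c] = min(int(d // dr_um), n - 1)
    return idx


# ---------------------------------------------------------------------------
# Ring construction


def test_ring_count_200um_confinement_25um_rings():
    geom = geometry(100, 100, 100)  # radius 100 um at 1 um/px
    rings = sm.build_ring_index(geom, (201, 201), 25.0)
    assert rings.ring_count == 4
    assert rings.mid_radii_um.tolist() == [12.5, 37.5, 62.5, 87.5]
    assert rings.inner_radii_um.tolist() == [0.0, 25.0, 50.0, 75.0]
    assert rings.outer_radii_um.tolist() == [25.0, 50.0, 75.0, 100.0]


def test_single_ring_limit_when_thickness_exceeds_radius():
    geom = geometry(10, 10, 8)
    rings = sm.build_ring_index(geom, (21, 21), 50.0)
    assert rings.ring_count == 1
    inside = rings.ring_index != OUTSIDE
    assert (rings.ring_index[inside] == 0).all()


def test_nonpositive_thickness_is_configuration_error():
    with pytest.raises(ConfigurationError):
        sm.build_ring_index(geometry(5, 5, 4), (11, 11), 0.0)


def test_ring_assignment_matches_exhaustive_enumeration_21px():
    """Central pixel of a 21x21 grid, 1 um/px, 3 um rings, 9 um radius:
    all 441 pixel distances enumerated by brute force."""
    geom = geometry(10, 10, 9)
    rings = sm.build_ring_index(geom, (21, 21), 3.0)
    oracle = brute_force_rings(geom, (21, 21), 3.0)
    assert np.array_equal(rings.ring_index, oracle)
    for k in range(rings.ring_count):
        assert (rings.ring_index == k).sum() == (oracle == k).sum()


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    cx=st.floats(2, 30),
    cy=st.floats(2, 30),
    radius=st.floats(3, 25),
    dr=st.floats(1.5, 12),
)
def test_partition_property_random_geometries(cx, cy, radius, dr):
    """Rings partition the in-circle pixels exactly: disjoint, exhaustive,
    and the per-ring counts sum to the in-circle total."""
    geom = geometry(cx, cy, radius)
    rings = sm.build_ring_index(geom, (32, 32), dr)
    idx = rings.ring_index
    rows = np.arange(32)[:, None]
    cols = np.arange(32)[None, :]
    dist = np.hypot(cols - cx, rows - cy)
    assert np.array_equal(idx != OUTSIDE, dist < radius)
    counts = np.bincount(idx[idx != OUTSIDE], minlength=rings.ring_count)
    assert counts.sum() == (dist < radius).sum()
    assert idx.max() < rings.ring_count


# ---------------------------------------------------------------------------
# Fractions


def test_uniform_osteogenic_map_fractions():
    geom = geometry(32, 32, 30)
    rings = sm.build_ring_index(geom, (65, 65), 10.0)
    labels = np.full((65, 65), int(StainClass.OSTEOGENIC))
    prof = sm.compute_ring_fractions(labels, rings)
    nonempty = prof.pixel_counts > 0
    assert np.allclose(prof.fraction(StainClass.OSTEOGENIC)[nonempty], 1.0)
    assert np.allclose(prof.fraction(StainClass.ADIPOGENIC)[nonempty], 0.0)


def test_constructed_two_zone_map_gives_exact_fractions():
    geom = geometry(32, 32, 30)
    rings = sm.build_ring_index(geom, (65, 65), 10.0)
    labels = np.where(
        rings.ring_index < 2, int(StainClass.ADIPOGENIC), int(StainClass.OSTEOGENIC)
    )
    prof = sm.compute_ring_fractions(labels, rings)
    adipo = prof.fraction(StainClass.ADIPOGENIC)
    assert adipo[:2].tolist() == [1.0, 1.0]
    assert adipo[2:].tolist() == [0.0] * (prof.ring_count - 2)


@pytest.mark.parametrize("shape", [(21, 21), (64, 64)])
@pytest.mark.parametrize("seed", [11, 12, 13, 14, 15])
def test_random_label_tallies_match_brute_force(shape, seed):
    """Per-ring pixel counts and class tallies equal exhaustive per-pixel
    counting, exactly; non-empty fractions sum to 1 within 1e-9."""
    rng = np.random.default_rng(seed)
    labels = rng.integers(1, 4, size=shape)
    geom = geometry(shape[1] / 2 - 0.5, shape[0] / 2 - 0.5, shape[0] / 2 - 1)
    rings = sm.build_ring_index(geom, shape, 5.0)
    prof = sm.compute_ring_fractions(labels, rings)

    oracle_idx = brute_force_rings(geom, shape, 5.0)
    assert np.array_equal(rings.ring_index, oracle_idx)
    for k in range(prof.ring_count):
        in_ring = oracle_idx == k
        assert prof.pixel_counts[k] == in_ring.sum()
        for j, code in enumerate(CLASS_CODES):
            expected = int(np.sum(labels[in_ring] == code))
            if in_ring.sum():
                assert prof.fractions[k, j] == expected / in_ring.sum()
    nonempty = prof.pixel_counts > 0
    assert np.allclose(prof.fractions[nonempty].sum(axis=1), 1.0, atol=1e-9)


def test_dimension_mismatch_is_contract_error():
    geom = geometry(5, 5, 4)
    rings = sm.build_ring_index(geom, (11, 11), 2.0)
    with pytest.raises(ContractError):
        sm.compute_ring_fractions(np.full((5, 5), 3), rings)


def test_empty_rings_are_nan_flagged():
    # center far in a corner so outer rings exist but have no pixels
    geom = geometry(0, 0, 50)
    rings = sm.build_ring_index(geom, (10, 10), 5.0)
    labels = np.full((10, 10), int(StainClass.NEGATIVE))
    prof = sm.compute_ring_fractions(labels, rings)
    empty = prof.pixel_counts == 0
    assert empty.any()
    assert np.isnan(prof.fractions[empty]).all()


# ---------------------------------------------------------------------------
# Aggregation


def make_profile(fracs, counts=None):
    fracs = np.asarray(fracs, dtype=float)
    n = fracs.shape[0]
    return sm.RingProfile(
        pixel_counts=np.asarray(counts) if counts is not None else np.full(n, 100),
        fractions=fracs,
        inner_radii_um=np.arange(n) * 25.0,
        outer_radii_um=(np.arange(n) + 1) * 25.0,
        ring_thickness_um=25.0,
        radius_um=n * 25.0,
    )


def test_two_point_aggregation_closed_form():
    p1 = make_profile([[0.4, 0.6, 0.0]])
    p2 = make_profile([[0.6, 0.4, 0.0]])
    agg = sm.aggregate_profiles([p1, p2])
    assert agg.mean[0, 0] == pytest.approx(0.5)
    assert agg.sd[0, 0] == pytest.approx(math.sqrt(0.02))
    assert agg.n_replicates == 2


def test_identical_profiles_have_zero_sd():
    p = make_profile([[0.2, 0.3, 0.5], [0.1, 0.1, 0.8]])
    agg = sm.aggregate_profiles([p] * 5)
    assert np.allclose(agg.sd, 0.0)
    assert np.allclose(agg.mean, p.fractions)
    assert agg.n_replicates == 5
    assert np.allclose(agg.mean.sum(axis=1), 1.0, atol=1e-9)


def test_replicate_count_bookkeeping_n12():
    profiles = [make_profile([[0.5, 0.4, 0.1]]) for _ in range(12)]
    agg = sm.aggregate_profiles(profiles)
    assert agg.n_replicates == 12
    assert agg.n_per_ring.tolist() == [12]


def test_mixed_diameters_are_contract_error():
    p1 = make_profile([[1.0, 0.0, 0.0]])
    p2 = make_profile([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
    with pytest.raises(ContractError):
        sm.aggregate_profiles([p1, p2])


def test_empty_rings_excluded_from_aggregation_not_imputed():
    p1 = make_profile([[0.4, 0.6, 0.0]], counts=[100])
    p2 = make_profile([[np.nan, np.nan, np.nan]], counts=[0])
    p3 = make_profile([[0.6, 0.4, 0.0]], counts=[100])
    agg = sm.aggregate_profiles([p1, p2, p3])
    assert agg.n_per_ring.tolist() == [2]
    assert agg.mean[0, 0] == pytest.approx(0.5)
    assert agg.sd[0, 0] == pytest.approx(math.sqrt(0.02))


def test_single_replicate_sd_is_not_available():
    agg = sm.aggregate_profiles([make_profile([[0.4, 0.6, 0.0]])])
    assert np.isnan(agg.sd).all()


# ---------------------------------------------------------------------------
# Export / import


def test_export_table_mid_radii_and_wall_distances(tmp_path):
    agg = sm.aggregate_profiles(
        [make_profile([[1, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])] * 2
    )
    path = tmp_path / "profile.csv"
    sm.export_profile_table(agg, path)
    import pandas as pd

    df = pd.read_csv(path)
    assert df["mid_radius_um"].tolist() == [12.5, 37.5, 62.5, 87.5]
    assert df["distance_from_wall_um"].tolist() == [87.5, 62.5, 37.5, 12.5]
    assert len(df) == 4


def test_profile_table_roundtrip_exact(tmp_path):
    p1 = make_profile([[0.25, 0.5, 0.25], [0.125, 0.75, 0.125]])
    p2 = make_profile([[0.5, 0.25, 0.25], [0.375, 0.5, 0.125]])
    agg = sm.aggregate_profiles([p1, p2])
    path = tmp_path / "roundtrip.csv"
    sm.export_profile_table(agg, path)
    back = sm.read_profile_table(path)
    assert np.array_equal(back.mean, agg.mean)
    assert np.array_equal(back.sd, agg.sd)
    assert back.n_replicates == agg.n_replicates
    assert np.array_equal(back.n_per_ring, agg.n_per_ring)
    assert back.ring_thickness_um == agg.ring_thickness_um
    assert back.radius_um == agg.radius_um


# ---------------------------------------------------------------------------
# Confinement detection


def disk_labels(shape, cx, cy, radius):
    rows = np.arange(shape[0])[:, None]
    cols = np.arange(shape[1])[None, :]
    inside = np.hypot(cols - cx, rows - cy) < radius
    return np.where(inside, int(StainClass.ADIPOGENIC), int(StainClass.NEGATIVE))


def test_detect_exact_disk_center_and_radius():
    labels = disk_labels((240, 260), 100, 120, 80)
    geom = sm.detect_confinement(labels, pixel_size_um=1.0)
    assert abs(geom.center_x - 100) <= 1.0
    assert abs(geom.center_y - 120) <= 1.0
    assert abs(geom.radius_px - 80) <= 0.02 * 80


def test_detect_with_salt_and_pepper_label_noise():
    labels = disk_labels((240, 260), 100, 120, 80)
    rng = np.random.default_rng(3)
    flip = rng.random(labels.shape) < 0.05
    noisy = labels.copy()
    noisy[flip] = np.where(
        labels[flip] == int(StainClass.NEGATIVE),
        int(StainClass.ADIPOGENIC),
        int(StainClass.NEGATIVE),
    )
    geom = sm.detect_confinement(noisy, pixel_size_um=1.0, expected_diameter_um=160.0)
    clean = sm.detect_confinement(labels, pixel_size_um=1.0)
    assert math.hypot(geom.center_x - clean.center_x, geom.center_y - clean.center_y) <= 2.0
    assert geom.radius_px == 80.0  # expected diameter wins


def test_all_background_raises_detection_error():
    labels = np.full((50, 50), int(StainClass.NEGATIVE))
    with pytest.raises(DetectionError):
        sm.detect_confinement(labels, pixel_size_um=1.0)


def test_expected_diameter_overrides_deviant_foreground(caplog):
    labels = disk_labels((100, 100), 50, 50, 20)  # much smaller than expected
    import logging

    with caplog.at_level(logging.WARNING, logger="stainmap.profiler"):
        geom = sm.detect_confinement(labels, pixel_size_um=1.0, expected_diameter_um=120.0)
    assert geom.radius_px == 60.0
    assert any("deviates" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# Crossing radius helper


def test_crossing_radius_linear_interpolation():
    mid = np.array([12.5, 37.5, 62.5, 87.5])
    frac = np.array([1.0, 1.0, 0.0, 0.0])
    assert sm.crossing_radius(mid, frac) == pytest.approx(50.0)
    assert math.isnan(sm.crossing_radius(mid, np.ones(4)))
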