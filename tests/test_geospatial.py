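"""IDW interpolation, Moran's I, correlograms, and cline detection."""

import math

import numpy as np
import pytest

from mthaplopop.geospatial import (
    Correlogram,
    CorrelogramClass,
    GeoPoint,
    IDWConfig,
    correlogram,
    detect_cline,
    greatcircle_distance,
    idw_interpolate,
    morans_i,
    pairwise_distances,
)
from mthaplopop.simulate import generate_clinal_populations


def gp(lat, lon, value=0.5, name="p"):
    return GeoPoint(name, lat, lon, value)


def test_greatcircle_examples():
    assert greatcircle_distance(gp(10, 20), gp(10, 20)) == 0.0
    half = greatcircle_distance(gp(0, 0), gp(0, 180))
    assert half == pytest.approx(math.pi * 6371.0, rel=1e-6)  # ~20015 km
    a, b = gp(30, -5), gp(12, 8)
    assert greatcircle_distance(a, b) == pytest.approx(greatcircle_distance(b, a))


def test_geopoint_validation():
    with pytest.raises(ValueError):
        GeoPoint("x", 95.0, 0.0, 0.5)
    with pytest.raises(ValueError):
        GeoPoint("x", 0.0, 0.0, 1.5)


def test_idw_two_point_hand_case():
    # z=0.2 at 1 km, z=0.4 at 2 km, power 2: (0.2*1 + 0.4*0.25)/1.25 = 0.24
    km = 1.0 / 111.19492664455873  # one km along a meridian, in degrees
    pts = [gp(km, 0, 0.2), gp(2 * km, 0, 0.4)]
    cfg = IDWConfig(lat_min=0.0, lat_max=0.0, lon_min=0.0, lon_max=0.0, cell_size_deg=1.0)
    surf = idw_interpolate(pts, cfg)
    assert surf.values[0, 0] == pytest.approx(0.24, abs=1e-6)


def test_idw_exact_at_sample_and_bounded():
    pts = [gp(0, 0, 0.1), gp(5, 5, 0.9), gp(0, 5, 0.4)]
    cfg = IDWConfig(lat_min=0, lat_max=5, lon_min=0, lon_max=5, cell_size_deg=1.0)
    surf = idw_interpolate(pts, cfg)
    assert surf.values[0, 0] == 0.1  # grid node on a sample
    assert surf.values[5, 5] == 0.9
    assert surf.values.min() >= 0.1 - 1e-12
    assert surf.values.max() <= 0.9 + 1e-12


def test_idw_constant_field_and_scale_equivariance():
    pts = [gp(0, 0, 0.3), gp(4, 2, 0.3), gp(1, 3, 0.3)]
    cfg = IDWConfig(lat_min=0, lat_max=4, lon_min=0, lon_max=3, cell_size_deg=1.0)
    surf = idw_interpolate(pts, cfg)
    assert np.allclose(surf.values, 0.3)

    a = [gp(0, 0, 0.2), gp(4, 2, 0.8), gp(1, 3, 0.6)]
    half = [GeoPoint(p.population, p.lat, p.lon, p.value / 2) for p in a]
    sa = idw_interpolate(a, cfg)
    sh = idw_interpolate(half, cfg)
    assert np.allclose(sh.values, sa.values / 2)


def _brute_force_moran(z, w):
    n = len(z)
    zbar = sum(z) / n
    num = sum(w[i][j] * (z[i] - zbar) * (z[j] - zbar) for i in range(n) for j in range(n))
    den = sum((zi - zbar) ** 2 for zi in z)
    W = sum(sum(row) for row in w)
    return n / W * num / den


def test_morans_i_against_brute_force_oracle():
    rng = np.random.default_rng(11)
    for _ in range(100):
        n = int(rng.integers(4, 12))
        z = rng.uniform(size=n)
        w = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        mask = rng.uniform(size=iu[0].size) < 0.5
        if not mask.any():
            mask[0] = True
        w[iu[0][mask], iu[1][mask]] = 1.0
        w = w + w.T
        assert morans_i(z, w) == pytest.approx(
            _brute_force_moran(list(z), w.tolist()), abs=1e-12
        )


def test_morans_i_checkerboard_is_minus_one():
    # two alternating values where every weighted pair crosses the classes
    z = [1.0, 0.0, 1.0, 0.0]
    w = np.array(
        [
            [0, 1, 0, 1],
            [1, 0, 1, 0],
            [0, 1, 0, 1],
            [1, 0, 1, 0],
        ],
        dtype=float,
    )
    assert morans_i(z, w) == pytest.approx(-1.0)


def test_morans_i_errors_and_undefined():
    z = [0.1, 0.2, 0.3]
    with pytest.raises(ValueError):
        morans_i(z, np.zeros((3, 3)))  # empty weights
    w = np.ones((3, 3)) - np.eye(3)
    assert math.isnan(morans_i([0.5, 0.5, 0.5], w))


def test_morans_i_permutation_expectation():
    """E[I] over value permutations is -1/(n-1) (Monte-Carlo check)."""
    rng = np.random.default_rng(23)
    n = 8
    z = rng.uniform(size=n)
    w = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    w[iu[0][::2], iu[1][::2]] = 1.0
    w = w + w.T
    sims = [morans_i(z[rng.permutation(n)], w) for _ in range(4000)]
    assert float(np.mean(sims)) == pytest.approx(-1 / (n - 1), abs=0.01)


def test_correlogram_partition_exhaustive_and_disjoint():
    pts = generate_clinal_populations(noise_sd=0.02, seed=5)
    c = correlogram(pts, n_classes=14, reps=49, seed=0)
    n = len(pts)
    assert sum(cl.n_pairs for cl in c.classes) == n * (n - 1) // 2
    assert len(c.classes) == 14
    # equal-count classes differ by at most one pair
    sizes = [cl.n_pairs for cl in c.classes]
    assert max(sizes) - min(sizes) <= 1


def test_correlogram_deterministic_under_seed():
    pts = generate_clinal_populations(seed=2)
    a = correlogram(pts, reps=99, seed=4)
    b = correlogram(pts, reps=99, seed=4)
    assert a == b


def test_correlogram_of_cline_starts_positive_ends_negative():
    pts = generate_clinal_populations(noise_sd=0.0, gradient=(-0.02, 0.0), seed=0)
    c = correlogram(pts, reps=199, seed=1)
    assert c.classes[0].morans_i > 0
    assert c.classes[0].p_value < 0.05
    assert min(cl.morans_i for cl in c.classes[-3:]) < 0


def test_detect_cline_on_synthetic_surfaces():
    pts = generate_clinal_populations(noise_sd=0.0, gradient=(-0.02, 0.0), seed=0)
    assert detect_cline(correlogram(pts, reps=199, seed=1))


def test_detect_cline_false_for_constant_surface():
    pts = generate_clinal_populations(noise_sd=0.0, gradient=(0.0, 0.0), seed=0)
    c = correlogram(pts, reps=99, seed=0)
    assert detect_cline(c) is False


def test_too_few_pairs_reduces_classes_with_warning():
    pts = [gp(0, 0, 0.2), gp(1, 1, 0.4), gp(2, 0, 0.6), gp(1, 2, 0.9)]
    with pytest.warns(UserWarning):
        c = correlogram(pts, n_classes=14, reps=49, seed=0)
    assert len(c.classes) == 6  # C(4,2) pairs
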