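"""Gradient-descent readout: descent, recognition, minima discovery, and
the online learning-with-recognition loop."""

import numpy as np
import pytest

import plasticfield as pf
from plasticfield import descend, find_minima, recognize, run_online
from plasticfield.errors import InvalidInputError

from conftest import two_dent_meshfree


def test_descend_single_dent_reaches_center(kernel01):
    M = two_dent_meshfree([0.7])
    for x0 in (0.2, 0.9, 1.5):
        tr = descend(M, np.array([x0]))
        assert tr.converged
        assert tr.endpoint[0] == pytest.approx(0.7, abs=1e-3)


def test_descend_respects_basins():
    # dents at -1 and +2; the basin boundary (sign change of grad V,
    # located by dense scan) separates the starts
    M = two_dent_meshfree([-1.0, 2.0])
    xs = np.linspace(-1.5, 2.5, 4001)
    _, g = M.value_and_grad(xs[:, None].reshape(-1, 1))
    sign_change = xs[np.where(np.diff(np.sign(g.ravel())) < 0)[0]]
    boundary = sign_change[(sign_change > -0.5) & (sign_change < 1.5)][0]
    tr = descend(M, np.array([-0.5]))
    assert -0.5 < boundary  # start is left of the boundary
    assert tr.endpoint[0] == pytest.approx(-1.0, abs=1e-3)
    tr2 = descend(M, np.array([boundary + 0.3]))
    assert tr2.endpoint[0] == pytest.approx(2.0, abs=1e-3)


def test_descent_never_increases_V():
    rng = np.random.default_rng(7)
    for trial in range(100):
        centers = rng.uniform(-2, 2, size=rng.integers(1, 6))
        M = two_dent_meshfree(centers, sigma2=0.1 + rng.random())
        x0 = rng.uniform(-2.5, 2.5, size=1)
        tr = descend(M, x0)
        vals = [M.value_and_grad(s)[0] for s in tr.states]
        assert np.all(np.diff(vals) <= 1e-12)


def test_descend_rejects_nonfinite_start(kernel01):
    M = two_dent_meshfree([0.0])
    with pytest.raises(InvalidInputError):
        descend(M, np.array([np.nan]))


def test_find_minima_constant_stimulus(kernel01):
    s = pf.StimulusSeries(np.full(50, 1.3), dt=1.0)
    L = pf.GridLandscape.for_series(s, kernel01, form="U")
    pf.learn(L, s)
    ms = find_minima(pf.U_to_V(L), n_starts=50, seed=0)
    assert len(ms) == 1
    assert ms.locations[0, 0] == pytest.approx(1.3, abs=1e-3)


def test_find_minima_bimodal(kernel01, bimodal_landscape):
    # two categories of unequal mass -> two minima near the minima of the
    # asymptotic field -(g * p), with basin counts ordered like the mode
    # masses (0.635 vs 0.365).  The smoothed minima are displaced ~0.09 and
    # ~0.13 from the raw density modes by kernel-smoothing bias.
    dens = pf.true_density_iid(pf.BimodalTransformSpec())
    A = pf.asymptotic_landscape(dens, bimodal_landscape.kernel,
                                bimodal_landscape.bounds, bimodal_landscape.n_nodes)
    v = A.values
    target = np.sort(A.axes[0][np.where((v[1:-1] < v[:-2]) & (v[1:-1] < v[2:]))[0] + 1])
    ms = find_minima(bimodal_landscape, n_starts=2000, seed=0)
    assert len(ms) == 2
    locs = np.sort(ms.locations.ravel())
    np.testing.assert_allclose(locs, target, atol=0.1)
    # deeper (left) minimum listed first and its basin collects more restarts
    assert ms.locations[0, 0] < 0 < ms.locations[1, 0]
    assert ms.basin_counts[0] > ms.basin_counts[1]
    masses = dens.mode_masses()
    assert masses[0] > masses[1]


def test_find_minima_deterministic(bimodal_landscape):
    a = find_minima(bimodal_landscape, n_starts=300, seed=42)
    b = find_minima(bimodal_landscape, n_starts=300, seed=42)
    np.testing.assert_array_equal(a.locations, b.locations)
    np.testing.assert_array_equal(a.basin_counts, b.basin_counts)


def test_find_minima_stable_under_more_starts(bimodal_landscape):
    a = find_minima(bimodal_landscape, n_starts=500, seed=1)
    b = find_minima(bimodal_landscape, n_starts=1000, seed=1)
    assert len(a) == len(b)
    np.testing.assert_allclose(a.locations, b.locations, atol=1e-3)


def test_find_minima_agrees_with_dense_scan(bimodal_landscape):
    # brute-force oracle: local minima of the grid values themselves
    v = bimodal_landscape.values
    x = bimodal_landscape.axes[0]
    scan = x[np.where((v[1:-1] < v[:-2]) & (v[1:-1] < v[2:]))[0] + 1]
    depth = v.min()
    scan = [s for s in scan if bimodal_landscape.value_and_grad(np.array([s]))[0] < 0.01 * depth]
    ms = find_minima(bimodal_landscape, n_starts=500, seed=3)
    assert len(ms) == len(scan)
    dx = x[1] - x[0]
    np.testing.assert_allclose(np.sort(ms.locations.ravel()), np.sort(scan), atol=dx)


def test_recognize_at_minimum_and_nearby(kernel01):
    M = two_dent_meshfree([-1.0, 2.0])
    ms = find_minima(M, n_starts=100, seed=0, bounds=[(-2.0, 3.0)])
    i_left = int(np.argmin(ms.locations[:, 0]))
    assert recognize(M, ms.locations[i_left], ms) == i_left
    assert recognize(M, np.array([-1.0 + 0.3]), ms) == i_left  # within sigma_z of the dent


def test_close_stimuli_merge_into_one_category(kernel01):
    # two dents closer than sigma_z fuse into a single minimum; both
    # stimuli are then recognized as the same category
    sz = kernel01.sigma_z
    M = two_dent_meshfree([0.0, 0.4 * sz])
    xs = np.linspace(-1, 1, 8001)
    v, _ = M.value_and_grad(xs.reshape(-1, 1))
    n_min = int(np.sum((v[1:-1] < v[:-2]) & (v[1:-1] < v[2:])))
    assert n_min == 1
    ms = find_minima(M, n_starts=100, seed=0, bounds=[(-1.0, 1.0)])
    assert len(ms) == 1
    assert recognize(M, np.array([0.0]), ms) == recognize(M, np.array([0.4 * sz]), ms) == 0


def test_run_online_constant_stream(kernel01):
    s = pf.StimulusSeries(np.full(40, -0.8), dt=1.0)
    L = pf.GridLandscape.for_series(s, kernel01, form="V")
    _, log = run_online(s, L, recognition_interval=1)
    assert (log["category"] == 0).all()


def test_run_online_recognition_is_read_only(kernel01):
    s = pf.gen_iid_bimodal(150, seed=4)
    L1 = pf.GridLandscape.for_series(s, kernel01, form="V")
    run_online(s, L1, recognition_interval=5)
    L2 = pf.GridLandscape.for_series(s, kernel01, form="V")
    pf.learn(L2, s)
    np.testing.assert_array_equal(L1.values, L2.values)


def test_run_online_bimodal_labels_match_modes(kernel01):
    # late-time recognition should attribute samples to the nearer density
    # mode almost always (the basin boundary nearly coincides with the
    # density antimode)
    dens = pf.true_density_iid(pf.BimodalTransformSpec())
    modes = dens.modes()
    s = pf.gen_iid_bimodal(3000, seed=8)
    L = pf.GridLandscape.for_series(s, kernel01, form="V")
    _, log = run_online(s, L, recognition_interval=10)
    late = log[log["time"] >= 1500]
    end_mode = np.argmin(np.abs(late["end1"].to_numpy()[:, None] - modes[None, :]), axis=1)
    eta_mode = np.argmin(np.abs(late["eta1"].to_numpy()[:, None] - modes[None, :]), axis=1)
    assert (end_mode == eta_mode).mean() >= 0.95
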