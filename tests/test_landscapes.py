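"""Synthetic landscapes: calibration exactness, gradients, alchemical pairs."""

import numpy as np
import pytest
import scipy.optimize as so
from hypothesis import given, settings, strategies as st

import stringfe as sf
from stringfe.constants import kbt
from stringfe.sampler import free_energy_quadrature

from conftest import MB_MINIMA, MB_MIN_ENERGIES, MB_SADDLES


# ---------------------------------------------------------------------------
# Muller-Brown
# ---------------------------------------------------------------------------


def test_muller_brown_stationary_points_have_zero_gradient(mb):
    for p in np.vstack([MB_MINIMA, MB_SADDLES]):
        assert np.linalg.norm(mb.gradient(p)) < 1e-4


def test_muller_brown_deepest_minimum_matches_grid_oracle(mb):
    # independent oracle: coarse grid search + local refinement
    xs = np.linspace(-1.8, 1.2, 400)
    ys = np.linspace(-0.5, 2.2, 400)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    E = mb.energy(np.stack([X, Y], axis=-1))
    i, j = np.unravel_index(np.argmin(E), E.shape)
    res = so.minimize(lambda p: mb.energy(p), [xs[i], ys[j]],
                      jac=lambda p: mb.gradient(p))
    assert res.fun == pytest.approx(-146.6995, abs=1e-3)
    assert res.fun == pytest.approx(MB_MIN_ENERGIES[0], abs=1e-6)


def test_muller_brown_two_lowest_minima_gap_matches_grid_oracle(mb):
    energies = []
    for guess in MB_MINIMA[:2]:
        res = so.minimize(lambda p: mb.energy(p), guess + 0.05,
                          jac=lambda p: mb.gradient(p))
        energies.append(res.fun)
    gap = energies[1] - energies[0]
    assert gap == pytest.approx(MB_MIN_ENERGIES[1] - MB_MIN_ENERGIES[0], abs=1e-6)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.floats(-1.5, 1.0), st.floats(-0.2, 2.0))
def test_muller_brown_gradient_consistency(x, y):
    mb = sf.muller_brown()
    p = np.array([x, y])
    h = 1e-6
    num = np.array([(mb.energy(p + h * e) - mb.energy(p - h * e)) / (2 * h)
                    for e in np.eye(2)])
    scale = max(1.0, np.linalg.norm(num))
    assert np.linalg.norm(mb.gradient(p) - num) / scale < 1e-5


# ---------------------------------------------------------------------------
# StationarySpec
# ---------------------------------------------------------------------------


def test_spec_rejects_non_alternating_kinds():
    with pytest.raises(ValueError, match="alternate"):
        sf.StationarySpec(["a", "b"], ["minimum", "minimum"], [0.0, 1.0])


def test_spec_rejects_saddle_below_flanking_minimum():
    with pytest.raises(ValueError, match="above both"):
        sf.StationarySpec(["a", "ts", "b"], ["minimum", "saddle", "minimum"],
                          [0.0, 2.0, 3.0])


def test_spec_csv_round_trip(tmp_path):
    spec = sf.load_stage_spec("deacylation")
    path = tmp_path / "spec.csv"
    spec.to_csv(path)
    back = sf.StationarySpec.from_csv(path, "ACE")
    assert back.labels == spec.labels
    np.testing.assert_allclose(back.free_energies, spec.free_energies)


def test_packaged_stage_tables_have_expected_values():
    acyl = sf.load_stage_spec("acylation")
    np.testing.assert_allclose(
        acyl.free_energies,
        [1.4, 14.0, 11.2, 18.6, 11.7, 13.7, 11.7, 13.6, 2.7])
    assert acyl.zero_reference_label == "MC"
    deacyl = sf.load_stage_spec("deacylation")
    np.testing.assert_allclose(deacyl.free_energies, [0.0, 18.6, 12.7, 20.9, 5.8])


# ---------------------------------------------------------------------------
# Calibrated landscapes
# ---------------------------------------------------------------------------

STAGES = ["acylation", "deacylation", "regeneration"]


@pytest.mark.parametrize("stage", STAGES)
def test_station_energies_exact(stage):
    spec = sf.load_stage_spec(stage)
    pot = sf.make_reaction_landscape(spec)
    e = pot.energy(pot.meta["stations"])
    np.testing.assert_allclose(e, spec.free_energies, atol=1e-6)


def test_station_gradients_vanish(deacylation_landscape):
    g = deacylation_landscape.gradient(deacylation_landscape.meta["stations"])
    assert np.abs(g).max() < 1e-8


def test_single_minimum_spec_gives_single_basin():
    spec = sf.StationarySpec(["only"], ["minimum"], [0.0])
    pot = sf.make_reaction_landscape(spec)
    station = pot.meta["stations"][0]
    assert pot.energy(station) == pytest.approx(0.0, abs=1e-12)
    # energy rises in every direction away from the basin
    for d in [np.array([1.0, 0]), np.array([-1, 0.0]), np.array([0, 1.0])]:
        assert pot.energy(station + 0.5 * d) > 1.0


def test_exact_pmf_along_curve_matches_prescription():
    """Transverse Gaussian quadrature oracle: PMF(t) = f(t) + const."""
    spec = sf.load_stage_spec("deacylation")
    pot = sf.make_reaction_landscape(spec)
    stations = pot.meta["stations"]
    ts = np.linspace(stations[0, 0], stations[-1, 0], 33)
    y = np.linspace(-1.5, 1.5, 801)
    pmf = []
    for t in ts:
        pts = np.stack([np.full_like(y, t), y], axis=1)
        e = pot.energy(pts)
        pmf.append(-kbt(310.0) * np.log(np.trapezoid(np.exp(-e / kbt(310.0)), y)))
    pmf = np.array(pmf)
    exact = pot.energy(np.stack([ts, np.zeros_like(ts)], axis=1))
    dev = (pmf - exact)
    assert dev.max() - dev.min() < 1e-3   # constant offset only


@pytest.mark.parametrize("geometry", ["line", "sine"])
def test_gradient_consistency_of_reaction_landscape(geometry):
    spec = sf.load_stage_spec("deacylation")
    pot = sf.make_reaction_landscape(spec, geometry=geometry)
    rng = np.random.default_rng(4)
    pts = rng.uniform([-0.2, -0.8], [5.2, 0.8], size=(40, 2))
    h = 1e-6
    for p in pts:
        num = np.array([(pot.energy(p + h * e) - pot.energy(p - h * e)) / (2 * h)
                        for e in np.eye(2)])
        scale = max(1.0, np.linalg.norm(num))
        assert np.linalg.norm(pot.gradient(p) - num) / scale < 1e-5


def test_relative_pmf_independent_of_transverse_stiffness():
    spec = sf.load_stage_spec("acylation")
    p1 = sf.make_reaction_landscape(spec, transverse_k=50.0)
    p2 = sf.make_reaction_landscape(spec, transverse_k=200.0)
    e1 = p1.energy(p1.meta["stations"])
    e2 = p2.energy(p2.meta["stations"])
    np.testing.assert_allclose(np.diff(e1), np.diff(e2), atol=1e-3)


def test_landscape_rejects_bad_inputs():
    spec = sf.load_stage_spec("deacylation")
    with pytest.raises(ValueError):
        sf.make_reaction_landscape(spec, dimension=1)
    with pytest.raises(ValueError):
        sf.make_reaction_landscape(spec, transverse_k=-1.0)


# ---------------------------------------------------------------------------
# Alchemical pairs
# ---------------------------------------------------------------------------


def test_mixing_endpoints_reproduce_end_states():
    pair = sf.make_alchemical_pair("harmonic-stiffness", k_a=1.0, k_b=3.0)
    rng = np.random.default_rng(1)
    x = rng.normal(size=(20, 1))
    np.testing.assert_allclose(pair.mixing(0.0).energy(x),
                               pair.end_state_A.energy(x), atol=1e-10)
    np.testing.assert_allclose(pair.mixing(1.0).energy(x),
                               pair.end_state_B.energy(x), atol=1e-10)


def test_identical_end_states_have_zero_dg():
    pair = sf.make_alchemical_pair("harmonic-stiffness", k_a=2.0, k_b=2.0)
    assert pair.analytic_dg == 0.0


def test_stiffness_ratio_e_squared_gives_kbt():
    pair = sf.make_alchemical_pair("harmonic-stiffness", k_a=1.0,
                                   k_b=float(np.exp(2)), temperature=310.0)
    assert pair.analytic_dg == pytest.approx(0.616, abs=1e-3)


def test_well_offset_dg_is_offset():
    pair = sf.make_alchemical_pair("well-offset", k_a=1.0, delta_v0=-2.5)
    assert pair.analytic_dg == -2.5


@pytest.mark.parametrize("kind,kw", [
    ("harmonic-stiffness", dict(k_a=1.0, k_b=4.0)),
    ("well-offset", dict(k_a=2.0, delta_v0=1.3)),
])
def test_analytic_dg_matches_boltzmann_quadrature(kind, kw):
    pair = sf.make_alchemical_pair(kind, **kw)
    box = np.array([[-15.0, 15.0]])
    dg = (free_energy_quadrature(pair.end_state_B, box, n=2001, temperature=310.0)
          - free_energy_quadrature(pair.end_state_A, box, n=2001, temperature=310.0))
    assert dg == pytest.approx(pair.analytic_dg, abs=1e-6)


def test_release_toy_calibration_is_exact():
    toy = sf.make_alchemical_pair("release-toy", target_dg=-4.47)
    assert toy.site.analytic_dg - toy.bulk.analytic_dg == pytest.approx(-4.47, abs=1e-10)
    # legs individually nontrivial
    assert abs(toy.site.analytic_dg) > 1.0


def test_nonpositive_stiffness_rejected():
    with pytest.raises(ValueError):
        sf.make_alchemical_pair("harmonic-stiffness", k_a=-1.0, k_b=1.0)


# ---------------------------------------------------------------------------
# OU series
# ---------------------------------------------------------------------------


def test_ou_variance_matches_equipartition():
    series = sf.make_ou_series(400_000, stiffness=1.0, temperature=310.0, seed=5)
    var = series.values.var()
    # exact stationary variance k_B T / k with a generous 3-sigma band
    n_eff = 400_000 / 20
    se = 0.6160 * np.sqrt(2.0 / n_eff)
    assert abs(var - 0.616032) < 3 * se


def test_ou_stiff_limit_collapses_variance():
    series = sf.make_ou_series(5000, stiffness=1e7, temperature=310.0, seed=5)
    assert series.values.var() < 1e-4


def test_ou_seed_reproducibility():
    a = sf.make_ou_series(1000, 1.0, seed=7)
    b = sf.make_ou_series(1000, 1.0, seed=7)
    np.testing.assert_array_equal(a.values, b.values)
    c = sf.make_ou_series(1000, 1.0, seed=8)
    assert not np.array_equal(a.values, c.values)


def test_ou_rejects_bad_parameters():
    with pytest.raises(ValueError):
        sf.make_ou_series(1, 1.0)
    with pytest.raises(ValueError):
        sf.make_ou_series(100, -1.0)
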