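"""Umbrella sampling, WHAM reconstruction and stationary-point extraction."""

import numpy as np
import pytest

import stringfe as sf
from stringfe.constants import kbt
from stringfe.path_coordinate import PathCV
from stringfe.pmf import (
    PMFProfile,
    WindowSet,
    extract_stationary,
    place_windows,
    pmf_error,
    run_umbrella,
    wham,
)
from stringfe.sampler import SamplerConfig

from conftest import harmonic_potential


def straight_path(length=4.0, n=9, dimension=2, start=0.0):
    xs = start + np.linspace(0.0, length, n)
    nodes = np.zeros((n, dimension))
    nodes[:, 0] = xs
    return PathCV(nodes, np.ones(dimension))


def walled_harmonic(k=2.0, lo=-1.0, hi=2.0, k_wall=100.0):
    """Harmonic along x with steep confining walls beyond [lo, hi]."""

    def energy(x):
        x = np.asarray(x, float)
        e = 0.5 * k * x[..., 0] ** 2 + 0.5 * 50.0 * x[..., 1] ** 2
        e = e + 0.5 * k_wall * np.clip(x[..., 0] - hi, 0, None) ** 2
        e = e + 0.5 * k_wall * np.clip(lo - x[..., 0], 0, None) ** 2
        return e

    def gradient(x):
        x = np.asarray(x, float)
        gx = (k * x[..., 0]
              + k_wall * np.clip(x[..., 0] - hi, 0, None)
              - k_wall * np.clip(lo - x[..., 0], 0, None))
        return np.stack([gx, 50.0 * x[..., 1]], axis=-1)

    import stringfe as sf
    return sf.Potential(2, energy, gradient, np.ones(2), "walled-harmonic")


@pytest.fixture(scope="module")
def harmonic_windows():
    """8 umbrella windows on a 1-D harmonic potential along a 2-D path.

    The path spans x in [-1, 2]; confining walls beyond the path ends keep
    every window's density inside the path (no clamped s = 0/1 pile-up),
    mirroring how the calibrated landscapes are built.
    """
    pot = walled_harmonic()
    # path padded half an angstrom beyond the walls, as the landscape
    # pipeline pads paths beyond the terminal minima
    path = straight_path(length=4.0, n=9, start=-1.5)
    ws = place_windows(pot, path, n_windows=8, seed=5,
                       pilot_config=SamplerConfig(n_steps=2000, burn_in=400,
                                                  friction=5.0, timestep=0.5))
    cfg = SamplerConfig(n_steps=500_000, burn_in=10_000, friction=5.0,
                        timestep=0.5)
    return pot, path, run_umbrella(pot, path, ws, config=cfg, seed=5)


def test_two_windows_use_interior_centers():
    pot = harmonic_potential(k=[0.0, 50.0], dimension=2)
    path = straight_path()
    ws = place_windows(pot, path, n_windows=2, seed=1,
                       pilot_config=SamplerConfig(n_steps=1500, burn_in=300,
                                                  friction=20.0))
    np.testing.assert_allclose(ws.centers, [0.25, 0.75])


def test_flat_potential_rescaling_near_unity():
    pot = harmonic_potential(k=[0.0, 50.0], dimension=2)   # flat along the path
    path = straight_path()
    ws = place_windows(pot, path, n_windows=8, seed=1,
                       pilot_config=SamplerConfig(n_steps=4000, burn_in=800,
                                                  friction=20.0, timestep=0.5))
    k0 = 4.0 * kbt(ws.temperature) * 8**2
    np.testing.assert_allclose(ws.stiffnesses, k0, rtol=0.45)
    # observed sd close to the target on a flat stretch
    assert np.median(np.abs(ws.pilot_sd / ws.target_sd - 1.0)) < 0.2


def test_narrowed_window_reduces_stiffness():
    """Stiff longitudinal confinement -> observed sd below target -> the
    rescaling formula reduces the force constant by the squared ratio."""
    pot = harmonic_potential(k=[500.0, 50.0], dimension=2)
    path = straight_path(length=1.0, n=5)
    ws = place_windows(pot, path, n_windows=4, seed=2,
                       pilot_config=SamplerConfig(n_steps=3000, burn_in=600,
                                                  friction=20.0, timestep=0.5))
    k0 = 4.0 * kbt(ws.temperature) * 4**2
    expected = k0 * np.clip((ws.pilot_sd / ws.target_sd) ** 2, 0.25, 4.0)
    np.testing.assert_allclose(ws.stiffnesses, expected, rtol=1e-12)
    assert np.all(ws.pilot_sd < ws.target_sd)
    assert np.all(ws.stiffnesses < k0)


def test_window_centers_must_increase():
    with pytest.raises(ValueError):
        WindowSet(centers=[0.5, 0.25], stiffnesses=[1.0, 1.0], temperature=310.0)


def test_degenerate_single_window_matches_unbiased_histogram():
    """Zero-stiffness single-window WHAM reduces to -kT ln(histogram)."""
    pot = harmonic_potential(k=[3.0, 50.0], dimension=2)
    path = straight_path(length=3.0, n=7)
    ws = WindowSet(centers=np.array([0.5]), stiffnesses=np.array([0.0]),
                   temperature=310.0)
    cfg = SamplerConfig(n_steps=80_000, burn_in=5_000, friction=20.0,
                        timestep=0.5)
    ws = run_umbrella(pot, path, ws, config=cfg, seed=7)
    prof = wham(ws, n_bins=60, compute_uncertainty=False)
    hist, edges = np.histogram(ws.samples[:, 0], bins=60, range=(0, 1))
    with np.errstate(divide="ignore"):
        ref = -kbt(310.0) * np.log(hist / hist.sum())
    ref -= np.nanmin(np.where(hist > 0, ref, np.nan))
    valid = hist > 0
    np.testing.assert_allclose(prof.free_energy[valid], ref[valid], atol=1e-9)


def test_wham_recovers_harmonic_profile(harmonic_windows):
    pot, path, ws = harmonic_windows
    prof = wham(ws, n_bins=100, compute_uncertainty=False)
    # exact PMF along the path: 0.5 * k * x(s)^2 with x = -1.5 + s L
    x = -1.5 + prof.grid * path.total_length
    exact = 0.5 * 2.0 * x**2
    ref = np.argmin(np.abs(prof.grid - 0.35))
    diff = (prof.free_energy - prof.free_energy[ref]) - (exact - exact[ref])
    # the sampled range: bins with solid occupation across the window set
    hist, _ = np.histogram(ws.samples.ravel(), bins=100, range=(0, 1))
    sampled = (hist > 500) & np.isfinite(prof.free_energy)
    # walls distort the exact harmonic reference outside [-1, 2]
    x_ok = (x > -0.99) & (x < 1.99)
    assert np.nanmax(np.abs(diff[sampled & x_ok])) < 0.05


def test_wham_fails_on_gap():
    ws = WindowSet(centers=np.array([0.2, 0.8]),
                   stiffnesses=np.array([1e5, 1e5]), temperature=310.0)
    rng = np.random.default_rng(0)
    ws.samples = np.stack([rng.normal(0.2, 0.005, 4000),
                           rng.normal(0.8, 0.005, 4000)], axis=1)
    with pytest.raises(RuntimeError, match="overlap"):
        wham(ws, compute_uncertainty=False)


def test_wham_reports_nonconvergence():
    ws = WindowSet(centers=np.array([0.4, 0.6]),
                   stiffnesses=np.array([50.0, 50.0]), temperature=310.0)
    rng = np.random.default_rng(0)
    ws.samples = np.stack([rng.normal(0.45, 0.1, 4000) % 1.0,
                           rng.normal(0.55, 0.1, 4000) % 1.0], axis=1)
    with pytest.raises(RuntimeError, match="converge"):
        wham(ws, max_iter=2, compute_uncertainty=False)


# ---------------------------------------------------------------------------
# Stationary-point extraction
# ---------------------------------------------------------------------------


def _profile_from(g, err=None):
    grid = np.linspace(0, 1, len(g))
    return PMFProfile(grid=grid, free_energy=np.asarray(g, float),
                      uncertainty=err, zero_reference="global_min")


def test_monotonic_profile_yields_endpoints_only():
    table = extract_stationary(_profile_from(np.linspace(0, 5, 101)),
                               smoothing_window=1)
    assert table.note.startswith("no interior extremum")
    assert len(table.labels) == 2


def test_analytic_extrema_recovered_within_one_bin():
    s = np.linspace(0, 1, 501)
    g = 3.0 * np.sin(2 * np.pi * s) ** 2                # extrema at 1/4, 1/2, 3/4
    prof = _profile_from(g)
    table = extract_stationary(prof, smoothing_window=1, min_prominence=0.5)
    from scipy.signal import argrelextrema
    true_max = s[argrelextrema(g, np.greater)[0]]
    true_min = s[argrelextrema(g, np.less)[0]]
    got_max = table.s_locations[[k == "maximum" for k in table.kinds]]
    got_min = table.s_locations[[k == "minimum" for k in table.kinds]]
    bin_w = s[1] - s[0]
    np.testing.assert_allclose(np.sort(got_max), np.sort(true_max), atol=bin_w)
    np.testing.assert_allclose(np.sort(got_min), np.sort(true_min), atol=bin_w)
    # energies read off the profile exactly
    for loc, e in zip(table.s_locations, table.free_energies):
        assert e == pytest.approx(g[np.argmin(np.abs(s - loc))], abs=1e-6)


def test_extraction_alternates_kinds():
    rng = np.random.default_rng(2)
    g = np.cumsum(rng.normal(0, 0.3, 400))
    table = extract_stationary(_profile_from(g), smoothing_window=7,
                               min_prominence=0.5)
    for a, b in zip(table.kinds, table.kinds[1:]):
        assert a != b


def test_stationary_table_csv_round_trip(tmp_path):
    table = extract_stationary(
        _profile_from(3 * np.sin(2 * np.pi * np.linspace(0, 1, 301)) ** 2))
    p = tmp_path / "table.csv"
    table.to_csv(p)
    back = sf.StationaryTable.from_csv(p)
    np.testing.assert_allclose(back.free_energies, table.free_energies)
    assert back.labels == table.labels


# ---------------------------------------------------------------------------
# Bootstrap uncertainty
# ---------------------------------------------------------------------------


def test_pmf_error_is_seed_reproducible(harmonic_windows):
    _, _, ws = harmonic_windows
    e1 = pmf_error(ws, n_bins=100, n_resamples=20, seed=3)
    e2 = pmf_error(ws, n_bins=100, n_resamples=20, seed=3)
    np.testing.assert_array_equal(e1, e2)
    assert np.nanmax(e1) > 0


def test_pmf_error_shrinks_with_more_samples(harmonic_windows):
    pot, path, ws = harmonic_windows
    half = WindowSet(centers=ws.centers, stiffnesses=ws.stiffnesses,
                     temperature=ws.temperature)
    half.samples = ws.samples[: ws.samples.shape[0] // 2]
    e_half = pmf_error(half, n_bins=100, n_resamples=40, seed=3)
    e_full = pmf_error(ws, n_bins=100, n_resamples=40, seed=3)
    ratio = np.nanmean(e_full) / np.nanmean(e_half)
    assert 0.55 < ratio < 0.9      # ~1/sqrt(2) Monte-Carlo scaling


def test_duplicated_windows_leave_profile_unchanged(harmonic_windows):
    _, _, ws = harmonic_windows
    order = np.argsort(np.concatenate([ws.centers, ws.centers + 1e-9]))
    dup = WindowSet(centers=np.concatenate([ws.centers, ws.centers + 1e-9])[order],
                    stiffnesses=np.tile(ws.stiffnesses, 2)[order],
                    temperature=ws.temperature)
    dup.samples = np.concatenate([ws.samples, ws.samples], axis=1)[:, order]
    p1 = wham(ws, n_bins=100, compute_uncertainty=False)
    p2 = wham(dup, n_bins=100, compute_uncertainty=False)
    valid = np.isfinite(p1.free_energy) & np.isfinite(p2.free_energy)
    assert np.nanmax(np.abs(p1.free_energy[valid] - p2.free_energy[valid])) < 0.02


def test_pmf_error_requires_enough_blocks():
    ws = WindowSet(centers=np.array([0.5]), stiffnesses=np.array([1.0]),
                   temperature=310.0)
    ws.samples = np.full((10, 1), 0.5)
    with pytest.raises(ValueError, match="block"):
        pmf_error(ws, n_blocks=20, n_resamples=5)
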