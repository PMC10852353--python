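"""Umbrella sampling along the path-CV, WHAM, and stationary-point tables.

Windows are placed at equally spaced interior centers on s in [0, 1] with
an initial force constant of 4 k_B T / (delta s)^2 (biased Gaussian sd of
half the spacing).  A short pilot run measures the realized sd per window
and rescales each force constant by (observed sd / target sd)^2, clipped
to [0.25, 4] times the initial value — the "on-the-fly" calibration that
keeps the reaction-coordinate density homogeneous.  The profile is then
reconstructed by self-consistent WHAM on a fixed grid, shifted so the
declared zero reference is 0, with per-bin uncertainties from a seeded
block bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .constants import DEFAULT_TEMPERATURE, kbt
from .path_coordinate import PathCV, build_path, project
from .sampler import SamplerConfig, derive_rng, langevin_baoab
from .string_mfep import converge_string

__all__ = [
    "WindowSet",
    "PMFProfile",
    "StationaryTable",
    "place_windows",
    "run_umbrella",
    "wham",
    "extract_stationary",
    "pmf_error",
    "run_profile_pipeline",
    "PipelineResult",
]


# ---------------------------------------------------------------------------
# Window placement and sampling
# ---------------------------------------------------------------------------


@dataclass
class WindowSet:
    centers: np.ndarray                 # (W,) strictly increasing in [0, 1]
    stiffnesses: np.ndarray             # (W,) [kcal/mol per unit s^2]
    temperature: float
    samples: Optional[np.ndarray] = None        # (n_kept, W) s-series
    pilot_sd: Optional[np.ndarray] = None
    target_sd: float = 0.0

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.stiffnesses = np.asarray(self.stiffnesses, dtype=float)
        if np.any(np.diff(self.centers) <= 0):
            raise ValueError("window centers must be strictly increasing")
        if self.centers.min() < 0 or self.centers.max() > 1:
            raise ValueError("window centers must lie in [0, 1]")

    @property
    def n_windows(self) -> int:
        return len(self.centers)


def _sample_s(potential, path: PathCV, centers, stiffnesses, config: SamplerConfig, rng):
    """Batched biased sampling; returns the (n_kept, W) series of s values."""
    centers = np.asarray(centers, dtype=float)
    ks = np.asarray(stiffnesses, dtype=float)
    x0 = np.atleast_2d(path.point_at(centers))

    def force_fn(x):
        s, grad_s = path.project_with_gradient(x)
        return -potential.gradient(x) - (ks * (s - centers))[:, None] * grad_s

    def observe(x):
        s, _ = path.project_with_gradient(x)
        return s

    traj, _ = langevin_baoab(
        force_fn, x0, potential.masses, config, rng, store=True, observe=observe
    )
    return np.asarray(traj)             # (n_kept, W)


def place_windows(
    potential,
    path: PathCV,
    n_windows: int = 48,
    temperature: float = DEFAULT_TEMPERATURE,
    pilot_config: Optional[SamplerConfig] = None,
    seed: int = 0,
) -> WindowSet:
    """Equally spaced windows with pilot-calibrated force constants."""
    if n_windows < 2:
        raise ValueError("n_windows must be >= 2")
    centers = (np.arange(n_windows) + 0.5) / n_windows
    spacing = 1.0 / n_windows
    target_sd = spacing / 2.0
    k0 = 4.0 * kbt(temperature) / spacing**2
    ks = np.full(n_windows, k0)
    if pilot_config is None:
        pilot_config = SamplerConfig(n_steps=3000, burn_in=600,
                                     temperature=temperature, timestep=0.5)
    pilot_config = pilot_config.replace(temperature=temperature)

    for attempt in range(2):
        rng = derive_rng(seed, 0, attempt)
        s = _sample_s(potential, path, centers, ks, pilot_config, rng)
        sd = s.std(axis=0)
        if np.all(sd > 0):
            break
        ks = np.where(sd > 0, ks, ks * 4.0)    # empty/degenerate pilot window
    else:
        raise RuntimeError("pilot sampling produced degenerate windows twice")

    factor = np.clip((sd / target_sd) ** 2, 0.25, 4.0)
    return WindowSet(
        centers=centers,
        stiffnesses=k0 * factor,
        temperature=temperature,
        pilot_sd=sd,
        target_sd=target_sd,
    )


def run_umbrella(
    potential,
    path: PathCV,
    windows: WindowSet,
    config: Optional[SamplerConfig] = None,
    seed: int = 0,
) -> WindowSet:
    """Production umbrella sampling with the calibrated force constants."""
    if config is None:
        config = SamplerConfig(n_steps=110_000, burn_in=10_000, friction=10.0,
                               temperature=windows.temperature, timestep=0.5)
    config = config.replace(temperature=windows.temperature)
    rng = derive_rng(seed, 1)
    windows.samples = _sample_s(potential, path, windows.centers,
                                windows.stiffnesses, config, rng)
    return windows


# ---------------------------------------------------------------------------
# WHAM
# ---------------------------------------------------------------------------


@dataclass
class PMFProfile:
    grid: np.ndarray                    # (B,) bin midpoints in s
    free_energy: np.ndarray             # (B,) [kcal/mol], NaN where unsampled
    uncertainty: Optional[np.ndarray]   # (B,) [kcal/mol]
    zero_reference: str = "global_min"
    temperature: float = DEFAULT_TEMPERATURE
    meta: dict = field(default_factory=dict)

    def value_at(self, s: float | np.ndarray) -> np.ndarray:
        valid = np.isfinite(self.free_energy)
        return np.interp(np.asarray(s, dtype=float),
                         self.grid[valid], self.free_energy[valid])

    def to_csv(self, path: str | Path) -> None:
        err = self.uncertainty if self.uncertainty is not None else np.full_like(self.grid, np.nan)
        pd.DataFrame({"s": self.grid, "free_energy": self.free_energy,
                      "error": err}).to_csv(path, index=False)


def _wham_core(hist, n_w, bias, beta, tol, max_iter, f_init=None):
    """Self-consistent WHAM on binned data.

    hist: (B,) total counts; n_w: (W,) per-window counts; bias: (W, B)
    bias energies at bin centers.  Returns (G (B,), f (W,), n_iter).
    Stabilized matrix iteration in probability space (exponent shifts make
    it equivalent to the log-space form).
    """
    b = np.exp(-beta * (bias - bias.min()))            # (W, B), in (0, 1]
    f = np.zeros(len(n_w)) if f_init is None else f_init.copy()
    sampled = hist > 0
    residual = np.inf
    for it in range(max_iter):
        expf = np.exp(beta * (f - f.max()))
        denom = (n_w * expf) @ b                       # (B,)
        p = np.where(denom > 0, hist / np.maximum(denom, 1e-300), 0.0)
        z = b @ p                                       # (W,)
        f_new = -np.log(np.maximum(z, 1e-300)) / beta
        f_new -= f_new[0]
        residual = np.max(np.abs(f_new - f)) / max(1.0, np.max(np.abs(f_new)))
        f = f_new
        if residual < tol:
            break
    else:
        raise RuntimeError(
            f"WHAM did not converge in {max_iter} iterations (residual {residual:.3e})"
        )
    with np.errstate(divide="ignore"):
        g = np.where(sampled, -np.log(np.where(sampled, p, 1.0)) / beta, np.nan)
    return g, f, it + 1


def _apply_zero_reference(g: np.ndarray, grid: np.ndarray, zero_reference) -> np.ndarray:
    valid = np.isfinite(g)
    if isinstance(zero_reference, (int, np.integer)):
        return g - g[int(zero_reference)]
    if zero_reference == "global_min":
        return g - np.nanmin(g)
    if zero_reference == "first_min":
        gv = g[valid]
        peaks, _ = find_peaks(-gv)
        ref = gv[peaks[0]] if len(peaks) else np.nanmin(g)
        return g - ref
    raise ValueError(f"unknown zero reference {zero_reference!r}")


def wham(
    windows: WindowSet,
    temperature: Optional[float] = None,
    n_bins: int = 200,
    tolerance: float = 1e-10,
    max_iter: int = 500_000,
    zero_reference="global_min",
    seed: int = 0,
    n_resamples: int = 100,
    n_blocks: int = 20,
    compute_uncertainty: bool = True,
) -> PMFProfile:
    """Weighted-histogram reconstruction of the free-energy profile.

    Fails if adjacent windows share no occupied bin (naming the gap) or if
    the self-consistent iteration does not reach ``tolerance`` within
    ``max_iter``.  Uncertainty is a seeded block bootstrap (see
    :func:`pmf_error`).
    """
    if windows.samples is None:
        raise ValueError("windows carry no samples; run run_umbrella first")
    temperature = windows.temperature if temperature is None else temperature
    beta = 1.0 / kbt(temperature)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])

    s = windows.samples                                    # (n, W)
    counts = np.stack([np.histogram(s[:, w], bins=edges)[0]
                       for w in range(windows.n_windows)])  # (W, B)
    occupied = counts > 0
    for w in range(windows.n_windows - 1):
        if not np.any(occupied[w] & occupied[w + 1]):
            raise RuntimeError(
                f"no histogram overlap between windows {w} (center "
                f"{windows.centers[w]:.4f}) and {w + 1} (center "
                f"{windows.centers[w + 1]:.4f})"
            )
    hist = counts.sum(axis=0)
    n_w = counts.sum(axis=1).astype(float)
    bias = 0.5 * windows.stiffnesses[:, None] * (mids[None, :] - windows.centers[:, None]) ** 2

    g, f, n_iter = _wham_core(hist, n_w, bias, beta, tolerance, max_iter)
    g = _apply_zero_reference(g, mids, zero_reference)

    unc = None
    if compute_uncertainty:
        unc = pmf_error(windows, n_bins=n_bins, n_resamples=n_resamples,
                        seed=seed, n_blocks=n_blocks, zero_reference=zero_reference,
                        temperature=temperature, f_init=f)
    return PMFProfile(
        grid=mids, free_energy=g, uncertainty=unc,
        zero_reference=str(zero_reference), temperature=temperature,
        meta={"wham_iterations": n_iter, "window_free_energies": f},
    )


def pmf_error(
    windows: WindowSet,
    n_bins: int = 200,
    n_resamples: int = 100,
    seed: int = 0,
    n_blocks: int = 20,
    zero_reference="global_min",
    temperature: Optional[float] = None,
    f_init: Optional[np.ndarray] = None,
    tolerance: float = 1e-8,
    max_iter: int = 200_000,
) -> np.ndarray:
    """Per-bin block-bootstrap standard deviation of the WHAM profile.

    Each window's time series is cut into ``n_blocks`` contiguous blocks
    (capturing autocorrelation); resamples draw blocks with replacement and
    re-solve WHAM (warm-started).  Seeded and reproducible.
    """
    if n_resamples < 2:
        raise ValueError("need at least 2 resamples")
    if windows.samples is None:
        raise ValueError("windows carry no samples")
    n = windows.samples.shape[0]
    if n < 2 * n_blocks:
        raise ValueError("fewer than 2 samples per block in each window")
    temperature = windows.temperature if temperature is None else temperature
    beta = 1.0 / kbt(temperature)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    bias = 0.5 * windows.stiffnesses[:, None] * (mids[None, :] - windows.centers[:, None]) ** 2

    # per-block histograms once; each bootstrap resample is then just a sum
    blocks = np.array_split(np.arange(n), n_blocks)
    w_count = windows.n_windows
    block_hist = np.empty((n_blocks, w_count, n_bins))
    for bi, idx in enumerate(blocks):
        s = windows.samples[idx]
        for w in range(w_count):
            block_hist[bi, w] = np.histogram(s[:, w], bins=edges)[0]

    rng = derive_rng(seed, 2)
    profiles = []
    f_warm = f_init
    for _ in range(n_resamples):
        pick = rng.integers(0, n_blocks, size=n_blocks)
        counts = block_hist[pick].sum(axis=0)
        hist = counts.sum(axis=0)
        n_w = counts.sum(axis=1)
        try:
            g, f_warm, _ = _wham_core(hist, n_w, bias, beta, tolerance, max_iter,
                                      f_init=f_warm)
        except RuntimeError:
            continue
        profiles.append(_apply_zero_reference(g, mids, zero_reference))
    stack = np.array(profiles)
    with warnings.catch_warnings():
        # bins sampled in no resample are all-NaN columns -> NaN uncertainty
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanstd(stack, axis=0, ddof=1)


# ---------------------------------------------------------------------------
# Stationary-point extraction
# ---------------------------------------------------------------------------


@dataclass
class StationaryTable:
    labels: list
    kinds: list                          # "minimum" / "maximum"
    s_locations: np.ndarray
    free_energies: np.ndarray
    errors: np.ndarray
    note: str = ""

    def __post_init__(self) -> None:
        self.s_locations = np.asarray(self.s_locations, dtype=float)
        self.free_energies = np.asarray(self.free_energies, dtype=float)
        self.errors = np.asarray(self.errors, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "label": self.labels, "kind": self.kinds, "s": self.s_locations,
            "free_energy": self.free_energies, "error": self.errors,
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "StationaryTable":
        df = pd.read_csv(path)
        err = df["error"].to_numpy(dtype=float) if "error" in df else np.zeros(len(df))
        s = df["s"].to_numpy(dtype=float) if "s" in df else np.linspace(0, 1, len(df))
        return cls(labels=[str(x) for x in df["label"]],
                   kinds=[str(x) for x in df["kind"]],
                   s_locations=s,
                   free_energies=df["free_energy"].to_numpy(dtype=float),
                   errors=err)


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y
    return pd.Series(y).rolling(window, center=True, min_periods=1).mean().to_numpy()


def extract_stationary(
    profile: PMFProfile,
    smoothing_window: int = 5,
    min_prominence: float = 0.5,
) -> StationaryTable:
    """Local minima/maxima of the (optionally smoothed) profile.

    Peaks must have prominence >= ``min_prominence`` kcal/mol.  Energies
    and errors are read from the unsmoothed profile at the peak bins and
    are relative to the profile's declared zero.  A profile with no
    interior extremum yields an endpoints-only table with a note.
    """
    valid = np.isfinite(profile.free_energy)
    g = profile.free_energy[valid]
    s = profile.grid[valid]
    err = (profile.uncertainty[valid] if profile.uncertainty is not None
           else np.zeros_like(g))
    if len(g) == 0:
        raise ValueError("empty profile")
    gs = _smooth(g, smoothing_window)
    maxima, _ = find_peaks(gs, prominence=min_prominence)
    minima, _ = find_peaks(-gs, prominence=min_prominence)
    idx = sorted([(i, "maximum") for i in maxima] + [(i, "minimum") for i in minima])

    # enforce alternation: among same-kind neighbors keep the more extreme
    cleaned = []
    for i, kind in idx:
        if cleaned and cleaned[-1][1] == kind:
            j, _ = cleaned[-1]
            better = (g[i] > g[j]) if kind == "maximum" else (g[i] < g[j])
            if better:
                cleaned[-1] = (i, kind)
        else:
            cleaned.append((i, kind))

    note = ""
    if not cleaned:
        cleaned = [(0, "minimum" if g[0] <= g[-1] else "maximum"),
                   (len(g) - 1, "minimum" if g[-1] < g[0] else "maximum")]
        note = "no interior extremum; endpoints only"

    labels, kinds, locs, energies, errors = [], [], [], [], []
    n_min = n_max = 0
    for i, kind in cleaned:
        if kind == "minimum":
            n_min += 1
            labels.append(f"MIN{n_min}")
        else:
            n_max += 1
            labels.append(f"TS{n_max}")
        kinds.append(kind)
        locs.append(s[i])
        energies.append(g[i])
        errors.append(err[i])
    return StationaryTable(labels=labels, kinds=kinds, s_locations=np.array(locs),
                           free_energies=np.array(energies), errors=np.array(errors),
                           note=note)


# ---------------------------------------------------------------------------
# End-to-end pipeline: string -> path-CV -> umbrella sampling -> WHAM
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    string_state: object
    path: PathCV
    windows: WindowSet
    profile: PMFProfile
    stationary: StationaryTable
    station_s: Optional[np.ndarray] = None
    station_energies: Optional[np.ndarray] = None      # relative to first station
    station_energies_ref: Optional[np.ndarray] = None  # on the calibration's
    station_labels: Optional[list] = None              # external reference scale


def run_profile_pipeline(
    potential,
    endpoints=None,
    seed: int = 0,
    n_nodes: int = 25,
    string_config: Optional[SamplerConfig] = None,
    string_iterations: int = 80,
    string_step: float = 0.02,
    node_stiffness: float = 300.0,
    n_windows: int = 48,
    production_config: Optional[SamplerConfig] = None,
    n_bins: int = 200,
    n_resamples: int = 60,
    temperature: float = DEFAULT_TEMPERATURE,
    path_padding: Optional[float] = None,
) -> PipelineResult:
    """Full free-energy-profile reconstruction on one landscape.

    Refines the string, builds the path-CV (extended slightly beyond the
    terminal minima so they sit in the window interior), calibrates and
    runs umbrella sampling, reconstructs the profile by WHAM (zero at the
    first station / first minimum), and extracts stationary points.  If
    the potential carries calibration-station metadata, the recovered
    station energies are also reported on the calibration's reference
    scale.
    """
    meta = getattr(potential, "meta", {})
    if endpoints is None:
        if "endpoints" not in meta:
            raise ValueError("no endpoints given and none in potential metadata")
        endpoints = meta["endpoints"]
    a, b = np.asarray(endpoints[0], float), np.asarray(endpoints[1], float)

    if string_config is None:
        string_config = SamplerConfig(n_steps=400, burn_in=120, friction=10.0,
                                      temperature=temperature)
    state = converge_string(
        potential, a, b, n_nodes=n_nodes, sampler_config=string_config,
        step_size=string_step, max_iterations=string_iterations,
        node_stiffness=node_stiffness, seed=seed,
    )
    path = build_path(state, override=True)
    if path_padding is None:
        path_padding = 0.08 * path.total_length
    if path_padding > 0:
        path = path.extended(path_padding)

    windows = place_windows(potential, path, n_windows=n_windows,
                            temperature=temperature, seed=seed)
    windows = run_umbrella(potential, path, windows,
                           config=production_config, seed=seed)

    station_s = station_g = station_ref = station_labels = None
    zero_ref = "first_min"
    if "stations" in meta:
        station_s, _ = project(np.asarray(meta["stations"], float), path)
        station_labels = list(meta.get("station_labels", []))

    profile = wham(windows, temperature=temperature, n_bins=n_bins,
                   zero_reference=zero_ref, seed=seed, n_resamples=n_resamples)
    stationary = extract_stationary(profile)

    if station_s is not None:
        g_at = profile.value_at(station_s)
        station_g = g_at - g_at[0]
        station_ref = station_g + float(meta["station_energies"][0])

    return PipelineResult(
        string_state=state, path=path, windows=windows, profile=profile,
        stationary=stationary, station_s=station_s, station_energies=station_g,
        station_energies_ref=station_ref, station_labels=station_labels,
    )
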