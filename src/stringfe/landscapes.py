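"""Synthetic collective-variable landscapes and alchemical end-state pairs.

This module generates the analytic test systems on which the rest of the
package operates:

* :func:`muller_brown` -- the canonical three-well, two-saddle 2-D surface
  used to validate minimum-free-energy-path algorithms.
* :func:`make_reaction_landscape` -- multi-basin landscapes calibrated so
  that the free energy along an embedded curve passes *exactly* through a
  prescribed sequence of stationary values (minima and saddles), with
  uniform harmonic confinement transverse to the curve.  Because the
  transverse confinement is uniform, the exact potential of mean force
  along the curve equals the prescribed profile plus an additive constant.
* :func:`make_alchemical_pair` -- paired end-state potentials with a
  closed-form free-energy difference, for exercising thermodynamic
  integration.
* :func:`make_ou_series` -- stationary Ornstein-Uhlenbeck time series used
  as fixtures for trajectory descriptors.

Calibration tables for the asparaginase catalytic stages (acylation,
deacylation/hydrolysis, enzyme regeneration) ship as CSV files under
``stringfe/data`` and are loaded by :func:`load_stage_spec`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicHermiteSpline

from .constants import DEFAULT_TEMPERATURE, kbt

__all__ = [
    "Potential",
    "StationarySpec",
    "AlchemicalPair",
    "ReleaseToy",
    "muller_brown",
    "make_reaction_landscape",
    "make_alchemical_pair",
    "make_ou_series",
    "load_stage_spec",
    "stage_spec_path",
]


# ---------------------------------------------------------------------------
# Potential
# ---------------------------------------------------------------------------

@dataclass
class Potential:
    """A differentiable scalar energy field over a low-dimensional CV vector.

    ``energy`` maps arrays of shape ``(..., dimension)`` [A] to energies of
    shape ``(...)`` [kcal/mol]; ``gradient`` maps the same input to
    gradients of shape ``(..., dimension)`` [kcal/mol/A].  ``masses`` carry
    the per-coordinate masses [amu] defining the mass-weighted metric
    (transferred-proton coordinates conventionally get 2 amu).
    """

    dimension: int
    energy: Callable[[np.ndarray], np.ndarray]
    gradient: Callable[[np.ndarray], np.ndarray]
    masses: np.ndarray
    label: str = ""
    sampling_box: Optional[np.ndarray] = None  # (dimension, 2)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dimension < 1:
            raise ValueError("Potential dimension must be positive")
        self.masses = np.atleast_1d(np.asarray(self.masses, dtype=float))
        if self.masses.shape != (self.dimension,):
            raise ValueError("masses must have one entry per coordinate")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.energy(x)

    def metadata_json(self) -> str:
        """JSON serialization of the potential's metadata (not the field)."""
        payload = {
            "dimension": self.dimension,
            "masses": self.masses.tolist(),
            "label": self.label,
            "sampling_box": None
            if self.sampling_box is None
            else np.asarray(self.sampling_box).tolist(),
        }
        for key, value in self.meta.items():
            if isinstance(value, np.ndarray):
                payload[key] = value.tolist()
            elif isinstance(value, (str, int, float, list, dict, bool, type(None))):
                payload[key] = value
        return json.dumps(payload, indent=2)


# ---------------------------------------------------------------------------
# Muller-Brown surface
# ---------------------------------------------------------------------------

_MB_A = np.array([-200.0, -100.0, -170.0, 15.0])
_MB_a = np.array([-1.0, -1.0, -6.5, 0.7])
_MB_b = np.array([0.0, 0.0, 11.0, 0.6])
_MB_c = np.array([-10.0, -10.0, -6.5, 0.7])
_MB_x0 = np.array([1.0, 0.0, -0.5, -1.0])
_MB_y0 = np.array([0.0, 0.5, 1.5, 1.0])


def muller_brown() -> Potential:
    """The canonical three-well, two-saddle 2-D test surface.

    Energies are treated as kcal/mol on the package's unit system so the
    surface can be sampled directly.
    """

    def energy(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        u = x[..., 0, None] - _MB_x0
        v = x[..., 1, None] - _MB_y0
        terms = _MB_A * np.exp(_MB_a * u**2 + _MB_b * u * v + _MB_c * v**2)
        return terms.sum(axis=-1)

    def gradient(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        u = x[..., 0, None] - _MB_x0
        v = x[..., 1, None] - _MB_y0
        terms = _MB_A * np.exp(_MB_a * u**2 + _MB_b * u * v + _MB_c * v**2)
        gx = (terms * (2.0 * _MB_a * u + _MB_b * v)).sum(axis=-1)
        gy = (terms * (_MB_b * u + 2.0 * _MB_c * v)).sum(axis=-1)
        return np.stack([gx, gy], axis=-1)

    return Potential(
        dimension=2,
        energy=energy,
        gradient=gradient,
        masses=np.ones(2),
        label="muller-brown",
        sampling_box=np.array([[-1.8, 1.2], [-0.5, 2.2]]),
    )


# ---------------------------------------------------------------------------
# StationarySpec
# ---------------------------------------------------------------------------

_KINDS = ("minimum", "saddle")


@dataclass
class StationarySpec:
    """Ordered stationary points (label, kind, free energy) along a path.

    Entries must alternate minimum/saddle/minimum..., starting and ending
    with minima, and every saddle must lie above both flanking minima.
    ``zero_reference_label`` names the state whose free energy defines zero;
    it may be one of the entries (then that entry must be at 0) or an
    external reference state (e.g. the Michaelis complex for an acylation
    stage whose first on-path state already includes an activation cost).
    """

    labels: list[str]
    kinds: list[str]
    free_energies: np.ndarray
    zero_reference_label: str = ""

    def __post_init__(self) -> None:
        self.free_energies = np.asarray(self.free_energies, dtype=float)
        self.validate()

    @property
    def n_stations(self) -> int:
        return len(self.labels)

    def validate(self) -> None:
        n = len(self.labels)
        if not (n == len(self.kinds) == len(self.free_energies)):
            raise ValueError("labels, kinds and free_energies must align")
        if n < 1:
            raise ValueError("spec needs at least one stationary point")
        for i, kind in enumerate(self.kinds):
            if kind not in _KINDS:
                raise ValueError(f"unknown kind {kind!r}")
            expected = "minimum" if i % 2 == 0 else "saddle"
            if kind != expected:
                raise ValueError(
                    "stationary points must alternate minimum/saddle/minimum; "
                    f"entry {i} ({self.labels[i]}) is {kind!r}, expected {expected!r}"
                )
        if self.kinds[-1] != "minimum":
            raise ValueError("last stationary point must be a minimum")
        g = self.free_energies
        for i, kind in enumerate(self.kinds):
            if kind == "saddle" and not (g[i] > g[i - 1] and g[i] > g[i + 1]):
                raise ValueError(
                    f"saddle {self.labels[i]} ({g[i]:.3f}) must lie above both "
                    f"flanking minima ({g[i - 1]:.3f}, {g[i + 1]:.3f})"
                )
        if self.zero_reference_label in self.labels:
            idx = self.labels.index(self.zero_reference_label)
            if abs(g[idx]) > 1e-12:
                raise ValueError(
                    "the entry carrying the zero reference must have free energy 0"
                )

    @classmethod
    def from_csv(cls, path: str | Path, zero_reference_label: str = "") -> "StationarySpec":
        df = pd.read_csv(path)
        return cls(
            labels=[str(x) for x in df["label"]],
            kinds=[str(x) for x in df["kind"]],
            free_energies=df["free_energy"].to_numpy(dtype=float),
            zero_reference_label=zero_reference_label,
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"label": self.labels, "kind": self.kinds, "free_energy": self.free_energies}
        ).to_csv(path, index=False)


_STAGE_REFERENCES = {
    "acylation": "MC",
    "deacylation": "ACE",
    "regeneration": "P",
}


def stage_spec_path(stage: str) -> Path:
    """Filesystem path of a packaged stage calibration table."""
    if stage not in _STAGE_REFERENCES:
        raise ValueError(f"unknown stage {stage!r}; choose from {sorted(_STAGE_REFERENCES)}")
    return Path(str(resources.files("stringfe").joinpath(f"data/{stage}_stations.csv")))


def load_stage_spec(stage: str) -> StationarySpec:
    """Load a packaged catalytic-stage calibration table.

    Stages: ``acylation`` (Michaelis complex as external zero reference),
    ``deacylation`` (acyl-enzyme as zero), ``regeneration`` (hydrolysis
    product as zero).
    """
    return StationarySpec.from_csv(stage_spec_path(stage), _STAGE_REFERENCES[stage])


# ---------------------------------------------------------------------------
# Calibrated reaction landscapes
# ---------------------------------------------------------------------------


def _polyline_project(points: np.ndarray, verts: np.ndarray, cum: np.ndarray):
    """Nearest point on a polyline (Euclidean).

    Returns (arc, proj, tangent_idx, on_segment); ``on_segment`` is False
    where the projection clamps to a vertex (there the arc coordinate is
    locally constant, so the longitudinal gradient term vanishes).  Ties
    between segments resolve to the lower segment index (argmin picks the
    first minimum).
    """
    seg = verts[1:] - verts[:-1]            # (S, D)
    seg_len2 = (seg * seg).sum(axis=1)      # (S,)
    diff = points[:, None, :] - verts[None, :-1, :]      # (N, S, D)
    t_raw = (diff * seg).sum(axis=2) / seg_len2          # (N, S)
    t = np.clip(t_raw, 0.0, 1.0)
    proj = verts[None, :-1, :] + t[..., None] * seg      # (N, S, D)
    d2 = ((points[:, None, :] - proj) ** 2).sum(axis=2)  # (N, S)
    j = np.argmin(d2, axis=1)                            # (N,)
    rows = np.arange(len(points))
    arc = cum[j] + t[rows, j] * np.sqrt(seg_len2[j])
    on_segment = (t_raw[rows, j] > 0.0) & (t_raw[rows, j] < 1.0)
    return arc, proj[rows, j], j, on_segment


def make_reaction_landscape(
    spec: StationarySpec,
    dimension: int = 2,
    transverse_k: float = 50.0,
    geometry: str = "line",
    station_spacing: float = 1.0,
    bend_amplitude: float = 0.5,
    end_padding: float = 0.5,
    masses: Optional[Sequence[float]] = None,
    label: str = "",
) -> Potential:
    """Build a potential whose exact PMF along an embedded curve is ``spec``.

    The prescribed free energies are placed at equally spaced arc-length
    stations along the curve and connected by a cubic Hermite interpolant
    with zero slope clamped at every station, so each station is exactly
    stationary and monotonicity between stations is preserved.  Transverse
    to the curve the potential is uniformly harmonic with stiffness
    ``transverse_k`` [kcal/mol/A^2], so the transverse free-energy term is
    a position-independent constant and relative free energies along the
    curve are independent of ``transverse_k``.  Beyond the terminal
    stations the longitudinal profile continues as a quadratic wall.

    geometry ``"line"`` embeds a straight segment along the first CV axis;
    ``"sine"`` (2-D only) adds a sinusoidal bend of amplitude
    ``bend_amplitude`` to exercise path curvature.
    """
    spec.validate()
    if dimension < 2:
        raise ValueError("dimension must be >= 2")
    if transverse_k <= 0:
        raise ValueError("transverse_k must be positive")
    m = spec.n_stations
    h = float(station_spacing)
    pad = end_padding * h
    span = (m - 1) * h if m > 1 else h

    if geometry == "line":
        arcs = pad + h * np.arange(m)
        verts = np.zeros((m + 2, dimension))
        verts[1:-1, 0] = arcs
        verts[0, 0] = 0.0
        verts[-1, 0] = arcs[-1] + pad
        station_points = verts[1:-1].copy()
    elif geometry == "sine":
        if dimension != 2:
            raise ValueError("sine geometry is only defined for dimension 2")
        tgrid = np.linspace(0.0, span, 4097)
        base = np.stack(
            [tgrid, bend_amplitude * np.sin(np.pi * tgrid / span)], axis=1
        )
        # linear tangent extensions of length `pad` at both ends
        t0 = base[1] - base[0]
        t0 /= np.linalg.norm(t0)
        t1 = base[-1] - base[-2]
        t1 /= np.linalg.norm(t1)
        verts = np.vstack([base[0] - pad * t0, base, base[-1] + pad * t1])
        seg_len = np.linalg.norm(np.diff(verts, axis=0), axis=1)
        cum_tmp = np.concatenate([[0.0], np.cumsum(seg_len)])
        total_main = cum_tmp[-2] - cum_tmp[1]
        arcs = cum_tmp[1] + total_main * np.arange(m) / max(m - 1, 1)
        station_points = np.stack(
            [np.interp(arcs, cum_tmp, verts[:, 0]), np.interp(arcs, cum_tmp, verts[:, 1])],
            axis=1,
        )
    else:
        raise ValueError(f"unknown geometry {geometry!r}")

    seg_len = np.linalg.norm(np.diff(verts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])

    g = spec.free_energies
    if m > 1:
        spline = CubicHermiteSpline(arcs, g, np.zeros(m))
        dspline = spline.derivative()
    else:
        spline = None
        dspline = None
    k_wall = transverse_k

    def f_long(arc: np.ndarray) -> np.ndarray:
        arc = np.asarray(arc, dtype=float)
        if m == 1:
            return g[0] + 0.5 * k_wall * (arc - arcs[0]) ** 2
        out = np.empty_like(arc)
        lo = arc < arcs[0]
        hi = arc > arcs[-1]
        mid = ~(lo | hi)
        out[mid] = spline(arc[mid])
        out[lo] = g[0] + 0.5 * k_wall * (arc[lo] - arcs[0]) ** 2
        out[hi] = g[-1] + 0.5 * k_wall * (arc[hi] - arcs[-1]) ** 2
        return out

    def f_long_prime(arc: np.ndarray) -> np.ndarray:
        arc = np.asarray(arc, dtype=float)
        if m == 1:
            return k_wall * (arc - arcs[0])
        out = np.empty_like(arc)
        lo = arc < arcs[0]
        hi = arc > arcs[-1]
        mid = ~(lo | hi)
        out[mid] = dspline(arc[mid])
        out[lo] = k_wall * (arc[lo] - arcs[0])
        out[hi] = k_wall * (arc[hi] - arcs[-1])
        return out

    seg_vec = np.diff(verts, axis=0)
    seg_tan = seg_vec / seg_len[:, None]

    def _flat(x):
        x = np.asarray(x, dtype=float)
        shape = x.shape
        return x.reshape(-1, dimension), shape

    def energy(x: np.ndarray) -> np.ndarray:
        pts, shape = _flat(x)
        arc, proj, _, _ = _polyline_project(pts, verts, cum)
        d2 = ((pts - proj) ** 2).sum(axis=1)
        e = f_long(arc) + 0.5 * transverse_k * d2
        return e.reshape(shape[:-1])

    def gradient(x: np.ndarray) -> np.ndarray:
        pts, shape = _flat(x)
        arc, proj, j, on_seg = _polyline_project(pts, verts, cum)
        tau = seg_tan[j]
        grad = ((f_long_prime(arc) * on_seg)[:, None] * tau
                + transverse_k * (pts - proj))
        return grad.reshape(shape)

    if masses is None:
        masses = np.ones(dimension)
    box = np.zeros((dimension, 2))
    lo = verts.min(axis=0) - 1.0
    hi = verts.max(axis=0) + 1.0
    box[:, 0], box[:, 1] = lo, hi

    return Potential(
        dimension=dimension,
        energy=energy,
        gradient=gradient,
        masses=np.asarray(masses, dtype=float),
        label=label or f"reaction-landscape[{','.join(spec.labels)}]",
        sampling_box=box,
        meta={
            "geometry": geometry,
            "transverse_k": transverse_k,
            "station_spacing": h,
            "stations": station_points,
            "station_arcs": arcs,
            "station_energies": g.copy(),
            "station_labels": list(spec.labels),
            "station_kinds": list(spec.kinds),
            "zero_reference_label": spec.zero_reference_label,
            "endpoints": (station_points[0].copy(), station_points[-1].copy()),
        },
    )


# ---------------------------------------------------------------------------
# Alchemical pairs
# ---------------------------------------------------------------------------


def _harmonic_potential(k: float, v0: float, dimension: int, label: str) -> Potential:
    def energy(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return 0.5 * k * (x * x).sum(axis=-1) + v0

    def gradient(x: np.ndarray) -> np.ndarray:
        return k * np.asarray(x, dtype=float)

    sd = np.sqrt(kbt(DEFAULT_TEMPERATURE) / k)
    box = np.tile([-8.0 * sd, 8.0 * sd], (dimension, 1))
    return Potential(
        dimension=dimension,
        energy=energy,
        gradient=gradient,
        masses=np.ones(dimension),
        label=label,
        sampling_box=box,
        meta={"k": k, "v0": v0},
    )


@dataclass
class AlchemicalPair:
    """Two end-state potentials linearly coupled through lambda in [0, 1].

    ``mixing(lam)`` returns the interpolated potential
    ``(1-lam) V_A + lam V_B``; ``du_dlambda`` is its lambda-derivative,
    ``V_B - V_A``.  ``analytic_dg`` (kcal/mol, at ``temperature``) is the
    closed-form free-energy difference when known.
    """

    end_state_A: Potential
    end_state_B: Potential
    analytic_dg: Optional[float] = None
    temperature: float = DEFAULT_TEMPERATURE
    label: str = ""

    def __post_init__(self) -> None:
        if self.end_state_A.dimension != self.end_state_B.dimension:
            raise ValueError("end states must share dimension")

    @property
    def dimension(self) -> int:
        return self.end_state_A.dimension

    @property
    def masses(self) -> np.ndarray:
        return self.end_state_A.masses

    def du_dlambda(self, x: np.ndarray) -> np.ndarray:
        return self.end_state_B.energy(x) - self.end_state_A.energy(x)

    def mixing(self, lam: float) -> Potential:
        if not 0.0 <= lam <= 1.0:
            raise ValueError("lambda must be in [0, 1]")
        ea, eb = self.end_state_A, self.end_state_B

        def energy(x):
            return (1.0 - lam) * ea.energy(x) + lam * eb.energy(x)

        def gradient(x):
            return (1.0 - lam) * ea.gradient(x) + lam * eb.gradient(x)

        box = ea.sampling_box
        if box is not None and eb.sampling_box is not None:
            box = np.stack([
                np.minimum(box[:, 0], eb.sampling_box[:, 0]),
                np.maximum(box[:, 1], eb.sampling_box[:, 1]),
            ], axis=1)
        return Potential(
            dimension=ea.dimension,
            energy=energy,
            gradient=gradient,
            masses=ea.masses,
            label=f"{self.label}[lambda={lam:g}]",
            sampling_box=box,
        )


@dataclass
class ReleaseToy:
    """Two-leg alchemical cycle surrogate (annihilation in two environments).

    ``site`` and ``bulk`` legs share the same stiffness ratio so that the
    analytic leg difference equals the requested target exactly; only the
    constant well offsets differ between the environments.
    """

    site: AlchemicalPair
    bulk: AlchemicalPair
    analytic_dg: float


def make_alchemical_pair(
    kind: str,
    *,
    k_a: float = 1.0,
    k_b: float = 1.0,
    delta_v0: float = 0.0,
    target_dg: float = 0.0,
    dimension: int = 1,
    temperature: float = DEFAULT_TEMPERATURE,
    label: str = "",
):
    """Construct a toy alchemical transformation with known analytic dG.

    kinds:
      - ``harmonic-stiffness``: A = k_a/2 |x|^2, B = k_b/2 |x|^2;
        dG = dimension * (k_B T / 2) ln(k_b / k_a).
      - ``well-offset``: B = A + delta_v0; dG = delta_v0.
      - ``release-toy``: returns a :class:`ReleaseToy` whose site-leg minus
        bulk-leg analytic difference equals ``target_dg`` exactly.
    """
    if kind == "harmonic-stiffness":
        if k_a <= 0 or k_b <= 0:
            raise ValueError("stiffnesses must be positive")
        dg = dimension * 0.5 * kbt(temperature) * np.log(k_b / k_a)
        return AlchemicalPair(
            end_state_A=_harmonic_potential(k_a, 0.0, dimension, "A"),
            end_state_B=_harmonic_potential(k_b, 0.0, dimension, "B"),
            analytic_dg=float(dg),
            temperature=temperature,
            label=label or "harmonic-stiffness",
        )
    if kind == "well-offset":
        if k_a <= 0:
            raise ValueError("stiffness must be positive")
        return AlchemicalPair(
            end_state_A=_harmonic_potential(k_a, 0.0, dimension, "A"),
            end_state_B=_harmonic_potential(k_a, delta_v0, dimension, "B"),
            analytic_dg=float(delta_v0),
            temperature=temperature,
            label=label or "well-offset",
        )
    if kind == "release-toy":
        # Both legs soften the well by the same factor (ratio 0.4) so the
        # stiffness contributions cancel exactly in the leg difference; the
        # environments differ only through their constant offsets.
        ratio = 0.4
        base = 0.5 * kbt(temperature) * np.log(ratio) * dimension
        offset_bulk = 1.0
        offset_site = offset_bulk + target_dg
        site = AlchemicalPair(
            end_state_A=_harmonic_potential(2.0, 0.0, dimension, "site-A"),
            end_state_B=_harmonic_potential(2.0 * ratio, offset_site, dimension, "site-B"),
            analytic_dg=float(base + offset_site),
            temperature=temperature,
            label=(label or "release-toy") + ":site",
        )
        bulk = AlchemicalPair(
            end_state_A=_harmonic_potential(1.5, 0.0, dimension, "bulk-A"),
            end_state_B=_harmonic_potential(1.5 * ratio, offset_bulk, dimension, "bulk-B"),
            analytic_dg=float(base + offset_bulk),
            temperature=temperature,
            label=(label or "release-toy") + ":bulk",
        )
        return ReleaseToy(site=site, bulk=bulk, analytic_dg=float(target_dg))
    raise ValueError(f"unknown alchemical pair kind {kind!r}")


# ---------------------------------------------------------------------------
# Ornstein-Uhlenbeck fixtures
# ---------------------------------------------------------------------------


def make_ou_series(
    n: int,
    stiffness: float,
    temperature: float = DEFAULT_TEMPERATURE,
    friction: float = 2.0,
    seed: int = 0,
    dt: float = 0.1,
    dimension: int = 1,
    labels: Optional[Sequence[str]] = None,
):
    """Stationary Gaussian (overdamped Langevin) CV series.

    Exact OU discretization with relaxation rate ``stiffness * 418.4 /
    friction`` [ps^-1] and stationary variance ``k_B T / stiffness`` [A^2]
    per coordinate.  Reproducible under ``seed``.
    """
    from .constants import KCAL_PER_MOL_TO_AMU_A2_PS2
    from .traj_metrics import CVSeries

    if n < 2:
        raise ValueError("n must be >= 2")
    if stiffness <= 0 or temperature <= 0 or friction <= 0:
        raise ValueError("stiffness, temperature and friction must be positive")
    rate = stiffness * KCAL_PER_MOL_TO_AMU_A2_PS2 / friction  # ps^-1
    var = kbt(temperature) / stiffness
    decay = np.exp(-rate * dt)
    noise_sd = np.sqrt(var * (1.0 - decay**2))
    rng = np.random.default_rng(seed)
    x = np.empty((n, dimension))
    x[0] = rng.normal(0.0, np.sqrt(var), size=dimension)
    xi = rng.normal(size=(n - 1, dimension))
    for i in range(1, n):
        x[i] = decay * x[i - 1] + noise_sd * xi[i - 1]
    times = dt * np.arange(n)
    if labels is None:
        labels = [f"cv{i + 1}" for i in range(dimension)]
    return CVSeries(times=times, values=x, labels=list(labels),
                    meta={"stiffness": stiffness, "temperature": temperature,
                          "friction": friction, "seed": seed})
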