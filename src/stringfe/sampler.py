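"""Langevin dynamics on CV-space potentials, plus deterministic quadrature.

The sampling engine behind the string, umbrella-sampling and thermodynamic
integration modules.  The integrator is the BAOAB splitting of underdamped
Langevin dynamics, which gives near-exact configurational sampling at the
1 fs-equivalent timesteps used throughout.  All stochastic entry points
take an explicit seed (or :class:`numpy.random.Generator`); per-window /
per-node streams are derived from ``(seed, index)`` spawn keys so that
batched and sequential execution give identical results.

:func:`equilibrium_moment` is the brute-force Boltzmann-quadrature oracle
used by the test-suite to validate every sampled moment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np

from .constants import (
    DEFAULT_FRICTION,
    DEFAULT_TEMPERATURE,
    DEFAULT_TIMESTEP,
    KCAL_PER_MOL_TO_AMU_A2_PS2,
    kbt,
)

__all__ = [
    "SamplerConfig",
    "Restraint",
    "SampleResult",
    "SamplingError",
    "sample",
    "langevin_baoab",
    "equilibrium_moment",
    "free_energy_quadrature",
    "derive_rng",
    "save_trajectory",
    "load_trajectory",
]


class SamplingError(RuntimeError):
    """Raised when dynamics encounter non-finite energies or forces."""


@dataclass
class SamplerConfig:
    """Langevin sampling parameters.

    Defaults follow the enzyme-simulation conventions this package mirrors:
    310 K, collision frequency 2.0 ps^-1, 1 fs timestep.  ``burn_in``
    defaults to 10% of ``n_steps``.
    """

    n_steps: int = 10_000
    temperature: float = DEFAULT_TEMPERATURE
    friction: float = DEFAULT_FRICTION
    timestep: float = DEFAULT_TIMESTEP  # fs
    burn_in: Optional[int] = None
    seed: int = 0
    masses: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.temperature <= 0 or self.friction <= 0 or self.timestep <= 0:
            raise ValueError("temperature, friction and timestep must be positive")
        if self.n_steps <= 0:
            raise ValueError("n_steps must be positive")
        if self.burn_in is None:
            self.burn_in = self.n_steps // 10
        if not 0 <= self.burn_in < self.n_steps:
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_steps")

    def replace(self, **kw) -> "SamplerConfig":
        data = {
            "n_steps": self.n_steps,
            "temperature": self.temperature,
            "friction": self.friction,
            "timestep": self.timestep,
            "burn_in": self.burn_in,
            "seed": self.seed,
            "masses": self.masses,
        }
        data.update(kw)
        return SamplerConfig(**data)


@dataclass
class Restraint:
    """Harmonic restraint, coupled to the full CV vector or to a path-CV.

    For ``coupling="full-vector"``, the bias is k/2 |x - center|^2 with a
    scalar or per-coordinate stiffness.  For ``coupling="path-coordinate"``,
    ``center`` is a scalar s-value, ``path`` must provide
    ``project_with_gradient`` and the bias is k/2 (s(x) - center)^2.
    """

    center: np.ndarray | float
    stiffness: np.ndarray | float
    coupling: str = "full-vector"
    path: object = None

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.stiffness) < 0):
            raise ValueError("stiffness must be >= 0")
        if self.coupling not in ("full-vector", "path-coordinate"):
            raise ValueError(f"unknown coupling {self.coupling!r}")
        if self.coupling == "path-coordinate" and self.path is None:
            raise ValueError("path-coordinate restraint needs a path")

    def force(self, x: np.ndarray) -> np.ndarray:
        if self.coupling == "full-vector":
            return -np.asarray(self.stiffness) * (x - np.asarray(self.center))
        s, grad_s = self.path.project_with_gradient(x)
        return -(np.asarray(self.stiffness) * (s - self.center))[..., None] * grad_s


@dataclass
class SampleResult:
    trajectory: np.ndarray          # (n_kept, D)
    mean_position: np.ndarray       # (D,)
    mean_restraint_force: Optional[np.ndarray]
    config: SamplerConfig = field(repr=False, default=None)


def derive_rng(seed: int, *key: int) -> np.random.Generator:
    """Counter-style reproducible stream for (seed, node/window index...)."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=tuple(key)))


def langevin_baoab(
    force_fn: Callable[[np.ndarray], np.ndarray],
    x0: np.ndarray,
    masses: np.ndarray,
    config: SamplerConfig,
    rng: np.random.Generator,
    store: bool = True,
    callback: Optional[Callable[[int, np.ndarray, np.ndarray], None]] = None,
    callback_interval: int = 0,
    observe: Optional[Callable[[np.ndarray], np.ndarray]] = None,
):
    """Integrate underdamped Langevin dynamics for a batch of walkers.

    ``x0`` has shape (W, D); ``force_fn`` maps (W, D) -> (W, D) in
    kcal/mol/A.  Velocities start from the Maxwell-Boltzmann distribution.
    ``callback(step, x, v)`` may mutate positions/velocities in place (used
    for Hamiltonian neighbor exchange).  If ``observe`` is given, the list
    of per-step observables after burn-in is returned instead of raw
    positions.  Returns (trajectory_or_observables, mean_position).
    """
    x = np.array(x0, dtype=float)
    w, d = x.shape
    m = np.asarray(masses, dtype=float).reshape(1, d)
    dt = config.timestep * 1e-3  # ps
    c1 = np.exp(-config.friction * dt)
    v_th = np.sqrt(kbt(config.temperature) * KCAL_PER_MOL_TO_AMU_A2_PS2 / m)
    c2 = np.sqrt(1.0 - c1 * c1) * v_th
    half = 0.5 * dt

    v = rng.normal(size=(w, d)) * v_th
    f = force_fn(x)
    if not np.all(np.isfinite(f)):
        bad = np.argwhere(~np.isfinite(f))[0]
        raise SamplingError(f"non-finite force at start, walker {bad[0]} position {x[bad[0]]}")

    n_keep = config.n_steps - config.burn_in
    kept = []
    pos_sum = np.zeros((w, d))
    n_sum = 0
    accel = KCAL_PER_MOL_TO_AMU_A2_PS2 / m

    for step in range(config.n_steps):
        v += half * f * accel
        x += half * v
        v = c1 * v + c2 * rng.normal(size=(w, d))
        x += half * v
        f = force_fn(x)
        if not np.all(np.isfinite(f)):
            bad = np.argwhere(~np.isfinite(f))[0]
            raise SamplingError(
                f"non-finite force at step {step}, walker {bad[0]} position {x[bad[0]]}"
            )
        v += half * f * accel
        if callback is not None and callback_interval and (step + 1) % callback_interval == 0:
            callback(step + 1, x, v)
            f = force_fn(x)
        if step >= config.burn_in:
            pos_sum += x
            n_sum += 1
            if store:
                kept.append(observe(x).copy() if observe is not None else x.copy())

    mean_pos = pos_sum / max(n_sum, 1)
    traj = np.array(kept) if store else np.empty((0, w, d))
    return traj, mean_pos


def sample(
    potential,
    restraint: Optional[Restraint],
    config: SamplerConfig,
    x0: Optional[np.ndarray] = None,
) -> SampleResult:
    """Sample one walker on ``potential`` (+ optional harmonic restraint).

    Post-burn-in samples are Boltzmann-distributed for the total potential
    at ``config.temperature``; ``mean_restraint_force`` is the arithmetic
    identity ``stiffness * (mean_position - center)``.  Identical configs
    and seeds give identical trajectories.
    """
    if potential.dimension < 1:
        raise ValueError("zero-dimension potential")
    if x0 is None:
        if restraint is not None and restraint.coupling == "full-vector":
            x0 = np.asarray(restraint.center, dtype=float)
        else:
            x0 = np.zeros(potential.dimension)
    x0 = np.atleast_2d(np.asarray(x0, dtype=float))
    masses = config.masses if config.masses is not None else potential.masses

    def force_fn(x):
        f = -potential.gradient(x)
        if restraint is not None:
            f = f + restraint.force(x)
        return f

    rng = derive_rng(config.seed)
    traj, mean_pos = langevin_baoab(force_fn, x0, masses, config, rng)
    traj = traj[:, 0, :]
    mean_pos = mean_pos[0]
    mrf = None
    if restraint is not None and restraint.coupling == "full-vector":
        mrf = np.asarray(restraint.stiffness) * (mean_pos - np.asarray(restraint.center))
    return SampleResult(trajectory=traj, mean_position=mean_pos,
                        mean_restraint_force=mrf, config=config)


# ---------------------------------------------------------------------------
# Boltzmann quadrature oracle
# ---------------------------------------------------------------------------


def _grid_weights(box: np.ndarray, n: int):
    axes = [np.linspace(lo, hi, n) for lo, hi in box]
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([g.ravel() for g in mesh], axis=-1)
    # trapezoid weights along each axis
    wts = np.ones(pts.shape[0]).reshape([n] * len(axes))
    for ax, a in enumerate(axes):
        shape = [1] * len(axes)
        shape[ax] = n
        w1 = np.full(n, a[1] - a[0])
        w1[0] *= 0.5
        w1[-1] *= 0.5
        wts = wts * w1.reshape(shape)
    return pts, wts.ravel(), mesh


def equilibrium_moment(
    potential,
    observable: Callable[[np.ndarray], np.ndarray],
    box: np.ndarray,
    n: int = 201,
    temperature: float = DEFAULT_TEMPERATURE,
):
    """Deterministic Boltzmann average <observable> over a box (dim <= 3).

    Returns ``(value, discretization_error)`` where the error is the
    difference against a half-resolution grid.  Warns if the Boltzmann
    density at the box boundary exceeds 1e-10 of its maximum.
    """
    box = np.atleast_2d(np.asarray(box, dtype=float))
    if potential.dimension > 3:
        raise ValueError("quadrature oracle supports dimension <= 3")

    def estimate(npts):
        pts, wts, _ = _grid_weights(box, npts)
        e = potential.energy(pts)
        e = e - e.min()
        rho = np.exp(-e / kbt(temperature)) * wts
        z = rho.sum()
        obs = np.asarray(observable(pts), dtype=float)
        return float((rho * obs).sum() / z), rho / wts

    n_coarse = n // 2 + 1
    value, dens = estimate(n)
    coarse, _ = estimate(n_coarse)

    shape = [n] * potential.dimension
    dens_nd = dens.reshape(shape)
    boundary = dens_nd.max() * 0.0
    for ax in range(potential.dimension):
        boundary = max(
            boundary,
            float(np.take(dens_nd, 0, axis=ax).max()),
            float(np.take(dens_nd, -1, axis=ax).max()),
        )
    if boundary > 1e-10 * dens_nd.max():
        warnings.warn("sampling box too small: boundary density exceeds 1e-10 of max")
    return value, abs(value - coarse)


def free_energy_quadrature(
    potential,
    box: np.ndarray,
    n: int = 201,
    temperature: float = DEFAULT_TEMPERATURE,
) -> float:
    """-k_B T ln Z over the box (configurational part, fixed measure)."""
    box = np.atleast_2d(np.asarray(box, dtype=float))
    pts, wts, _ = _grid_weights(box, n)
    e = potential.energy(pts)
    e0 = e.min()
    z = (np.exp(-(e - e0) / kbt(temperature)) * wts).sum()
    return float(e0 - kbt(temperature) * np.log(z))


# ---------------------------------------------------------------------------
# Trajectory persistence
# ---------------------------------------------------------------------------


def save_trajectory(path: str | Path, trajectory: np.ndarray, **attrs) -> None:
    """Persist a trajectory as HDF5 (.h5/.hdf5) or CSV (anything else)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("positions", data=trajectory)
            fh.create_dataset("step", data=np.arange(len(trajectory)))
            for key, val in attrs.items():
                fh.attrs[key] = val
    else:
        import pandas as pd

        arr = np.atleast_2d(trajectory)
        df = pd.DataFrame(arr, columns=[f"cv{i + 1}" for i in range(arr.shape[1])])
        df.insert(0, "step", np.arange(len(df)))
        df.to_csv(path, index=False)


def load_trajectory(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as fh:
            return fh["positions"][...]
    import pandas as pd

    df = pd.read_csv(path)
    return df.drop(columns=["step"]).to_numpy()
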