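"""Adaptive string method: restrained-node evolution to the MFEP.

An ordered set of nodes (replicas) connects the reactant and product
basins in collective-variable space.  Each iteration, every interior node
is sampled under a harmonic restraint; the local free-energy gradient is
estimated from the harmonic identity ``grad G = -k (<x> - center)``, the
node is displaced along the negative gradient component transverse to the
local path tangent (in the mass-weighted metric), and the string is
reparametrized to equal mass-weighted arc length.  Hamiltonian exchange
between neighbor nodes is attempted every 50 sampler steps (alternating
even/odd pairing) to speed up convergence.  Convergence is declared when
the mass-weighted RMSD against the running-average string stays below a
threshold (default 0.1 amu^1/2 A) over a trailing window equivalent to
2 ps of sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .constants import kbt
from .sampler import SamplerConfig, SamplingError, derive_rng, langevin_baoab

__all__ = [
    "StringState",
    "initialize_string",
    "string_iteration",
    "attempt_neighbor_exchange",
    "check_convergence",
    "converge_string",
    "mw_rmsd",
]


def _mw(nodes: np.ndarray, masses: np.ndarray) -> np.ndarray:
    return nodes * np.sqrt(masses)


def mw_lengths(nodes: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Mass-weighted segment lengths [amu^1/2 A]."""
    y = _mw(nodes, masses)
    return np.linalg.norm(np.diff(y, axis=0), axis=1)


def mw_rmsd(a: np.ndarray, b: np.ndarray, masses: np.ndarray) -> float:
    """Mass-weighted RMSD between two strings [amu^1/2 A]."""
    d = _mw(a - b, masses)
    return float(np.sqrt((d * d).sum(axis=1).mean()))


@dataclass
class StringState:
    nodes: np.ndarray                       # (N, D) [A]
    node_stiffness: float                   # [kcal/mol/A^2]
    metric_masses: np.ndarray               # (D,) [amu]
    iteration: int = 0
    rmsd_history: list = field(default_factory=list)   # [(iteration, rmsd)]
    converged: bool = False
    steps_per_iteration: int = 0
    mean_nodes: Optional[np.ndarray] = None  # running average string
    n_averaged: int = 0

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.metric_masses = np.asarray(self.metric_masses, dtype=float)
        if self.nodes.shape[0] < 3:
            raise ValueError("a string needs at least 3 nodes")
        if np.any(mw_lengths(self.nodes, self.metric_masses) <= 0):
            raise ValueError("consecutive nodes must be distinct")

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    def to_csv(self, path: str | Path) -> None:
        d = self.nodes.shape[1]
        df = pd.DataFrame(self.nodes, columns=[f"cv{i + 1}" for i in range(d)])
        df.insert(0, "node", np.arange(self.n_nodes))
        df.to_csv(path, index=False)


def initialize_string(
    endpoint_a: np.ndarray,
    endpoint_b: np.ndarray,
    n_nodes: int,
    masses: Optional[np.ndarray] = None,
    node_stiffness: float = 200.0,
) -> StringState:
    """Linearly interpolated string, equidistant in the mass-weighted metric.

    On a straight segment, equal fractions of the displacement are
    equidistant in any diagonal metric, so endpoints are preserved exactly.
    """
    a = np.atleast_1d(np.asarray(endpoint_a, dtype=float))
    b = np.atleast_1d(np.asarray(endpoint_b, dtype=float))
    if n_nodes < 3:
        raise ValueError("n_nodes must be >= 3")
    if masses is None:
        masses = np.ones(a.shape[0])
    masses = np.asarray(masses, dtype=float)
    if np.linalg.norm(_mw(b - a, masses)) == 0:
        raise ValueError("endpoints coincide")
    frac = np.linspace(0.0, 1.0, n_nodes)[:, None]
    nodes = a + frac * (b - a)
    nodes[0], nodes[-1] = a, b          # exact endpoints, no roundoff
    return StringState(nodes=nodes, node_stiffness=node_stiffness, metric_masses=masses)


def _resample_once(nodes: np.ndarray, masses: np.ndarray) -> np.ndarray:
    n = nodes.shape[0]
    seg = mw_lengths(nodes, masses)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, cum[-1], n)
    idx = np.clip(np.searchsorted(cum, targets, side="right") - 1, 0, n - 2)
    t = (targets - cum[idx]) / seg[idx]
    new = nodes[idx] + t[:, None] * (nodes[idx + 1] - nodes[idx])
    new[0] = nodes[0]
    new[-1] = nodes[-1]
    return new


def reparametrize(nodes: np.ndarray, masses: np.ndarray, rtol: float = 1e-6,
                  max_sweeps: int = 100) -> np.ndarray:
    """Resample the polyline to equal mass-weighted arc length.

    Piecewise-linear resampling; endpoints and node count are conserved.
    Because resampling a bent polyline cuts corners (chords shorten where
    the path bends), the sweep is repeated until consecutive segment
    lengths agree within ``rtol`` relative.  A point equidistant from two
    segments is assigned to the lower index (searchsorted side='right').
    """
    new = nodes
    for _ in range(max_sweeps):
        new = _resample_once(new, masses)
        seg = mw_lengths(new, masses)
        if (seg.max() - seg.min()) <= rtol * seg.mean():
            break
    return new


def attempt_neighbor_exchange(
    potential,
    centers: np.ndarray,
    stiffness: float,
    positions: np.ndarray,
    temperature: float,
    rng: np.random.Generator,
    parity: int = 0,
):
    """Metropolis Hamiltonian exchange between neighbor restrained walkers.

    Pairs (i, i+1) with i of the given parity are considered.  With
    ``U_k(x) = V(x) + k/2 |x - c_k|^2``, the swap is accepted with
    probability ``min(1, exp(-beta * delta))`` where
    ``delta = U_i(x_j) + U_j(x_i) - U_i(x_i) - U_j(x_j)``.  Returns the
    (possibly swapped) positions and an acceptance log.
    """
    x = np.array(positions, dtype=float)
    beta = 1.0 / kbt(temperature)
    log = []
    n = x.shape[0]

    def u(pos, c):
        return potential.energy(pos) + 0.5 * stiffness * ((pos - c) ** 2).sum(axis=-1)

    for i in range(parity % 2, n - 1, 2):
        j = i + 1
        delta = (u(x[j], centers[i]) + u(x[i], centers[j])
                 - u(x[i], centers[i]) - u(x[j], centers[j]))
        accept = rng.random() < math.exp(min(0.0, -beta * delta))
        if accept:
            x[[i, j]] = x[[j, i]]
        log.append((i, j, float(delta), bool(accept)))
    return x, log


def _smooth_nodes(nodes: np.ndarray, passes: int = 1) -> np.ndarray:
    """Binomial [1,2,1]/4 smoothing of interior nodes (endpoints fixed)."""
    out = nodes.copy()
    for _ in range(passes):
        out[1:-1] = 0.25 * out[:-2] + 0.5 * out[1:-1] + 0.25 * out[2:]
    return out


def _descend(potential, x0: np.ndarray, tol: float = 1e-3, max_iter: int = 2000) -> np.ndarray:
    """Steepest descent to the local minimum (endpoint relaxation)."""
    x = np.array(x0, dtype=float)
    eta = 1e-3
    e = float(potential.energy(x))
    for _ in range(max_iter):
        g = potential.gradient(x)
        if np.linalg.norm(g) < tol:
            break
        x_new = x - eta * g
        e_new = float(potential.energy(x_new))
        if e_new <= e:
            x, e = x_new, e_new
            eta = min(eta * 1.2, 0.05)
        else:
            eta *= 0.5
            if eta < 1e-10:
                break
    return x


def string_iteration(
    state: StringState,
    potential,
    sampler_config: SamplerConfig,
    step_size: float = 0.01,
    exchange_interval: int = 50,
    max_displacement: float = 0.01,
) -> StringState:
    """One adaptive-string update.

    Samples each interior node under its harmonic restraint (with neighbor
    Hamiltonian exchange every ``exchange_interval`` steps), estimates the
    free-energy gradient from the restraint-mean displacement, moves each
    node along the negative transverse gradient component in the
    mass-weighted metric, relaxes the endpoints by steepest descent within
    their basins, and reparametrizes to equal mass-weighted arc length.
    If a step produces coinciding nodes, it is halved and retried (up to
    10 times).
    """
    if potential.dimension != state.nodes.shape[1]:
        raise ValueError("potential dimension does not match string")
    nodes = state.nodes
    masses = state.metric_masses
    k = state.node_stiffness
    centers = nodes[1:-1].copy()
    rng = derive_rng(sampler_config.seed, state.iteration)

    exchange_count = [0]

    def callback(step, x, v):
        x_new, _ = attempt_neighbor_exchange(
            potential, centers, k, x, sampler_config.temperature, rng,
            parity=exchange_count[0] % 2,
        )
        # positions swap; velocities stay Maxwellian i.i.d., so no v swap needed
        x[...] = x_new
        exchange_count[0] += 1

    def force_fn(x):
        return -potential.gradient(x) - k * (x - centers)

    _, mean_pos = langevin_baoab(
        force_fn, centers, masses, sampler_config, rng, store=False,
        callback=callback, callback_interval=exchange_interval,
    )

    grad = -k * (mean_pos - centers)       # estimated free-energy gradient
    if not np.all(np.isfinite(grad)):
        raise SamplingError("non-finite free-energy gradient estimate")

    sq = np.sqrt(masses)
    y = _mw(nodes, masses)
    g_y = grad / sq                        # gradient in mass-weighted coords
    # tangents from a lightly smoothed string: raw node noise would leak the
    # (large) longitudinal gradient into the transverse move
    y_s = _mw(_smooth_nodes(nodes), masses)
    tau = y_s[2:] - y_s[:-2]
    tau /= np.linalg.norm(tau, axis=1, keepdims=True)
    g_perp = g_y - (g_y * tau).sum(axis=1, keepdims=True) * tau

    step = step_size
    for attempt in range(11):
        disp = -step * g_perp
        # cap per-node motion: near steep walls the raw gradient would throw
        # nodes across ridges in a single move
        norm = np.linalg.norm(disp, axis=1, keepdims=True)
        disp = np.where(norm > max_displacement, disp * max_displacement / norm, disp)
        y_new = y.copy()
        y_new[1:-1] = y[1:-1] + disp
        cand = y_new / sq
        cand[0] = _descend(potential, nodes[0])
        cand[-1] = _descend(potential, nodes[-1])
        if np.all(mw_lengths(cand, masses) > 1e-10):
            break
        step *= 0.5
    else:
        raise SamplingError("node collision persisted after 10 step halvings")

    new_nodes = reparametrize(cand, masses)

    prev_avg = state.mean_nodes if state.mean_nodes is not None else state.nodes
    rmsd = mw_rmsd(new_nodes, prev_avg, masses)
    n_avg = state.n_averaged + 1
    new_avg = prev_avg + (new_nodes - prev_avg) / n_avg if state.mean_nodes is not None \
        else new_nodes.copy()

    new_state = replace(
        state,
        nodes=new_nodes,
        iteration=state.iteration + 1,
        rmsd_history=state.rmsd_history + [(state.iteration + 1, rmsd)],
        steps_per_iteration=sampler_config.n_steps,
        mean_nodes=new_avg,
        n_averaged=n_avg,
    )
    return new_state


def check_convergence(
    state: StringState,
    window_steps: int = 2000,
    threshold: float = 0.1,
) -> bool:
    """True iff the string RMSD stayed <= threshold over a trailing window.

    The window is expressed in sampler steps (default 2000, i.e. 2 ps at a
    1 fs timestep) and converted to iterations through
    ``state.steps_per_iteration``.  A window longer than the available
    history returns False.
    """
    if not state.rmsd_history:
        return False
    spi = max(state.steps_per_iteration, 1)
    window_iters = max(1, math.ceil(window_steps / spi))
    if len(state.rmsd_history) < window_iters:
        return False
    tail = [r for _, r in state.rmsd_history[-window_iters:]]
    return bool(max(tail) <= threshold)


def converge_string(
    potential,
    endpoint_a: np.ndarray,
    endpoint_b: np.ndarray,
    n_nodes: int = 32,
    sampler_config: Optional[SamplerConfig] = None,
    step_size: float = 0.01,
    max_iterations: int = 200,
    threshold: float = 0.1,
    window_steps: int = 2000,
    node_stiffness: float = 200.0,
    seed: int = 0,
    averaging_iterations: int = 15,
    max_displacement: float = 0.01,
) -> StringState:
    """Drive string iterations until RMSD convergence or max_iterations.

    After the convergence loop, ``averaging_iterations`` additional
    iterations are run and their node positions averaged, suppressing the
    Monte-Carlo jitter of single-iteration strings before the path-CV is
    built from the result.
    """
    if sampler_config is None:
        sampler_config = SamplerConfig(n_steps=400, burn_in=120, friction=10.0)
    state = initialize_string(
        endpoint_a, endpoint_b, n_nodes,
        masses=potential.masses, node_stiffness=node_stiffness,
    )
    for it in range(max_iterations):
        cfg = sampler_config.replace(seed=seed)
        state = string_iteration(state, potential, cfg, step_size=step_size,
                                 max_displacement=max_displacement)
        if check_convergence(state, window_steps=window_steps, threshold=threshold):
            state.converged = True
            break
    if averaging_iterations > 0:
        acc = np.zeros_like(state.nodes)
        for _ in range(averaging_iterations):
            state = string_iteration(state, potential,
                                     sampler_config.replace(seed=seed),
                                     step_size=step_size,
                                     max_displacement=max_displacement)
            acc += state.nodes
        converged = state.converged or check_convergence(
            state, window_steps=window_steps, threshold=threshold)
        final = _smooth_nodes(acc / averaging_iterations, passes=2)
        state = replace(state, nodes=reparametrize(final, state.metric_masses))
        state.converged = converged
    return state
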