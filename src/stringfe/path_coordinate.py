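"""Path collective variable: normalized progress along a converged string.

The path-CV ``s`` of a configuration is defined by nearest-point
projection onto the piecewise-linear reference path in the mass-weighted
metric: ``s`` is the normalized cumulative arc length of the projection
(clamped to [0, 1]) and ``z`` is the metric distance to the path.  This
projection-based realization gives exact on-path values and a simple
piecewise-constant gradient, which is what the umbrella-sampling bias
needs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path as FsPath
from typing import Tuple

import numpy as np
import pandas as pd

__all__ = ["PathCV", "build_path", "project"]


@dataclass
class PathCV:
    reference_nodes: np.ndarray    # (N, D) [A]
    metric_masses: np.ndarray      # (D,) [amu]

    def __post_init__(self) -> None:
        self.reference_nodes = np.asarray(self.reference_nodes, dtype=float)
        self.metric_masses = np.asarray(self.metric_masses, dtype=float)
        y = self._y_nodes = self.reference_nodes * np.sqrt(self.metric_masses)
        seg = np.diff(y, axis=0)
        self._seg_len = np.linalg.norm(seg, axis=1)
        if np.any(self._seg_len <= 0):
            raise ValueError("path nodes must be strictly increasing in arc length")
        self.arc_lengths = np.concatenate([[0.0], np.cumsum(self._seg_len)])
        self._tangents = seg / self._seg_len[:, None]   # metric-unit tangents

    @property
    def total_length(self) -> float:
        return float(self.arc_lengths[-1])

    @property
    def s_nodes(self) -> np.ndarray:
        """s-value of each reference node: L_i / L_total."""
        return self.arc_lengths / self.total_length

    # -- projection ---------------------------------------------------------

    def project_with_gradient(self, x: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """(s, ds/dx) for configurations of shape (..., D).

        The gradient is taken from the nearest segment (also beyond the
        clamped ends, so a path-coordinate bias keeps a restoring force
        there).
        """
        x = np.asarray(x, dtype=float)
        shape = x.shape
        pts = (x.reshape(-1, shape[-1])) * np.sqrt(self.metric_masses)
        y = self._y_nodes
        seg = y[1:] - y[:-1]
        diff = pts[:, None, :] - y[None, :-1, :]
        t = (diff * seg).sum(axis=2) / (self._seg_len**2)
        t = np.clip(t, 0.0, 1.0)
        proj = y[None, :-1, :] + t[..., None] * seg
        d2 = ((pts[:, None, :] - proj) ** 2).sum(axis=2)
        j = np.argmin(d2, axis=1)           # ties -> lower segment index
        rows = np.arange(len(pts))
        s = (self.arc_lengths[j] + t[rows, j] * self._seg_len[j]) / self.total_length
        s = np.clip(s, 0.0, 1.0)
        grad = (self._tangents[j] * np.sqrt(self.metric_masses)) / self.total_length
        return s.reshape(shape[:-1]), grad.reshape(shape)

    def point_at(self, s: float | np.ndarray) -> np.ndarray:
        """Cartesian point(s) on the path at normalized arc length s."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        arc = np.clip(s, 0.0, 1.0) * self.total_length
        idx = np.clip(np.searchsorted(self.arc_lengths, arc, side="right") - 1,
                      0, len(self._seg_len) - 1)
        t = (arc - self.arc_lengths[idx]) / self._seg_len[idx]
        nodes = self.reference_nodes
        out = nodes[idx] + t[:, None] * (nodes[idx + 1] - nodes[idx])
        return out if out.shape[0] > 1 else out[0]

    def extended(self, pad_arc: float) -> "PathCV":
        """Path with linear tangent extensions of metric length pad_arc.

        End tangents are averaged over the last few segments so that
        residual node noise does not skew the extension direction.
        """
        nodes = self.reference_nodes
        sq = np.sqrt(self.metric_masses)
        k = min(3, len(self._tangents))
        t0 = self._tangents[:k].mean(axis=0)
        t0 /= np.linalg.norm(t0)
        t1 = self._tangents[-k:].mean(axis=0)
        t1 /= np.linalg.norm(t1)
        first = nodes[0] - pad_arc * (t0 / sq)
        last = nodes[-1] + pad_arc * (t1 / sq)
        return PathCV(np.vstack([first, nodes, last]), self.metric_masses)

    # -- serialization ------------------------------------------------------

    def to_csv(self, path: str | FsPath) -> None:
        d = self.reference_nodes.shape[1]
        df = pd.DataFrame(self.reference_nodes,
                          columns=[f"cv{i + 1}" for i in range(d)])
        df.insert(0, "node", np.arange(len(df)))
        df.to_csv(path, index=False)
        meta = FsPath(path).with_suffix(".json")
        meta.write_text(json.dumps({"metric_masses": self.metric_masses.tolist()}))

    @classmethod
    def from_csv(cls, path: str | FsPath) -> "PathCV":
        df = pd.read_csv(path)
        nodes = df.drop(columns=["node"]).to_numpy(dtype=float)
        meta = FsPath(path).with_suffix(".json")
        masses = np.ones(nodes.shape[1])
        if meta.exists():
            masses = np.asarray(json.loads(meta.read_text())["metric_masses"])
        return cls(nodes, masses)


def build_path(state, override: bool = False) -> PathCV:
    """Path-CV from a converged string state.

    Refuses unconverged strings unless ``override`` is set.
    """
    if not state.converged and not override:
        raise ValueError("string state is not converged (pass override=True to force)")
    return PathCV(state.nodes.copy(), state.metric_masses.copy())


def project(x: np.ndarray, path: PathCV) -> Tuple[np.ndarray, np.ndarray]:
    """(s, z) of configuration(s) x: normalized arc position in [0, 1] and
    mass-weighted transverse distance [amu^1/2 A] to the path."""
    x = np.asarray(x, dtype=float)
    shape = x.shape
    pts = x.reshape(-1, shape[-1]) * np.sqrt(path.metric_masses)
    y = path._y_nodes
    seg = y[1:] - y[:-1]
    diff = pts[:, None, :] - y[None, :-1, :]
    t = np.clip((diff * seg).sum(axis=2) / (path._seg_len**2), 0.0, 1.0)
    proj = y[None, :-1, :] + t[..., None] * seg
    d2 = ((pts[:, None, :] - proj) ** 2).sum(axis=2)
    j = np.argmin(d2, axis=1)
    rows = np.arange(len(pts))
    s = np.clip((path.arc_lengths[j] + t[rows, j] * path._seg_len[j]) / path.total_length,
                0.0, 1.0)
    z = np.sqrt(d2[rows, j])
    if len(shape) == 1:
        return float(s[0]), float(z[0])
    return s.reshape(shape[:-1]), z.reshape(shape[:-1])
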