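"""Descriptors on collective-variable time series.

Generic trajectory analyses mirroring the classical-MD characterization
of an enzyme-substrate complex: per-coordinate RMSF, weighted RMSD to a
reference frame (pure CV-space distance, no superposition), and 2-D
state-density maps with a time-resolved track (for distance-vs-dihedral
conformational-state plots).  Angular coordinates use degrees in
[-180, 180) and wrap periodically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["CVSeries", "rmsf", "rmsd_to_reference", "state_density_2d", "Density2D"]


@dataclass
class CVSeries:
    """Uniformly spaced CV trajectory: times [ps] and per-frame CV vectors."""

    times: np.ndarray               # (n,)
    values: np.ndarray              # (n, D)
    labels: list
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != len(self.times):
            raise ValueError("times and values must align")
        if len(self.labels) != self.values.shape[1]:
            raise ValueError("one label per coordinate required")
        if len(self.times) > 2:
            dt = np.diff(self.times)
            if not np.allclose(dt, dt[0], rtol=1e-8, atol=1e-12):
                raise ValueError("time spacing must be uniform")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("missing/non-finite frames are not allowed")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def column(self, label: str) -> np.ndarray:
        return self.values[:, self.labels.index(label)]

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, columns=self.labels)
        df.insert(0, "t", self.times)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CVSeries":
        df = pd.read_csv(path)
        times = df["t"].to_numpy(dtype=float)
        vals = df.drop(columns=["t"])
        return cls(times=times, values=vals.to_numpy(dtype=float),
                   labels=list(vals.columns))

    def to_hdf5(self, path: str | Path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("times", data=self.times)
            fh.create_dataset("values", data=self.values)
            fh.attrs["labels"] = np.array(self.labels, dtype="S")

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "CVSeries":
        import h5py

        with h5py.File(path, "r") as fh:
            return cls(times=fh["times"][...], values=fh["values"][...],
                       labels=[s.decode() for s in fh.attrs["labels"]])


def rmsf(series: CVSeries) -> np.ndarray:
    """Root-mean-square fluctuation of each coordinate about its mean."""
    if series.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    x = series.values
    return np.sqrt(((x - x.mean(axis=0)) ** 2).mean(axis=0))


def rmsd_to_reference(
    series: CVSeries,
    reference_frame: np.ndarray,
    weights: Optional[Sequence[float]] = None,
) -> np.ndarray:
    """Weighted CV-space distance of every frame to a reference vector.

    ``sqrt(sum_d w_d (x_d - ref_d)^2)`` per frame; no superposition is
    performed (these are collective variables, not Cartesian coordinates).
    """
    ref = np.asarray(reference_frame, dtype=float)
    if ref.shape != (series.values.shape[1],):
        raise ValueError("reference dimension mismatch")
    if weights is None:
        weights = np.ones_like(ref)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != ref.shape:
        raise ValueError("weight length mismatch")
    d = series.values - ref
    return np.sqrt((weights * d * d).sum(axis=1))


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    return ((a + 180.0) % 360.0) - 180.0


@dataclass
class Density2D:
    hist: np.ndarray          # (bx, by), sums to 1
    x_edges: np.ndarray
    y_edges: np.ndarray
    track: pd.DataFrame       # columns t, x, y

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.hist).to_csv(path, index=False)


def state_density_2d(
    series: CVSeries,
    coord_x: str,
    coord_y: str,
    bins: int = 60,
    periodic_x: bool = False,
    periodic_y: bool = False,
) -> Density2D:
    """Normalized 2-D density of two coordinates plus the (x, y, t) track.

    Coordinates declared periodic are treated as angles in degrees and
    wrapped into [-180, 180) before binning, so 185 degrees bins
    identically to -175 degrees.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    x = series.column(coord_x).copy()
    y = series.column(coord_y).copy()
    if periodic_x:
        x = _wrap_angle(x)
    if periodic_y:
        y = _wrap_angle(y)
    range_x = (-180.0, 180.0) if periodic_x else (x.min(), x.max())
    range_y = (-180.0, 180.0) if periodic_y else (y.min(), y.max())
    hist, xe, ye = np.histogram2d(x, y, bins=bins, range=[range_x, range_y])
    hist /= hist.sum()
    track = pd.DataFrame({"t": series.times, "x": x, "y": y})
    return Density2D(hist=hist, x_edges=xe, y_edges=ye, track=track)
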