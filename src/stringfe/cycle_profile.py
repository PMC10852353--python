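"""Assembly of the full catalytic cycle and rate-determining-step analysis.

Stage profiles (stationary tables relative to each stage's own zero) are
joined into one sequence of states with absolute free energies relative
to the first stage's reference (the Michaelis complex for a catalytic
cycle).  Scalar corrections — e.g. the nucleophile deprotonation penalty
or the ligand-release free energy — are inserted after named states and
shift everything downstream.  Steps may be marked irreversible (release
of a product to the bulk); the effective-barrier search then never pairs
a transition state with a resting intermediate on the far side of such a
mark.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .pmf import StationaryTable

__all__ = [
    "StageProfile",
    "AssembledCycle",
    "BarrierReport",
    "join_stages",
    "effective_barrier",
    "render_cycle_table",
    "stage_from_pipeline",
]

_MIN_KINDS = {"minimum", "min"}


def _is_min(kind: str) -> bool:
    return kind.lower() in _MIN_KINDS


@dataclass
class StageProfile:
    """One catalytic stage: a stationary table plus bookkeeping.

    ``reference`` names the state the stage's zero of energy refers to;
    ``includes_deprotonation`` records whether an activation penalty is
    already folded into the stage energies (then supplying the same
    penalty again as an explicit correction is an error).
    """

    table: StationaryTable
    stage_label: str
    reference: str = ""
    includes_deprotonation: bool = False

    def __post_init__(self) -> None:
        if len(self.table.labels) < 1:
            raise ValueError("empty stage table")


@dataclass
class AssembledCycle:
    labels: list
    kinds: list
    stages: list
    energies: np.ndarray              # absolute, relative to first reference
    errors: np.ndarray
    corrections: list                 # [(state_index, label, value)]
    irreversible_marks: set           # indices i: step i -> i+1 irreversible

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        self.errors = np.asarray(self.errors, dtype=float)

    @property
    def n_states(self) -> int:
        return len(self.labels)

    def conservation_residual(self) -> float:
        """|sum of step dGs - (final - initial)|; zero by construction."""
        steps = np.diff(self.energies)
        return float(abs(steps.sum() - (self.energies[-1] - self.energies[0])))


def join_stages(
    stages: Sequence[StageProfile],
    corrections: Sequence[tuple] = (),
    irreversible_after: Sequence[str] = (),
    deprotonation_correction: Optional[float] = None,
) -> AssembledCycle:
    """Concatenate stage profiles into one absolute free-energy sequence.

    ``corrections`` are ``(after_state_label, label, value)`` tuples: the
    scalar ``value`` is added to every state downstream of the named
    state (the physical picture: a spontaneous off-path event such as
    ligand release re-levels the remaining profile).  Each following
    stage is offset so its reactant energy equals the previous stage's
    corrected product energy (continuity).  ``deprotonation_correction``,
    if given, is applied at the very start; supplying it while the first
    stage already folds the penalty in is an error.  ``irreversible_after``
    names states whose outgoing step is irreversible.
    """
    if not stages:
        raise ValueError("no stages to join")
    seen = set()
    for st in stages:
        if st.stage_label in seen:
            raise ValueError(f"repeated stage label {st.stage_label!r}")
        seen.add(st.stage_label)
    if deprotonation_correction is not None and stages[0].includes_deprotonation:
        raise ValueError(
            "deprotonation penalty supplied both pre-applied in the first stage "
            "and as an explicit correction"
        )
    return _join_clean(stages, list(corrections), irreversible_after,
                       deprotonation_correction)


def _join_clean(stages, corrections, irreversible_after, deprotonation_correction):
    labels, kinds, stage_col, energies, errors = [], [], [], [], []
    applied = []
    used = [False] * len(corrections)

    first = stages[0]
    if first.reference and first.reference != first.table.labels[0]:
        labels.append(first.reference)
        kinds.append("minimum")
        stage_col.append("reference")
        energies.append(0.0)
        errors.append(0.0)

    start_shift = deprotonation_correction or 0.0
    if deprotonation_correction is not None:
        applied.append((max(len(labels) - 1, 0), "deprotonation",
                        deprotonation_correction))

    anchor = None          # (energy, error) the next stage's reactant must meet
    for si, st in enumerate(stages):
        t = st.table
        if si == 0:
            stage_offset, anchor_err = start_shift, 0.0
        else:
            stage_offset = anchor[0] - t.free_energies[0]
            anchor_err = anchor[1]
        for li in range(len(t.labels)):
            labels.append(t.labels[li])
            kinds.append(t.kinds[li])
            stage_col.append(st.stage_label)
            energies.append(float(t.free_energies[li]) + stage_offset)
            errors.append(math.hypot(float(t.errors[li]), anchor_err))
        # corrections attached to this stage's product (or any of its states)
        prod_energy, prod_err = energies[-1], errors[-1]
        for ci, (after, clabel, value) in enumerate(corrections):
            if after in t.labels:
                idx = len(labels) - len(t.labels) + t.labels.index(after)
                if idx != len(labels) - 1:
                    raise ValueError(
                        f"correction after {after!r} must follow a stage product"
                    )
                prod_energy += value
                applied.append((idx, clabel, value))
                used[ci] = True
        anchor = (prod_energy, prod_err)

    for ci, (after, clabel, value) in enumerate(corrections):
        if not used[ci]:
            raise ValueError(f"correction references unknown state {after!r}")

    marks = set()
    for name in irreversible_after:
        if name not in labels:
            raise ValueError(f"irreversible mark references unknown state {name!r}")
        marks.add(labels.index(name))

    return AssembledCycle(
        labels=labels, kinds=kinds, stages=stage_col,
        energies=np.array(energies), errors=np.array(errors),
        corrections=applied, irreversible_marks=marks,
    )


def stage_from_pipeline(result, spec, stage_label: str,
                        includes_deprotonation: bool = False) -> StageProfile:
    """Stage profile from a reconstructed free-energy pipeline result.

    Station energies recovered by the string/US/WHAM pipeline (relative to
    the stage reactant) are labeled with the calibration spec's state names;
    per-station errors are interpolated from the profile's bootstrap
    uncertainty.
    """
    if result.station_energies is None:
        raise ValueError("pipeline result carries no station recovery")
    prof = result.profile
    if prof.uncertainty is not None:
        valid = np.isfinite(prof.uncertainty)
        errors = np.interp(result.station_s, prof.grid[valid],
                           prof.uncertainty[valid])
    else:
        errors = np.zeros_like(result.station_s)
    kinds = ["minimum" if k == "minimum" else "maximum" for k in spec.kinds]
    external_ref = (spec.zero_reference_label
                    and spec.zero_reference_label not in spec.labels)
    energies = (result.station_energies_ref if external_ref
                else result.station_energies)
    table = StationaryTable(
        labels=list(spec.labels), kinds=kinds,
        s_locations=result.station_s,
        free_energies=energies,
        errors=errors,
    )
    return StageProfile(table=table, stage_label=stage_label,
                        reference=spec.zero_reference_label or spec.labels[0],
                        includes_deprotonation=includes_deprotonation)


@dataclass
class BarrierReport:
    determining_step: str
    barrier: float
    resting_state: str
    barrier_error: float = float("nan")

    def to_json(self) -> str:
        return json.dumps({
            "determining_step": self.determining_step,
            "barrier_kcal_mol": self.barrier,
            "resting_state": self.resting_state,
            "barrier_error": None if math.isnan(self.barrier_error)
            else self.barrier_error,
        }, indent=2)


def effective_barrier(cycle: AssembledCycle) -> BarrierReport:
    """Rate-determining span: max G(TS_j) - G(I_i) over admissible pairs.

    A pair (resting intermediate i, transition state j > i) is admissible
    when no irreversible step lies between them; an irreversible step
    resets the accessible resting-state window.  Single forward pass with
    a running minimum.
    """
    has_ts = any(not _is_min(k) for k in cycle.kinds)
    if not has_ts:
        raise ValueError("assembled cycle contains no transition state")

    best = -np.inf
    best_ts = best_rest = None
    run_min = np.inf
    run_min_idx = None
    for i in range(cycle.n_states):
        if _is_min(cycle.kinds[i]):
            if cycle.energies[i] < run_min:
                run_min = cycle.energies[i]
                run_min_idx = i
        else:
            if run_min_idx is not None:
                span = cycle.energies[i] - run_min
                if span > best:
                    best = span
                    best_ts, best_rest = i, run_min_idx
        if i in cycle.irreversible_marks:
            run_min = np.inf
            run_min_idx = None

    err = math.hypot(cycle.errors[best_ts], cycle.errors[best_rest])
    return BarrierReport(
        determining_step=cycle.labels[best_ts],
        barrier=float(best),
        resting_state=cycle.labels[best_rest],
        barrier_error=err,
    )


def render_cycle_table(cycle: AssembledCycle):
    """Tabular report: one row per state with absolute G and step dG.

    Returns ``(DataFrame, aligned_text)``; write the frame with
    ``df.to_csv(path, index=False)`` for a bit-exact decimal round trip.
    """
    step = np.concatenate([[np.nan], np.diff(cycle.energies)])
    df = pd.DataFrame({
        "label": cycle.labels,
        "stage": cycle.stages,
        "kind": cycle.kinds,
        "free_energy": cycle.energies,
        "error": cycle.errors,
        "step_dG": step,
    })
    return df, df.to_string(index=False, float_format=lambda v: f"{v:8.2f}")
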