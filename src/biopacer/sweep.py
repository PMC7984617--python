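"""Mapping pacemaking state and cycle length over the (I_K1, I_f) plane.

The grid is parameterized by current densities at -80 mV (pA/pF), the same
axes used to describe expression levels; each point is simulated
independently from the default resting initial state (no continuation
between points, which would hysteretically bias burst detection), then
classified and measured.  Failed integrations are recorded, not fatal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import classify_state, detect_waves, InsufficientDataError
from .integrate import SimulationConfig, Trace, integrate
from .metrics import UndefinedMetricError, cycle_length, VALID_CL_MAX
from .model import ModelParameters

__all__ = ["SweepResult", "run_sweep", "stability_boundary"]


@dataclass
class SweepResult:
    """Long-format table of per-point labels and cycle lengths."""

    table: pd.DataFrame          # ik1_density, if_density, state, CL_ms, valid, failed
    ik1_grid: np.ndarray
    if_grid: np.ndarray
    meta: dict = field(default_factory=dict)

    def state_grid(self) -> pd.DataFrame:
        """States pivoted to a (if_density x ik1_density) matrix."""
        return self.table.pivot(index="if_density", columns="ik1_density",
                                values="state")

    def cl_grid(self) -> pd.DataFrame:
        return self.table.pivot(index="if_density", columns="ik1_density",
                                values="CL_ms")

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path) -> None:
        payload = {
            "ik1_grid": self.ik1_grid.tolist(),
            "if_grid": self.if_grid.tolist(),
            "points": self.table.to_dict(orient="records"),
            "meta": self.meta,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=str)


def _classify_point(trace: Trace) -> tuple[int | None, float, bool]:
    """(state, CL_ms, valid) for one simulated point."""
    try:
        events = detect_waves(trace)
        label = classify_state(events, trace)
    except InsufficientDataError:
        return None, float("nan"), False
    cl = float("nan")
    if label.state in (4, 5):
        try:
            cl = cycle_length(trace, events)
        except UndefinedMetricError:
            cl = float("nan")
    valid = label.state == 5 and np.isfinite(cl) and cl <= VALID_CL_MAX
    return label.state, cl, valid


def run_sweep(ik1_grid, if_grid, sim_config: SimulationConfig | None = None,
              include_I_CaT: bool = False, params_base: dict | None = None,
              progress: bool = False) -> SweepResult:
    """Simulate, classify and measure every grid point.

    ``ik1_grid`` and ``if_grid`` are densities at -80 mV in pA/pF
    (I_K1 >= 0, I_f <= 0).  Each point starts fresh from the default
    resting state and is deterministic.
    """
    ik1_grid = np.atleast_1d(np.asarray(ik1_grid, dtype=float))
    if_grid = np.atleast_1d(np.asarray(if_grid, dtype=float))
    if ik1_grid.size == 0 or if_grid.size == 0:
        raise ValueError("sweep grids must be non-empty")
    cfg = sim_config or SimulationConfig(duration=300.0)
    base = params_base or {}

    rows = []
    for iff in if_grid:
        for ik1 in ik1_grid:
            params = ModelParameters.from_densities(
                float(ik1), float(iff), include_I_CaT=include_I_CaT, **base)
            trace = integrate(params, cfg, raise_on_failure=False)
            if trace.failed:
                rows.append(dict(ik1_density=ik1, if_density=iff, state=None,
                                 CL_ms=float("nan"), valid=False, failed=True))
                continue
            state, cl, valid = _classify_point(trace)
            rows.append(dict(ik1_density=ik1, if_density=iff, state=state,
                             CL_ms=cl, valid=valid, failed=False))
            if progress:   # pragma: no cover - cosmetic
                print(f"  ({ik1:.3f}, {iff:+.3f}) -> State-{state} CL={cl:.0f}")
    table = pd.DataFrame(rows)
    meta = {"duration_s": cfg.duration, "dt_ms": cfg.dt,
            "include_I_CaT": include_I_CaT}
    return SweepResult(table=table, ik1_grid=ik1_grid, if_grid=if_grid, meta=meta)


def stability_boundary(result: SweepResult, criterion: str = "state5"):
    """Largest I_K1 density per I_f column meeting the criterion.

    ``criterion`` is ``"state5"`` (label is State-5) or ``"valid"``
    (State-5 with CL <= 1000 ms).  Returns a dict mapping if_density ->
    boundary ik1_density (NaN where no grid point qualifies).
    """
    if criterion not in ("state5", "valid"):
        raise ValueError("criterion must be 'state5' or 'valid'")
    out = {}
    for iff, sub in result.table.groupby("if_density"):
        if criterion == "state5":
            ok = sub[sub["state"] == 5]
        else:
            ok = sub[sub["valid"]]
        out[float(iff)] = float(ok["ik1_density"].max()) if len(ok) else float("nan")
    return out
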