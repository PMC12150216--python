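"""Deterministic sensitivity analyses.

One-way threshold analysis finds the value of a single parameter at which
the cost-effective strategy (by net monetary benefit at the stated
willingness to pay) switches, all other parameters held at base and the
calibrated structural constants frozen — recalibrating at every swept point
would erase the sensitivity being measured.  Two-way analysis maps the
decision over a grid of two parameters.

Sweeping a parameter rebuilds both arms, so the swept value propagates
through the transition structure mechanistically: e.g. sweeping the
remote-arm severe-BP acknowledgment probability moves the severe->readmitted
flow (with the calibrated acknowledgment scaling frozen), and sweeping the
readmission cost reprices the event flows.  Note that in direct mode the
per-14-day readmission *inputs* act through the frozen scaling, so sweeping
them has no effect by construction; sweep the acknowledgment probabilities
instead.

Default search intervals are deliberately wider than the published
plausibility ranges ([0, 1.5 x high] for costs, [0, 1] for probabilities
and utilities): the published threshold for the readmission cost lies far
below its own published range, so the source analysis evidently searched
wider too.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .markov import Calibration, evaluate_arm
from .parameters import ParameterSet

#: Absolute bisection tolerances by parameter kind (parameter units).
DEFAULT_TOLERANCES = {"cost": 0.01, "probability": 1e-4, "utility": 1e-4, "count": 1e-4}
N_PILOT = 11


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of a one-way threshold search.

    ``threshold`` is None when the decision is constant over the whole
    search interval.  If the pilot scan shows more than one sign change the
    analysis is flagged multi-threshold and every crossing is reported in
    ``thresholds`` (``threshold`` holds the first).
    """

    parameter: str
    threshold: float | None
    thresholds: tuple[float, ...]
    decision_below: str
    decision_above: str
    interval: tuple[float, float]
    tolerance: float
    multi_threshold: bool = False

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "threshold": self.threshold,
            "decision_below": self.decision_below,
            "decision_above": self.decision_above,
            "interval_low": self.interval[0],
            "interval_high": self.interval[1],
            "tolerance": self.tolerance,
            "multi_threshold": self.multi_threshold,
        }


@dataclass(frozen=True)
class TwoWayGrid:
    """Decision label per cell over a two-parameter grid."""

    parameter_x: str
    parameter_y: str
    grid_x: np.ndarray
    grid_y: np.ndarray
    decisions: np.ndarray  # (len(grid_y), len(grid_x)) of strategy labels

    def __post_init__(self):
        if self.decisions.shape != (len(self.grid_y), len(self.grid_x)):
            raise ValueError("decision grid shape does not match axis lengths")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {self.parameter_x: x, self.parameter_y: y,
             "decision": self.decisions[j, i]}
            for j, y in enumerate(self.grid_y)
            for i, x in enumerate(self.grid_x)
        ]
        return pd.DataFrame(rows)


def default_interval(params: ParameterSet, name: str) -> tuple[float, float]:
    spec = params.spec(name)
    if spec.kind == "cost":
        return (0.0, 1.5 * spec.high)
    return (0.0, 1.0)


def nmb_difference_fn(params: ParameterSet, calibration: Calibration | None,
                      name: str, wtp: float, mode: str = "direct"
                      ) -> Callable[[float], float]:
    """f(x) = NMB(remote) - NMB(usual care) with parameter ``name`` set to x."""
    params.spec(name)  # raise early on unknown parameter

    def f(x: float) -> float:
        p = params.with_value(name, float(x))
        rbpm = evaluate_arm(p, "rbpm", calibration, mode)
        usual = evaluate_arm(p, "usual_care", calibration, mode)
        return rbpm.net_monetary_benefit(wtp) - usual.net_monetary_benefit(wtp)

    return f


def _decision(value: float) -> str:
    # NMB ties break toward the incumbent strategy (usual care)
    return "rbpm" if value > 0.0 else "usual_care"


def one_way_threshold(params: ParameterSet, name: str,
                      calibration: Calibration | None = None,
                      interval: tuple[float, float] | None = None,
                      wtp: float | None = None, tol: float | None = None,
                      mode: str = "direct") -> ThresholdResult:
    """Locate where the cost-effective strategy switches as ``name`` varies.

    Scans ``N_PILOT`` equally spaced pilot points to map the sign pattern of
    the NMB difference, then bisects every sign-change bracket to ``tol``
    (absolute, in the parameter's units).  A constant sign over all pilot
    points (including both endpoints) reports no threshold.
    """
    spec = params.spec(name)
    if interval is None:
        interval = default_interval(params, name)
    lo, hi = float(interval[0]), float(interval[1])
    if not lo < hi:
        raise ValueError(f"invalid search interval {interval}")
    if wtp is None:
        wtp = params.wtp
    if tol is None:
        tol = DEFAULT_TOLERANCES[spec.kind]

    f = nmb_difference_fn(params, calibration, name, wtp, mode)
    xs = np.linspace(lo, hi, N_PILOT)
    ys = np.array([f(x) for x in xs])
    signs = np.sign(ys)

    crossings: list[float] = []
    for i in range(N_PILOT - 1):
        if signs[i] == 0.0:  # exact zero at a pilot point is itself a root
            crossings.append(float(xs[i]))
        elif signs[i] * signs[i + 1] < 0.0:
            crossings.append(float(brentq(f, xs[i], xs[i + 1], xtol=tol)))
    if signs[-1] == 0.0:
        crossings.append(float(xs[-1]))

    return ThresholdResult(
        parameter=name,
        threshold=crossings[0] if crossings else None,
        thresholds=tuple(crossings),
        decision_below=_decision(ys[0]),
        decision_above=_decision(ys[-1]),
        interval=(lo, hi),
        tolerance=tol,
        multi_threshold=len(crossings) > 1,
    )


def threshold_report(results: Sequence[ThresholdResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])


def two_way_grid(params: ParameterSet, name_x: str, name_y: str,
                 grid_x: Sequence[float], grid_y: Sequence[float],
                 calibration: Calibration | None = None,
                 wtp: float | None = None, mode: str = "direct") -> TwoWayGrid:
    """Decision by net monetary benefit over the cross product of two grids."""
    if wtp is None:
        wtp = params.wtp
    gx = np.asarray(grid_x, dtype=float)
    gy = np.asarray(grid_y, dtype=float)
    if gx.size == 0 or gy.size == 0:
        raise ValueError("grids must be nonempty")
    decisions = np.empty((gy.size, gx.size), dtype=object)
    for j, y in enumerate(gy):
        for i, x in enumerate(gx):
            p = params.with_value(name_x, float(x)).with_value(name_y, float(y))
            rbpm = evaluate_arm(p, "rbpm", calibration, mode)
            usual = evaluate_arm(p, "usual_care", calibration, mode)
            decisions[j, i] = _decision(
                rbpm.net_monetary_benefit(wtp) - usual.net_monetary_benefit(wtp)
            )
    return TwoWayGrid(name_x, name_y, gx, gy, decisions)
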