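"""Patient-level microsimulation: synthetic-data generator and brute-force
oracle for the cohort model.

Individual patients walk the identical daily transition structure the
cohort model integrates in expectation: each day the next state is drawn
from the patient's current transition-matrix row, and costs/QALYs accrue
under the identical rules.  Sample means over patients therefore converge
on the cohort model's expectations — the central correctness check of the
package — and the simulated trajectories double as exportable synthetic
datasets.

Medication titration is carried as a per-patient annotation (a single
Bernoulli draw against the per-14-day titration probability); it has no
cost or utility consequence in the base model, mirroring the source
analysis's exclusion of medication costs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import markov
from .markov import (
    Calibration, DAYS_PER_YEAR, DEFAULT_HORIZON, DEATH, MORB, READM, STATES,
)
from .parameters import ParameterSet


@dataclass(frozen=True)
class PatientTrajectory:
    """One simulated patient's 14-day path and accrued outcomes."""

    patient_id: int
    strategy: str
    states: tuple[str, ...]          # day 0..horizon state labels
    readmitted_days: tuple[int, ...]
    morbidity_day: int | None
    death_day: int | None
    med_titration: bool
    cost: float
    qaly: float


class Trajectories:
    """A simulated patient collection (columnar storage, row-object access)."""

    def __init__(self, states: np.ndarray, med_titration: np.ndarray,
                 cost: np.ndarray, qaly: np.ndarray, strategy: str,
                 params: ParameterSet, seed: int):
        self.states = states            # (n, horizon+1) int8 state indices
        self.med_titration = med_titration
        self.cost = cost
        self.qaly = qaly
        self.strategy = strategy
        self.params = params
        self.seed = seed

    def __len__(self) -> int:
        return self.states.shape[0]

    @property
    def horizon(self) -> int:
        return self.states.shape[1] - 1

    def readmission_counts(self) -> np.ndarray:
        """Readmission entries per patient (the one-day tunnel means each
        occupied readmitted day is a distinct entry, costed once)."""
        return (self.states == READM).sum(axis=1)

    def morbidity_entries(self) -> np.ndarray:
        into = (self.states[:, 1:] == MORB) & (self.states[:, :-1] != MORB)
        return into.sum(axis=1)

    def dead_at_end(self) -> np.ndarray:
        return self.states[:, -1] == DEATH

    def __getitem__(self, i: int) -> PatientTrajectory:
        row = self.states[i]
        readm_days = tuple(int(d) for d in np.flatnonzero(row == READM))
        morb_days = np.flatnonzero(row == MORB)
        death_days = np.flatnonzero(row == DEATH)
        return PatientTrajectory(
            patient_id=i,
            strategy=self.strategy,
            states=tuple(STATES[s] for s in row),
            readmitted_days=readm_days,
            morbidity_day=int(morb_days[0]) if morb_days.size else None,
            death_day=int(death_days[0]) if death_days.size else None,
            med_titration=bool(self.med_titration[i]),
            cost=float(self.cost[i]),
            qaly=float(self.qaly[i]),
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: one row per patient-day, with event flags."""
        n, days = self.states.shape
        patient = np.repeat(np.arange(n), days)
        day = np.tile(np.arange(days), n)
        flat = self.states.ravel()
        event = np.where(
            flat == READM, "readmission",
            np.where(flat == MORB, "severe_morbidity",
                     np.where(flat == DEATH, "death", "")),
        )
        return pd.DataFrame(
            {
                "patient": patient,
                "day": day,
                "state": [STATES[s] for s in flat],
                "event": event,
                "med_titration": np.repeat(self.med_titration, days),
            }
        )


def simulate_patients(params: ParameterSet, strategy: str, n: int, seed: int,
                      calibration: Calibration | None = None,
                      mode: str = "direct",
                      horizon_days: int = DEFAULT_HORIZON) -> Trajectories:
    """Simulate ``n`` patients starting normotensive on day 0.

    Transition matrix, calibration constants, and accrual rules are shared
    with the cohort model.  Reproducible given ``seed``; the draw order is
    one uniform per patient per day, then the titration Bernoulli batch.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    structure = calibration.structure if calibration else markov.DEFAULT_STRUCTURE
    scale = calibration.ack_scale.get(strategy) if (calibration and mode == "direct") else None
    matrix = markov.build_transition_matrix(params, strategy, mode,
                                            ack_scale=scale, structure=structure)
    cdf = np.cumsum(matrix.matrix, axis=1)
    cdf[:, -1] = 1.0  # guard against float round-off in the last column

    rng = np.random.default_rng(seed)
    states = np.zeros((n, horizon_days + 1), dtype=np.int8)
    for d in range(1, horizon_days + 1):
        u = rng.random(n)
        row_cdf = cdf[states[:, d - 1]]
        states[:, d] = (u[:, None] > row_cdf).sum(axis=1)
    med = rng.random(n) < params.p_med_titration

    traj = Trajectories(states, med, np.zeros(n), np.zeros(n), strategy, params, seed)
    events = (
        traj.readmission_counts()
        + structure.morbidity_cost_multiple * traj.morbidity_entries()
    )
    event_mult = calibration.cost_multiplier.get(strategy, 1.0) if calibration else 1.0
    overhead = calibration.overhead.get(strategy, 0.0) if calibration else 0.0
    traj.cost = params.fixed_cost(strategy) + overhead \
        + event_mult * params.c_readm * events

    u_states = markov.state_utilities(params)
    qaly14 = u_states[states[:, 1:]].sum(axis=1) / DAYS_PER_YEAR
    uplift = calibration.rbpm_uplift if calibration else params.rbpm_uplift
    phf = params.persistent_htn_fraction
    u_persistent = min(
        params.u_norm - params.u_persistent_decrement
        + (uplift if strategy == "rbpm" else 0.0),
        1.0,
    )
    u_mix = (1.0 - phf) * params.u_norm + phf * u_persistent
    alive = ~traj.dead_at_end()
    traj.qaly = qaly14 + alive * (DAYS_PER_YEAR - horizon_days) * u_mix / DAYS_PER_YEAR
    return traj


@dataclass(frozen=True)
class EmpiricalArmResult:
    """Sample means (with standard errors) over simulated patients."""

    strategy: str
    n: int
    cost: float
    cost_se: float
    qaly: float
    qaly_se: float
    readmissions: float
    readmissions_se: float
    deaths: float
    deaths_se: float

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "n": self.n,
            "cost": self.cost, "cost_se": self.cost_se,
            "qaly": self.qaly, "qaly_se": self.qaly_se,
            "readmissions": self.readmissions, "readmissions_se": self.readmissions_se,
            "deaths": self.deaths, "deaths_se": self.deaths_se,
        }


def _mean_se(x: np.ndarray) -> tuple[float, float]:
    n = len(x)
    mean = float(np.mean(x))
    se = float(np.std(x, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return mean, se


def summarize(traj: Trajectories) -> EmpiricalArmResult:
    """Empirical per-patient means mirroring the cohort :class:`ArmResult`."""
    if len(traj) == 0:
        raise ValueError("cannot summarize an empty trajectory collection")
    cost, cost_se = _mean_se(traj.cost)
    qaly, qaly_se = _mean_se(traj.qaly)
    readm, readm_se = _mean_se(traj.readmission_counts().astype(float))
    dead, dead_se = _mean_se(traj.dead_at_end().astype(float))
    return EmpiricalArmResult(traj.strategy, len(traj), cost, cost_se,
                              qaly, qaly_se, readm, readm_se, dead, dead_se)


def transition_frequencies(traj: Trajectories) -> np.ndarray:
    """Empirical daily transition frequencies (row-normalized counts) from
    the simulated paths; recovers the generating matrix within binomial
    error (parameter-recovery diagnostic)."""
    counts = np.zeros((len(STATES), len(STATES)))
    src = traj.states[:, :-1].ravel()
    dst = traj.states[:, 1:].ravel()
    np.add.at(counts, (src, dst), 1.0)
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(totals > 0, counts / totals, 0.0)
    return freq
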