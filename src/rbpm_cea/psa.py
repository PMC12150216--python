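"""Probabilistic sensitivity analysis (PSA).

Monte Carlo propagation of parameter uncertainty through the calibrated
model: every varied input is drawn independently from its fitted
distribution (gamma for costs, beta for probabilities; see
:mod:`rbpm_cea.parameters`), both arms are rebuilt per trial, and the
incremental cost and incremental effectiveness (remote management minus
usual care) are recorded.  The headline summary is the acceptability
fraction: the share of trials in which remote management has the higher net
monetary benefit at the willingness to pay.

Varied inputs (matching the source analysis): the five daily BP outcome
probabilities (the normotensive probability re-absorbs the simplex residual
after sampling, preserving the sampled tail probabilities), the
acknowledgment probabilities in both arms, the per-14-day readmission
probabilities (configurable off), and all unit costs.  Death hazards,
utility weights, and the calibrated structural constants stay at their
base/calibrated values.

Per trial the direct-mode acknowledgment scaling is re-solved so the 14-day
cumulative readmissions match the trial's sampled readmission targets; when
a sampled target exceeds what the sampled severe-BP incidence can generate
(the mechanistic ceiling), the scaling saturates and the trial is counted
in ``n_clipped``.

The engine is vectorized over trials: it evolves all cohorts
simultaneously with hand-unrolled state updates that mirror the transition
matrix of :mod:`rbpm_cea.markov` exactly (an equivalence the test suite
asserts), and solves the per-trial scalings by vectorized bisection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from . import markov
from .markov import Calibration, DEFAULT_HORIZON, DAYS_PER_YEAR, ModelStructure
from .parameters import BP_OUTCOME_NAMES, DistributionSpec, ParameterSet, make_distribution

logger = logging.getLogger(__name__)

_BISECT_ITERS = 60

#: Cost parameters sampled per trial.
_COST_NAMES = ("c_readm", "c_program", "c_cuff", "c_nurse_annual", "c_outpatient")
#: Acknowledgment probabilities sampled per trial.
_ACK_NAMES = ("ack_mild_rbpm", "ack_sev_rbpm", "ack_mild_uc", "ack_sev_uc")
_READM_NAMES = ("p_readm_rbpm", "p_readm_uc")


@dataclass(frozen=True)
class PSAResult:
    """Per-trial incremental outcomes (remote management minus usual care)."""

    n_trials: int
    seed: int
    wtp: float
    delta_cost: np.ndarray    # USD; negative = remote management saves money
    delta_effect: np.ndarray  # QALY; positive = remote management gains QALYs
    n_renormalized: int       # trials whose BP simplex needed rescaling
    n_clipped: int            # trials with a saturated readmission target

    def nmb_difference(self, wtp: float | None = None) -> np.ndarray:
        if wtp is None:
            wtp = self.wtp
        return wtp * self.delta_effect - self.delta_cost

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(self.n_trials),
                "delta_cost": self.delta_cost,
                "delta_effect": self.delta_effect,
                "nmb_diff": self.nmb_difference(),
            }
        )


# ---------------------------------------------------------------------------
# vectorized cohort engine
# ---------------------------------------------------------------------------

def _unrec_hazards_vec(p_morb, p_death, p_death_sevpe, escalation):
    # competing hazards, mirroring the matrix assembly: death first, then
    # escalated morbidity, each capped to keep the row stochastic
    death_h = np.minimum(p_death + p_death_sevpe, 1.0)
    morb_h = np.minimum(escalation * p_morb, 1.0 - death_h)
    return death_h, morb_h


def _ack_ceiling_vec(p_morb, p_death, p_death_sevpe, escalation):
    death_h, morb_h = _unrec_hazards_vec(p_morb, p_death, p_death_sevpe, escalation)
    return 1.0 - death_h - morb_h


def _evolve(bp: Sequence[np.ndarray], a: np.ndarray, p_death_sevpe: float,
            p_death_morb: float, escalation: float,
            horizon: int = DEFAULT_HORIZON, readm_only: bool = False):
    """Evolve all trial cohorts for ``horizon`` days.

    ``bp`` are the five BP outcome probabilities (arrays broadcastable over
    trials), ``a`` the effective daily acknowledged-severe probability.
    Mirrors the transition matrix of :mod:`rbpm_cea.markov` state by state.
    Returns (cum_readm, cum_morb, occupancy dict) or just cum_readm.
    """
    p_norm, p_mild, p_sev, p_morb, p_death = bp
    shape = np.broadcast(p_norm, a).shape
    norm = np.ones(shape)
    mild = np.zeros(shape)
    unrec = np.zeros(shape)
    readm = np.zeros(shape)
    morb = np.zeros(shape)
    dead = np.zeros(shape)
    cum_readm = np.zeros(shape)
    cum_morb = np.zeros(shape)
    occ_hist = None if readm_only else []

    death_h, morb_h = _unrec_hazards_vec(p_morb, p_death, p_death_sevpe, escalation)
    unrec_stay = 1.0 - a - morb_h - death_h
    for _ in range(horizon):
        from_bp = norm + mild
        inflow_readm = from_bp * p_sev * a + unrec * a
        inflow_morb = from_bp * p_morb + unrec * morb_h
        new_norm = from_bp * p_norm + readm
        new_mild = from_bp * p_mild
        new_unrec = from_bp * p_sev * (1.0 - a) + unrec * unrec_stay
        new_dead = dead + from_bp * p_death + unrec * death_h \
            + morb * p_death_morb
        new_morb = morb * (1.0 - p_death_morb) + inflow_morb
        norm, mild, unrec, readm, morb, dead = (
            new_norm, new_mild, new_unrec, inflow_readm, new_morb, new_dead
        )
        cum_readm = cum_readm + inflow_readm
        cum_morb = cum_morb + inflow_morb
        if occ_hist is not None:
            occ_hist.append((norm, mild, unrec, readm, morb, dead))
    if readm_only:
        return cum_readm
    return cum_readm, cum_morb, occ_hist


def _solve_scale_vec(bp, ack_sev, target, p_death_sevpe, p_death_morb,
                     escalation, horizon=DEFAULT_HORIZON):
    """Vectorized bisection for the per-trial acknowledgment scaling.

    Returns (scale, clipped) where ``clipped`` marks trials whose target
    exceeds the mechanistic ceiling (scale saturates at its maximum).
    """
    p_morb, p_death = bp[3], bp[4]
    ceiling = _ack_ceiling_vec(p_morb, p_death, p_death_sevpe, escalation)
    s_max = ceiling / np.maximum(ack_sev, 1e-300)

    def cum(s):
        a = np.minimum(ack_sev * s, ceiling)
        return _evolve(bp, a, p_death_sevpe, p_death_morb, escalation,
                       horizon, readm_only=True)

    reachable = cum(s_max)
    clipped = reachable < target
    lo = np.zeros_like(s_max)
    hi = s_max.copy()
    for _ in range(_BISECT_ITERS):
        mid = 0.5 * (lo + hi)
        too_low = cum(mid) < target
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    scale = np.where(clipped, s_max, 0.5 * (lo + hi))
    scale = np.where(target <= 0.0, 0.0, scale)
    return scale, clipped


def _arm_outcomes(params: ParameterSet, calibration: Calibration, strategy: str,
                  bp, ack_sev, readm_target, costs: Mapping[str, np.ndarray],
                  horizon: int):
    """Per-trial cost/QALY/readmission/death arrays for one strategy."""
    st: ModelStructure = calibration.structure
    scale, clipped = _solve_scale_vec(bp, ack_sev, readm_target,
                                      params.p_death_sevpe, params.p_death_morb,
                                      st.morbidity_escalation, horizon)
    ceiling = _ack_ceiling_vec(bp[3], bp[4], params.p_death_sevpe,
                               st.morbidity_escalation)
    a = np.minimum(ack_sev * scale, ceiling)
    cum_readm, cum_morb, occ_hist = _evolve(
        bp, a, params.p_death_sevpe, params.p_death_morb,
        st.morbidity_escalation, horizon
    )

    if strategy == "rbpm":
        # nurse cost per patient rounds to cents, matching the cohort path
        fixed = (costs["c_program"] + costs["c_cuff"]
                 + np.round(costs["c_nurse_annual"] / params.patients_per_year, 2))
    else:
        fixed = costs["c_outpatient"]
    event = costs["c_readm"] * (cum_readm + st.morbidity_cost_multiple * cum_morb)
    total_cost = (fixed + calibration.overhead.get(strategy, 0.0)
                  + calibration.cost_multiplier.get(strategy, 1.0) * event)

    u = markov.state_utilities(params)
    qaly14 = sum(
        u[0] * n + u[1] * mi + u[2] * un + u[3] * re + u[4] * mo
        for (n, mi, un, re, mo, _d) in occ_hist
    ) / DAYS_PER_YEAR
    dead14 = occ_hist[-1][5]
    uplift = calibration.rbpm_uplift if strategy == "rbpm" else 0.0
    phf = params.persistent_htn_fraction
    u_persistent = min(params.u_norm - params.u_persistent_decrement + uplift, 1.0)
    u_mix = (1.0 - phf) * params.u_norm + phf * u_persistent
    qaly = qaly14 + (1.0 - dead14) * (DAYS_PER_YEAR - horizon) * u_mix / DAYS_PER_YEAR
    return total_cost, qaly, cum_readm, dead14, clipped


def build_psa_distributions(params: ParameterSet, vary_readmission_probs: bool = True,
                            convention: str = "ci95") -> dict[str, DistributionSpec]:
    """Fitted sampling distribution for every PSA-varied parameter."""
    dists: dict[str, DistributionSpec] = {}
    for spec in params:
        if not spec.varied_in_psa:
            continue
        if spec.name in _READM_NAMES and not vary_readmission_probs:
            continue
        dists[spec.name] = make_distribution(spec, convention)
    return dists


def run_psa(params: ParameterSet, n_trials: int, seed: int,
            calibration: Calibration | None = None, wtp: float | None = None,
            vary_readmission_probs: bool = True, convention: str = "ci95",
            horizon: int = DEFAULT_HORIZON) -> PSAResult:
    """Monte Carlo PSA over all varied parameters.

    Deterministic given ``seed`` (a fixed parameter-sampling order feeds a
    single :class:`numpy.random.Generator`).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if calibration is None:
        calibration = markov.calibrate_base_case(params)
    if wtp is None:
        wtp = params.wtp

    dists = build_psa_distributions(params, vary_readmission_probs, convention)
    rng = np.random.default_rng(seed)
    draws: dict[str, np.ndarray] = {}
    for name in sorted(dists):  # fixed order => bit-reproducible
        draws[name] = np.asarray(dists[name].sample(rng, size=n_trials), dtype=float)

    def col(name: str) -> np.ndarray:
        return draws.get(name, np.full(n_trials, params.value(name)))

    # BP outcome simplex: the normotensive probability absorbs the residual.
    p_mild, p_sev = col("p_mild"), col("p_sev")
    p_morb, p_death = col("p_morb"), col("p_death")
    rest = p_mild + p_sev + p_morb + p_death
    bad = rest >= 1.0
    n_renorm = int(bad.sum())
    if n_renorm:
        logger.warning("PSA: %d trials rescaled onto the BP simplex", n_renorm)
        shrink = np.where(bad, (1.0 - 1e-9) / rest, 1.0)
        p_mild, p_sev = p_mild * shrink, p_sev * shrink
        p_morb, p_death = p_morb * shrink, p_death * shrink
        rest = p_mild + p_sev + p_morb + p_death
    p_norm = 1.0 - rest
    bp = (p_norm, p_mild, p_sev, p_morb, p_death)

    costs = {name: col(name) for name in _COST_NAMES}
    arm_inputs = {
        "rbpm": (col("ack_sev_rbpm"), col("p_readm_rbpm")),
        "usual_care": (col("ack_sev_uc"), col("p_readm_uc")),
    }
    out = {}
    clipped = np.zeros(n_trials, dtype=bool)
    for strategy, (ack, target) in arm_inputs.items():
        cost, qaly, _readm, _dead, clip = _arm_outcomes(
            params, calibration, strategy, bp, ack, target, costs, horizon
        )
        out[strategy] = (cost, qaly)
        clipped |= clip
    n_clipped = int(clipped.sum())
    if n_clipped:
        logger.info("PSA: %d trials hit the mechanistic readmission ceiling", n_clipped)

    delta_cost = out["rbpm"][0] - out["usual_care"][0]
    delta_effect = out["rbpm"][1] - out["usual_care"][1]
    return PSAResult(n_trials, seed, float(wtp), delta_cost, delta_effect,
                     n_renorm, n_clipped)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def acceptability_at(result: PSAResult, wtp: float) -> float:
    """Fraction of trials in which remote management has the higher net
    monetary benefit at ``wtp`` (exact ties count as not cost-effective)."""
    if result.n_trials == 0:
        raise ValueError("empty PSA result")
    return float(np.mean(result.nmb_difference(wtp) > 0.0))


def ceac(result: PSAResult, wtp_grid: Sequence[float]) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve over a WTP grid."""
    grid = np.asarray(list(wtp_grid), dtype=float)
    if np.any(grid < 0.0):
        raise ValueError("WTP grid must be nonnegative")
    if np.any(np.diff(grid) < 0.0):
        raise ValueError("WTP grid must be sorted ascending")
    fractions = [acceptability_at(result, w) for w in grid]
    return pd.DataFrame({"wtp": grid, "fraction": fractions})


@dataclass(frozen=True)
class CEPlaneSummary:
    """Mean, covariance, and 95% confidence ellipse of the CE-plane cloud
    (x = incremental effectiveness, y = incremental cost)."""

    mean_effect: float
    mean_cost: float
    covariance: np.ndarray       # 2x2, (effect, cost) order
    semi_axes: tuple[float, float]
    angle_deg: float             # major-axis angle from the effect axis
    degenerate: bool

    def to_dict(self) -> dict:
        return {
            "mean_effect": self.mean_effect,
            "mean_cost": self.mean_cost,
            "covariance": self.covariance.tolist(),
            "semi_axes": list(self.semi_axes),
            "angle_deg": self.angle_deg,
            "degenerate": self.degenerate,
        }


_CHI2_95_2DF = float(chi2.ppf(0.95, df=2))


def ce_plane_summary(result: PSAResult) -> CEPlaneSummary:
    """Sample moments of the incremental cloud and its 95% ellipse.

    The ellipse is the set of points whose Mahalanobis distance from the
    sample mean satisfies d^2 <= chi-square(2, 0.95); for Gaussian clouds it
    covers ~95% of trials.  A singular covariance collapses the ellipse to a
    segment and is flagged degenerate.
    """
    if result.n_trials < 3:
        raise ValueError("need at least 3 trials for a CE-plane summary")
    pts = np.column_stack([result.delta_effect, result.delta_cost])
    mean = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    # degeneracy must be scale-free: the two axes carry different units
    # (QALY vs USD), so test the correlation, not the raw eigenvalues
    var = np.diag(cov)
    if np.any(var <= 0.0):
        degenerate = True
    else:
        corr = cov[0, 1] / np.sqrt(var[0] * var[1])
        degenerate = bool(abs(corr) >= 1.0 - 1e-12)
    eigvals, eigvecs = np.linalg.eigh(cov)
    if degenerate:
        logger.warning("CE-plane covariance is singular; ellipse collapses to a segment")
    semi = np.sqrt(np.maximum(eigvals, 0.0) * _CHI2_95_2DF)
    major = eigvecs[:, 1]
    angle = float(np.degrees(np.arctan2(major[1], major[0])))
    return CEPlaneSummary(float(mean[0]), float(mean[1]), cov,
                          (float(semi[1]), float(semi[0])), angle, degenerate)


def fraction_inside_ellipse(result: PSAResult, summary: CEPlaneSummary) -> float:
    """Empirical coverage of the 95% ellipse (diagnostic)."""
    pts = np.column_stack([result.delta_effect, result.delta_cost])
    centered = pts - [summary.mean_effect, summary.mean_cost]
    d2 = np.einsum("ij,jk,ik->i", centered, np.linalg.pinv(summary.covariance), centered)
    return float(np.mean(d2 <= _CHI2_95_2DF))
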