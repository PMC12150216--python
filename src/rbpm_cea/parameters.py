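"""Model inputs for the postpartum hypertension monitoring cost-effectiveness model.

This module is the single source of truth for every model input: the daily
blood-pressure (BP) outcome probabilities, acknowledgment probabilities,
14-day readmission probabilities, death hazards, per-patient costs, the
willingness-to-pay, and the utility weights used for QALY accrual.  Each
input is a :class:`ParameterSpec` carrying a base-case value and a
plausibility range; ranges feed both the deterministic sensitivity analyses
and the probabilistic sensitivity analysis (PSA), where they are converted
into beta (probabilities, utilities) or gamma (costs) distributions by
method of moments.

Two published-range anomalies are handled explicitly:

* The severe-range BP probability is printed with the range "0.0060–0.0012",
  which cannot bracket its base value 0.008; it is implemented as
  0.006–0.012.
* The daily BP outcome probabilities sum to slightly more than 1
  (0.962 + 0.03 + 0.008 + 0.00007 + 0.000019 = 1.000089); the normotensive
  probability acts as the slack state and absorbs the residual so that
  transition-matrix rows are exactly stochastic (see
  :meth:`ParameterSet.bp_probabilities`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, ValidationError

logger = logging.getLogger(__name__)

KINDS = ("probability", "cost", "utility", "count")


@dataclass(frozen=True)
class ParameterSpec:
    """One model input: base-case value, plausibility range, and metadata."""

    name: str
    base: float
    low: float
    high: float
    kind: str
    units: str
    varied_in_psa: bool = False
    description: str = ""

    def validate(self) -> None:
        if self.kind not in KINDS:
            raise ValidationError(f"{self.name}: unknown kind {self.kind!r}")
        if not (self.low <= self.base <= self.high):
            raise ValidationError(
                f"{self.name}: base {self.base} outside range [{self.low}, {self.high}]"
            )
        if self.kind in ("probability", "utility"):
            if self.low < 0.0 or self.high > 1.0:
                raise ValidationError(
                    f"{self.name}: {self.kind} range [{self.low}, {self.high}] not within [0, 1]"
                )
        if self.kind == "cost" and self.low < 0.0:
            raise ValidationError(f"{self.name}: cost lower bound {self.low} < 0")


def _spec(name, base, low, high, kind, units, psa=False, desc=""):
    return ParameterSpec(name, base, low, high, kind, units, psa, desc)


#: Base-case inputs.  Probabilities and costs carry the published base values
#: and ranges; utility weights are not published and are package defaults
#: (documented in docs/methods.md), exposed for configuration like any other
#: input.
DEFAULT_SPECS: tuple[ParameterSpec, ...] = (
    # Daily BP outcome probabilities (day-1 values held constant over 14 days)
    _spec("p_norm", 0.962, 0.95, 0.98, "probability", "per-day probability", True,
          "normotensive BP on a given day (slack state of the BP simplex)"),
    _spec("p_mild", 0.03, 0.02, 0.08, "probability", "per-day probability", True,
          "mild-range BP (SBP 140-159 or DBP 90-109 mm Hg)"),
    _spec("p_sev", 0.008, 0.006, 0.012, "probability", "per-day probability", True,
          "severe-range BP (SBP >=160 or DBP >=110 mm Hg); published range corrected from '0.0060-0.0012'"),
    _spec("p_morb", 0.00007, 0.00001, 0.0001, "probability", "per-day probability", True,
          "severe morbidity (eclampsia, stroke, ICU admission)"),
    _spec("p_death", 0.000019, 0.000019, 0.00003, "probability", "per-day probability", True,
          "death"),
    # Acknowledgment probabilities: an abnormal reading is reported and acted on
    _spec("ack_mild_rbpm", 0.65, 0.59, 0.88, "probability", "per-day probability", True,
          "acknowledged mild-range BP under remote management (bookkeeping only)"),
    _spec("ack_sev_rbpm", 0.86, 0.80, 0.95, "probability", "per-day probability", True,
          "acknowledged severe-range BP under remote management"),
    _spec("ack_mild_uc", 0.04, 0.01, 0.10, "probability", "per-day probability", True,
          "acknowledged mild-range BP under usual care (bookkeeping only)"),
    _spec("ack_sev_uc", 0.60, 0.59, 0.62, "probability", "per-day probability", True,
          "acknowledged severe-range BP under usual care"),
    # 14-day readmission probabilities (direct-mode calibration targets)
    _spec("p_readm_rbpm", 0.01, 0.0, 0.15, "probability", "per-14-day probability", True,
          "postpartum readmission for severe hypertension, remote management"),
    _spec("p_readm_uc", 0.05, 0.037, 0.15, "probability", "per-14-day probability", True,
          "postpartum readmission for severe hypertension, usual care"),
    # Additional daily death hazards
    _spec("p_death_sevpe", 0.00006, 0.00004, 0.00008, "probability", "per-day probability", False,
          "death from severe preeclampsia (unrecognized severe BP state)"),
    _spec("p_death_morb", 0.00006, 0.00004, 0.00008, "probability", "per-day probability", False,
          "death from severe morbidity"),
    # Bookkeeping probability: no cost or utility consequence in the base model
    _spec("p_med_titration", 0.30, 0.23, 0.62, "probability", "per-14-day probability", False,
          "requiring medication titration by day 14 (microsimulation annotation)"),
    # Costs (USD, per patient unless stated)
    _spec("c_readm", 17549.0, 17364.0, 17734.0, "cost", "USD", True,
          "readmission for severe-range BP or severe morbidity"),
    _spec("c_program", 139.0, 110.0, 150.0, "cost", "USD", True,
          "remote BP monitoring program enrollment"),
    _spec("c_cuff", 50.0, 40.0, 60.0, "cost", "USD", True,
          "automated (non-Bluetooth) BP cuff"),
    _spec("c_nurse_annual", 127374.0, 101400.0, 156000.0, "cost", "USD per year", True,
          "nurse practitioner at 1.0 FTE overseeing the program, incl. 30% benefits"),
    _spec("c_outpatient", 145.0, 100.0, 200.0, "cost", "USD", True,
          "outpatient BP check visit under usual care"),
    _spec("patients_per_year", 900.0, 900.0, 900.0, "count", "patients per year", False,
          "program volume over which the nurse FTE is spread"),
    # Decision threshold
    _spec("wtp", 100000.0, 100000.0, 100000.0, "cost", "USD per QALY", False,
          "willingness to pay per quality-adjusted life-year"),
    # Utility weights (package defaults; not published)
    _spec("u_norm", 1.0, 0.95, 1.0, "utility", "dimensionless", False,
          "daily utility, normotensive"),
    _spec("u_mild", 0.98, 0.95, 1.0, "utility", "dimensionless", False,
          "daily utility, mild-range BP"),
    _spec("u_sev", 0.90, 0.80, 0.95, "utility", "dimensionless", False,
          "daily utility, severe-range BP (unrecognized or readmitted)"),
    _spec("u_morb", 0.60, 0.40, 0.80, "utility", "dimensionless", False,
          "daily utility, severe morbidity"),
    _spec("u_persistent_decrement", 0.02, 0.0, 0.05, "utility", "dimensionless", False,
          "utility decrement for persistent hypertension beyond 2 weeks"),
    _spec("persistent_htn_fraction", 0.50, 0.25, 0.50, "probability", "dimensionless", False,
          "fraction of the cohort with persistent hypertension beyond 6 weeks"),
    _spec("rbpm_uplift", 0.0, 0.0, 0.02, "utility", "dimensionless", False,
          "utility uplift on the persistent-hypertension component in the remote arm; "
          "set by base-case calibration"),
)

_DEFAULT_NAMES = {s.name for s in DEFAULT_SPECS}

#: Names of the five daily BP outcome probabilities, in simplex order.
BP_OUTCOME_NAMES = ("p_norm", "p_mild", "p_sev", "p_morb", "p_death")


class ParameterSet:
    """An immutable-by-convention collection of :class:`ParameterSpec`.

    Attribute access returns base-case values (``params.p_sev`` -> 0.008);
    :meth:`spec` returns the full record.  Use :meth:`with_value` /
    :meth:`with_spec` to derive modified copies (originals are never mutated).
    """

    def __init__(self, specs: Mapping[str, ParameterSpec] | None = None):
        if specs is None:
            specs = {s.name: s for s in DEFAULT_SPECS}
        self._specs: dict[str, ParameterSpec] = dict(specs)
        self.validate()

    # -- access ----------------------------------------------------------
    def __getattr__(self, name: str) -> float:
        specs = object.__getattribute__(self, "_specs")
        if name in specs:
            return specs[name].base
        raise AttributeError(name)

    def __iter__(self) -> Iterator[ParameterSpec]:
        return iter(self._specs.values())

    def __contains__(self, name: str) -> bool:
        return name in self._specs

    def __eq__(self, other) -> bool:
        return isinstance(other, ParameterSet) and self._specs == other._specs

    def names(self) -> list[str]:
        return list(self._specs)

    def spec(self, name: str) -> ParameterSpec:
        try:
            return self._specs[name]
        except KeyError:
            raise KeyError(f"unknown parameter {name!r}") from None

    def value(self, name: str) -> float:
        return self.spec(name).base

    # -- derived quantities ----------------------------------------------
    def bp_probabilities(self) -> np.ndarray:
        """The five daily BP outcome probabilities, renormalized to a simplex.

        The published values sum to 1.000089; the normotensive probability is
        the slack state, so ``p_norm`` is replaced by ``1 - sum(others)``.
        """
        others = np.array([self.value(n) for n in BP_OUTCOME_NAMES[1:]])
        slack = 1.0 - others.sum()
        if not (0.0 <= slack <= 1.0):
            raise ValidationError(
                "BP outcome probabilities other than p_norm sum to "
                f"{others.sum():.6f}; no valid slack remains for p_norm"
            )
        return np.concatenate([[slack], others])

    def nurse_cost_per_patient(self) -> float:
        return per_patient_nurse_cost(self.c_nurse_annual, self.patients_per_year)

    def fixed_cost(self, strategy: str) -> float:
        """Per-patient strategy cost that does not depend on clinical events."""
        if strategy == "rbpm":
            return self.c_program + self.c_cuff + self.nurse_cost_per_patient()
        if strategy == "usual_care":
            return self.c_outpatient
        raise ValueError(f"unknown strategy {strategy!r}")

    # -- derivation ------------------------------------------------------
    def with_spec(self, spec: ParameterSpec) -> "ParameterSet":
        if spec.name not in self._specs:
            raise KeyError(f"unknown parameter {spec.name!r}")
        specs = dict(self._specs)
        specs[spec.name] = spec
        return ParameterSet(specs)

    def with_value(self, name: str, base: float) -> "ParameterSet":
        """Copy with ``name`` set to ``base``; bounds widen to keep it valid."""
        old = self.spec(name)
        return self.with_spec(
            replace(old, base=base, low=min(old.low, base), high=max(old.high, base))
        )

    def with_values(self, **kwargs: float) -> "ParameterSet":
        out = self
        for name, base in kwargs.items():
            out = out.with_value(name, base)
        return out

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        missing = _DEFAULT_NAMES - set(self._specs)
        if missing:
            raise ValidationError(f"missing parameters: {sorted(missing)}")
        for spec in self._specs.values():
            spec.validate()
        self.bp_probabilities()  # raises if the simplex slack is infeasible
        if self.patients_per_year <= 0:
            raise ValidationError("patients_per_year must be positive")

    # -- I/O ---------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Parameter dump with the distribution family the PSA would use."""
        rows = []
        for s in self._specs.values():
            rows.append(
                {
                    "name": s.name,
                    "base": s.base,
                    "low": s.low,
                    "high": s.high,
                    "kind": s.kind,
                    "units": s.units,
                    "varied_in_psa": s.varied_in_psa,
                    "distribution_family": make_distribution(s).family,
                }
            )
        return pd.DataFrame(rows)

    def to_config_dict(self) -> dict:
        return {
            s.name: {"base": s.base, "low": s.low, "high": s.high}
            for s in self._specs.values()
        }


# ---------------------------------------------------------------------------
# configuration loading
# ---------------------------------------------------------------------------

def _apply_overrides(params: ParameterSet, overrides: Mapping, where: str) -> ParameterSet:
    for name, entry in overrides.items():
        if name not in params:
            raise ConfigError(f"{where}: unknown parameter {name!r}")
        old = params.spec(name)
        if isinstance(entry, Mapping):
            unknown = set(entry) - {"base", "low", "high"}
            if unknown:
                raise ConfigError(f"{where}: {name}: unknown keys {sorted(unknown)}")
            base = float(entry.get("base", old.base))
            low = float(entry.get("low", min(old.low, base)))
            high = float(entry.get("high", max(old.high, base)))
        else:  # scalar shorthand sets the base value
            base = float(entry)
            low, high = min(old.low, base), max(old.high, base)
        new = replace(old, base=base, low=low, high=high)
        new.validate()
        params = params.with_spec(new)
    return params


def load_parameters(path: str | Path | None = None, scenario: str | None = None) -> ParameterSet:
    """Load the default parameter set, optionally overlaid with a config file.

    The config is YAML (or JSON, a YAML subset): a mapping
    ``name -> {base, low, high}`` (scalars set the base), optionally nested
    under a ``parameters:`` block, plus an optional ``scenarios:`` block of
    named override groups selected via ``scenario=``.
    """
    params = ParameterSet()
    if path is None:
        if scenario is not None:
            raise ConfigError(f"scenario {scenario!r} requested but no config given")
        return params

    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:  # name the offending line
        mark = getattr(exc, "problem_mark", None)
        loc = f" at line {mark.line + 1}" if mark is not None else ""
        raise ConfigError(f"{path}: malformed YAML{loc}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: top level must be a mapping")

    scenarios = raw.get("scenarios", {})
    overrides = dict(raw.get("parameters", {}))
    for key, entry in raw.items():
        if key in ("parameters", "scenarios"):
            continue
        overrides[key] = entry
    params = _apply_overrides(params, overrides, str(path))

    if scenario is not None:
        if scenario not in scenarios:
            raise ConfigError(f"{path}: unknown scenario {scenario!r}")
        params = _apply_overrides(params, scenarios[scenario], f"{path}:{scenario}")
    params.validate()
    return params


def per_patient_nurse_cost(c_nurse_annual: float, patients_per_year: float) -> float:
    """Annual nurse-practitioner cost spread over annual program volume.

    Rounded half-up to cents (127374 / 900 -> 141.53).
    """
    if patients_per_year <= 0:
        raise ValidationError("patients_per_year must be positive")
    if c_nurse_annual < 0:
        raise ValidationError("c_nurse_annual must be nonnegative")
    cents = Decimal(c_nurse_annual) / Decimal(patients_per_year)
    return float(cents.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# sampling distributions for the PSA
# ---------------------------------------------------------------------------

#: Divisor turning a central 95% interval width into a standard deviation
#: (2 x 1.96, the conventional two-sided normal quantile).
_CI95_WIDTH_SD = 2.0 * 1.96


@dataclass(frozen=True)
class DistributionSpec:
    """A fitted sampling distribution for one parameter.

    ``family`` is ``beta`` (support [0, 1]), ``gamma`` (support [0, inf)) or
    ``degenerate`` (a point mass).  ``a``/``b`` are the beta shapes, or the
    gamma shape/scale, or (value, value) for a point mass.
    """

    family: str
    a: float
    b: float
    support: tuple[float, float] = field(default=(0.0, 1.0))

    def mean(self) -> float:
        if self.family == "beta":
            return self.a / (self.a + self.b)
        if self.family == "gamma":
            return self.a * self.b
        return self.a

    def sd(self) -> float:
        if self.family == "beta":
            n = self.a + self.b
            return float(np.sqrt(self.a * self.b / (n * n * (n + 1.0))))
        if self.family == "gamma":
            return float(np.sqrt(self.a) * self.b)
        return 0.0

    def sample(self, rng: np.random.Generator, size=None) -> np.ndarray | float:
        if self.family == "beta":
            return rng.beta(self.a, self.b, size=size)
        if self.family == "gamma":
            return rng.gamma(self.a, self.b, size=size)
        if size is None:
            return self.a
        return np.full(size, self.a)


def make_distribution(spec: ParameterSpec, convention: str = "ci95") -> DistributionSpec:
    """Fit a sampling distribution to a parameter by method of moments.

    The mean is pinned to the base-case value.  The published range is read
    as a central 95% interval (``convention='ci95'``, sd = width / 3.92) or,
    alternatively, as the support of a uniform with matching sd
    (``convention='minmax'``, sd = width / sqrt(12)).  Probabilities and
    utilities get beta distributions, costs get gamma, zero-width ranges
    (and counts) collapse to point masses.
    """
    spec.validate()
    m = spec.base
    width = spec.high - spec.low
    if convention == "ci95":
        sd = width / _CI95_WIDTH_SD
    elif convention == "minmax":
        sd = width / np.sqrt(12.0)
    else:
        raise ValueError(f"unknown range convention {convention!r}")

    if spec.kind == "count" or width <= 0.0 or sd == 0.0:
        if width <= 0.0 and not (spec.low <= m <= spec.high):
            logger.warning("%s: zero-width range excludes base; degenerate at base", spec.name)
        return DistributionSpec("degenerate", m, m, (m, m))

    v = sd * sd
    if spec.kind in ("probability", "utility"):
        if m <= 0.0 or m >= 1.0:
            logger.warning("%s: beta mean %s on the boundary; degenerate at base", spec.name, m)
            return DistributionSpec("degenerate", m, m, (m, m))
        vmax = m * (1.0 - m)
        if v >= vmax:
            logger.warning(
                "%s: moment fit infeasible (var %.3g >= mean(1-mean) %.3g); clamping",
                spec.name, v, vmax,
            )
            v = 0.99 * vmax
        n = vmax / v - 1.0
        return DistributionSpec("beta", m * n, (1.0 - m) * n, (0.0, 1.0))

    # costs: gamma with mean m = shape * scale, var = shape * scale^2
    if m <= 0.0:
        logger.warning("%s: nonpositive cost mean; degenerate at base", spec.name)
        return DistributionSpec("degenerate", m, m, (m, m))
    shape = m * m / v
    scale = v / m
    return DistributionSpec("gamma", shape, scale, (0.0, np.inf))


def sample(dist: DistributionSpec, rng: np.random.Generator) -> float:
    """Draw one value from a fitted distribution (reproducible given ``rng``)."""
    return float(dist.sample(rng))
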