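"""Comparative cost-effectiveness statistics.

Incremental cost, incremental effectiveness, the incremental
cost-effectiveness ratio (ICER) with dominance classification, net monetary
benefit (NMB), and cost per readmission averted.

Orientation conventions (both reported, since the source analysis uses an
unusual one):

* ``delta_cost``  = cost(usual care) - cost(remote management): the extra
  spending usual care incurs;
* ``delta_effect`` = QALY(remote management) - QALY(usual care): the QALY
  gain of remote management.

With both deltas positive, remote management is *dominant* (cheaper and
more effective) and ``icer`` equals the published framing "incremental cost
per QALY gained in the usual care group" (what each QALY forgone by staying
with usual care costs).  The decision field always maximizes NMB at the
stated willingness to pay; exact NMB ties break toward usual care (the
incumbent).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .markov import ArmResult


def net_monetary_benefit(arm: ArmResult, wtp: float) -> float:
    """NMB = WTP x QALYs - cost (USD)."""
    if wtp < 0:
        raise ValueError("willingness to pay must be nonnegative")
    return wtp * arm.qaly_total - arm.total_cost


def classify_dominance(delta_cost: float, delta_effect: float) -> str | None:
    """Dominance label from the signs of the two deltas, or None when the
    ICER is informative (one strategy trades cost against effect)."""
    if delta_cost > 0 and delta_effect > 0:
        return "dominant(rbpm)"
    if delta_cost < 0 and delta_effect < 0:
        return "dominant(usual_care)"
    if delta_cost == 0 and delta_effect == 0:
        return "equivalent"
    return None


@dataclass(frozen=True)
class CEAResult:
    delta_cost: float          # USD, usual care minus remote management
    delta_effect: float        # QALY, remote management minus usual care
    delta_readmissions: float  # probability, usual care minus remote management
    icer: float | None         # USD/QALY; None when delta_effect == 0
    dominance: str | None
    nmb_rbpm: float
    nmb_usual: float
    wtp: float
    decision: str

    @property
    def nmb_difference(self) -> float:
        return self.nmb_rbpm - self.nmb_usual

    def to_dict(self) -> dict:
        return {
            "delta_cost_usual_minus_rbpm": round(self.delta_cost, 2),
            "delta_effect_rbpm_minus_usual": self.delta_effect,
            "delta_readmissions_usual_minus_rbpm": self.delta_readmissions,
            "icer_usd_per_qaly": None if self.icer is None else round(self.icer, 2),
            "icer_rbpm_vs_usual": None if self.icer is None else round(-self.icer, 2),
            "dominance": self.dominance,
            "nmb_rbpm": round(self.nmb_rbpm, 2),
            "nmb_usual_care": round(self.nmb_usual, 2),
            "wtp": self.wtp,
            "decision": self.decision,
        }


def compare(rbpm: ArmResult, usual: ArmResult, wtp: float) -> CEAResult:
    """Full incremental comparison of the two strategies at a given WTP."""
    delta_cost = usual.total_cost - rbpm.total_cost
    delta_effect = rbpm.qaly_total - usual.qaly_total
    delta_readm = usual.readmissions - rbpm.readmissions
    icer = None if delta_effect == 0.0 else delta_cost / delta_effect
    nmb_r = net_monetary_benefit(rbpm, wtp)
    nmb_u = net_monetary_benefit(usual, wtp)
    decision = "rbpm" if nmb_r > nmb_u else "usual_care"
    return CEAResult(delta_cost, delta_effect, delta_readm, icer,
                     classify_dominance(delta_cost, delta_effect),
                     nmb_r, nmb_u, wtp, decision)


def cost_per_readmission_averted(rbpm: ArmResult, usual: ArmResult) -> float:
    """Signed incremental cost per readmission averted by remote management:
    (cost_rbpm - cost_usual) / (readm_usual - readm_rbpm).  Negative values
    mean each averted readmission SAVES money."""
    averted = usual.readmissions - rbpm.readmissions
    if math.isclose(averted, 0.0, abs_tol=1e-15):
        raise ZeroDivisionError(
            "readmission probabilities are equal; cost per readmission averted undefined"
        )
    return (rbpm.total_cost - usual.total_cost) / averted
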