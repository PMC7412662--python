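"""Cost-effectiveness comparison of two strategy outcomes.

The incremental cost-effectiveness ratio (ICER) is the cost difference per
QALY gained of the more expensive strategy over the cheaper one.  When the
cheaper strategy is also at least as effective it dominates and no ratio
is meaningful (a negative ICER is uninterpretable), so the comparison then
carries a dominance label instead of a number.  Net monetary benefit (NMB)
at willingness to pay ``wtp`` is ``wtp * QALYs - cost``; the strategy with
the higher NMB is the cost-effective one at that threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import pandas as pd

from .model import StrategyOutcome, run_cohort
from .parameters import LifeTable, ParameterSet

__all__ = [
    "CEAComparison",
    "compare_strategies",
    "compute_icer",
    "net_monetary_benefit",
]


def net_monetary_benefit(outcome: StrategyOutcome, wtp: float) -> float:
    """``wtp * QALYs - cost`` for one strategy outcome."""
    if wtp < 0:
        raise ValueError("willingness to pay must be non-negative")
    return wtp * outcome.qalys - outcome.cost


@dataclass(frozen=True)
class CEAComparison:
    """Incremental comparison of two strategies.

    ``reference`` is the cheaper strategy, ``comparator`` the more
    expensive; deltas are comparator minus reference.  ``icer`` is a number
    only for a genuine trade-off (comparator costlier *and* more
    effective); otherwise it is ``None`` and ``dominance`` explains why.
    """

    reference: StrategyOutcome
    comparator: StrategyOutcome
    delta_cost: float
    delta_qalys: float
    icer: float | None
    dominance: str
    wtp: float
    nmb: dict[str, float]

    def outcome(self, strategy: str) -> StrategyOutcome:
        for o in (self.reference, self.comparator):
            if o.strategy == strategy:
                return o
        raise KeyError(strategy)

    @property
    def cost_effective(self) -> str:
        """Strategy with the higher NMB at ``wtp`` (ties to the cheaper)."""
        a, b = self.reference, self.comparator
        if self.nmb[a.strategy] >= self.nmb[b.strategy]:
            return a.strategy  # reference is the cheaper strategy
        return b.strategy

    def icer_display(self) -> str:
        if self.icer is not None:
            return f"{self.icer:,.0f}"
        return self.dominance

    def to_record(self) -> dict:
        rec: dict = {}
        for o in sorted((self.reference, self.comparator), key=lambda s: s.strategy):
            rec[f"cost_{o.strategy}"] = o.cost
            rec[f"qalys_{o.strategy}"] = o.qalys
            rec[f"nmb_{o.strategy}"] = self.nmb[o.strategy]
        rec.update(
            reference=self.reference.strategy,
            comparator=self.comparator.strategy,
            delta_cost=self.delta_cost,
            delta_qalys=self.delta_qalys,
            icer=self.icer,
            dominance=self.dominance,
            cost_effective=self.cost_effective,
            wtp=self.wtp,
        )
        return rec

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.to_record()])

    def to_json(self) -> str:
        return json.dumps(self.to_record(), indent=2)

    def summary(self) -> str:
        a, b = self.reference, self.comparator
        lines = [
            f"{'':<12}{'cost (SGD)':>14}{'QALYs':>10}{'NMB@{:,.0f}'.format(self.wtp):>16}",
        ]
        for o in (a, b):
            lines.append(f"{o.strategy:<12}{o.cost:>14,.0f}{o.qalys:>10.2f}"
                         f"{self.nmb[o.strategy]:>16,.0f}")
        lines.append(f"incremental ({b.strategy} vs {a.strategy}): "
                     f"dCost={self.delta_cost:,.0f}, dQALY={self.delta_qalys:.3f}, "
                     f"ICER={self.icer_display()}")
        lines.append(f"cost-effective at WTP {self.wtp:,.0f}: {self.cost_effective}")
        return "\n".join(lines)


def compute_icer(a: StrategyOutcome, b: StrategyOutcome,
                 wtp: float = 50000.0) -> CEAComparison:
    """Compare two outcomes; ordering is by cost, so the result does not
    depend on argument order."""
    ref, comp = sorted((a, b), key=lambda o: (o.cost, o.qalys))
    dc = comp.cost - ref.cost
    dq = comp.qalys - ref.qalys
    icer: float | None = None
    if dc == 0 and dq == 0:
        dominance = "equivalent"
    elif dq == 0:
        dominance = "cost-minimization"
    elif dc == 0:
        dominance = "comparator dominant" if dq > 0 else "reference dominant"
    elif dq < 0:
        # the cheaper strategy is also more effective
        dominance = "reference dominant"
    else:
        dominance = "trade-off"
        icer = dc / dq
    nmb = {o.strategy: net_monetary_benefit(o, wtp) for o in (ref, comp)}
    return CEAComparison(ref, comp, dc, dq, icer, dominance, wtp, nmb)


def compare_strategies(params: ParameterSet, life_table: LifeTable,
                       wtp: float | None = None) -> CEAComparison:
    """Run both strategies on ``params`` and compare them."""
    uapr = run_cohort("UAPR", params, life_table)
    ciup = run_cohort("CIUP", params, life_table)
    return compute_icer(uapr, ciup, wtp=params.wtp if wtp is None else wtp)
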