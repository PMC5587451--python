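"""Reward accrual, discounting, intervention costing and incremental
cost-effectiveness analysis.

Rewards are attached to the post-transition distribution of each cycle
(no half-cycle correction): a person who recovers during a cycle is
credited the destination state's utility and cost for that whole year.
QALYs and costs share a single annual discount rate; two exponent
conventions are selectable (see :class:`DiscountSpec`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .cohort import CohortTrace, alive_fractions
from .states import RewardSet, ValidationError

#: Swedish willingness-to-pay bands, euro per QALY.
LOW_THRESHOLD = 11_000.0
MODERATE_THRESHOLD = 55_000.0

DiscountConvention = Literal["from-first-cycle", "after-first-cycle"]


@dataclass(frozen=True)
class DiscountSpec:
    """Annual discounting of future QALYs and costs.

    ``rate`` is the annual fraction (0.03 here).  ``convention`` chooses
    the exponent attached to cycle t = 1..T:

    - ``from-first-cycle``: factor (1 + rate)^-t — the first year's
      rewards are already discounted once (default; reproduces the
      published totals);
    - ``after-first-cycle``: factor (1 + rate)^-(t - 1) — the first
      year is taken at face value.
    """

    rate: float = 0.03
    convention: DiscountConvention = "from-first-cycle"

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValidationError(f"discount rate must be >= 0, got {self.rate}")
        if self.convention not in ("from-first-cycle", "after-first-cycle"):
            raise ValidationError(f"unknown discount convention {self.convention!r}")

    def factor(self, cycle: int) -> float:
        e = cycle if self.convention == "from-first-cycle" else cycle - 1
        return (1.0 + self.rate) ** (-e)

    def factors(self, T: int) -> np.ndarray:
        return np.array([self.factor(t) for t in range(1, T + 1)])


@dataclass(frozen=True)
class EconResult:
    """Per-cycle and total QALYs, costs and life-years for one strategy."""

    strategy: str
    qaly: np.ndarray  # undiscounted, per cycle
    cost: np.ndarray
    life_years_per_cycle: np.ndarray
    qaly_disc: np.ndarray
    cost_disc: np.ndarray
    life_years_disc: np.ndarray

    @property
    def horizon_T(self) -> int:
        return len(self.qaly)

    @property
    def total_qaly(self) -> float:
        return float(self.qaly_disc.sum())

    @property
    def total_cost(self) -> float:
        return float(self.cost_disc.sum())

    @property
    def total_life_years(self) -> float:
        return float(self.life_years_disc.sum())

    @property
    def total_qaly_undiscounted(self) -> float:
        return float(self.qaly.sum())

    @property
    def total_cost_undiscounted(self) -> float:
        return float(self.cost.sum())

    def to_frame(self) -> pd.DataFrame:
        """Per-cycle ledger, one row per cycle."""
        T = self.horizon_T
        return pd.DataFrame(
            {
                "strategy": self.strategy,
                "cycle": np.arange(1, T + 1),
                "qaly": self.qaly,
                "qaly_discounted": self.qaly_disc,
                "cost": self.cost,
                "cost_discounted": self.cost_disc,
                "life_years": self.life_years_per_cycle,
                "life_years_discounted": self.life_years_disc,
            }
        )


def accrue(
    trace: CohortTrace,
    rewards: RewardSet,
    discount: DiscountSpec,
    intervention_cost: float = 0.0,
    strategy: str = "strategy",
) -> EconResult:
    """Accrue QALYs, costs and life-years over a cohort trace.

    Cycle-t QALY is the dot product of the post-transition occupancy
    with the utilities; cycle-t cost likewise with the annual costs,
    plus ``intervention_cost`` in cycle 1.  Discounted series multiply
    each cycle by its discount factor.
    """
    if trace.states.labels != rewards.states.labels:
        raise ValidationError("trace and rewards are defined over different state spaces")
    T = trace.horizon_T
    q = trace.per_cycle @ rewards.utility
    c = trace.per_cycle @ rewards.annual_cost
    c = c.copy()
    c[0] += intervention_cost
    ly = alive_fractions(trace)
    f = discount.factors(T)
    return EconResult(
        strategy=strategy,
        qaly=q,
        cost=c,
        life_years_per_cycle=ly,
        qaly_disc=q * f,
        cost_disc=c * f,
        life_years_disc=ly * f,
    )


@dataclass(frozen=True)
class CostingInputs:
    """Ingredients of the per-person intervention cost.

    ``n_visits`` home visits with ``total_contact_hours`` of direct
    contact, plus ``travel_admin_per_visit`` hours of travel and
    administration per visit, valued at ``wage`` euro/hour; technical
    aids add ``aids_cost`` euro.
    """

    n_visits: int
    total_contact_hours: float
    travel_admin_per_visit: float = 0.5
    wage: float = 28.5
    aids_cost: float = 26.0

    def __post_init__(self) -> None:
        vals = (self.n_visits, self.total_contact_hours, self.travel_admin_per_visit, self.wage, self.aids_cost)
        if any(v < 0 for v in vals):
            raise ValidationError(f"costing inputs must be nonnegative, got {vals}")


def intervention_unit_cost(c: CostingInputs) -> float:
    """Per-person intervention cost in euro:
    (contact hours + visits x travel/admin hours) x wage + aids."""
    return (c.total_contact_hours + c.n_visits * c.travel_admin_per_visit) * c.wage + c.aids_cost


Verdict = Literal["intervention dominates", "comparator dominates", "icer", "no difference"]
ThresholdClass = Literal["low", "moderate", "high", "not-applicable"]


@dataclass(frozen=True)
class CEAComparison:
    """Incremental result of strategy ``a`` (intervention) vs ``b``
    (comparator): QALY and cost differences, dominance verdict, ICER
    when applicable, and the willingness-to-pay class of the ICER."""

    delta_qaly: float
    delta_cost: float
    verdict: Verdict
    icer: float | None
    threshold_class: ThresholdClass


def classify_icer(icer: float | None) -> ThresholdClass:
    """Willingness-to-pay band of an ICER: low (<= 11,000 euro/QALY),
    moderate (<= 55,000), high (> 55,000).  ``None`` (a dominance
    verdict) maps to not-applicable."""
    if icer is None:
        return "not-applicable"
    if icer <= LOW_THRESHOLD:
        return "low"
    if icer <= MODERATE_THRESHOLD:
        return "moderate"
    return "high"


def compare(a: EconResult, b: EconResult, atol: float = 1e-12) -> CEAComparison:
    """Incremental cost-effectiveness of ``a`` relative to ``b``.

    A strategy dominates when it has at least as many QALYs and no
    higher costs, with at least one strict inequality; otherwise the
    ICER delta_cost / delta_qaly is reported and classified.
    """
    if a.horizon_T != b.horizon_T:
        raise ValidationError(f"horizon mismatch: {a.horizon_T} vs {b.horizon_T} cycles")
    dq = a.total_qaly - b.total_qaly
    dc = a.total_cost - b.total_cost
    q_eq, c_eq = abs(dq) <= atol, abs(dc) <= atol
    if q_eq and c_eq:
        return CEAComparison(dq, dc, "no difference", None, "not-applicable")
    if dq >= -atol and dc <= atol:
        return CEAComparison(dq, dc, "intervention dominates", None, "not-applicable")
    if dq <= atol and dc >= -atol:
        return CEAComparison(dq, dc, "comparator dominates", None, "not-applicable")
    icer = dc / dq
    return CEAComparison(dq, dc, "icer", icer, classify_icer(icer))
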