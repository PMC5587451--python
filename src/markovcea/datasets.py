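"""Published model inputs for the bathing-disability evaluation.

These are the inputs of a published Swedish cost-effectiveness
evaluation of a reablement intervention for community-dwelling older
people with bathing disability: an annual five-state transition matrix
estimated from a Canadian ageing cohort, per-state quality-of-life
utilities and annual societal costs, a 1.4 relative increase of the
severe-to-moderate recovery probability applied in the first year, a
128 euro occupational-therapy intervention cost (546 euro for the
multi-professional alternative), 3% annual discounting and an 8-year
horizon with the whole cohort starting in severe dependency.
"""

from __future__ import annotations

import numpy as np

from .cohort import InterventionSpec
from .economics import DiscountSpec
from .states import RewardSet, StateSpace, TransitionMatrix

#: Canonical five-state dependency space.
STATES = StateSpace(("mild", "moderate", "severe", "total", "death"), frozenset({"death"}))

#: Published annual transition probabilities between dependency states.
TRANSITIONS = np.array(
    [
        [0.79, 0.13, 0.03, 0.02, 0.03],  # mild
        [0.08, 0.82, 0.03, 0.01, 0.06],  # moderate
        [0.02, 0.12, 0.61, 0.11, 0.14],  # severe
        [0.00, 0.03, 0.18, 0.63, 0.16],  # total
        [0.00, 0.00, 0.00, 0.00, 1.00],  # death (absorbing)
    ]
)

#: Published per-state QoL utilities.
UTILITIES = {"mild": 0.77, "moderate": 0.60, "severe": 0.47, "total": 0.41, "death": 0.0}

#: Published per-state annual societal costs, euro/year.
ANNUAL_COSTS = {"mild": 2864.0, "moderate": 8593.0, "severe": 22_915.0, "total": 68_746.0, "death": 0.0}

#: Occupational-therapy and multi-professional per-person costs, euro.
OT_COST = 128.0
MULTIPROF_COST = 546.0

MAIN_EFFECT = 1.4
SENSITIVITY_EFFECT = 1.2

HORIZON_YEARS = 8
DISCOUNT_RATE = 0.03


def transition_matrix() -> TransitionMatrix:
    """The published five-state annual transition matrix."""
    return TransitionMatrix(STATES, TRANSITIONS)


def rewards() -> RewardSet:
    """The published per-state utilities and annual societal costs."""
    return RewardSet.from_mappings(STATES, UTILITIES, ANNUAL_COSTS)


def intervention(effect_multiplier: float = MAIN_EFFECT, per_person_cost: float = OT_COST) -> InterventionSpec:
    """The bathing-disability intervention: a one-off relative boost of
    severe -> moderate recovery in cycle 1, mass donated by the
    severe -> severe diagonal."""
    return InterventionSpec(
        from_state="severe",
        to_state="moderate",
        effect_multiplier=effect_multiplier,
        donor="severe",
        cycles_applied=frozenset({1}),
        per_person_cost=per_person_cost,
    )


def discount() -> DiscountSpec:
    return DiscountSpec(rate=DISCOUNT_RATE, convention="from-first-cycle")


def initial_distribution() -> dict[str, float]:
    """Everyone starts in severe dependency (bathing disability)."""
    return {"severe": 1.0}
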