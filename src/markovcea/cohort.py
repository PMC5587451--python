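"""Deterministic cohort propagation and first-cycle intervention effects.

The cohort is a unit probability mass distributed over the dependency
states; "per 100 persons" figures are a reporting scale only.  An
intervention is modelled as a relative increase of one recovery
transition (severe -> moderate) during a chosen set of cycles, with the
added probability mass taken from a donor transition in the same row
(by default the severe -> severe diagonal, leaving mortality and
decline risks untouched).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .states import StateSpace, TransitionMatrix, ValidationError, as_distribution, ROW_SUM_TOL


@dataclass(frozen=True)
class InterventionSpec:
    """A one-off relative boost to a recovery transition.

    Parameters
    ----------
    from_state, to_state
        The targeted transition (default severe -> moderate recovery).
    effect_multiplier
        Relative probability of the targeted transition under the
        intervention (1.4 in the main analysis, 1.2 in sensitivity).
    donor
        Destination of the transition that surrenders the added mass;
        same source row.  Default: the from-state itself (stay put).
    cycles_applied
        Annual cycles (1-based) in which the modified matrix is used.
    per_person_cost
        Intervention cost in euro, charged once in cycle 1.
    """

    from_state: str = "severe"
    to_state: str = "moderate"
    effect_multiplier: float = 1.4
    donor: str | None = None
    cycles_applied: frozenset[int] = frozenset({1})
    per_person_cost: float = 128.0

    def __post_init__(self) -> None:
        if self.effect_multiplier <= 0:
            raise ValidationError(f"effect multiplier must be > 0, got {self.effect_multiplier}")
        if self.per_person_cost < 0:
            raise ValidationError(f"per-person cost must be >= 0, got {self.per_person_cost}")
        object.__setattr__(self, "cycles_applied", frozenset(int(c) for c in self.cycles_applied))

    @property
    def donor_state(self) -> str:
        return self.donor if self.donor is not None else self.from_state

    def replace(self, **kwargs) -> "InterventionSpec":
        from dataclasses import replace

        return replace(self, **kwargs)


def apply_intervention(m: TransitionMatrix, spec: InterventionSpec) -> TransitionMatrix:
    """Return the intervention-modified matrix for the cycles it applies.

    The targeted probability is multiplied by ``spec.effect_multiplier``
    and the added mass subtracted from the donor transition of the same
    source row; everything else is unchanged.  Raises
    :class:`ValidationError` if the modified target exceeds 1 or the
    donor would go negative.
    """
    i = m.states.index(spec.from_state)
    j = m.states.index(spec.to_state)
    k = m.states.index(spec.donor_state)
    if j == k:
        raise ValidationError("target and donor transitions must differ")
    p_target = m.p[i, j]
    new_target = spec.effect_multiplier * p_target
    delta = new_target - p_target
    new_donor = m.p[i, k] - delta
    if new_target > 1 + ROW_SUM_TOL:
        raise ValidationError(
            f"modified p({spec.from_state} -> {spec.to_state}) = {new_target:.6f} exceeds 1"
        )
    if new_donor < -ROW_SUM_TOL:
        raise ValidationError(
            f"donor p({spec.from_state} -> {spec.donor_state}) would become {new_donor:.6f} < 0"
        )
    row = m.p[i].copy()
    row[j] = new_target
    row[k] = new_donor
    return m.with_row(spec.from_state, row)


@dataclass(frozen=True)
class CohortTrace:
    """State-occupancy distributions after each annual cycle.

    ``per_cycle[t-1]`` is the distribution after ``t`` annual
    transitions; ``initial`` is the time-0 distribution.
    """

    states: StateSpace
    initial: np.ndarray
    per_cycle: np.ndarray  # shape (T, n_states)

    def __post_init__(self) -> None:
        init = as_distribution(self.initial, self.states)
        pc = np.asarray(self.per_cycle, dtype=float)
        if pc.ndim != 2 or pc.shape[1] != self.states.n:
            raise ValidationError(f"per-cycle trace has shape {pc.shape}, expected (T, {self.states.n})")
        for t, s in enumerate(pc, start=1):
            if (s < -ROW_SUM_TOL).any() or abs(s.sum() - 1.0) > 1e-9:
                raise ValidationError(f"cycle-{t} occupancy is not a distribution: {s.tolist()}")
        for lab in self.states.absorbing:
            col = pc[:, self.states.index(lab)]
            full = np.concatenate([[init[self.states.index(lab)]], col])
            if (np.diff(full) < -1e-12).any():
                raise ValidationError(f"absorbing-state occupancy {lab!r} decreased along the trace")
        init.setflags(write=False)
        pc = pc.copy()
        pc.setflags(write=False)
        object.__setattr__(self, "initial", init)
        object.__setattr__(self, "per_cycle", pc)

    @property
    def horizon_T(self) -> int:
        return self.per_cycle.shape[0]

    def occupancy(self, cycle: int) -> np.ndarray:
        """Distribution after ``cycle`` transitions (cycle 0 = initial)."""
        if cycle == 0:
            return self.initial
        return self.per_cycle[cycle - 1]

    def per_hundred(self, cycle: int) -> dict[str, int]:
        """Occupancy per 100 persons, half-up rounded, as the published
        cohort counts are reported."""
        s = self.occupancy(cycle)
        return {lab: int(np.floor(100 * v + 0.5)) for lab, v in zip(self.states.labels, s)}


def propagate(
    initial,
    matrices_by_cycle: TransitionMatrix | Mapping[int, TransitionMatrix],
    T: int,
) -> CohortTrace:
    """Propagate a cohort distribution through ``T`` annual cycles.

    ``matrices_by_cycle`` is either a single matrix used for every cycle
    or a mapping cycle (1-based) -> matrix covering 1..T.
    """
    if T < 1:
        raise ValidationError(f"horizon must be >= 1 year, got {T}")
    if isinstance(matrices_by_cycle, TransitionMatrix):
        matrices = {t: matrices_by_cycle for t in range(1, T + 1)}
    else:
        matrices = dict(matrices_by_cycle)
        missing = [t for t in range(1, T + 1) if t not in matrices]
        if missing:
            raise ValidationError(f"no transition matrix defined for cycles {missing}")
    states = matrices[1].states
    for t, m in matrices.items():
        if m.states.labels != states.labels:
            raise ValidationError(f"cycle-{t} matrix uses a different state space")
    s = as_distribution(initial, states)
    out = np.empty((T, states.n))
    for t in range(1, T + 1):
        s = s @ matrices[t].p
        out[t - 1] = s
    return CohortTrace(states, as_distribution(initial, states), out)


def cycle_matrices(base: TransitionMatrix, spec: InterventionSpec | None, T: int) -> dict[int, TransitionMatrix]:
    """Per-cycle matrices: the intervention-modified matrix in the
    cycles the spec covers, the base matrix elsewhere."""
    if spec is None:
        return {t: base for t in range(1, T + 1)}
    modified = apply_intervention(base, spec)
    return {t: (modified if t in spec.cycles_applied else base) for t in range(1, T + 1)}


def alive_fractions(trace: CohortTrace) -> np.ndarray:
    """Fraction of the cohort alive after each cycle (1 minus total
    absorbing-death occupancy)."""
    dead = np.zeros(trace.horizon_T)
    for lab in trace.states.absorbing:
        dead += trace.per_cycle[:, trace.states.index(lab)]
    return 1.0 - dead


def life_years(trace: CohortTrace, discount=None) -> tuple[np.ndarray, float]:
    """Per-cycle alive fractions and cumulative (optionally discounted)
    life-years over the horizon.

    ``discount`` is a :class:`markovcea.economics.DiscountSpec` or None.
    Each cycle lived in a non-death state counts one (discounted) year.
    """
    alive = alive_fractions(trace)
    if discount is None:
        total = float(alive.sum())
    else:
        total = float((alive * discount.factors(trace.horizon_T)).sum())
    return alive, total
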