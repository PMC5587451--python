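"""Domain types for discrete-state Markov cohort models of dependency.

The model describes annual transitions of older adults between ordered
levels of dependency in activities of daily living — mild, moderate,
severe and total dependency — plus an absorbing death state.  This module
holds the state space, the row-stochastic annual transition matrix, the
per-state rewards (a quality-of-life utility and an annual societal cost),
and the rule that collapses a fine-grained disability-profile matrix
(e.g. the 14 Iso-SMAF profiles plus long-term-care facility) into the
five coarse model states.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical ordering of the five dependency states.
DEFAULT_LABELS: tuple[str, ...] = ("mild", "moderate", "severe", "total", "death")

#: Row sums must match 1 to this tolerance for a matrix to validate.
ROW_SUM_TOL = 1e-9

#: Largest row-sum deviation the optional repair mode will renormalise
#: away; matches the worst case of a matrix published at two decimals.
REPAIR_TOL = 0.005


class ValidationError(ValueError):
    """A matrix, distribution or partition violates a model invariant."""


@dataclass(frozen=True)
class StateSpace:
    """Ordered set of health-state labels with a designated absorbing subset.

    Parameters
    ----------
    labels
        Unique, non-empty state names in model order.
    absorbing
        Labels whose rows must be unit self-transitions (here: death).
    """

    labels: tuple[str, ...] = DEFAULT_LABELS
    absorbing: frozenset[str] = frozenset({"death"})

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "absorbing", frozenset(self.absorbing))
        if not labels:
            raise ValidationError("state space needs at least one label")
        if len(set(labels)) != len(labels):
            raise ValidationError(f"duplicate state labels in {labels}")
        missing = self.absorbing - set(labels)
        if missing:
            raise ValidationError(f"absorbing labels not in state space: {sorted(missing)}")

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise ValidationError(f"unknown state label {label!r}; states are {self.labels}") from None

    @property
    def absorbing_indices(self) -> tuple[int, ...]:
        return tuple(i for i, lab in enumerate(self.labels) if lab in self.absorbing)


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic annual transition probabilities over a state space.

    ``p[i, j]`` is the probability of moving from state ``i`` to state
    ``j`` over one annual cycle.  Construction validates all invariants;
    use :func:`validate_matrix` to re-check an instance explicitly.
    """

    states: StateSpace
    p: np.ndarray
    repair: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValidationError(f"transition grid must be square, got shape {p.shape}")
        if p.shape[0] != self.states.n:
            raise ValidationError(
                f"grid is {p.shape[0]}x{p.shape[0]} but state space has {self.states.n} labels"
            )
        if self.repair:
            p = _repair_rows(p, self.states)
        p = p.copy()
        # forgive sub-tolerance float overshoot from sums/averages
        tiny = ((p > 1) & (p <= 1 + ROW_SUM_TOL)) | ((p < 0) & (p >= -ROW_SUM_TOL))
        p[tiny] = np.clip(p[tiny], 0.0, 1.0)
        p.setflags(write=False)
        object.__setattr__(self, "p", p)
        _check_matrix(self)

    def row(self, label: str) -> np.ndarray:
        return self.p[self.states.index(label)]

    def prob(self, from_state: str, to_state: str) -> float:
        return float(self.p[self.states.index(from_state), self.states.index(to_state)])

    def with_row(self, label: str, new_row: Sequence[float]) -> "TransitionMatrix":
        """Return a copy with one source row replaced (re-validated)."""
        p = self.p.copy()
        p[self.states.index(label)] = np.asarray(new_row, dtype=float)
        return TransitionMatrix(self.states, p)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.p, index=list(self.states.labels), columns=list(self.states.labels))

    @classmethod
    def from_frame(cls, df: pd.DataFrame, states: StateSpace | None = None, repair: bool = False) -> "TransitionMatrix":
        """Build from a labelled DataFrame, reordering rows/columns to the
        state space's canonical order (labels are authoritative, never
        position)."""
        if states is None:
            states = StateSpace(tuple(df.index))
        order = list(states.labels)
        missing_rows = set(order) - set(df.index)
        missing_cols = set(order) - set(df.columns)
        if missing_rows or missing_cols:
            raise ValidationError(
                f"matrix is missing rows {sorted(missing_rows)} / columns {sorted(missing_cols)}"
            )
        return cls(states, df.loc[order, order].to_numpy(dtype=float), repair=repair)

    @classmethod
    def from_csv(cls, path, states: StateSpace | None = None, repair: bool = False) -> "TransitionMatrix":
        """Read a matrix from CSV: header row = to-state labels, first
        column = from-state labels."""
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.astype(str).str.strip()
        df.columns = df.columns.astype(str).str.strip()
        return cls.from_frame(df, states=states, repair=repair)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="from_state")


def _repair_rows(p: np.ndarray, states: StateSpace) -> np.ndarray:
    """Renormalise rows whose sums are off by at most REPAIR_TOL.

    Published matrices rounded to two decimals can miss 1 by up to 0.005
    per row; larger deviations are real errors and are left for
    validation to reject.
    """
    p = p.copy()
    sums = p.sum(axis=1)
    for i, s in enumerate(sums):
        dev = abs(s - 1.0)
        if ROW_SUM_TOL < dev <= REPAIR_TOL and s > 0:
            p[i] = p[i] / s
            logger.info("repaired row %r: sum %.6f renormalised to 1", states.labels[i], s)
    return p


def _check_matrix(m: TransitionMatrix) -> None:
    p, states = m.p, m.states
    bad = np.argwhere((p < 0) | (p > 1))
    if bad.size:
        i, j = bad[0]
        raise ValidationError(
            f"probability out of [0, 1]: p({states.labels[i]} -> {states.labels[j]}) = {p[i, j]}"
        )
    sums = p.sum(axis=1)
    off = np.where(np.abs(sums - 1.0) > ROW_SUM_TOL)[0]
    if off.size:
        i = off[0]
        raise ValidationError(f"row {states.labels[i]!r} sums to {sums[i]:.10f}, expected 1")
    for i in states.absorbing_indices:
        unit = np.zeros(states.n)
        unit[i] = 1.0
        if not np.array_equal(p[i], unit):
            raise ValidationError(
                f"absorbing state {states.labels[i]!r} must have a unit self-transition row, got {p[i].tolist()}"
            )


def validate_matrix(m: TransitionMatrix) -> TransitionMatrix:
    """Re-check every TransitionMatrix invariant; return ``m`` unchanged.

    Raises :class:`ValidationError` naming the offending row or entry.
    Construction already validates, so this exists for callers that
    mutate underlying arrays or load from untrusted sources.
    """
    _check_matrix(m)
    return m


@dataclass(frozen=True)
class ProfilePartition:
    """Mapping from fine disability profiles to coarse model states.

    ``mapping`` assigns every fine label to a non-absorbing coarse state.
    ``source_weights`` (optional, per fine label) weight fine rows when
    several profiles merge into one coarse source state; default is
    equal weighting within each group.
    """

    fine_labels: tuple[str, ...]
    mapping: Mapping[str, str]
    source_weights: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "fine_labels", tuple(self.fine_labels))
        unmapped = [f for f in self.fine_labels if f not in self.mapping]
        if unmapped:
            raise ValidationError(f"fine labels without a coarse assignment: {unmapped}")
        if self.source_weights is not None:
            neg = {k: w for k, w in self.source_weights.items() if w < 0}
            if neg:
                raise ValidationError(f"negative source weights: {neg}")

    def groups(self) -> dict[str, list[str]]:
        """Coarse label -> ordered fine labels assigned to it."""
        out: dict[str, list[str]] = {}
        for f in self.fine_labels:
            out.setdefault(self.mapping[f], []).append(f)
        return out


def aggregate_profiles(
    fine: TransitionMatrix,
    part: ProfilePartition,
    coarse_states: StateSpace | None = None,
) -> TransitionMatrix:
    """Collapse a fine-profile transition matrix into coarse model states.

    Destination probabilities are summed over each coarse group (the
    probability of reaching *any* profile in the group).  When a coarse
    source state contains several fine profiles, their rows are combined
    as a weighted average (``part.source_weights``, default equal), which
    preserves row-stochasticity.

    Parameters
    ----------
    fine
        Valid matrix over the fine profile space (ordering must match
        ``part.fine_labels``).
    part
        Total mapping of fine labels onto coarse non-absorbing states.
    coarse_states
        Target state space; defaults to one state per coarse group plus
        the fine space's absorbing states, in first-appearance order.
    """
    if tuple(fine.states.labels) != part.fine_labels:
        raise ValidationError(
            "partition fine labels do not match the fine matrix state space"
        )
    groups = part.groups()
    if coarse_states is None:
        coarse_labels = list(dict.fromkeys(part.mapping[f] for f in part.fine_labels))
        absorbing_fine = [lab for lab in fine.states.labels if lab in fine.states.absorbing]
        for lab in absorbing_fine:
            if lab in groups and groups[lab] != [lab]:
                raise ValidationError(f"absorbing state {lab!r} cannot merge with other profiles")
        coarse_states = StateSpace(tuple(coarse_labels), frozenset(fine.states.absorbing) & set(coarse_labels))

    n = coarse_states.n
    # column collapse: membership matrix fine -> coarse destinations
    col = np.zeros((fine.states.n, n))
    for j, lab in enumerate(coarse_states.labels):
        for f in groups.get(lab, []):
            col[fine.states.index(f), j] = 1.0
    collapsed = fine.p @ col  # destination sums per fine source row

    p = np.zeros((n, n))
    for i, lab in enumerate(coarse_states.labels):
        members = groups.get(lab, [])
        if not members:
            raise ValidationError(f"coarse state {lab!r} has no fine profiles assigned")
        if part.source_weights is None or all(f not in part.source_weights for f in members):
            # no weights given for this group: equal weighting
            w = np.ones(len(members))
        else:
            w = np.array([part.source_weights.get(f, 0.0) for f in members], dtype=float)
        if w.sum() <= 0:
            raise ValidationError(f"all-zero source weights within coarse group {lab!r}")
        w = w / w.sum()
        rows = np.stack([collapsed[fine.states.index(f)] for f in members])
        p[i] = w @ rows
    return TransitionMatrix(coarse_states, p)


@dataclass(frozen=True)
class RewardSet:
    """Per-state annual rewards: a QoL utility in [0, 1] and a societal
    cost in euro per year in state.  Death carries zero utility and cost."""

    states: StateSpace
    utility: np.ndarray
    annual_cost: np.ndarray

    def __post_init__(self) -> None:
        u = np.asarray(self.utility, dtype=float)
        c = np.asarray(self.annual_cost, dtype=float)
        if u.shape != (self.states.n,) or c.shape != (self.states.n,):
            raise ValidationError(
                f"rewards must have one value per state ({self.states.n}), got {u.shape} / {c.shape}"
            )
        if ((u < 0) | (u > 1)).any():
            raise ValidationError(f"utilities outside [0, 1]: {u.tolist()}")
        if (c < 0).any():
            raise ValidationError(f"negative annual costs: {c.tolist()}")
        for i in self.states.absorbing_indices:
            if u[i] != 0 or c[i] != 0:
                raise ValidationError(
                    f"absorbing state {self.states.labels[i]!r} must have zero utility and cost"
                )
        u.setflags(write=False)
        c.setflags(write=False)
        object.__setattr__(self, "utility", u)
        object.__setattr__(self, "annual_cost", c)

    @classmethod
    def from_mappings(
        cls,
        states: StateSpace,
        utility: Mapping[str, float],
        annual_cost: Mapping[str, float],
    ) -> "RewardSet":
        u = np.array([utility[lab] for lab in states.labels], dtype=float)
        c = np.array([annual_cost[lab] for lab in states.labels], dtype=float)
        return cls(states, u, c)


def as_distribution(x: Iterable[float] | Mapping[str, float], states: StateSpace) -> np.ndarray:
    """Coerce a sequence or label->mass mapping into a validated
    occupancy distribution over ``states`` (nonnegative, sums to 1)."""
    if isinstance(x, Mapping):
        unknown = set(x) - set(states.labels)
        if unknown:
            raise ValidationError(f"unknown states in distribution: {sorted(unknown)}")
        v = np.array([float(x.get(lab, 0.0)) for lab in states.labels])
    else:
        v = np.asarray(list(x), dtype=float)
    if v.shape != (states.n,):
        raise ValidationError(f"distribution has {v.shape[0]} entries, expected {states.n}")
    if (v < 0).any():
        raise ValidationError(f"negative occupancy in distribution: {v.tolist()}")
    if abs(v.sum() - 1.0) > ROW_SUM_TOL:
        raise ValidationError(f"distribution sums to {v.sum():.10f}, expected 1")
    return v
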