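"""Individual-level microsimulation and panel-based matrix estimation.

This module serves two roles:

1. a brute-force Monte Carlo oracle for the deterministic cohort engine
   (mean occupancies and mean discounted QALYs/costs converge to the
   cohort-model values by the law of large numbers), and
2. a generator of synthetic longitudinal panels of annual dependency
   states — the data structure of the ageing cohorts from which annual
   transition matrices are estimated in practice — so the count-based
   matrix estimator can be exercised in a parameter-recovery loop
   without any external data.

All randomness flows through a numpy Generator seeded explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import InterventionSpec, cycle_matrices
from .economics import DiscountSpec, EconResult
from .states import RewardSet, StateSpace, TransitionMatrix, ValidationError, as_distribution


@dataclass(frozen=True)
class IndividualPanel:
    """Annual state sequences for a simulated cohort.

    ``codes[i, t]`` is the state index of subject ``i`` after ``t``
    annual transitions (column 0 is the start state).  Death is
    absorbing: once entered, a subject stays.
    """

    states: StateSpace
    codes: np.ndarray  # int, shape (n_subjects, T + 1)
    seed: int | None = None

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes)
        if codes.ndim != 2 or codes.shape[1] < 2:
            raise ValidationError(f"panel must be (n_subjects, T+1) with T >= 1, got {codes.shape}")
        if codes.min() < 0 or codes.max() >= self.states.n:
            raise ValidationError("panel contains state codes outside the state space")
        for a in self.states.absorbing_indices:
            entered = codes == a
            # every entry after the first absorption must remain absorbed
            if (entered[:, :-1] & ~entered[:, 1:]).any():
                raise ValidationError(f"subjects leave absorbing state {self.states.labels[a]!r}")
        codes = codes.copy()
        codes.setflags(write=False)
        object.__setattr__(self, "codes", codes)

    @property
    def n_subjects(self) -> int:
        return self.codes.shape[0]

    @property
    def horizon_T(self) -> int:
        return self.codes.shape[1] - 1

    def occupancy(self, cycle: int) -> np.ndarray:
        """Empirical state distribution after ``cycle`` transitions."""
        return np.bincount(self.codes[:, cycle], minlength=self.states.n) / self.n_subjects

    def to_frame(self) -> pd.DataFrame:
        """Long format (subject, cycle, state), the standard layout for
        multi-state panel data."""
        n, w = self.codes.shape
        return pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), w),
                "cycle": np.tile(np.arange(w), n),
                "state": np.asarray(self.states.labels)[self.codes.ravel()],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, states: StateSpace) -> "IndividualPanel":
        wide = df.pivot(index="subject", columns="cycle", values="state").sort_index()
        wide = wide[sorted(wide.columns)]
        lut = {lab: i for i, lab in enumerate(states.labels)}
        try:
            codes = wide.map(lut.__getitem__).to_numpy(dtype=int)
        except KeyError as e:
            raise ValidationError(f"unknown state label in panel: {e.args[0]!r}") from None
        return cls(states, codes)

    @classmethod
    def from_csv(cls, path, states: StateSpace) -> "IndividualPanel":
        return cls.from_frame(pd.read_csv(path), states)


def _step(codes: np.ndarray, cum: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One annual transition for every subject, vectorised: draw a
    uniform per subject and invert the cumulative row of their state."""
    u = rng.random(codes.shape[0])
    return (u[:, None] > cum[codes]).sum(axis=1)


def simulate_individuals(
    m: TransitionMatrix,
    initial,
    n: int,
    T: int,
    seed: int | np.random.Generator,
    matrices_by_cycle: dict[int, TransitionMatrix] | None = None,
) -> IndividualPanel:
    """Simulate ``n`` subjects for ``T`` annual cycles.

    Start states are drawn from ``initial``; each annual step samples
    the subject's current matrix row.  ``matrices_by_cycle`` (1-based)
    overrides ``m`` for specific cycles, e.g. an intervention-modified
    first year.
    """
    if n < 1 or T < 1:
        raise ValidationError(f"need n >= 1 subjects and T >= 1 cycles, got n={n}, T={T}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p0 = as_distribution(initial, m.states)
    cums = {}

    def cum_for(t: int) -> np.ndarray:
        mt = matrices_by_cycle.get(t, m) if matrices_by_cycle else m
        key = id(mt)
        if key not in cums:
            cums[key] = np.cumsum(mt.p, axis=1)
        return cums[key]

    codes = np.empty((n, T + 1), dtype=np.int64)
    codes[:, 0] = (rng.random(n)[:, None] > np.cumsum(p0)[None, :]).sum(axis=1)
    for t in range(1, T + 1):
        codes[:, t] = _step(codes[:, t - 1], cum_for(t), rng)
    seed_val = None if isinstance(seed, np.random.Generator) else int(seed)
    return IndividualPanel(m.states, codes, seed=seed_val)


@dataclass(frozen=True)
class TransitionEstimate:
    """Count-based matrix estimate together with its provenance.

    ``undefined_rows`` names non-absorbing states never observed as a
    source; their rows carry a unit self-transition placeholder so the
    matrix validates, and the flag travels with the result instead of
    the gap being silently imputed.  ``counts`` holds the raw pooled
    transition counts.
    """

    matrix: TransitionMatrix
    undefined_rows: tuple[str, ...]
    counts: np.ndarray

    def require_complete(self) -> TransitionMatrix:
        """The estimated matrix, raising if any row was undefined."""
        if self.undefined_rows:
            raise ValidationError(
                f"no outgoing transitions observed from non-absorbing states "
                f"{list(self.undefined_rows)}; rows undefined"
            )
        return self.matrix


def estimate_transition_matrix(panel: IndividualPanel) -> TransitionEstimate:
    """Count-based row-normalised estimator of the annual transition
    matrix from a longitudinal panel.

    Entry (i, j) is the number of observed i -> j transitions divided
    by the total transitions out of i, pooled over subjects and cycles.
    Absorbing rows are forced to unit self-transitions.  Non-absorbing
    states never observed as a source are reported in
    ``TransitionEstimate.undefined_rows``; use
    :meth:`TransitionEstimate.require_complete` to insist on a fully
    identified matrix.
    """
    k = panel.states.n
    counts = np.zeros((k, k))
    src = panel.codes[:, :-1].ravel()
    dst = panel.codes[:, 1:].ravel()
    np.add.at(counts, (src, dst), 1)
    totals = counts.sum(axis=1)
    absorbing = set(panel.states.absorbing_indices)
    undefined = tuple(panel.states.labels[i] for i in range(k) if i not in absorbing and totals[i] == 0)
    p = np.zeros((k, k))
    for i in range(k):
        if i in absorbing or totals[i] == 0:
            p[i, i] = 1.0
        else:
            p[i] = counts[i] / totals[i]
    return TransitionEstimate(TransitionMatrix(panel.states, p), undefined, counts)


def microsim_cea(
    m: TransitionMatrix,
    rewards: RewardSet,
    discount: DiscountSpec,
    spec: InterventionSpec | None,
    initial,
    T: int,
    n: int,
    seed: int | np.random.Generator,
    strategy: str = "microsim",
) -> EconResult:
    """Monte Carlo estimate of the cohort pipeline's economic result.

    Simulates ``n`` individual trajectories (with the intervention
    modification in the cycles ``spec`` covers, and its per-person cost
    charged in cycle 1), accrues each subject's yearly utility and cost
    on the post-transition state, and averages the ledgers.  Matches
    the deterministic cohort EconResult in expectation.
    """
    matrices = cycle_matrices(m, spec, T) if spec is not None else None
    panel = simulate_individuals(m, initial, n, T, seed, matrices_by_cycle=matrices)
    q = np.empty(T)
    c = np.empty(T)
    ly = np.empty(T)
    dead = set(panel.states.absorbing_indices)
    alive_mask = ~np.isin(np.arange(panel.states.n), list(dead))
    for t in range(1, T + 1):
        occ = panel.occupancy(t)
        q[t - 1] = occ @ rewards.utility
        c[t - 1] = occ @ rewards.annual_cost
        ly[t - 1] = occ[alive_mask].sum()
    if spec is not None:
        c[0] += spec.per_person_cost
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
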