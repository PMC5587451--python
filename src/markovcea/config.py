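"""Run configuration: YAML schema, loading, validation and defaults.

A run config bundles everything one evaluation needs: the state space,
the annual transition matrix (inline, label-keyed, or a CSV path), the
per-state rewards, discounting, horizon, initial distribution, the
intervention and the sensitivity scenarios.  All matrices and
distributions are keyed by state label, never by position, so a config
written in a permuted state order loads to identical results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .cohort import InterventionSpec
from .economics import DiscountSpec
from .scenarios import ScenarioSpec
from .states import RewardSet, StateSpace, TransitionMatrix, ValidationError, as_distribution


class ConfigError(ValidationError):
    """A config file violates the schema; the message carries the field path."""


@dataclass(frozen=True)
class RunConfig:
    states: StateSpace
    matrix: TransitionMatrix
    rewards: RewardSet
    discount: DiscountSpec
    horizon: int
    initial: np.ndarray
    intervention: InterventionSpec
    scenarios: tuple[ScenarioSpec, ...]
    seed: int = 0

    def to_dict(self) -> dict:
        """Plain-data echo of every input, for run logs."""
        return {
            "states": {"labels": list(self.states.labels), "absorbing": sorted(self.states.absorbing)},
            "transition_matrix": {
                f: {t: float(self.matrix.prob(f, t)) for t in self.states.labels}
                for f in self.states.labels
            },
            "rewards": {
                "utility": {lab: float(u) for lab, u in zip(self.states.labels, self.rewards.utility)},
                "annual_cost": {lab: float(c) for lab, c in zip(self.states.labels, self.rewards.annual_cost)},
            },
            "discount": {"rate": self.discount.rate, "convention": self.discount.convention},
            "horizon": self.horizon,
            "initial": {lab: float(v) for lab, v in zip(self.states.labels, self.initial) if v > 0},
            "intervention": {
                "from_state": self.intervention.from_state,
                "to_state": self.intervention.to_state,
                "effect_multiplier": self.intervention.effect_multiplier,
                "donor": self.intervention.donor_state,
                "cycles_applied": sorted(self.intervention.cycles_applied),
                "per_person_cost": self.intervention.per_person_cost,
            },
            "scenarios": [
                {k: v for k, v in
                 {"name": s.name, "effect_multiplier": s.effect_multiplier,
                  "per_person_cost": s.per_person_cost}.items() if v is not None}
                for s in self.scenarios
            ],
            "seed": self.seed,
        }


def _require(d: dict, key: str, path: str):
    if key not in d:
        raise ConfigError(f"missing required field {path}.{key}" if path else f"missing required field {key}")
    return d[key]


def _matrix_from_mapping(raw: dict, states: StateSpace, repair: bool) -> TransitionMatrix:
    p = np.zeros((states.n, states.n))
    for f, row in raw.items():
        if f not in states.labels:
            raise ConfigError(f"transition_matrix: unknown from-state {f!r}")
        if not isinstance(row, dict):
            raise ConfigError(f"transition_matrix.{f}: expected a to-state -> probability mapping")
        for t, v in row.items():
            if t not in states.labels:
                raise ConfigError(f"transition_matrix.{f}: unknown to-state {t!r}")
            p[states.index(f), states.index(t)] = float(v)
    missing = set(states.labels) - set(raw)
    if missing:
        raise ConfigError(f"transition_matrix: missing rows for states {sorted(missing)}")
    return TransitionMatrix(states, p, repair=repair)


def load_config(path: str | Path | dict, base_dir: Path | None = None) -> RunConfig:
    """Load and fully validate a run config from a YAML file (or an
    already-parsed dict).  Defaults: horizon 8, all-severe start,
    3% from-first-cycle discounting, no scenarios, seed 0.
    """
    if isinstance(path, dict):
        raw = path
        base_dir = base_dir or Path(".")
    else:
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text())
        base_dir = base_dir or path.parent
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")

    st = raw.get("states", {})
    labels = tuple(st.get("labels", ("mild", "moderate", "severe", "total", "death")))
    absorbing = frozenset(st.get("absorbing", ("death",)))
    states = StateSpace(labels, absorbing)
    repair = bool(raw.get("repair_rows", False))

    if "transition_matrix" in raw:
        matrix = _matrix_from_mapping(_require(raw, "transition_matrix", ""), states, repair)
    elif "transition_matrix_csv" in raw:
        csv_path = base_dir / raw["transition_matrix_csv"]
        if not csv_path.exists():
            raise ConfigError(f"transition_matrix_csv: file not found: {csv_path}")
        matrix = TransitionMatrix.from_csv(csv_path, states=states, repair=repair)
    else:
        raise ConfigError("missing required field transition_matrix (or transition_matrix_csv)")

    rw = _require(raw, "rewards", "")
    try:
        rewards = RewardSet.from_mappings(states, _require(rw, "utility", "rewards"), _require(rw, "annual_cost", "rewards"))
    except KeyError as e:
        raise ConfigError(f"rewards: no value for state {e.args[0]!r}") from None

    dr = raw.get("discount", {})
    discount = DiscountSpec(rate=float(dr.get("rate", 0.03)), convention=dr.get("convention", "from-first-cycle"))

    horizon = int(raw.get("horizon", 8))
    if horizon < 1:
        raise ConfigError(f"horizon must be >= 1, got {horizon}")

    initial = as_distribution(raw.get("initial", {"severe": 1.0}), states)

    iv = raw.get("intervention", {})
    intervention = InterventionSpec(
        from_state=iv.get("from_state", "severe"),
        to_state=iv.get("to_state", "moderate"),
        effect_multiplier=float(iv.get("effect_multiplier", 1.4)),
        donor=iv.get("donor"),
        cycles_applied=frozenset(iv.get("cycles_applied", [1])),
        per_person_cost=float(iv.get("per_person_cost", 128.0)),
    )
    for lab, where in ((intervention.from_state, "from_state"), (intervention.to_state, "to_state"), (intervention.donor_state, "donor")):
        if lab not in states.labels:
            raise ConfigError(f"intervention.{where}: unknown state {lab!r}")

    scen = []
    for i, s in enumerate(raw.get("scenarios", [])):
        if "name" not in s:
            raise ConfigError(f"scenarios[{i}]: missing required field name")
        scen.append(
            ScenarioSpec(
                name=s["name"],
                effect_multiplier=s.get("effect_multiplier"),
                per_person_cost=s.get("per_person_cost"),
            )
        )

    return RunConfig(
        states=states,
        matrix=matrix,
        rewards=rewards,
        discount=discount,
        horizon=horizon,
        initial=initial,
        intervention=intervention,
        scenarios=tuple(scen),
        seed=int(raw.get("seed", 0)),
    )


def example_config_path(name: str = "bathing_disability") -> Path:
    """Path to a shipped example config (the published model inputs)."""
    p = resources.files("markovcea").joinpath("data", f"{name}.yaml")
    with resources.as_file(p) as fp:
        return Path(fp)


def load_example(name: str = "bathing_disability") -> RunConfig:
    return load_config(example_config_path(name))
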