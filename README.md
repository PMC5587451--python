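# markovcea

Markov cohort cost-effectiveness modelling of dependency in older
adults, built for health economists and rehabilitation researchers who
want a tested, scriptable alternative to spreadsheet decision models.

The core is a five-state annual-cycle Markov cohort model of
dependency — mild, moderate, severe and total dependency in activities
of daily living, plus absorbing death. A unit cohort `s_0` (all in
severe dependency, the state representing bathing disability) is
propagated through the row-stochastic annual matrix `P`:

    s_t = s_{t-1} P_t ,    t = 1..T  (T = 8 years)

Each state carries a QoL utility `u` and an annual societal cost `c`;
cycle-t accruals `s_t·u` and `s_t·c` are discounted by `(1+r)^-t`
(r = 3%) and summed into QALYs and costs per strategy. A reablement
intervention is modelled as a one-off relative increase (×1.4) of the
severe → moderate recovery probability in year 1, the added mass taken
from the severe → severe diagonal, plus a 128 € per-person cost.
Strategies are compared incrementally (ΔQALY, ΔCost, dominance or
ICER against willingness-to-pay bands), with deterministic sensitivity
scenarios, an individual-level microsimulation oracle, and a
count-based estimator that recovers transition matrices from
longitudinal panels. See `docs/methods.md` for the full model account.

## Worked example

```python
from markovcea import load_example, run_arms

cfg = load_example("bathing_disability")   # shipped published inputs
control, intervention, cmp = run_arms(
    cfg.matrix, cfg.rewards, cfg.discount, cfg.intervention, cfg.initial, cfg.horizon
)
```

Running `python examples/main_analysis.py` prints:

```
control:      2.211 QALYs,   101,870 EUR
intervention: 2.263 QALYs,    99,282 EUR
incremental:  +0.052 QALYs, -2,588 EUR
verdict: intervention dominates
```

Over 8 years the intervention gains 0.052 discounted QALYs per person
(about 19 days in full health) while saving roughly 2,600 € of
societal cost — it dominates no intervention, so no cost-per-QALY
ratio is needed. QALY figures reproduce the published evaluation to
the printed precision; cost totals land about 7% above the published
figures because the published transition matrix is rounded to two
decimals (see `docs/methods.md`).

Further scripts in `examples/` cover sensitivity scenarios, the
microsimulation cross-check, matrix estimation from synthetic panels,
and fine-profile aggregation. The same pipelines are available from
the shell:

```sh
markovcea run --config bathing_disability --out-dir out
markovcea scenarios --config bathing_disability --out-dir out
markovcea microsim --config bathing_disability --n 100000 --seed 1 --out-dir out
markovcea estimate --panel out/panel.csv --config bathing_disability --out-dir out
```

Each command writes CSV artifacts (trace, ledger, comparison/scenario
table, panel) and a `run_log.json` capturing every input and
convention, so runs are reproducible byte-for-byte from config + seed.

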