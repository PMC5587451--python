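"""Run the main cost-effectiveness analysis from the shipped inputs.

Both arms of the five-state dependency model are propagated for 8
years from an all-severe start; QALYs and societal costs are accrued
with 3% discounting and compared incrementally.
"""

from markovcea import load_example, run_arms

cfg = load_example("bathing_disability")
control, intervention, cmp = run_arms(
    cfg.matrix, cfg.rewards, cfg.discount, cfg.intervention, cfg.initial, cfg.horizon
)

print(f"control:      {control.total_qaly:.3f} QALYs, {control.total_cost:>9,.0f} EUR")
print(f"intervention: {intervention.total_qaly:.3f} QALYs, {intervention.total_cost:>9,.0f} EUR")
print(f"incremental:  {cmp.delta_qaly:+.3f} QALYs, {cmp.delta_cost:+,.0f} EUR")
print(f"verdict: {cmp.verdict}")
# Positive QALY gain with negative incremental cost means the
# intervention both improves quality-adjusted survival and saves money:
# no ICER is needed, the intervention dominates.
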