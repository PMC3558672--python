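"""Simulate one fly under the curated defaults and show its life in eggs.

The simulator couples a daily energy budget, a yolk-protein pipeline and a
bank of ovarioles with random maturation times; the output is the day-by-day
egg count from hatching to death.
"""

from ovisim import default_config, simulate_fly

config = default_config(seed=1)
pattern, trajectory = simulate_fly(config)

print(f"life span: {pattern.life_span} days")
print(f"total eggs: {pattern.total_eggs}")
print(f"death cause (ledger): {pattern.death_cause_raw}")
print(f"first 10 days of laying: {pattern.daily_eggs[:10]}")
onset = trajectory.loc[trajectory["senescence_onset_flag"] == 1, "day"]
print(f"senescence onset (first energy-deficit day): day {int(onset.iloc[0])}")
# The counts ramp up as the first portions mature, sit on a noisy plateau
# near RC = min(L/2, a) = 50 eggs/day, then collapse once expenditure
# outruns intake and the processing capacity ages away.
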