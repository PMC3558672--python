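"""Fit the five-parameter three-stage skeleton to a simulated pattern.

The skeleton - zero before the first egg at t0, plateau RC up to day T, then
an exponential tail with time constant tau until death at LS - separates the
slow, age-driven shape of a pattern from its day-to-day scatter.
"""

from ovisim import classify_phenotype, default_config, fit_three_stage, simulate_fly

pattern, _ = simulate_fly(default_config(seed=1))
fit = fit_three_stage(pattern)
p = fit.params

print(f"t0  = {p.t0:3d} days   (first egg)")
print(f"T   = {p.T:3d} days   (end of plateau)")
print(f"RC  = {p.RC:5.1f} eggs/day (plateau rate)")
print(f"tau = {p.tau:5.1f} days   (tail time constant)")
print(f"LS  = {p.LS:3d} days   (life span)")
print(f"rss = {fit.rss:.1f} eggs^2 (residual; the day-to-day 'teeth')")

call = classify_phenotype(pattern, fit)
print(f"phenotype: {call.label} (death by {call.death_cause}); "
      f"reproduction complete at day {call.evidence['reproduction_end']:.1f}")
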