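"""Why directionless records are imputed as r = 0 instead of dropped.

Studies often report a nonsignificant correlation without its sign.  Dropping
those records keeps only significant (mostly large, mostly negative) effects
and biases the pooled mean away from zero; entering them as r = 0 keeps the
evidence they carry.  Here every nonsignificant effect is censored to make
the contrast stark.
"""

import ornameta as om

params = om.SimParams(n_species=40, censor_prob=1.0, seed=2)
dataset, truth = om.simulate_dataset(params)
report = om.censor_report(dataset, truth)

print(f"k = {report.n_total}, censored (directionless) = {report.n_censored}")
print(f"true grand mean (z scale)        = {params.beta0:+.3f}")
print(f"weighted mean, censored dropped  = {report.naive_mean:+.3f}")
print(f"weighted mean, imputed as r = 0  = {report.imputed_mean:+.3f}")
# The dropped version overshoots the true mean; the imputed version sits
# closer to it (slightly attenuated toward zero, the known cost of the rule).
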