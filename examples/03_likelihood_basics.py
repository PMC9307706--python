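"""Wiener first-passage likelihood: densities, absorption, outlier mixture.

Shows the closed-form absorption probability, density normalization over
both boundaries, and how the 5% uniform contaminant mixture floors the
trial log likelihood.
"""

import numpy as np

import motorddm as m

v, a, z = 2.57, 1.78, 0.5
print(f"P(correct | v={v}, a={a}, z={z}) = "
      f"{m.choice_probability(v, a, z):.4f}")

params = m.DDMParameters(v=v, a=a, ter=0.58, z=z, sv=0.5, st=0.15, sz=0.1)
t = np.concatenate([np.linspace(params.ter - params.st / 2, 3, 40_000),
                    np.linspace(3.0001, 30, 10_000)])
total = np.trapezoid(m.full_density(t, "upper", params)
                     + m.full_density(t, "lower", params), t)
print(f"density mass over both boundaries: {total:.6f} (should be 1)")

trial = m.TrialRecord("s01", 1, 1, m.Condition(3, "soft"), match=True,
                      response="match", rt=0.9)
for p_out in (0.0, 0.05):
    ll = m.trial_loglik(trial, params, p_outlier=p_out)
    print(f"log lik of a 0.9 s correct response, p_outlier={p_out}: {ll:.4f}")
# With p_outlier > 0 the mixture bounds every trial's likelihood away from
# zero: implausible response times cost, but can never veto the fit.
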