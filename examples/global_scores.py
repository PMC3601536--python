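"""Estimate global network integration by five methods.

Simulates a 30-agency network whose perceived rating matches its expected
rating with probability 0.6 in every cell, then summarises the P1 global
score by the plain mean, the inverse-variance weighted mean, and the
standard / balanced / Bayesian bootstrap (B = 10,000 replicates here; the
published setting of 40,000 changes the third decimal at most).
"""

from netagree import SyntheticConfig, generate, global_table, globals_frame

pair = generate(SyntheticConfig(n_agencies=30, agreement_prob=0.6, seed=42))
estimates = global_table(pair, perspectives=("P1",), B=10_000, seed=42)

print(globals_frame(estimates).to_string(index=False))
print(
    "\nAll five estimates sit near the generative agreement level of 60%.\n"
    "The weighted method uses a binomial within-agency variance model, so\n"
    "its interval can be wider or narrower than the others; the bootstrap\n"
    "intervals (BCa or credible) adjust for bias and skew of the scores."
)
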