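"""Calibration and power of the test on synthetic data.

Generates features from the model's own generative chain (u ~ Beta, counts
conditionally binomial given a pair total of 100): a null batch with
alpha = beta = 8 (no effect, realistic between-pair spread) and an effect
batch with alpha/beta = 3, then reports rejection rates at the 0.05 cutoff
and the recovered fold change at a large sample size.
"""

import numpy as np

from ibbpair import SimulationConfig, fit_full, ibb_test, simulate_ibb_dataset

N_FEATURES = 300  # modest batch so the example runs in a few seconds

null_cfg = SimulationConfig(alpha=8, beta=8, n_pairs=5, n_features=N_FEATURES, seed=1)
p_null = np.array([ibb_test(ps).p_value for ps in simulate_ibb_dataset(null_cfg, 100)])

effect_cfg = SimulationConfig(alpha=24, beta=8, n_pairs=5, n_features=N_FEATURES, seed=2)
p_eff = np.array([ibb_test(ps).p_value for ps in simulate_ibb_dataset(effect_cfg, 100)])

print(f"null (alpha=beta=8, N=5):     rejection rate at 0.05 = {(p_null < 0.05).mean():.3f}")
print(f"effect (alpha/beta=3, N=5):   rejection rate at 0.05 = {(p_eff < 0.05).mean():.3f}")

recovery_cfg = SimulationConfig(alpha=12, beta=4, n_pairs=400, n_features=1, seed=7)
fit = fit_full(simulate_ibb_dataset(recovery_cfg, 200)[0])
print(f"recovered fold change at N=400 (true 3.0): {fit.alpha / fit.beta:.3f}")
print()
print("With only N=5 pairs the chi-square reference is somewhat anti-")
print("conservative (null rate above 0.05); the effect batch rejects far more")
print("often, and the common fold change is recovered accurately at large N.")
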