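"""Landing-level bycatch estimation and the eDNA-vs-bucket precision contest.

Simulates a six-tank, 1200 t landing with heterogeneous herring bycatch,
estimates the herring tonnage from triplicate factory-water eDNA samples,
compares it with a 15-bucket visual estimate, and runs the Monte-Carlo
precision experiment showing why well-mixed production water beats sparse
subsampling.
"""

import numpy as np
from scipy.special import expit, logit

from ednabycatch import (
    GeneratorConfig,
    LandingDataset,
    bucket_estimate,
    compare_methods,
    estimate_landing,
    fit_beta_glm,
    generate_calibration_design,
    precision_experiment,
    simulate_landing,
)

rng = np.random.default_rng(4242)

# calibrate on a simulated March factory-water experiment
config = GeneratorConfig(seed=31, alpha=0.1, beta=1.0, phi=50.0,
                         season_label="March", water_type="factory")
model = fit_beta_glm(generate_calibration_design(config))

# a landing whose tanks hold very different bycatch levels
law = lambda r, n: np.clip(r.normal(0.25, 0.15, n), 0.02, 0.98)
landing = simulate_landing(6, [200.0] * 6, law, seed=77)
truth = landing.true_fraction
print(f"six-tank landing, 1200 t; true herring fraction {truth:.3f} "
      f"({truth * 1200:.0f} t)")

# factory water is well mixed: every sample sees the landing-level fraction
mu = expit(model.alpha + model.beta_slope * logit(truth))
factory = {f"interval{i}": tuple(rng.beta(mu * 50.0, (1 - mu) * 50.0, 3)) for i in range(8)}
dataset = LandingDataset(landing_id="sim", total_landed_weight=1200.0,
                         factory_samples=factory)
edna = estimate_landing(dataset, model, "factory")
print(f"eDNA estimate:   {edna.bycatch_tonnes:6.1f} t  (se {edna.se_tonnes:5.1f} t, "
      f"{edna.n} samples x 3 replicates)")

# the bucket method samples whole fish from whichever tank the bucket hits
buckets = [float(landing.tanks[rng.integers(6)][2]) for _ in range(15)]
visual = bucket_estimate(buckets, 1200.0, landing_id="sim")
print(f"bucket estimate: {visual.bycatch_tonnes:6.1f} t  (se {visual.se_tonnes:5.1f} t, "
      f"{visual.n} buckets)")

print("\npairwise method differences (t):")
print(compare_methods([edna, visual]).to_string(index=False))

out = precision_experiment(
    lambda r: simulate_landing(6, [200.0] * 6, law, seed=int(r.integers(2**31))),
    edna_config={"n_samples": 8, "n_replicates": 3, "phi": 200.0},
    bucket_config={"n_buckets": 15},
    n_trials=200,
    seed=5,
)
print(f"\nMonte-Carlo over {out['n_trials']} landings: eDNA reported SE lower than "
      f"bucket SE in {out['edna_se_lower_share']:.0%} of trials "
      f"(mean SE {out['edna_mean_reported_se']:.4f} vs {out['bucket_mean_reported_se']:.4f} "
      "on the fraction scale)")
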