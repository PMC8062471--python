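"""Model comparison across a small cohort of simulated subjects.

Draws 12 agents from the s1w fitting priors, fits all eight models to
each, and builds the mean-evidence comparison table (complete cases only).
"""

import numpy as np

from stressrl import AgentParams, TaskConfig, compare_models, fit_subject, simulate_agent
from stressrl.fit import fits_to_frame
from stressrl.models import MODEL_NAMES
from stressrl.priors import get_priors

priors = get_priors()
rng = np.random.default_rng(5)
fits = []
for i in range(12):
    truth = AgentParams(
        "s1w",
        alpha=float(priors["alpha"].sample(rng)),
        gamma=float(priors["gamma"].sample(rng)),
        beta=float(priors["beta"].sample(rng)),
    )
    trials = simulate_agent(truth, TaskConfig(), rng=rng)
    for model in MODEL_NAMES:
        fits.append(
            fit_subject(model, trials, n_restarts=30,
                        seed=int(rng.integers(2**31)), subject_id=f"s{i:02d}")
        )

table = compare_models(fits_to_frame(fits), max_missing_fraction=0.25)
print(table.to_string(index=False))
print("\nEvery subject was generated from s1w; with enough subjects the")
print("winner row should name s1w, with the simpler nested s1 close behind")
print("and the dynamic (Pearce-Hall) models clearly worse.")
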