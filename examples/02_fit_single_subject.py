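"""Fit all eight learning models to one simulated subject.

Simulates a subject from the s1w model (one learning rate plus a
probability-weighting slope), then estimates every model's parameters by
multi-start MAP and scores each with its Laplace log evidence.
"""

from stressrl import AgentParams, TaskConfig, fit_subject, simulate_agent
from stressrl.models import MODEL_NAMES, MODEL_FREE_PARAMS

truth = AgentParams("s1w", alpha=0.12, gamma=1.8, beta=0.12)
trials = simulate_agent(truth, TaskConfig(), seed=3)
print(f"generating model s1w with alpha={truth.alpha}, gamma={truth.gamma}, "
      f"beta={truth.beta}\n")

print(f"{'model':5} {'parameters':28} {'log post':>9} {'log evidence':>13}")
for model in MODEL_NAMES:
    fit = fit_subject(model, trials, n_restarts=50, seed=7)
    params = ", ".join(
        f"{name}={getattr(fit.params, name):.3f}"
        for name in MODEL_FREE_PARAMS[model]
    )
    evidence = f"{fit.log_evidence:13.3f}" if fit.log_evidence is not None else "      missing"
    print(f"{model:5} {params:28} {fit.log_post:9.3f} {evidence}")

print("\nHigher (less negative) log evidence is better; the Laplace")
print("approximation automatically penalizes extra free parameters, so a")
print("more flexible model only wins if its fit improvement earns it.")
print("A 'missing' evidence marks a fit whose optimum sat on a parameter")
print("bound, where the Gaussian approximation is undefined.")
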