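"""Simulate the two-option probabilistic reward task for one agent.

Builds a 60-trial session (three blocks of 20 with a re-randomized
0.75/0.25 contingency and complementary point magnitudes), lets a
Rescorla-Wagner agent with probability weighting play it, and prints the
first trials plus session summaries.
"""

import numpy as np

from stressrl import AgentParams, TaskConfig, simulate_agent
from stressrl.analysis import score_correct_choices

config = TaskConfig(rng_seed=1)
agent = AgentParams("s1w", alpha=0.15, gamma=1.3, beta=0.1)
trials = simulate_agent(agent, config, seed=42)

print("trial block high  mag_A mag_B chosen rewarded points")
for t in trials[:8]:
    print(
        f"{t.trial_index:5d} {t.block_index:5d} {t.high_prob_option:>4} "
        f"{t.magnitude_A:5d} {t.magnitude_B:5d} {t.chosen:>6} "
        f"{t.rewarded:>8} {t.points_earned:6d}"
    )

total = sum(t.points_earned for t in trials)
perf = score_correct_choices(trials, config)
print(f"\ntotal points earned: {total}")
print(f"proportion of higher-expected-value choices: "
      f"{perf.prop_correct_overall:.3f} over {perf.n_scored} scorable trials")
print("per-block:", {b: round(p, 3) for b, p in perf.prop_correct_block.items()})
print("\nA 'correct' choice picks the option whose true reward probability")
print("times displayed magnitude is larger; an agent guessing at random")
print("would sit near 0.5, a perfect expected-value maximizer at 1.0.")
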