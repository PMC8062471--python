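"""Independent reference implementations used only as test oracles.

Deliberately naive and structured differently from the package code: state
is kept per option in a dict, every formula is written out longhand, and no
package internals are reused beyond the data classes.
"""

from __future__ import annotations

import math


def naive_log_likelihood(params, trials, reset_at_block=True, s0=1.0):
    """Trial-by-trial log-likelihood of a completed trial log.

    Mirrors the model definitions from first principles: learned
    probabilities start at 0.5 (re-initialized each block), expected value
    is magnitude times (optionally gamma-weighted) probability, choices are
    sigmoidal in the value difference, and the chosen option's probability
    is updated from its reward indicator.
    """
    name = params.model_name
    weighted = name.endswith("w")
    base = name[:2]
    n_total = len(trials)
    p = {"A": 0.5, "B": 0.5}
    assoc = s0
    total = 0.0
    block = trials[0].block_index
    for rec in trials:
        if reset_at_block and rec.block_index != block:
            block = rec.block_index
            p = {"A": 0.5, "B": 0.5}
            assoc = s0

        def weight(x):
            if not weighted:
                return x
            y = params.gamma * (x - 0.5) + 0.5
            return min(max(y, 0.0), 1.0)

        q = {
            "A": rec.magnitude_A * weight(p["A"]),
            "B": rec.magnitude_B * weight(p["B"]),
        }
        z = -params.beta * (q["A"] - q["B"])
        if z > 700:
            p_choose_a = 0.0
        elif z < -700:
            p_choose_a = 1.0
        else:
            p_choose_a = 1.0 / (1.0 + math.exp(z))
        if not rec.response_made or rec.chosen is None:
            continue
        prob = p_choose_a if rec.chosen == "A" else 1.0 - p_choose_a
        total += math.log(prob) if prob > 0 else -math.inf

        r = 1.0 if rec.chosen == rec.rewarded else 0.0
        delta = r - p[rec.chosen]
        if base == "s1":
            rate = params.alpha
        elif base == "s2":
            if delta > 0:
                rate = params.alpha_pos
            elif delta < 0:
                rate = params.alpha_neg
            else:
                rate = params.alpha_pos
        elif base == "d2":
            half = n_total / 2.0
            rate = params.alpha1 if rec.trial_index <= half else params.alpha2
        else:  # d1
            assoc = (1.0 - params.mu) * assoc + params.mu * abs(delta)
            rate = min(params.kappa * assoc, 1.0)
        p[rec.chosen] = p[rec.chosen] + rate * delta
        other = "B" if rec.chosen == "A" else "A"
        p[other] = 1.0 - p[rec.chosen]
    return total


def naive_correct_proportion(trials, p_high=0.75):
    """Brute-force proportion of higher-true-expected-value choices."""
    n_correct = 0
    n_scored = 0
    for rec in trials:
        if not rec.response_made or rec.chosen is None:
            continue
        ev = {}
        for opt, mag in (("A", rec.magnitude_A), ("B", rec.magnitude_B)):
            prob = p_high if rec.high_prob_option == opt else 1.0 - p_high
            ev[opt] = prob * mag
        if ev["A"] == ev["B"]:
            continue
        n_scored += 1
        best = "A" if ev["A"] > ev["B"] else "B"
        if rec.chosen == best:
            n_correct += 1
    return (n_correct / n_scored) if n_scored else float("nan")
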