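"""Compiled likelihood kernel used by the fitting routines.

The model stepping here mirrors :mod:`stressrl.models` exactly; a test pins
the two paths against each other. Keeping the kernel free of Python objects
lets a multi-start simplex search evaluate the 60-trial likelihood in a few
microseconds.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

BASE_S1, BASE_S2, BASE_D1, BASE_D2 = 0, 1, 2, 3

_BASE_CODE = {"s1": BASE_S1, "s2": BASE_S2, "d1": BASE_D1, "d2": BASE_D2}


def encode(params) -> tuple[int, bool, float, float, float, float]:
    """Flatten an AgentParams into the kernel's (base, weighted, a1, a2,
    gamma, beta) layout. a1/a2 hold (alpha, -), (alpha+, alpha-), (mu,
    kappa) or (alpha1, alpha2) depending on the base model."""
    name = params.model_name
    base = _BASE_CODE[name.rstrip("w")]
    weighted = name.endswith("w")
    if base == BASE_S1:
        a1, a2 = params.alpha, 0.0
    elif base == BASE_S2:
        a1, a2 = params.alpha_pos, params.alpha_neg
    elif base == BASE_D1:
        a1, a2 = params.mu, params.kappa
    else:
        a1, a2 = params.alpha1, params.alpha2
    gamma = params.gamma if weighted else 1.0
    return base, weighted, float(a1), float(a2), gamma, float(params.beta)


@njit(cache=False)
def loglik(
    base,
    weighted,
    a1,
    a2,
    gamma,
    beta,
    chosen,
    reward,
    responded,
    mag_a,
    mag_b,
    block,
    tidx,
    n_trials,
    reset_at_block,
    s0,
    associability_first,
):
    p_a = 0.5
    S = s0
    ll = 0.0
    current_block = block[0]
    half = n_trials / 2.0
    for i in range(chosen.shape[0]):
        if reset_at_block and block[i] != current_block:
            current_block = block[i]
            p_a = 0.5
            S = s0
        if weighted:
            fa = gamma * (p_a - 0.5) + 0.5
            if fa < 0.0:
                fa = 0.0
            elif fa > 1.0:
                fa = 1.0
        else:
            fa = p_a
        q_a = mag_a[i] * fa
        q_b = mag_b[i] * (1.0 - fa)
        x = beta * (q_a - q_b)
        if x >= 0.0:
            pc_a = 1.0 / (1.0 + math.exp(-x))
        else:
            e = math.exp(x)
            pc_a = e / (1.0 + e)
        if not responded[i]:
            continue
        c = chosen[i]
        p_obs = pc_a if c == 0 else 1.0 - pc_a
        if p_obs <= 0.0:
            return -np.inf
        ll += math.log(p_obs)
        p_c = p_a if c == 0 else 1.0 - p_a
        delta = reward[i] - p_c
        if base == BASE_S1:
            alpha = a1
        elif base == BASE_S2:
            alpha = a1 if delta > 0.0 else (a2 if delta < 0.0 else a1)
        elif base == BASE_D2:
            alpha = a1 if tidx[i] <= half else a2
        else:
            if associability_first:
                S = (1.0 - a1) * S + a1 * abs(delta)
                alpha = a2 * S
            else:
                alpha = a2 * S
            if alpha > 1.0:
                alpha = 1.0
            if not associability_first:
                S = (1.0 - a1) * S + a1 * abs(delta)
        p_c = p_c + alpha * delta
        p_a = p_c if c == 0 else 1.0 - p_c
    return ll


@njit(cache=False)
def loglik_many(
    base,
    weighted,
    thetas,  # (n, 4) columns a1, a2, gamma, beta
    chosen,
    reward,
    responded,
    mag_a,
    mag_b,
    block,
    tidx,
    n_trials,
    reset_at_block,
    s0,
    associability_first,
):
    """Batch evaluation over many parameter vectors (grid-search support)."""
    out = np.empty(thetas.shape[0])
    for j in range(thetas.shape[0]):
        out[j] = loglik(
            base,
            weighted,
            thetas[j, 0],
            thetas[j, 1],
            thetas[j, 2],
            thetas[j, 3],
            chosen,
            reward,
            responded,
            mag_a,
            mag_b,
            block,
            tidx,
            n_trials,
            reset_at_block,
            s0,
            associability_first,
        )
    return out


# ---------------------------------------------------------------------------
# Compiled posterior objective and multi-start Nelder-Mead
# ---------------------------------------------------------------------------

FAM_BETA, FAM_GAMMA = 0, 1


@njit(cache=False)
def _prior_logpdf(fam, p1, p2, x):
    if fam == FAM_BETA:
        if x <= 0.0 or x >= 1.0:
            return -np.inf
        log_b = math.lgamma(p1) + math.lgamma(p2) - math.lgamma(p1 + p2)
        return (p1 - 1.0) * math.log(x) + (p2 - 1.0) * math.log1p(-x) - log_b
    if x <= 0.0:
        return -np.inf
    return (p1 - 1.0) * math.log(x) - x / p2 - math.lgamma(p1) - p1 * math.log(p2)


@njit(cache=False)
def neg_log_post(
    theta,
    base,
    weighted,
    fam,
    p1,
    p2,
    chosen,
    reward,
    responded,
    mag_a,
    mag_b,
    block,
    tidx,
    n_trials,
    reset_at_block,
    s0,
    associability_first,
):
    k = theta.shape[0]
    lp = 0.0
    for i in range(k):
        lp += _prior_logpdf(fam[i], p1[i], p2[i], theta[i])
        if lp == -np.inf:
            return np.inf
    a1 = theta[0]
    a2 = theta[1] if base != BASE_S1 else 0.0
    gamma = theta[k - 2] if weighted else 1.0
    beta = theta[k - 1]
    ll = loglik(
        base, weighted, a1, a2, gamma, beta,
        chosen, reward, responded, mag_a, mag_b, block, tidx,
        n_trials, reset_at_block, s0, associability_first,
    )
    return -(ll + lp)


@njit(cache=False)
def nelder_mead(
    x0,
    base,
    weighted,
    fam,
    p1,
    p2,
    chosen,
    reward,
    responded,
    mag_a,
    mag_b,
    block,
    tidx,
    n_trials,
    reset_at_block,
    s0,
    associability_first,
    xatol,
    fatol,
    maxiter,
):
    """Simplex minimization of neg_log_post, mirroring the classic
    fminsearch scheme (reflection 1, expansion 2, contraction 0.5,
    shrink 0.5; initial simplex perturbs each coordinate by 5%)."""
    k = x0.shape[0]
    nvert = k + 1
    sim = np.empty((nvert, k))
    fsim = np.empty(nvert)
    for j in range(k):
        sim[0, j] = x0[j]
    for i in range(k):
        for j in range(k):
            sim[i + 1, j] = x0[j]
        if x0[i] != 0.0:
            sim[i + 1, i] = 1.05 * x0[i]
        else:
            sim[i + 1, i] = 0.00025
    for i in range(nvert):
        fsim[i] = neg_log_post(
            sim[i], base, weighted, fam, p1, p2,
            chosen, reward, responded, mag_a, mag_b, block, tidx,
            n_trials, reset_at_block, s0, associability_first,
        )
    order = np.argsort(fsim)
    sim = sim[order]
    fsim = fsim[order]
    nfev = nvert
    converged = False
    for _ in range(maxiter):
        dx = 0.0
        df = 0.0
        for i in range(1, nvert):
            if abs(fsim[i] - fsim[0]) > df:
                df = abs(fsim[i] - fsim[0])
            for j in range(k):
                if abs(sim[i, j] - sim[0, j]) > dx:
                    dx = abs(sim[i, j] - sim[0, j])
        if dx <= xatol and df <= fatol:
            converged = True
            break
        xbar = np.zeros(k)
        for i in range(nvert - 1):
            for j in range(k):
                xbar[j] += sim[i, j]
        for j in range(k):
            xbar[j] /= nvert - 1
        xr = 2.0 * xbar - sim[-1]
        fxr = neg_log_post(
            xr, base, weighted, fam, p1, p2,
            chosen, reward, responded, mag_a, mag_b, block, tidx,
            n_trials, reset_at_block, s0, associability_first,
        )
        nfev += 1
        shrink = False
        if fxr < fsim[0]:
            xe = 3.0 * xbar - 2.0 * sim[-1]
            fxe = neg_log_post(
                xe, base, weighted, fam, p1, p2,
                chosen, reward, responded, mag_a, mag_b, block, tidx,
                n_trials, reset_at_block, s0, associability_first,
            )
            nfev += 1
            if fxe < fxr:
                sim[-1] = xe
                fsim[-1] = fxe
            else:
                sim[-1] = xr
                fsim[-1] = fxr
        elif fxr < fsim[-2]:
            sim[-1] = xr
            fsim[-1] = fxr
        elif fxr < fsim[-1]:
            xc = 1.5 * xbar - 0.5 * sim[-1]
            fxc = neg_log_post(
                xc, base, weighted, fam, p1, p2,
                chosen, reward, responded, mag_a, mag_b, block, tidx,
                n_trials, reset_at_block, s0, associability_first,
            )
            nfev += 1
            if fxc <= fxr:
                sim[-1] = xc
                fsim[-1] = fxc
            else:
                shrink = True
        else:
            xcc = 0.5 * xbar + 0.5 * sim[-1]
            fxcc = neg_log_post(
                xcc, base, weighted, fam, p1, p2,
                chosen, reward, responded, mag_a, mag_b, block, tidx,
                n_trials, reset_at_block, s0, associability_first,
            )
            nfev += 1
            if fxcc < fsim[-1]:
                sim[-1] = xcc
                fsim[-1] = fxcc
            else:
                shrink = True
        if shrink:
            for i in range(1, nvert):
                for j in range(k):
                    sim[i, j] = sim[0, j] + 0.5 * (sim[i, j] - sim[0, j])
                fsim[i] = neg_log_post(
                    sim[i], base, weighted, fam, p1, p2,
                    chosen, reward, responded, mag_a, mag_b, block, tidx,
                    n_trials, reset_at_block, s0, associability_first,
                )
                nfev += 1
        order = np.argsort(fsim)
        sim = sim[order]
        fsim = fsim[order]
    return sim[0], fsim[0], converged, nfev


@njit(cache=False)
def multistart_nelder_mead(
    starts,
    base,
    weighted,
    fam,
    p1,
    p2,
    chosen,
    reward,
    responded,
    mag_a,
    mag_b,
    block,
    tidx,
    n_trials,
    reset_at_block,
    s0,
    associability_first,
    xatol,
    fatol,
    maxiter,
):
    """Best optimum over simplex runs from each row of ``starts``."""
    k = starts.shape[1]
    best_x = np.full(k, np.nan)
    best_f = np.inf
    n_converged = 0
    for r in range(starts.shape[0]):
        x, f, conv, _ = nelder_mead(
            starts[r], base, weighted, fam, p1, p2,
            chosen, reward, responded, mag_a, mag_b, block, tidx,
            n_trials, reset_at_block, s0, associability_first,
            xatol, fatol, maxiter,
        )
        if conv and np.isfinite(f):
            n_converged += 1
        if np.isfinite(f) and f < best_f:
            best_f = f
            best_x = x
    return best_x, best_f, n_converged
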