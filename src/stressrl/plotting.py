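"""Vector-graphics figures for group results.

Three standard views: group bars of proportion correct with per-subject
points, the linear probability-weighting curves implied by group-mean
gamma, and performance-vs-parameter scatter plots with fitted lines.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .models import weight_probability

_SEX_COLORS = {"male": "#2a9d8f", "female": "#e76f51"}


def plot_group_performance(perf: pd.DataFrame, path) -> Path:
    """Bars of mean proportion correct per sex x stress cell, with
    per-subject points and SEM error bars."""
    fig, ax = plt.subplots(figsize=(5, 4))
    cells = [
        (stress, sex)
        for stress in ("low", "high")
        for sex in ("male", "female")
    ]
    rng = np.random.default_rng(0)  # jitter only
    for x, (stress, sex) in enumerate(cells):
        vals = perf.loc[
            (perf.stress_group == stress) & (perf.sex == sex), "prop_correct"
        ].dropna()
        if vals.empty:
            continue
        sem = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
        ax.bar(x, vals.mean(), yerr=sem, color=_SEX_COLORS[sex], alpha=0.6,
               capsize=4)
        ax.scatter(
            x + rng.uniform(-0.15, 0.15, len(vals)), vals,
            s=12, color=_SEX_COLORS[sex], edgecolor="k", linewidth=0.3, zorder=3,
        )
    ax.set_xticks(range(4))
    ax.set_xticklabels([f"{st[:1].upper()}S-{sx[0].upper()}" for st, sx in cells])
    ax.set_ylabel("proportion correct")
    ax.set_ylim(0, 1)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path)
    plt.close(fig)
    return path


def plot_weighting_curves(gamma_by_group: dict[str, float], path) -> Path:
    """Weighted vs predicted probability for each group's mean gamma."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    p = np.linspace(0, 1, 201)
    for label, gamma in gamma_by_group.items():
        ax.plot(p, [weight_probability(x, gamma) for x in p],
                label=f"{label} (γ={gamma:.2f})")
    ax.plot(p, p, "k:", linewidth=0.8, label="identity (γ=1)")
    ax.set_xlabel("predicted probability")
    ax.set_ylabel("weighted probability")
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path)
    plt.close(fig)
    return path


def plot_parameter_scatter(
    perf: pd.DataFrame,
    params: pd.DataFrame,
    parameter: str,
    path,
) -> Path:
    """Per-sex scatter of proportion correct against a fitted parameter,
    with least-squares lines."""
    data = perf.merge(params, on="subject_id")
    fig, ax = plt.subplots(figsize=(5, 4))
    for sex, sub in data.groupby("sex"):
        sub = sub.dropna(subset=[parameter, "prop_correct"])
        ax.scatter(sub[parameter], sub.prop_correct, s=18,
                   color=_SEX_COLORS.get(sex, "gray"), label=sex)
        if len(sub) > 2 and sub[parameter].nunique() > 1:
            coef = np.polyfit(sub[parameter], sub.prop_correct, 1)
            xs = np.linspace(sub[parameter].min(), sub[parameter].max(), 50)
            ax.plot(xs, np.polyval(coef, xs), color=_SEX_COLORS.get(sex, "gray"))
    ax.set_xlabel(f"fitted {parameter}")
    ax.set_ylabel("proportion correct")
    ax.legend()
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path)
    plt.close(fig)
    return path


def standard_figures(
    perf: pd.DataFrame, params: pd.DataFrame, out_dir
) -> list[Path]:
    """The default figure set written by the analyze stage (SVG)."""
    out = Path(out_dir)
    figures = [plot_group_performance(perf, out / "fig_performance.svg")]
    merged = perf.merge(params, on="subject_id")
    if "gamma" in merged.columns:
        gamma_by_group = (
            merged.groupby(["stress_group", "sex"])["gamma"].mean().to_dict()
        )
        figures.append(
            plot_weighting_curves(
                {f"{st}-{sx}": g for (st, sx), g in gamma_by_group.items()},
                out / "fig_weighting.svg",
            )
        )
        figures.append(
            plot_parameter_scatter(perf, params, "gamma", out / "fig_scatter_gamma.svg")
        )
    if "alpha" in merged.columns:
        figures.append(
            plot_parameter_scatter(perf, params, "alpha", out / "fig_scatter_alpha.svg")
        )
    return figures
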