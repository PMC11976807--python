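"""Figures: time–concentration curves per organ and an LOA chart.

Plots are artifacts for inspection; the numeric CSVs are the authoritative
pipeline output.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_tissue_curves(corrected_obs: pd.DataFrame, fits: dict, outdir: str | Path) -> list[Path]:
    """One panel per organ: observed mean ± SE tissue concentrations per
    compartment with the fitted population curves superimposed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    obs = corrected_obs.copy()
    obs["t_mid"] = 0.5 * (obs["t_start_min"] + obs["t_end_min"])
    organs = sorted(obs["organ"].unique()) if "organ" in obs.columns else [None]
    paths = []
    t_grid = np.linspace(0, 480, 481)
    for organ in organs:
        sub = obs if organ is None else obs[obs["organ"] == organ]
        fig, ax = plt.subplots(figsize=(6, 4))
        for tissue, grp in sub.groupby("tissue"):
            g = grp.groupby("t_mid")["c_tissue_ug_ml"]
            mean, se = g.mean(), g.std() / np.sqrt(g.size())
            (line,) = ax.plot(mean.index, mean.values, "o", ms=4, label=str(tissue))
            ax.errorbar(mean.index, mean.values, yerr=se.values, fmt="none", ecolor=line.get_color(), alpha=0.5)
            if tissue in fits:
                ax.plot(t_grid, fits[tissue].predict(t_grid), "-", color=line.get_color(), lw=1.5)
        ax.set_xlabel("time since perfusion start (min)")
        ax.set_ylabel("free tissue concentration (µg/mL)")
        ax.set_title(str(organ) if organ else "all tissues")
        ax.legend(fontsize=8)
        fig.tight_layout()
        p = outdir / f"curves_{organ or 'all'}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)
    return paths


def plot_loa(loa: pd.DataFrame, outdir: str | Path) -> Path:
    """Dot-and-interval chart of LOA factors per tissue and parameter."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(6, 0.5 + 0.4 * len(loa)))
    labels = [f"{r.tissue} / {r.parameter}" for r in loa.itertuples()]
    y = np.arange(len(loa))
    ax.plot(loa["loa_factor"], y, "o")
    if "ci_low" in loa.columns and loa["ci_low"].notna().any():
        ax.hlines(y, loa["ci_low"], loa["ci_high"], alpha=0.6)
    ax.axvline(1.0, color="grey", lw=0.8)
    ax.set_yticks(y, labels, fontsize=8)
    ax.set_xscale("log")
    ax.set_xlabel("limits-of-agreement factor (log scale)")
    fig.tight_layout()
    p = outdir / "loa.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    return p
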