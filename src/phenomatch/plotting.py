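"""Dot-and-interval charts for the statistical layer (SVG output)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

# deterministic SVG output (stable element ids, no timestamp)
matplotlib.rcParams["svg.hashsalt"] = "phenomatch"
_SVG_META = {"Date": None}

__all__ = ["plot_enrichment", "plot_regression"]


def plot_enrichment(enrichment: pd.DataFrame, path: str | Path) -> None:
    """Odds ratios with 95% CIs per disease category, log-scaled x axis."""
    df = enrichment.sort_values("odds_ratio").reset_index(drop=True)
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(df) + 1.2))
    y = np.arange(len(df))
    finite = np.isfinite(df["odds_ratio"])
    ax.errorbar(
        df.loc[finite, "odds_ratio"], y[finite.to_numpy()],
        xerr=[
            df.loc[finite, "odds_ratio"] - df.loc[finite, "ci_low"],
            df.loc[finite, "ci_high"] - df.loc[finite, "odds_ratio"],
        ],
        fmt="o", color="#2c5f8a", ecolor="#8ab0cc", capsize=3,
    )
    ax.axvline(1.0, color="grey", linewidth=0.8, linestyle="--")
    ax.set_yticks(y)
    ax.set_yticklabels(df["category"])
    ax.set_xscale("log")
    ax.set_xlabel("odds ratio (matches vs non-matches, category vs rest)")
    fig.tight_layout()
    fig.savefig(path, format="svg", metadata=_SVG_META)
    plt.close(fig)


def plot_regression(regression: pd.DataFrame, path: str | Path) -> None:
    """Logistic-regression coefficients (log-odds) with 95% CIs."""
    df = regression[regression["feature"] != "intercept"].reset_index(drop=True)
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(df) + 1.2))
    y = np.arange(len(df))
    ax.errorbar(
        df["estimate"], y,
        xerr=[df["estimate"] - df["ci_low"], df["ci_high"] - df["estimate"]],
        fmt="o", color="#8a2c2c", ecolor="#cc8a8a", capsize=3,
    )
    ax.axvline(0.0, color="grey", linewidth=0.8, linestyle="--")
    ax.set_yticks(y)
    ax.set_yticklabels(df["feature"])
    ax.set_xlabel("log-odds coefficient (95% CI)")
    fig.tight_layout()
    fig.savefig(path, format="svg", metadata=_SVG_META)
    plt.close(fig)
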