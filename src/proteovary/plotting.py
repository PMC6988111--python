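"""Plain plotting helpers for the main pipeline readouts."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_roc(records, ax=None):
    """ROC curves of one or more covariation records (one line per record)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    for rec in records:
        if not rec.roc_points:
            continue
        fpr, tpr = zip(*rec.roc_points)
        ax.plot(fpr, tpr, label=f"{rec.category} (AUC={rec.auc:.2f})")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_volcano(moderated: pd.DataFrame, contrast: str, q_cutoff: float = 0.01, ax=None):
    """log2 fold-change vs -log10 p for moderated stoichiometry contrasts."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    sub = moderated[moderated["contrast"] == contrast]
    sig = sub["q_value"] < q_cutoff
    ax.scatter(sub.loc[~sig, "log2_fc"], -np.log10(sub.loc[~sig, "p_value"]),
               s=6, c="grey", alpha=0.6)
    ax.scatter(sub.loc[sig, "log2_fc"], -np.log10(sub.loc[sig, "p_value"]),
               s=8, c="firebrick")
    ax.set_xlabel(f"log2 fold change ({contrast})")
    ax.set_ylabel("-log10 p (moderated t)")
    return ax


def plot_landscape(records, ax=None):
    """Aggregated complex landscape: median rank fraction with class colors."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    colors = {"stable": "steelblue", "variable": "firebrick",
              "intermediate": "grey", "NA": "lightgrey"}
    recs = [r for r in records if not np.isnan(r.median_rank_fraction)]
    xs = np.arange(len(recs))
    ax.bar(xs, [1 - r.median_rank_fraction for r in recs],
           color=[colors[r.label] for r in recs], width=1.0)
    ax.set_xlabel("complexes (sorted)")
    ax.set_ylabel("co-abundance rank (1 = top)")
    return ax
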