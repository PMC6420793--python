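"""Figure helpers: volcano, rescue scatter and fidelity pies.

Conventions follow the field's rescue plots: red for genes significant in
both knockdown and rescue, gray for knockdown-only, yellow for rescue-only,
black for no detectable change; pies show concordant (red), paradoxical
(blue) and unchanged (gray) fractions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

STATUS_COLORS = {
    "both_significant": "#d62728",
    "kd_only": "#7f7f7f",
    "rescue_only": "#e6c229",
    "neither": "#000000",
}


def volcano(de: pd.DataFrame, alpha: float = 0.05, lfc_cutoff: float = 1.0, ax=None):
    """Volcano plot: -log10 p against log2 fold change."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    p = de["p"].to_numpy(dtype=float)
    lfc = de["log2fc"].to_numpy(dtype=float)
    padj = de["padj"].to_numpy(dtype=float)
    y = -np.log10(np.clip(p, 1e-300, 1.0))
    sig = np.nan_to_num(padj, nan=1.0) < alpha
    big = np.abs(lfc) > lfc_cutoff
    colors = np.where(sig & big, "green", np.where(sig, "red",
                      np.where(big, "#e6c229", "black")))
    ax.scatter(lfc, y, s=4, c=colors, linewidths=0)
    ax.set_xlabel("log2(fold change)")
    ax.set_ylabel("-log10(p)")
    return ax


def rescue_scatter(endo: pd.DataFrame, construct: pd.DataFrame, calls: pd.DataFrame,
                   strength=None, ax=None):
    """Construct log2FC against endogenous log2FC, colored by rescue status."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    merged = (calls.merge(endo[["gene", "log2fc"]], on="gene")
              .merge(construct[["gene", "log2fc"]], on="gene", suffixes=("_endo", "_construct")))
    for status, color in STATUS_COLORS.items():
        sub = merged[merged["status"] == status]
        ax.scatter(sub["log2fc_endo"], sub["log2fc_construct"], s=5, c=color,
                   linewidths=0, label=status)
    ax.axhline(0, color="k", lw=0.5, ls=":")
    ax.axvline(0, color="k", lw=0.5, ls=":")
    if strength is not None and np.isfinite(strength.slope):
        xs = np.array(ax.get_xlim())
        ax.plot(xs, strength.intercept + strength.slope * xs, "r-", lw=1)
        ax.set_title(f"r = {strength.pearson_r:.2f}, slope = {strength.slope:.2f}")
    ax.set_xlabel("endogenous log2(fold change)")
    ax.set_ylabel("construct log2(fold change)")
    ax.legend(fontsize=6, loc="upper left")
    return ax


def fidelity_pie(row: pd.Series, ax=None):
    """Pie of concordant / paradoxical / unchanged fractions (one table row)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(3, 3))
    fracs = [row["frac_rescued_concordant"], row["frac_paradoxical"], row["frac_unchanged"]]
    ax.pie(fracs, colors=["#d62728", "#1f77b4", "#7f7f7f"],
           labels=["concordant", "paradoxical", "unchanged"],
           autopct="%1.0f%%", textprops={"fontsize": 6})
    ax.set_title(f"{row['construct']} / {row['element_class']}", fontsize=8)
    return ax
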