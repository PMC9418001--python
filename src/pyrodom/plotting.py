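"""Plot helpers: Van Krevelen scatter, NOSC densities, AI boxplots."""

from __future__ import annotations

import pandas as pd


def van_krevelen(metrics: pd.DataFrame, ax=None, **scatter_kw):
    """Scatter of H/C vs O/C colored by compound class."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    df = metrics.dropna(subset=["hc", "oc"])
    for name, grp in df.groupby("vk_class"):
        ax.scatter(grp["oc"], grp["hc"], s=6, label=name, **scatter_kw)
    ax.set_xlabel("O/C")
    ax.set_ylabel("H/C")
    ax.legend(fontsize=6, markerscale=2)
    return ax


def nosc_density(density: pd.DataFrame, medians: pd.Series | None = None, ax=None):
    """Line plot of the exported per-group NOSC histogram densities."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    for g, grp in density.groupby("group"):
        ax.plot(grp["nosc"], grp["density"], label=g)
        if medians is not None and g in medians:
            ax.axvline(medians[g], linestyle="--", linewidth=0.8)
    ax.set_xlabel("NOSC")
    ax.set_ylabel("density")
    ax.legend(fontsize=7)
    return ax


def ai_boxplot(sample_means: pd.Series, metadata: pd.DataFrame, ax=None):
    """Per-condition boxplot of per-sample mean aromaticity index."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    md = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    df = pd.DataFrame({"mean_ai": sample_means, "condition": md["condition"]})
    order = list(dict.fromkeys(md["condition"]))
    data = [df.loc[df["condition"] == c, "mean_ai"].dropna() for c in order]
    ax.boxplot(data, tick_labels=order)
    ax.set_ylabel("mean AI per sample")
    return ax
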