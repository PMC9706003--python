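"""Matplotlib layouts for model qualification figures.

Four-panel goodness-of-fit (DV vs PRED/IPRED, CWRES vs PRED/time), VPC
percentile bands, and the NPDE QQ/histogram/scatter panel.  These are
thin presentation helpers over the DataFrames the diagnostics return.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def gof_panel(gof, fig=None):
    """2x2 goodness-of-fit panel from :func:`tacropk.gof_quantities` output."""
    import matplotlib.pyplot as plt

    fig = fig or plt.figure(figsize=(9, 8))
    axes = fig.subplots(2, 2)
    lim = (0, max(gof["DV"].max(), gof["PRED"].max()) * 1.05)
    for ax, col, label in [
        (axes[0, 0], "IPRED", "individual predictions"),
        (axes[0, 1], "PRED", "population predictions"),
    ]:
        ax.plot(gof[col], gof["DV"], "o", ms=3, alpha=0.5)
        ax.plot(lim, lim, "k--", lw=1)
        ax.set_xlabel(f"{label} (ug/L)")
        ax.set_ylabel("observed (ug/L)")
        ax.set_xlim(lim)
        ax.set_ylim(lim)
    for ax, xcol, xlabel in [
        (axes[1, 0], "PRED", "population prediction (ug/L)"),
        (axes[1, 1], "TIME", "time (h)"),
    ]:
        ax.plot(gof[xcol], gof["CWRES"], "o", ms=3, alpha=0.5)
        for yv in (-2, 0, 2):
            ax.axhline(yv, color="k", ls="--", lw=0.8)
        ax.set_xlabel(xlabel)
        ax.set_ylabel("CWRES")
    fig.tight_layout()
    return fig


def vpc_plot(vpc, ax=None):
    """Observed percentiles with simulated confidence bands, one bin per
    x-position (trough bins in time order, then peaks)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 5))
    bins = vpc.bins
    order = sorted(bins["bin"].unique(), key=lambda b: (b == "peak", b))
    xpos = {b: i for i, b in enumerate(order)}
    colors = {5: "tab:blue", 50: "tab:red", 95: "tab:blue"}
    for pct in vpc.percentiles:
        sub = bins[bins["percentile"] == pct].copy()
        x = sub["bin"].map(xpos)
        ax.fill_between(x, sub["band_lo"], sub["band_hi"],
                        alpha=0.25, color=colors.get(pct, "gray"))
        ax.plot(x, sub["observed"], "o-", color=colors.get(pct, "gray"),
                label=f"observed P{pct}")
    ax.set_xticks(range(len(order)), order)
    ax.set_ylabel("concentration (ug/L)")
    ax.legend()
    return ax


def npde_panel(res, fig=None):
    """QQ plot, histogram, and scatter vs time/DV for an NPDE result."""
    import matplotlib.pyplot as plt

    fig = fig or plt.figure(figsize=(9, 8))
    axes = fig.subplots(2, 2)
    vals = res.values
    stats.probplot(vals, dist="norm", plot=axes[0, 0])
    axes[0, 0].set_title("")
    x = np.linspace(-4, 4, 200)
    axes[0, 1].hist(vals, bins=20, density=True, alpha=0.6)
    axes[0, 1].plot(x, stats.norm.pdf(x), "k-")
    axes[0, 1].set_xlabel("npde")
    axes[1, 0].plot(res.table["TIME"], vals, "o", ms=3, alpha=0.5)
    axes[1, 0].axhline(0, color="k", ls="--", lw=0.8)
    axes[1, 0].set_xlabel("time (h)")
    axes[1, 0].set_ylabel("npde")
    axes[1, 1].plot(res.table["DV"], vals, "o", ms=3, alpha=0.5)
    axes[1, 1].axhline(0, color="k", ls="--", lw=0.8)
    axes[1, 1].set_xlabel("observed concentration (ug/L)")
    axes[1, 1].set_ylabel("npde")
    fig.tight_layout()
    return fig
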