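"""Minimal Manhattan and QQ plots for association scans."""

from __future__ import annotations

import numpy as np

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from scipy import stats  # noqa: E402


def manhattan(table, threshold: float | None = None, ax=None, path=None):
    """Manhattan plot from a per-marker table (chrom, pos, score)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    offset = 0
    ticks, labels = [], []
    for i, (c, sub) in enumerate(table.groupby("chrom", sort=True)):
        x = sub["pos"].to_numpy() + offset
        ax.scatter(x, sub["score"], s=4,
                   color="tab:blue" if i % 2 == 0 else "tab:grey")
        ticks.append(offset + sub["pos"].max() / 2)
        labels.append(str(c))
        offset += sub["pos"].max() + 1
    if threshold is not None:
        ax.axhline(threshold, ls="--", color="k", lw=0.8)
    ax.set_xticks(ticks, labels, rotation=45, fontsize=7)
    ax.set_ylabel(r"$-\log_{10} p$")
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def qq(p_values, ax=None, path=None):
    """Observed vs expected -log10 p quantile plot."""
    p = np.sort(np.asarray(p_values, dtype=float))
    p = p[np.isfinite(p)]
    n = len(p)
    exp = -np.log10(stats.beta.median(np.arange(1, n + 1), n - np.arange(n)))
    obs = -np.log10(p)
    if ax is None:
        _, ax = plt.subplots(figsize=(3.2, 3.2))
    ax.scatter(np.sort(exp), np.sort(obs), s=5)
    lim = max(np.max(exp), np.max(obs))
    ax.plot([0, lim], [0, lim], color="k", lw=0.8)
    ax.set_xlabel("expected " + r"$-\log_{10} p$")
    ax.set_ylabel("observed " + r"$-\log_{10} p$")
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
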