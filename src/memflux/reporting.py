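"""Optional figure-style summaries (series plots, histograms).

Plotting is never load-bearing: every number lives in the TSV/JSON outputs,
and these helpers only render them.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np

from .core import ResultTable


def _mpl():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_series(table: ResultTable, y: str, path: str | Path, x: str = "frame",
                ylabel: str | None = None) -> None:
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.plot(table.data[x], table.data[y], lw=1)
    ax.set_xlabel(x)
    ax.set_ylabel(ylabel or y)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_histogram(values, path: str | Path, xlabel: str, bins="auto") -> None:
    plt = _mpl()
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.hist(values, bins=bins, color="steelblue", edgecolor="black")
    ax.set_xlabel(xlabel)
    ax.set_ylabel("frames")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
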