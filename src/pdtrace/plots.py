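"""Optional matplotlib exports for recovery reports."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_cumulative_excretion(curve: pd.DataFrame, path: Path) -> None:
    """Cumulative excreted Pd as % of dose vs time."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.step(curve["time_h"], curve["cumulative_pct"], where="post")
    ax.set_xlabel("time post-gavage (h)")
    ax.set_ylabel("cumulative excretion (% of dose)")
    ax.set_ylim(bottom=0)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_recovery_bars(per_organ: pd.DataFrame, path: Path) -> None:
    """Per-organ %-of-dose bars, grouped by quantification method."""
    fig, ax = plt.subplots(figsize=(6, 3.2))
    pivot = per_organ.pivot_table(index="organ", columns="method", values="pct_dose")
    pivot.plot.bar(ax=ax)
    ax.set_ylabel("% of dose")
    ax.set_xlabel("")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
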