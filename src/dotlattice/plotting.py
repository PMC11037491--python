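"""Logit-curve figures for simulated dot-lattice experiments."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .errors import AnalysisError


def plot_curves(
    summary: dict[str, pd.DataFrame],
    path: str | Path,
    overlay: dict[str, pd.DataFrame] | None = None,
) -> Path:
    """Two-panel figure: logit p(0 deg) vs aspect ratio for the first
    lattice, and for the second lattice split by the first-lattice percept.

    ``overlay`` (e.g. a sampled-mode summary over an expected-mode one) is
    drawn as open markers on the same axes.
    """
    l1, l2 = summary["l1"], summary["l2"]
    for r1 in (0.0, 90.0):
        if l2[l2.r1 == r1].empty:
            raise AnalysisError(f"cannot plot: no rows for r1 = {r1:g} deg")

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4), sharex=True)
    ax1.plot(np.log(l1.ar), l1.logit_p0, "o-", color="tab:blue")
    ax1.set_title("First lattice")
    ax1.set_ylabel("logit p(relative 0°)")

    colors = {0.0: "tab:orange", 90.0: "tab:olive"}
    for r1, sub in l2.groupby("r1"):
        ax2.plot(
            np.log(sub.ar), sub.logit_p0, "o-",
            color=colors.get(r1, "k"), label=f"r1 = {r1:g}°",
        )
    if overlay is not None:
        o1, o2 = overlay["l1"], overlay["l2"]
        ax1.plot(np.log(o1.ar), o1.logit_p0, "o", mfc="none", color="tab:blue")
        for r1, sub in o2.groupby("r1"):
            ax2.plot(np.log(sub.ar), sub.logit_p0, "o", mfc="none",
                     color=colors.get(r1, "k"))
    ax2.set_title("Second lattice")
    ax2.legend(frameon=False)
    for ax in (ax1, ax2):
        ax.set_xlabel("log aspect ratio")
        ax.axhline(0.0, lw=0.5, color="grey")

    path = Path(path)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
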