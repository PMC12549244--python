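"""Per-participant predicted-vs-reported trust traces for one MCCV split."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_trust_traces"]


def plot_trust_traces(
    keys_test: pd.DataFrame,
    y_test: np.ndarray,
    y_pred: np.ndarray,
    out_dir,
    n_epochs_per_trial: int | None = None,
) -> list:
    """One panel per participant: reported and predicted trust across the
    withheld epochs, with session delimiters.  Returns written file paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = keys_test.copy()
    df["y"] = np.asarray(y_test, dtype=float)
    df["pred"] = np.asarray(y_pred, dtype=float)
    participants = sorted(df["participant"].unique())

    n = len(participants)
    ncols = min(4, n)
    nrows = int(np.ceil(n / ncols))
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(4 * ncols, 2.5 * nrows), squeeze=False, sharey=True
    )
    for i, p in enumerate(participants):
        ax = axes[i // ncols][i % ncols]
        sub = df[df["participant"] == p].sort_values(["session", "trial", "epoch"])
        x = np.arange(len(sub)) + 1
        ax.plot(x, sub["y"], color="firebrick", lw=1.2, label="reported")
        ax.plot(x, sub["pred"], color="navy", lw=1.2, label="predicted")
        # session delimiters
        bounds = np.flatnonzero(np.diff(sub["session"].to_numpy()) != 0) + 1.5
        for b in bounds:
            ax.axvline(b, color="gray", ls="--", lw=0.8)
        ax.set_ylim(-0.02, 1.02)
        ax.set_title(f"participant {p}", fontsize=9)
        if i == 0:
            ax.legend(fontsize=7, loc="lower right")
    for j in range(n, nrows * ncols):
        axes[j // ncols][j % ncols].axis("off")
    fig.supxlabel("withheld epoch")
    fig.supylabel("trust")
    fig.tight_layout()
    out = out_dir / "trust_traces.png"
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return [out]
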