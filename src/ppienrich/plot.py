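"""Minimal plotting helper for beta scans."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def beta_scan_heatmap(scan: pd.DataFrame, path: str, alpha: float = 0.05) -> None:
    """Render a pathway x beta heatmap of -log10 BH-adjusted p-values.

    Rows are ordered by coverage (as in the per-pathway heatmap views of
    beta scans); cells at or below `alpha` are the detection calls.
    """
    pivot = scan.pivot_table(index="pathway_id", columns="beta", values="bh")
    coverage = scan.groupby("pathway_id")["coverage"].max()
    pivot = pivot.loc[coverage.sort_values(ascending=False).index]
    values = -np.log10(pivot.to_numpy(dtype=float))
    fig, ax = plt.subplots(
        figsize=(1.2 * pivot.shape[1] + 3, 0.3 * pivot.shape[0] + 2)
    )
    im = ax.imshow(values, aspect="auto", cmap="viridis")
    ax.set_xticks(range(pivot.shape[1]), [f"{b:g}" for b in pivot.columns])
    ax.set_yticks(range(pivot.shape[0]), pivot.index, fontsize=7)
    ax.set_xlabel("beta")
    fig.colorbar(im, ax=ax, label="-log10 BH p")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
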