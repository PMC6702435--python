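"""Optional plotting helpers (matplotlib, headless backend)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .signatures import cluster_signature, encode_signature


def plot_signature_heatmap(sig: pd.DataFrame, path: str | Path) -> None:
    """Clustered unit x condition heatmap (up = red, down = green, as in
    stress-response figures)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    wide = encode_signature(sig)
    clust = cluster_signature(sig)
    ordered = wide.loc[clust.row_order, clust.col_order]
    fig, ax = plt.subplots(
        figsize=(0.4 * len(ordered.columns) + 2, 0.18 * len(ordered.index) + 2)
    )
    im = ax.imshow(ordered.values, cmap="RdYlGn_r", vmin=-1, vmax=1, aspect="auto")
    ax.set_xticks(range(len(ordered.columns)), ordered.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(ordered.index)), ordered.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="response (+1 up / -1 down)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
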