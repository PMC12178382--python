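"""Optional UMAP scatter plots of patch or slide embeddings.

Convenience only: lets you eyeball how filtered versus unfiltered patch
features (or slide vectors) organize in two dimensions. Requires the
optional ``umap-learn`` extra; import errors surface immediately.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np


def umap_scatter(
    features: np.ndarray,
    labels: Sequence[str],
    out_path: str | Path,
    seed: int = 0,
    title: str = "",
):
    """Project rows to 2-D with UMAP and save a labelled scatter plot."""
    try:
        import umap
    except ImportError as exc:  # pragma: no cover - optional extra
        raise ImportError(
            "umap-learn is required for embedding plots; install the "
            "'umap' extra"
        ) from exc
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    emb = umap.UMAP(random_state=seed).fit_transform(np.asarray(features))
    fig, ax = plt.subplots(figsize=(6, 5))
    for lab in sorted(set(labels)):
        mask = np.asarray([l == lab for l in labels])
        ax.scatter(emb[mask, 0], emb[mask, 1], s=8, label=lab, alpha=0.7)
    ax.legend(fontsize=7, markerscale=2)
    ax.set_xlabel("UMAP-1")
    ax.set_ylabel("UMAP-2")
    if title:
        ax.set_title(title)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return out_path
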