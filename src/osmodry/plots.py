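"""Optional figure rendering for the pipeline bundle (heatmap, dendrogram, biplot)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
from scipy.cluster import hierarchy

from .dataset import DesignTable
from .multivariate import ClusterResult, CorrelationResult, PCAResult

__all__ = ["save_correlation_heatmap", "save_dendrogram", "save_biplot"]


def save_correlation_heatmap(corr: CorrelationResult, path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(7, 6))
    image = ax.imshow(corr.r.to_numpy(), vmin=-1, vmax=1, cmap="RdBu")
    ax.set_xticks(range(len(corr.r.columns)), corr.r.columns, rotation=90)
    ax.set_yticks(range(len(corr.r.index)), corr.r.index)
    fig.colorbar(image, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def save_dendrogram(clusters: ClusterResult, path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(7, 4))
    hierarchy.dendrogram(clusters.merges, labels=sorted(clusters.labels), ax=ax)
    ax.set_ylabel(f"{clusters.metric} distance ({clusters.linkage} linkage)")
    ax.set_xlabel("run")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def save_biplot(pca: PCAResult, table: DesignTable, path: str | Path) -> Path:
    """Runs scored on PC1/PC2 with variable loading vectors overlaid."""
    responses = table.responses()
    z = (responses - responses.mean()) / responses.std(ddof=1)
    scores = z.to_numpy() @ pca.loadings.to_numpy()[:, :2]
    fig, ax = plt.subplots(figsize=(7, 6))
    ax.scatter(scores[:, 0], scores[:, 1], color="tab:blue")
    for run, (x, y) in zip(responses.index, scores):
        ax.annotate(str(int(run)), (x, y), fontsize=9)
    scale = 0.8 * max(abs(scores[:, 0]).max(), abs(scores[:, 1]).max())
    for var, (lx, ly) in pca.loadings.iloc[:, :2].iterrows():
        ax.arrow(0, 0, scale * lx, scale * ly, color="tab:red",
                 head_width=0.05, length_includes_head=True)
        ax.annotate(var, (scale * lx * 1.1, scale * ly * 1.1),
                    color="tab:red", fontsize=8)
    ax.set_xlabel(f"PC1 ({pca.percent_variance[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({pca.percent_variance[1]:.1f}%)")
    ax.axhline(0, color="0.8", lw=0.5)
    ax.axvline(0, color="0.8", lw=0.5)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
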