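"""Multivariate characterization of a run table.

Three classical views of the response matrix:

* pairwise Pearson correlations with two-sided p-values from the exact
  t-transform ``t = r * sqrt((n-2) / (1-r^2))`` on ``n-2`` degrees of
  freedom (no multiple-testing adjustment);
* agglomerative hierarchical clustering of runs, by default complete
  linkage on city-block (Manhattan) distances over the raw, unstandardized
  response vectors -- on heterogeneous units the large-magnitude mineral
  columns then dominate sample proximity, which is the convention of the
  reference analysis;
* PCA of the correlation matrix (i.e. of z-scored columns), with percent
  variance per component and squared-loading variable contributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .dataset import DesignTable

__all__ = [
    "CorrelationResult",
    "ClusterResult",
    "PCAResult",
    "pearson_matrix",
    "cluster_runs",
    "pca_correlation",
]


@dataclass(frozen=True)
class CorrelationResult:
    """Symmetric Pearson coefficient and p-value matrices over ``n`` runs."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: int


@dataclass(frozen=True)
class ClusterResult:
    """A hierarchical merge tree plus the flat partition at ``k`` clusters.

    ``merges`` is the (n-1) x 4 linkage matrix in scipy convention (child
    indices, merge height, member count); ``labels`` maps each run id to its
    flat cluster label (1..k).
    """

    merges: np.ndarray
    labels: dict[int, int]
    k: int
    metric: str
    linkage: str

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def members(self) -> dict[int, frozenset[int]]:
        """Flat clusters as run-id sets keyed by cluster label."""
        out: dict[int, set[int]] = {}
        for run, lab in self.labels.items():
            out.setdefault(lab, set()).add(run)
        return {lab: frozenset(runs) for lab, runs in out.items()}


@dataclass(frozen=True)
class PCAResult:
    """Correlation-matrix PCA decomposition.

    ``loadings`` holds unit-norm eigenvectors (variables x components); the
    correlation matrix is reconstructed as
    ``loadings @ diag(eigenvalues) @ loadings.T``.  ``contributions`` are
    squared loadings per component, rescaled to sum to 100 within each
    component.
    """

    eigenvalues: np.ndarray
    loadings: pd.DataFrame
    percent_variance: np.ndarray
    contributions: pd.DataFrame


def _response_matrix(table: DesignTable, columns: Sequence[str] | None) -> pd.DataFrame:
    responses = table.responses()
    if columns is not None:
        missing = [c for c in columns if c not in responses.columns]
        if missing:
            raise KeyError(f"unknown response column(s): {missing}")
        responses = responses[list(columns)]
    return responses


def pearson_matrix(table: DesignTable, columns: Sequence[str] | None = None) -> CorrelationResult:
    """Pairwise Pearson correlations between response columns.

    Requires at least 3 runs.  Pairs involving a constant column are
    reported as NaN with a warning.
    """
    X = _response_matrix(table, columns)
    n = len(X)
    if n < 3:
        raise ValueError("Pearson correlation needs at least 3 runs")
    values = X.to_numpy(dtype=float)
    sd = values.std(axis=0, ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"constant column(s) {list(X.columns[constant])}: correlations undefined",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(values, rowvar=False)
        r[constant, :] = np.nan
        r[:, constant] = np.nan
        np.clip(r, -1.0, 1.0, out=r)
        tstat = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    np.fill_diagonal(r, np.where(constant, np.nan, 1.0))
    np.fill_diagonal(p, np.where(constant, np.nan, 0.0))
    cols = X.columns
    return CorrelationResult(
        r=pd.DataFrame(r, index=cols, columns=cols),
        p=pd.DataFrame(p, index=cols, columns=cols),
        n=n,
    )


def cluster_runs(table: DesignTable, metric: str = "cityblock",
                 linkage: str = "complete", k: int = 4) -> ClusterResult:
    """Agglomerative clustering of runs on their raw response vectors."""
    X = table.responses()
    if k > len(X):
        raise ValueError(f"cannot cut {len(X)} runs into {k} clusters")
    if k < 1:
        raise ValueError("k must be at least 1")
    merges = hierarchy.linkage(pdist(X.to_numpy(dtype=float), metric=metric), method=linkage)
    flat = hierarchy.fcluster(merges, t=k, criterion="maxclust")
    labels = {int(run): int(lab) for run, lab in zip(X.index, flat)}
    return ClusterResult(merges=merges, labels=labels, k=k, metric=metric, linkage=linkage)


def pca_correlation(table: DesignTable, columns: Sequence[str] | None = None) -> PCAResult:
    """PCA of the correlation matrix of the selected response columns.

    Columns are z-scored, so each variable contributes unit variance and
    the eigenvalues sum to the number of variables.  Component signs are
    fixed so that each component's largest-magnitude loading is positive.
    """
    X = _response_matrix(table, columns)
    if len(X) < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 runs and 2 columns")
    values = X.to_numpy(dtype=float)
    sd = values.std(axis=0, ddof=1)
    if (sd == 0).any():
        name = X.columns[sd == 0][0]
        raise ValueError(f"constant column {name!r}: correlation PCA undefined")
    corr = np.corrcoef(values, rowvar=False)
    eigenvalues, vectors = np.linalg.eigh(corr)
    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = np.clip(eigenvalues[order], 0.0, None)
    vectors = vectors[:, order]
    # orient each component so its dominant variable loads positively
    for j in range(vectors.shape[1]):
        pivot = np.argmax(np.abs(vectors[:, j]))
        if vectors[pivot, j] < 0:
            vectors[:, j] *= -1.0
    percent = 100.0 * eigenvalues / eigenvalues.sum()
    comp_names = [f"PC{i + 1}" for i in range(len(eigenvalues))]
    loadings = pd.DataFrame(vectors, index=X.columns, columns=comp_names)
    contributions = 100.0 * loadings**2 / (loadings**2).sum(axis=0)
    return PCAResult(
        eigenvalues=eigenvalues,
        loadings=loadings,
        percent_variance=percent,
        contributions=contributions,
    )
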