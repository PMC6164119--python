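"""Fusion of conscious and subconscious responses: PCA and cluster analysis.

Per-sample means of the self-reported liking scales (FStability, FHeight,
Aroma, TBitter, MCarb, Flavor, Overall, FS) are fused with the physiological
channels (HR, SP, DP, IR) and the emotion/head-pose variables into one
samples x variables feature matrix.  The matrix is decomposed by principal
component analysis on the correlation matrix (variables mix units — bpm,
degrees C, liking scales — so z-scoring is the default), and the PC scores
are clustered agglomeratively with Euclidean distances to group stimuli by
the joint response pattern they evoke.

The PCA is computed by explicit eigendecomposition of the correlation (or
covariance) matrix so that the explained-variance accounting and the sign
convention are fully specified: eigenvalues are sorted in decreasing order,
explained percentages are eigenvalue / trace x 100 and sum to exactly 100 %
over all components, and each loading vector is oriented so its
largest-magnitude element is positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

__all__ = [
    "FeatureMatrix",
    "PCAResult",
    "ClusterTree",
    "assemble_features",
    "pca",
    "cluster",
    "biplot",
]

#: Canonical variable order for fused matrices (columns present are ordered so).
CANONICAL_VARIABLES = (
    "FStability", "FHeight", "Aroma", "TBitter", "MCarb", "Flavor", "Overall", "FS",
    "HR", "SP", "DP", "IR",
    "happy", "neutral", "sad", "scared", "surprised", "angry", "contempt", "disgusted",
    "valence", "arousal", "X-Head", "Y-Head", "Z-Head", "GDir",
)


@dataclass
class FeatureMatrix:
    """Samples x variables table of per-sample mean responses."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.shape[0] < 2 or self.data.shape[1] < 2:
            raise ValueError(
                f"feature matrix needs >= 2 rows and >= 2 columns, got {self.data.shape}"
            )
        if self.data.isna().any().any():
            raise ValueError("feature matrix has missing cells; enable imputation upstream")

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


def assemble_features(
    responses: Optional[pd.DataFrame] = None,
    vitals: Optional[pd.DataFrame] = None,
    temps: Optional[pd.DataFrame] = None,
    emotions: Optional[pd.DataFrame] = None,
    impute: bool = False,
) -> FeatureMatrix:
    """Fuse per-(participant, sample) sources into a per-sample feature matrix.

    Each source is a tidy frame with ``participant`` and ``sample`` key
    columns plus numeric variable columns; values are averaged over
    participants within each sample, then the per-sample means are joined on
    sample.  A sample missing from any supplied source is an error unless
    ``impute`` is set, in which case the missing cells take the column mean.
    """
    sources = [s for s in (responses, vitals, temps, emotions) if s is not None]
    if not sources:
        raise ValueError("at least one source table is required")
    per_sample = []
    for src in sources:
        for key in ("participant", "sample"):
            if key not in src.columns:
                raise ValueError(f"source table lacks required key column {key!r}")
        means = src.drop(columns="participant").groupby("sample").mean()
        per_sample.append(means)
    fused = pd.concat(per_sample, axis=1, join="outer")
    if fused.isna().any().any():
        if not impute:
            missing = sorted(fused.index[fused.isna().any(axis=1)])
            raise ValueError(
                f"samples missing from some source: {missing}; pass impute=True to fill"
            )
        fused = fused.fillna(fused.mean())
    ordered = [v for v in CANONICAL_VARIABLES if v in fused.columns]
    ordered += [v for v in fused.columns if v not in ordered]
    return FeatureMatrix(data=fused[ordered].sort_index())


@dataclass
class PCAResult:
    """Loadings, scores and explained-variance percentages of a PCA."""

    loadings: pd.DataFrame      # variables x components
    scores: pd.DataFrame        # samples x components
    explained_pct: np.ndarray   # one entry per component, sums to 100
    standardized: bool = True
    dropped_columns: list[str] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return len(self.explained_pct)


def pca(matrix: FeatureMatrix, standardize: bool = True) -> PCAResult:
    """Principal component analysis of the feature matrix.

    With ``standardize`` (default) the decomposition is of the correlation
    matrix: columns are z-scored (ddof=1) first, so every variable enters
    with unit weight.  Constant columns cannot be standardized and are
    dropped with a warning.  Scores are the projections of the (centred or
    z-scored) rows onto the eigenvectors.
    """
    df = matrix.data
    if df.shape[0] < 2:
        raise ValueError("PCA needs at least two samples")
    X = df.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    dropped = []
    if standardize:
        keep = sd > 1e-12
        if not keep.all():
            dropped = [c for c, k in zip(df.columns, keep) if not k]
            warnings.warn(f"dropping constant column(s) before PCA: {dropped}")
            df = df.loc[:, keep]
            X, sd = X[:, keep], sd[keep]
        if df.shape[1] < 2:
            raise ValueError("fewer than 2 non-constant columns; PCA is meaningless")
        Z = (X - X.mean(axis=0)) / sd
    else:
        Z = X - X.mean(axis=0)

    C = (Z.T @ Z) / (Z.shape[0] - 1)
    eigval, eigvec = np.linalg.eigh(C)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = np.clip(eigval[order], 0.0, None), eigvec[:, order]
    # deterministic orientation: largest-|loading| element positive
    for j in range(eigvec.shape[1]):
        i = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[i, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    trace = eigval.sum()
    if trace <= 0:  # all rows identical: no variance to apportion
        explained = np.zeros_like(eigval)
    else:
        explained = 100.0 * eigval / trace
    comp_names = [f"PC{j + 1}" for j in range(len(eigval))]
    return PCAResult(
        loadings=pd.DataFrame(eigvec, index=df.columns, columns=comp_names),
        scores=pd.DataFrame(Z @ eigvec, index=df.index, columns=comp_names),
        explained_pct=explained,
        standardized=standardize,
        dropped_columns=dropped,
    )


@dataclass
class ClusterTree:
    """Agglomerative merge tree over samples.

    ``merges`` is the scipy linkage matrix: each row (i, j, dist, size)
    merges clusters i and j at the given Euclidean-derived distance.
    """

    merges: np.ndarray
    labels: list[str]
    linkage_method: str

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.merges)]

    def cut_by_count(self, k: int) -> dict[str, int]:
        """Assign each sample a cluster id (1..k) at the k-cluster cut."""
        flat = hierarchy.fcluster(self.merges, k, criterion="maxclust")
        return dict(zip(self.labels, (int(c) for c in flat)))

    def cut_by_distance(self, threshold: float) -> dict[str, int]:
        flat = hierarchy.fcluster(self.merges, threshold, criterion="distance")
        return dict(zip(self.labels, (int(c) for c in flat)))


def cluster(
    result: PCAResult, n_components: int = 2, linkage: str = "average"
) -> ClusterTree:
    """Hierarchical clustering of samples on their leading PC scores.

    Distances are Euclidean in the space of the first ``n_components``
    scores; the linkage rule defaults to average (UPGMA), with single,
    complete and ward selectable.
    """
    if linkage not in ("average", "single", "complete", "ward"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    if n_components > result.n_components:
        raise ValueError(
            f"requested {n_components} components but only {result.n_components} available"
        )
    pts = result.scores.iloc[:, :n_components].to_numpy()
    merges = hierarchy.linkage(pts, method=linkage, metric="euclidean")
    return ClusterTree(
        merges=merges, labels=list(result.scores.index), linkage_method=linkage
    )


def biplot(result: PCAResult, components: tuple[int, int] = (1, 2), ax=None):
    """PCA biplot: sample scores as points, variable loadings as arrows.

    Axis labels carry the explained-variance percentage of each component.
    Returns the matplotlib figure.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    ci, cj = components[0] - 1, components[1] - 1
    if max(ci, cj) >= result.n_components or min(ci, cj) < 0:
        raise ValueError(f"components {components} out of range")
    if ax is None:
        fig, ax = plt.subplots(figsize=(7, 6))
    else:
        fig = ax.figure
    xs = result.scores.iloc[:, ci]
    ys = result.scores.iloc[:, cj]
    ax.scatter(xs, ys, color="tab:blue", zorder=3)
    for name, x, y in zip(result.scores.index, xs, ys):
        ax.annotate(str(name), (x, y), fontsize=8, xytext=(3, 3),
                    textcoords="offset points")
    scale = 0.9 * max(np.abs(xs).max(), np.abs(ys).max(), 1e-9)
    for var in result.loadings.index:
        lx = result.loadings.iloc[:, ci][var] * scale
        ly = result.loadings.iloc[:, cj][var] * scale
        ax.annotate("", xy=(lx, ly), xytext=(0, 0),
                    arrowprops=dict(arrowstyle="->", color="tab:red", lw=0.8))
        ax.annotate(var, (lx, ly), color="tab:red", fontsize=7)
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel(f"PC{ci + 1} ({result.explained_pct[ci]:.2f}%)")
    ax.set_ylabel(f"PC{cj + 1} ({result.explained_pct[cj]:.2f}%)")
    total = result.explained_pct[ci] + result.explained_pct[cj]
    ax.set_title(f"PCA biplot ({total:.2f}% of variance)")
    return fig
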