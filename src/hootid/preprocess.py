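"""Standardisation and PCA of the 11 call features.

Beecher's statistic requires uncorrelated variables, so the feature columns
(10 PFC values + duration) are z-scored and rotated onto principal
components.  All components are kept and the scores are *not* rescaled to
unit variance: the per-component variance ratio is exactly the information
HS consumes.  Because the rotation is orthogonal, Euclidean distances in
score space (WID, BID) equal distances between standardized feature
vectors, which downstream tests exploit as an invariance check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

logger = logging.getLogger("hootid.preprocess")

__all__ = ["table_to_features", "standardize", "pca_scores", "PCScores",
           "export_scores", "plot_scores"]

INDEX_LEVELS = ["individual_id", "group_label", "call_id"]


def table_to_features(table, min_calls: int = 2) -> pd.DataFrame:
    """Build the feature matrix from a call table.

    Rows are calls (MultiIndex ``individual_id, group_label, call_id``),
    columns the 10 PFC values plus ``duration_s``.  Individuals with fewer
    than ``min_calls`` calls are dropped with a warning — within-individual
    variation is undefined for them.
    """
    df = table.to_frame()
    counts = df["individual_id"].value_counts()
    small = counts[counts < min_calls].index.tolist()
    if small:
        logger.warning("dropping individuals with < %d calls: %s", min_calls, small)
        df = df[~df["individual_id"].isin(small)]
    if df.empty:
        raise ValueError("no individuals with enough calls")
    df = df.set_index(INDEX_LEVELS)
    # feature order: PFC samples then duration last
    cols = [c for c in df.columns if c.startswith("pfc_")] + ["duration_s"]
    return df[cols].astype(float)


def standardize(m: pd.DataFrame) -> pd.DataFrame:
    """Center each column to mean 0 and scale to sample SD 1 (ddof=1)."""
    if len(m) < 2:
        raise ValueError("standardize needs at least 2 rows")
    sd = m.std(ddof=1)
    dead = sd.index[(sd == 0) | ~np.isfinite(sd)].tolist()
    if dead:
        raise ValueError(f"zero-variance column(s): {dead}")
    return (m - m.mean()) / sd


@dataclass
class PCScores:
    """Principal-component scores of the standardized feature matrix.

    ``scores`` keeps the input row order and labels; ``loadings`` are the
    orthonormal component vectors (columns); ``explained_variance`` the
    per-component score variance (ddof=1), in decreasing order.
    """

    scores: pd.DataFrame
    loadings: np.ndarray
    explained_variance: np.ndarray
    feature_names: list

    @property
    def labels(self) -> np.ndarray:
        """Individual label per row (from the index)."""
        return self.scores.index.get_level_values("individual_id").to_numpy()

    @property
    def groups(self) -> np.ndarray:
        return self.scores.index.get_level_values("group_label").to_numpy()

    def values(self) -> np.ndarray:
        return self.scores.to_numpy()


def pca_scores(m: pd.DataFrame) -> PCScores:
    """Project a standardized feature matrix on its principal components.

    All components are retained, ordered by decreasing explained variance.
    Signs are fixed deterministically: the largest-magnitude element of each
    loading vector is made positive, so score files are reproducible across
    platforms.  When ``n_rows <= n_cols`` the trailing components have
    near-zero variance; they are retained but flagged in the log.
    """
    X = m.to_numpy(dtype=float)
    n, p = X.shape
    pca = PCA(n_components=min(n, p), svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # p x k, orthonormal columns
    if loadings.shape[1] < p:
        # fewer rows than features: pad with an orthonormal complement so the
        # rotation stays square (padded scores are exactly zero)
        basis = np.linalg.qr(np.eye(p) - loadings @ loadings.T)[0][:, : p - loadings.shape[1]]
        loadings = np.hstack([loadings, basis])
        scores = np.hstack([scores, np.zeros((n, p - scores.shape[1]))])
    # deterministic sign: largest-|loading| element of each component positive
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(p)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = scores * flip
    ev = scores.var(axis=0, ddof=1)
    near_zero = int(np.sum(ev <= 1e-10 * max(ev.max(), 1.0)))
    if near_zero:
        logger.info("%d trailing component(s) have near-zero variance "
                    "(n_rows=%d, n_features=%d)", near_zero, n, p)
    cols = [f"pc_{i:02d}" for i in range(1, p + 1)]
    return PCScores(
        scores=pd.DataFrame(scores, index=m.index, columns=cols),
        loadings=loadings,
        explained_variance=ev,
        feature_names=list(m.columns),
    )


def export_scores(ps: PCScores, path) -> None:
    """Write the score table as flat CSV (call labels + pc_01..pc_k)."""
    ps.scores.reset_index().to_csv(path, index=False)


def plot_scores(ps: PCScores, path, components=(0, 1)) -> None:
    """Basic 2-D score scatter coloured by individual (plumbing figure)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    i, j = components
    fig, ax = plt.subplots(figsize=(6, 5))
    X = ps.values()
    for ind in pd.unique(ps.labels):
        mask = ps.labels == ind
        ax.scatter(X[mask, i], X[mask, j], s=12, label=str(ind))
    ax.set_xlabel(f"PC{i + 1}")
    ax.set_ylabel(f"PC{j + 1}")
    if len(pd.unique(ps.labels)) <= 12:
        ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
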