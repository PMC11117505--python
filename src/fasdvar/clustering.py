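"""PCA of pathway burden scores and diagnostic-group separation.

PCA is an eigendecomposition of the covariance (or, when scaling, the
correlation) matrix of the individuals x pathways burden matrix, computed
via SVD of the centered/scaled data.  Group separation on the first two
principal components is quantified by the mean silhouette coefficient of
the diagnosis labels plus a label-permutation p-value — a testable stand-in
for the visual "clusters by diagnosis" judgement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

__all__ = ["PCAResult", "pca", "SeparationReport", "separation", "plot_scores"]


@dataclass
class PCAResult:
    """Scores, loadings and explained variance of a PCA fit.

    ``scores``: individuals x components; ``loadings``: variables x
    components (orthonormal columns); ``variance_explained``: fraction per
    component, nonincreasing; ``preprocessing``: record of the centering /
    scaling applied (means, scales, dropped zero-variance columns).
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_explained: np.ndarray
    preprocessing: dict

    @property
    def degenerate(self) -> bool:
        return self.variance_explained.size == 0

    def reconstruct(self) -> pd.DataFrame:
        """Invert the transform (exact when all components are kept)."""
        x = self.scores.to_numpy() @ self.loadings.to_numpy().T
        x = x * self.preprocessing["scale"] + self.preprocessing["mean"]
        return pd.DataFrame(x, index=self.scores.index, columns=self.loadings.index)


def pca(matrix: pd.DataFrame, center: bool = True, scale: bool = True) -> PCAResult:
    """PCA of an individuals x variables matrix.

    Zero-variance columns are dropped (with a warning) when scaling, since
    they cannot be standardized.  Sample standard deviations (ddof=1) are
    used, so scaled PCA diagonalizes the correlation matrix.  The sign of
    each component is fixed by making its largest-magnitude loading
    positive.  If the centered matrix has zero total variance (all rows
    identical) the result is explicitly degenerate: no components.
    """
    if matrix.shape[0] < 2:
        raise ValueError("PCA needs at least 2 individuals")
    x = matrix.to_numpy(dtype=float)
    cols = list(matrix.columns)
    dropped: list[str] = []
    std = x.std(axis=0, ddof=1)
    if scale:
        keep = std > 0
        if not keep.all():
            dropped = [c for c, k in zip(cols, keep) if not k]
            warnings.warn(f"dropping zero-variance column(s) {dropped} before scaling", stacklevel=2)
            x, std = x[:, keep], std[keep]
            cols = [c for c, k in zip(cols, keep) if k]
    if len(cols) < 2:
        raise ValueError("PCA needs at least 2 usable columns")

    mean = x.mean(axis=0) if center else np.zeros(x.shape[1])
    scale_ = std if scale else np.ones(x.shape[1])
    xc = (x - mean) / scale_
    if not np.any(np.abs(xc - xc[0]) > 1e-12):  # all rows identical
        return PCAResult(
            scores=pd.DataFrame(index=matrix.index),
            loadings=pd.DataFrame(index=cols),
            variance_explained=np.empty(0),
            preprocessing={"center": center, "scale_applied": scale, "mean": mean, "scale": scale_, "dropped": dropped},
        )

    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    # deterministic sign: largest-magnitude loading positive per component
    for j in range(vt.shape[0]):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    scores = u * s
    var = s**2 / np.sum(s**2)
    comp_names = [f"PC{i + 1}" for i in range(len(s))]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=comp_names),
        loadings=pd.DataFrame(vt.T, index=cols, columns=comp_names),
        variance_explained=var,
        preprocessing={"center": center, "scale_applied": scale, "mean": mean, "scale": scale_, "dropped": dropped},
    )


@dataclass(frozen=True)
class SeparationReport:
    """Mean silhouette of group labels on PC1-2 and its permutation p."""

    silhouette: float
    permutation_p: float
    n_permutations: int

    def __post_init__(self) -> None:
        if not -1.0 <= self.silhouette <= 1.0:
            raise ValueError("silhouette must lie in [-1, 1]")
        if not 0.0 < self.permutation_p <= 1.0:
            raise ValueError("permutation_p must lie in (0, 1]")


def separation(
    scores: pd.DataFrame,
    labels,
    n_permutations: int = 999,
    seed: int = 0,
) -> SeparationReport:
    """Quantify group separation on the first two score components.

    The permutation p-value is the add-one fraction of label shufflings
    whose mean silhouette is at least the observed one; at least two label
    classes with at least two members each are required.
    """
    lab = np.asarray(labels)
    if len(lab) != len(scores):
        raise ValueError("labels and scores must have equal length")
    classes, counts = np.unique(lab, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("need >= 2 label classes with >= 2 members each")
    if scores.shape[1] < 2:
        raise ValueError("need at least two score components")
    x = scores.iloc[:, :2].to_numpy(dtype=float)
    obs = float(silhouette_score(x, lab))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(lab)
        if len(np.unique(perm)) < 2:  # cannot happen, but keep silhouette safe
            continue
        if silhouette_score(x, perm) >= obs:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return SeparationReport(obs, p, n_permutations)


def plot_scores(
    result: PCAResult,
    diagnosis,
    ancestry=None,
    path: str | None = None,
):
    """PC1 vs PC2 scatter, colored by diagnosis, marker-shaped by ancestry."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if result.degenerate or result.scores.shape[1] < 2:
        raise ValueError("PCA result has fewer than two components")
    x = result.scores.iloc[:, 0]
    y = result.scores.iloc[:, 1]
    diagnosis = np.asarray(diagnosis)
    markers = ["o", "s", "^", "D", "v"]
    fig, ax = plt.subplots(figsize=(5, 4))
    colors = {d: f"C{i}" for i, d in enumerate(dict.fromkeys(diagnosis))}
    if ancestry is None:
        ancestry = np.array(["" for _ in diagnosis])
    else:
        ancestry = np.asarray(ancestry)
    marker_of = {a: markers[i % len(markers)] for i, a in enumerate(dict.fromkeys(ancestry))}
    seen = set()
    for i in range(len(x)):
        label = f"{diagnosis[i]}" + (f" / {ancestry[i]}" if ancestry[i] else "")
        ax.scatter(
            x.iloc[i], y.iloc[i],
            c=colors[diagnosis[i]], marker=marker_of[ancestry[i]],
            label=None if label in seen else label, edgecolor="k", linewidth=0.3,
        )
        seen.add(label)
    ve = result.variance_explained
    ax.set_xlabel(f"PC1 ({100 * ve[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * ve[1]:.1f}%)")
    ax.legend(fontsize=7, loc="best")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
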