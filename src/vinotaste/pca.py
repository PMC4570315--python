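"""Principal component analysis of the 24-colour feature matrix.

Mean-centred SVD only by default — the 24 features share units (RGB
counts), so autoscaling is off unless requested.  Loadings carry a fixed
sign convention (largest-magnitude element of each column positive) so
score plots are reproducible run to run.  Explained variance is reported
against the total variance of the data, and over all ``min(n-1, p)``
components sums to 100%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PcaModel", "fit_pca", "project", "score_plot"]


@dataclass
class PcaModel:
    mean: np.ndarray  # (p,)
    loadings: np.ndarray  # (p, k), orthonormal columns
    explained_variance_pct: np.ndarray  # (k,)
    scores: np.ndarray  # (n, k), training-data projections
    eigenvalues: np.ndarray  # (k,) sample variances along each PC
    scale: np.ndarray | None = None  # (p,) std devs when autoscaled

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def fit_pca(features: np.ndarray, n_components: int, autoscale: bool = False) -> PcaModel:
    """Fit PCA by SVD of the (optionally autoscaled) centred matrix."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D matrix")
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    max_k = min(n - 1, p)
    if not (1 <= n_components <= max_k):
        raise ValueError(f"n_components must be in [1, {max_k}]")
    mean = X.mean(axis=0)
    Xc = X - mean
    scale = None
    if autoscale:
        scale = Xc.std(axis=0, ddof=1)
        if np.any(scale == 0):
            raise ValueError("zero-variance column; cannot autoscale")
        Xc = Xc / scale
    total_var = float(np.sum(Xc**2) / (n - 1))
    if total_var == 0:
        raise ValueError("constant feature matrix has no principal components")
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = s**2 / (n - 1)
    loadings = vt[:n_components].T
    # sign convention: dominant element of each loading column positive
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(n_components)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = Xc @ loadings
    return PcaModel(
        mean=mean,
        loadings=loadings,
        explained_variance_pct=100.0 * eigvals[:n_components] / total_var,
        scores=scores,
        eigenvalues=eigvals[:n_components],
        scale=scale,
    )


def project(model: PcaModel, features: np.ndarray) -> np.ndarray:
    """Project new samples onto the fitted components."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != model.mean.size:
        raise ValueError(
            f"feature width {X.shape[1]} does not match model width {model.mean.size}"
        )
    Xc = X - model.mean
    if model.scale is not None:
        Xc = Xc / model.scale
    return Xc @ model.loadings


def score_plot(
    model: PcaModel,
    labels: list[str] | None = None,
    clusters: list[str] | None = None,
    pcs: tuple[int, int] = (1, 2),
    path=None,
):
    """PC-vs-PC scatter with optional sample labels; saves PNG if given a path."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    i, j = pcs[0] - 1, pcs[1] - 1
    fig, ax = plt.subplots(figsize=(6, 5))
    if clusters is not None:
        for cl in sorted(set(clusters)):
            sel = [k for k, c in enumerate(clusters) if c == cl]
            ax.scatter(model.scores[sel, i], model.scores[sel, j], label=cl, s=30)
        ax.legend()
    else:
        ax.scatter(model.scores[:, i], model.scores[:, j], s=30)
    if labels is not None:
        for k, lab in enumerate(labels):
            ax.annotate(lab, (model.scores[k, i], model.scores[k, j]), fontsize=6)
    ax.set_xlabel(f"PC{pcs[0]} ({model.explained_variance_pct[i]:.2f}%)")
    ax.set_ylabel(f"PC{pcs[1]} ({model.explained_variance_pct[j]:.2f}%)")
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
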