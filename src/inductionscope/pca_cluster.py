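"""PCA of SNV-transformed trajectories and PC1 score-band regime labels.

With trajectories on a common grid, the first principal component of the
SNV matrix captures the shape of the growth curve (timing of the rise),
and the second correlates with expression performance. Regime labelling by
PC1 score bands is therefore possible but inherently dataset-specific: the
score scale depends on the dataset that defined the components, so the
default band edges (2 and 4) are a configuration starting point, not
universal constants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from inductionscope.errors import InsufficientDataError
from inductionscope.preprocess import AlignedMatrix

REGIME_INSUFFICIENT = "insufficient"
REGIME_OPTIMAL = "optimal"
REGIME_TOO_STRONG = "too_strong"


@dataclass
class PCAResult:
    """Scores, loadings and the full explained-variance spectrum.

    ``variance_explained`` always covers the complete spectrum (percent,
    summing to 100) even when ``scores``/``loadings`` are truncated to the
    requested number of components. Each loading vector is sign-fixed so
    its largest-magnitude entry is positive.
    """

    scores: np.ndarray  # cultures x n_components
    loadings: np.ndarray  # n_components x grid points
    variance_explained: np.ndarray  # percent, full spectrum
    well_ids: list[str]

    def __post_init__(self) -> None:
        ve = np.asarray(self.variance_explained, dtype=float)
        if np.any(ve < -1e-12) or np.any(np.diff(ve) > 1e-9):
            raise ValueError("variance_explained must be non-negative and non-increasing")
        if abs(float(ve.sum()) - 100.0) > 1e-6:
            raise ValueError("variance_explained must sum to 100%")
        gram = self.loadings @ self.loadings.T
        if not np.allclose(gram, np.eye(self.loadings.shape[0]), atol=1e-8):
            raise ValueError("loading vectors must be orthonormal")


@dataclass
class PCScoreBands:
    """PC1 score thresholds separating the three induction regimes."""

    insufficient_below: float = 2.0
    too_strong_above: float = 4.0

    def __post_init__(self) -> None:
        if not self.insufficient_below < self.too_strong_above:
            raise ValueError("insufficient_below must be < too_strong_above")


def fit_pca(matrix: AlignedMatrix, n_components: int = 2) -> PCAResult:
    """Covariance PCA of the aligned SNV matrix.

    Columns are mean-centered before the decomposition (SNV centers rows,
    not columns); no column scaling is applied since all values are already
    on the SNV scale. Scores are the centered data projected on the
    loadings, so the full-rank reconstruction equals the centered data.
    """
    rows = matrix.rows
    if rows.shape[0] < 3:
        raise InsufficientDataError("PCA needs at least 3 cultures")
    if not 1 <= n_components <= min(rows.shape):
        raise ValueError(f"n_components must be in [1, {min(rows.shape)}]")
    pca = PCA(n_components=None, svd_solver="full")
    scores = pca.fit_transform(rows)
    loadings = pca.components_
    # sign convention: largest-magnitude entry of each loading is positive
    for k in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[k])))
        if loadings[k, j] < 0:
            loadings[k] *= -1.0
            scores[:, k] *= -1.0
    return PCAResult(
        scores=scores[:, :n_components],
        loadings=loadings[:n_components],
        variance_explained=pca.explained_variance_ratio_ * 100.0,
        well_ids=list(matrix.well_ids),
    )


def band_classify(result: PCAResult, bands: PCScoreBands | None = None) -> list[str]:
    """Label each culture by its PC1 score band.

    PC1 below ``insufficient_below`` → insufficient (growth close to the
    non-induced pattern); above ``too_strong_above`` → too strong (extended
    lag); in between → optimal.
    """
    if result.scores.shape[1] < 1:
        raise ValueError("PCAResult must retain at least one component")
    bands = bands or PCScoreBands()
    labels = []
    for pc1 in result.scores[:, 0]:
        if pc1 < bands.insufficient_below:
            labels.append(REGIME_INSUFFICIENT)
        elif pc1 > bands.too_strong_above:
            labels.append(REGIME_TOO_STRONG)
        else:
            labels.append(REGIME_OPTIMAL)
    return labels
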