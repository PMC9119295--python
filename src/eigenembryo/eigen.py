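"""Pixel-level principal component analysis of normalized embryo images.

This is the eigenface-style decomposition at the heart of the pipeline:
the n x 4096 pixel matrix is column-mean-centered (no variance scaling —
all pixels share brightness units) and factored by SVD. Each retained
component supplies

* a *basis image* — its 4096-vector of loadings reshaped to the 64x64
  frame, interpretable as the spatial brightness pattern the component
  emphasizes;
* a *contribution ratio* — the fraction of total pixel-brightness
  variance it explains;
* one *score* per embryo — the projection of that embryo's centered
  pixel vector onto the basis.

Component indexing is 1-based in all user-facing interfaces ("PC3" is
the third component). Component sign is fixed so the largest-magnitude
loading is positive, making the fit deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .preprocess import TARGET_SIDE, PixelMatrix

__all__ = ["EigenModel", "fit_pca", "basis_image", "render_basis_image", "project"]


@dataclass
class EigenModel:
    """Fitted eigenimage decomposition.

    Attributes
    ----------
    mean_vector : (4096,) array
        Per-pixel mean brightness of the training matrix.
    basis : (k, 4096) array
        Orthonormal component loadings, one row per component, ordered by
        decreasing explained variance.
    contribution_ratios : (k,) array
        Fraction of total centered variance per component; nonnegative,
        non-increasing, summing to <= 1.
    scores : (n, k) array
        Projections of the centered training rows onto the basis.
    ids : list of str
        Training-row identifiers aligned to ``scores`` rows.
    """

    mean_vector: np.ndarray
    basis: np.ndarray
    contribution_ratios: np.ndarray
    scores: np.ndarray
    ids: list[str] = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.basis.shape[0]

    @property
    def n(self) -> int:
        return self.scores.shape[0]

    def scores_frame(self) -> pd.DataFrame:
        """Scores as a DataFrame with 1-based ``pc1..pck`` columns."""
        return pd.DataFrame(
            self.scores, index=pd.Index(self.ids, name="id"),
            columns=[f"pc{j + 1}" for j in range(self.k)])

    def save(self, path: str | Path) -> None:
        np.savez_compressed(
            path, mean_vector=self.mean_vector, basis=self.basis,
            contribution_ratios=self.contribution_ratios, scores=self.scores,
            ids=np.asarray(self.ids, dtype=object))

    @classmethod
    def load(cls, path: str | Path) -> "EigenModel":
        with np.load(path, allow_pickle=True) as z:
            return cls(mean_vector=z["mean_vector"], basis=z["basis"],
                       contribution_ratios=z["contribution_ratios"],
                       scores=z["scores"], ids=[str(s) for s in z["ids"]])


def fit_pca(matrix: PixelMatrix) -> EigenModel:
    """Fit the pixel-brightness PCA on a pooled cohort.

    Columns are mean-centered (never scaled) and decomposed by SVD. All
    components with nonzero singular value are retained; a constant
    matrix therefore yields zero components. Contribution ratios are
    singular values squared over the total centered sum of squares.
    """
    X = matrix.values
    n = X.shape[0]
    if n < 2:
        raise ValueError("PCA needs at least 2 rows")
    mean = X.mean(axis=0)
    Xc = X - mean
    # n << 4096 in practice; thin SVD is exact and fast
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float(np.sum(s ** 2))
    if total <= 0:
        return EigenModel(mean_vector=mean, basis=np.empty((0, X.shape[1])),
                          contribution_ratios=np.empty(0),
                          scores=np.empty((n, 0)), ids=list(matrix.ids))
    keep = s > s[0] * 1e-12
    U, s, Vt = U[:, keep], s[keep], Vt[keep]
    ratios = s ** 2 / total
    scores = U * s
    # sign convention: largest-|loading| pixel of each component positive
    for j in range(Vt.shape[0]):
        pivot = np.argmax(np.abs(Vt[j]))
        if Vt[j, pivot] < 0:
            Vt[j] = -Vt[j]
            scores[:, j] = -scores[:, j]
    return EigenModel(mean_vector=mean, basis=Vt, contribution_ratios=ratios,
                      scores=scores, ids=list(matrix.ids))


def basis_image(model: EigenModel, component_index: int) -> np.ndarray:
    """Loadings of one component reshaped to the 64x64 frame (signed).

    ``component_index`` is 1-based: ``basis_image(model, 3)`` is the
    spatial pattern of PC3.
    """
    if not 1 <= component_index <= model.k:
        raise IndexError(
            f"component index {component_index} out of range 1..{model.k}")
    return model.basis[component_index - 1].reshape(TARGET_SIDE, TARGET_SIDE)


def render_basis_image(model: EigenModel, component_index: int,
                       path: str | Path | None = None) -> np.ndarray:
    """Min-max rendering of a basis image to 8-bit, optionally saved as PNG.

    The signed loadings are mapped linearly with min -> 0 and max -> 255;
    an all-equal component renders as a uniform mid-gray image.
    """
    img = basis_image(model, component_index)
    lo, hi = float(img.min()), float(img.max())
    if hi > lo:
        out = (img - lo) / (hi - lo) * 255.0
    else:
        out = np.full_like(img, 127.5)
    out = np.rint(out).astype(np.uint8)
    if path is not None:
        Image.fromarray(out).save(path)
    return out


def project(model: EigenModel, new_matrix: PixelMatrix | np.ndarray) -> np.ndarray:
    """Score new embryos with a trained basis: ``(rows - mean) @ basis.T``."""
    values = (new_matrix.values if isinstance(new_matrix, PixelMatrix)
              else np.asarray(new_matrix, dtype=float))
    if values.ndim == 1:
        values = values[None, :]
    if values.shape[1] != model.mean_vector.shape[0]:
        raise ValueError(
            f"column count {values.shape[1]} does not match the model's "
            f"{model.mean_vector.shape[0]} pixels")
    return (values - model.mean_vector) @ model.basis.T
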