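"""Image normalization: circular crop, 64x64 resize, pixel-matrix assembly.

Every embryo image is reduced to the same representation before the
eigen-decomposition: the circular region of interest (the zona pellucida
outline) is cut out of the micrograph, brightness outside the circle is
set to 0, the square crop is resized to 64 x 64 pixels to normalize the
embryo size, and the canonical inscribed-circle mask is re-applied so the
four corners stay exactly zero after interpolation. Each normalized image
is flattened row-major into a 4096-vector; a cohort stacks into an
``n x 4096`` matrix.

Coordinates are (row, col), 0-based, with pixel centers at integer
positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import resize

from .cohort import EmbryoRecord

__all__ = [
    "PixelMatrix",
    "load_image",
    "crop_circle",
    "resize_64",
    "canonical_mask",
    "build_matrix",
]

TARGET_SIDE = 64
N_PIXELS = TARGET_SIDE * TARGET_SIDE


@dataclass
class PixelMatrix:
    """Masked, resized, flattened brightness values for a cohort.

    Attributes
    ----------
    values : (n, 4096) float array
        One row per embryo; row-major flattening of the 64x64 image.
        Entries outside ``mask`` are exactly 0.
    ids : list of str
        Embryo identifiers aligned to rows.
    mask : (4096,) bool array
        The canonical inscribed-circle mask in the 64x64 frame.
    """

    values: np.ndarray
    ids: list[str]
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 2 or self.values.shape[1] != N_PIXELS:
            raise ValueError(f"values must be n x {N_PIXELS}")
        if len(self.ids) != self.values.shape[0]:
            raise ValueError("ids not aligned to rows")
        if self.mask.shape != (N_PIXELS,):
            raise ValueError(f"mask must have length {N_PIXELS}")
        if not np.isfinite(self.values).all():
            raise ValueError("pixel matrix contains non-finite values")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=pd.Index(self.ids, name="id"))
        df.columns = [f"px{j:04d}" for j in range(N_PIXELS)]
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PixelMatrix":
        df = pd.read_csv(path, index_col="id")
        return cls(values=df.to_numpy(dtype=float),
                   ids=[str(i) for i in df.index],
                   mask=canonical_mask().ravel())


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF micrograph as a 2-D grid scaled to [0, 255].

    RGB inputs are converted to luminance; 16-bit inputs are rescaled
    linearly from [0, 65535] to [0, 255]. Multi-frame files are rejected.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            if getattr(im, "n_frames", 1) > 1:
                raise ValueError(f"{path.name}: multi-frame images not supported")
            mode = im.mode
            if mode in ("RGB", "RGBA", "P", "LA"):
                arr = np.asarray(im.convert("RGB"), dtype=float)
                # ITU-R 601 luminance
                arr = arr @ np.array([0.299, 0.587, 0.114])
            elif mode in ("I;16", "I;16B", "I;16L", "I"):
                arr = np.asarray(im, dtype=float)
                arr = arr * (255.0 / 65535.0)
            elif mode in ("L", "1"):
                arr = np.asarray(im.convert("L"), dtype=float)
            elif mode == "F":
                arr = np.asarray(im, dtype=float)
            else:
                raise ValueError(f"{path.name}: unsupported image mode {mode!r}")
    except (OSError, SyntaxError) as exc:
        raise ValueError(f"cannot read image file {path}: {exc}") from exc
    if arr.ndim != 2:
        raise ValueError(f"{path.name}: expected a single-channel image")
    return np.clip(arr, 0.0, 255.0)


def crop_circle(image: np.ndarray, center: tuple[int, int],
                radius: int) -> np.ndarray:
    """Cut the ``(2r+1) x (2r+1)`` square around a circle, zeroing outside.

    Pixels whose center lies at Euclidean distance > ``radius`` from the
    circle center are set to 0; the boundary (distance == radius) is kept.
    """
    image = np.asarray(image, dtype=float)
    r0, c0 = int(center[0]), int(center[1])
    radius = int(radius)
    if radius < 1:
        raise ValueError("radius must be >= 1")
    n_rows, n_cols = image.shape
    if (r0 - radius < 0 or r0 + radius >= n_rows
            or c0 - radius < 0 or c0 + radius >= n_cols):
        raise ValueError(
            f"circle (center=({r0},{c0}), r={radius}) exits image bounds "
            f"{image.shape}")
    patch = image[r0 - radius:r0 + radius + 1,
                  c0 - radius:c0 + radius + 1].copy()
    offsets = np.arange(-radius, radius + 1, dtype=float)
    dist = np.hypot(offsets[:, None], offsets[None, :])
    patch[dist > radius] = 0.0
    return patch


def resize_64(image: np.ndarray) -> np.ndarray:
    """Bilinear resize to exactly 64 x 64; a 64x64 input passes through."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < 2:
        raise ValueError("input must be a 2-D grid of at least 2x2 pixels")
    if image.shape == (TARGET_SIDE, TARGET_SIDE):
        return image.copy()
    out = resize(image, (TARGET_SIDE, TARGET_SIDE), order=1, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    # bilinear interpolation is a convex combination of input pixels, but
    # guard against float round-off at the extremes
    return np.clip(out, image.min(), image.max())


def canonical_mask() -> np.ndarray:
    """Inscribed-circle mask of the 64x64 frame (True inside).

    Center (31.5, 31.5), radius 31.5: the disk touches all four frame
    edges, and the four corners are trimmed.
    """
    offsets = np.arange(TARGET_SIDE, dtype=float) - (TARGET_SIDE - 1) / 2.0
    dist = np.hypot(offsets[:, None], offsets[None, :])
    return dist <= (TARGET_SIDE - 1) / 2.0


def build_matrix(records: Sequence[EmbryoRecord],
                 remask_after_resize: bool = True) -> PixelMatrix:
    """Normalize every record and stack into a :class:`PixelMatrix`.

    Applies :func:`crop_circle` then :func:`resize_64` per record and, by
    default, re-zeroes outside the canonical inscribed circle so
    interpolation cannot leak brightness into the corners.
    """
    mask2d = canonical_mask()
    rows = []
    ids = []
    for rec in records:
        try:
            patch = crop_circle(rec.image, rec.roi_center, rec.roi_radius)
            small = resize_64(patch)
        except ValueError as exc:
            raise ValueError(f"preprocessing failed for record {rec.id!r}: {exc}"
                             ) from exc
        if remask_after_resize:
            small = np.where(mask2d, small, 0.0)
        rows.append(small.ravel())
        ids.append(rec.id)
    values = (np.vstack(rows) if rows
              else np.empty((0, N_PIXELS)))
    return PixelMatrix(values=values, ids=ids, mask=mask2d.ravel())
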