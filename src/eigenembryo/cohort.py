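"""Synthetic blastocyst cohorts.

Renders textured-disk phantoms that emulate day-5 blastocyst micrographs —
a circular embryo inside a brighter zona-pellucida ring on a dark
background — and simulates the clinical metadata the downstream analysis
consumes (hCG outcome, Gardner >=3BB call, fragmentation %, abortion,
maternal covariates).

Two latent morphology classes are rendered:

* ``grainy`` — the interior is a jittered-site cell mosaic with darkened
  cell boundaries, i.e. individual cells are visually distinct;
* ``non-grainy`` — the same mosaic is low-pass filtered (cells blur into
  each other, as when squashed cellular debris obscures boundaries) and
  overlaid with small low-contrast debris speckles.

Graininess is tied to early-cleavage fragmentation by a deterministic
rule: every embryo with fragmentation >= 20% is non-grainy, and only
non-grainy embryos can receive fragmentation >= 20%.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from PIL import Image
from scipy.ndimage import gaussian_filter

__all__ = [
    "CohortConfig",
    "EmbryoRecord",
    "render_embryo",
    "simulate_cohort",
    "save_cohort",
    "load_cohort",
    "paper_scale_config",
]

FRAG_NONGRAINY_THRESHOLD = 20.0  # % fragmentation at/above which morphology is non-grainy

_METADATA_COLUMNS = [
    "id", "hcg", "gardner", "frag_pct", "abortion", "age", "bmi", "amh",
    "eval_day", "roi_row", "roi_col", "roi_radius", "grainy_truth",
]

# Gardner score strings consistent with a >=3BB ("good quality") call and
# with a below-3BB call; sampled uniformly given the simulated binary flag.
_GARDNER_GOOD = ("3BB", "3AB", "4AA", "4AB", "4BB", "5AB")
_GARDNER_POOR = ("1", "2", "3BC", "3CB", "3CC", "4BC")


@dataclass(frozen=True)
class CohortConfig:
    """Generative parameters of a synthetic cohort.

    Defaults mirror the clinical cohort the analysis is designed for:
    129 hCG-positive and 105 hCG-negative single transfers, grainy
    morphology in 65% of positives and 38% of negatives, every non-grainy
    embryo carrying >=20% fragmentation, and a Gardner >=3BB call with
    sensitivity 0.96 / specificity 0.029 for the hCG outcome.
    """

    n_positive: int = 129
    n_negative: int = 105
    image_side: int = 256
    embryo_radius_range: tuple[int, int] = (80, 104)
    grain_contrast: float = 40.0
    smooth_sigma: float = 6.0
    p_grainy_given_pos: float = 0.65
    p_grainy_given_neg: float = 0.38
    frag_high_rate_nongrainy: float = 1.0
    gardner_sens: float = 0.96
    gardner_spec: float = 0.029
    abortion_rate: float = 0.248
    noise_sd: float = 4.0
    seed: int = 0
    # Draw per-stratum grainy/Gardner counts as round(p * n) instead of
    # Bernoulli, so cohort-level tallies are reproduced exactly.
    exact_strata: bool = False

    def validate(self) -> None:
        if self.n_positive < 0 or self.n_negative < 0:
            raise ValueError("cohort sizes must be nonnegative")
        if self.image_side < 64:
            raise ValueError("image_side must be >= 64")
        lo, hi = self.embryo_radius_range
        if not (8 <= lo <= hi):
            raise ValueError("embryo_radius_range must satisfy 8 <= min <= max")
        if hi >= self.image_side // 2 - 4:
            raise ValueError(
                f"max radius {hi} does not fit inside a {self.image_side}px canvas "
                "(4px jitter margin required)"
            )
        for name in ("p_grainy_given_pos", "p_grainy_given_neg",
                     "frag_high_rate_nongrainy", "gardner_sens",
                     "gardner_spec", "abortion_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("grain_contrast", "smooth_sigma", "noise_sd"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and nonnegative")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["embryo_radius_range"] = list(self.embryo_radius_range)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "embryo_radius_range" in d:
            d["embryo_radius_range"] = tuple(d["embryo_radius_range"])
        cfg = cls(**d)
        cfg.validate()
        return cfg


def paper_scale_config(seed: int = 0, **overrides) -> CohortConfig:
    """Default-size cohort (129 + 105) with exact per-stratum counts.

    With exact strata the cohort contains exactly 84 + 40 = 124 grainy and
    110 non-grainy embryos, all 110 non-grainy carrying >=20%
    fragmentation, and a Gardner >=3BB call on exactly 124 positives and
    102 negatives.
    """
    return CohortConfig(seed=seed, exact_strata=True, **overrides)


@dataclass
class EmbryoRecord:
    """One synthetic embryo: an 8-bit image, its circular ROI and labels."""

    id: str
    image: np.ndarray  # 2-D uint8
    roi_center: tuple[int, int]  # (row, col)
    roi_radius: int
    hcg: int
    grainy_truth: int | None = None
    gardner: str | None = None
    fragmentation_pct: float | None = None
    abortion: int | None = None
    age: float | None = None
    bmi: float | None = None
    amh: float | None = None
    eval_day: int | None = None

    def __post_init__(self) -> None:
        r, c = self.roi_center
        n_rows, n_cols = self.image.shape
        if not (r - self.roi_radius >= 0 and r + self.roi_radius < n_rows
                and c - self.roi_radius >= 0 and c + self.roi_radius < n_cols):
            raise ValueError(f"ROI circle of record {self.id!r} exits image bounds")
        if self.fragmentation_pct is not None and not 0 <= self.fragmentation_pct <= 100:
            raise ValueError("fragmentation_pct outside [0, 100]")
        if self.hcg not in (0, 1):
            raise ValueError("hcg must be 0 or 1")


def _mosaic_sites(radius: float, rng: np.random.Generator) -> np.ndarray:
    """Jittered-grid cell centers covering a disk of the given radius.

    Spacing ~ radius / 3.2 gives roughly 30 cells across the embryo
    cross-section, comparable to a day-5 blastocyst's visible cell count.
    """
    spacing = max(radius / 3.2, 3.0)
    coords = np.arange(-radius - spacing, radius + spacing + 1e-9, spacing)
    gy, gx = np.meshgrid(coords, coords, indexing="ij")
    sites = np.stack([gy.ravel(), gx.ravel()], axis=1)
    sites += rng.uniform(-0.45, 0.45, size=sites.shape) * spacing
    keep = np.hypot(sites[:, 0], sites[:, 1]) <= radius + spacing
    return sites[keep]


def render_embryo(
    grainy: bool,
    radius: int,
    grain_contrast: float = 40.0,
    smooth_sigma: float = 6.0,
    noise_sd: float = 4.0,
    rng: np.random.Generator | int | None = None,
    image_side: int = 256,
    center: tuple[int, int] | None = None,
) -> np.ndarray:
    """Render one textured-disk blastocyst phantom.

    Parameters
    ----------
    grainy
        Latent morphology class. Grainy interiors keep the full-contrast
        cell mosaic; non-grainy interiors are Gaussian-blurred with
        ``smooth_sigma`` and overlaid with low-contrast debris speckles.
    radius
        Embryo radius in pixels (>= 8); the outer ~14% is rendered as the
        brighter zona-pellucida ring.
    grain_contrast
        Amplitude (brightness units) of per-cell variation and boundary
        darkening; 0 yields a spatially constant interior.
    noise_sd
        SD of additive Gaussian sensor noise, in brightness units.
    rng
        Seed or ``numpy`` Generator; identical state gives bit-identical
        images.

    Returns
    -------
    ndarray
        ``image_side`` x ``image_side`` uint8 image.
    """
    if radius < 8:
        raise ValueError("radius must be >= 8 px")
    for name, v in (("grain_contrast", grain_contrast),
                    ("smooth_sigma", smooth_sigma), ("noise_sd", noise_sd)):
        if not np.isfinite(v) or v < 0:
            raise ValueError(f"{name} must be finite and nonnegative")
    rng = np.random.default_rng(rng)
    if center is None:
        center = (image_side // 2, image_side // 2)
    cr, cc = center
    if (cr - radius < 0 or cr + radius >= image_side
            or cc - radius < 0 or cc + radius >= image_side):
        raise ValueError(f"radius {radius} at center {center} exceeds the "
                         f"{image_side}px canvas")

    rows = np.arange(image_side, dtype=float)[:, None] - cr
    cols = np.arange(image_side, dtype=float)[None, :] - cc
    dist = np.hypot(rows, cols)

    interior_radius = radius * 0.86  # inner edge of the zona ring
    disk = dist <= radius
    interior = dist <= interior_radius
    ring = disk & ~interior

    background = 25.0
    interior_base = 120.0
    ring_level = 175.0

    # Cell mosaic over the full canvas (constant outside the interior so
    # that low-pass filtering cannot bleed ring/background values in).
    tex = np.full((image_side, image_side), interior_base)
    if interior.any():
        sites = _mosaic_sites(interior_radius, rng)
        cell_offsets = rng.uniform(-0.5, 0.5, size=len(sites)) * grain_contrast
        iy, ix = np.nonzero(interior)
        pts = np.stack([iy - float(cr), ix - float(cc)], axis=1)
        # distances to every site: |interior| x n_sites, both small
        d = np.hypot(pts[:, 0:1] - sites[None, :, 0], pts[:, 1:2] - sites[None, :, 1])
        first = np.argmin(d, axis=1)
        dpart = np.partition(d, 1, axis=1)
        d1, d2 = dpart[:, 0], dpart[:, 1]
        # darken near cell boundaries (where the two nearest sites are
        # nearly equidistant); width 1.5 px
        boundary = np.exp(-((d2 - d1) / 1.5) ** 2)
        tex[iy, ix] = interior_base + cell_offsets[first] - 0.9 * grain_contrast * boundary

    img = np.full((image_side, image_side), background)
    # soft radial shading on the ring so it reads as a translucent shell
    img[ring] = ring_level - 25.0 * (dist[ring] - interior_radius) / max(
        radius - interior_radius, 1e-9)
    img[interior] = tex[interior]

    if not grainy and smooth_sigma > 0:
        # Squashed cellular debris makes the embryo contents hazy: blend a
        # blurred copy over the interior, tapering the weight from 1 at the
        # inner edge of the zona to 0 at the embryo boundary, so cell
        # boundaries wash out and the inner zona edge softens while the
        # outer zona contour stays sharp. The blur strength varies between
        # embryos (debris load differs), so edge softening and interior
        # haze vary independently across the cohort.
        sigma_eff = smooth_sigma * rng.uniform(0.7, 1.3)
        blurred = gaussian_filter(img, sigma_eff, mode="nearest")
        w = np.clip((radius - dist) / max(radius - interior_radius, 1e-9),
                    0.0, 1.0)
        img = w * blurred + (1.0 - w) * img
    if not grainy:
        # translucent debris haze brightens the interior by a per-embryo
        # random amount (zero when grain_contrast is zero)
        haze = rng.uniform(0.05, 0.30) * grain_contrast
        img = img + np.where(interior, haze, 0.0)
        # small low-contrast debris speckles, amplitude tied to grain_contrast
        n_debris = rng.poisson(12)
        for _ in range(n_debris):
            ang = rng.uniform(0, 2 * np.pi)
            rad = np.sqrt(rng.uniform()) * interior_radius * 0.9
            dr = rad * np.sin(ang)
            dc = rad * np.cos(ang)
            size = rng.uniform(1.5, 3.5)
            amp = rng.uniform(-0.3, 0.3) * grain_contrast
            blob = np.exp(-((rows - dr) ** 2 + (cols - dc) ** 2)
                          / (2 * size ** 2))
            img = img + np.where(interior, amp * blob, 0.0)

    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def _round_count(p: float, n: int) -> int:
    return int(np.clip(round(p * n), 0, n))


def _stratum_flags(n: int, p: float, rng: np.random.Generator, exact: bool) -> np.ndarray:
    if exact:
        k = _round_count(p, n)
        flags = np.zeros(n, dtype=bool)
        flags[rng.permutation(n)[:k]] = True
        return flags
    return rng.uniform(size=n) < p


def simulate_cohort(config: CohortConfig) -> tuple[list[EmbryoRecord], pd.DataFrame]:
    """Draw a full synthetic cohort: images plus a metadata table.

    hCG status is assigned first (``n_positive`` positives then
    ``n_negative`` negatives); grainy morphology is drawn conditional on
    hCG; fragmentation respects the deterministic >=20% => non-grainy
    rule; the Gardner >=3BB flag is drawn from ``gardner_sens`` /
    ``gardner_spec`` independently of morphology. Fully reproducible from
    ``config.seed``.
    """
    config.validate()
    n = config.n_positive + config.n_negative
    root = np.random.SeedSequence(config.seed)
    meta_rng = np.random.default_rng(root.spawn(1)[0])
    embryo_seeds = root.spawn(n + 1)[1:]

    hcg = np.concatenate([np.ones(config.n_positive, dtype=int),
                          np.zeros(config.n_negative, dtype=int)])
    grainy = np.zeros(n, dtype=bool)
    grainy[hcg == 1] = _stratum_flags(config.n_positive, config.p_grainy_given_pos,
                                      meta_rng, config.exact_strata)
    grainy[hcg == 0] = _stratum_flags(config.n_negative, config.p_grainy_given_neg,
                                      meta_rng, config.exact_strata)

    gardner_flag = np.zeros(n, dtype=bool)
    gardner_flag[hcg == 1] = _stratum_flags(config.n_positive, config.gardner_sens,
                                            meta_rng, config.exact_strata)
    gardner_flag[hcg == 0] = _stratum_flags(config.n_negative, 1 - config.gardner_spec,
                                            meta_rng, config.exact_strata)

    records: list[EmbryoRecord] = []
    rows = []
    lo, hi = config.embryo_radius_range
    for i in range(n):
        rng = np.random.default_rng(embryo_seeds[i])
        is_grainy = bool(grainy[i])
        # fragmentation: >=20% forces (and is restricted to) non-grainy
        if not is_grainy and rng.uniform() < config.frag_high_rate_nongrainy:
            frag = float(np.round(rng.uniform(FRAG_NONGRAINY_THRESHOLD, 80.0), 1))
        else:
            frag = float(np.round(rng.uniform(0.0, 15.0), 1))
        gardner = str(rng.choice(_GARDNER_GOOD if gardner_flag[i] else _GARDNER_POOR))
        abortion = (int(rng.uniform() < config.abortion_rate)
                    if hcg[i] == 1 else None)
        age = float(np.round(np.clip(
            rng.normal(33.3 if is_grainy else 34.0, 3.1 if is_grainy else 3.3),
            20, 49), 1))
        bmi = float(np.round(np.clip(rng.normal(21.5, 2.5), 15, 40), 1))
        amh = float(np.round(rng.lognormal(1.1, 0.6), 2))
        eval_day = int(rng.choice([5, 6, 7], p=[0.8, 0.15, 0.05]))

        radius = int(rng.integers(lo, hi + 1))
        c0 = config.image_side // 2
        jitter = 4
        cr = int(c0 + rng.integers(-jitter, jitter + 1))
        cc = int(c0 + rng.integers(-jitter, jitter + 1))
        image = render_embryo(
            is_grainy, radius,
            grain_contrast=config.grain_contrast,
            smooth_sigma=config.smooth_sigma,
            noise_sd=config.noise_sd,
            rng=rng, image_side=config.image_side, center=(cr, cc),
        )
        rec = EmbryoRecord(
            id=f"emb{i:04d}", image=image, roi_center=(cr, cc), roi_radius=radius,
            hcg=int(hcg[i]), grainy_truth=int(is_grainy), gardner=gardner,
            fragmentation_pct=frag, abortion=abortion, age=age, bmi=bmi,
            amh=amh, eval_day=eval_day,
        )
        records.append(rec)
        rows.append({
            "id": rec.id, "hcg": rec.hcg, "gardner": rec.gardner,
            "frag_pct": frag, "abortion": abortion, "age": age, "bmi": bmi,
            "amh": amh, "eval_day": eval_day, "roi_row": cr, "roi_col": cc,
            "roi_radius": radius, "grainy_truth": rec.grainy_truth,
        })
    meta = pd.DataFrame(rows, columns=_METADATA_COLUMNS)
    return records, meta


def save_cohort(records: Sequence[EmbryoRecord], meta: pd.DataFrame,
                directory: str | Path, image_format: str = "png") -> Path:
    """Write one image file per embryo plus ``metadata.csv``."""
    directory = Path(directory)
    (directory / "images").mkdir(parents=True, exist_ok=True)
    if image_format not in ("png", "tiff"):
        raise ValueError("image_format must be 'png' or 'tiff'")
    for rec in records:
        Image.fromarray(rec.image).save(
            directory / "images" / f"{rec.id}.{image_format}")
    meta.to_csv(directory / "metadata.csv", index=False)
    return directory


def load_cohort(directory: str | Path) -> tuple[list[EmbryoRecord], pd.DataFrame]:
    """Read a cohort written by :func:`save_cohort`."""
    from .preprocess import load_image

    directory = Path(directory)
    meta = pd.read_csv(directory / "metadata.csv")
    records = []
    for row in meta.itertuples(index=False):
        matches = sorted((directory / "images").glob(f"{row.id}.*"))
        if not matches:
            raise FileNotFoundError(f"no image file for record {row.id!r}")
        image = load_image(matches[0]).astype(np.uint8)
        records.append(EmbryoRecord(
            id=row.id, image=image,
            roi_center=(int(row.roi_row), int(row.roi_col)),
            roi_radius=int(row.roi_radius), hcg=int(row.hcg),
            grainy_truth=(int(row.grainy_truth)
                          if pd.notna(row.grainy_truth) else None),
            gardner=row.gardner if pd.notna(row.gardner) else None,
            fragmentation_pct=(float(row.frag_pct)
                               if pd.notna(row.frag_pct) else None),
            abortion=int(row.abortion) if pd.notna(row.abortion) else None,
            age=float(row.age) if pd.notna(row.age) else None,
            bmi=float(row.bmi) if pd.notna(row.bmi) else None,
            amh=float(row.amh) if pd.notna(row.amh) else None,
            eval_day=int(row.eval_day) if pd.notna(row.eval_day) else None,
        ))
    return records, meta
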