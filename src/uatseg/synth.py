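"""Synthetic ophthalmic-like segmentation datasets.

Three presets emulate, at desk scale, the geometry of the three retinal
segmentation tasks the uncertainty-aware training pipeline targets:

* ``ga_like`` — irregular bright lesions: a union of 2–5 overlapping random
  ellipses on a darker background (geographic-atrophy-like);
* ``cup_like`` — a bright ellipse nested inside a larger, dimmer concentric
  ellipse (optic cup within optic disc); the cup is the foreground;
* ``faz_like`` — a small central dark blob with radial dark line textures
  (foveal avascular zone surrounded by vessels).

Each sample carries a controllable boundary ambiguity: the rendered
intensity edge is Gaussian-blurred (``boundary_sigma``), and mask labels in
a band of half-width ``label_flip_band`` pixels around the true edge are
flipped independently with probability 0.5 — irreducible annotation noise
concentrated exactly where real graders disagree. Generation is bit-exact
reproducible from (preset, n, seed).

Datasets are written as 8-bit PNG image/mask pairs plus a manifest CSV, and
split four ways (train/test/calibration/validation) by seeded
largest-remainder apportionment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

__all__ = [
    "SynthPreset",
    "SplitSpec",
    "SynthSample",
    "preset",
    "generate_dataset",
    "split_dataset",
    "write_dataset",
    "read_dataset",
    "boundary_distance",
]



@dataclass(frozen=True)
class SynthPreset:
    """Generation parameters for one synthetic task."""

    name: str
    image_size: int = 64
    fg_fraction_range: tuple[float, float] = (0.05, 0.25)
    boundary_sigma: float = 1.5
    noise_sd: float = 0.05
    label_flip_band: float = 1.5

    def __post_init__(self):
        if self.name not in ("ga_like", "cup_like", "faz_like"):
            raise ValueError(f"unknown preset name {self.name!r}")
        if self.image_size % 4:
            raise ValueError("image_size must be divisible by 4")
        lo, hi = self.fg_fraction_range
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError("fg_fraction_range must satisfy 0 < min <= max < 1")
        if self.boundary_sigma < 0 or self.label_flip_band < 0 or self.noise_sd < 0:
            raise ValueError("sigma, noise and flip band must be >= 0")


_PRESET_DEFAULTS = {
    # fg range, boundary sigma, noise sd, flip band
    "ga_like": ((0.05, 0.25), 1.5, 0.05, 1.5),
    "cup_like": ((0.04, 0.12), 1.5, 0.05, 1.5),
    "faz_like": ((0.01, 0.05), 1.0, 0.05, 1.0),
}


def preset(name: str, image_size: int = 64, **overrides) -> SynthPreset:
    """Named preset with task-appropriate defaults; keyword overrides allowed."""
    if name not in _PRESET_DEFAULTS:
        raise ValueError(f"unknown preset name {name!r}")
    fg, sigma, noise, band = _PRESET_DEFAULTS[name]
    base = SynthPreset(name=name, image_size=image_size, fg_fraction_range=fg,
                       boundary_sigma=sigma, noise_sd=noise, label_flip_band=band)
    return replace(base, **overrides) if overrides else base


@dataclass(frozen=True)
class SplitSpec:
    """Four-way split proportions (train, test, calibration, validation).

    Fractions must sum to 1; use :meth:`from_counts` for ratio-style splits
    such as 50/40/10/10 image counts (normalised by their sum).
    """

    fractions: tuple[float, float, float, float] = (50 / 110, 40 / 110, 10 / 110, 10 / 110)
    seed: int = 0

    def __post_init__(self):
        fr = tuple(float(f) for f in self.fractions)
        if len(fr) != 4 or any(f < 0 for f in fr):
            raise ValueError("need four nonnegative fractions")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1 (within 1e-9)")
        object.__setattr__(self, "fractions", fr)

    @classmethod
    def from_counts(cls, train, test, calibration, validation, seed: int = 0):
        total = train + test + calibration + validation
        return cls(tuple(c / total for c in (train, test, calibration, validation)),
                   seed=seed)


@dataclass
class SynthSample:
    """One generated image/mask pair.

    ``clean_mask`` is the unflipped ground-truth shape (available only for
    in-session generated samples, not after a disk round-trip); ``meta``
    records preset name, per-sample seed and the stored-mask foreground
    fraction.
    """

    image: np.ndarray
    mask: np.ndarray
    meta: dict = field(default_factory=dict)
    clean_mask: np.ndarray | None = None


def _ellipse(size: int, cx, cy, a, b, theta) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    xr = (xx - cx) * math.cos(theta) + (yy - cy) * math.sin(theta)
    yr = -(xx - cx) * math.sin(theta) + (yy - cy) * math.cos(theta)
    return (xr / a) ** 2 + (yr / b) ** 2 <= 1.0


def _draw_shape(p: SynthPreset, rng: np.random.Generator):
    """Return (clean foreground mask, clean intensity image in [0,1])."""
    s = p.image_size
    if p.name == "ga_like":
        n_lobes = rng.integers(2, 6)
        shape = np.zeros((s, s), dtype=bool)
        cx0, cy0 = rng.uniform(0.3 * s, 0.7 * s, size=2)
        for _ in range(n_lobes):
            cx = cx0 + rng.uniform(-0.12 * s, 0.12 * s)
            cy = cy0 + rng.uniform(-0.12 * s, 0.12 * s)
            a = rng.uniform(0.06 * s, 0.18 * s)
            b = rng.uniform(0.06 * s, 0.18 * s)
            shape |= _ellipse(s, cx, cy, a, b, rng.uniform(0, math.pi))
        img = np.where(shape, 0.75, 0.25)
    elif p.name == "cup_like":
        cx, cy = rng.uniform(0.4 * s, 0.6 * s, size=2)
        disc_a = rng.uniform(0.22 * s, 0.32 * s)
        disc_b = disc_a * rng.uniform(0.85, 1.15)
        ratio = rng.uniform(0.45, 0.65)
        theta = rng.uniform(0, math.pi)
        disc = _ellipse(s, cx, cy, disc_a, disc_b, theta)
        cup = _ellipse(s, cx, cy, ratio * disc_a, ratio * disc_b, theta)
        shape = cup
        img = np.full((s, s), 0.3)
        img[disc] = 0.65
        img[cup] = 0.9
    else:  # faz_like
        cx, cy = rng.uniform(0.45 * s, 0.55 * s, size=2)
        a = rng.uniform(0.06 * s, 0.13 * s)
        b = a * rng.uniform(0.8, 1.25)
        shape = _ellipse(s, cx, cy, a, b, rng.uniform(0, math.pi))
        img = np.full((s, s), 0.7)
        yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
        ang = np.arctan2(yy - cy, xx - cx)
        rad = np.hypot(yy - cy, xx - cx)
        n_vessels = rng.integers(5, 9)
        for theta in rng.uniform(-math.pi, math.pi, size=n_vessels):
            dtheta = np.abs(np.angle(np.exp(1j * (ang - theta))))
            vessel = (dtheta * np.maximum(rad, 1.0) < 1.2) & ~shape
            img[vessel] = 0.35
        img[shape] = 0.2
    return shape, img


def _flip_band_mask(shape: np.ndarray, band: float) -> np.ndarray:
    """Pixels within ``band`` px of the foreground/background boundary."""
    if band <= 0 or not shape.any() or shape.all():
        return np.zeros_like(shape, dtype=bool)
    dist_in = ndimage.distance_transform_edt(shape)
    dist_out = ndimage.distance_transform_edt(~shape)
    return (shape & (dist_in <= band)) | (~shape & (dist_out <= band))


def boundary_distance(clean_mask: np.ndarray) -> np.ndarray:
    """Per-pixel Euclidean distance to the true foreground boundary."""
    m = clean_mask.astype(bool)
    dist_in = ndimage.distance_transform_edt(m)
    dist_out = ndimage.distance_transform_edt(~m)
    return np.where(m, dist_in, dist_out)


def generate_dataset(p: SynthPreset, n: int, seed: int) -> list[SynthSample]:
    """Generate ``n`` reproducible samples for a preset.

    Each sample: draw the clean shape (rejection-sampled until the stored
    mask's foreground fraction falls in ``fg_fraction_range``, at most 100
    attempts), render the intensity image, blur the edge, add clipped
    Gaussian noise, and flip mask labels in the boundary band with
    probability 0.5.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    root = np.random.SeedSequence(seed)
    samples = []
    for idx, child in enumerate(root.spawn(n)):
        rng = np.random.default_rng(child)
        lo, hi = p.fg_fraction_range
        for attempt in range(100):
            shape, img = _draw_shape(p, rng)
            band = _flip_band_mask(shape, p.label_flip_band)
            flips = band & (rng.random(shape.shape) < 0.5)
            mask = shape ^ flips
            frac = mask.mean()
            if lo <= frac <= hi:
                break
        else:
            raise RuntimeError(
                f"could not draw a {p.name} shape with foreground fraction in "
                f"[{lo}, {hi}] after 100 attempts"
            )
        if p.boundary_sigma > 0:
            img = ndimage.gaussian_filter(img, p.boundary_sigma)
        if p.noise_sd > 0:
            img = img + rng.normal(0.0, p.noise_sd, size=img.shape)
        img = np.clip(img, 0.0, 1.0)
        samples.append(SynthSample(
            image=img,
            mask=mask.astype(np.uint8),
            meta={"preset": p.name, "sample_seed": int(idx), "dataset_seed": int(seed),
                  "fg_fraction": float(frac)},
            clean_mask=shape.astype(np.uint8),
        ))
    return samples


def _apportion(n: int, fractions) -> list[int]:
    """Largest-remainder apportionment of n over the fractions (sums to n)."""
    targets = [f * n for f in fractions]
    sizes = [math.floor(t) for t in targets]
    remainder = n - sum(sizes)
    order = sorted(range(len(fractions)), key=lambda i: (targets[i] - sizes[i]),
                   reverse=True)
    for i in order[:remainder]:
        sizes[i] += 1
    return sizes


def split_dataset(samples, spec: SplitSpec):
    """Seeded random four-way partition (train, test, calibration, validation).

    Sizes come from largest-remainder apportionment of the split fractions
    over ``len(samples)``; every split must end up nonempty.
    """
    n = len(samples)
    if n < 4:
        raise ValueError("need at least 4 samples for a four-way split")
    sizes = _apportion(n, spec.fractions)
    if any(s == 0 for s in sizes):
        raise ValueError(
            f"split sizes {sizes} contain an empty split for n={n}; "
            "adjust fractions or dataset size"
        )
    order = np.random.default_rng(spec.seed).permutation(n)
    parts, start = [], 0
    for s in sizes:
        parts.append([samples[i] for i in order[start:start + s]])
        start += s
    return tuple(parts)


def write_dataset(samples, directory, splits=None) -> None:
    """Write images/ and masks/ PNG pairs plus manifest.csv.

    Images are 8-bit grayscale (intensity x 255, rounded); masks use {0, 255}.
    ``splits`` is an optional parallel list of split names per sample
    (defaults to "train").
    """
    from pathlib import Path

    directory = Path(directory)
    (directory / "images").mkdir(parents=True, exist_ok=True)
    (directory / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(samples):
        fname = f"sample_{i:05d}.png"
        img8 = np.round(np.clip(s.image, 0, 1) * 255.0).astype(np.uint8)
        Image.fromarray(img8, mode="L").save(directory / "images" / fname)
        Image.fromarray((s.mask.astype(np.uint8) * 255), mode="L").save(
            directory / "masks" / fname)
        rows.append({
            "filename": fname,
            "split": splits[i] if splits is not None else "train",
            "preset": s.meta.get("preset", ""),
            "seed": s.meta.get("sample_seed", i),
            "fg_fraction": s.meta.get("fg_fraction", float(np.mean(s.mask))),
        })
    pd.DataFrame(rows).to_csv(directory / "manifest.csv", index=False)


def read_dataset(directory) -> list[SynthSample]:
    """Read a dataset directory back into samples.

    Images quantised at 8 bits round-trip to within 1/255; masks are exact.
    RGB images are accepted and converted to grayscale by channel mean.
    The split name is carried in ``meta['split']``.
    """
    from pathlib import Path

    directory = Path(directory)
    manifest_path = directory / "manifest.csv"
    if not manifest_path.exists():
        raise FileNotFoundError(f"missing manifest: {manifest_path}")
    manifest = pd.read_csv(manifest_path)
    required = {"filename", "split", "preset", "seed", "fg_fraction"}
    if not required.issubset(manifest.columns):
        raise ValueError(
            f"manifest {manifest_path} is missing columns "
            f"{sorted(required - set(manifest.columns))}"
        )
    samples = []
    for row in manifest.itertuples(index=False):
        img_path = directory / "images" / row.filename
        mask_path = directory / "masks" / row.filename
        for path in (img_path, mask_path):
            if not path.exists():
                raise FileNotFoundError(f"manifest names missing file: {path}")
        img_arr = np.asarray(Image.open(img_path), dtype=np.float64)
        if img_arr.ndim == 3:
            img_arr = img_arr.mean(axis=2)
        img = img_arr / 255.0
        mask_arr = np.asarray(Image.open(mask_path))
        vals = np.unique(mask_arr)
        if not np.all(np.isin(vals, (0, 255))):
            raise ValueError(f"mask {mask_path} has values outside {{0, 255}}")
        samples.append(SynthSample(
            image=img,
            mask=(mask_arr == 255).astype(np.uint8),
            meta={"preset": row.preset, "sample_seed": int(row.seed),
                  "fg_fraction": float(row.fg_fraction), "split": row.split},
        ))
    return samples
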