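"""Dataset handling: patient-grouped splitting, paired geometric augmentation,
and a seeded synthetic gallbladder-phantom generator.

The phantom generator stands in for a private clinical CT cohort.  It emulates
the statistics that drive the segmentation problem rather than CT physics: a
single small hypodense ellipse (the gallbladder target, ~0.55% of pixels by
default) embedded in a large bright smoothly textured region (the liver),
plus distractor structures — including one ellipse of similar intensity to the
target, which exercises the characteristic failure mode of attention models on
look-alike neighbors.  Every phantom is fully determined by ``(seed, index)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse as draw_ellipse
from skimage.transform import AffineTransform, warp


class SplitError(ValueError):
    """Invalid split specification or too few patients."""


class PhantomError(ValueError):
    """Invalid phantom specification."""


@dataclass(eq=False)
class Sample:
    """One training/evaluation unit: image, binary mask, patient identifier."""

    image: np.ndarray
    mask: np.ndarray
    patient_id: str

    def __post_init__(self):
        self.image = np.asarray(self.image)
        self.mask = np.asarray(self.mask)
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask shapes must match")
        vals = np.unique(self.mask)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask must be strictly binary")


@dataclass
class SplitSpec:
    """Partition fractions; they must be positive and sum to one."""

    train_frac: float = 0.54
    val_frac: float = 0.06
    test_frac: float = 0.40

    def __post_init__(self):
        fracs = (self.train_frac, self.val_frac, self.test_frac)
        if any(f <= 0 for f in fracs):
            raise SplitError("split fractions must be positive")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise SplitError("split fractions must sum to 1")


@dataclass
class AugmentSpec:
    """Ranges for the four geometric augmentations, sampled uniformly.

    Defaults: rotation ±15°, shift ±10% of the side length, shear ±10°,
    zoom ±10%.
    """

    rotation_deg: tuple[float, float] = (-15.0, 15.0)
    shift_frac: tuple[float, float] = (-0.10, 0.10)
    shear_deg: tuple[float, float] = (-10.0, 10.0)
    zoom_frac: tuple[float, float] = (-0.10, 0.10)

    def __post_init__(self):
        for name in ("rotation_deg", "shift_frac", "shear_deg", "zoom_frac"):
            lo, hi = getattr(self, name)
            if not (np.isfinite(lo) and np.isfinite(hi)) or lo > hi:
                raise ValueError(f"invalid range for {name}")
        if self.zoom_frac[0] <= -1:
            raise ValueError("zoom lower bound must exceed -1")


@dataclass
class PhantomSpec:
    """Parameters of the synthetic phantom generator.

    ``fg_fraction_target`` is the expected foreground (gallbladder) pixel
    fraction; ``contrast`` the mean intensity gap between the liver region and
    the target ellipse (the gallbladder is hypodense relative to liver on CT);
    ``noise_sd`` the additive Gaussian noise level on [0, 1] intensities.
    """

    size: tuple[int, int] = (256, 256)
    fg_fraction_target: float = 0.0055
    contrast: float = 0.25
    noise_sd: float = 0.03
    n_background_structures: int = 3
    seed: int = 0

    def __post_init__(self):
        self.size = tuple(self.size)
        if not 0 < self.fg_fraction_target < 0.5:
            raise PhantomError("fg_fraction_target must lie in (0, 0.5)")
        if self.size[0] < 32 or self.size[1] < 32:
            raise PhantomError("phantom size must be at least 32x32")


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------


def _largest_remainder(n: int, fracs) -> list[int]:
    raw = [f * n for f in fracs]
    base = [math.floor(r) for r in raw]
    remaining = n - sum(base)
    # ties broken by partition order: train > val > test
    order = sorted(range(len(fracs)), key=lambda i: (-(raw[i] - base[i]), i))
    for i in order[:remaining]:
        base[i] += 1
    return base


def split_by_patient(
    samples: list[Sample], spec: SplitSpec, seed: int
) -> tuple[list[Sample], list[Sample], list[Sample]]:
    """Partition samples into train/val/test with patient-disjoint groups.

    Patient counts per partition follow largest-remainder rounding of the
    fractions.  Patients are sorted before shuffling, so the split depends
    only on the set of patient ids and the seed, not on sample order.
    """
    patients = sorted({s.patient_id for s in samples})
    if len(patients) < 3:
        raise SplitError("need at least 3 distinct patients to split")
    counts = _largest_remainder(
        len(patients), (spec.train_frac, spec.val_frac, spec.test_frac)
    )
    rng = np.random.default_rng(seed)
    shuffled = [patients[i] for i in rng.permutation(len(patients))]
    bounds = np.cumsum([0] + counts)
    groups = [set(shuffled[lo:hi]) for lo, hi in zip(bounds[:-1], bounds[1:])]
    parts: tuple[list[Sample], ...] = ([], [], [])
    for s in samples:
        for part, grp in zip(parts, groups):
            if s.patient_id in grp:
                part.append(s)
                break
    return parts


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------


def _paired_warp(
    image: np.ndarray,
    mask: np.ndarray,
    rotation_deg: float,
    shift: tuple[float, float],
    shear_deg: float,
    zoom_frac: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one affine transform (about the image center) to an image/mask
    pair: bilinear for the image, nearest-neighbor for the mask, constant 0
    fill outside the source."""
    h, w = image.shape
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    zoom = 1.0 + zoom_frac
    core = AffineTransform(
        rotation=np.deg2rad(rotation_deg),
        shear=np.deg2rad(shear_deg),
        scale=(zoom, zoom),
    )
    tform = (
        AffineTransform(translation=-center)
        + core
        + AffineTransform(translation=center + np.asarray(shift))
    )
    img_out = warp(
        image.astype(np.float64), tform.inverse, order=1, cval=0.0, preserve_range=True
    )
    mask_out = warp(
        mask.astype(np.float64), tform.inverse, order=0, cval=0.0, preserve_range=True
    )
    return img_out, (mask_out >= 0.5).astype(np.uint8)


def augment_pair(
    sample: Sample, spec: AugmentSpec, rng: np.random.Generator
) -> Sample:
    """One random draw of the rotation/shift/shear/zoom transform, applied
    identically to image and mask; the mask is re-binarized at 0.5."""
    h, w = sample.image.shape
    rot = rng.uniform(*spec.rotation_deg)
    shift = (
        rng.uniform(*spec.shift_frac) * w,
        rng.uniform(*spec.shift_frac) * h,
    )
    shear = rng.uniform(*spec.shear_deg)
    zoom = rng.uniform(*spec.zoom_frac)
    img, mask = _paired_warp(sample.image, sample.mask, rot, shift, shear, zoom)
    return Sample(img.astype(sample.image.dtype), mask, sample.patient_id)


def expand_training_set(
    samples: list[Sample],
    spec: AugmentSpec,
    copies_per_sample: int,
    seed: int,
) -> list[Sample]:
    """Pre-expanded augmentation: each sample is retained and followed by
    ``copies_per_sample`` augmented copies.  Reproducible given the seed."""
    if copies_per_sample < 0:
        raise ValueError("copies_per_sample must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for s in samples:
        out.append(s)
        for _ in range(copies_per_sample):
            out.append(augment_pair(s, spec, rng))
    return out


# ---------------------------------------------------------------------------
# phantom generator
# ---------------------------------------------------------------------------


def _smooth_noise(rng, shape, sigma):
    field_ = gaussian_filter(rng.standard_normal(shape), sigma)
    sd = field_.std()
    return field_ / sd if sd > 0 else field_


def _sample_ellipse(rng, area_px, h, w, center_box):
    """Random eccentricity/orientation ellipse of ~area_px pixels whose
    bounding circle stays inside the image; returns (rr, cc, params)."""
    ratio = rng.uniform(0.45, 0.95)
    a = math.sqrt(area_px / (math.pi * ratio))  # semi-major
    b = ratio * a
    angle = rng.uniform(0.0, math.pi)
    m = a + 2.0
    (r0, r1), (c0, c1) = center_box
    r0, c0 = max(r0, m), max(c0, m)
    r1, c1 = min(r1, h - 1 - m), min(c1, w - 1 - m)
    if r1 <= r0 or c1 <= c0:  # box too tight for this ellipse; center it
        r0 = r1 = h / 2.0
        c0 = c1 = w / 2.0
    rc = rng.uniform(r0, r1)
    cc_ = rng.uniform(c0, c1)
    rr, cc = draw_ellipse(rc, cc_, a, b, shape=(h, w), rotation=angle)
    return rr, cc, (rc, cc_, a)


def make_phantom(spec: PhantomSpec, index: int) -> Sample:
    """Generate one synthetic slice; fully determined by ``(spec.seed, index)``.

    The mask is a single filled ellipse targeting ``fg_fraction_target`` of
    the pixels (the drawn area is jittered ±15% around the target, so the
    mean over many phantoms concentrates on the target).
    """
    h, w = spec.size
    target_px = spec.fg_fraction_target * h * w
    if target_px < 6:
        raise PhantomError(
            "fg_fraction_target is unreachable at this size (fewer than ~6 pixels)"
        )
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed & 0x7FFFFFFF, index]))

    # liver-like bright region on a darker abdominal background
    img = 0.35 + 0.03 * _smooth_noise(rng, (h, w), sigma=max(8, h // 16))
    liver_r = rng.uniform(0.30, 0.38) * h
    liver_c_rad = rng.uniform(0.30, 0.38) * w
    liver_center = (h * rng.uniform(0.42, 0.52), w * rng.uniform(0.42, 0.52))
    lr, lc = draw_ellipse(
        liver_center[0],
        liver_center[1],
        liver_r,
        liver_c_rad,
        shape=(h, w),
        rotation=rng.uniform(0, math.pi),
    )
    liver_mask = np.zeros((h, w))
    liver_mask[lr, lc] = 1.0
    liver_soft = gaussian_filter(liver_mask, sigma=max(2, h // 64))
    liver_level = 0.65
    texture = 0.04 * _smooth_noise(rng, (h, w), sigma=2)
    img = img * (1 - liver_soft) + (liver_level + texture) * liver_soft

    # gallbladder target: hypodense ellipse inside the liver
    area = target_px * rng.uniform(0.85, 1.15)
    inner = 0.45
    box = (
        (liver_center[0] - inner * liver_r, liver_center[0] + inner * liver_r),
        (liver_center[1] - inner * liver_c_rad, liver_center[1] + inner * liver_c_rad),
    )
    rr, cc, (tr, tc, ta) = _sample_ellipse(rng, area, h, w, box)
    mask = np.zeros((h, w), dtype=np.uint8)
    mask[rr, cc] = 1
    tgt_soft = gaussian_filter(mask.astype(float), sigma=0.7)
    tgt_soft /= max(tgt_soft.max(), 1e-9)
    img = img * (1 - tgt_soft) + (liver_level - spec.contrast) * tgt_soft

    # distractors; the first mimics the target's intensity at half contrast
    for k in range(spec.n_background_structures):
        d_area = area * rng.uniform(1.5, 4.0)
        for _ in range(10):
            drr, dcc, (dr, dc, da) = _sample_ellipse(
                rng, d_area, h, w, ((0.1 * h, 0.9 * h), (0.1 * w, 0.9 * w))
            )
            if (dr - tr) ** 2 + (dc - tc) ** 2 > (da + ta + 3) ** 2:
                break
        else:
            continue
        d_mask = np.zeros((h, w))
        d_mask[drr, dcc] = 1.0
        d_soft = gaussian_filter(d_mask, sigma=0.7)
        d_soft /= max(d_soft.max(), 1e-9)
        if k == 0:
            level = liver_level - 0.5 * spec.contrast
        else:
            level = rng.choice([0.15, 0.8]) + rng.uniform(-0.03, 0.03)
        img = img * (1 - d_soft) + level * d_soft

    img = img + rng.normal(0.0, spec.noise_sd, size=(h, w))
    img = np.clip(img, 0.0, 1.0)
    return Sample(img.astype(np.float32), mask, f"P{index:05d}")


def make_phantom_dataset(
    n: int, spec: PhantomSpec, slices_per_patient: int = 5, start_index: int = 0
) -> list[Sample]:
    """``n`` phantoms with patient-grouped identifiers (consecutive slices
    share a synthetic patient), emulating a multi-slice-per-patient cohort."""
    out = []
    for i in range(start_index, start_index + n):
        s = make_phantom(spec, i)
        out.append(Sample(s.image, s.mask, f"P{i // slices_per_patient:04d}"))
    return out


# ---------------------------------------------------------------------------
# manifests and on-disk phantom sets
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["patient_id", "image_path", "mask_path", "partition"]


def write_phantom_set(
    out_dir,
    n: int,
    spec: PhantomSpec,
    slices_per_patient: int = 5,
) -> pd.DataFrame:
    """Write ``n`` phantoms as paired 16-bit PNGs plus a manifest CSV; the
    generator parameters are echoed to ``params.json``."""
    from . import preprocess

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(n):
        s = make_phantom(spec, i)
        img_p = out / f"img_{i:05d}.png"
        msk_p = out / f"mask_{i:05d}.png"
        preprocess.write_png(img_p, s.image)
        preprocess.write_png(msk_p, s.mask.astype(float))
        rows.append(
            {
                "patient_id": f"P{i // slices_per_patient:04d}",
                "image_path": img_p.name,
                "mask_path": msk_p.name,
                "partition": "",
            }
        )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out / "manifest.csv", index=False)
    (out / "params.json").write_text(
        json.dumps(
            {
                "n": n,
                "size": list(spec.size),
                "fg_fraction_target": spec.fg_fraction_target,
                "contrast": spec.contrast,
                "noise_sd": spec.noise_sd,
                "n_background_structures": spec.n_background_structures,
                "seed": spec.seed,
                "slices_per_patient": slices_per_patient,
            },
            indent=2,
        )
    )
    return manifest


def read_manifest_samples(manifest_path) -> list[Sample]:
    """Load image/mask pairs referenced by a manifest CSV (paths relative to
    the manifest's directory)."""
    from . import preprocess

    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    root = manifest_path.parent
    samples = []
    for _, row in df.iterrows():
        img = preprocess.read_png(root / row["image_path"]).pixels / 65535.0
        msk = (preprocess.read_png(root / row["mask_path"]).pixels > 32767).astype(
            np.uint8
        )
        samples.append(Sample(img.astype(np.float32), msk, str(row["patient_id"])))
    return samples
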