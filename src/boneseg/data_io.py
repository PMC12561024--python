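"""Dataset loading, resizing, augmentation and group-aware splitting.

Frames carry per-axis physical pixel spacing (mm/px) because non-square
resizes change the mm conversion of the distance metrics.  Labels are
binary centerline masks and are resized by a binary-preserving rule
(forward coordinate mapping on downscale, nearest neighbour on upscale).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
import numpy as np
from PIL import Image
from scipy import ndimage


@dataclass
class BModeFrame:
    pixels: np.ndarray                     # (H, W) float32 in [0, 1]
    pixel_spacing_mm: tuple[float, float]  # (row, col) mm per pixel
    source_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("frame intensities must lie in [0, 1]")
        if any(s <= 0 for s in self.pixel_spacing_mm):
            raise ValueError("pixel spacing must be positive")


@dataclass
class CenterlineMask:
    pixels: np.ndarray                     # (H, W) uint8 in {0, 1}
    pixel_spacing_mm: tuple[float, float]

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        vals = np.unique(self.pixels)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask must be binary {0, 1}")
        self.pixels = self.pixels.astype(np.uint8)

    @property
    def is_empty(self) -> bool:
        return not self.pixels.any()


@dataclass(frozen=True)
class AugmentConfig:
    """Stochastic augmentation recipe applied to a fraction of the samples.

    With probability ``augment_fraction`` a sample is augmented; each enabled
    operation (blur, rotate, shear, contrast) is then applied independently
    with probability 0.5.  Geometric ops warp image and mask identically;
    photometric ops touch the image only.
    """

    blur_sigma: float = 5.0
    rotation_deg: tuple[float, float] = (-10.0, 10.0)
    shear_factor: tuple[float, float] = (-0.2, 0.2)
    contrast_range: tuple[float, float] = (0.25, 1.75)
    augment_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self):
        for lo, hi in (self.rotation_deg, self.shear_factor, self.contrast_range):
            if lo > hi:
                raise ValueError("augmentation ranges must be ordered (lo <= hi)")
        if not 0.0 <= self.augment_fraction <= 1.0:
            raise ValueError("augment_fraction must be in [0, 1]")


def load_pair(image_path, label_path, target_size=(192, 192)):
    """Load an image/label PNG pair, resize, normalise, track spacing.

    The image is resized bilinearly then min-max rescaled to [0, 1]; the
    label by the binary-preserving mask rule.  PNGs carry no physical
    spacing, so this assumes 1 mm/px at native resolution; use
    :func:`load_pair_with_spacing` with the manifest's spacing instead.
    """
    return load_pair_with_spacing(image_path, label_path, 1.0, target_size)


def load_pair_with_spacing(image_path, label_path, spacing_mm,
                           target_size=(192, 192)):
    img = np.asarray(Image.open(image_path).convert("F"), dtype=np.float32)
    lab = np.asarray(Image.open(label_path).convert("L"))
    if img.shape != lab.shape:
        raise ValueError(f"image/label shape mismatch: {img.shape} vs {lab.shape}")
    lab = (lab > 0).astype(np.uint8)
    th, tw = target_size
    h, w = img.shape
    frame_px = _resize_bilinear(img, (th, tw))
    lo, hi = frame_px.min(), frame_px.max()
    frame_px = (frame_px - lo) / (hi - lo) if hi > lo else np.zeros_like(frame_px)
    lab_px = _resize_mask(lab, (th, tw))
    spacing = (float(spacing_mm) * h / th, float(spacing_mm) * w / tw)
    frame = BModeFrame(frame_px, spacing, source_id=str(image_path))
    mask = CenterlineMask(lab_px, spacing)
    return frame, mask


def _resize_bilinear(a, size):
    im = Image.fromarray(a.astype(np.float32), mode="F")
    return np.asarray(im.resize((size[1], size[0]), Image.BILINEAR),
                      dtype=np.float32)


def _resize_mask(a, size):
    """Binary-preserving mask resize.

    Downscaling uses forward coordinate mapping (every labelled source pixel
    marks its target cell) because inverse nearest sampling can skip a
    1-px-wide curve entirely; upscaling uses ordinary nearest neighbour.
    """
    th, tw = size
    h, w = a.shape
    if th <= h and tw <= w:
        out = np.zeros((th, tw), dtype=np.uint8)
        rr, cc = np.nonzero(a)
        if rr.size:
            out[(rr * th) // h, (cc * tw) // w] = 1
        return out
    im = Image.fromarray((a > 0).astype(np.uint8))
    return np.asarray(im.resize((tw, th), Image.NEAREST)).astype(np.uint8)


def augment(frame: BModeFrame, mask: CenterlineMask, cfg: AugmentConfig, rng,
            with_info: bool = False):
    """Paper-recipe augmentation of one sample.

    Returns a new (frame, mask); the inputs are untouched.  With
    ``with_info=True`` a dict describing the applied ops (including whether
    the mask became empty after warping) is appended to the return tuple.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    img = frame.pixels.copy()
    lab = mask.pixels.copy()
    info = {"augmented": False, "ops": [], "mask_emptied": False}

    if rng.random() < cfg.augment_fraction:
        info["augmented"] = True
        do_blur, do_rot, do_shear, do_contrast = rng.random(4) < 0.5
        angle = rng.uniform(*cfg.rotation_deg)
        shear = rng.uniform(*cfg.shear_factor)
        contrast = rng.uniform(*cfg.contrast_range)
        if do_rot or do_shear:
            mat = np.eye(2)
            if do_rot:
                th = np.deg2rad(angle)
                mat = mat @ np.array([[np.cos(th), -np.sin(th)],
                                      [np.sin(th), np.cos(th)]])
                info["ops"].append(("rotate", angle))
            if do_shear:
                mat = mat @ np.array([[1.0, shear], [0.0, 1.0]])
                info["ops"].append(("shear", shear))
            center = (np.array(img.shape) - 1) / 2.0
            offset = center - mat @ center
            img = ndimage.affine_transform(img, mat, offset=offset, order=1,
                                           mode="constant", cval=0.0)
            lab = ndimage.affine_transform(lab, mat, offset=offset, order=0,
                                           mode="constant", cval=0)
            img = np.clip(img, 0.0, 1.0)
            lab = (lab > 0).astype(np.uint8)
            if not lab.any() and mask.pixels.any():
                info["mask_emptied"] = True
        if do_blur:
            img = np.clip(ndimage.gaussian_filter(img, cfg.blur_sigma), 0.0, 1.0)
            info["ops"].append(("blur", cfg.blur_sigma))
        if do_contrast:
            m = img.mean()
            img = np.clip(m + contrast * (img - m), 0.0, 1.0)
            info["ops"].append(("contrast", contrast))

    out_frame = replace(frame, pixels=img)
    out_mask = CenterlineMask(lab, mask.pixel_spacing_mm)
    if with_info:
        return out_frame, out_mask, info
    return out_frame, out_mask


# ----------------------------------------------------------------------
# manifest handling and splitting
# ----------------------------------------------------------------------

def read_manifest(path) -> list[dict]:
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    for r in rows:
        r["is_empty"] = int(r["is_empty"])
        r["pixel_spacing_mm"] = float(r["pixel_spacing_mm"])
    return rows


def write_manifest(rows, path):
    if not rows:
        raise ValueError("empty manifest")
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)


def split_dataset(rows: list[dict], ratios=(0.8, 0.1, 0.1),
                  stratify_by="anatomy", group_by="group_id", seed=0):
    """Assign each manifest row a split in {train, val, test}.

    Groups (patients) are atomic: no group crosses splits.  Groups are
    clustered by their dominant stratum value; within each cluster with at
    least as many groups as splits, the first groups are dealt one to each
    split (largest ratio first) so every split sees every well-represented
    stratum, and the remainder go greedily to the split with the largest
    remaining image-count deficit.  Deterministic under ``seed``.
    """
    split_names = ("train", "val", "test")[:len(ratios)]
    ratios = np.asarray(ratios, dtype=float)
    ratios = ratios / ratios.sum()
    groups: dict[str, list[dict]] = {}
    for r in rows:
        groups.setdefault(r[group_by], []).append(r)
    if len(groups) < len(split_names):
        raise ValueError(f"need at least {len(split_names)} groups, "
                         f"got {len(groups)}")
    rng = np.random.default_rng(seed)
    total = len(rows)
    target = ratios * total
    counts = np.zeros(len(split_names))
    order_by_ratio = np.argsort(-ratios, kind="stable")

    # cluster groups by dominant stratum value
    clusters: dict[str, list[str]] = {}
    for gid, grows in groups.items():
        if stratify_by:
            vals, cnts = np.unique([r[stratify_by] for r in grows],
                                   return_counts=True)
            dom = str(vals[np.argmax(cnts)])
        else:
            dom = "all"
        clusters.setdefault(dom, []).append(gid)

    assignment: dict[str, int] = {}
    for dom in sorted(clusters):
        gids = sorted(clusters[dom])
        rng.shuffle(gids)
        for i, gid in enumerate(gids):
            if len(gids) >= len(split_names) and i < len(split_names):
                s = int(order_by_ratio[i])   # deal one to each split
            else:
                s = int(np.argmax(target - counts))
            assignment[gid] = s
            counts[s] += len(groups[gid])

    out = []
    for r in rows:
        r = dict(r)
        r["split"] = split_names[assignment[r[group_by]]]
        out.append(r)
    return out


def split_proportions(rows, key="anatomy"):
    """Per-split stratum proportions, for auditing a split."""
    out: dict[str, dict[str, float]] = {}
    for split in sorted({r["split"] for r in rows}):
        sub = [r for r in rows if r["split"] == split]
        vals, cnts = np.unique([r[key] for r in sub], return_counts=True)
        out[split] = {str(v): c / len(sub) for v, c in zip(vals, cnts)}
    return out
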