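"""Synthetic B-mode bone-phantom generator.

Renders grayscale images that mimic the appearance of bone in brightness-mode
ultrasound: a bright curvilinear echo at the periosteal surface, an acoustic
shadow beneath it (bone transmits almost no sound), multiplicative speckle,
horizontal soft-tissue layer boundaries, and brighter fascia-like distractor
lines above the bone — the structures that cause false positives in practice.
Each frame comes with a 1-pixel-wide centerline label marking the echo ridge,
or an empty label for frames without bone.

The model is an appearance phantom, not an acoustic simulation: the bone is a
quadratic arc with a Gaussian cross-profile, speckle is smoothed Rayleigh
multiplicative noise, and the probe sits at row 0 (depth grows with the row
index).
"""

from __future__ import annotations

import csv
import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

ANATOMIES = ("pelvis", "ribs_sternum", "radius_ulna", "humerus",
             "femur", "tibia_fibula")
AGE_GROUPS = ("<10", ">=10")

MANIFEST_COLUMNS = ("image_path", "label_path", "group_id", "anatomy",
                    "age_group", "is_empty", "pixel_spacing_mm")


@dataclass(frozen=True)
class PhantomConfig:
    """Rendering parameters of the bone phantom.

    ``bone_depth_range_px`` is the row interval for the bone apex (the
    shallowest point of the arc); ``None`` derives it as (0.30 H, 0.78 H)
    so the bone sits at mid-to-deep field like in vivo imaging at 2-6 cm.
    """

    height_px: int = 192
    width_px: int = 192
    pixel_spacing_mm: float = 0.2
    bone_depth_range_px: tuple[int, int] | None = None
    bone_curvature_range: tuple[float, float] = (0.001, 0.008)
    bone_brightness: float = 0.95
    bone_thickness_px: float = 1.5
    shadow_attenuation: float = 0.25
    speckle_scale: float = 0.35
    n_distractor_lines: int = 2
    gain_range: tuple[float, float] = (0.75, 1.25)
    empty_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.height_px <= 0 or self.width_px <= 0:
            raise ValueError("image dims must be positive")
        if not 0.0 <= self.empty_fraction <= 1.0:
            raise ValueError("empty_fraction must be in [0, 1]")
        if not 0.0 <= self.shadow_attenuation <= 1.0:
            raise ValueError("shadow_attenuation must be in [0, 1]")
        if not 0.0 < self.bone_brightness <= 1.0:
            raise ValueError("bone_brightness must be in (0, 1]")
        lo, hi = self.depth_range()
        if not (0 <= lo <= hi < self.height_px):
            raise ValueError("bone apex depth range must lie inside the image")

    def depth_range(self) -> tuple[int, int]:
        if self.bone_depth_range_px is not None:
            return self.bone_depth_range_px
        return int(0.30 * self.height_px), int(0.78 * self.height_px)


@dataclass
class PhantomSample:
    image: np.ndarray          # (H, W) float in [0, 1]
    label: np.ndarray          # (H, W) uint8 in {0, 1}
    anatomy: str
    age_group: str
    is_empty: bool
    pixel_spacing_mm: float


def _bone_curve(cfg: PhantomConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    """Column indices and (float) rows of the bone arc.

    The column span is clipped so the arc slope never exceeds 1 px/column,
    keeping the rasterised centerline a single 8-connected curve.
    """
    h, w = cfg.height_px, cfg.width_px
    lo, hi = cfg.depth_range()
    apex_row = rng.integers(lo, hi + 1)
    curv = rng.uniform(*cfg.bone_curvature_range)
    apex_col = rng.uniform(0.3 * w, 0.7 * w)
    max_half = min(0.45 * w, 0.5 / (2.0 * curv))  # slope = 2*curv*halfwidth <= 1
    half = rng.uniform(0.55, 1.0) * max_half
    c0 = int(np.clip(apex_col - half, 0, w - 2))
    c1 = int(np.clip(apex_col + half, c0 + 4, w - 1))
    cols = np.arange(c0, c1 + 1)
    rows = apex_row + curv * (cols - apex_col) ** 2
    keep = rows < h - 2
    cols, rows = cols[keep], rows[keep]
    if cols.size < 4:
        raise ValueError("bone arc would leave the image; adjust depth/curvature")
    return cols, rows


def _tissue_background(cfg: PhantomConfig, rng) -> np.ndarray:
    h, w = cfg.height_px, cfg.width_px
    depth = np.linspace(0.0, 1.0, h)[:, None]
    base = 0.28 - 0.08 * depth + np.zeros((h, w))
    # smooth horizontal soft-tissue layer boundaries
    for _ in range(rng.integers(2, 5)):
        r = rng.uniform(0.05, 0.95) * h
        amp = rng.uniform(0.015, 0.04)
        sig = rng.uniform(2.0, 5.0)
        rowprof = amp * np.exp(-0.5 * ((np.arange(h) - r) / sig) ** 2)
        base += rowprof[:, None]
    return base


def _speckle(cfg: PhantomConfig, shape, rng) -> np.ndarray:
    """Smoothed multiplicative Rayleigh speckle, unit mean, clipped tails."""
    ray = rng.rayleigh(scale=1.0, size=shape)
    ray = ndimage.gaussian_filter(ray, sigma=0.8)
    ray /= ray.mean()
    factor = 1.0 + cfg.speckle_scale * (ray - 1.0)
    return np.clip(factor, 0.4, 1.6)


def render_sample(cfg: PhantomConfig, rng) -> PhantomSample:
    """Render one frame and its centerline label.

    ``rng`` is a ``numpy.random.Generator``; identical generator state gives
    bit-identical output.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    h, w = cfg.height_px, cfg.width_px
    is_empty = bool(rng.random() < cfg.empty_fraction)

    label = np.zeros((h, w), dtype=np.uint8)
    img = _tissue_background(cfg, rng)
    img *= _speckle(cfg, (h, w), rng)

    if not is_empty:
        cols, rows = _bone_curve(cfg, rng)
        ridge_rows = np.round(rows).astype(int)
        label[ridge_rows, cols] = 1
        min_curve_row = int(ridge_rows.min())
    else:
        cols = rows = ridge_rows = None
        min_curve_row = h  # distractors may appear anywhere

    # fascia-like bright distractor lines, strictly above the bone
    rr = np.arange(h)[:, None]
    n_lines = rng.integers(1, cfg.n_distractor_lines + 1)
    top_limit = max(min_curve_row - 6, 8)
    for _ in range(n_lines):
        if top_limit <= 6:
            break
        r0 = rng.uniform(4, top_limit)
        tilt = rng.uniform(-0.05, 0.05)
        line_rows = r0 + tilt * np.arange(w)[None, :]
        amp = rng.uniform(0.25, 0.45) * cfg.bone_brightness
        sig = rng.uniform(0.8, 1.4)
        prof = amp * np.exp(-0.5 * ((rr - line_rows) / sig) ** 2)
        prof[top_limit:, :] = 0.0  # distractors never reach the bone rows
        img += prof

    if not is_empty:
        # acoustic shadow: attenuate everything below the bone in bone columns
        shadow = np.ones((h, w))
        onset = rows + 2.0 * cfg.bone_thickness_px
        below = rr >= onset[None, :]
        col_mask = np.zeros(w, bool)
        col_mask[cols] = True
        ramp = np.clip((rr - onset[None, :]) / 6.0, 0.0, 1.0)
        att = 1.0 - (1.0 - cfg.shadow_attenuation) * ramp
        shadow[:, cols] = np.where(below, att, 1.0)
        img *= shadow

        # bright periosteal echo: Gaussian cross-profile along the arc
        per_col_gain = 0.9 + 0.2 * rng.random(cols.size)
        echo = (cfg.bone_brightness * per_col_gain[None, :]
                * np.exp(-0.5 * ((rr - rows[None, :]) / cfg.bone_thickness_px) ** 2))
        img[:, cols] += echo

    gain = rng.uniform(*cfg.gain_range)
    img = img * gain
    # compress to [0, 1] by peak normalisation rather than hard clipping so
    # saturation cannot create intensity ties between bone and distractors
    peak = img.max()
    if peak > 1.0:
        img = img / peak
    img = np.clip(img, 0.0, 1.0)

    anatomy = str(rng.choice(ANATOMIES))
    age_group = str(rng.choice(AGE_GROUPS))
    return PhantomSample(image=img, label=label, anatomy=anatomy,
                         age_group=age_group, is_empty=is_empty,
                         pixel_spacing_mm=cfg.pixel_spacing_mm)


def generate_dataset(cfg: PhantomConfig, n_images: int, out_dir,
                     n_groups: int = 16, seed: int | None = None):
    """Write ``n_images`` image/label PNG pairs plus a CSV manifest.

    Samples are attributed to ``n_groups`` synthetic patients (groups); a
    group carries one age tag, mirroring how clinical frames cluster by
    patient.  Returns the manifest as a list of row dicts.
    """
    if n_images <= 0:
        raise ValueError("n_images must be positive")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "labels").mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(cfg.seed if seed is None else seed)
    group_ages = [str(master.choice(AGE_GROUPS)) for _ in range(n_groups)]
    group_of = master.integers(0, n_groups, size=n_images)

    rows = []
    for i in range(n_images):
        sample = render_sample(cfg, master)
        g = int(group_of[i])
        img_path = out_dir / "images" / f"img_{i:05d}.png"
        lab_path = out_dir / "labels" / f"lab_{i:05d}.png"
        Image.fromarray((sample.image * 255.0).round().astype(np.uint8)).save(img_path)
        Image.fromarray(sample.label * 255).save(lab_path)
        rows.append({
            "image_path": str(img_path),
            "label_path": str(lab_path),
            "group_id": f"g{g:03d}",
            "anatomy": sample.anatomy,
            "age_group": group_ages[g],
            "is_empty": int(sample.is_empty),
            "pixel_spacing_mm": cfg.pixel_spacing_mm,
        })

    manifest_path = out_dir / "manifest.csv"
    with open(manifest_path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(MANIFEST_COLUMNS))
        writer.writeheader()
        writer.writerows(rows)
    return rows


def render_arrays(cfg: PhantomConfig, n_images: int, n_groups: int = 16,
                  seed: int | None = None):
    """In-memory variant of :func:`generate_dataset` (no file IO).

    Returns a list of ``(PhantomSample, group_id)`` with the same seeded
    stream as the on-disk generator.
    """
    if n_images <= 0:
        raise ValueError("n_images must be positive")
    master = np.random.default_rng(cfg.seed if seed is None else seed)
    group_ages = [str(master.choice(AGE_GROUPS)) for _ in range(n_groups)]
    group_of = master.integers(0, n_groups, size=n_images)
    out = []
    for i in range(n_images):
        sample = render_sample(cfg, master)
        g = int(group_of[i])
        sample.age_group = group_ages[g]
        out.append((sample, f"g{g:03d}"))
    return out


def config_to_dict(cfg: PhantomConfig) -> dict:
    return dataclasses.asdict(cfg)
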