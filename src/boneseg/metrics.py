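"""Hard evaluation metrics for thin-curve segmentations.

Centerline Dice (clDice) is the harmonic mean of topology precision
(fraction of the prediction's skeleton lying inside the label mask) and
topology sensitivity (fraction of the label's skeleton lying inside the
prediction mask).  The distance metric is the *directed* mean surface
distance: for every label-skeleton point, the Euclidean distance (in mm,
per-axis spacing applied) to the nearest predicted-skeleton point,
averaged.  The signed probe-axis offset is the mean depth displacement of
the matched prediction relative to the label: positive when the prediction
sits shallower, i.e. toward the transducer at row 0.

Empty-set conventions (the formulas are undefined on empty skeletons):
both masks empty -> clDice 1 (a correctly silent prediction on an empty
label); exactly one empty -> clDice 0 (missed bone or false detection);
the distance metrics are undefined and excluded from aggregation in either
case, with exclusions counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from skimage.morphology import skeletonize as _sk_skeletonize


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """Morphological thinning to a 1-px-wide skeleton (uint8 in/out)."""
    mask = np.asarray(mask)
    vals = np.unique(mask)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("skeletonize expects a binary {0,1} mask")
    return _sk_skeletonize(mask.astype(bool)).astype(np.uint8)


@dataclass
class SegScores:
    cl_dice: float
    t_prec: float | None
    t_sens: float | None
    mean_surface_distance_mm: float | None
    signed_offset_mm: float | None
    n_label_points: int
    n_pred_points: int

    @property
    def msd_defined(self) -> bool:
        return self.mean_surface_distance_mm is not None


def cl_dice(pred: np.ndarray, label: np.ndarray) -> SegScores:
    """Topology precision/sensitivity and their harmonic mean.

    ``pred`` and ``label`` are binary masks (any thickness); skeletons are
    computed internally by morphological thinning.
    """
    pred = np.asarray(pred)
    label = np.asarray(label)
    if pred.shape != label.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {label.shape}")
    s_p = skeletonize(pred)
    s_l = skeletonize(label)
    pred_b = pred.astype(bool)
    label_b = label.astype(bool)
    n_sp = int(s_p.sum())
    n_sl = int(s_l.sum())
    if n_sp == 0 and n_sl == 0:
        return SegScores(1.0, None, None, None, None, 0, 0)
    if n_sp == 0 or n_sl == 0:
        return SegScores(0.0, None, None, None, None, n_sl, n_sp)
    t_prec = float((s_p.astype(bool) & label_b).sum()) / n_sp
    t_sens = float((s_l.astype(bool) & pred_b).sum()) / n_sl
    if t_prec + t_sens == 0.0:
        cld = 0.0
    else:
        cld = 2.0 * t_prec * t_sens / (t_prec + t_sens)
    return SegScores(cld, t_prec, t_sens, None, None, n_sl, n_sp)


def mean_surface_distance(pred: np.ndarray, label: np.ndarray,
                          spacing_mm) -> tuple[float | None, float | None]:
    """Directed (label -> prediction) mean skeleton distance, in mm.

    Returns ``(msd_mm, signed_offset_mm)``; both ``None`` when either
    skeleton is empty.  ``spacing_mm`` is scalar or per-axis (row, col).
    """
    spacing = np.broadcast_to(np.atleast_1d(np.asarray(spacing_mm, float)), (2,))
    if (spacing <= 0).any():
        raise ValueError("spacing must be positive")
    s_p = skeletonize(np.asarray(pred))
    s_l = skeletonize(np.asarray(label))
    pts_p = np.argwhere(s_p)
    pts_l = np.argwhere(s_l)
    if len(pts_p) == 0 or len(pts_l) == 0:
        return None, None
    d = cdist(pts_l * spacing, pts_p * spacing)
    nearest = d.argmin(axis=1)
    msd = float(d[np.arange(len(pts_l)), nearest].mean())
    # positive offset = prediction shallower (smaller row) than the label
    offset = float(((pts_l[:, 0] - pts_p[nearest, 0]) * spacing[0]).mean())
    return msd, offset


def score_pair(pred, label, spacing_mm) -> SegScores:
    """All per-image scores for one prediction/label pair."""
    scores = cl_dice(pred, label)
    msd, offset = mean_surface_distance(pred, label, spacing_mm)
    scores.mean_surface_distance_mm = msd
    scores.signed_offset_mm = offset
    return scores


@dataclass
class AggregateReport:
    """Mean +/- SD (sample SD, n-1) of the per-image scores, per stratum."""

    per_image: pd.DataFrame
    overall: dict = field(default_factory=dict)
    by_stratum: dict = field(default_factory=dict)
    n_msd_excluded: int = 0

    def format_table(self) -> str:
        def fmt(stats):
            return (f"clDice {stats['cl_dice_mean']:.2f} ± {stats['cl_dice_sd']:.2f}"
                    f" | MSD {stats['msd_mean']:.2f} ± {stats['msd_sd']:.2f} mm,"
                    f" {stats['offset_mean']:+.2f} mm"
                    if stats["n_msd"] else
                    f"clDice {stats['cl_dice_mean']:.2f} ± {stats['cl_dice_sd']:.2f}"
                    f" | MSD undefined")
        lines = [f"{'all':<12}" + fmt(self.overall)]
        for k in sorted(self.by_stratum):
            lines.append(f"{k:<12}" + fmt(self.by_stratum[k]))
        lines.append(f"(sample SD; {self.n_msd_excluded} image(s) excluded "
                     f"from distance aggregation)")
        return "\n".join(lines)


def _aggregate(df: pd.DataFrame) -> dict:
    msd = df["mean_surface_distance_mm"].dropna()
    off = df["signed_offset_mm"].dropna()
    return {
        "n": int(len(df)),
        "cl_dice_mean": float(df["cl_dice"].mean()),
        "cl_dice_sd": float(df["cl_dice"].std(ddof=1)) if len(df) > 1 else 0.0,
        "n_msd": int(len(msd)),
        "msd_mean": float(msd.mean()) if len(msd) else float("nan"),
        "msd_sd": float(msd.std(ddof=1)) if len(msd) > 1 else 0.0,
        "offset_mean": float(off.mean()) if len(off) else float("nan"),
    }


def evaluate_set(pairs, strata_key=None) -> AggregateReport:
    """Score a list of ``(pred, label, metadata)`` tuples.

    ``metadata`` must contain ``pixel_spacing_mm`` (scalar or per-axis) and,
    when ``strata_key`` is given, that key (e.g. ``age_group``).
    """
    if not pairs:
        raise ValueError("evaluate_set needs at least one pair")
    records = []
    for pred, label, meta in pairs:
        s = score_pair(pred, label, meta["pixel_spacing_mm"])
        rec = {
            "cl_dice": s.cl_dice, "t_prec": s.t_prec, "t_sens": s.t_sens,
            "mean_surface_distance_mm": s.mean_surface_distance_mm,
            "signed_offset_mm": s.signed_offset_mm,
            "n_label_points": s.n_label_points,
            "n_pred_points": s.n_pred_points,
        }
        if strata_key is not None:
            rec[strata_key] = meta.get(strata_key, "unknown")
        records.append(rec)
    df = pd.DataFrame.from_records(records)
    report = AggregateReport(per_image=df, overall=_aggregate(df))
    report.n_msd_excluded = int(df["mean_surface_distance_mm"].isna().sum())
    if strata_key is not None:
        for key, sub in df.groupby(strata_key):
            report.by_stratum[str(key)] = _aggregate(sub)
    return report
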