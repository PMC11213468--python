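"""Per-segment stain intensity, polarity metrics, Laurdan GP maps, and
nuclear marker quantification.

The polarity index of a cell is the downstream share of its summed
per-segment mean intensities,

    polarity_index = down / (up + mid + down),

so a uniformly stained cell scores exactly 1/3 and full downstream
confinement scores 1.  Intensities are background-subtracted means over each
segment mask, clipped at zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import SEGMENT_NAMES, CellGeometry, CellLabelMap

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentProfile",
    "GPImage",
    "estimate_background",
    "segment_intensity_profile",
    "profile_table",
    "polarity_test",
    "gp_map",
    "nuclear_intensity",
]


@dataclass
class SegmentProfile:
    """Per-segment mean intensity (upstream, mid_body, downstream) for one
    cell and stain channel, with the derived polarity index."""

    cell_id: int
    channel: str
    mean_intensity: tuple[float, float, float]
    polarity_index: float  # NaN when the intensity sum is zero (undefined)
    valid: bool = True
    clipped_pixels: int = 0

    @property
    def is_defined(self) -> bool:
        return self.valid and np.isfinite(self.polarity_index)


@dataclass
class GPImage:
    """Generalized-polarization image: per-pixel (I_ord - G*I_dis)/(I_ord + G*I_dis).

    Finite pixels lie in [-1, 1]; pixels whose denominator is zero are NaN.
    """

    gp: np.ndarray
    g_factor: float = 1.0


def estimate_background(image: np.ndarray, label_map: CellLabelMap) -> float:
    """Median intensity of background (label 0) pixels; 0 if none exist.

    Pass the *unfiltered* segmentation here: after border-cell filtering the
    dropped cells are relabeled 0 and would contaminate the background
    estimate with cell-body signal.
    """
    bg = np.asarray(image, dtype=float)[label_map.labels == 0]
    if bg.size == 0:
        logger.warning("no background pixels; background set to 0")
        return 0.0
    return float(np.median(bg))


def segment_intensity_profile(
    image: np.ndarray,
    geometry: CellGeometry,
    background: float = 0.0,
    channel: str = "stain",
) -> SegmentProfile:
    """Background-subtracted mean intensity over each of the three segments.

    Negative values after subtraction are clipped at zero; the number of
    clipped pixels is recorded on the profile.  A cell with an empty segment
    mask (pathological shape) is flagged invalid rather than dropped.
    """
    img = np.asarray(image, dtype=float)
    if img.shape != geometry.mask.shape:
        raise ValueError("image and mask shapes differ")
    means = []
    clipped = 0
    valid = True
    for seg in geometry.segment_masks:
        if not seg.any():
            valid = False
            means.append(np.nan)
            continue
        vals = img[seg] - background
        clipped += int((vals < 0).sum())
        means.append(float(np.clip(vals, 0, None).mean()))
    total = float(np.nansum(means))
    if valid and total > 0:
        pol = means[2] / total
    else:
        pol = float("nan")
    if clipped:
        logger.info("cell %d: %d pixel(s) clipped at 0 after background "
                    "subtraction", geometry.cell_id, clipped)
    return SegmentProfile(
        cell_id=geometry.cell_id,
        channel=channel,
        mean_intensity=(means[0], means[1], means[2]),
        polarity_index=pol,
        valid=valid,
        clipped_pixels=clipped,
    )


def profile_table(profiles: list[SegmentProfile]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "cell_id": p.cell_id,
            "channel": p.channel,
            "up_mean": p.mean_intensity[0],
            "mid_mean": p.mean_intensity[1],
            "down_mean": p.mean_intensity[2],
            "polarity_index": p.polarity_index,
            "valid": p.valid,
        }
        for p in profiles
    ])


def polarity_test(profiles: list[SegmentProfile]) -> dict:
    """Compare per-segment intensities across cells.

    Returns per-segment mean +/- SD, the one-way ANOVA F statistic and p-value
    over the three segments, and Tukey-HSD adjusted p-values for the three
    pairwise comparisons.  Cells with undefined profiles are excluded.
    """
    usable = [p for p in profiles if p.is_defined]
    if len(usable) < 2:
        raise ValueError("need at least 2 cells with defined profiles")
    arr = np.array([p.mean_intensity for p in usable])  # (n, 3)
    groups = [arr[:, k] for k in range(3)]
    summary = {
        name: {"mean": float(g.mean()), "sd": float(g.std(ddof=1))}
        for name, g in zip(SEGMENT_NAMES, groups)
    }
    if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
        f_stat, p_val = 0.0, 1.0
        pairwise = {f"{a}_vs_{b}": 1.0
                    for i, a in enumerate(SEGMENT_NAMES)
                    for b in SEGMENT_NAMES[i + 1:]}
    else:
        f_stat, p_val = stats.f_oneway(*groups)
        tukey = stats.tukey_hsd(*groups)
        pairwise = {}
        for i, a in enumerate(SEGMENT_NAMES):
            for j, b in enumerate(SEGMENT_NAMES):
                if j > i:
                    pairwise[f"{a}_vs_{b}"] = float(tukey.pvalue[i, j])
    return {
        "n_cells": len(usable),
        "per_segment": summary,
        "anova_F": float(f_stat),
        "anova_p": float(p_val),
        "tukey_p": pairwise,
    }


def two_group_test(a: np.ndarray, b: np.ndarray) -> dict:
    """Unpaired two-tailed t test between two groups of per-cell values."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(a, b)
    return {"t": float(t), "p": float(p),
            "mean_a": float(a.mean()), "mean_b": float(b.mean())}


def anova_null_calibration(n_sims: int = 10_000, n_cells: int = 12,
                           alpha: float = 0.05, seed: int = 0) -> float:
    """Empirical type-I error of the per-segment one-way ANOVA under a true
    null (all three segments drawn from one distribution).

    Runs the same F test that ``polarity_test`` applies, vectorized over
    ``n_sims`` simulated datasets of ``n_cells`` cells each; returns the
    fraction rejected at ``alpha``.  A calibrated test returns ~alpha.
    """
    rng = np.random.default_rng(seed)
    x = rng.normal(100.0, 10.0, (3, n_cells, n_sims))
    _, p = stats.f_oneway(x[0], x[1], x[2], axis=0)
    return float((p < alpha).mean())


def gp_map(
    ordered_channel: np.ndarray,
    disordered_channel: np.ndarray,
    g_factor: float = 1.0,
) -> GPImage:
    """Laurdan generalized polarization, GP = (I_ord - G*I_dis)/(I_ord + G*I_dis).

    Higher GP indicates a more ordered (rigid) membrane.  Pixels with zero
    denominator are NaN.  The G factor calibrates the two detection channels;
    default 1 (uncalibrated).
    """
    if g_factor <= 0:
        raise ValueError("g_factor must be positive")
    i_ord = np.asarray(ordered_channel, dtype=float)
    i_dis = np.asarray(disordered_channel, dtype=float)
    if i_ord.shape != i_dis.shape:
        raise ValueError("channel shapes differ")
    num = i_ord - g_factor * i_dis
    den = i_ord + g_factor * i_dis
    with np.errstate(divide="ignore", invalid="ignore"):
        gp = np.where(den != 0, num / den, np.nan)
    return GPImage(gp=gp, g_factor=g_factor)


def nuclear_intensity(
    marker_image: np.ndarray, nucleus_labels: np.ndarray
) -> pd.DataFrame:
    """Mean marker fluorescence per nucleus (e.g. nuclear NF-kB p65).

    Returns a table of nucleus_id, mean_intensity, area_px.  An empty label
    image yields an empty table with a warning.
    """
    img = np.asarray(marker_image, dtype=float)
    lab = np.asarray(nucleus_labels)
    if img.shape != lab.shape:
        raise ValueError("image and label shapes differ")
    ids = np.unique(lab)
    ids = ids[ids > 0]
    if ids.size == 0:
        logger.warning("no nuclei in label image; empty table returned")
        return pd.DataFrame(columns=["nucleus_id", "mean_intensity", "area_px"])
    flat_lab = lab.ravel()
    sums = np.bincount(flat_lab, weights=img.ravel())
    counts = np.bincount(flat_lab)
    return pd.DataFrame({
        "nucleus_id": ids,
        "mean_intensity": sums[ids] / counts[ids],
        "area_px": counts[ids],
    })
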