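"""GCaMP trace extraction, index-of-dispersion activity calling, peak
detection, and subcellular localization of calcium activity.

The activity statistic is the index of dispersion (IoD), the variance-to-mean
ratio of a background-subtracted fluorescence trace:

    IoD = s^2 / mean,   s^2 the sample (n-1) variance.

A constant trace has IoD 0; independent shot-noise (Poisson) samples have
IoD ~ 1; oscillatory calcium influx inflates the variance far above the mean,
so cells with IoD > 2 (default threshold) in any region are called active.
IoD is not scale-invariant (IoD(c*x) = c*IoD(x)), so traces must stay in
fixed units (background-subtracted camera units here) before thresholding.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, signal, stats

from .geometry import SEGMENT_NAMES, CellGeometry, CellLabelMap

logger = logging.getLogger(__name__)

__all__ = [
    "IntensityTrace",
    "ActivityCall",
    "REGIONS",
    "CATEGORIES",
    "extract_traces",
    "detrend",
    "index_of_dispersion",
    "classify_activity",
    "detect_peaks",
    "activity_summary",
    "correlate_aspect_activity",
]

REGIONS = ("whole",) + SEGMENT_NAMES
CATEGORIES = ("inactive", "upstream", "mid_body", "downstream", "whole_cell")


@dataclass
class IntensityTrace:
    """Uniformly sampled mean-ROI fluorescence (background-subtracted camera
    units) for one cell region."""

    values: np.ndarray
    frame_interval: float = 3.0  # seconds per frame
    cell_id: int = 0
    region: str = "whole"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("trace needs at least 2 frames")
        if not np.all(np.isfinite(v)):
            raise ValueError("trace contains missing/non-finite frames")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        self.values = v

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) * self.frame_interval


@dataclass
class ActivityCall:
    """Activity call for one cell: IoD per region, active flag, localization
    category and per-region peak counts."""

    cell_id: int
    iod: dict[str, float]
    active: bool
    category: str
    peak_count: dict[str, int] = field(default_factory=dict)
    threshold: float = 2.0


def extract_traces(
    movie: np.ndarray,
    label_map: CellLabelMap,
    geometries: list[CellGeometry],
    frame_interval: float = 3.0,
) -> dict[int, dict[str, IntensityTrace]]:
    """Per-frame mean fluorescence for each cell's whole body and its three
    segments, minus the per-frame background (median over label-0 pixels).

    Returns {cell_id: {region: trace}} with four traces per cell.  The
    whole-cell trace is by construction the area-weighted mean of the three
    segment traces.

    ``label_map`` should be the unfiltered segmentation (its label-0 pixels
    define the background); ``geometries`` may be the border-filtered
    subset of cells to analyze.
    """
    mov = np.asarray(movie, dtype=float)
    if mov.ndim != 3:
        raise ValueError("movie must be a (T, Y, X) stack")
    if mov.shape[0] < 2:
        raise ValueError("movie needs at least 2 frames")
    if mov.shape[1:] != label_map.labels.shape:
        raise ValueError("movie frames and label map shapes differ")

    t = mov.shape[0]
    flat = mov.reshape(t, -1)
    bg_idx = (label_map.labels == 0).ravel()
    if bg_idx.any():
        background = np.median(flat[:, bg_idx], axis=1)
    else:
        logger.warning("no background pixels; background assumed 0")
        background = np.zeros(t)

    out: dict[int, dict[str, IntensityTrace]] = {}
    for g in geometries:
        traces: dict[str, IntensityTrace] = {}
        for region, m in zip(REGIONS, (g.mask,) + g.segment_masks):
            idx = m.ravel()
            vals = flat[:, idx].mean(axis=1) - background
            traces[region] = IntensityTrace(vals, frame_interval,
                                            g.cell_id, region)
        out[g.cell_id] = traces
    return out


def detrend(trace: IntensityTrace, mode: str = "none") -> IntensityTrace:
    """Remove a fitted baseline (photobleaching correction) and re-center the
    trace on its original mean, preserving the IoD scale.

    Modes: ``none`` (identity), ``linear`` (least-squares line), or
    ``exponential`` (a*exp(-t/tau) + c; falls back to linear with a warning
    when the fit does not converge).
    """
    if mode == "none":
        return trace
    v = trace.values
    if v.size < 3:
        raise ValueError("detrending needs at least 3 frames")
    t = trace.times
    orig_mean = v.mean()
    if mode == "linear":
        baseline = np.polyval(np.polyfit(t, v, 1), t)
    elif mode == "exponential":
        def model(t, a, tau, c):
            return a * np.exp(-t / tau) + c
        span = v.max() - v.min()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = optimize.curve_fit(
                    model, t, v,
                    p0=[max(span, 1e-6), max(t[-1] / 2, trace.frame_interval),
                        v.min()],
                    maxfev=5000,
                )
            if popt[1] <= 0 or not np.all(np.isfinite(popt)):
                raise RuntimeError("bad exponential fit")
            baseline = model(t, *popt)
        except (RuntimeError, optimize.OptimizeWarning):
            logger.warning("exponential fit failed; falling back to linear")
            baseline = np.polyval(np.polyfit(t, v, 1), t)
    else:
        raise ValueError(f"unknown detrend mode {mode!r}")
    out = v - baseline + orig_mean
    return IntensityTrace(out, trace.frame_interval, trace.cell_id, trace.region)


def index_of_dispersion(trace: IntensityTrace | np.ndarray) -> float:
    """Variance-to-mean ratio of a trace; NaN (with a warning) when the mean
    is not positive."""
    v = trace.values if isinstance(trace, IntensityTrace) else np.asarray(trace, float)
    m = v.mean()
    if m <= 0:
        logger.warning("trace mean <= 0; IoD undefined")
        return float("nan")
    return float(v.var(ddof=1) / m)


def classify_activity(iods: dict[str, float], threshold: float = 2.0) -> str:
    """Localization category from the three segment IoDs.

    ``inactive`` if no segment exceeds the threshold; the segment's own name
    if exactly one does; ``whole_cell`` if several do (spatially unconfined
    activity).
    """
    missing = [s for s in SEGMENT_NAMES if s not in iods or iods[s] is None]
    if missing:
        raise ValueError(f"missing segment IoD(s): {missing}")
    above = [s for s in SEGMENT_NAMES
             if np.isfinite(iods[s]) and iods[s] > threshold]
    if not above:
        return "inactive"
    if len(above) == 1:
        return "mid_body" if above[0] == "mid_body" else above[0]
    return "whole_cell"


def call_activity(
    traces: dict[str, IntensityTrace],
    threshold: float = 2.0,
    detrend_mode: str = "none",
    peak_prominence_mads: float = 5.0,
    peak_min_separation_s: float = 9.0,
) -> ActivityCall:
    """Full activity call for one cell from its four regional traces."""
    iods: dict[str, float] = {}
    peaks: dict[str, int] = {}
    cell_id = next(iter(traces.values())).cell_id
    for region in REGIONS:
        tr = detrend(traces[region], detrend_mode)
        iods[region] = index_of_dispersion(tr)
        times, _ = detect_peaks(tr, prominence_mads=peak_prominence_mads,
                                min_separation_s=peak_min_separation_s)
        peaks[region] = len(times)
    category = classify_activity(iods, threshold)
    whole_active = np.isfinite(iods["whole"]) and iods["whole"] > threshold
    active = whole_active or category != "inactive"
    if active and category == "inactive":
        # whole-cell trace exceeds threshold without any single confined
        # segment doing so: spatially unconfined activity
        category = "whole_cell"
    return ActivityCall(cell_id=cell_id, iod=iods, active=active,
                        category=category, peak_count=peaks,
                        threshold=threshold)


def detect_peaks(
    trace: IntensityTrace,
    prominence_mads: float = 5.0,
    min_separation_s: float = 9.0,
) -> tuple[np.ndarray, int]:
    """Oscillation peaks: local maxima with prominence >= k * MAD of the
    (detrended) trace, separated by at least ``min_separation_s`` seconds.

    Returns (peak times in seconds, count).  A flat trace has no peaks.
    """
    v = trace.values
    mad = float(np.median(np.abs(v - np.median(v))))
    if mad == 0:
        if np.ptp(v) == 0:
            return np.empty(0), 0
        # noise floor is zero (flat baseline with isolated events): any
        # positive prominence counts, leaving only the separation rule
        mad = float(np.ptp(v)) * 1e-9 / prominence_mads
    distance = max(int(round(min_separation_s / trace.frame_interval)), 1)
    idx, _ = signal.find_peaks(v, prominence=prominence_mads * mad,
                               distance=distance)
    return idx * trace.frame_interval, len(idx)


def activity_summary(calls: list[ActivityCall]) -> dict:
    """Population summary: fraction of active cells and, among active cells,
    the share of each localization category."""
    if not calls:
        raise ValueError("no activity calls")
    n = len(calls)
    active = [c for c in calls if c.active]
    frac_active = len(active) / n
    if active:
        shares = {cat: sum(c.category == cat for c in active) / len(active)
                  for cat in CATEGORIES if cat != "inactive"}
    else:
        shares = {cat: float("nan") for cat in CATEGORIES if cat != "inactive"}
    return {
        "n_cells": n,
        "n_active": len(active),
        "fraction_active": frac_active,
        "category_shares_among_active": shares,
    }


def call_table(calls: list[ActivityCall]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "cell_id": c.cell_id,
            "active": c.active,
            "category": c.category,
            "threshold": c.threshold,
            **{f"iod_{r}": c.iod.get(r, float("nan")) for r in REGIONS},
            **{f"peaks_{r}": c.peak_count.get(r, 0) for r in REGIONS},
        }
        for c in calls
    ])


def correlate_aspect_activity(
    geometries: list[CellGeometry],
    calls: list[ActivityCall],
    measure: str = "iod_downstream",
) -> dict:
    """Pearson correlation between cell aspect ratio and downstream calcium
    activity (downstream IoD by default, or downstream peak count)."""
    call_by_id = {c.cell_id: c for c in calls}
    x, y = [], []
    for g in geometries:
        c = call_by_id.get(g.cell_id)
        if c is None:
            continue
        if measure == "iod_downstream":
            val = c.iod.get("downstream", float("nan"))
        elif measure == "peaks_downstream":
            val = float(c.peak_count.get("downstream", 0))
        else:
            raise ValueError(f"unknown measure {measure!r}")
        if np.isfinite(val):
            x.append(g.aspect_ratio)
            y.append(val)
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    x = np.asarray(x)
    y = np.asarray(y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"r": float("nan"), "p": float("nan"), "n": len(x),
                "defined": False}
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n": len(x), "defined": True}


def trace_table(traces: dict[int, dict[str, IntensityTrace]]) -> pd.DataFrame:
    """Long-format trace export (cell_id, region, frame, time_s, intensity)."""
    rows = []
    for cid, regs in traces.items():
        for region, tr in regs.items():
            rows.append(pd.DataFrame({
                "cell_id": cid,
                "region": region,
                "frame": np.arange(tr.values.size),
                "time_s": tr.times,
                "intensity": tr.values,
            }))
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["cell_id", "region", "frame", "time_s", "intensity"])
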