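"""Cell segmentation, shape measurement, and flow-oriented tripartition.

Coordinate convention (used package-wide): images are 2D numpy arrays indexed
``(row, col)`` i.e. ``(y, x)``, 0-based, origin at the top-left, pixel centers
at integer coordinates.  A flow direction is a unit vector ``(dx, dy)`` in
these image coordinates (x = column axis, y = row axis).  The scalar
projection of a pixel at (y, x) onto the flow axis is ``p = x*dx + y*dy``;
larger ``p`` is further downstream (flow passes over it last).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed

logger = logging.getLogger(__name__)

__all__ = [
    "FlowField",
    "CellLabelMap",
    "CellGeometry",
    "SegmentationParams",
    "segment_cells",
    "filter_full_length",
    "compute_aspect_ratio",
    "partition_cell",
    "measure_geometry",
    "geometry_table",
]

SEGMENT_NAMES = ("upstream", "mid_body", "downstream")


@dataclass(frozen=True)
class FlowField:
    """Direction flow points, as a unit vector (dx, dy) in image coordinates.

    The upstream end of a cell faces ``-direction``; the downstream end is the
    portion of the cell furthest along ``+direction``.
    """

    direction: tuple[float, float]

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        if d.shape != (2,) or not np.all(np.isfinite(d)):
            raise ValueError("flow direction must be two finite numbers (dx, dy)")
        n = float(np.hypot(d[0], d[1]))
        if n == 0:
            raise ValueError("flow direction must be non-zero")
        if abs(n - 1.0) > 1e-9:
            object.__setattr__(self, "direction", (d[0] / n, d[1] / n))

    @property
    def dx(self) -> float:
        return self.direction[0]

    @property
    def dy(self) -> float:
        return self.direction[1]

    def reversed(self) -> "FlowField":
        return FlowField((-self.dx, -self.dy))

    def project(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Scalar projection of pixel centers (rows, cols) onto the flow axis."""
        return cols * self.dx + rows * self.dy


@dataclass
class CellLabelMap:
    """Integer-labeled cell image (0 = background) plus the field's flow vector."""

    labels: np.ndarray
    flow: FlowField
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError("labels must be a 2D image")
        if not np.issubdtype(lab.dtype, np.integer):
            if np.any(lab != np.round(lab)):
                raise ValueError("labels must be integers")
            lab = lab.astype(np.int32)
        if lab.min() < 0:
            raise ValueError("labels must be non-negative")
        self.labels = lab
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def cell_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def mask(self, cell_id: int) -> np.ndarray:
        m = self.labels == cell_id
        if not m.any():
            raise KeyError(f"no cell with label {cell_id}")
        return m


@dataclass
class CellGeometry:
    """Per-cell shape record: mask, centroid, aspect ratio and the three
    flow-oriented segment masks (upstream, mid_body, downstream)."""

    cell_id: int
    mask: np.ndarray
    area: int
    centroid: tuple[float, float]  # (y, x)
    aspect_ratio: float
    proj_min: float
    proj_max: float
    segment_masks: tuple[np.ndarray, np.ndarray, np.ndarray]
    border_touching: bool = False

    def segment(self, name: str) -> np.ndarray:
        return self.segment_masks[SEGMENT_NAMES.index(name)]


@dataclass
class SegmentationParams:
    sigma: float = 2.0          # Gaussian smoothing of the junction channel (px)
    min_cell_area_px: int = 50  # components smaller than this are dropped
    min_seed_distance: int = 10  # minimum spacing between fallback seeds (px)


def segment_cells(
    junction_image: np.ndarray,
    nucleus_image: np.ndarray | None = None,
    params: SegmentationParams | None = None,
    flow: FlowField | None = None,
    pixel_size: float = 1.0,
    label_mask: np.ndarray | None = None,
) -> CellLabelMap:
    """Segment a monolayer into labeled cells.

    The junction channel marks cell boundaries (bright ridges at cell-cell
    contacts).  Cells are recovered by seeded watershed on the smoothed
    junction intensity, which acts as the elevation map: ridges are barriers,
    cell interiors are basins.  Seeds come from the nucleus channel when
    given (one local maximum per nucleus), otherwise from local minima of the
    elevation map.

    Passing ``label_mask`` bypasses segmentation entirely and wraps the
    provided integer label image unchanged (the accept-mask path for
    externally produced masks).
    """
    if flow is None:
        flow = FlowField((1.0, 0.0))
    if label_mask is not None:
        return CellLabelMap(np.asarray(label_mask), flow, pixel_size)

    params = params or SegmentationParams()
    img = np.asarray(junction_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("junction image must be 2D")
    if nucleus_image is not None and np.asarray(nucleus_image).shape != img.shape:
        raise ValueError("junction and nucleus images must have the same shape")
    if img.max() == img.min():
        raise ValueError("no cells found: junction image is constant")

    elevation = gaussian(img, sigma=params.sigma, preserve_range=True)

    if nucleus_image is not None:
        nuc = gaussian(np.asarray(nucleus_image, dtype=float),
                       sigma=params.sigma, preserve_range=True)
        thr = threshold_otsu(nuc)
        # one point seed per nucleus: local maxima above the nucleus
        # threshold, so touching nuclei still seed separate cells
        coords = peak_local_max(nuc, min_distance=params.min_seed_distance,
                                threshold_abs=thr, exclude_border=False)
        if len(coords) == 0:
            raise ValueError("no cells found: nucleus channel yields no seeds")
        seeds = np.zeros(img.shape, dtype=np.int32)
        seeds[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    else:
        # fallback: one seed per local minimum of the elevation map
        coords = peak_local_max(elevation.max() - elevation,
                                min_distance=params.min_seed_distance,
                                exclude_border=False)
        if len(coords) == 0:
            raise ValueError("no cells found: no local minima in junction channel")
        seeds = np.zeros(img.shape, dtype=np.int32)
        seeds[tuple(coords.T)] = np.arange(1, len(coords) + 1)

    labels = watershed(elevation, markers=seeds)

    # drop fragments below the area floor
    ids, counts = np.unique(labels, return_counts=True)
    small = ids[(ids > 0) & (counts < params.min_cell_area_px)]
    if small.size:
        labels[np.isin(labels, small)] = 0
    if labels.max() == 0:
        raise ValueError("no cells found after area filtering")
    return CellLabelMap(labels.astype(np.int32), flow, pixel_size)


def filter_full_length(label_map: CellLabelMap) -> CellLabelMap:
    """Drop every cell whose mask touches any image border.

    Only complete cell bodies ("full-length" cells) are analyzable for
    upstream/downstream polarity; partial cells at the field edge are
    excluded.  Remaining labels keep their original ids.
    """
    lab = label_map.labels
    border = np.unique(np.concatenate([
        lab[0, :], lab[-1, :], lab[:, 0], lab[:, -1]
    ]))
    border = border[border > 0]
    out = lab.copy()
    if border.size:
        out[np.isin(out, border)] = 0
    if out.max() == 0:
        warnings.warn("all cells touch the image border; empty label map returned")
    return CellLabelMap(out, label_map.flow, label_map.pixel_size)


def compute_aspect_ratio(cell_mask: np.ndarray) -> float:
    """Major/minor axis ratio of the mask's moment-equivalent ellipse (>= 1).

    The minor axis is floored at one pixel so skeletal (1-px-wide) masks give
    a finite, large ratio instead of dividing by zero.
    """
    mask = np.asarray(cell_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    props = regionprops(mask.astype(np.uint8))[0]
    major = props.axis_major_length
    minor = max(props.axis_minor_length, 1.0)
    major = max(major, 1.0)
    return float(max(major / minor, 1.0))


def partition_cell(
    cell_mask: np.ndarray, flow: FlowField
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split a cell into three equal-length segments along the flow axis.

    Each pixel center is projected onto the flow direction; the projected span
    [proj_min, proj_max] is cut into three equal intervals.  The lowest-
    projection third is the upstream segment (the end flow reaches first),
    the highest-projection third is downstream.

    The boundary rule is symmetric about the span center (strict inequalities
    at +/- span/6 from the center), so negating the flow vector swaps the
    upstream and downstream masks exactly, with the mid-body unchanged.
    """
    mask = np.asarray(cell_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    rows, cols = np.nonzero(mask)
    p = flow.project(rows, cols)
    pmin, pmax = float(p.min()), float(p.max())
    span = pmax - pmin
    if span < 3.0 - 1e-9:
        raise ValueError("cell too short to partition: projected span < 3 px")
    center = (pmin + pmax) / 2.0
    u = p - center
    edge = span / 6.0
    seg_idx = np.ones(p.shape, dtype=np.int8)  # mid_body by default
    seg_idx[u < -edge] = 0   # upstream
    seg_idx[u > edge] = 2    # downstream
    out = []
    for k in range(3):
        m = np.zeros_like(mask)
        sel = seg_idx == k
        m[rows[sel], cols[sel]] = True
        out.append(m)
    return tuple(out)  # type: ignore[return-value]


def measure_geometry(
    label_map: CellLabelMap,
    min_span_px: float = 3.0,
) -> list[CellGeometry]:
    """Measure every cell in a label map: area, centroid, aspect ratio and the
    three flow-oriented segment masks.

    Cells whose projected span is below ``min_span_px`` cannot be partitioned
    and are reported with a warning rather than silently dropped.
    """
    lab = label_map.labels
    flow = label_map.flow
    h, w = lab.shape
    geometries: list[CellGeometry] = []
    skipped: list[int] = []
    for cid in label_map.cell_ids:
        mask = lab == cid
        rows, cols = np.nonzero(mask)
        p = flow.project(rows, cols)
        pmin, pmax = float(p.min()), float(p.max())
        border = bool(
            rows.min() == 0 or rows.max() == h - 1
            or cols.min() == 0 or cols.max() == w - 1
        )
        try:
            segs = partition_cell(mask, flow)
        except ValueError:
            skipped.append(int(cid))
            continue
        geometries.append(CellGeometry(
            cell_id=int(cid),
            mask=mask,
            area=int(mask.sum()),
            centroid=(float(rows.mean()), float(cols.mean())),
            aspect_ratio=compute_aspect_ratio(mask),
            proj_min=pmin,
            proj_max=pmax,
            segment_masks=segs,
            border_touching=border,
        ))
    if skipped:
        warnings.warn(
            f"{len(skipped)} cell(s) too short to partition, skipped: {skipped}"
        )
    return geometries


def geometry_table(geometries: list[CellGeometry]) -> pd.DataFrame:
    """Per-cell geometry as a tidy table."""
    return pd.DataFrame([
        {
            "cell_id": g.cell_id,
            "area_px": g.area,
            "centroid_y": g.centroid[0],
            "centroid_x": g.centroid[1],
            "aspect_ratio": g.aspect_ratio,
            "border_touching": g.border_touching,
        }
        for g in geometries
    ])
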