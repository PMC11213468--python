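"""Ground-truthed synthetic monolayer scenes and GCaMP movies.

The generator emulates the statistical structure of a flow-aligned
endothelial monolayer so the whole pipeline is testable without real data:

* cell mosaics from an anisotropically stretched Voronoi tessellation —
  controllable aspect ratio along the flow axis, guaranteed tiling, thin
  background ribbons at cell-cell boundaries;
* a junction channel (bright boundary ridges), a nucleus channel (one blob
  per cell), a stain channel with a per-segment intensity profile
  (downstream/upstream fold is the polarization parameter), and a puncta
  channel with flat-top spots placed at per-segment densities (flat-top, so
  the ground-truth spot area is analytic);
* time-lapse GCaMP movies: per-cell baseline, additive oscillation confined
  to a sampled source region for active cells, optional exponential
  photobleaching;
* a two-stage noise model (signal-dependent Poisson with gain ``g``, then
  additive Gaussian read noise) approximating sCMOS acquisition.

Every randomized step derives from a single integer seed; identical seeds
produce bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .geometry import (
    SEGMENT_NAMES,
    CellGeometry,
    CellLabelMap,
    FlowField,
    measure_geometry,
)

__all__ = [
    "SceneSpec",
    "MovieSpec",
    "GroundTruth",
    "Scene",
    "Movie",
    "generate_monolayer",
    "generate_gcamp_movie",
]

_MIN_CELL_AREA = 25  # px^2; below this a requested packing is infeasible


@dataclass
class SceneSpec:
    """Parameters of a synthetic monolayer scene.

    Defaults describe a flow-aligned arterial monolayer: strongly elongated
    cells (aspect ratio ~4, the regime in which localized signaling is
    sustained), 3-fold downstream enrichment of the polarized stain, and
    puncta concentrated in the downstream third.
    """

    n_cells: int = 60
    fov: tuple[int, int] = (300, 400)           # (height, width) px
    aspect_ratio_mean: float = 4.0
    aspect_ratio_sd: float = 0.8
    flow: FlowField = field(default_factory=lambda: FlowField((1.0, 0.0)))
    polarization_fold: float = 3.0              # downstream/upstream stain ratio
    base_intensity: float = 100.0               # upstream-segment stain mean
    background_level: float = 10.0              # extracellular offset, all channels
    junction_peak: float = 150.0
    nucleus_peak: float = 200.0
    punctum_density: tuple[float, float, float] = (0.05, 0.05, 0.30)
    # puncta per 100 px^2 for (upstream, mid_body, downstream)
    punctum_radius: int = 2                     # px
    punctum_min_separation: float | None = None  # px between centers; default
                                                 # 2*radius + 2 (discrete spots)
    punctum_peak: float = 60.0                  # amplitude above local baseline
    puncta_baseline: float = 40.0               # within-cell puncta-channel floor
    noise_gain: float = 1.0                     # Poisson gain g (0 = no shot noise)
    read_noise_sd: float = 2.0                  # Gaussian read noise SD (0 = none)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.polarization_fold < 0:
            raise ValueError("polarization_fold must be >= 0")
        if min(self.punctum_density) < 0:
            raise ValueError("punctum densities must be >= 0")
        if self.noise_gain < 0 or self.read_noise_sd < 0:
            raise ValueError("noise parameters must be >= 0")
        h, w = self.fov
        if self.n_cells * _MIN_CELL_AREA > h * w:
            raise ValueError(
                f"infeasible packing: {self.n_cells} cells do not fit a "
                f"{h}x{w} px field at >= {_MIN_CELL_AREA} px^2 each")


@dataclass
class MovieSpec:
    """Parameters of a synthetic GCaMP time-lapse.

    Defaults mirror the population structure of a flow-aligned monolayer
    under high laminar shear: about half the cells active, and activity
    restricted to the downstream end in three quarters of the active cells.
    """

    scene: SceneSpec = field(default_factory=SceneSpec)
    n_frames: int = 200
    frame_interval: float = 3.0                  # s; one frame every 3 s
    active_fraction: float = 0.5
    localization_probs: dict[str, float] = field(default_factory=lambda: {
        "upstream": 0.08, "mid_body": 0.07, "downstream": 0.75,
        "whole_cell": 0.10,
    })
    baseline: float = 100.0                      # resting GCaMP level per cell
    oscillation_amplitude: float = 100.0         # peak-to-trough additive signal
    oscillation_period: float = 60.0             # s
    waveform: str = "sine"                       # "sine" or "transients"
    transient_width: float = 6.0                 # s (transients waveform)
    bleach_tau: float | None = None              # s; None = no photobleaching
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if not 0 <= self.active_fraction <= 1:
            raise ValueError("active_fraction must be in [0, 1]")
        tot = sum(self.localization_probs.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError("localization_probs must sum to 1")
        bad = set(self.localization_probs) - set(SEGMENT_NAMES) - {"whole_cell"}
        if bad:
            raise ValueError(f"unknown localization categories: {bad}")


@dataclass
class CellTruth:
    cell_id: int
    aspect_ratio: float
    centroid: tuple[float, float]
    area: int
    border_touching: bool
    segment_means: tuple[float, float, float] | None = None
    polarity_index: float | None = None
    puncta: list[tuple[float, float]] = field(default_factory=list)
    puncta_per_segment: tuple[int, int, int] = (0, 0, 0)
    active: bool | None = None
    localization: str | None = None
    peak_times: list[float] = field(default_factory=list)


@dataclass
class GroundTruth:
    """Everything the generator knows about what it rendered."""

    labels: np.ndarray
    flow: FlowField
    cells: dict[int, CellTruth]

    def to_json(self) -> str:
        def cell_rec(c: CellTruth) -> dict:
            d = dataclasses.asdict(c)
            d["puncta"] = [list(p) for p in c.puncta]
            return d
        return json.dumps({
            "flow": list(self.flow.direction),
            "cells": {str(k): cell_rec(c) for k, c in self.cells.items()},
        }, indent=1)


@dataclass
class Scene:
    channels: dict[str, np.ndarray]   # junction, nucleus, stain, puncta
    label_map: CellLabelMap
    geometries: list[CellGeometry]
    truth: GroundTruth
    spec: SceneSpec

    def stack(self) -> np.ndarray:
        """(C, Y, X) stack in channel order junction, nucleus, stain, puncta."""
        order = ("junction", "nucleus", "stain", "puncta")
        return np.stack([self.channels[c] for c in order])


@dataclass
class Movie:
    frames: np.ndarray                # (T, Y, X)
    label_map: CellLabelMap
    geometries: list[CellGeometry]
    truth: GroundTruth
    spec: MovieSpec


# ---------------------------------------------------------------------------
# tessellation

def _tessellate(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Labeled mosaic of elongated cells tiling the field of view.

    Seeds sit on a jittered grid in flow-rotated coordinates; each pixel is
    assigned to the seed minimizing an anisotropic distance whose along-flow
    axis is shrunk by the seed's own stretch factor, which elongates cells
    along flow by roughly that factor.  Disconnected fragments are
    reassigned to the nearest surviving region so every label is connected.
    Boundary pixels (any 4-neighbour with a different label) become
    background ribbons (label 0).
    """
    h, w = spec.fov
    yy, xx = np.mgrid[0:h, 0:w]
    dx, dy = spec.flow.dx, spec.flow.dy
    u = (xx * dx + yy * dy).ravel()      # along flow
    v = (-xx * dy + yy * dx).ravel()     # perpendicular

    area = h * w / spec.n_cells
    ar = max(spec.aspect_ratio_mean, 1.0)
    du = math.sqrt(area * ar)
    dv = math.sqrt(area / ar)

    u0, u1 = u.min(), u.max()
    v0, v1 = v.min(), v.max()
    n_u = max(1, round((u1 - u0) / du))
    n_v = max(1, math.ceil(spec.n_cells / n_u))
    n_u = math.ceil(spec.n_cells / n_v)
    gu = u0 + (u1 - u0) * (np.arange(n_u) + 0.5) / n_u
    gv = v0 + (v1 - v0) * (np.arange(n_v) + 0.5) / n_v
    seeds_u, seeds_v = np.meshgrid(gu, gv, indexing="ij")
    seeds_u = seeds_u.ravel()[: spec.n_cells].copy()
    seeds_v = seeds_v.ravel()[: spec.n_cells].copy()
    n = seeds_u.size
    seeds_u += rng.uniform(-0.25, 0.25, n) * (u1 - u0) / n_u
    seeds_v += rng.uniform(-0.25, 0.25, n) * (v1 - v0) / n_v
    stretch = np.clip(
        rng.normal(spec.aspect_ratio_mean, spec.aspect_ratio_sd, n), 1.2, None)

    # candidate seeds via KD-tree in grid-normalized coordinates, exact
    # anisotropic argmin over the candidates
    tree = cKDTree(np.column_stack([seeds_u / du, seeds_v / dv]))
    k = min(12, n)
    _, cand = tree.query(np.column_stack([u / du, v / dv]), k=k)
    cand = np.atleast_2d(cand.reshape(u.size, k))
    d2 = (((u[:, None] - seeds_u[cand]) / stretch[cand]) ** 2
          + (v[:, None] - seeds_v[cand]) ** 2)
    labels = cand[np.arange(u.size), d2.argmin(axis=1)] + 1
    labels = labels.reshape(h, w).astype(np.int32)

    # enforce connectivity: keep each label's largest 4-connected piece,
    # then fill orphaned pixels from the nearest kept region
    clean = np.zeros_like(labels)
    for cid in range(1, n + 1):
        comp, nc = ndi.label(labels == cid)
        if nc == 0:
            continue
        if nc > 1:
            sizes = ndi.sum_labels(np.ones_like(comp), comp, range(1, nc + 1))
            comp = comp == (1 + int(np.argmax(sizes)))
        else:
            comp = comp > 0
        clean[comp] = cid
    if (clean == 0).any():
        _, (iy, ix) = ndi.distance_transform_edt(clean == 0, return_indices=True)
        clean = clean[iy, ix]

    # boundary ribbons -> background
    boundary = np.zeros((h, w), dtype=bool)
    boundary[:-1, :] |= clean[:-1, :] != clean[1:, :]
    boundary[1:, :] |= clean[1:, :] != clean[:-1, :]
    boundary[:, :-1] |= clean[:, :-1] != clean[:, 1:]
    boundary[:, 1:] |= clean[:, 1:] != clean[:, :-1]
    out = clean.copy()
    out[boundary] = 0
    # ribbon carving can itself disconnect or erase a label; keep only
    # labels that survive connected
    for cid in np.unique(out):
        if cid == 0:
            continue
        comp, nc = ndi.label(out == cid)
        if nc > 1:
            sizes = ndi.sum_labels(np.ones_like(comp), comp, range(1, nc + 1))
            keep = 1 + int(np.argmax(sizes))
            out[(out == cid) & (comp != keep)] = 0
    return out


def _apply_noise(img: np.ndarray, gain: float, read_sd: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Two-stage noise: Poisson with gain ``g`` (variance = g * mean on a
    uniform region), then additive Gaussian read noise."""
    out = np.asarray(img, dtype=float)
    if gain > 0:
        out = rng.poisson(np.clip(out, 0, None) / gain) * gain
    if read_sd > 0:
        out = out + rng.normal(0.0, read_sd, out.shape)
    return out.astype(np.float32)


def _disk_offsets(radius: int) -> tuple[np.ndarray, np.ndarray]:
    r = int(radius)
    oy, ox = np.mgrid[-r:r + 1, -r:r + 1]
    keep = oy ** 2 + ox ** 2 <= r ** 2
    return oy[keep], ox[keep]


def generate_monolayer(spec: SceneSpec) -> Scene:
    """Render a multi-channel monolayer scene with full ground truth.

    Channels: ``junction`` (boundary ridges), ``nucleus`` (one blob per
    cell), ``stain`` (per-segment means base * (1, 1, fold)), ``puncta``
    (flat-top spots at the per-segment densities).  Noise is applied last.
    """
    rng = np.random.default_rng(spec.seed)
    labels = _tessellate(spec, rng)
    label_map = CellLabelMap(labels, spec.flow)
    geometries = measure_geometry(label_map)
    h, w = spec.fov

    junction = np.full((h, w), spec.background_level, dtype=float)
    ridge = ndi.gaussian_filter((labels == 0).astype(float), 1.0)
    if ridge.max() > 0:
        junction += spec.junction_peak * ridge / ridge.max()

    nucleus = np.full((h, w), spec.background_level, dtype=float)
    stain = np.full((h, w), spec.background_level, dtype=float)
    puncta = np.full((h, w), spec.background_level, dtype=float)

    fold = spec.polarization_fold
    seg_scale = (1.0, 1.0, fold)
    pol_truth = fold / (2.0 + fold) if (2.0 + fold) > 0 else float("nan")
    oy, ox = _disk_offsets(spec.punctum_radius)

    cells: dict[int, CellTruth] = {}
    for g in geometries:
        # nucleus blob at the centroid
        cy, cx = g.centroid
        sig = max(math.sqrt(g.area) / 6.0, 1.5)
        yy, xx = np.nonzero(g.mask)
        blob = spec.nucleus_peak * np.exp(
            -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sig ** 2))
        nucleus[yy, xx] += blob

        seg_means = []
        puncta_coords: list[tuple[float, float]] = []
        per_seg_counts = [0, 0, 0]
        for k, seg in enumerate(g.segment_masks):
            level = spec.base_intensity * seg_scale[k]
            stain[seg] = spec.background_level + level
            seg_means.append(level)
            # puncta: Poisson count at the per-segment density, uniform
            # placement over the segment's pixels
            seg_area = int(seg.sum())
            lam = spec.punctum_density[k] * seg_area / 100.0
            n_p = rng.poisson(lam)
            if n_p and seg_area:
                # rejection sampling keeps spots discrete (PLA puncta are
                # resolvable objects, not a continuum)
                min_sep = (spec.punctum_min_separation
                           if spec.punctum_min_separation is not None
                           else 2 * spec.punctum_radius + 2)
                ry, rx = np.nonzero(seg)
                order = rng.permutation(seg_area)
                placed = 0
                for py, px in zip(ry[order], rx[order]):
                    if placed >= n_p:
                        break
                    if any((py - qy) ** 2 + (px - qx) ** 2 < min_sep ** 2
                           for qy, qx in puncta_coords):
                        continue
                    puncta_coords.append((float(py), float(px)))
                    per_seg_counts[k] += 1
                    placed += 1
                    sy = np.clip(py + oy, 0, h - 1)
                    sx = np.clip(px + ox, 0, w - 1)
                    puncta[sy, sx] = (spec.background_level
                                      + spec.puncta_baseline
                                      + spec.punctum_peak)
        puncta[g.mask & (puncta <= spec.background_level)] = (
            spec.background_level + spec.puncta_baseline)

        cells[g.cell_id] = CellTruth(
            cell_id=g.cell_id,
            aspect_ratio=g.aspect_ratio,
            centroid=g.centroid,
            area=g.area,
            border_touching=g.border_touching,
            segment_means=tuple(seg_means),  # type: ignore[arg-type]
            polarity_index=pol_truth,
            puncta=puncta_coords,
            puncta_per_segment=tuple(per_seg_counts),  # type: ignore[arg-type]
        )

    channels = {
        "junction": _apply_noise(junction, spec.noise_gain,
                                 spec.read_noise_sd, rng),
        "nucleus": _apply_noise(nucleus, spec.noise_gain,
                                spec.read_noise_sd, rng),
        "stain": _apply_noise(stain, spec.noise_gain,
                              spec.read_noise_sd, rng),
        "puncta": _apply_noise(puncta, spec.noise_gain,
                               spec.read_noise_sd, rng),
    }
    truth = GroundTruth(labels=labels, flow=spec.flow, cells=cells)
    return Scene(channels=channels, label_map=label_map,
                 geometries=geometries, truth=truth, spec=spec)


def _waveform(spec: MovieSpec, times: np.ndarray,
              rng: np.random.Generator) -> tuple[np.ndarray, list[float]]:
    """Additive, non-negative oscillation signal and its true peak times."""
    a = spec.oscillation_amplitude
    if a == 0:
        return np.zeros_like(times), []
    if spec.waveform == "sine":
        phase = rng.uniform(0, 2 * math.pi)
        sig = 0.5 * a * (1.0 + np.sin(2 * math.pi * times / spec.oscillation_period
                                      + phase))
        # true peaks: sin argument = pi/2 + 2*pi*k, inside the record
        p = spec.oscillation_period
        k0 = math.ceil((phase - math.pi / 2) / (2 * math.pi))
        peaks = []
        t = ((math.pi / 2) + 2 * math.pi * k0 - phase) * p / (2 * math.pi)
        while t <= times[-1]:
            if t >= 0:
                peaks.append(t)
            t += p
        return sig, peaks
    if spec.waveform == "transients":
        duration = times[-1]
        n_ev = max(1, rng.poisson(duration / spec.oscillation_period))
        lo = 2 * spec.transient_width
        hi = max(duration - 2 * spec.transient_width, lo + 1e-6)
        centers = np.sort(rng.uniform(lo, hi, n_ev))
        # enforce separation so events stay resolvable
        keep = [centers[0]]
        for c in centers[1:]:
            if c - keep[-1] >= 4 * spec.transient_width:
                keep.append(c)
        sig = np.zeros_like(times)
        for c in keep:
            sig += a * np.exp(-((times - c) ** 2)
                              / (2 * spec.transient_width ** 2))
        return sig, [float(c) for c in keep]
    raise ValueError(f"unknown waveform {spec.waveform!r}")


def generate_gcamp_movie(spec: MovieSpec) -> Movie:
    """Render a GCaMP time-lapse over a generated monolayer.

    Every cell fluoresces at ``baseline``; a fraction ``active_fraction`` of
    non-border cells additionally receives the oscillation signal over its
    sampled source region (one segment, or the whole cell).  Optional
    exponential photobleaching multiplies the whole frame; the two-stage
    noise model is applied per frame.
    """
    rng = np.random.default_rng(spec.seed)
    scene_spec = dataclasses.replace(spec.scene, seed=spec.seed)
    labels = _tessellate(scene_spec, rng)
    label_map = CellLabelMap(labels, scene_spec.flow)
    geometries = measure_geometry(label_map)
    h, w = scene_spec.fov
    times = np.arange(spec.n_frames) * spec.frame_interval

    base = np.full((h, w), scene_spec.background_level, dtype=float)
    base[labels > 0] = scene_spec.background_level + spec.baseline

    cats = sorted(spec.localization_probs)
    probs = np.array([spec.localization_probs[c] for c in cats])

    cells: dict[int, CellTruth] = {}
    active_signals: list[tuple[np.ndarray, np.ndarray]] = []  # (flat idx, signal)
    for g in geometries:
        is_active = bool(rng.random() < spec.active_fraction)
        loc = None
        peak_times: list[float] = []
        if is_active:
            loc = cats[rng.choice(len(cats), p=probs)]
            src = g.mask if loc == "whole_cell" else g.segment(loc)
            sig, peak_times = _waveform(spec, times, rng)
            active_signals.append((np.flatnonzero(src.ravel()), sig))
            if spec.oscillation_amplitude == 0:
                is_active = False  # degenerate: nothing actually injected
                loc = None
                peak_times = []
        cells[g.cell_id] = CellTruth(
            cell_id=g.cell_id,
            aspect_ratio=g.aspect_ratio,
            centroid=g.centroid,
            area=g.area,
            border_touching=g.border_touching,
            active=is_active,
            localization=loc,
            peak_times=peak_times,
        )

    frames = np.empty((spec.n_frames, h, w), dtype=np.float32)
    flat_base = base.ravel()
    for t in range(spec.n_frames):
        frame = flat_base.copy()
        for idx, sig in active_signals:
            frame[idx] += sig[t]
        if spec.bleach_tau is not None:
            frame = frame * math.exp(-times[t] / spec.bleach_tau)
        frames[t] = _apply_noise(frame.reshape(h, w), scene_spec.noise_gain,
                                 scene_spec.read_noise_sd, rng)

    truth = GroundTruth(labels=labels, flow=scene_spec.flow, cells=cells)
    return Movie(frames=frames, label_map=label_map, geometries=geometries,
                 truth=truth, spec=spec)
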