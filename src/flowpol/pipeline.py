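"""Pipeline orchestration: stage graph, run directory, manifest.

Stages form a small dependency graph::

    simulate (optional, synthetic inputs)
    segment -> geometry -> polarity
                        -> clusters
                        -> calcium -> summarize

Each stage writes its outputs into the run directory; a manifest records
every file with its SHA-256 checksum so reruns are verifiable, and the
resolved configuration is written beside the outputs.  Requesting a stage
whose prerequisite has not run raises an error naming the missing stage.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import calcium as ca
from . import clusters as cl
from . import geometry as geo
from . import io
from . import polarity as pol
from . import synthetic as syn
from .config import RunConfig

logger = logging.getLogger(__name__)

STAGES = ("simulate", "segment", "geometry", "polarity", "clusters",
          "calcium", "summarize")
_DEPS = {
    "segment": (),
    "geometry": ("segment",),
    "polarity": ("geometry",),
    "clusters": ("geometry",),
    "calcium": ("geometry",),
    "summarize": ("calcium",),
}


class PipelineError(RuntimeError):
    pass


class PipelineRun:
    """One run over one field of view."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self._done: set[str] = set()
        self._files: list[Path] = []
        # in-memory state
        self.scene: syn.Scene | None = None
        self.movie_arr: np.ndarray | None = None
        self.label_map: geo.CellLabelMap | None = None
        self.label_map_full: geo.CellLabelMap | None = None  # pre-filter;
        # its label-0 pixels are true background, used for bg estimation
        self.geometries: list[geo.CellGeometry] | None = None
        self.calls: list[ca.ActivityCall] | None = None

    # -- helpers -----------------------------------------------------------
    def _save_table(self, name: str, table: pd.DataFrame) -> Path:
        path = self.out / name
        io.write_table(path, table, package_version=__version__)
        self._files.append(path)
        return path

    def _save_image(self, name: str, arr: np.ndarray, label: bool = False) -> Path:
        path = self.out / name
        (io.write_label_mask if label else io.write_image)(path, arr)
        self._files.append(path)
        return path

    def _require(self, stage: str) -> None:
        for dep in _DEPS.get(stage, ()):
            if dep not in self._done:
                raise PipelineError(
                    f"stage '{stage}' requires stage '{dep}' to run first")

    def _flow(self) -> geo.FlowField:
        return geo.FlowField(tuple(self.config.flow_direction))

    # -- stages ------------------------------------------------------------
    def simulate(self) -> None:
        s = self.config.synthetic
        scene_spec = syn.SceneSpec(
            n_cells=s.n_cells, fov=tuple(s.fov),
            aspect_ratio_mean=s.aspect_ratio_mean,
            aspect_ratio_sd=s.aspect_ratio_sd,
            polarization_fold=s.polarization_fold,
            flow=self._flow(), seed=self.config.seed)
        self.scene = syn.generate_monolayer(scene_spec)
        movie = syn.generate_gcamp_movie(syn.MovieSpec(
            scene=scene_spec, n_frames=s.n_frames,
            frame_interval=self.config.calcium.frame_interval_s,
            active_fraction=s.active_fraction, seed=self.config.seed))
        self.movie_arr = movie.frames
        self._save_image("scene.tif", self.scene.stack())
        self._save_image("movie.tif", movie.frames)
        self._save_image("true_labels.tif", self.scene.truth.labels, label=True)
        path = self.out / "ground_truth.json"
        path.write_text(self.scene.truth.to_json())
        self._files.append(path)
        self._done.add("simulate")

    def segment(self) -> None:
        self._require("segment")
        cfg = self.config
        flow = self._flow()
        if cfg.label_mask is not None:
            labels = io.read_label_mask(cfg.label_mask)
            lm = geo.segment_cells(np.zeros_like(labels, dtype=float),
                                   flow=flow, label_mask=labels,
                                   pixel_size=cfg.pixel_size_um)
        else:
            if self.scene is not None:
                junction = self.scene.channels["junction"]
                nucleus = self.scene.channels["nucleus"]
            elif cfg.image is not None:
                stack = io.read_image(cfg.image)
                if stack.ndim == 2:
                    stack = stack[None]
                junction = stack[cfg.channels.junction]
                nucleus = (stack[cfg.channels.nucleus]
                           if stack.shape[0] > cfg.channels.nucleus else None)
            else:
                raise PipelineError(
                    "stage 'segment' needs an input image, a label mask, or "
                    "a prior 'simulate' stage")
            params = geo.SegmentationParams(
                sigma=cfg.segmentation.sigma,
                min_cell_area_px=cfg.segmentation.min_cell_area_px)
            lm = geo.segment_cells(junction, nucleus, params, flow=flow,
                                   pixel_size=cfg.pixel_size_um)
        self.label_map_full = lm
        self.label_map = geo.filter_full_length(lm)
        self._save_image("labels.tif", self.label_map.labels, label=True)
        self._done.add("segment")

    def geometry(self) -> None:
        self._require("geometry")
        assert self.label_map is not None
        self.geometries = geo.measure_geometry(self.label_map)
        self._save_table("geometry.csv", geo.geometry_table(self.geometries))
        self._done.add("geometry")

    def polarity(self) -> None:
        self._require("polarity")
        assert self.label_map is not None and self.geometries is not None
        if self.scene is not None:
            stain = self.scene.channels["stain"]
        elif self.config.image is not None:
            stack = io.read_image(self.config.image)
            stain = stack[self.config.channels.stain]
        else:
            raise PipelineError("stage 'polarity' needs a stain image")
        bg = (self.config.background
              if self.config.background is not None
              else pol.estimate_background(
                  stain, self.label_map_full or self.label_map))
        profiles = [pol.segment_intensity_profile(stain, g, bg)
                    for g in self.geometries]
        self._save_table("polarity.csv", pol.profile_table(profiles))
        if len([p for p in profiles if p.is_defined]) >= 2:
            stats_path = self.out / "polarity_stats.json"
            stats_path.write_text(json.dumps(pol.polarity_test(profiles),
                                             indent=1))
            self._files.append(stats_path)
        self._done.add("polarity")

    def clusters(self) -> None:
        self._require("clusters")
        assert self.label_map is not None and self.geometries is not None
        if self.scene is not None:
            img = self.scene.channels["puncta"]
        elif self.config.image is not None:
            stack = io.read_image(self.config.image)
            img = stack[self.config.channels.puncta]
        else:
            raise PipelineError("stage 'clusters' needs a puncta image")
        c = self.config.clusters
        params = cl.DetectionParams(tophat_radius=c.tophat_radius,
                                    min_area=c.min_area,
                                    pla_size_band=tuple(c.pla_size_band))
        sets = [cl.detect_clusters(img, g.mask, params, g.cell_id)
                for g in self.geometries]
        self._save_table("clusters.csv", cl.cluster_table(sets, self.geometries))
        idx_rows = []
        for cs, g in zip(sets, self.geometries):
            prof = cl.cluster_index(cs, g)
            idx_rows.append({
                "cell_id": g.cell_id,
                **{f"index_{n}": prof.index[k]
                   for k, n in enumerate(geo.SEGMENT_NAMES)},
                **{f"mean_area_{n}": prof.mean_cluster_area[k]
                   for k, n in enumerate(geo.SEGMENT_NAMES)},
            })
        self._save_table("cluster_index.csv", pd.DataFrame(idx_rows))
        self._save_table("puncta_counts.csv",
                         cl.count_puncta(img, self.label_map,
                                         self.geometries, params))
        self._done.add("clusters")

    def calcium(self) -> None:
        self._require("calcium")
        assert self.label_map is not None and self.geometries is not None
        if self.movie_arr is not None:
            mov = self.movie_arr
        elif self.config.movie is not None:
            mov = io.read_movie(self.config.movie)
        else:
            raise PipelineError("stage 'calcium' needs a movie")
        c = self.config.calcium
        traces = ca.extract_traces(mov, self.label_map_full or self.label_map,
                                   self.geometries,
                                   frame_interval=c.frame_interval_s)
        self.calls = [ca.call_activity(
            tr, threshold=c.threshold_iod, detrend_mode=c.detrend,
            peak_prominence_mads=c.peak_prominence_mads,
            peak_min_separation_s=c.peak_min_separation_s)
            for tr in traces.values()]
        self._save_table("traces.csv", ca.trace_table(traces))
        self._save_table("activity_calls.csv", ca.call_table(self.calls))
        self._done.add("calcium")

    def summarize(self) -> None:
        self._require("summarize")
        assert self.calls is not None
        summary = ca.activity_summary(self.calls)
        if self.geometries is not None and len(self.calls) >= 3:
            try:
                summary["aspect_vs_downstream_iod"] = \
                    ca.correlate_aspect_activity(self.geometries, self.calls)
            except ValueError:
                pass
        path = self.out / "summary.json"
        path.write_text(json.dumps(summary, indent=1))
        self._files.append(path)
        self._done.add("summarize")

    # -- driver ------------------------------------------------------------
    def run(self, stages: list[str]) -> Path:
        from .config import dump_config
        for s in stages:
            if s not in STAGES:
                raise PipelineError(f"unknown stage '{s}'")
        for s in stages:
            getattr(self, s)()
        cfg_path = self.out / "config_resolved.yaml"
        dump_config(self.config, cfg_path)
        self._files.append(cfg_path)
        manifest = {
            "package_version": __version__,
            "stages": [s for s in STAGES if s in self._done],
            "files": {p.name: io.sha256_file(p) for p in self._files},
        }
        mpath = self.out / "manifest.json"
        mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return mpath


def run_pipeline(config: RunConfig, stages: list[str]) -> Path:
    """Run the requested stages in order; returns the manifest path."""
    return PipelineRun(config).run(stages)
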