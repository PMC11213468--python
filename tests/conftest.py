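import numpy as np
import pytest

import flowpol as fp


@pytest.fixture(scope="session")
def noisefree_scene() -> fp.Scene:
    """Small noise-free scene: fold-3 downstream stain enrichment."""
    spec = fp.SceneSpec(n_cells=20, fov=(220, 300), seed=11,
                        noise_gain=0.0, read_noise_sd=0.0)
    return fp.generate_monolayer(spec)


@pytest.fixture(scope="session")
def noisy_scene() -> fp.Scene:
    """Default-noise scene (Poisson gain 1, read SD 2)."""
    spec = fp.SceneSpec(n_cells=20, fov=(220, 300), seed=12)
    return fp.generate_monolayer(spec)


def interior(scene: fp.Scene):
    """Full-length (non-border) cells of a scene."""
    return [g for g in scene.geometries if not g.border_touching]


def match_detections(truth_pts, detected_pts, tol_px: float = 3.0):
    """Greedy one-to-one matching of detected centroids to true spot
    positions; returns (tp, fp, fn)."""
    used: set[int] = set()
    tp = 0
    for ty, tx in truth_pts:
        best, bd = None, tol_px ** 2
        for i, (dy, dx) in enumerate(detected_pts):
            if i in used:
                continue
            d = (ty - dy) ** 2 + (tx - dx) ** 2
            if d <= bd:
                bd, best = d, i
        if best is not None:
            used.add(best)
            tp += 1
    return tp, len(detected_pts) - len(used), len(truth_pts) - tp


def rect_mask(shape, y0, y1, x0, x1):
    m = np.zeros(shape, dtype=bool)
    m[y0:y1, x0:x1] = True
    return m
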