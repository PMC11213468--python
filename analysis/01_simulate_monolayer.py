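"""Generate the reference synthetic field of view.

Renders a flow-aligned endothelial monolayer (elongated cells, 3-fold
downstream stain enrichment, downstream-weighted puncta) plus a GCaMP
time-lapse in which half the cells oscillate, three quarters of them with
activity confined to the downstream third.  Images, label masks and the
generator's ground truth go to results/monolayer/ for the downstream
analysis scripts.
"""

import pathlib
import sys

SEED = 20
OUT = pathlib.Path("results/monolayer")


def main() -> None:
    import flowpol as fp
    from flowpol import io

    OUT.mkdir(parents=True, exist_ok=True)
    scene_spec = fp.SceneSpec(n_cells=120, fov=(400, 520), seed=SEED)
    scene = fp.generate_monolayer(scene_spec)
    movie = fp.generate_gcamp_movie(fp.MovieSpec(scene=scene_spec,
                                                 n_frames=200, seed=SEED))

    io.write_image(OUT / "scene.tif", scene.stack())
    io.write_image(OUT / "movie.tif", movie.frames)
    io.write_label_mask(OUT / "true_labels.tif", scene.truth.labels)
    (OUT / "ground_truth.json").write_text(scene.truth.to_json())
    (OUT / "movie_truth.json").write_text(movie.truth.to_json())

    n = len(scene.geometries)
    n_int = sum(not g.border_touching for g in scene.geometries)
    n_act = sum(bool(c.active) for c in movie.truth.cells.values())
    print(f"rendered {n} cells ({n_int} full-length) in a "
          f"{scene_spec.fov[0]}x{scene_spec.fov[1]} px field")
    print(f"movie: {movie.frames.shape[0]} frames at "
          f"{movie.spec.frame_interval} s/frame; {n_act} truly active cells")
    print(f"outputs in {OUT}/")


if __name__ == "__main__":
    sys.exit(main())
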