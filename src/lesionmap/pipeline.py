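"""End-to-end orchestration: cohort -> overlay -> VLSM x2 -> conjunction.

``run_all`` drives the whole analysis from a single config: load (or
synthesize) the cohort, flip lesions onto one hemisphere, build the coverage
inclusion mask, map both scores, select significant voxels (FDR for the
reference score, a lenient fixed-z criterion - by default derived from the
reference's minimum FDR-surviving z - for the second), extract and tabulate
clusters, classify the conjunction, and write volumes, tables and a manifest
recording every threshold and count.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import conjunction as conj
from . import lesion_io, synthetic, vlsm

__all__ = ["RunConfig", "run_all"]

log = logging.getLogger("lesionmap")


@dataclass
class RunConfig:
    """Parameters of one full pipeline run (all defaults recorded)."""

    out_dir: str = "lesionmap_run"
    masks_dir: str | None = None  # None -> synthesize a cohort
    scores_path: str | None = None
    score_a: str = "FMA_UL"  # reference score (FDR-corrected analysis)
    score_b: str = "TSRT"
    coverage: float = vlsm.DEFAULT_COVERAGE
    q: float = 0.05
    min_cluster: int = vlsm.DEFAULT_MIN_CLUSTER
    adjacency: int = vlsm.DEFAULT_ADJACENCY
    lenient_mode: str = "derived"  # "derived" from score-A FDR, or "fixed"
    lenient_z: float = 2.09  # used when lenient_mode == "fixed"
    flip: bool = True
    seed: int = 0
    atlas_blocks: tuple[int, int, int] = (2, 3, 2)

    def __post_init__(self) -> None:
        if self.lenient_mode not in ("derived", "fixed"):
            raise ValueError("lenient_mode must be 'derived' or 'fixed'")


def _load_or_synthesize(config: RunConfig):
    if config.masks_dir is None:
        spec = dataclasses.replace(synthetic.SyntheticSpec(), seed=config.seed)
        cohort, _ = synthetic.generate_cohort(spec)
        return cohort
    masks_dir = Path(config.masks_dir)
    paths = sorted(masks_dir.glob("*.nii*"))
    if not paths:
        raise FileNotFoundError(f"no NIfTI masks under {masks_dir}")
    masks = [lesion_io.read_mask(p) for p in paths]
    for m in masks[1:]:
        masks[0].grid.require_match(m.grid, m.subject_id)
    if config.scores_path is None:
        raise ValueError("scores_path is required when masks_dir is given")
    scores = lesion_io.read_scores(config.scores_path)
    return lesion_io.Cohort(masks=masks, scores=scores)


def _save_result(out: Path, tag: str, result: vlsm.VlsmResult, clusters, atlas) -> dict:
    lesion_io.write_volume(out / f"{tag}_z.nii.gz", np.nan_to_num(result.z), result.grid)
    lesion_io.write_volume(out / f"{tag}_p.nii.gz", np.nan_to_num(result.p, nan=1.0), result.grid)
    lesion_io.write_volume(out / f"{tag}_sig.nii.gz", result.sig, result.grid)
    cluster_rows = [
        {
            "cluster_id": i + 1,
            "size": c.size,
            "max_z": c.max_z,
            "x_mm": c.report_mm[0],
            "y_mm": c.report_mm[1],
            "z_mm": c.report_mm[2],
        }
        for i, c in enumerate(clusters)
    ]
    import pandas as pd

    pd.DataFrame(
        cluster_rows, columns=["cluster_id", "size", "max_z", "x_mm", "y_mm", "z_mm"]
    ).to_csv(out / f"{tag}_clusters.tsv", sep="\t", index=False)
    vlsm.tabulate_structures(result, clusters, atlas).to_csv(
        out / f"{tag}_structures.tsv", sep="\t", index=False
    )
    return {
        "score": result.score_name,
        "n_included": result.n_included,
        "n_significant": result.n_significant,
        "threshold_info": result.threshold_info,
        "n_clusters": len(clusters),
        "cluster_sizes": [c.size for c in clusters],
    }


def save_overlay_png(path: Path, volume: np.ndarray, grid, n_slices: int = 6) -> None:
    """Orthogonal axial slices of a count/z volume as a quick-look figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ks = np.linspace(0, volume.shape[2] - 1, n_slices + 2).astype(int)[1:-1]
    fig, axes = plt.subplots(1, n_slices, figsize=(2.2 * n_slices, 2.6))
    vmax = max(1, volume.max())
    for ax, k in zip(np.atleast_1d(axes), ks):
        im = ax.imshow(volume[:, :, k].T, origin="lower", cmap="hot",
                       vmin=0, vmax=vmax)
        z_mm = grid.voxel_to_world(np.array([0, 0, k]))[2]
        ax.set_title(f"z = {z_mm:.0f} mm", fontsize=8)
        ax.axis("off")
    fig.colorbar(im, ax=axes, shrink=0.7, label="subjects")
    fig.savefig(path, dpi=110, bbox_inches="tight")
    plt.close(fig)


def run_all(config: RunConfig) -> Path:
    """Run the whole chain; returns the output directory.

    Stage failures raise with a stage-tagged message; outputs written before
    the failure are retained for inspection.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    manifest: dict = {"config": dataclasses.asdict(config)}
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh)

    stage = "load"
    try:
        cohort = _load_or_synthesize(config)
        log.info("cohort: n=%d grid=%s", cohort.n_subjects, cohort.grid.dims)

        stage = "flip"
        if config.flip:
            masks, flipped = lesion_io.unify_hemisphere(cohort.masks)
            cohort = lesion_io.Cohort(masks=masks, scores=cohort.scores)
            manifest["flipped_subjects"] = flipped
            log.info("flipped %d right-hemisphere masks to the left", len(flipped))

        stage = "overlay"
        overlay = lesion_io.overlay_map(cohort)
        lesion_io.write_volume(out / "overlay.nii.gz", overlay, cohort.grid)
        save_overlay_png(out / "overlay.png", overlay, cohort.grid)
        manifest["overlay_max"] = int(overlay.max())

        stage = "inclusion"
        inclusion, min_lesioned = vlsm.inclusion_mask(cohort, config.coverage)
        lesion_io.write_volume(out / "inclusion.nii.gz", inclusion, cohort.grid)
        manifest["n_subjects"] = cohort.n_subjects
        manifest["min_lesioned"] = min_lesioned
        manifest["n_included_voxels"] = int(inclusion.sum())
        log.info("inclusion: min_lesioned=%d voxels=%d", min_lesioned, inclusion.sum())

        atlas = synthetic.toy_atlas(cohort.grid, config.atlas_blocks)

        stage = f"vlsm:{config.score_a}"
        res_a = vlsm.map_scores(cohort, config.score_a, inclusion, min_lesioned)
        res_a = vlsm.fdr_select(res_a, config.q)
        clusters_a = vlsm.extract_clusters(res_a, config.min_cluster, config.adjacency)
        manifest["vlsm_a"] = _save_result(out, "score_a", res_a, clusters_a, atlas)

        stage = "lenient-threshold"
        if config.lenient_mode == "derived" and res_a.n_significant > 0:
            z_star = vlsm.derive_lenient_threshold(res_a)
            manifest["lenient_source"] = "derived_from_score_a_fdr"
        else:
            z_star = config.lenient_z
            manifest["lenient_source"] = "fixed"
        manifest["z_star"] = z_star
        log.info("lenient threshold z* = %.3f (%s)", z_star, manifest["lenient_source"])

        stage = f"vlsm:{config.score_b}"
        res_b = vlsm.map_scores(cohort, config.score_b, inclusion, min_lesioned)
        res_b = vlsm.lenient_select(res_b, z_star)
        clusters_b = vlsm.extract_clusters(res_b, config.min_cluster, config.adjacency)
        manifest["vlsm_b"] = _save_result(out, "score_b", res_b, clusters_b, atlas)

        stage = "conjunction"
        result = conj.classify(
            res_a.z, res_b.z, inclusion, z_star, config.score_a, config.score_b
        )
        lesion_io.write_volume(out / "conjunction.nii.gz", result.category, cohort.grid)
        conj.tabulate(result, atlas).to_csv(
            out / "conjunction_counts.tsv", sep="\t", index=False
        )
        pct_a, pct_b = conj.selective_fractions(result)
        manifest["conjunction"] = {
            "counts": result.counts,
            "selective_pct_a": pct_a,
            "selective_pct_b": pct_b,
        }
        log.info("conjunction counts: %s", result.counts)

        stage = "manifest"
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=_json_default)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
    return out


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
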