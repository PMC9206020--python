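"""Synthetic stroke cohorts with planted lesion-behavior structure.

The generator emulates the statistical shape of a subacute middle-cerebral-
artery stroke cohort so every pipeline stage can be exercised without
patient data: connected lesion blobs of lognormally distributed volume
confined to one hemisphere's MCA-like territory, an FMA-UL-like paresis
score on [0, 66] depressed by damage to a planted "paresis" region, a
TSRT-like spasticity angle depressed by damage to a smaller, partially
overlapping "spasticity" region, and passive-stretch trials whose reflex
burst fires on a planted linear angle-velocity threshold. The two planted
regions overlap partially by construction, so a conjunction analysis of the
recovered maps has shared and selective voxels to find.

All randomness flows from a single integer seed. Defaults mirror the cohort
conditions the analysis is designed for: n=41 subjects, lesion volumes with
mean ~32 cc, SD ~45 cc in the 0.4-182 cc range, paresis scores with cohort
mean ~32 of 66, spasticity thresholds with cohort mean ~107 deg. The grid is
4 mm isotropic by default (2 mm works through the ``grid`` field) so a full
cohort builds in well under a second.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lesion_io import AtlasVolume, Cohort, LesionMask, VolumeGrid
from .tsrt import StretchTrial

__all__ = [
    "SyntheticSpec",
    "ScoreModel",
    "StretchModel",
    "default_grid",
    "generate_lesions",
    "generate_scores",
    "generate_cohort",
    "generate_stretch_trials",
    "toy_atlas",
]


def default_grid(voxel_mm: float = 4.0, dims: tuple[int, int, int] = (40, 48, 40)) -> VolumeGrid:
    """Centered MNI-style grid: world x right, y anterior, z superior."""
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    affine[:3, 3] = -voxel_mm * (np.array(dims) - 1) / 2.0
    return VolumeGrid(dims=dims, affine=affine)


@dataclass(frozen=True)
class ScoreModel:
    """Linear lesion->deficit model: score = clip(baseline - effect*frac + noise).

    ``frac`` is the fraction of the planted critical region covered by the
    subject's lesion, so ``effect`` is the full-coverage deficit in score
    units. ``ceiling`` of None disables clipping from above.
    """

    baseline: float
    effect: float  # deficit at full regional coverage
    noise_sd: float
    floor: float | None = None
    ceiling: float | None = None


@dataclass(frozen=True)
class StretchModel:
    """Parameters of the simulated passive-stretch protocol."""

    n_trials: int = 20
    slope: float = -0.3  # deg per (deg/s): dynamic threshold vs velocity
    angle_noise_sd: float = 3.0  # trial-to-trial threshold perturbation, deg
    gonio_noise_sd: float = 0.2  # goniometer measurement noise, deg
    fs: float = 1000.0  # Hz
    start_angle_deg: float = 25.0
    end_angle_deg: float = 175.0
    baseline_s: float = 0.5  # pre-stretch rest recorded per trial
    tail_s: float = 0.3
    emg_noise_sd: float = 1.0
    burst_amplitude: float = 20.0
    # velocity bands, deg/s; trials split equally and shuffled (randomized order)
    bands: tuple[tuple[float, float], ...] = ((40.0, 80.0), (90.0, 150.0), (160.0, 240.0))


def _box(lo: tuple[int, int, int], hi: tuple[int, int, int]) -> tuple[slice, slice, slice]:
    return tuple(slice(l, h) for l, h in zip(lo, hi))


@dataclass(frozen=True)
class SyntheticSpec:
    """Everything that defines one synthetic cohort draw."""

    n_subjects: int = 41
    grid: VolumeGrid = field(default_factory=default_grid)
    # sub-box of the grid where lesions may occur (left hemisphere, MCA-like)
    territory_lo: tuple[int, int, int] = (3, 10, 8)
    territory_hi: tuple[int, int, int] = (18, 38, 32)
    # lognormal lesion volume in cc: ln-mean/ln-sd matching mean 31.7, SD 44.7
    volume_mu: float = 2.909
    volume_sigma: float = 1.046
    volume_range_cc: tuple[float, float] = (0.4, 182.3)
    # lesion seeding: mixture of Gaussian foci (sub-territory strokes) plus a
    # uniform component over the whole territory
    seed_centers: tuple[tuple[float, float, float], ...] = (
        (9.5, 20.0, 18.0),
        (10.5, 25.0, 18.5),
    )
    seed_scatter: tuple[float, float, float] = (2.5, 3.0, 3.0)
    uniform_seed_frac: float = 0.25
    # planted critical regions (voxel-index boxes)
    region_a_lo: tuple[int, int, int] = (6, 17, 15)
    region_a_hi: tuple[int, int, int] = (13, 24, 21)
    region_b_lo: tuple[int, int, int] = (8, 22, 16)
    region_b_hi: tuple[int, int, int] = (13, 28, 21)
    score_a: ScoreModel = ScoreModel(baseline=39.5, effect=40.0, noise_sd=6.0, floor=0.0, ceiling=66.0)
    score_b: ScoreModel = ScoreModel(baseline=126.5, effect=84.0, noise_sd=8.0)
    score_a_name: str = "FMA_UL"
    score_b_name: str = "TSRT"
    stretch: StretchModel = StretchModel()
    seed: int = 0

    def region_a(self) -> np.ndarray:
        mask = np.zeros(self.grid.dims, dtype=bool)
        mask[_box(self.region_a_lo, self.region_a_hi)] = True
        return mask

    def region_b(self) -> np.ndarray:
        mask = np.zeros(self.grid.dims, dtype=bool)
        mask[_box(self.region_b_lo, self.region_b_hi)] = True
        return mask

    def territory(self) -> np.ndarray:
        mask = np.zeros(self.grid.dims, dtype=bool)
        mask[_box(self.territory_lo, self.territory_hi)] = True
        return mask

    def __post_init__(self) -> None:
        a, b = self.region_a(), self.region_b()
        t = self.territory()
        if not (a & b).any():
            raise ValueError("planted regions must overlap")
        if not (b & ~a).any():
            raise ValueError("region B must extend outside region A")
        if not (t[a].all() and t[b].all()):
            raise ValueError("planted regions must lie inside the territory")


_NEIGHBOR_OFFSETS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


def _grow_lesion(
    seed_voxel: np.ndarray,
    n_voxels: int,
    territory: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Connected blob of ``n_voxels`` grown by randomized frontier expansion."""
    dims = territory.shape
    lesion = np.zeros(dims, dtype=bool)
    lesion[tuple(seed_voxel)] = True
    frontier = [tuple(seed_voxel)]
    in_frontier = {tuple(seed_voxel)}
    while lesion.sum() < n_voxels and frontier:
        pick = rng.integers(len(frontier))
        vox = np.array(frontier[pick])
        neighbors = vox + _NEIGHBOR_OFFSETS
        valid = []
        for nb in neighbors:
            if (nb < 0).any() or (nb >= dims).any():
                continue
            t = tuple(nb)
            if territory[t] and not lesion[t] and t not in in_frontier:
                valid.append(t)
        if not valid:
            frontier.pop(pick)
            in_frontier.discard(tuple(vox))
            continue
        new = valid[rng.integers(len(valid))]
        lesion[new] = True
        frontier.append(new)
        in_frontier.add(new)
    return lesion


def generate_lesions(spec: SyntheticSpec, rng: np.random.Generator | None = None) -> list[LesionMask]:
    """One connected lesion per subject, inside the territory.

    Seed voxels scatter around the territory focus (so central voxels reach
    the >= 20% coverage needed for voxelwise testing, as in a single-artery
    stroke cohort); volumes are drawn from the lognormal, clipped to the
    cohort range and converted to voxel counts on the spec grid.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    territory = spec.territory()
    territory_idx = np.argwhere(territory)
    voxel_cc = spec.grid.voxel_volume_mm3 / 1000.0
    masks = []
    for i in range(spec.n_subjects):
        cc = float(
            np.clip(
                rng.lognormal(spec.volume_mu, spec.volume_sigma), *spec.volume_range_cc
            )
        )
        n_voxels = int(np.clip(round(cc / voxel_cc), 1, len(territory_idx)))
        while True:
            if rng.random() < spec.uniform_seed_frac:
                seed_voxel = territory_idx[rng.integers(len(territory_idx))]
                break
            center = spec.seed_centers[rng.integers(len(spec.seed_centers))]
            seed_voxel = np.rint(rng.normal(center, spec.seed_scatter)).astype(int)
            if (
                (seed_voxel >= 0).all()
                and (seed_voxel < territory.shape).all()
                and territory[tuple(seed_voxel)]
            ):
                break
        lesion = _grow_lesion(seed_voxel, n_voxels, territory, rng)
        masks.append(
            LesionMask(
                subject_id=f"sub{i + 1:03d}",
                grid=spec.grid,
                data=lesion.astype(np.uint8),
            )
        )
    return masks


def _apply_score_model(
    model: ScoreModel, frac: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    raw = model.baseline - model.effect * frac + rng.normal(0, model.noise_sd, len(frac))
    lo = -np.inf if model.floor is None else model.floor
    hi = np.inf if model.ceiling is None else model.ceiling
    return np.clip(raw, lo, hi)


def generate_scores(
    masks: list[LesionMask],
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Behavioral scores from the planted lesion->deficit models.

    Returns the long scores table and a truth record (per-subject regional
    coverage fractions and the planted parameters) for recovery checks.
    """
    rng = np.random.default_rng(spec.seed + 1) if rng is None else rng
    region_a, region_b = spec.region_a(), spec.region_b()
    frac_a = np.array([m.data[region_a].sum() / region_a.sum() for m in masks])
    frac_b = np.array([m.data[region_b].sum() / region_b.sum() for m in masks])
    vals_a = _apply_score_model(spec.score_a, frac_a, rng)
    vals_b = _apply_score_model(spec.score_b, frac_b, rng)
    ids = [m.subject_id for m in masks]
    scores = pd.DataFrame(
        {
            "subject_id": ids * 2,
            "score": [spec.score_a_name] * len(ids) + [spec.score_b_name] * len(ids),
            "value": np.concatenate([vals_a, vals_b]),
        }
    )
    truth = {
        "region_a": region_a,
        "region_b": region_b,
        "frac_a": frac_a,
        "frac_b": frac_b,
        "spec": spec,
    }
    return scores, truth


def generate_cohort(spec: SyntheticSpec = SyntheticSpec()) -> tuple[Cohort, dict]:
    """Lesions plus scores as a ready-to-analyze :class:`Cohort`."""
    rng = np.random.default_rng(spec.seed)
    masks = generate_lesions(spec, rng)
    scores, truth = generate_scores(masks, spec, rng)
    return Cohort(masks=masks, scores=scores), truth


def generate_stretch_trials(
    tsrt_true: float,
    model: StretchModel = StretchModel(),
    seed: int = 0,
) -> list[StretchTrial]:
    """Simulated passive-stretch series with a planted linear threshold.

    Each trial ramps the elbow from the start angle toward full extension at
    a velocity drawn from one of the slow/moderate/fast bands (equal split,
    shuffled order, mirroring randomized stretch presentation). The reflex
    burst switches on when the true angle crosses the planted dynamic
    threshold ``tsrt_true + slope * velocity`` perturbed by trial noise; a
    threshold never reached within the ramp yields a burst-free trial, which
    downstream exclusion logic must handle.
    """
    rng = np.random.default_rng(seed)
    per_band = model.n_trials // len(model.bands)
    extra = model.n_trials - per_band * len(model.bands)
    band_of_trial = [i for i in range(len(model.bands)) for _ in range(per_band)]
    band_of_trial += list(rng.integers(len(model.bands), size=extra))
    rng.shuffle(band_of_trial)
    band_names = (
        ["slow", "moderate", "fast"]
        if len(model.bands) == 3
        else [f"band{i}" for i in range(len(model.bands))]
    )
    trials = []
    for k, band_idx in enumerate(band_of_trial):
        lo, hi = model.bands[band_idx]
        velocity = float(rng.uniform(lo, hi))
        ramp_s = (model.end_angle_deg - model.start_angle_deg) / velocity
        n = int(round((model.baseline_s + ramp_s + model.tail_s) * model.fs))
        t = np.arange(n) / model.fs
        angle_true = np.clip(
            model.start_angle_deg + velocity * (t - model.baseline_s),
            model.start_angle_deg,
            model.end_angle_deg,
        )
        angle = angle_true + rng.normal(0, model.gonio_noise_sd, n)
        angle = np.clip(angle, 0.0, 180.0)
        emg = rng.normal(0, model.emg_noise_sd, n)
        threshold = tsrt_true + model.slope * velocity + rng.normal(0, model.angle_noise_sd)
        crossing = np.flatnonzero(angle_true >= threshold)
        if len(crossing) and angle_true[-1] > angle_true[0]:
            onset = int(crossing[0])
            burst_sign = rng.choice([-1.0, 1.0], size=n - onset)
            emg[onset:] += model.burst_amplitude * burst_sign
        trials.append(
            StretchTrial(
                trial_id=f"trial{k + 1:02d}",
                fs=model.fs,
                angle=angle,
                emg=emg,
                nominal_speed=band_names[band_idx],
            )
        )
    return trials


def toy_atlas(grid: VolumeGrid, n_per_axis: tuple[int, int, int] = (2, 3, 2)) -> AtlasVolume:
    """Block parcellation standing in for an anatomical atlas.

    Splits the grid into a small number of convex box "structures"; the
    damage-tabulation logic is atlas-agnostic, so any label volume works.
    """
    labels = np.zeros(grid.dims, dtype=np.int32)
    edges = [
        np.linspace(0, d, n + 1).astype(int) for d, n in zip(grid.dims, n_per_axis)
    ]
    names = {}
    label = 0
    for i in range(n_per_axis[0]):
        for j in range(n_per_axis[1]):
            for k in range(n_per_axis[2]):
                label += 1
                labels[
                    edges[0][i] : edges[0][i + 1],
                    edges[1][j] : edges[1][j + 1],
                    edges[2][k] : edges[2][k + 1],
                ] = label
                names[label] = f"block_{i}{j}{k}"
    return AtlasVolume(grid=grid, labels=labels, names=names)
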