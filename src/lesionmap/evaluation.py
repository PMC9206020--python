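"""Planted-truth validation runs on synthetic cohorts.

These routines measure how well the analysis chain recovers what the
generator planted: Dice overlap between each score's lenient significance
map and its planted critical region, false-positive behaviour of the FDR
selection under zero-effect cohorts, and Monte-Carlo recovery of a planted
tonic stretch reflex threshold. They drive both the test suite and the
reproduction script.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from . import synthetic, tsrt, vlsm
from .conjunction import classify

__all__ = [
    "dice",
    "RecoveryResult",
    "planted_region_recovery",
    "null_calibration",
    "tsrt_monte_carlo",
    "tsrt_full_chain",
]


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) of two boolean volumes."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = int(a.sum()) + int(b.sum())
    return 2.0 * int((a & b).sum()) / denom if denom else float("nan")


@dataclass
class RecoveryResult:
    """Per-seed planted-region recovery of one synthetic cohort."""

    seed: int
    dice_a: float
    dice_b: float
    z_star: float
    both_hits_overlap: int  # conjunction "both" voxels inside region A ∩ B
    n_included: int


def planted_region_recovery(
    seeds: range | list[int],
    spec: synthetic.SyntheticSpec | None = None,
) -> list[RecoveryResult]:
    """Run the full VLSM chain on synthetic cohorts and score localization.

    For each seed: generate a cohort, build the coverage mask, FDR-select the
    paresis map, derive the lenient z from its minimum surviving z, threshold
    both maps there, and compare each significance map with its planted
    region restricted to the tested voxels.
    """
    base = synthetic.SyntheticSpec() if spec is None else spec
    out = []
    for seed in seeds:
        s = dataclasses.replace(base, seed=int(seed))
        cohort, truth = synthetic.generate_cohort(s)
        inclusion, min_lesioned = vlsm.inclusion_mask(cohort)
        res_a = vlsm.fdr_select(
            vlsm.map_scores(cohort, s.score_a_name, inclusion, min_lesioned)
        )
        if res_a.n_significant == 0:
            out.append(
                RecoveryResult(seed, 0.0, 0.0, float("nan"), 0, int(inclusion.sum()))
            )
            continue
        z_star = vlsm.derive_lenient_threshold(res_a)
        sel_a = vlsm.lenient_select(res_a, z_star)
        res_b = vlsm.lenient_select(
            vlsm.map_scores(cohort, s.score_b_name, inclusion, min_lesioned), z_star
        )
        conj = classify(res_a.z, res_b.z, inclusion, z_star)
        overlap = truth["region_a"] & truth["region_b"]
        out.append(
            RecoveryResult(
                seed=seed,
                dice_a=dice(sel_a.sig, truth["region_a"] & inclusion),
                dice_b=dice(res_b.sig, truth["region_b"] & inclusion),
                z_star=z_star,
                both_hits_overlap=int(((conj.category == 3) & overlap).sum()),
                n_included=int(inclusion.sum()),
            )
        )
    return out


def null_calibration(
    seeds: range | list[int],
    spec: synthetic.SyntheticSpec | None = None,
    q: float = 0.05,
) -> int:
    """Count seeds whose zero-effect cohorts yield empty FDR selections.

    Both scores are generated with their lesion effects disabled, so any FDR
    rejection is a false positive at the map level.
    """
    base = synthetic.SyntheticSpec() if spec is None else spec
    empty = 0
    for seed in seeds:
        s = dataclasses.replace(
            base,
            seed=int(seed),
            score_a=dataclasses.replace(base.score_a, effect=0.0),
            score_b=dataclasses.replace(base.score_b, effect=0.0),
        )
        cohort, _ = synthetic.generate_cohort(s)
        inclusion, min_lesioned = vlsm.inclusion_mask(cohort)
        res_a = vlsm.fdr_select(
            vlsm.map_scores(cohort, s.score_a_name, inclusion, min_lesioned), q
        )
        res_b = vlsm.fdr_select(
            vlsm.map_scores(cohort, s.score_b_name, inclusion, min_lesioned), q
        )
        if res_a.n_significant == 0 and res_b.n_significant == 0:
            empty += 1
    return empty


def tsrt_monte_carlo(
    n_replicates: int = 500,
    tsrt_true: float = 107.4,
    seed: int = 0,
    model: synthetic.StretchModel | None = None,
) -> np.ndarray:
    """Intercept errors of the threshold regression under the noise model.

    Each replicate draws 20 dynamic thresholds (velocities split equally
    across the slow/moderate/fast bands, angles on the planted line with the
    configured angle noise) and refits the zero-velocity extrapolation.
    Returns the vector of (estimate - truth) errors in degrees.
    """
    model = synthetic.StretchModel() if model is None else model
    rng = np.random.default_rng(seed)
    errors = np.empty(n_replicates)
    per_band = model.n_trials // len(model.bands)
    for rep in range(n_replicates):
        velocities = np.concatenate(
            [rng.uniform(lo, hi, per_band) for lo, hi in model.bands]
        )
        extra = model.n_trials - len(velocities)
        if extra:
            lo, hi = model.bands[rng.integers(len(model.bands))]
            velocities = np.concatenate([velocities, rng.uniform(lo, hi, extra)])
        angles = (
            tsrt_true
            + model.slope * velocities
            + rng.normal(0, model.angle_noise_sd, len(velocities))
        )
        thresholds = [
            tsrt.DynamicThreshold(f"t{i}", 0, a, v)
            for i, (a, v) in enumerate(zip(angles, velocities))
        ]
        errors[rep] = tsrt.estimate_tsrt(thresholds).tsrt_deg - tsrt_true
    return errors


def tsrt_full_chain(
    tsrt_true: float = 107.4,
    seed: int = 0,
    model: synthetic.StretchModel | None = None,
) -> tsrt.TsrtEstimate:
    """Simulate one 20-stretch series and run the complete estimation chain."""
    model = synthetic.StretchModel() if model is None else model
    trials = synthetic.generate_stretch_trials(tsrt_true, model, seed=seed)
    estimate, _ = tsrt.run_protocol(trials)
    return estimate
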