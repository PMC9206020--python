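"""Tonic stretch reflex threshold (TSRT) estimation from passive stretches.

A relaxed elbow flexor is stretched at varied velocities while its surface
EMG and the elbow angle are recorded. At each stretch the reflex fires at a
velocity-dependent *dynamic* threshold: the joint angle at which the EMG
rises and stays above background. Regressing those dynamic threshold angles
on their stretch velocities and extrapolating to zero velocity gives the
TSRT - the angle at which the stretch reflex would engage in the resting
muscle. A TSRT inside the biomechanical range (here 180 deg = full elbow
extension) means the muscle cannot be fully relaxed across the range; a
smaller angle means more severe spasticity.

Angles are in degrees and velocities in degrees/second throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StretchTrial",
    "DynamicThreshold",
    "TsrtEstimate",
    "TsrtConfig",
    "rectified_envelope",
    "smoothed_velocity",
    "stretch_start",
    "detect_onset",
    "dynamic_threshold",
    "estimate_tsrt",
    "run_protocol",
    "read_trials",
]

#: Joint angle of full elbow extension, the end of the biomechanical range.
FULL_EXTENSION_DEG = 180.0


@dataclass(frozen=True)
class StretchTrial:
    """One passive-stretch recording: angle and EMG traces at a fixed rate."""

    trial_id: str
    fs: float  # Hz
    angle: np.ndarray  # degrees
    emg: np.ndarray  # arbitrary amplitude units
    nominal_speed: str = "moderate"  # slow | moderate | fast

    def __post_init__(self) -> None:
        angle = np.asarray(self.angle, dtype=float)
        emg = np.asarray(self.emg, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if angle.shape != emg.shape or angle.ndim != 1:
            raise ValueError("angle and emg must be 1D traces of equal length")
        if len(angle) < 2:
            raise ValueError("trial too short")
        if np.nanmin(angle) < 0 or np.nanmax(angle) > FULL_EXTENSION_DEG:
            raise ValueError("angles must lie in [0, 180] degrees")
        object.__setattr__(self, "angle", angle)
        object.__setattr__(self, "emg", emg)


@dataclass(frozen=True)
class DynamicThreshold:
    """Angle/velocity at which one stretch elicited the reflex response."""

    trial_id: str
    onset_sample: int
    angle_deg: float
    velocity_dps: float


@dataclass(frozen=True)
class TsrtEstimate:
    """Zero-velocity extrapolation of the dynamic thresholds."""

    tsrt_deg: float  # regression intercept at zero velocity
    slope: float  # degrees per (degree/second)
    n_trials_used: int
    r_squared: float
    residual_sd: float  # degrees
    in_range: bool  # tsrt_deg <= 180 (inside the biomechanical range)


@dataclass(frozen=True)
class TsrtConfig:
    """Detection and fitting parameters for the 20-stretch protocol.

    The EMG chain is full-wave rectification followed by a moving-average
    envelope; background statistics come from a pre-stretch baseline window
    and onset requires the envelope to stay ``k_sd`` SDs above background for
    ``persist_ms``. Defaults: 20 ms envelope, 200 ms baseline, 3 SD, 25 ms.
    """

    baseline_ms: float = 200.0
    k_sd: float = 3.0
    persist_ms: float = 25.0
    envelope_ms: float = 20.0
    angle_smooth_ms: float = 50.0
    velocity_start_dps: float = 5.0  # angular speed defining stretch start
    min_trials: int = 5


def _window_samples(ms: float, fs: float) -> int:
    return max(1, int(round(ms * fs / 1000.0)))


def rectified_envelope(emg: np.ndarray, fs: float, envelope_ms: float = 20.0) -> np.ndarray:
    """Full-wave rectified EMG smoothed with a causal moving average.

    The window trails the current sample so the envelope never anticipates a
    burst; early samples average over the partial window.
    """
    rect = np.abs(np.asarray(emg, dtype=float))
    w = _window_samples(envelope_ms, fs)
    csum = np.concatenate([[0.0], np.cumsum(rect)])
    t = np.arange(len(rect))
    lo = np.maximum(t - w + 1, 0)
    return (csum[t + 1] - csum[lo]) / (t + 1 - lo)


def _smooth_angle(angle: np.ndarray, fs: float, smooth_ms: float) -> np.ndarray:
    from scipy.ndimage import uniform_filter1d

    w = _window_samples(smooth_ms, fs)
    return uniform_filter1d(np.asarray(angle, dtype=float), size=w, mode="nearest")


def smoothed_velocity(
    angle: np.ndarray, fs: float, smooth_ms: float = 50.0
) -> np.ndarray:
    """Angular velocity (deg/s): centered difference of the smoothed trace.

    The difference half-span equals half the smoothing window, so the
    velocity noise floor scales with the smoothing rather than the raw
    sample spacing (a single-sample stencil at 1 kHz would amplify 0.2 deg
    of goniometer noise into several deg/s). Edge samples copy the nearest
    interior estimate; exact for a linear ramp.
    """
    a = _smooth_angle(angle, fs, smooth_ms)
    h = max(1, _window_samples(smooth_ms, fs) // 2)
    v = np.empty_like(a)
    if len(a) <= 2 * h:
        return np.gradient(a) * fs
    v[h:-h] = (a[2 * h :] - a[: -2 * h]) * (fs / (2 * h))
    v[:h] = v[h]
    v[-h:] = v[-h - 1]
    return v


def stretch_start(trial: StretchTrial, config: TsrtConfig = TsrtConfig()) -> int:
    """First sample where the smoothed angular speed exceeds the start criterion.

    The exceedance must persist for half the smoothing window, and the first
    full smoothing window is skipped (its velocity estimates are edge-
    contaminated), so goniometer noise cannot trigger a spurious start.
    """
    v = smoothed_velocity(trial.angle, trial.fs, config.angle_smooth_ms)
    w = _window_samples(config.angle_smooth_ms, trial.fs)
    persist = max(1, w // 2)
    above = v > config.velocity_start_dps
    runs = np.convolve(above.astype(np.int32), np.ones(persist, dtype=np.int32), "valid")
    moving = np.flatnonzero(runs == persist)
    moving = moving[moving >= w]
    if len(moving) == 0:
        raise ValueError(f"trial {trial.trial_id}: no stretch phase found")
    return int(moving[0])


def detect_onset(
    trial: StretchTrial,
    config: TsrtConfig = TsrtConfig(),
    start: int | None = None,
) -> int | None:
    """First sample from stretch start whose envelope stays above threshold.

    Threshold is baseline mean + k_sd * baseline SD of the envelope, computed
    over the ``baseline_ms`` window immediately preceding stretch start; the
    exceedance must persist for ``persist_ms``. Returns None when no burst
    satisfies the rule (e.g. the reflex threshold was never crossed).
    """
    env = rectified_envelope(trial.emg, trial.fs, config.envelope_ms)
    t0 = stretch_start(trial, config) if start is None else int(start)
    wb = _window_samples(config.baseline_ms, trial.fs)
    b_lo = max(0, t0 - wb)
    # Background level statistics come from the rectified RAW signal: the
    # envelope's own SD is shrunk by the averaging window, and k_sd times it
    # would be a margin that smoothed baseline noise drifts across.
    baseline = np.abs(np.asarray(trial.emg, dtype=float))[b_lo:t0]
    if len(baseline) < 2:
        raise ValueError(f"trial {trial.trial_id}: baseline window is empty")
    b_sd = float(baseline.std(ddof=1))
    if b_sd == 0:
        raise ValueError(f"trial {trial.trial_id}: degenerate (zero-variance) baseline EMG")
    threshold = float(baseline.mean()) + config.k_sd * b_sd
    persist = _window_samples(config.persist_ms, trial.fs)
    above = env > threshold
    if len(above) < persist:
        return None
    # run of `persist` consecutive exceedances starting at t
    runs = np.convolve(above.astype(np.int32), np.ones(persist, dtype=np.int32), "valid")
    candidates = np.flatnonzero(runs == persist)
    candidates = candidates[candidates >= t0]
    return int(candidates[0]) if len(candidates) else None


def dynamic_threshold(
    trial: StretchTrial, onset: int, config: TsrtConfig = TsrtConfig()
) -> DynamicThreshold:
    """Angle and velocity at the detected reflex onset."""
    if not 2 <= onset < len(trial.angle) - 2:
        raise ValueError(
            f"trial {trial.trial_id}: onset {onset} too close to the trace boundary"
        )
    velocity = smoothed_velocity(trial.angle, trial.fs, config.angle_smooth_ms)[onset]
    return DynamicThreshold(
        trial_id=trial.trial_id,
        onset_sample=int(onset),
        angle_deg=float(trial.angle[onset]),
        velocity_dps=float(velocity),
    )


def estimate_tsrt(
    thresholds: list[DynamicThreshold], min_trials: int = 5
) -> TsrtEstimate:
    """OLS of dynamic threshold angle on stretch velocity; TSRT = intercept.

    Only thresholds with positive velocity (stretch direction) are usable.
    The estimate is order-free in the trials. An intercept above 180 deg is
    returned as-is with ``in_range=False``: it encodes a reflex threshold
    outside the biomechanical range (a muscle that can fully relax), and
    clamping it would destroy that information.
    """
    usable = [t for t in thresholds if t.velocity_dps > 0]
    if len(usable) < max(min_trials, 2):
        raise ValueError(
            f"need >= {max(min_trials, 2)} usable thresholds, got {len(usable)}"
        )
    v = np.array([t.velocity_dps for t in usable])
    a = np.array([t.angle_deg for t in usable])
    if np.ptp(v) == 0:
        raise ValueError("all stretch velocities identical; slope unidentifiable")
    fit = stats.linregress(v, a)
    residuals = a - (fit.intercept + fit.slope * v)
    dof = len(usable) - 2
    residual_sd = float(np.sqrt((residuals**2).sum() / dof)) if dof > 0 else 0.0
    return TsrtEstimate(
        tsrt_deg=float(fit.intercept),
        slope=float(fit.slope),
        n_trials_used=len(usable),
        r_squared=float(fit.rvalue**2),
        residual_sd=residual_sd,
        in_range=bool(fit.intercept <= FULL_EXTENSION_DEG),
    )


def run_protocol(
    trials: list[StretchTrial], config: TsrtConfig = TsrtConfig()
) -> tuple[TsrtEstimate, pd.DataFrame]:
    """Full chain over a stretch series: onsets -> thresholds -> regression.

    Trials with no detected burst or non-positive onset velocity are excluded
    and tallied. Returns the estimate and a per-trial log with columns
    trial_id, used, reason, onset_sample, angle_deg, velocity_dps.
    """
    if not trials:
        raise ValueError("no trials supplied")
    thresholds: list[DynamicThreshold] = []
    log_rows = []
    for trial in trials:
        row = {
            "trial_id": trial.trial_id,
            "used": False,
            "reason": "",
            "onset_sample": pd.NA,
            "angle_deg": np.nan,
            "velocity_dps": np.nan,
        }
        onset = detect_onset(trial, config)
        if onset is None:
            row["reason"] = "no_burst"
        else:
            dt = dynamic_threshold(trial, onset, config)
            row["onset_sample"] = dt.onset_sample
            row["angle_deg"] = dt.angle_deg
            row["velocity_dps"] = dt.velocity_dps
            if dt.velocity_dps <= 0:
                row["reason"] = "nonpositive_velocity"
            else:
                row["used"] = True
                thresholds.append(dt)
        log_rows.append(row)
    log = pd.DataFrame(log_rows)
    if len(thresholds) < config.min_trials:
        raise ValueError(
            f"only {len(thresholds)} usable trials after exclusions "
            f"(minimum {config.min_trials}); exclusions: "
            f"{log.loc[~log['used'], 'reason'].value_counts().to_dict()}"
        )
    estimate = estimate_tsrt(thresholds, config.min_trials)
    return estimate, log


def read_trials(manifest_path: str) -> list[StretchTrial]:
    """Load a stretch series from a manifest TSV (trial_id, file, nominal_speed).

    Each trial file is a TSV with columns time_s, angle_deg, emg; the
    sampling rate is inferred from the time column and must be uniform.
    """
    from pathlib import Path

    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path, sep="\t")
    required = {"trial_id", "file"}
    if not required.issubset(manifest.columns):
        raise ValueError("manifest must have columns trial_id and file")
    trials = []
    for rec in manifest.to_dict("records"):
        path = manifest_path.parent / rec["file"]
        df = pd.read_csv(path, sep="\t")
        t = df["time_s"].to_numpy(dtype=float)
        dt = np.diff(t)
        if len(dt) == 0 or not np.allclose(dt, dt[0], rtol=1e-4):
            raise ValueError(f"{path}: time column is not uniformly sampled")
        trials.append(
            StretchTrial(
                trial_id=str(rec["trial_id"]),
                fs=1.0 / dt[0],
                angle=df["angle_deg"].to_numpy(dtype=float),
                emg=df["emg"].to_numpy(dtype=float),
                nominal_speed=str(rec.get("nominal_speed", "moderate")),
            )
        )
    return trials
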