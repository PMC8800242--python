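"""Synthetic elbow-flexion trials standing in for the tracking hardware.

The simulator drives a planar two-segment linkage: the humerus is fixed,
the forearm rotates about the epicondylar axis through ramp-and-hold
trajectories (three-second holds separated by one-second ramps). Two
bone-fixed sensors and a digitizing stylus are emulated with the tracker's
stated accuracy (0.76 mm RMS position, 0.15° RMS orientation, 60 Hz);
examiner hold placement jitters by a configurable SD. In-vivo mode adds a
soft-tissue artifact — a per-hold random rotation of the forearm sensor
whose SD grows in proportion to the true flexion angle, mimicking brace
displacement from biceps contraction — and draws a paired radiographic
reading as ground truth plus small Gaussian error.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .agreement import (
    BlandAltmanResult,
    CorrelationResult,
    ICCResult,
    bland_altman,
    icc,
    pearson,
)
from .kinematics import AngleSeries, angle_timeseries
from .plateau import DEFAULT_NOMINALS, detect_plateaus, match_to_nominal, summarize_by_nominal
from .registration import (
    FOREARM,
    HUMERUS,
    HOST_SENSOR,
    Landmark,
    LandmarkRegistry,
    digitize_landmark,
)
from .rigid import PoseStream, ValidationError, rotation_quaternion

__all__ = [
    "SimConfig",
    "SimulatedTrial",
    "ValidationReport",
    "simulate_model_bone_trial",
    "simulate_in_vivo_trial",
    "run_validation_experiment",
]


@dataclass(frozen=True)
class SimConfig:
    """Geometry, noise, and protocol parameters of a simulated trial.

    Lengths in mm, times in seconds, angles/SDs in degrees. Noise levels
    default to the tracker's stated RMS accuracy; setting them to zero
    gives the exact noiseless linkage.
    """

    humerus_length: float = 300.0
    forearm_length: float = 250.0
    epicondylar_halfwidth: float = 30.0
    wrist_halfwidth: float = 25.0
    sensor_offset: float = 20.0
    rate_hz: float = 60.0
    pos_noise_rms: float = 0.76
    ori_noise_rms: float = 0.15
    hold_s: float = 3.0
    ramp_s: float = 1.0
    hold_sd_deg: float = 1.0
    digitization_noise_mm: float = 0.76
    n_digitize_samples: int = 60
    artifact_gain: float = 0.08
    xray_noise_sd_deg: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "humerus_length",
            "forearm_length",
            "epicondylar_halfwidth",
            "wrist_halfwidth",
            "sensor_offset",
            "rate_hz",
            "hold_s",
            "ramp_s",
        ):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive, got {getattr(self, name)}")
        for name in (
            "pos_noise_rms",
            "ori_noise_rms",
            "hold_sd_deg",
            "digitization_noise_mm",
            "artifact_gain",
            "xray_noise_sd_deg",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative, got {getattr(self, name)}")
        if self.n_digitize_samples < 1:
            raise ValidationError("n_digitize_samples must be at least 1")


@dataclass
class SimulatedTrial:
    """One simulated recording plus its ground truth."""

    humerus_stream: PoseStream
    forearm_stream: PoseStream
    registry: LandmarkRegistry
    truth: AngleSeries
    config: SimConfig
    hold_targets: list[float]
    xray_readings: list[float] | None = None


# fixed, arbitrary mounting orientations of the two bone sensors; any
# non-trivial rotation exercises the full transform chain
_R_HUMERUS_SENSOR = Rotation.from_euler("xyz", [15.0, -10.0, 25.0], degrees=True)
_R_FOREARM_SENSOR = Rotation.from_euler("xyz", [-20.0, 5.0, 40.0], degrees=True)


def _skeleton(cfg: SimConfig):
    """Straight-arm world geometry: landmark positions and sensor poses.

    The humeral shaft runs along +z with the epicondylar midpoint at the
    origin and the epicondylar axis along x; the straight forearm extends
    along −z. Flexion rotates the forearm rigidly about +x.
    """
    landmarks = {
        Landmark.GREATER_TUBERCLE: np.array([0.0, 0.0, cfg.humerus_length]),
        Landmark.MEDIAL_EPICONDYLE: np.array([-cfg.epicondylar_halfwidth, 0.0, 0.0]),
        Landmark.LATERAL_EPICONDYLE: np.array([cfg.epicondylar_halfwidth, 0.0, 0.0]),
        Landmark.RADIAL_STYLOID: np.array([cfg.wrist_halfwidth, 0.0, -cfg.forearm_length]),
        Landmark.ULNAR_STYLOID: np.array([-cfg.wrist_halfwidth, 0.0, -cfg.forearm_length]),
    }
    humerus_pos = np.array([0.0, cfg.sensor_offset, cfg.humerus_length / 2.0])
    forearm_pos = np.array([0.0, cfg.sensor_offset, -cfg.forearm_length / 2.0])
    return landmarks, (humerus_pos, _R_HUMERUS_SENSOR), (forearm_pos, _R_FOREARM_SENSOR)


def _ramp_hold(values, hold_s: float, ramp_s: float, rate_hz: float) -> np.ndarray:
    """Per-sample trajectory holding each value, cosine-easing between them."""
    n_hold = max(1, int(round(hold_s * rate_hz)))
    n_ramp = max(1, int(round(ramp_s * rate_hz)))
    pieces = []
    for j, v in enumerate(values):
        if j > 0:
            frac = np.arange(1, n_ramp + 1) / n_ramp
            ease = 0.5 - 0.5 * np.cos(np.pi * frac)
            pieces.append(values[j - 1] + (v - values[j - 1]) * ease)
        pieces.append(np.full(n_hold, v))
    return np.concatenate(pieces)


def _position_noise(rng: np.random.Generator, shape, rms: float) -> np.ndarray:
    # per-axis sigma = rms/sqrt(3) makes the 3-D vector-norm RMS equal rms
    if rms == 0.0:
        return np.zeros(shape)
    return rng.normal(0.0, rms / np.sqrt(3.0), shape)


def _orientation_noise(rng: np.random.Generator, n: int, rms_deg: float) -> Rotation:
    """Small random rotations: |N(0, rms²)| angle about a uniform axis."""
    if rms_deg == 0.0:
        return Rotation.from_rotvec(np.zeros((n, 3)))
    angles = np.abs(rng.normal(0.0, np.radians(rms_deg), n))
    axes = rng.normal(size=(n, 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    return Rotation.from_rotvec(axes * angles[:, None])


def _noisy_stream(
    rng: np.random.Generator,
    sensor_id: str,
    t: np.ndarray,
    positions: np.ndarray,
    rotations: Rotation,
    cfg: SimConfig,
) -> PoseStream:
    n = t.size
    pos = positions + _position_noise(rng, (n, 3), cfg.pos_noise_rms)
    rot = _orientation_noise(rng, n, cfg.ori_noise_rms) * rotations
    return PoseStream(
        sensor_id=sensor_id,
        t=t,
        positions=pos,
        orientations=rotation_quaternion(rot),
        rate_hz=cfg.rate_hz,
    )


def _digitize_registry(rng: np.random.Generator, cfg: SimConfig) -> LandmarkRegistry:
    """Emulate the stylus protocol: touch each landmark at the straight arm.

    The host sensor stream carries the tracker's own noise; the stylus tip
    scatters around the true landmark with the digitization noise level.
    """
    landmarks, (h_pos, h_rot), (f_pos, f_rot) = _skeleton(cfg)
    t = np.arange(cfg.n_digitize_samples) / cfg.rate_hz
    n = cfg.n_digitize_samples
    entries = {}
    for lm in Landmark:
        base_pos, base_rot = (h_pos, h_rot) if HOST_SENSOR[lm] == HUMERUS else (f_pos, f_rot)
        host = _noisy_stream(
            rng,
            HOST_SENSOR[lm],
            t,
            np.broadcast_to(base_pos, (n, 3)),
            Rotation.concatenate([base_rot] * n),
            cfg,
        )
        tips = landmarks[lm] + _position_noise(rng, (n, 3), cfg.digitization_noise_mm)
        stylus = PoseStream(
            sensor_id="stylus",
            t=t,
            positions=tips,
            orientations=np.tile([1.0, 0.0, 0.0, 0.0], (n, 1)),
            rate_hz=cfg.rate_hz,
        )
        entries[lm] = digitize_landmark(stylus, host, lm)
    return LandmarkRegistry(entries=entries)


def _simulate_trial(
    cfg: SimConfig,
    hold_targets: list[float],
    artifact_targets: list[float] | None,
    rng: np.random.Generator,
) -> SimulatedTrial:
    registry = _digitize_registry(rng, cfg)
    _, (h_pos, h_rot), (f_pos, f_rot) = _skeleton(cfg)

    phi = _ramp_hold(hold_targets, cfg.hold_s, cfg.ramp_s, cfg.rate_hz)
    art = (
        _ramp_hold(artifact_targets, cfg.hold_s, cfg.ramp_s, cfg.rate_hz)
        if artifact_targets is not None
        else np.zeros_like(phi)
    )
    t = np.arange(phi.size) / cfg.rate_hz

    # forearm segment rotates about the epicondylar axis (+x through the
    # epicondylar midpoint); the soft-tissue artifact rotates the sensor
    # (not the bone), so it enters the sensor pose but not the truth
    flex = Rotation.from_rotvec(np.outer(np.radians(phi + art), [1.0, 0.0, 0.0]))
    forearm_positions = flex.apply(f_pos)
    forearm_rotations = flex * f_rot

    n = t.size
    humerus_stream = _noisy_stream(
        rng, HUMERUS, t, np.broadcast_to(h_pos, (n, 3)), Rotation.concatenate([h_rot] * n), cfg
    )
    forearm_stream = _noisy_stream(rng, FOREARM, t, forearm_positions, forearm_rotations, cfg)

    # the acos-style angle cannot be negative: slight hyperextension folds
    truth = AngleSeries(t=t, phi=np.abs(phi))
    return SimulatedTrial(
        humerus_stream=humerus_stream,
        forearm_stream=forearm_stream,
        registry=registry,
        truth=truth,
        config=cfg,
        hold_targets=[float(v) for v in hold_targets],
    )


def simulate_model_bone_trial(cfg: SimConfig, nominal=DEFAULT_NOMINALS) -> SimulatedTrial:
    """One model-bone trial: holds at each nominal angle plus examiner jitter.

    The examiner pauses at each nominal target; actual held angles deviate
    by N(0, ``hold_sd_deg``²) per hold. Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    targets = [float(v) + rng.normal(0.0, cfg.hold_sd_deg) if cfg.hold_sd_deg > 0 else float(v)
               for v in nominal]
    return _simulate_trial(cfg, targets, None, rng)


def simulate_in_vivo_trial(cfg: SimConfig, extremes: tuple[float, float]) -> SimulatedTrial:
    """One in-vivo trial: hold at maximum extension, then maximum flexion.

    The forearm sensor additionally suffers a per-hold soft-tissue
    artifact rotation with SD = ``artifact_gain`` × true angle, and each
    extreme gets a paired radiographic reading (truth + Gaussian error).
    """
    extension_true, flexion_true = (float(v) for v in extremes)
    if not (0.0 <= extension_true < flexion_true <= 180.0):
        raise ValidationError(
            f"extremes must satisfy 0 <= extension < flexion <= 180, got {extremes}"
        )
    rng = np.random.default_rng(cfg.seed)
    held = [v + rng.normal(0.0, cfg.hold_sd_deg) if cfg.hold_sd_deg > 0 else v
            for v in (extension_true, flexion_true)]
    held = [abs(v) for v in held]
    artifacts = [rng.normal(0.0, cfg.artifact_gain * v) if cfg.artifact_gain > 0 else 0.0
                 for v in held]
    trial = _simulate_trial(cfg, held, artifacts, rng)
    trial.xray_readings = [
        v + (rng.normal(0.0, cfg.xray_noise_sd_deg) if cfg.xray_noise_sd_deg > 0 else 0.0)
        for v in held
    ]
    return trial


def _measure_trial(trial: SimulatedTrial, nominal=None) -> list:
    """EMS angle per hold: plateau means of the reconstructed angle series."""
    series = angle_timeseries(trial.humerus_stream, trial.forearm_stream, trial.registry)
    plateaus = detect_plateaus(series)
    if nominal is not None:
        return match_to_nominal(plateaus, nominal=nominal)
    return plateaus


@dataclass
class ValidationReport:
    """Full accuracy/reliability analysis of a batch of simulated trials."""

    mode: str
    measurements: pd.DataFrame
    summary: pd.DataFrame
    pearson: dict[str, CorrelationResult]
    icc: list[ICCResult]
    bland_altman: dict[str, BlandAltmanResult] = field(default_factory=dict)

    def max_abs_error(self) -> float:
        """Model-bone: worst per-nominal |mean measured − nominal|."""
        err = self.summary["mean_deg"] - self.summary.index.to_numpy(dtype=float)
        return float(err.abs().max())

    def max_sd(self) -> float:
        """Model-bone: worst per-nominal SD of plateau means."""
        return float(self.summary["sd_deg"].max())

    def icc_by_label(self, label: str) -> ICCResult:
        for r in self.icc:
            if r.label == label:
                return r
        raise KeyError(label)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "summary": self.summary.reset_index().to_dict(orient="records"),
            "pearson": {k: v.to_dict() for k, v in self.pearson.items()},
            "bland_altman": {k: v.to_dict() for k, v in self.bland_altman.items()},
            "icc": [r.to_dict() for r in self.icc],
        }


def _model_bone_experiment(cfg: SimConfig, n_reps: int, n_raters: int) -> ValidationReport:
    nominal = DEFAULT_NOMINALS
    rows = []
    trial_plateaus = []
    trial_index = 0
    for rater in range(n_raters):
        for rep in range(n_reps):
            sub = dataclasses.replace(cfg, seed=cfg.seed + trial_index)
            trial_index += 1
            trial = simulate_model_bone_trial(sub, nominal=nominal)
            matched = _measure_trial(trial, nominal=nominal)
            trial_plateaus.append(matched)
            for p in matched:
                if p.nominal_deg is not None:
                    rows.append(
                        {
                            "rater": rater,
                            "rep": rep,
                            "nominal_deg": p.nominal_deg,
                            "measured_deg": p.mean_deg,
                            "within_sd_deg": p.sd_deg,
                        }
                    )
    df = pd.DataFrame(rows)
    summary = summarize_by_nominal(trial_plateaus)
    corr = pearson(df["nominal_deg"], df["measured_deg"])

    iccs: list[ICCResult] = []
    for rater in range(n_raters):
        mat = (
            df[df.rater == rater]
            .pivot(index="nominal_deg", columns="rep", values="measured_deg")
            .to_numpy()
        )
        for unit in ("single", "average"):
            res = icc(mat, model="oneway", unit=unit)
            iccs.append(dataclasses.replace(res, label=f"intra_rater_{rater + 1}_{unit}"))
    if n_raters >= 2:
        mat = (
            df.pivot(index=["nominal_deg", "rep"], columns="rater", values="measured_deg")
            .to_numpy()
        )
        for unit in ("single", "average"):
            res = icc(mat, model="twoway_random", unit=unit)
            iccs.append(dataclasses.replace(res, label=f"inter_rater_{unit}"))

    return ValidationReport(
        mode="model_bone",
        measurements=df,
        summary=summary,
        pearson={"nominal_vs_measured": corr},
        icc=iccs,
    )


def _in_vivo_experiment(
    cfg: SimConfig, n_reps: int, n_raters: int, n_subjects: int = 6
) -> ValidationReport:
    # subject-specific true extremes drawn from the measured population
    # (radiographic extension 2.7 ± 2.0°, flexion 130.8 ± 4.5°)
    rng_pop = np.random.default_rng([cfg.seed, 1])
    subjects = []
    for _ in range(n_subjects):
        ext = max(0.0, rng_pop.normal(2.7, 2.0))
        flex = rng_pop.normal(130.8, 4.5)
        subjects.append((ext, max(flex, ext + 30.0)))

    rows = []
    trial_index = 0
    for rater in range(n_raters):
        for rep in range(n_reps):
            for subject, extremes in enumerate(subjects):
                sub = dataclasses.replace(cfg, seed=cfg.seed + 1000 + trial_index)
                trial_index += 1
                trial = simulate_in_vivo_trial(sub, extremes)
                plateaus = sorted(_measure_trial(trial), key=lambda p: p.mean_deg)
                if len(plateaus) < 2:
                    raise ValidationError("in-vivo trial did not yield two holds")
                for extreme, p, xray in zip(
                    ("extension", "flexion"),
                    (plateaus[0], plateaus[-1]),
                    trial.xray_readings,
                ):
                    rows.append(
                        {
                            "subject": subject,
                            "rater": rater,
                            "rep": rep,
                            "extreme": extreme,
                            "ems_deg": p.mean_deg,
                            "xray_deg": xray,
                        }
                    )
    df = pd.DataFrame(rows)

    summary = (
        df.groupby("extreme")
        .agg(
            ems_mean_deg=("ems_deg", "mean"),
            ems_sd_deg=("ems_deg", lambda s: s.std(ddof=1)),
            xray_mean_deg=("xray_deg", "mean"),
            xray_sd_deg=("xray_deg", lambda s: s.std(ddof=1)),
            n=("ems_deg", "count"),
        )
    )
    corrs = {}
    bas = {}
    for extreme, grp in df.groupby("extreme"):
        corrs[extreme] = pearson(grp["ems_deg"], grp["xray_deg"])
        bas[extreme] = bland_altman(grp["ems_deg"], grp["xray_deg"])

    iccs: list[ICCResult] = []
    for rater in range(n_raters):
        mat = (
            df[df.rater == rater]
            .pivot(index=["subject", "extreme"], columns="rep", values="ems_deg")
            .to_numpy()
        )
        if mat.shape[1] >= 2:
            for unit in ("single", "average"):
                res = icc(mat, model="oneway", unit=unit)
                iccs.append(dataclasses.replace(res, label=f"intra_rater_{rater + 1}_{unit}"))
    if n_raters >= 2:
        mat = (
            df.pivot(index=["subject", "extreme", "rep"], columns="rater", values="ems_deg")
            .to_numpy()
        )
        for unit in ("single", "average"):
            res = icc(mat, model="twoway_random", unit=unit)
            iccs.append(dataclasses.replace(res, label=f"inter_rater_{unit}"))

    return ValidationReport(
        mode="in_vivo",
        measurements=df,
        summary=summary,
        pearson=corrs,
        icc=iccs,
        bland_altman=bas,
    )


def run_validation_experiment(
    cfg: SimConfig,
    mode: str = "model_bone",
    n_reps: int = 10,
    n_raters: int = 2,
    n_subjects: int = 6,
) -> ValidationReport:
    """Simulate a full validation study and run every analysis stage.

    ``model_bone`` reproduces the bench protocol (holds at 0/45/90/135°,
    ``n_raters`` × ``n_reps`` trials); ``in_vivo`` reproduces the
    volunteer protocol (``n_subjects`` subjects, each measured
    ``n_raters`` × ``n_reps`` times at their extremes, with paired
    radiographic readings). Per-trial seeds derive from ``cfg.seed`` plus
    the trial index, so the whole experiment is reproducible.
    """
    if n_reps < 2:
        raise ValidationError(f"need at least 2 repetitions, got {n_reps}")
    if n_raters < 1:
        raise ValidationError(f"need at least 1 rater, got {n_raters}")
    if mode == "model_bone":
        return _model_bone_experiment(cfg, n_reps, n_raters)
    if mode == "in_vivo":
        return _in_vivo_experiment(cfg, n_reps, n_raters, n_subjects)
    raise ValidationError(f"unknown mode {mode!r}")
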