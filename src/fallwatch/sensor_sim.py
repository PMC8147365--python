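"""Synthetic sensor streams for the hybridized fall-detection platform.

The real platform pairs a webcam (transverse face-centroid motion, in
pixels) with a three-element ultrasonic array (longitudinal chest range,
in cm).  This module generates per-frame sensor records with the same
statistical structure so that every downstream stage — fusion, DDFT
clustering, the probabilistic fall map, and cross-validated evaluation —
can be exercised without hardware.

Each simulated event reproduces the experimental protocol: a subject
rotates in place inside the 2 m trigger zone (normal motion: constant
range, near-zero centroid speed), begins to lose balance (transition:
the vertical image centroid drops and the range shifts at a moderate
rate), and falls (the centroid drops rapidly toward floor level, the
range changes abruptly, and the subject comes to rest lying on the
floor).  Stage boundaries are placed at fixed fractions of the raw
frame count; the canonical experiment uses 140 events of 40 raw frames
at 5 Hz, of which 30 per event survive downstream windowing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError

STAGES = ("normal", "transition", "fall")
N_SUBJECTS = 7

SENSOR_CSV_COLUMNS = [
    "event_id", "frame_idx", "t", "u", "v", "d1", "d2", "d3",
    "face_valid", "r1_valid", "r2_valid", "r3_valid", "stage",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic experiment.

    Defaults reproduce the canonical study conditions: 140 fall events
    from 7 subjects of height 164.2 ± 12 cm, a 2 m trigger distance
    inside a 0.4–5 m sensing range, 40 raw frames per event at 5 Hz
    split 30/10/60 % across the normal/transition/fall stages, so the
    30 retained points per event hold 10 normal, 4 transition and 16
    fall samples (about one third normal motion, as in the reference
    confusion counts).
    """

    n_events: int = 140
    points_per_event_raw: int = 40
    sample_period: float = 0.2          # s
    subject_height_mean: float = 164.2  # cm
    subject_height_sd: float = 12.0     # cm
    trigger_distance: float = 200.0     # cm
    range_min: float = 40.0             # cm
    range_max: float = 500.0            # cm
    stage_fractions: tuple[float, float, float] = (0.3, 0.1, 0.6)
    noise_sd_image: float = 2.0         # px
    noise_sd_ultrasonic: float = 3.0    # cm
    dropout_prob: float = 0.05
    seed: int = 0

    # kinematic parameters (stage-specific slopes of the piecewise-linear
    # trajectory) and per-event diversity
    vz_transition: float = -30.0   # cm/s, longitudinal shift while staggering
    vz_fall: float = -80.0         # cm/s, abrupt range change during the fall
    vy_transition: float = 80.0    # px/s, moderate vertical centroid drop
    vy_fall: float = 250.0         # px/s, rapid drop toward floor level
    fall_active_duration: float = 0.6  # s of rapid descent; the subject
                                       # then lies at rest for the remainder
    lying_noise_factor: float = 5.0    # noise multiplier once the subject is
                                       # down: the face tracker drifts and the
                                       # ultrasonic returns turn erratic on a
                                       # prone body (tracking is shut off 5 s
                                       # after detection for this reason)
    lying_breath_cms: float = 2.0      # amplitude (cm/s) of the deterministic
                                       # chest micro-motion while lying; a
                                       # prone body is never perfectly still
    slope_jitter: float = 0.3      # fractional SD of the per-event slope
                                   # scalings (transition and fall draw
                                   # independent scalings: subjects fall in
                                   # different ways)
    start_z_jitter: float = 15.0   # cm, SD of per-event starting range
    sway_px: float = 3.0           # transverse sway amplitude while rotating

    def __post_init__(self) -> None:
        f = self.stage_fractions
        if len(f) != 3 or abs(sum(f) - 1.0) > 1e-9 or any(x <= 0 for x in f):
            raise ConfigurationError(
                f"stage_fractions must be 3 positive proportions summing to 1, got {f}")
        if not (self.range_min < self.trigger_distance <= self.range_max):
            raise ConfigurationError(
                "require range_min < trigger_distance <= range_max, got "
                f"{self.range_min}, {self.trigger_distance}, {self.range_max}")
        if min(self.noise_sd_image, self.noise_sd_ultrasonic,
               self.subject_height_sd, self.slope_jitter,
               self.start_z_jitter, self.sway_px) < 0:
            raise ConfigurationError("all noise/jitter SDs must be >= 0")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ConfigurationError(f"dropout_prob must be in [0,1], got {self.dropout_prob}")
        if self.points_per_event_raw < 34:
            raise ConfigurationError(
                f"points_per_event_raw must be >= 34 so the 30-point window "
                f"(raw indices 3..32) exists, got {self.points_per_event_raw}")
        if self.n_events < 0:
            raise ConfigurationError("n_events must be >= 0")
        if self.sample_period <= 0:
            raise ConfigurationError("sample_period must be > 0")
        if any(n < 1 for n in self.stage_counts()):
            raise ConfigurationError("every stage must contain at least one frame")

    def stage_counts(self) -> tuple[int, int, int]:
        """Frames per stage: boundaries at stage_fractions x frame count."""
        n = self.points_per_event_raw
        n_normal = int(round(self.stage_fractions[0] * n))
        n_trans = int(round(self.stage_fractions[1] * n))
        return n_normal, n_trans, n - n_normal - n_trans

    def noiseless(self) -> "SimConfig":
        """Copy with every stochastic term removed.

        Zeroes the sensor noise SDs, the dropout probability, the
        subject-height spread, and all per-event kinematic diversity
        (slope jitter, starting-range jitter, transverse sway), leaving
        each event a deterministic piecewise-linear trajectory whose
        per-stage feature distributions are exactly disjoint.
        """
        return replace(self, noise_sd_image=0.0, noise_sd_ultrasonic=0.0,
                       dropout_prob=0.0, slope_jitter=0.0,
                       start_z_jitter=0.0, sway_px=0.0,
                       subject_height_sd=0.0)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stage_fractions"] = list(self.stage_fractions)
        return d


@dataclass
class GroundTruth:
    """Per-frame stage labels for one simulated event."""

    event_id: int
    subject_height: float               # cm
    stages: np.ndarray = field(repr=False)  # str array, one per raw frame

    def __post_init__(self) -> None:
        order = {s: i for i, s in enumerate(STAGES)}
        codes = np.array([order[s] for s in self.stages])
        if np.any(np.diff(codes) < 0):
            raise ConfigurationError("stages must progress normal -> transition -> fall")

    @property
    def fall_onset_index(self) -> int | None:
        """Raw frame index of the first fall-stage frame, None if absent."""
        idx = np.flatnonzero(self.stages == "fall")
        return None if idx.size == 0 else int(idx[0])


def _stage_labels(config: SimConfig) -> np.ndarray:
    n_normal, n_trans, n_fall = config.stage_counts()
    return np.array(["normal"] * n_normal + ["transition"] * n_trans
                    + ["fall"] * n_fall)


def simulate_event(config: SimConfig, event_id: int,
                   rng: np.random.Generator | None = None,
                   subject_height: float | None = None,
                   ) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate one fall event.

    Returns a frame table (sensor CSV contract columns) and its ground
    truth.  The vertical image centroid and the longitudinal range follow
    a piecewise-linear trajectory whose slope over the interval from
    frame k to k+1 is the slope of frame k's stage, so that a central
    finite difference evaluated at the last frame of a stage still
    recovers that stage's own velocity in the noiseless limit.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, event_id])
    if subject_height is None:
        subject_height = config.subject_height_mean

    n = config.points_per_event_raw
    dt = config.sample_period
    stages = _stage_labels(config)
    t = np.arange(n) * dt

    # per-event kinematic diversity: independent slope scalings for the
    # transition and the fall, and a jittered starting range
    scale_t = scale_f = 1.0
    if config.slope_jitter > 0:
        scale_t, scale_f = np.clip(
            1.0 + config.slope_jitter * rng.standard_normal(2), 0.3, 2.0)
    z0 = config.trigger_distance
    if config.start_z_jitter > 0:
        z0 = float(z0 + config.start_z_jitter * rng.standard_normal())
    z0 = float(np.clip(z0, config.range_min + 130.0, config.range_max))

    # per-frame slopes: rotation in place, staggering shift, rapid descent
    # for fall_active_duration, then lying at rest
    n_active = max(1, int(round(config.fall_active_duration / dt)))
    fall_start = int(np.argmax(stages == "fall"))
    vz_f = np.zeros(n)
    vy_f = np.zeros(n)
    trans = stages == "transition"
    vz_f[trans] = scale_t * config.vz_transition
    vy_f[trans] = scale_t * config.vy_transition
    active_end = min(fall_start + n_active, n)
    # the body accelerates while falling: slopes ramp up to the peak rate
    ramp = np.arange(1, active_end - fall_start + 1) / n_active
    vz_f[fall_start:active_end] = scale_f * config.vz_fall * ramp
    vy_f[fall_start:active_end] = scale_f * config.vy_fall * ramp
    # breathing chest motion while lying (~0.3 Hz, deterministic)
    if active_end < n:
        phase_t = t[active_end:] - t[active_end - 1]
        vz_f[active_end:] = config.lying_breath_cms * np.sin(
            2 * np.pi * 0.3 * phase_t)

    # integrate with left-endpoint slopes, so a central difference at a
    # stage's last frame still recovers that stage's own velocity
    z = np.empty(n)
    v = np.empty(n)
    z[0] = z0
    v[0] = 240.0 - 1.2 * (subject_height - config.subject_height_mean)
    for k in range(n - 1):
        z[k + 1] = z[k] + dt * vz_f[k]
        v[k + 1] = v[k] + dt * vy_f[k]

    u = np.full(n, 320.0)
    if config.sway_px > 0:
        phase = rng.uniform(0, 2 * np.pi)
        u = u + config.sway_px * np.sin(2 * np.pi * 0.5 * t + phase)

    # sensing degrades once the subject is down (prone body, drifting tracker)
    noise_gain = np.ones(n)
    noise_gain[active_end:] = config.lying_noise_factor

    if config.noise_sd_image > 0:
        u = u + config.noise_sd_image * noise_gain * rng.standard_normal(n)
        v = v + config.noise_sd_image * noise_gain * rng.standard_normal(n)

    # three receivers aimed at the same target: equal means, independent noise
    d = np.repeat(z[:, None], 3, axis=1)
    if config.noise_sd_ultrasonic > 0:
        d = d + (config.noise_sd_ultrasonic * noise_gain[:, None]
                 * rng.standard_normal((n, 3)))

    ranges_valid = (d >= config.range_min) & (d <= config.range_max)
    face_valid = rng.random(n) >= config.dropout_prob
    u = np.where(face_valid, u, np.nan)
    v = np.where(face_valid, v, np.nan)

    frames = pd.DataFrame({
        "event_id": event_id,
        "frame_idx": np.arange(n),
        "t": t,
        "u": u,
        "v": v,
        "d1": d[:, 0], "d2": d[:, 1], "d3": d[:, 2],
        "face_valid": face_valid,
        "r1_valid": ranges_valid[:, 0],
        "r2_valid": ranges_valid[:, 1],
        "r3_valid": ranges_valid[:, 2],
        "stage": stages,
    })
    gt = GroundTruth(event_id=event_id, subject_height=subject_height,
                     stages=stages)
    return frames, gt


def simulate_dataset(config: SimConfig) -> tuple[pd.DataFrame, list[GroundTruth]]:
    """Simulate the full experiment.

    Subject heights are drawn once from Normal(height_mean, height_sd^2)
    for 7 distinct subject identities, cycled deterministically across
    events.  Returns a single concatenated frame table plus one
    GroundTruth per event.
    """
    rng = np.random.default_rng(config.seed)
    heights = (config.subject_height_mean
               + config.subject_height_sd * rng.standard_normal(N_SUBJECTS))

    frames_list, truths = [], []
    for event_id in range(config.n_events):
        h = float(heights[event_id % N_SUBJECTS])
        frames, gt = simulate_event(config, event_id, subject_height=h)
        frames_list.append(frames)
        truths.append(gt)
    if frames_list:
        dataset = pd.concat(frames_list, ignore_index=True)
    else:
        dataset = pd.DataFrame(columns=SENSOR_CSV_COLUMNS)
    return dataset, truths


def subject_heights(config: SimConfig) -> np.ndarray:
    """The 7 subject heights (cm) a dataset with this config uses."""
    rng = np.random.default_rng(config.seed)
    return (config.subject_height_mean
            + config.subject_height_sd * rng.standard_normal(N_SUBJECTS))
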