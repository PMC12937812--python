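"""Seeded synthetic neurofeedback sessions.

Generates everything a closed-loop motor-imagery neurofeedback session
produces — block schedules, button-press (tap) streams, 4D BOLD runs on
a small voxel grid, brain/visual-exclusion masks — with known ground
truth, so the downstream decoding and group analyses can be tested for
recovery and calibration without any acquisition.

The emulated session comprises six runs at TR 2 s in the fixed order
tapping, tapping, imagery, imagery, tapping, tapping.  Tapping runs
alternate six blocks of paced tapping (1 Hz or 4 Hz) with six rest
blocks; imagery runs open with two practice blocks and continue with
six alternating ITAP ("imagine tapping") / noITAP blocks.  Block
durations are drawn from {28, 30, 32} s (whole TRs).  The planted BOLD
signal is a condition boxcar convolved with the canonical HRF in a
motor voxel set, on top of a constant baseline, a linear drift, a small
motion-coupled nuisance, and white Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .glm import boxcar_from_schedule, canonical_hrf, convolve_with_hrf

__all__ = [
    "Block",
    "BlockSchedule",
    "TapStream",
    "VolumeSeries",
    "MaskSet",
    "GroundTruth",
    "SyntheticSession",
    "TAP_CONDITIONS",
    "IMAGERY_CONDITIONS",
    "generate_tap_stream",
    "make_masks",
    "default_region_specs",
    "generate_tapping_schedule",
    "generate_imagery_schedule",
    "generate_bold_run",
    "generate_session",
    "generate_cohort",
    "simulate_contrast_cohort",
]

TAP_CONDITIONS = ("tap1Hz", "tap4Hz")
IMAGERY_CONDITIONS = ("ITAP", "noITAP")
PRACTICE_CONDITIONS = ("practiceITAP", "practiceNoITAP")
ALL_CONDITIONS = TAP_CONDITIONS + ("rest",) + PRACTICE_CONDITIONS \
    + IMAGERY_CONDITIONS

BLOCK_DURATION_CHOICES_S = (28.0, 30.0, 32.0)


@dataclass(frozen=True)
class Block:
    condition: str
    onset_s: float
    duration_s: float


@dataclass
class BlockSchedule:
    """Contiguous, non-overlapping blocks of one run."""

    blocks: list[Block]
    run_kind: str               # "tapping" | "imagery"
    tr_s: float

    def __post_init__(self):
        self.validate()

    @property
    def duration_s(self) -> float:
        last = self.blocks[-1]
        return last.onset_s + last.duration_s

    @property
    def n_trs(self) -> int:
        return int(round(self.duration_s / self.tr_s))

    def conditions_per_tr(self) -> list[str]:
        out = []
        for b in self.blocks:
            out.extend([b.condition] * int(round(b.duration_s / self.tr_s)))
        return out

    def condition_at(self, tr_index: int) -> str:
        return self.conditions_per_tr()[tr_index]

    def validate(self) -> None:
        if self.run_kind not in ("tapping", "imagery"):
            raise ValueError(f"unknown run_kind {self.run_kind!r}")
        t = 0.0
        for b in self.blocks:
            if b.condition not in ALL_CONDITIONS:
                raise ValueError(f"unknown condition {b.condition!r}")
            if abs(b.onset_s - t) > 1e-9:
                raise ValueError("blocks must be contiguous")
            if b.condition not in PRACTICE_CONDITIONS and not \
                    (28.0 - 1e-9 <= b.duration_s <= 32.0 + 1e-9):
                raise ValueError("block duration outside [28, 32] s")
            t += b.duration_s
        conds = [b.condition for b in self.blocks]
        if self.run_kind == "tapping":
            if sum(c in TAP_CONDITIONS for c in conds) != 6 or \
                    sum(c == "rest" for c in conds) != 6:
                raise ValueError("tapping run needs 6 tap and 6 rest blocks")
            for a, b in zip(conds, conds[1:]):
                if (a == "rest") == (b == "rest"):
                    raise ValueError("tap and rest blocks must alternate")
        else:
            if conds[0] != "practiceNoITAP" or conds[1] != "practiceITAP":
                raise ValueError(
                    "imagery run must open with practice noITAP then ITAP")
            body = conds[2:]
            if len(body) != 6 or any(c not in IMAGERY_CONDITIONS
                                     for c in body):
                raise ValueError("imagery run needs 6 ITAP/noITAP blocks")
            for a, b in zip(body, body[1:]):
                if a == b:
                    raise ValueError("ITAP and noITAP blocks must alternate")


@dataclass
class TapStream:
    """Button presses of one block with its instructed pace."""

    block_id: str
    instructed_rate_hz: float
    onset_s: float
    duration_s: float
    tap_times_s: np.ndarray

    def __post_init__(self):
        self.tap_times_s = np.asarray(self.tap_times_s, dtype=float)
        if self.tap_times_s.size and (
                np.any(np.diff(self.tap_times_s) <= 0)
                or self.tap_times_s[0] < self.onset_s - 1e-9
                or self.tap_times_s[-1] > self.onset_s + self.duration_s
                + 1e-9):
            raise ValueError("tap times must be strictly increasing and "
                             "within the block")


@dataclass
class VolumeSeries:
    """One run of 4D BOLD data on the synthetic voxel grid."""

    data: np.ndarray            # (x, y, z, t)
    tr_s: float
    run_index: int              # 1-based, study order

    def __post_init__(self):
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (x, y, z, t)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume data must be finite")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_trs(self) -> int:
        return self.data.shape[3]


@dataclass
class MaskSet:
    brain_mask: np.ndarray
    visual_exclusion_mask: np.ndarray
    analysis_mask: np.ndarray

    def __post_init__(self):
        expected = self.brain_mask & ~self.visual_exclusion_mask
        if not np.array_equal(self.analysis_mask, expected):
            raise ValueError(
                "analysis_mask must equal brain AND NOT visual_exclusion")
        if not self.analysis_mask.any():
            raise ValueError("empty analysis mask: classifier untrainable")


@dataclass
class GroundTruth:
    """Simulation truth against which recovery is scored."""

    motor_voxel_set: np.ndarray             # bool volume
    activation_amplitude: dict[str, float]  # per condition, signal units
    drift_slope: np.ndarray                 # per voxel, units per TR
    noise_sd: float
    motion_params: dict[int, np.ndarray]    # run_index -> (n_trs, 6)
    motion_loadings: np.ndarray             # (x, y, z, 6) spatial coupling
    subject_coupling: float                 # imagery amp <-> improvement
    baseline: float = 100.0
    tr_s: float = 2.0
    ar1_coef: float = 0.0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class SyntheticSession:
    """Six runs in the study order with behavior and ground truth."""

    subject_id: int
    runs: dict[int, tuple[VolumeSeries, BlockSchedule]]   # 1..6
    tap_streams: dict[int, list[TapStream]]               # runs 1,2,5,6
    truth: GroundTruth
    masks: MaskSet
    covariates: dict[str, float]      # imagery_amplitude, icars, targets
    seed: int

    RUN_KINDS = ("tapping", "tapping", "imagery", "imagery",
                 "tapping", "tapping")


# ---------------------------------------------------------------------------
# tap streams


def generate_tap_stream(rate_hz: float, timing_sd_s: float, miss_prob: float,
                        onset_s: float, duration_s: float,
                        seed) -> TapStream:
    """Jittered, thinned tap times for one paced block.

    Nominal taps sit at multiples of ``1/rate_hz`` from the block onset;
    each receives independent Gaussian timing jitter and is dropped with
    probability ``miss_prob``.  Jittered times are clipped to the block
    and de-duplicated so the stream is strictly increasing.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if rate_hz <= 0 or timing_sd_s < 0 or not 0 <= miss_prob <= 1:
        raise ValueError("invalid tap-stream parameters")
    rng = np.random.default_rng(seed)
    n_nominal = int(round(duration_s * rate_hz))
    nominal = onset_s + np.arange(n_nominal) / rate_hz
    keep = rng.random(n_nominal) >= miss_prob
    times = nominal[keep] + rng.normal(0.0, timing_sd_s, keep.sum())
    times = np.clip(np.sort(times), onset_s, onset_s + duration_s)
    if times.size:
        strict = np.concatenate([[True], np.diff(times) > 0])
        times = times[strict]
    return TapStream(block_id="", instructed_rate_hz=rate_hz,
                     onset_s=onset_s, duration_s=duration_s,
                     tap_times_s=times)


# ---------------------------------------------------------------------------
# masks


def _occupancy(source: np.ndarray, grid_shape) -> np.ndarray:
    """Fraction of each target voxel covered by a finer source region."""
    source = np.asarray(source, dtype=bool)
    factors = []
    for s, g in zip(source.shape, grid_shape):
        if s % g:
            raise ValueError("source grid must subdivide the target grid")
        factors.append(s // g)
    fx, fy, fz = factors
    gx, gy, gz = grid_shape
    blocks = source.reshape(gx, fx, gy, fy, gz, fz)
    return blocks.mean(axis=(1, 3, 5))


def make_masks(grid_shape, brain_region_spec, visual_region_spec,
               overlap_fraction_threshold: float = 0.20) -> MaskSet:
    """Resample region specs to the analysis grid and compose the masks.

    Region specs are boolean volumes on a (possibly finer) source grid
    whose shape is an integer multiple of ``grid_shape`` per axis.  A
    target voxel is retained when the source region occupies at least
    ``overlap_fraction_threshold`` of its volume (default 20%).  The
    analysis mask is the brain mask minus the visual exclusion mask.
    """
    brain = _occupancy(brain_region_spec, grid_shape) \
        >= overlap_fraction_threshold - 1e-12
    visual = _occupancy(visual_region_spec, grid_shape) \
        >= overlap_fraction_threshold - 1e-12
    return MaskSet(brain_mask=brain, visual_exclusion_mask=visual,
                   analysis_mask=brain & ~visual)


def default_region_specs(grid_shape=(16, 16, 10), upsample: int = 2):
    """Ellipsoidal brain and posterior visual-cortex region on a finer grid.

    Desk-scale stand-ins for an automasked brain and a cytoarchitectonic
    visual-cortex union, used by the default session generator.
    """
    gx, gy, gz = grid_shape
    shape = (gx * upsample, gy * upsample, gz * upsample)
    idx = np.indices(shape, dtype=float) + 0.5
    center = np.array(shape, dtype=float)[:, None, None, None] / 2
    semi = center * np.array([0.92, 0.92, 0.95])[:, None, None, None]
    r2 = (((idx - center) / semi) ** 2).sum(axis=0)
    brain = r2 <= 1.0
    visual = np.zeros(shape, dtype=bool)
    # posterior slab (high y), mid-inferior z: the flashing-cross response
    visual[:, int(shape[1] * 0.80):, : int(shape[2] * 0.6)] = True
    visual &= brain
    return brain, visual


def default_motor_set(masks: MaskSet, rng) -> np.ndarray:
    """Plant a distributed 'motor network' inside the analysis mask.

    Several compact blobs totalling roughly a tenth of the analysis
    mask, echoing a sensorimotor/premotor/cerebellar network rather than
    a single focus.
    """
    gx, gy, gz = masks.analysis_mask.shape
    centers = [
        (int(gx * 0.30), int(gy * 0.35), int(gz * 0.70)),
        (int(gx * 0.65), int(gy * 0.40), int(gz * 0.70)),
        (int(gx * 0.50), int(gy * 0.30), int(gz * 0.30)),
    ]
    motor = np.zeros_like(masks.analysis_mask)
    for cx, cy, cz in centers:
        motor[cx - 1:cx + 2, cy - 1:cy + 2, cz - 1:cz + 2] = True
    motor &= masks.analysis_mask
    if not motor.any():
        raise ValueError("planted motor set fell outside the analysis mask")
    return motor


# ---------------------------------------------------------------------------
# schedules


def _draw_durations(n: int, rng) -> np.ndarray:
    return rng.choice(BLOCK_DURATION_CHOICES_S, size=n)


def generate_tapping_schedule(seed, tr_s: float = 2.0,
                              speed_order=("tap1Hz", "tap4Hz") * 3
                              ) -> BlockSchedule:
    """Six paced-tapping blocks alternating with six rest blocks."""
    rng = np.random.default_rng(seed)
    durations = _draw_durations(12, rng)
    blocks, t = [], 0.0
    for i in range(6):
        for cond in (speed_order[i], "rest"):
            d = float(durations[len(blocks)])
            blocks.append(Block(cond, t, d))
            t += d
    return BlockSchedule(blocks=blocks, run_kind="tapping", tr_s=tr_s)


def generate_imagery_schedule(seed, tr_s: float = 2.0) -> BlockSchedule:
    """Two practice blocks then six alternating ITAP/noITAP blocks."""
    rng = np.random.default_rng(seed)
    durations = _draw_durations(8, rng)
    order = ["practiceNoITAP", "practiceITAP",
             "ITAP", "noITAP", "ITAP", "noITAP", "ITAP", "noITAP"]
    blocks, t = [], 0.0
    for cond, d in zip(order, durations):
        blocks.append(Block(cond, t, float(d)))
        t += float(d)
    return BlockSchedule(blocks=blocks, run_kind="imagery", tr_s=tr_s)


# ---------------------------------------------------------------------------
# BOLD runs


def _simulate_motion(n_trs: int, rng, scale: float = 0.1) -> np.ndarray:
    """Six slow random-walk nuisance series (3 translations, 3 rotations)."""
    steps = rng.normal(0.0, scale, size=(n_trs, 6))
    walk = np.cumsum(steps, axis=0)
    return walk - walk.mean(axis=0)


def generate_bold_run(schedule: BlockSchedule, masks: MaskSet,
                      truth: GroundTruth, seed,
                      run_index: int = 1) -> VolumeSeries:
    """One synthetic BOLD run realizing the ground-truth signal model.

    Voxel time course = baseline + amplitude x (condition boxcar
    convolved with the canonical HRF) inside the motor voxel set
    + drift_slope x t + motion-coupled nuisance + Gaussian noise
    (optionally AR(1) filtered).  Deterministic given the seed.
    """
    if abs(schedule.tr_s - truth.tr_s) > 1e-9:
        raise ValueError("schedule TR does not match ground-truth TR")
    rng = np.random.default_rng(seed)
    n_trs = schedule.n_trs
    grid = masks.brain_mask.shape
    hrf = canonical_hrf(schedule.tr_s)

    signal_t = np.zeros(n_trs)
    for cond, amp in truth.activation_amplitude.items():
        if amp == 0.0:
            continue
        box = boxcar_from_schedule(schedule, cond)
        if box.any():
            signal_t += amp * convolve_with_hrf(box, hrf)

    motion = truth.motion_params.get(run_index)
    if motion is None:
        motion = np.zeros((n_trs, 6))
    if motion.shape[0] != n_trs:
        raise ValueError("motion series length does not match the run")

    t = np.arange(n_trs, dtype=float)
    data = np.empty(grid + (n_trs,), dtype=float)
    data[...] = truth.baseline
    data += truth.drift_slope[..., None] * t[None, None, None, :]
    data[truth.motor_voxel_set] += signal_t
    if np.any(motion):
        data += np.einsum("xyzk,tk->xyzt", truth.motion_loadings, motion)
    if truth.noise_sd > 0:
        noise = rng.normal(0.0, truth.noise_sd, size=grid + (n_trs,))
        if truth.ar1_coef:
            for i in range(1, n_trs):
                noise[..., i] += truth.ar1_coef * noise[..., i - 1]
        data += noise
    return VolumeSeries(data=data, tr_s=schedule.tr_s, run_index=run_index)


# ---------------------------------------------------------------------------
# sessions and cohorts


#: Default condition-to-RMSE-target means/SDs (Hz), by run, at each pace.
#: Scaled to a mildly impaired tapping population: slow pacing is easier
#: than fast pacing and early runs are noisier than practiced ones.
_RMSE_TARGET_MEAN = {
    (1, 1.0): 0.038, (2, 1.0): 0.024, (5, 1.0): 0.023, (6, 1.0): 0.033,
    (1, 4.0): 0.056, (2, 4.0): 0.062, (5, 4.0): 0.061, (6, 4.0): 0.065,
}
_RMSE_TARGET_SD = 0.010


@dataclass
class SessionConfig:
    """Tunable study conditions for one synthetic session."""

    grid_shape: tuple[int, int, int] = (16, 16, 10)
    tr_s: float = 2.0
    # per-voxel, per-TR CNR of 2/6 ~ 0.33: block averaging, smoothing and
    # multivoxel pooling carry the decoder, as with real BOLD
    noise_sd: float = 6.0
    tap_amplitude: float = 2.0
    imagery_amplitude_mean: float = 1.2  # imagery runs activate less
    imagery_amplitude_sd: float = 0.4
    drift_slope_sd: float = 0.01        # units per TR
    motion_scale: float = 0.1
    motion_coupling: float = 0.05
    # misses are rare events; a single one at 1 Hz adds ~0.05 Hz to the
    # run RMSE, so frequent misses would drown the pacing-jitter signal
    # that the improvement score tracks
    miss_prob: float = 0.001
    ar1_coef: float = 0.0


def _jitter_for_rmse(rmse_hz: float, rate_hz: float) -> float:
    """Timing jitter SD that yields the target instantaneous-rate RMSE.

    For small jitter sd s, consecutive-difference noise has SD s*sqrt(2)
    and the rate error is approximately -rate^2 * interval error, so
    RMSE ~= rate^2 * s * sqrt(2).
    """
    return max(rmse_hz, 1e-4) / (rate_hz ** 2 * np.sqrt(2.0))


def _session_tap_streams(schedule: BlockSchedule, run_index: int,
                         rmse_targets: dict, miss_prob: float,
                         rng) -> list[TapStream]:
    streams = []
    for i, b in enumerate(schedule.blocks):
        if b.condition not in TAP_CONDITIONS:
            continue
        rate = 1.0 if b.condition == "tap1Hz" else 4.0
        sd = _jitter_for_rmse(rmse_targets[(run_index, rate)], rate)
        s = generate_tap_stream(rate, sd, miss_prob, b.onset_s,
                                b.duration_s,
                                rng.integers(0, 2 ** 31 - 1))
        s.block_id = f"run{run_index}_block{i}"
        streams.append(s)
    return streams


def generate_session(subject_id: int, seed,
                     config: SessionConfig | None = None,
                     imagery_amplitude: float | None = None,
                     delta_rmse_1hz: float | None = None) -> SyntheticSession:
    """One full six-run session with planted signal and behavior.

    ``imagery_amplitude`` and ``delta_rmse_1hz`` override the per-subject
    draws; the cohort generator uses them to impose a known coupling
    between imagery activation and tapping improvement.
    """
    config = config or SessionConfig()
    root = np.random.SeedSequence([int(seed), int(subject_id)])
    # 0: subject draws; 1-6: schedules; 7-12: motion; 13: tap streams;
    # 14-19: BOLD runs
    seeds = root.spawn(20)
    rng = np.random.default_rng(seeds[0])

    brain_spec, visual_spec = default_region_specs(config.grid_shape)
    masks = make_masks(config.grid_shape, brain_spec, visual_spec)
    motor = default_motor_set(masks, rng)

    if imagery_amplitude is None:
        imagery_amplitude = float(np.clip(
            rng.normal(config.imagery_amplitude_mean,
                       config.imagery_amplitude_sd), 0.05, None))
    amplitudes = {
        "tap1Hz": config.tap_amplitude,
        "tap4Hz": config.tap_amplitude,
        "rest": 0.0,
        "ITAP": imagery_amplitude,
        "practiceITAP": imagery_amplitude,
        "noITAP": 0.0,
        "practiceNoITAP": 0.0,
    }

    # behavioral RMSE targets; the 1 Hz run-2 -> run-5 change is the
    # subject's improvement score
    targets = {}
    for (run, rate), mu in _RMSE_TARGET_MEAN.items():
        targets[(run, rate)] = float(np.clip(
            rng.normal(mu, _RMSE_TARGET_SD), 0.004, None))
    if delta_rmse_1hz is not None:
        targets[(5, 1.0)] = float(np.clip(
            targets[(2, 1.0)] - delta_rmse_1hz, 0.004, None))

    schedules = {}
    for run, kind in enumerate(SyntheticSession.RUN_KINDS, start=1):
        gen = generate_tapping_schedule if kind == "tapping" \
            else generate_imagery_schedule
        schedules[run] = gen(seeds[run], tr_s=config.tr_s)

    drift = rng.normal(0.0, config.drift_slope_sd, size=config.grid_shape)
    loadings = rng.normal(0.0, config.motion_coupling,
                          size=config.grid_shape + (6,))
    motion = {run: _simulate_motion(schedules[run].n_trs,
                                    np.random.default_rng(seeds[6 + run]),
                                    config.motion_scale)
              for run in schedules}
    truth = GroundTruth(
        motor_voxel_set=motor, activation_amplitude=amplitudes,
        drift_slope=drift, noise_sd=config.noise_sd,
        motion_params=motion, motion_loadings=loadings,
        subject_coupling=float("nan"), baseline=100.0, tr_s=config.tr_s,
        ar1_coef=config.ar1_coef)

    runs, tap_streams = {}, {}
    stream_rng = np.random.default_rng(seeds[13])
    for run in schedules:
        vol = generate_bold_run(schedules[run], masks, truth,
                                seeds[13 + run], run_index=run)
        runs[run] = (vol, schedules[run])
        if SyntheticSession.RUN_KINDS[run - 1] == "tapping" \
                and run in (1, 2, 5, 6):
            tap_streams[run] = _session_tap_streams(
                schedules[run], run, targets, config.miss_prob, stream_rng)

    icars = float(np.clip(rng.normal(32.4, 19.2), 0.0, 100.0))
    covariates = {
        "imagery_amplitude": imagery_amplitude,
        "icars": icars,
        "delta_rmse_1hz_target": targets[(2, 1.0)] - targets[(5, 1.0)],
    }
    return SyntheticSession(
        subject_id=subject_id, runs=runs, tap_streams=tap_streams,
        truth=truth, masks=masks, covariates=covariates, seed=int(seed))


def generate_cohort(n_subjects: int, coupling_strength: float, seed,
                    config: SessionConfig | None = None,
                    delta_rmse_sd: float = 0.012
                    ) -> list[SyntheticSession]:
    """A cohort whose imagery amplitude and improvement are coupled.

    Per subject, standardized draws (z1, z2) give an imagery activation
    amplitude proportional to z1 and a 1 Hz RMSE improvement built from
    ``coupling_strength * z1 + sqrt(1 - coupling^2) * z2`` so the
    population correlation between the two equals ``coupling_strength``.
    An ICARS-like severity covariate is drawn independently.
    """
    if n_subjects < 3:
        raise ValueError("need at least 3 subjects")
    if abs(coupling_strength) > 1:
        raise ValueError("coupling_strength must lie in [-1, 1]")
    config = config or SessionConfig()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 777]))
    z1 = rng.normal(size=n_subjects)
    z2 = rng.normal(size=n_subjects)
    amps = np.clip(config.imagery_amplitude_mean
                   + config.imagery_amplitude_sd * z1, 0.05, None)
    deltas = delta_rmse_sd * (coupling_strength * z1
                              + np.sqrt(1 - coupling_strength ** 2) * z2)
    sessions = []
    for i in range(n_subjects):
        s = generate_session(i, seed, config,
                             imagery_amplitude=float(amps[i]),
                             delta_rmse_1hz=float(deltas[i]))
        s.truth.subject_coupling = float(coupling_strength)
        sessions.append(s)
    return sessions


def simulate_contrast_cohort(n_subjects: int, coupling_strength: float,
                             seed, grid_shape=(16, 16, 10),
                             effect_sd: float = 1.0,
                             noise_sd: float = 0.25,
                             region: np.ndarray | None = None):
    """Subject contrast maps with a region whose amplitude tracks behavior.

    A direct, cheap stand-in for the full pipeline at the group-model
    level: each subject's map is ``a_i x region + noise`` where the
    per-subject amplitudes ``a_i`` correlate with the returned
    improvement scores at ``coupling_strength``.  Used for calibration
    and recovery tests of the group covariate model.

    Returns ``(maps, delta_rmse, control, region)``.
    """
    if abs(coupling_strength) > 1:
        raise ValueError("coupling_strength must lie in [-1, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 4242]))
    if region is None:
        region = np.zeros(grid_shape, dtype=bool)
        cx, cy, cz = (g // 2 for g in grid_shape)
        region[cx - 2:cx + 3, cy - 2:cy + 3, cz - 2:cz + 2] = True
    z1 = rng.normal(size=n_subjects)
    z2 = rng.normal(size=n_subjects)
    amps = effect_sd * z1
    deltas = 0.012 * (coupling_strength * z1
                      + np.sqrt(1 - coupling_strength ** 2) * z2)
    control = rng.normal(32.4, 19.2, size=n_subjects)
    maps = [amps[i] * region
            + rng.normal(0.0, noise_sd, size=grid_shape)
            for i in range(n_subjects)]
    return maps, deltas, control, region
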