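"""Synthetic reach-to-grasp trials and MEP sweeps.

Emulates the study design the downstream analysis assumes: 9 stroke subjects,
two stimulation conditions (real / sham low-frequency rTMS over the
non-lesioned motor cortex), two times (pre / post), two dowel sizes
(1.2 cm / 7.2 cm diameter), 10 trials per block, motion capture at 120 Hz over
a 30 cm reach, and 10-sweep MEP blocks sampled at 2000 Hz.

The transport component is a minimum-jerk displacement along the reach axis
(analytically checkable: peak speed 15*D/(8*T) at mid-movement).  Grasp
aperture is a unimodal beta-density-shaped profile, rescaled piecewise so it
starts at a near-closed thumb-index opposition, peaks at
``object diameter + margin`` and closes onto the object diameter at lift-off.
Temporal transport-grasp coupling is injected by delaying the aperture profile
relative to the transport profile by ``coupling_lag`` seconds (positive lag =
transport velocity leads aperture, the convention used downstream).

The real-rTMS effect is concentrated on the small object, post stimulation:
shorter movement time, larger peak aperture, less within-trial aperture shape
variability (hence a higher transport-grasp cross-correlation) and a shorter
coupling lag.  MEP amplitudes after real rTMS are suppressed by a configurable
fraction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path

import numpy as np

from .errors import ParameterError

CONDITIONS = ("real", "sham")
TIMES = ("pre", "post")
OBJECTS = ("small", "large")


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectSizes:
    """Injected real-rTMS effects (applied to condition=real, time=post, object=small)."""

    tmt_reduction_small: float = 0.15      # s faster movement
    amax_increase_small: float = 0.008     # m wider peak aperture
    rmax_increase_small: float = 0.5       # fractional shrink of aperture shape noise
    lag_reduction_small: float = 0.060     # s shorter transport-grasp lag
    mep_suppression_fraction: float = 0.42  # fractional MEP amplitude drop

    def __post_init__(self) -> None:
        if not 0.0 <= self.mep_suppression_fraction < 1.0:
            raise ParameterError(
                f"mep_suppression_fraction must be in [0, 1), got {self.mep_suppression_fraction}"
            )
        if not 0.0 <= self.rmax_increase_small <= 1.0:
            raise ParameterError("rmax_increase_small must be in [0, 1]")


def _zero_effects() -> EffectSizes:
    return EffectSizes(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class SynthConfig:
    """Study-design parameters of the synthetic generator.

    Geometry and sampling follow the task apparatus (30 cm reach, 1.2 / 7.2 cm
    dowels, 120 Hz kinematics, 2000 Hz EMG).  Timing, dispersion and effect
    defaults are documented in docs/methods.md.
    """

    n_subjects: int = 9
    trials_per_block: int = 10
    fs_kinematic: float = 120.0
    fs_emg: float = 2000.0
    reach_distance: float = 0.30
    object_diameters: dict = field(
        default_factory=lambda: {"small": 0.012, "large": 0.072}
    )
    # stroke-like slowing; the small dowel is the harder (slower) target
    base_tmt: dict = field(default_factory=lambda: {"small": 1.3, "large": 1.1})
    aperture_margin: float = 0.030          # m opening beyond the object diameter
    aperture_baseline: float = 0.005        # m thumb-index opposition at rest
    aperture_peak_fraction: float = 0.5     # aperture peak aligned with velocity peak pre-shift
    # decoupled stroke baseline straddling the 80-125 ms nondisabled band
    coupling_lag: dict = field(default_factory=lambda: {"small": 0.180, "large": 0.100})
    noise_sd_position: float = 0.0005       # m additive sensor noise
    aperture_shape_noise: float = 0.002     # m smooth within-trial aperture variability
    # between-subject / between-session / between-trial dispersions
    subject_tmt_cv: float = 0.10
    session_tmt_sd: float = 0.05            # s
    trial_tmt_sd: float = 0.08              # s
    session_margin_sd: float = 0.004        # m
    trial_margin_sd: float = 0.003          # m
    session_lag_sd: float = 0.015           # s
    trial_lag_sd: float = 0.010             # s
    reaction_time_mean: float = 0.35        # s LED -> hand lift (recorded, not analyzed)
    reaction_time_sd: float = 0.05
    lead_in: float = 0.25                   # s recorded before the LED cue
    tail: float = 0.25                      # s recorded after object lift
    # MEP block
    mep_baseline_median: float = 700.0      # uV
    mep_baseline_sigma: float = 0.4         # lognormal sigma of subject baselines
    mep_noise_cv: float = 0.10              # multiplicative trial noise
    mep_background_sd: float = 3.0          # uV additive background EMG
    effects: EffectSizes = field(default_factory=EffectSizes)
    seed: int | None = None

    def __post_init__(self) -> None:
        positive = {
            "n_subjects": self.n_subjects,
            "trials_per_block": self.trials_per_block,
            "fs_kinematic": self.fs_kinematic,
            "fs_emg": self.fs_emg,
            "reach_distance": self.reach_distance,
            "aperture_margin": self.aperture_margin,
            "aperture_baseline": self.aperture_baseline,
            "mep_baseline_median": self.mep_baseline_median,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ParameterError(f"{name} must be strictly positive, got {value}")
        for obj in OBJECTS:
            if self.object_diameters[obj] <= 0:
                raise ParameterError(f"object_diameters[{obj}] must be positive")
            if self.base_tmt[obj] <= 0:
                raise ParameterError(f"base_tmt[{obj}] must be positive")
        if not self.object_diameters["small"] < self.object_diameters["large"]:
            raise ParameterError("object_diameters.small must be < object_diameters.large")
        if not 0.0 < self.aperture_peak_fraction < 1.0:
            raise ParameterError("aperture_peak_fraction must lie in (0, 1)")

    def with_zero_noise(self) -> "SynthConfig":
        """Deterministic copy: all dispersion parameters set to zero."""
        return replace(
            self,
            noise_sd_position=0.0,
            aperture_shape_noise=0.0,
            subject_tmt_cv=0.0,
            session_tmt_sd=0.0,
            trial_tmt_sd=0.0,
            session_margin_sd=0.0,
            trial_margin_sd=0.0,
            session_lag_sd=0.0,
            trial_lag_sd=0.0,
            reaction_time_sd=0.0,
            mep_noise_cv=0.0,
            mep_background_sd=0.0,
        )

    def with_zero_effects(self) -> "SynthConfig":
        return replace(self, effects=_zero_effects())


# --------------------------------------------------------------------------
# domain records
# --------------------------------------------------------------------------

@dataclass
class TrialTruth:
    """Generative ground truth of one synthetic trial (not written to disk)."""

    tmt: float           # s, injected movement duration
    a_max: float         # m, injected peak aperture (diameter + margin)
    lag: float           # s, requested construct-level coupling lag
    shift: float         # s, realized aperture-profile time shift (whole samples)
    lag_achieved: float  # s, noise-free construct lag actually realized (integer samples)


@dataclass
class TrialRecording:
    """Raw 3-sensor positions, event timestamps and metadata for one trial."""

    subject_id: str
    condition: str
    time: str
    object: str
    trial_index: int
    timestamps: np.ndarray          # (n,) s
    wrist_xyz: np.ndarray           # (n, 3) m
    thumb_xyz: np.ndarray           # (n, 3) m
    index_xyz: np.ndarray           # (n, 3) m
    led_onset: float
    hand_lift: float
    object_lift: float
    fs: float
    truth: TrialTruth | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.timestamps, dtype=float)
        n = t.shape[0]
        if n < 4:
            raise ParameterError(f"trial needs at least 4 samples, got {n}")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ParameterError("timestamps must be strictly increasing")
        if np.max(np.abs(dt - 1.0 / self.fs)) > 1e-9:
            raise ParameterError("timestamps must be uniform at 1/fs within 1e-9 s")
        for name in ("wrist_xyz", "thumb_xyz", "index_xyz"):
            arr = getattr(self, name)
            if arr.shape != (n, 3):
                raise ParameterError(f"{name} must have shape ({n}, 3), got {arr.shape}")
        if not (self.led_onset <= self.hand_lift < self.object_lift <= t[-1] + 1e-9):
            raise ParameterError(
                "event order must satisfy led_onset <= hand_lift < object_lift <= last sample"
            )


@dataclass
class SubjectEffects:
    """Stable per-subject random effects, drawn once per synthetic subject."""

    subject_id: str
    tmt_factor: float       # multiplicative slowing
    margin_offset: float    # m
    lag_offset: float       # s
    mep_baseline: float     # uV


# --------------------------------------------------------------------------
# generative profiles
# --------------------------------------------------------------------------

def generate_transport_profile(distance: float, duration: float, fs: float) -> np.ndarray:
    """Minimum-jerk displacement series x(t), t = 0 .. duration at 1/fs.

    x(tau) = D * (10 tau^3 - 15 tau^4 + 6 tau^5); boundary velocity and
    acceleration are zero and peak speed is 15 D / (8 T) at mid-movement.
    """
    if distance < 0:
        raise ParameterError(f"distance must be nonnegative, got {distance}")
    if duration <= 0 or fs <= 0:
        raise ParameterError("duration and fs must be strictly positive")
    n = int(round(duration * fs))
    tau = np.arange(n + 1) / (duration * fs)
    tau = np.clip(tau, 0.0, 1.0)
    return distance * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)


def _minimum_jerk_at(tau: np.ndarray, distance: float) -> np.ndarray:
    tau = np.clip(tau, 0.0, 1.0)
    return distance * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)


def _beta_shape(tau: np.ndarray, mode: float, concentration: float = 5.0) -> np.ndarray:
    """Unnormalized beta density with the given mode, scaled to peak 1."""
    p = 1.0 + concentration * mode
    q = 1.0 + concentration * (1.0 - mode)
    with np.errstate(invalid="ignore"):
        b = tau ** (p - 1.0) * (1.0 - tau) ** (q - 1.0)
    peak = mode ** (p - 1.0) * (1.0 - mode) ** (q - 1.0)
    return np.nan_to_num(b / peak, nan=0.0)


def _aperture_at(
    tau: np.ndarray,
    object_diameter: float,
    margin: float,
    peak_time_fraction: float,
    baseline: float,
) -> np.ndarray:
    """Aperture as a function of normalized movement time tau in [0, 1].

    Beta-density shape rescaled piecewise: the rising limb spans
    [baseline, diameter + margin], the closing limb spans
    [diameter, diameter + margin] so the hand ends on the object.
    """
    tau = np.clip(tau, 0.0, 1.0)
    shape = _beta_shape(tau, peak_time_fraction)
    peak = object_diameter + margin
    rise = baseline + (peak - baseline) * shape
    fall = object_diameter + (peak - object_diameter) * shape
    return np.where(tau <= peak_time_fraction, rise, fall)


def generate_aperture_profile(
    object_diameter: float,
    margin: float,
    duration: float,
    peak_time_fraction: float,
    fs: float,
    baseline: float = 0.005,
) -> np.ndarray:
    """Unimodal grasp-aperture series over one movement of ``duration`` seconds."""
    if margin < 0:
        raise ParameterError(f"margin must be nonnegative, got {margin}")
    if not 0.0 < peak_time_fraction < 1.0:
        raise ParameterError("peak_time_fraction must lie strictly inside (0, 1)")
    if object_diameter <= 0 or duration <= 0 or fs <= 0:
        raise ParameterError("object_diameter, duration and fs must be positive")
    n = int(round(duration * fs))
    tau = np.arange(n + 1) / (duration * fs)
    return _aperture_at(tau, object_diameter, margin, peak_time_fraction, baseline)


# --------------------------------------------------------------------------
# trial generation
# --------------------------------------------------------------------------

def draw_subject_effects(config: SynthConfig, rng: np.random.Generator) -> list[SubjectEffects]:
    if rng is None:
        raise ParameterError("an explicit numpy Generator is required")
    subjects = []
    for i in range(config.n_subjects):
        subjects.append(
            SubjectEffects(
                subject_id=f"S{i + 1}",
                tmt_factor=float(np.exp(rng.normal(0.0, config.subject_tmt_cv))),
                margin_offset=float(rng.normal(0.0, config.session_margin_sd)),
                lag_offset=float(rng.normal(0.0, config.session_lag_sd)),
                mep_baseline=float(
                    config.mep_baseline_median * np.exp(rng.normal(0.0, config.mep_baseline_sigma))
                ),
            )
        )
    return subjects


def _is_treated_cell(condition: str, time: str, obj: str) -> bool:
    return condition == "real" and time == "post" and obj == "small"


@lru_cache(maxsize=8192)
def _calibrated_shift(
    n_mov: int,
    diameter_um: int,
    margin_um: int,
    baseline_um: int,
    peak_frac_milli: int,
    lag_quarter_samples: int,
    fs: float,
) -> float:
    """Profile shift (s) whose construct-level coupling lag equals the request.

    The coupling lag is defined operationally: the lag maximizing the sliding
    Pearson correlation between transport velocity and aperture.  Because the
    aperture profile closes onto the object diameter (not back to baseline),
    its optimal alignment with the symmetric velocity bell is offset from a
    pure time shift; the generator solves for the shift that makes the
    noise-free construct value equal the configured lag, by fixed-point
    iteration on the clean sampled profiles.
    """
    from .coordination import cross_correlate  # deferred: avoids an import cycle

    from .signal import lowpass_zero_lag  # deferred: avoids an import cycle

    lag = lag_quarter_samples / (4.0 * fs)
    diameter = diameter_um * 1e-6
    margin = margin_um * 1e-6
    baseline = baseline_um * 1e-6
    m = peak_frac_milli / 1000.0
    tmt = n_mov / fs
    # emulate the production chain on a clean mini-trial: flat lead-in and
    # tail, 20 Hz zero-phase filtering, then the movement-window excerpt
    pad_pre, pad_post = 72, 30
    t = np.arange(pad_pre + n_mov + 1 + pad_post) / fs
    t0 = pad_pre / fs
    tau = (t - t0) / tmt
    x = _minimum_jerk_at(tau, 1.0)  # scale-free: correlation is affine invariant
    xf = lowpass_zero_lag(x, fs)
    v = np.abs(np.gradient(xf) * fs)[pad_pre : pad_pre + n_mov + 1]

    def est_samples(shift_samples: int) -> int:
        a = _aperture_at((t - t0 - shift_samples / fs) / tmt, diameter, margin, m, baseline)
        af = lowpass_zero_lag(a, fs)[pad_pre : pad_pre + n_mov + 1]
        return cross_correlate(v, af, fs=fs).lag_samples

    # shifts are whole samples so the aperture peak stays on the sample grid
    target = lag * fs
    s0 = int(round(target))
    s0 -= est_samples(s0) - int(round(target))  # first-order offset correction
    best_s, best_est = s0, est_samples(s0)
    best_err = abs(best_est - target)
    for s in range(s0 - 3, s0 + 4):
        est = est_samples(s)
        err = abs(est - target)
        if err < best_err - 1e-9 or (err < best_err + 1e-9 and abs(s - target) < abs(best_s - target)):
            best_s, best_est, best_err = s, est, err
    # (realized shift, achieved noise-free construct lag) in seconds
    return best_s / fs, best_est / fs


@dataclass
class _BlockParams:
    """Session-level (block) parameters shared by the trials of one cell."""

    tmt: float
    margin: float
    lag: float
    shape_noise: float


def _draw_block_params(
    config: SynthConfig,
    subject: SubjectEffects,
    condition: str,
    time: str,
    obj: str,
    rng: np.random.Generator,
) -> _BlockParams:
    eff = config.effects
    treated = _is_treated_cell(condition, time, obj)
    tmt = config.base_tmt[obj] * subject.tmt_factor + rng.normal(0.0, config.session_tmt_sd)
    margin = config.aperture_margin + subject.margin_offset + rng.normal(
        0.0, config.session_margin_sd
    )
    lag = config.coupling_lag[obj] + subject.lag_offset + rng.normal(0.0, config.session_lag_sd)
    shape_noise = config.aperture_shape_noise
    if treated:
        tmt -= eff.tmt_reduction_small
        margin += eff.amax_increase_small
        lag -= eff.lag_reduction_small
        shape_noise *= 1.0 - eff.rmax_increase_small
    return _BlockParams(tmt=tmt, margin=margin, lag=lag, shape_noise=shape_noise)


def generate_trial(
    config: SynthConfig,
    subject: SubjectEffects,
    condition: str,
    time: str,
    obj: str,
    rng: np.random.Generator,
    trial_index: int = 0,
    block: _BlockParams | None = None,
    finger_channels: bool = True,
) -> TrialRecording:
    """Generate one trial recording for the given design cell.

    ``block`` carries session-level parameters when trials belong to the same
    10-trial block; omitted, a fresh block draw is made.  ``finger_channels``
    can be disabled to skip thumb/index synthesis when only transport
    kinematics are needed (the channels are then wrist copies).
    """
    if rng is None:
        raise ParameterError("an explicit numpy Generator is required; refusing to self-seed")
    if condition not in CONDITIONS or time not in TIMES or obj not in OBJECTS:
        raise ParameterError(f"unknown design cell ({condition}, {time}, {obj})")
    if block is None:
        block = _draw_block_params(config, subject, condition, time, obj, rng)

    fs = config.fs_kinematic
    tmt = max(0.4, block.tmt + rng.normal(0.0, config.trial_tmt_sd))
    margin = max(0.004, block.margin + rng.normal(0.0, config.trial_margin_sd))
    lag = block.lag + rng.normal(0.0, config.trial_lag_sd)
    reaction = max(0.15, rng.normal(config.reaction_time_mean, config.reaction_time_sd))

    led = config.lead_in
    move_start = led + reaction
    move_end = move_start + tmt
    total = move_end + config.tail
    n = int(round(total * fs)) + 1
    t = np.arange(n) / fs

    tau = (t - move_start) / tmt
    x = _minimum_jerk_at(tau, config.reach_distance)
    wrist = np.column_stack([x, np.zeros(n), np.zeros(n)])

    shift, lag_achieved = 0.0, 0.0
    if finger_channels:
        diameter = config.object_diameters[obj]
        shift, lag_achieved = _calibrated_shift(
            int(round(tmt * fs)),
            int(round(diameter * 1e6)),
            int(round(margin * 2e3) * 500),            # margin quantized to 0.5 mm
            int(round(config.aperture_baseline * 1e6)),
            int(round(config.aperture_peak_fraction * 1000)),
            int(round(lag * fs * 4)),                  # lag quantized to 1/4 sample
            fs,
        )
        tau_ap = (t - move_start - shift) / tmt
        aperture = _aperture_at(
            tau_ap, diameter, margin, config.aperture_peak_fraction, config.aperture_baseline
        )
        if block.shape_noise > 0:
            # smooth low-frequency perturbation, vanishing at the movement edges
            env = np.sin(np.pi * np.clip(tau, 0.0, 1.0))
            phases = rng.uniform(0.0, 2 * np.pi, size=2)
            wobble = 0.8 * np.sin(2 * np.pi * 1.5 * np.clip(tau, 0, 1) + phases[0]) + 0.6 * np.sin(
                2 * np.pi * 2.5 * np.clip(tau, 0, 1) + phases[1]
            )
            aperture = np.maximum(aperture + block.shape_noise * env * wobble, 1e-4)
        half = aperture / 2.0
        offset = np.array([0.08, 0.0, 0.02])  # fingertips lead the wrist sensor
        thumb = wrist + offset
        index = wrist + offset
        thumb = thumb + np.column_stack([np.zeros(n), half, np.zeros(n)])
        index = index - np.column_stack([np.zeros(n), half, np.zeros(n)])
    else:
        thumb = wrist.copy()
        index = wrist.copy()

    if config.noise_sd_position > 0:
        wrist = wrist + rng.normal(0.0, config.noise_sd_position, size=(n, 3))
        thumb = thumb + rng.normal(0.0, config.noise_sd_position, size=(n, 3))
        index = index + rng.normal(0.0, config.noise_sd_position, size=(n, 3))

    return TrialRecording(
        subject_id=subject.subject_id,
        condition=condition,
        time=time,
        object=obj,
        trial_index=trial_index,
        timestamps=t,
        wrist_xyz=wrist,
        thumb_xyz=thumb,
        index_xyz=index,
        led_onset=led,
        hand_lift=move_start,
        object_lift=move_end,
        fs=fs,
        truth=TrialTruth(
            tmt=tmt,
            a_max=config.object_diameters[obj] + margin,
            lag=lag,
            shift=shift,
            lag_achieved=lag_achieved,
        ),
    )


def generate_block(
    config: SynthConfig,
    subject: SubjectEffects,
    condition: str,
    time: str,
    obj: str,
    rng: np.random.Generator,
    finger_channels: bool = True,
) -> list[TrialRecording]:
    """One 10-trial block sharing session-level parameters."""
    block = _draw_block_params(config, subject, condition, time, obj, rng)
    return [
        generate_trial(
            config, subject, condition, time, obj, rng,
            trial_index=i, block=block, finger_channels=finger_channels,
        )
        for i in range(config.trials_per_block)
    ]


def generate_dataset(
    config: SynthConfig,
    rng: np.random.Generator | None = None,
    objects: tuple[str, ...] = OBJECTS,
    finger_channels: bool = True,
) -> list[TrialRecording]:
    """All trials of the full within-subject design, in deterministic order."""
    if rng is None:
        if config.seed is None:
            raise ParameterError("provide an rng or set config.seed")
        rng = np.random.default_rng(config.seed)
    subjects = draw_subject_effects(config, rng)
    trials: list[TrialRecording] = []
    for subject in subjects:
        for condition in CONDITIONS:
            for time in TIMES:
                for obj in objects:
                    trials.extend(
                        generate_block(
                            config, subject, condition, time, obj, rng,
                            finger_channels=finger_channels,
                        )
                    )
    return trials


# --------------------------------------------------------------------------
# MEP sweeps
# --------------------------------------------------------------------------

@dataclass
class MEPSweepRecord:
    """One synthetic EMG sweep with its stimulus time (seconds from sweep start)."""

    timestamps: np.ndarray
    emg_uv: np.ndarray
    stimulus_time: float
    fs: float


def generate_mep_sweep(
    baseline_amp: float,
    suppression: float,
    fs: float,
    rng: np.random.Generator,
    noise_cv: float = 0.0,
    background_sd: float = 0.0,
    duration: float = 0.25,
    stimulus_time: float = 0.05,
) -> MEPSweepRecord:
    """Biphasic MEP-like deflection in the 10-60 ms post-stimulus window.

    Discrete peak-to-peak amplitude equals ``baseline_amp * (1 - suppression)``
    exactly at zero noise; trial noise is multiplicative lognormal with unit
    mean so session means stay unbiased.
    """
    if rng is None:
        raise ParameterError("an explicit numpy Generator is required")
    if baseline_amp <= 0:
        raise ParameterError(f"baseline_amp must be positive, got {baseline_amp}")
    if not 0.0 <= suppression < 1.0:
        raise ParameterError(f"suppression must be in [0, 1), got {suppression}")
    n = int(round(duration * fs)) + 1
    t = np.arange(n) / fs
    target = baseline_amp * (1.0 - suppression)
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        target *= float(np.exp(rng.normal(0.0, sigma) - sigma**2 / 2.0))
    # one biphasic cycle, Hann-windowed, centred 25 ms post stimulus
    onset, width = stimulus_time + 0.015, 0.020
    local = (t - onset) / width
    mask = (local >= 0.0) & (local <= 1.0)
    shape = np.zeros(n)
    shape[mask] = np.sin(2 * np.pi * local[mask]) * (0.5 - 0.5 * np.cos(2 * np.pi * local[mask]))
    p2p = float(shape.max() - shape.min())
    emg = shape * (target / p2p)
    if background_sd > 0:
        emg = emg + rng.normal(0.0, background_sd, size=n)
    return MEPSweepRecord(timestamps=t, emg_uv=emg, stimulus_time=stimulus_time, fs=fs)


def generate_mep_session(
    config: SynthConfig,
    subject: SubjectEffects,
    condition: str,
    time: str,
    rng: np.random.Generator,
    n_sweeps: int = 10,
) -> list[MEPSweepRecord]:
    """A 10-sweep MEP block; real-rTMS post sweeps are suppressed."""
    suppression = (
        config.effects.mep_suppression_fraction
        if (condition == "real" and time == "post")
        else 0.0
    )
    return [
        generate_mep_sweep(
            subject.mep_baseline,
            suppression,
            config.fs_emg,
            rng,
            noise_cv=config.mep_noise_cv,
            background_sd=config.mep_background_sd,
        )
        for _ in range(n_sweeps)
    ]


# --------------------------------------------------------------------------
# on-disk dialect
# --------------------------------------------------------------------------

TRIAL_COLUMNS = [
    "t", "wrist_x", "wrist_y", "wrist_z",
    "thumb_x", "thumb_y", "thumb_z",
    "index_x", "index_y", "index_z",
]


def write_trial(recording: TrialRecording, directory: Path) -> tuple[Path, Path]:
    """Write one trial as CSV + JSON sidecar; returns both paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = (
        f"{recording.subject_id}_{recording.condition}_{recording.time}_"
        f"{recording.object}_t{recording.trial_index:02d}"
    )
    csv_path = directory / f"{stem}.csv"
    data = np.column_stack(
        [recording.timestamps, recording.wrist_xyz, recording.thumb_xyz, recording.index_xyz]
    )
    header = ",".join(TRIAL_COLUMNS)
    np.savetxt(csv_path, data, delimiter=",", header=header, comments="", fmt="%.9f")
    sidecar = {
        "subject_id": recording.subject_id,
        "condition": recording.condition,
        "time": recording.time,
        "object": recording.object,
        "trial_index": recording.trial_index,
        "fs": recording.fs,
        "led_onset": recording.led_onset,
        "hand_lift": recording.hand_lift,
        "object_lift": recording.object_lift,
    }
    json_path = directory / f"{stem}.json"
    json_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
    return csv_path, json_path


def read_trial(csv_path: Path) -> TrialRecording:
    """Read one trial written by :func:`write_trial` (CSV + JSON sidecar)."""
    csv_path = Path(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    data = np.loadtxt(csv_path, delimiter=",", skiprows=1)
    return TrialRecording(
        subject_id=meta["subject_id"],
        condition=meta["condition"],
        time=meta["time"],
        object=meta["object"],
        trial_index=int(meta["trial_index"]),
        timestamps=data[:, 0],
        wrist_xyz=data[:, 1:4],
        thumb_xyz=data[:, 4:7],
        index_xyz=data[:, 7:10],
        led_onset=meta["led_onset"],
        hand_lift=meta["hand_lift"],
        object_lift=meta["object_lift"],
        fs=float(meta["fs"]),
    )


def write_dataset(trials: list[TrialRecording], directory: Path) -> Path:
    """Write all trials plus a manifest CSV indexing them; returns manifest path."""
    directory = Path(directory)
    rows = []
    for tr in trials:
        csv_path, _ = write_trial(tr, directory)
        rows.append(
            f"{tr.subject_id},{tr.condition},{tr.time},{tr.object},{tr.trial_index},{csv_path.name}"
        )
    manifest = directory / "manifest.csv"
    manifest.write_text(
        "subject_id,condition,time,object,trial_index,file\n" + "\n".join(rows) + "\n"
    )
    return manifest


def read_dataset(manifest_path: Path) -> list[TrialRecording]:
    manifest_path = Path(manifest_path)
    lines = manifest_path.read_text().strip().splitlines()[1:]
    trials = []
    for line in lines:
        fname = line.rsplit(",", 1)[1]
        trials.append(read_trial(manifest_path.parent / fname))
    return trials
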