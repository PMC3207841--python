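"""Synthetic thermal-video phantom of the periorbital regions.

The phantom emulates a radiometric recording of a face seen by a thermal
camera: a cool background, a warmer elliptical face plateau, and two hot
Gaussian spots at the inner canthi (the warmest facial regions, perfused by
the angular artery/vein).  On top of that static scene it layers the
stochastic structure the downstream analysis has to cope with:

* rigid integer-pixel head jitter (random walk) with occasional large
  "startle" jerks shortly after the stimulus,
* a slow non-stationary baseline drift of the canthus temperature,
* i.i.d. Gaussian sensor noise per pixel,
* an optional injected post-stimulus temperature effect that ramps in after
  a short physiological latency (default 0 K — the null model).

Trials are 30 s at 15 Hz; in half the trials an auditory stimulus occurs at
a uniformly random time no earlier than 2 s into the trial and no later
than 7 s before its end.  A study is 11 participants x 10 sessions x 10
trials with a per-participant Gaussian baseline temperature offset.

All temperatures are in Kelvin and all arithmetic is double precision.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from numpy.random import Generator, SeedSequence, default_rng
from scipy import signal


class InvalidConfigError(ValueError):
    """Raised when a phantom or study configuration violates its invariants."""


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------


@dataclass
class ThermalFrameStack:
    """Time-ordered stack of temperature frames (Kelvin).

    Parameters
    ----------
    frames : ndarray, shape (n_frames, rows, cols)
        Temperature pixels in Kelvin.
    fs : float
        Video sampling rate in Hz.
    """

    frames: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, rows, cols) array")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple:
        return self.frames.shape

    @property
    def duration(self) -> float:
        return self.n_frames / self.fs

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fs

    # ---- persistence (float32 multi-page TIFF is the primary on-disk form;
    #      HDF5 is the alternative reader path) ----

    def save_tiff(self, path) -> None:
        import tifffile

        tifffile.imwrite(
            str(path),
            self.frames.astype(np.float32),
            metadata={"fs_hz": self.fs, "units": "K"},
        )

    @classmethod
    def load_tiff(cls, path, fs: Optional[float] = None) -> "ThermalFrameStack":
        import tifffile

        with tifffile.TiffFile(str(path)) as tif:
            frames = tif.asarray()
            if fs is None:
                meta = tif.shaped_metadata or tif.imagej_metadata or {}
                if isinstance(meta, (list, tuple)) and meta:
                    meta = meta[0]
                fs = float((meta or {}).get("fs_hz", 15.0))
        if frames.ndim == 2:
            frames = frames[None]
        return cls(frames=np.asarray(frames, dtype=np.float64), fs=fs)

    def save_hdf5(self, path) -> None:
        import h5py

        with h5py.File(str(path), "w") as f:
            ds = f.create_dataset("frames", data=self.frames.astype(np.float32))
            ds.attrs["fs_hz"] = self.fs
            ds.attrs["units"] = "K"

    @classmethod
    def load_hdf5(cls, path) -> "ThermalFrameStack":
        import h5py

        with h5py.File(str(path), "r") as f:
            ds = f["frames"]
            return cls(
                frames=np.asarray(ds[...], dtype=np.float64),
                fs=float(ds.attrs.get("fs_hz", 15.0)),
            )


@dataclass
class AmbientStream:
    """Ambient temperature / airspeed recorded near the participant at 1 Hz."""

    timestamps: np.ndarray  # seconds, strictly increasing, 1 Hz spacing
    ambient_temp: np.ndarray  # K
    airspeed: np.ndarray  # m/s

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.ambient_temp = np.asarray(self.ambient_temp, dtype=float)
        self.airspeed = np.asarray(self.airspeed, dtype=float)
        dt = np.diff(self.timestamps)
        if len(dt) and (np.any(dt <= 0) or not np.allclose(dt, 1.0)):
            raise ValueError("timestamps must be strictly increasing at 1 Hz")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp_s": self.timestamps,
                "ambient_K": self.ambient_temp,
                "airspeed_mps": self.airspeed,
            }
        )

    def save_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def load_csv(cls, path) -> "AmbientStream":
        df = pd.read_csv(path)
        return cls(
            timestamps=df["timestamp_s"].to_numpy(),
            ambient_temp=df["ambient_K"].to_numpy(),
            airspeed=df["airspeed_mps"].to_numpy(),
        )


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------


@dataclass
class PhantomConfig:
    """Parameters of the synthetic scene and trial model.

    Defaults reproduce the recording conditions of the study design this
    package analyses: 640x480 temperature pixels at 15 Hz, 30 s trials,
    canthus peak temperature ~307.5 K, a 300 ms physiological response
    latency, and a null (0 K) injected effect.
    """

    frame_rows: int = 480
    frame_cols: int = 640
    fs_video: float = 15.0
    trial_duration: float = 30.0
    background_temp: float = 295.0
    face_temp: float = 306.0
    canthus_peak_temp: float = 307.5
    canthus_sigma: float = 10.0
    canthus_centers: Optional[tuple] = None  # two (row, col) pairs
    noise_sd: float = 0.03
    drift_amplitude: float = 0.05  # rms K of the slow baseline drift
    drift_timescale: float = 10.0  # s
    jitter_sd: float = 0.3  # pixels/frame random-walk step sd
    startle_jerk_amplitude: float = 6.0  # pixels
    startle_prob: float = 0.18  # P(visible formal startle | stimulus)
    effect_delta: float = 0.0  # K, injected post-stimulus effect (null: 0)
    effect_latency: float = 0.3  # s
    effect_ramp: float = 1.0  # s, 0 -> effect_delta ramp duration
    series_noise_sd: float = 0.033  # K, series-level measurement noise
    participant_sd: float = 0.3  # K, between-participant baseline sd
    ambient_temp: float = 295.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.canthus_centers is None:
            # inner canthi flank the nose near the facial midline, well
            # inside the face ellipse
            r = round(0.44 * self.frame_rows)
            self.canthus_centers = (
                (r, round(0.40 * self.frame_cols)),
                (r, round(0.60 * self.frame_cols)),
            )
        self.canthus_centers = tuple(
            (int(r), int(c)) for r, c in self.canthus_centers
        )
        if len(self.canthus_centers) != 2:
            raise InvalidConfigError("canthus_centers must hold two (row, col) pairs")
        if not (self.canthus_peak_temp > self.face_temp > self.background_temp):
            raise InvalidConfigError(
                "require canthus_peak_temp > face_temp > background_temp"
            )
        for name in ("background_temp", "face_temp", "canthus_peak_temp"):
            v = getattr(self, name)
            if not (270.0 <= v <= 330.0):
                raise InvalidConfigError(f"{name}={v} outside [270, 330] K")
        if self.noise_sd < 0 or self.drift_amplitude < 0:
            raise InvalidConfigError("noise_sd and drift_amplitude must be >= 0")
        if self.fs_video <= 0:
            raise InvalidConfigError("fs_video must be positive")
        if self.trial_duration < 10.0:
            raise InvalidConfigError("trial_duration must be at least 10 s")
        if self.canthus_sigma <= 0:
            raise InvalidConfigError("canthus_sigma must be positive")
        if not (0.0 <= self.startle_prob <= 1.0):
            raise InvalidConfigError("startle_prob must be in [0, 1]")

    @property
    def n_frames(self) -> int:
        return int(round(self.trial_duration * self.fs_video))

    def replace(self, **kwargs) -> "PhantomConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["canthus_centers"] = [list(c) for c in self.canthus_centers]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomConfig":
        d = dict(d)
        if d.get("canthus_centers") is not None:
            d["canthus_centers"] = tuple(tuple(c) for c in d["canthus_centers"])
        return cls(**d)


@dataclass
class TrialRecord:
    """One trial of one session: metadata, ground truth and (optionally) data."""

    participant_id: str
    session_index: int
    trial_index: int
    stimulus_flag: bool
    t_stim: Optional[float] = None
    stack: Optional[ThermalFrameStack] = None
    ambient: Optional[AmbientStream] = None
    ground_truth: dict = field(default_factory=dict)
    usable_flag: Optional[bool] = None
    formal_startle_flag: Optional[bool] = None
    stack_ref: Optional[str] = None
    seed_key: Optional[tuple] = None
    trial_duration: float = 30.0

    def __post_init__(self) -> None:
        if self.stimulus_flag != (self.t_stim is not None):
            raise ValueError("t_stim must be present iff stimulus_flag is set")
        if self.t_stim is not None and not (
            2.0 <= self.t_stim <= self.trial_duration - 7.0
        ):
            raise ValueError(
                f"t_stim={self.t_stim} outside [2, duration-7]"
            )

    @property
    def key(self) -> tuple:
        return (self.participant_id, self.session_index, self.trial_index)


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------


def schedule_stimulus_time(trial_duration: float, rng: Generator) -> float:
    """Draw the stimulus time uniformly on [2 s, trial_duration - 7 s]."""
    if trial_duration <= 9.0:
        raise InvalidConfigError(
            "trial_duration must exceed 9 s for a non-empty stimulus window"
        )
    return float(rng.uniform(2.0, trial_duration - 7.0))


def _scene(
    config: PhantomConfig,
    offset=(0, 0),
    drift_value: float = 0.0,
    effect_value: float = 0.0,
    baseline: float = 0.0,
) -> np.ndarray:
    """Noiseless analytic scene at a rigid integer offset."""
    rows, cols = config.frame_rows, config.frame_cols
    rr = np.arange(rows, dtype=float)[:, None]
    cc = np.arange(cols, dtype=float)[None, :]
    dr, dc = offset
    fr, fc = rows / 2.0 + dr, cols / 2.0 + dc
    # face ellipse; semi-axes leave a background margin on all sides
    mask = ((rr - fr) / (0.48 * rows)) ** 2 + ((cc - fc) / (0.42 * cols)) ** 2 <= 1.0
    frame = np.full((rows, cols), config.background_temp, dtype=np.float64)
    frame[mask] = config.face_temp + baseline
    amp = (
        config.canthus_peak_temp
        + baseline
        + drift_value
        + effect_value
        - (config.face_temp + baseline)
    )
    s2 = 2.0 * config.canthus_sigma**2
    for (r0, c0) in config.canthus_centers:
        frame += amp * np.exp(-(((rr - r0 - dr) ** 2) + ((cc - c0 - dc) ** 2)) / s2)
    return frame


def _off_frame(config: PhantomConfig, offset) -> bool:
    dr, dc = offset
    sig = config.canthus_sigma
    for (r0, c0) in config.canthus_centers:
        r, c = r0 + dr, c0 + dc
        if (
            r - sig < 0
            or r + sig > config.frame_rows - 1
            or c - sig < 0
            or c + sig > config.frame_cols - 1
        ):
            return True
    return False


def make_frame(
    config: PhantomConfig,
    t: float = 0.0,
    offset=(0, 0),
    drift_value: float = 0.0,
    effect_value: float = 0.0,
    rng: Optional[Generator] = None,
    baseline: float = 0.0,
):
    """Render one frame; returns ``(frame, off_frame_flag)``.

    The frame is background + elliptical face plateau + two Gaussian hot
    spots whose peak is ``canthus_peak_temp + drift_value + effect_value``
    (plus the participant baseline), with optional i.i.d. Gaussian sensor
    noise.  A frame whose canthus centres come within one sigma of the
    border is still rendered but flagged off-frame.
    """
    frame = _scene(config, offset, drift_value, effect_value, baseline)
    if rng is not None and config.noise_sd > 0:
        frame = frame + rng.normal(0.0, config.noise_sd, frame.shape)
    return frame, _off_frame(config, offset)


def _lowpassed_noise(
    rng: Generator, n: int, cutoff: float, fs: float, rms: float
) -> np.ndarray:
    """Smooth zero-mean process with the requested rms: low-passed white noise."""
    if rms <= 0:
        return np.zeros(n)
    burn = max(n, int(round(4 * fs / max(cutoff, 1e-6))))
    b, a = signal.butter(2, cutoff, fs=fs)
    x = signal.lfilter(b, a, rng.normal(size=n + burn))[burn:]
    x = x - x.mean()
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _effect_profile(config: PhantomConfig, times: np.ndarray, t_stim: float) -> np.ndarray:
    """Injected effect: 0 until t_stim + latency, then a linear ramp to delta."""
    ramp = np.clip((times - t_stim - config.effect_latency) / config.effect_ramp, 0.0, 1.0)
    return config.effect_delta * ramp


def _motion_trajectory(
    config: PhantomConfig,
    rng: Generator,
    n: int,
    t_stim: Optional[float],
    startle_occurred: bool,
):
    """Integer-pixel rigid-motion trajectory: random walk plus startle jerk."""
    fs = config.fs_video
    steps = rng.normal(0.0, config.jitter_sd, size=(n, 2))
    steps[0] = 0.0
    walk = np.cumsum(steps, axis=0)
    t_jerk = None
    if startle_occurred and t_stim is not None:
        t_jerk = float(
            t_stim + rng.uniform(0.0, min(3.0, config.trial_duration - t_stim - 0.5))
        )
        theta = rng.uniform(0.0, 2.0 * np.pi)
        k0 = int(round(t_jerk * fs))
        # sudden twitch: full amplitude within one frame, brief hold,
        # then a slower return to rest
        hold = max(int(round(0.2 * fs)), 1)
        back = max(int(round(0.2 * fs)), 1)
        prof = np.concatenate(
            [np.ones(hold), np.linspace(1, 0, back + 1)[1:]]
        )
        for j, p in enumerate(prof):
            k = k0 + j
            if k < n:
                walk[k, 0] += config.startle_jerk_amplitude * p * np.sin(theta)
                walk[k, 1] += config.startle_jerk_amplitude * p * np.cos(theta)
    offsets = np.rint(walk).astype(int)
    return offsets, t_jerk


def simulate_trial(
    config: PhantomConfig,
    stimulus_flag: bool,
    rng: Optional[Generator] = None,
    participant_offset: float = 0.0,
    render_frames: bool = True,
    participant_id: str = "P01",
    session_index: int = 1,
    trial_index: int = 1,
) -> TrialRecord:
    """Simulate one trial of thermal video plus ambient stream.

    Draw order is fixed (stimulus time, startle, jerk, walk, drift, ambient,
    then per-frame sensor noise) so the schedule of a trial can be produced
    without rendering frames and later re-rendered bit-identically from the
    same substream.
    """
    if rng is None:
        rng = default_rng(config.seed)
    n = config.n_frames
    fs = config.fs_video
    times = np.arange(n) / fs

    t_stim = schedule_stimulus_time(config.trial_duration, rng) if stimulus_flag else None
    startle_occurred = bool(stimulus_flag and (rng.random() < config.startle_prob))
    offsets, t_jerk = _motion_trajectory(config, rng, n, t_stim, startle_occurred)
    drift = _lowpassed_noise(
        rng, n, 1.0 / config.drift_timescale, fs, config.drift_amplitude
    )
    effect = (
        _effect_profile(config, times, t_stim) if t_stim is not None else np.zeros(n)
    )

    m = int(np.floor(config.trial_duration))
    ambient = AmbientStream(
        timestamps=np.arange(m, dtype=float),
        ambient_temp=config.ambient_temp + 0.02 * np.cumsum(rng.normal(size=m)) / np.sqrt(m),
        airspeed=np.abs(0.05 + 0.02 * rng.normal(size=m)),
    )

    stack = None
    off_frame = np.zeros(n, dtype=bool)
    if render_frames:
        frames = np.empty((n, config.frame_rows, config.frame_cols))
        for i in range(n):
            frames[i], off_frame[i] = make_frame(
                config,
                times[i],
                offset=tuple(offsets[i]),
                drift_value=drift[i],
                effect_value=effect[i],
                rng=rng if config.noise_sd > 0 else None,
                baseline=participant_offset,
            )
        stack = ThermalFrameStack(frames=frames, fs=fs)
    else:
        for i in range(n):
            off_frame[i] = _off_frame(config, tuple(offsets[i]))

    return TrialRecord(
        participant_id=participant_id,
        session_index=session_index,
        trial_index=trial_index,
        stimulus_flag=stimulus_flag,
        t_stim=t_stim,
        stack=stack,
        ambient=ambient,
        trial_duration=config.trial_duration,
        ground_truth={
            "offsets": offsets,
            "startle_occurred": startle_occurred,
            "t_jerk": t_jerk,
            "effect_delta": config.effect_delta,
            "drift": drift,
            "effect": effect,
            "off_frame": off_frame,
            "participant_offset": participant_offset,
        },
    )


def simulate_mean_series(
    config: PhantomConfig,
    stimulus_flag: bool,
    rng: Optional[Generator] = None,
    participant_offset: float = 0.0,
):
    """Series-level phantom: directly model the unfiltered mean-temperature series.

    This is the fast path for statistical experiments that do not exercise
    the imaging chain: baseline + participant offset + low-passed drift +
    ramped effect + white measurement noise (sd ``series_noise_sd``, chosen
    so the 2 Hz-filtered 2 s windows have variance near 3e-4 K^2).

    Returns ``(values, t_stim, ground_truth)``.
    """
    if rng is None:
        rng = default_rng(config.seed)
    n = config.n_frames
    times = np.arange(n) / config.fs_video
    t_stim = schedule_stimulus_time(config.trial_duration, rng) if stimulus_flag else None
    startle_occurred = bool(stimulus_flag and (rng.random() < config.startle_prob))
    drift = _lowpassed_noise(
        rng, n, 1.0 / config.drift_timescale, config.fs_video, config.drift_amplitude
    )
    effect = (
        _effect_profile(config, times, t_stim) if t_stim is not None else np.zeros(n)
    )
    values = (
        config.canthus_peak_temp
        + participant_offset
        + drift
        + effect
        + rng.normal(0.0, config.series_noise_sd, n)
    )
    gt = {
        "startle_occurred": startle_occurred,
        "drift": drift,
        "effect": effect,
        "participant_offset": participant_offset,
    }
    return values, t_stim, gt


def trial_seed_key(config_seed: int, participant: int, session: int, trial: int) -> tuple:
    """Deterministic per-trial substream key (sessions/trials are 1-based)."""
    return (config_seed, participant, session, trial)


def trial_rng(config_seed: int, participant: int, session: int, trial: int) -> Generator:
    return default_rng(SeedSequence(trial_seed_key(config_seed, participant, session, trial)))


def participant_offsets(config: PhantomConfig, n_participants: int) -> np.ndarray:
    """Per-participant Gaussian baseline shifts, drawn once per study."""
    rng = default_rng(SeedSequence((config.seed, 0)))
    return rng.normal(0.0, config.participant_sd, n_participants)


def simulate_study(
    config: PhantomConfig,
    n_participants: int = 11,
    n_sessions: int = 10,
    n_trials: int = 10,
    render_frames: bool = False,
) -> list:
    """Simulate a whole study schedule; exactly half the trials per session
    carry a stimulus, randomly interleaved.

    With ``render_frames=False`` (default) the returned records carry the
    full schedule and motion/drift ground truth but no frame stacks; any
    trial can later be rendered bit-identically with :func:`render_trial`.
    """
    if n_trials % 2 != 0:
        raise InvalidConfigError("n_trials must be even (half stimulus)")
    offsets = participant_offsets(config, n_participants)
    records = []
    for p in range(1, n_participants + 1):
        pid = f"P{p:02d}"
        for s in range(1, n_sessions + 1):
            sched_rng = default_rng(SeedSequence((config.seed, p, s)))
            flags = np.array([True] * (n_trials // 2) + [False] * (n_trials // 2))
            sched_rng.shuffle(flags)
            for t in range(1, n_trials + 1):
                rec = simulate_trial(
                    config,
                    bool(flags[t - 1]),
                    rng=trial_rng(config.seed, p, s, t),
                    participant_offset=float(offsets[p - 1]),
                    render_frames=render_frames,
                    participant_id=pid,
                    session_index=s,
                    trial_index=t,
                )
                rec.seed_key = trial_seed_key(config.seed, p, s, t)
                records.append(rec)
    return records


def render_trial(config: PhantomConfig, record: TrialRecord) -> TrialRecord:
    """Re-create a scheduled trial with its frame stack, bit-identically."""
    if record.seed_key is None:
        raise ValueError("record has no seed_key; was it produced by simulate_study?")
    seed, p, s, t = record.seed_key
    return dataclasses.replace(
        simulate_trial(
            config,
            record.stimulus_flag,
            rng=default_rng(SeedSequence(record.seed_key)),
            participant_offset=float(record.ground_truth.get("participant_offset", 0.0)),
            render_frames=True,
            participant_id=record.participant_id,
            session_index=s,
            trial_index=t,
        ),
        seed_key=record.seed_key,
    )


# --------------------------------------------------------------------------
# persistence
# --------------------------------------------------------------------------


def write_trial(record: TrialRecord, out_dir) -> Path:
    """Write ``stack.tiff`` + ``trial.json`` + ``ambient.csv`` for one trial."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if record.stack is not None:
        record.stack.save_tiff(out / "stack.tiff")
    if record.ambient is not None:
        record.ambient.save_csv(out / "ambient.csv")
    gt = record.ground_truth
    meta = {
        "participant": record.participant_id,
        "session": record.session_index,
        "trial": record.trial_index,
        "stimulus_flag": record.stimulus_flag,
        "t_stim": record.t_stim,
        "trial_duration": record.trial_duration,
        "seed_key": list(record.seed_key) if record.seed_key else None,
        "ground_truth": {
            "startle_occurred": bool(gt.get("startle_occurred", False)),
            "t_jerk": gt.get("t_jerk"),
            "effect_delta": gt.get("effect_delta", 0.0),
            "participant_offset": gt.get("participant_offset", 0.0),
            "offsets": np.asarray(gt["offsets"]).tolist() if "offsets" in gt else None,
        },
    }
    (out / "trial.json").write_text(json.dumps(meta, indent=1))
    return out


def read_trial(trial_dir) -> TrialRecord:
    """Read a trial written by :func:`write_trial`."""
    d = Path(trial_dir)
    meta = json.loads((d / "trial.json").read_text())
    gt = meta.get("ground_truth", {}) or {}
    if gt.get("offsets") is not None:
        gt["offsets"] = np.asarray(gt["offsets"], dtype=int)
    stack = (
        ThermalFrameStack.load_tiff(d / "stack.tiff")
        if (d / "stack.tiff").exists()
        else None
    )
    ambient = (
        AmbientStream.load_csv(d / "ambient.csv") if (d / "ambient.csv").exists() else None
    )
    return TrialRecord(
        participant_id=meta["participant"],
        session_index=int(meta["session"]),
        trial_index=int(meta["trial"]),
        stimulus_flag=bool(meta["stimulus_flag"]),
        t_stim=meta.get("t_stim"),
        trial_duration=float(meta.get("trial_duration", 30.0)),
        stack=stack,
        ambient=ambient,
        ground_truth=gt,
        seed_key=tuple(meta["seed_key"]) if meta.get("seed_key") else None,
        stack_ref=str(d / "stack.tiff"),
    )
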