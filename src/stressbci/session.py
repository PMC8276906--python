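"""Synthetic stress-session EEG and behavioral-report generator.

The study protocol this emulates: a 120 s eyes-open baseline, then four
blocks, each a 90 s timed mental-arithmetic stressor followed by a 200 s
breathing period; the first and third breathing periods are self-paced
(*unguided*), the second and fourth are entrained to ~6 breaths per minute
(*guided*). A 5-point stress self-report follows every stressor and every
breathing period. EEG is 16 channels of the 10-20 montage sampled at 125 Hz.

The raw study recordings were never released, so this module generates
sessions with the statistical structure the downstream analysis assumes:
condition-dependent oscillatory power in the theta (3-7 Hz), alpha (8-14 Hz)
and beta (15-30 Hz) bands, a 1/f background, sub-1 Hz sinusoidal drift and
a 60 Hz mains component. Band oscillations are amplitude-modulated
narrow-band noise mixed into the montage through a fixed per-participant
orthonormal matrix, so that conditions differ in spatial covariance (the
property CSP exploits), not merely in marginal channel power.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

RATE = 125.0
"""Sampling rate in Hz."""

CHANNELS = (
    "Fp1", "Fp2", "C3", "C4", "P7", "P8", "O1", "O2",
    "F7", "F8", "F3", "F4", "T7", "T8", "P3", "P4",
)
"""The 16-channel 10-20 montage, in acquisition order."""

BANDS = {"theta": (3.0, 7.0), "alpha": (8.0, 14.0), "beta": (15.0, 30.0)}
"""Oscillatory bands (Hz) whose power is condition-dependent."""

CONDITIONS = ("baseline", "stressor", "unguided", "guided")
"""The four trainable condition labels, in canonical class order."""

BASELINE_S = 120.0
STRESSOR_S = 90.0
BREATHING_S = 200.0
N_BLOCKS = 4

#: Default per-condition band-power multipliers: stress suppresses alpha and
#: raises beta; slow breathing raises theta/alpha, guided more than unguided.
DEFAULT_BAND_MODULATION = {
    "baseline": {"theta": 1.0, "alpha": 1.0, "beta": 1.0},
    "stressor": {"theta": 1.1, "alpha": 0.6, "beta": 1.8},
    "unguided": {"theta": 1.3, "alpha": 1.4, "beta": 0.9},
    "guided": {"theta": 1.6, "alpha": 1.8, "beta": 0.6},
    "rest": {"theta": 1.0, "alpha": 1.0, "beta": 1.0},
}

#: Source amplitudes per band, microvolts RMS at multiplier 1.
BAND_AMP_UV = {"theta": 8.0, "alpha": 12.0, "beta": 6.0}


@dataclass(frozen=True)
class ConditionSegment:
    """One contiguous stretch of the session with a single condition label."""

    label: str
    onset: float
    duration: float

    def __post_init__(self):
        if self.onset < 0:
            raise ValueError(f"segment onset must be >= 0, got {self.onset}")
        if self.duration <= 0:
            raise ValueError(f"segment duration must be > 0, got {self.duration}")
        if self.label not in CONDITIONS + ("rest",):
            raise ValueError(f"unknown segment label {self.label!r}")

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class SessionSchedule:
    """Ordered, contiguous condition segments covering one session."""

    segments: tuple[ConditionSegment, ...]

    def __post_init__(self):
        t = 0.0
        for seg in self.segments:
            if abs(seg.onset - t) > 1e-9:
                raise ValueError(
                    f"segments must be contiguous: expected onset {t}, got {seg.onset}"
                )
            t = seg.end

    @property
    def total_duration(self) -> float:
        return self.segments[-1].end if self.segments else 0.0

    def labeled_seconds(self) -> dict[str, float]:
        """Seconds per trainable condition (rest excluded)."""
        out = {c: 0.0 for c in CONDITIONS}
        for seg in self.segments:
            if seg.label in out:
                out[seg.label] += seg.duration
        return out


def make_schedule(rest_duration: float = 30.0) -> SessionSchedule:
    """Build the default session schedule.

    Baseline (120 s), then four blocks of stressor (90 s), rest, breathing
    (200 s, alternating unguided / guided starting unguided), rest. Rest
    segments model the self-report prompts; they carry no class label and
    are omitted entirely when ``rest_duration`` is 0.
    """
    if rest_duration < 0:
        raise ValueError(f"rest_duration must be >= 0, got {rest_duration}")
    segs: list[ConditionSegment] = []
    t = 0.0

    def push(label: str, dur: float):
        nonlocal t
        if dur > 0:
            segs.append(ConditionSegment(label, t, dur))
            t += dur

    push("baseline", BASELINE_S)
    for block in range(N_BLOCKS):
        push("stressor", STRESSOR_S)
        push("rest", rest_duration)
        push("unguided" if block % 2 == 0 else "guided", BREATHING_S)
        push("rest", rest_duration)
    return SessionSchedule(tuple(segs))


@dataclass(frozen=True)
class ParticipantProfile:
    """Generative parameters for one simulated participant."""

    id: str
    group: str  # "ASD" or "neurotypical"
    trait_anxiety: int  # STAI-C trait score
    seed: int
    band_modulation: dict = field(default_factory=lambda: DEFAULT_BAND_MODULATION)
    #: 0 = conditions modulate the gain of one fixed band topography;
    #: > 0 mixes in a condition-specific topography (distinct spatial
    #: covariance per mental state, the structure CSP exploits).
    spatial_variability: float = 1.0
    noise_level: float = 1.0  # relative 1/f background amplitude
    drift_amp_uv: float = 40.0  # 0.3 Hz sinusoidal drift, tests the 1 Hz high-pass
    drift_hz: float = 0.3
    line_amp_uv: float = 5.0  # 60 Hz mains, tests the 50 Hz low-pass
    line_hz: float = 60.0

    def __post_init__(self):
        if self.group not in ("ASD", "neurotypical"):
            raise ValueError(f"unknown group {self.group!r}")
        for cond, mods in self.band_modulation.items():
            for band, m in mods.items():
                if m <= 0:
                    raise ValueError(
                        f"band multiplier must be > 0: {cond}/{band} = {m}"
                    )

    def with_separation(self, scale: float) -> "ParticipantProfile":
        """Scale the class separation by ``scale``.

        Both discriminative axes shrink together: every band multiplier's
        deviation from 1.0 and the condition-specific share of the scalp
        topography. ``scale`` = 0 makes all conditions statistically
        identical; 1 reproduces the profile; > 1 exaggerates separation.
        """
        mods = {
            cond: {b: 1.0 + scale * (m - 1.0) for b, m in bands.items()}
            for cond, bands in self.band_modulation.items()
        }
        for bands in mods.values():
            for b, m in bands.items():
                if m <= 0:
                    raise ValueError("separation scaling produced non-positive multiplier")
        return replace(
            self,
            band_modulation=mods,
            spatial_variability=scale * self.spatial_variability,
        )


@dataclass
class EEGRecording:
    """Multichannel EEG with montage labels and condition annotations."""

    data: np.ndarray  # (16, n_samples) microvolts
    rate: float
    channel_names: tuple[str, ...]
    annotations: tuple[ConditionSegment, ...]
    participant_id: str

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"data must be (n_channels, n_samples) with {len(self.channel_names)} "
                f"channels, got shape {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate


def _narrowband_source(rng, n, lo, hi, rate):
    """Unit-RMS band-limited noise: white noise band-passed to (lo, hi) Hz."""
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _pink_noise(rng, n):
    """Unit-RMS 1/f-power background via FFT spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz] / freqs[nz][0])
    x = np.fft.irfft(spec * scale, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


_SOURCE_CONDITIONS = CONDITIONS + ("rest",)


def generate_recording(
    profile: ParticipantProfile, schedule: SessionSchedule
) -> EEGRecording:
    """Synthesize one session of 16-channel EEG for ``profile``.

    Per band, a single unit-RMS narrow-band noise source runs for the whole
    session. Its scalp projection during a segment is a unit vector
    interpolating between a fixed per-band topography and a
    (band, condition)-specific one — ``profile.spatial_variability`` sets
    the mix, so 0 reduces to pure gain modulation of one network while the
    default gives each mental state a distinct spatial covariance. The
    profile's band multiplier scales the amplitude, switching
    instantaneously at segment boundaries; projections are unit-norm, so
    band power summed over channels scales exactly with the squared
    multiplier regardless of direction. Channel-independent 1/f noise, a
    slow sinusoidal drift and a mains line component are added on top.
    Fully determined by ``profile.seed`` and the schedule.
    """
    rng = np.random.default_rng(profile.seed)
    n = int(np.floor(RATE * schedule.total_duration))
    n_ch = len(CHANNELS)
    t = np.arange(n) / RATE

    # Orthonormal frames: per-band base topographies and per-(band,
    # condition) deviation directions.
    q_base, _ = np.linalg.qr(rng.standard_normal((n_ch, n_ch)))
    q_cond, _ = np.linalg.qr(rng.standard_normal((n_ch, n_ch)))
    data = np.zeros((n_ch, n))

    for bi, (band, (lo, hi)) in enumerate(BANDS.items()):
        src = _narrowband_source(rng, n, lo, hi, RATE)
        gain = np.zeros((n_ch, n))
        for seg in schedule.segments:
            i0 = int(np.floor(seg.onset * RATE))
            i1 = min(int(np.floor(seg.end * RATE)), n)
            ci = _SOURCE_CONDITIONS.index(seg.label)
            col = (
                q_base[:, bi]
                + profile.spatial_variability
                * q_cond[:, bi * len(_SOURCE_CONDITIONS) + ci]
            )
            col = col / np.linalg.norm(col)
            mult = profile.band_modulation.get(seg.label, {}).get(band, 1.0)
            gain[:, i0:i1] = (col * np.sqrt(n_ch) * mult)[:, None]
        data += gain * (BAND_AMP_UV[band] * src)[None, :]

    if profile.noise_level > 0:
        for c in range(n_ch):
            data[c] += profile.noise_level * 5.0 * _pink_noise(rng, n)
    if profile.drift_amp_uv > 0:
        phases = rng.uniform(0, 2 * np.pi, n_ch)
        data += profile.drift_amp_uv * np.sin(
            2 * np.pi * profile.drift_hz * t[None, :] + phases[:, None]
        )
    if profile.line_amp_uv > 0:
        phase = rng.uniform(0, 2 * np.pi)
        data += profile.line_amp_uv * np.sin(2 * np.pi * profile.line_hz * t + phase)

    return EEGRecording(
        data=data,
        rate=RATE,
        channel_names=CHANNELS,
        annotations=schedule.segments,
        participant_id=profile.id,
    )


def _round_half_up(x):
    return np.floor(x + 0.5)


@dataclass(frozen=True)
class SelfReportSet:
    """5-point stress self-reports after every stressor and breathing period.

    The report given after the breathing period of block k serves as the
    pre-stressor score of block k+1; no report precedes the first stressor,
    so block 1 contributes no pre/post pair.
    """

    post_stressor: tuple[int, ...]  # one per block
    post_breathing: tuple[int, ...]  # one per block

    def __post_init__(self):
        for s in self.post_stressor + self.post_breathing:
            if s not in (1, 2, 3, 4, 5):
                raise ValueError(f"self-report scores must be in 1..5, got {s}")
        if len(self.post_stressor) != len(self.post_breathing):
            raise ValueError("need one stressor and one breathing report per block")

    @property
    def n_blocks(self) -> int:
        return len(self.post_stressor)

    def pre_scores(self) -> tuple:
        """Pre-stressor scores per block; ``None`` for block 1."""
        return (None,) + self.post_breathing[:-1]

    def pre_post_pairs(self) -> list[tuple[int, int]]:
        """(pre, post) stressor pairs for blocks 2..n."""
        return [
            (self.post_breathing[k - 1], self.post_stressor[k])
            for k in range(1, self.n_blocks)
        ]


def generate_self_reports(
    profile: ParticipantProfile,
    shift: float = 1.4,
    sd: float = 0.5,
    n_blocks: int = N_BLOCKS,
    relaxed_mean: float = 2.0,
    relaxed_sd: float = 0.6,
) -> SelfReportSet:
    """Simulate the per-block self-report series.

    Relaxed-state reports are drawn near ``relaxed_mean`` (default 2,
    "somewhat relaxed"); each post-stressor score is the preceding relaxed
    score shifted by ``shift`` plus Gaussian noise, rounded half-up and
    clipped to 1..5. ``sd`` >= 0 required.
    """
    if sd < 0:
        raise ValueError(f"sd must be >= 0, got {sd}")
    rng = np.random.default_rng([profile.seed, 0x5E1F])

    def relaxed():
        return int(np.clip(_round_half_up(rng.normal(relaxed_mean, relaxed_sd)), 1, 5))

    post_s, post_b = [], []
    pre = relaxed()  # latent starting state, never recorded
    for _ in range(n_blocks):
        post = int(np.clip(_round_half_up(pre + shift + rng.normal(0.0, sd)), 1, 5))
        post_s.append(post)
        pb = relaxed()
        post_b.append(pb)
        pre = pb
    return SelfReportSet(tuple(post_s), tuple(post_b))


def sample_profile(pid: str, group: str, seed: int) -> ParticipantProfile:
    """Draw one participant profile with a sampled STAI-C trait score.

    ASD participants draw from a slightly higher trait-anxiety distribution
    (mean 34 vs 31), consistent with elevated anxiety comorbidity.
    """
    rng = np.random.default_rng([seed, 0xA11CE])
    mean = 34.0 if group == "ASD" else 31.0
    stai = int(np.clip(_round_half_up(rng.normal(mean, 6.0)), 20, 60))
    return ParticipantProfile(id=pid, group=group, trait_anxiety=stai, seed=seed)


def generate_cohort(
    n_asd: int = 8,
    n_nt: int = 5,
    seed: int = 0,
    rest_duration: float = 30.0,
    report_shift: float = 1.4,
    report_sd: float = 0.5,
    bad_ids: tuple[str, ...] = (),
) -> list[tuple[ParticipantProfile, EEGRecording, SelfReportSet]]:
    """Generate a reproducible cohort: ``n_asd`` ASD (L1..) + ``n_nt``
    neurotypical (T1..) participants, each with a session recording and a
    self-report series.

    ``bad_ids`` marks participants whose recordings are corrupted the way
    high-impedance electrodes corrupt real data (one flat channel plus two
    grossly amplified channels); the rejection stage is expected to drop
    them.
    """
    if n_asd < 0 or n_nt < 0:
        raise ValueError("cohort counts must be >= 0")
    schedule = make_schedule(rest_duration)
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_asd + n_nt)]
    ids = [f"L{i + 1}" for i in range(n_asd)] + [f"T{i + 1}" for i in range(n_nt)]
    groups = ["ASD"] * n_asd + ["neurotypical"] * n_nt

    cohort = []
    for pid, group, pseed in zip(ids, groups, child_seeds):
        profile = sample_profile(pid, group, pseed)
        rec = generate_recording(profile, schedule)
        if pid in bad_ids:
            rec.data[2, :] = 0.0  # flat channel (lost contact)
            rec.data[[5, 9], :] *= 100.0  # high-impedance amplitude blow-up
        reports = generate_self_reports(profile, shift=report_shift, sd=report_sd)
        cohort.append((profile, rec, reports))
    return cohort
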