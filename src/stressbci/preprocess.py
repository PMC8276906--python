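"""Filtering, recording rejection, cropped window extraction and splits.

Preprocessing is deliberately minimal, mimicking what is feasible in an
online BCI: a zero-phase 1-50 Hz band-pass (the 0.5-1 Hz interval is
excluded because slow sinusoidal drift lives there), a per-recording
quality gate standing in for impedance checks, and a cropped training
strategy that tiles each labeled condition segment with fixed-length
windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .session import CONDITIONS, EEGRecording


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass specification.

    The contract is attenuation-based: >= 20 dB suppression at 0.5 Hz
    (drift) and 60 Hz (mains) with <= 1 dB ripple across 2-45 Hz, zero
    phase. The default design is a windowed-sinc FIR (Hamming window,
    applied centred so the net phase is zero): transition width 1 Hz at the
    high-pass edge and 5 Hz at the low-pass edge. ``design="iir-butter"``
    gives a forward-backward Butterworth cascade of configurable order
    instead.
    """

    highpass_hz: float = 1.0
    lowpass_hz: float = 50.0
    design: str = "fir"  # "fir" | "iir-butter"
    iir_order: int = 4
    hp_transition_hz: float = 1.0
    lp_transition_hz: float = 5.0

    def validate(self, rate: float) -> None:
        nyq = rate / 2.0
        if not (0 < self.highpass_hz < self.lowpass_hz < nyq):
            raise ValueError(
                f"need 0 < highpass ({self.highpass_hz}) < lowpass "
                f"({self.lowpass_hz}) < Nyquist ({nyq})"
            )
        if self.design not in ("fir", "iir-butter"):
            raise ValueError(f"unknown filter design {self.design!r}")

    def fir_taps(self, rate: float) -> np.ndarray:
        """Combined high-pass * low-pass linear-phase kernel."""
        self.validate(rate)

        def _odd(n):
            return int(n) + 1 - int(n) % 2

        n_hp = _odd(np.ceil(3.3 * rate / self.hp_transition_hz))
        n_lp = _odd(np.ceil(3.3 * rate / self.lp_transition_hz))
        hp = signal.firwin(n_hp, self.highpass_hz, fs=rate, pass_zero=False,
                           window="hamming")
        lp = signal.firwin(n_lp, self.lowpass_hz, fs=rate, pass_zero=True,
                           window="hamming")
        return np.convolve(hp, lp)


def bandpass(rec: EEGRecording, spec: FilterSpec | None = None) -> EEGRecording:
    """Zero-phase band-pass filter of every channel; annotations unchanged."""
    spec = spec or FilterSpec()
    spec.validate(rec.rate)
    if spec.design == "fir":
        taps = spec.fir_taps(rec.rate)
        half = len(taps) // 2
        padded = np.pad(rec.data, ((0, 0), (half, half)), mode="reflect")
        out = signal.oaconvolve(padded, taps[None, :], mode="valid", axes=1)
    else:
        sos_hp = signal.butter(spec.iir_order, spec.highpass_hz, btype="highpass",
                               fs=rec.rate, output="sos")
        sos_lp = signal.butter(spec.iir_order, spec.lowpass_hz, btype="lowpass",
                               fs=rec.rate, output="sos")
        out = signal.sosfiltfilt(sos_hp, rec.data, axis=1)
        out = signal.sosfiltfilt(sos_lp, out, axis=1)
    return EEGRecording(
        data=out,
        rate=rec.rate,
        channel_names=rec.channel_names,
        annotations=rec.annotations,
        participant_id=rec.participant_id,
    )


@dataclass(frozen=True)
class RejectionCriteria:
    """Thresholds standing in for impedance checks and visual inspection."""

    flat_std_uv: float = 1e-3  # channel std below this counts as flat
    amplitude_ratio: float = 100.0  # channel RMS this many times the reference
    min_bad_amplitude_channels: int = 2
    reference_rms_uv: float | None = None  # cohort median; per-recording median if None


def reject_recording(
    rec: EEGRecording, criteria: RejectionCriteria | None = None
) -> tuple[bool, str]:
    """Quality gate: ``(keep, reason)``. Never mutates the data.

    Rejects on any flat (near-constant) channel, or on
    ``min_bad_amplitude_channels`` or more channels whose RMS exceeds
    ``amplitude_ratio`` times the reference RMS (the cohort median when
    supplied, else this recording's own median channel RMS).
    """
    criteria = criteria or RejectionCriteria()
    stds = rec.data.std(axis=1)
    flat = np.flatnonzero(stds < criteria.flat_std_uv)
    if flat.size:
        names = ", ".join(rec.channel_names[i] for i in flat)
        return False, f"flat channel: {names}"
    rms = np.sqrt(np.mean(rec.data**2, axis=1))
    ref = criteria.reference_rms_uv or float(np.median(rms))
    loud = np.flatnonzero(rms > criteria.amplitude_ratio * ref)
    if loud.size >= criteria.min_bad_amplitude_channels:
        names = ", ".join(rec.channel_names[i] for i in loud)
        return False, f"amplitude outlier channels: {names}"
    return True, "ok"


LABEL_TO_ID = {c: i for i, c in enumerate(CONDITIONS)}


@dataclass
class WindowSet:
    """Fixed-length labeled training windows (window x channel x sample)."""

    windows: np.ndarray  # (n, n_channels, n_samples)
    labels: np.ndarray  # (n,) int ids into CONDITIONS
    participant_id: str
    length_s: float
    rate: float
    stride_s: float | None = None
    label_names: tuple[str, ...] = CONDITIONS

    def __post_init__(self):
        self.windows = np.asarray(self.windows, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.windows.ndim != 3:
            raise ValueError("windows must be (n, channels, samples)")
        if len(self.labels) != len(self.windows):
            raise ValueError("one label per window required")
        if self.labels.size and not (
            (self.labels >= 0) & (self.labels < len(self.label_names))
        ).all():
            raise ValueError("labels outside the condition set")

    def __len__(self) -> int:
        return len(self.windows)

    def class_counts(self) -> dict[str, int]:
        return {
            name: int((self.labels == i).sum())
            for i, name in enumerate(self.label_names)
        }

    def subset(self, idx) -> "WindowSet":
        return replace(self, windows=self.windows[idx], labels=self.labels[idx])

    def restrict_classes(self, names) -> "WindowSet":
        """Keep only windows of the given condition names (ids preserved)."""
        ids = [LABEL_TO_ID[n] for n in names]
        mask = np.isin(self.labels, ids)
        return self.subset(np.flatnonzero(mask))

    def standardized(self) -> "WindowSet":
        """Per-window, per-channel zero mean / unit variance copy."""
        mu = self.windows.mean(axis=2, keepdims=True)
        sd = self.windows.std(axis=2, keepdims=True)
        sd = np.where(sd < 1e-12, 1.0, sd)
        return replace(self, windows=(self.windows - mu) / sd)

    def balanced_subsample(self, seed: int = 0) -> "WindowSet":
        """Equal per-class counts (the minimum class count), seeded."""
        rng = np.random.default_rng(seed)
        present = np.unique(self.labels)
        n_min = min(int((self.labels == c).sum()) for c in present)
        keep = np.concatenate([
            rng.permutation(np.flatnonzero(self.labels == c))[:n_min]
            for c in present
        ])
        return self.subset(np.sort(keep))


def extract_windows(
    rec: EEGRecording, length_s: float = 1.0, stride_s: float | None = None
) -> WindowSet:
    """Crop every labeled segment into fixed-length windows.

    Windows tile each segment left-to-right with ``stride_s`` (defaulting to
    the window length, i.e. non-overlapping) and never straddle a segment
    boundary; rest segments contribute nothing.
    """
    if length_s <= 0:
        raise ValueError("length_s must be > 0")
    stride_s = length_s if stride_s is None else stride_s
    if stride_s <= 0:
        raise ValueError("stride_s must be > 0")
    win_n = int(round(length_s * rec.rate))
    stride_n = int(round(stride_s * rec.rate))

    wins, labels = [], []
    for seg in rec.annotations:
        if seg.label not in LABEL_TO_ID:
            continue
        i0 = int(np.floor(seg.onset * rec.rate))
        i1 = min(int(np.floor(seg.end * rec.rate)), rec.n_samples)
        for start in range(i0, i1 - win_n + 1, stride_n):
            wins.append(rec.data[:, start:start + win_n])
            labels.append(LABEL_TO_ID[seg.label])
    if not wins:
        raise ValueError(
            f"no labeled segment can hold a {length_s} s window"
        )
    return WindowSet(
        windows=np.stack(wins),
        labels=np.array(labels),
        participant_id=rec.participant_id,
        length_s=length_s,
        rate=rec.rate,
        stride_s=stride_s,
    )


@dataclass(frozen=True)
class SplitSpec:
    """Train/test split: 0.8 for the SVM stage, 0.7 for the deep stage."""

    train_fraction: float = 0.8
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must lie in (0, 1)")


def split_train_test(ws: WindowSet, spec: SplitSpec) -> tuple[WindowSet, WindowSet]:
    """Seeded disjoint, exhaustive split; stratified per class by default."""
    rng = np.random.default_rng(spec.seed)
    n = len(ws)
    if n < 2:
        raise ValueError("need at least 2 windows to split")
    if spec.stratified:
        train_idx = []
        for c in np.unique(ws.labels):
            idx = np.flatnonzero(ws.labels == c)
            if len(idx) < 2:
                raise ValueError(f"class id {c} has < 2 windows; cannot stratify")
            perm = rng.permutation(idx)
            n_train = int(round(spec.train_fraction * len(idx)))
            n_train = min(max(n_train, 1), len(idx) - 1)
            train_idx.append(perm[:n_train])
        train_idx = np.sort(np.concatenate(train_idx))
    else:
        perm = rng.permutation(n)
        n_train = min(max(int(round(spec.train_fraction * n)), 1), n - 1)
        train_idx = np.sort(perm[:n_train])
    mask = np.zeros(n, dtype=bool)
    mask[train_idx] = True
    return ws.subset(np.flatnonzero(mask)), ws.subset(np.flatnonzero(~mask))
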