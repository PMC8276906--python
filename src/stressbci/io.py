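"""Disk formats: EDF signals, TSV event sidecars, behavioral CSV.

Writing uses a minimal EDF implementation (16-bit samples with per-channel
physical scaling, 1 s data records); reading goes through MNE's native EDF
reader, so every file this package writes is independently parsed by a
third-party implementation. Annotations travel in a tab-separated sidecar
(columns: onset_s, duration_s, label) because EDF+ annotation streams add
complexity the pipeline does not need.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .session import CHANNELS, ConditionSegment, EEGRecording, SelfReportSet

_DIG_MIN, _DIG_MAX = -32768, 32767


def _ascii_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: EEGRecording, path) -> None:
    """Write a recording as EDF with 1 s data records.

    The signal is truncated to whole seconds (sessions are integer-second
    by construction). Per-channel physical ranges are set to the observed
    extrema, so the quantization step is (max - min) / 65535.
    """
    path = Path(path)
    spr = int(round(rec.rate))  # samples per 1 s record
    n_records = rec.n_samples // spr
    if n_records == 0:
        raise ValueError("recording shorter than one EDF record (1 s)")
    n_sig = len(rec.channel_names)
    data = rec.data[:, : n_records * spr]

    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    span = phys_max - phys_min
    degenerate = span <= 0
    phys_min = np.where(degenerate, phys_min - 1.0, phys_min)
    phys_max = np.where(degenerate, phys_max + 1.0, phys_max)

    header = b""
    header += _ascii_field("0", 8)
    header += _ascii_field(rec.participant_id or "X", 80)
    header += _ascii_field("Startdate 01-JAN-2000", 80)
    header += _ascii_field("01.01.00", 8)
    header += _ascii_field("00.00.00", 8)
    header += _ascii_field(256 * (1 + n_sig), 8)
    header += _ascii_field("", 44)
    header += _ascii_field(n_records, 8)
    header += _ascii_field(1, 8)
    header += _ascii_field(n_sig, 4)

    def sig_block(values, width):
        return b"".join(_ascii_field(v, width) for v in values)

    header += sig_block([f"EEG {ch}" for ch in rec.channel_names], 16)
    header += sig_block([""] * n_sig, 80)  # transducer
    header += sig_block(["uV"] * n_sig, 8)
    header += sig_block([f"{v:.8g}"[:8] for v in phys_min], 8)
    header += sig_block([f"{v:.8g}"[:8] for v in phys_max], 8)
    header += sig_block([_DIG_MIN] * n_sig, 8)
    header += sig_block([_DIG_MAX] * n_sig, 8)
    header += sig_block([""] * n_sig, 80)  # prefiltering
    header += sig_block([spr] * n_sig, 8)
    header += sig_block([""] * n_sig, 32)

    # re-read the truncated physical extrema exactly as the header states them
    pmin = np.array([float(f"{v:.8g}"[:8]) for v in phys_min])
    pmax = np.array([float(f"{v:.8g}"[:8]) for v in phys_max])
    gain = (_DIG_MAX - _DIG_MIN) / (pmax - pmin)
    digital = np.rint(
        (np.clip(data, pmin[:, None], pmax[:, None]) - pmin[:, None]) * gain[:, None]
        + _DIG_MIN
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            fh.write(digital[:, r * spr: (r + 1) * spr].tobytes())


def write_events(segments, path) -> None:
    """Tab-separated annotation sidecar: onset_s, duration_s, label."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["onset_s", "duration_s", "label"])
        for seg in segments:
            w.writerow([f"{seg.onset:g}", f"{seg.duration:g}", seg.label])


def read_events(path) -> tuple[ConditionSegment, ...]:
    """Read and validate an annotation sidecar (no overlapping segments)."""
    segs = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"onset_s", "duration_s", "label"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            missing = required - set(reader.fieldnames or ())
            raise ValueError(f"events sidecar missing columns: {sorted(missing)}")
        for row in reader:
            segs.append(
                ConditionSegment(
                    label=row["label"],
                    onset=float(row["onset_s"]),
                    duration=float(row["duration_s"]),
                )
            )
    segs.sort(key=lambda s: s.onset)
    for a, b in zip(segs, segs[1:]):
        if b.onset < a.end - 1e-9:
            raise ValueError(
                f"overlapping segments: {a.label}@{a.onset}s and {b.label}@{b.onset}s"
            )
    return tuple(segs)


def save_recording(rec: EEGRecording, directory, stem: str | None = None) -> Path:
    """Write ``<stem>.edf`` plus ``<stem>_events.tsv``; returns the EDF path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = stem or rec.participant_id
    edf_path = directory / f"{stem}.edf"
    write_edf(rec, edf_path)
    write_events(rec.annotations, directory / f"{stem}_events.tsv")
    return edf_path


def load_recording(edf_path, events_path=None) -> EEGRecording:
    """Load an EDF + events sidecar back into an :class:`EEGRecording`.

    The montage must match the 16-channel channel list exactly.
    """
    import mne

    edf_path = Path(edf_path)
    if events_path is None:
        events_path = edf_path.with_name(edf_path.stem + "_events.tsv")
    raw = mne.io.read_raw_edf(edf_path, preload=True, verbose="error")
    names = tuple(n.removeprefix("EEG ") for n in raw.ch_names)
    if names != tuple(CHANNELS):
        missing = set(CHANNELS) - set(names)
        extra = set(names) - set(CHANNELS)
        raise ValueError(
            f"channel mismatch vs the 16-channel montage: missing {sorted(missing)}, "
            f"unexpected {sorted(extra)}"
        )
    data_uv = raw.get_data() * 1e6  # MNE returns volts
    annotations = read_events(events_path)
    pid = raw.info.get("subject_info") or {}
    participant_id = pid.get("his_id", edf_path.stem)
    return EEGRecording(
        data=data_uv,
        rate=float(raw.info["sfreq"]),
        channel_names=names,
        annotations=annotations,
        participant_id=participant_id,
    )


def write_behavior_csv(records, path) -> None:
    """Behavioral CSV: one row per (participant, block).

    Columns: participant_id, group, stai_c, block, pre_score, post_score,
    post_breathing_score. ``records`` is an iterable of
    (ParticipantProfile, SelfReportSet).
    """
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([
            "participant_id", "group", "stai_c", "block",
            "pre_score", "post_score", "post_breathing_score",
        ])
        for profile, reports in records:
            pres = reports.pre_scores()
            for k in range(reports.n_blocks):
                w.writerow([
                    profile.id, profile.group, profile.trait_anxiety, k + 1,
                    "" if pres[k] is None else pres[k],
                    reports.post_stressor[k],
                    reports.post_breathing[k],
                ])


def read_behavior_csv(path) -> dict[str, dict]:
    """Inverse of :func:`write_behavior_csv`, keyed by participant id."""
    out: dict[str, dict] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            rec = out.setdefault(
                row["participant_id"],
                {"group": row["group"], "stai_c": int(row["stai_c"]),
                 "post_stressor": [], "post_breathing": []},
            )
            rec["post_stressor"].append(int(row["post_score"]))
            rec["post_breathing"].append(int(row["post_breathing_score"]))
    for rec in out.values():
        rec["reports"] = SelfReportSet(
            tuple(rec.pop("post_stressor")), tuple(rec.pop("post_breathing"))
        )
    return out
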