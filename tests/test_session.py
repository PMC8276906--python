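"""Session generator: schedule arithmetic, spectral structure, determinism."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_
from scipy import signal as ss

import stressbci as sb
from stressbci.session import (
    BANDS,
    CONDITIONS,
    DEFAULT_BAND_MODULATION,
    ParticipantProfile,
    generate_cohort,
    generate_recording,
    generate_self_reports,
    make_schedule,
)


class TestSchedule:
    def test_zero_rest_total_duration(self):
        assert make_schedule(0.0).total_duration == 120 + 4 * (90 + 200)

    def test_rest_adds_eight_segments(self):
        sched = make_schedule(30.0)
        assert sched.total_duration == 1280 + 8 * 30
        assert sum(s.label == "rest" for s in sched.segments) == 8

    @given(rest=st_.floats(0.0, 120.0, allow_nan=False))
    @settings(max_examples=25, deadline=None)
    def test_structure_invariant_under_rest_duration(self, rest):
        sched = make_schedule(rest)
        stressors = [s for s in sched.segments if s.label == "stressor"]
        assert len(stressors) == 4
        assert all(s.duration == 90.0 for s in stressors)
        breathing = [s for s in sched.segments if s.label in ("unguided", "guided")]
        assert [s.label for s in breathing] == ["unguided", "guided"] * 2
        assert all(s.duration == 200.0 for s in breathing)
        # contiguity: onsets are cumulative
        t = 0.0
        for seg in sched.segments:
            assert seg.onset == pytest.approx(t)
            t += seg.duration

    def test_labeled_seconds_accounting(self):
        for rest in (0.0, 30.0):
            assert make_schedule(rest).labeled_seconds() == {
                "baseline": 120.0, "stressor": 360.0,
                "unguided": 400.0, "guided": 400.0,
            }

    def test_negative_rest_rejected(self):
        with pytest.raises(ValueError):
            make_schedule(-1.0)


def _band_power_per_channel(rec, label, lo, hi):
    """Welch band power averaged over a condition's segments, per channel."""
    pows = []
    for seg in rec.annotations:
        if seg.label != label:
            continue
        i0, i1 = int(seg.onset * rec.rate), int(seg.end * rec.rate)
        f, p = ss.welch(rec.data[:, i0:i1], fs=rec.rate, nperseg=512)
        m = (f >= lo) & (f <= hi)
        pows.append(p[:, m].mean(axis=1))
    return np.mean(pows, axis=0)


class TestRecording:
    def test_determinism(self, default_profile):
        sched = make_schedule(0.0)
        a = generate_recording(default_profile, sched)
        b = generate_recording(default_profile, sched)
        assert np.array_equal(a.data, b.data)

    def test_shape_and_finiteness(self, full_recording):
        sched = make_schedule(30.0)
        assert full_recording.data.shape == (16, int(125 * sched.total_duration))
        assert np.all(np.isfinite(full_recording.data))
        assert full_recording.channel_names == sb.CHANNELS

    def test_beta_doubling_raises_stressor_beta_everywhere(self):
        """Stressor beta multiplier 2 vs baseline 1: periodogram band power
        over stressor segments exceeds baseline on every channel."""
        mods = {c: dict(m) for c, m in DEFAULT_BAND_MODULATION.items()}
        for c in mods:
            mods[c] = {"theta": 1.0, "alpha": 1.0, "beta": 1.0}
        mods["stressor"]["beta"] = 2.0
        prof = ParticipantProfile(
            id="P", group="ASD", trait_anxiety=30, seed=11,
            band_modulation=mods, noise_level=0.0, spatial_variability=0.0,
            drift_amp_uv=0.0, line_amp_uv=0.0,
        )
        rec = generate_recording(prof, make_schedule(0.0))
        base = _band_power_per_channel(rec, "baseline", 15, 30)
        stress = _band_power_per_channel(rec, "stressor", 15, 30)
        assert (stress > base).all()

    def test_unit_multipliers_equalize_total_band_power(self):
        """With all multipliers 1 and artifacts off, total (channel-summed)
        band power matches between stressor and baseline segments."""
        mods = {c: {"theta": 1.0, "alpha": 1.0, "beta": 1.0}
                for c in DEFAULT_BAND_MODULATION}
        prof = ParticipantProfile(
            id="P", group="ASD", trait_anxiety=30, seed=3,
            band_modulation=mods, noise_level=0.0,
            drift_amp_uv=0.0, line_amp_uv=0.0,
        )
        rec = generate_recording(prof, make_schedule(0.0))
        for lo, hi in BANDS.values():
            base = _band_power_per_channel(rec, "baseline", lo, hi).sum()
            stress = _band_power_per_channel(rec, "stressor", lo, hi).sum()
            assert stress == pytest.approx(base, rel=0.2)

    def test_band_power_ratio_tracks_squared_multiplier(self):
        """A multiplier ratio r between conditions gives a channel-summed
        band-power ratio of ~r^2 (within 20% on 200 s segments, noise off)."""
        r = 1.5
        mods = {c: {"theta": 1.0, "alpha": 1.0, "beta": 1.0}
                for c in DEFAULT_BAND_MODULATION}
        mods["guided"] = {"theta": 1.0, "alpha": r, "beta": 1.0}
        prof = ParticipantProfile(
            id="P", group="ASD", trait_anxiety=30, seed=7,
            band_modulation=mods, noise_level=0.0,
            drift_amp_uv=0.0, line_amp_uv=0.0,
        )
        rec = generate_recording(prof, make_schedule(0.0))
        lo, hi = BANDS["alpha"]
        p_guided = _band_power_per_channel(rec, "guided", lo, hi).sum()
        p_base = _band_power_per_channel(rec, "baseline", lo, hi).sum()
        assert p_guided / p_base == pytest.approx(r**2, rel=0.2)

    def test_nonpositive_multiplier_rejected(self):
        mods = {c: dict(m) for c, m in DEFAULT_BAND_MODULATION.items()}
        mods["stressor"]["beta"] = 0.0
        with pytest.raises(ValueError):
            ParticipantProfile(id="P", group="ASD", trait_anxiety=30,
                               seed=0, band_modulation=mods)


class TestSelfReports:
    def test_zero_shift_zero_noise_is_identity(self):
        prof = ParticipantProfile(id="P", group="ASD", trait_anxiety=30, seed=1)
        reports = generate_self_reports(prof, shift=0.0, sd=0.0)
        for pre, post in reports.pre_post_pairs():
            assert post == pre

    def test_forced_shift_arithmetic(self):
        """shift +1.5 with no noise: post = clip(round(pre + 1.5))."""
        prof = ParticipantProfile(id="P", group="ASD", trait_anxiety=30, seed=1)
        reports = generate_self_reports(prof, shift=1.5, sd=0.0)
        for pre, post in reports.pre_post_pairs():
            assert post == min(5, int(np.floor(pre + 1.5 + 0.5)))

    @given(shift=st_.floats(-3, 3, allow_nan=False),
           sd=st_.floats(0, 2, allow_nan=False),
           seed=st_.integers(0, 2**20))
    @settings(max_examples=50, deadline=None)
    def test_scores_always_in_range(self, shift, sd, seed):
        prof = ParticipantProfile(id="P", group="ASD", trait_anxiety=30,
                                  seed=seed)
        r = generate_self_reports(prof, shift=shift, sd=sd)
        assert set(r.post_stressor) | set(r.post_breathing) <= {1, 2, 3, 4, 5}

    def test_default_shift_detectable_in_large_sample(self):
        """At the default shift (+1.4, sd 0.5), 100 simulated participants
        give an overwhelming pre-vs-post Wilcoxon signal (p < 0.01)."""
        from stressbci.stats import wilcoxon_signed_rank

        pre, post = [], []
        for s in range(100):
            prof = ParticipantProfile(id=f"P{s}", group="ASD",
                                      trait_anxiety=30, seed=s)
            r = generate_self_reports(prof)
            for a, b in r.pre_post_pairs():
                pre.append(a)
                post.append(b)
        _, p = wilcoxon_signed_rank(pre, post, method="approx")
        assert p < 0.01


class TestCohort:
    def test_counts_and_groups(self):
        cohort = generate_cohort(n_asd=3, n_nt=2, seed=1)
        assert len(cohort) == 5
        assert [p.group for p, _, _ in cohort].count("ASD") == 3
        assert [p.id for p, _, _ in cohort] == ["L1", "L2", "L3", "T1", "T2"]

    def test_empty(self):
        assert generate_cohort(0, 0, seed=1) == []

    def test_determinism(self):
        a = generate_cohort(2, 1, seed=9)
        b = generate_cohort(2, 1, seed=9)
        for (pa, ra, sa), (pb, rb, sb_) in zip(a, b):
            assert pa == pb
            assert np.array_equal(ra.data, rb.data)
            assert sa == sb_

    def test_trait_anxiety_plausible(self):
        for p, _, _ in generate_cohort(4, 4, seed=2):
            assert 20 <= p.trait_anxiety <= 60
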