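"""Yin frame metrics and the per-trial sound-quality descriptors."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import autocorr_f0_frames
from sqvfs.audio_features import (
    BlockDesign,
    DegenerateTrialError,
    FeedbackPayload,
    FrameSeries,
    TrialAudio,
    TrialSoundDescriptors,
    block_percent_change,
    feedback_payload,
    frame_metrics,
    hz_to_cents,
    sound_instability,
    trial_descriptors,
)

SR = 44100.0


def sine(freq, duration=2.0, amplitude=0.5, sr=SR):
    t = np.arange(int(duration * sr)) / sr
    return amplitude * np.sin(2 * np.pi * freq * t)


def trial(samples, sr=SR):
    return TrialAudio("s01", "EG", 1, samples, sr)


# ---------------------------------------------------------------------------
# hz_to_cents
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "freq, expected, tol",
    [
        (440.0, 0.0, 1e-12),
        (880.0, 1200.0, 1e-9),
        (466.1638, 100.0, 0.01),  # equal-tempered semitone above A4
    ],
)
def test_hz_to_cents_reference_points(freq, expected, tol):
    assert hz_to_cents(freq) == pytest.approx(expected, abs=tol)


def test_hz_to_cents_rejects_nonpositive():
    with pytest.raises(ValueError):
        hz_to_cents(0.0)
    with pytest.raises(ValueError):
        hz_to_cents(440.0, reference=-1.0)


@given(st.floats(min_value=30.0, max_value=4000.0))
@settings(deadline=None, max_examples=50, derandomize=True)
def test_hz_to_cents_octave_additivity(freq):
    assert hz_to_cents(2 * freq) - hz_to_cents(freq) == pytest.approx(1200.0, abs=1e-9)


# ---------------------------------------------------------------------------
# frame_metrics (Yin)
# ---------------------------------------------------------------------------


def test_pure_sine_440_is_clean_and_centered():
    frames = frame_metrics(trial(sine(440.0)))
    assert np.nanmedian(frames.f0_cents) == pytest.approx(0.0, abs=1.0)
    assert np.median(frames.aperiodicity) < 0.02
    assert frames.voiced.all()


def test_octave_identity_880():
    frames = frame_metrics(trial(sine(880.0)))
    assert np.nanmedian(frames.f0_cents) == pytest.approx(1200.0, abs=1.0)


def test_white_noise_reads_as_aperiodic(rng):
    x = rng.normal(0.0, 0.1, int(2 * SR))
    frames = frame_metrics(trial(x))
    bad = (~frames.voiced) | (frames.aperiodicity > 0.5)
    assert bad.mean() >= 0.90
    # frame power estimates the noise variance
    assert np.mean(frames.power) == pytest.approx(0.01, rel=0.10)


def test_frame_power_matches_sine_mean_square():
    frames = frame_metrics(trial(sine(440.0, amplitude=0.5)))
    assert np.median(frames.power) == pytest.approx(0.125, rel=0.01)


def test_too_short_audio_raises():
    with pytest.raises(ValueError, match="too short"):
        frame_metrics(trial(sine(440.0, duration=0.04)))


def test_nonfinite_samples_rejected_at_construction():
    x = sine(440.0)
    x[5] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        trial(x)


def test_yin_matches_autocorrelation_oracle_on_harmonic_tones(rng):
    """On noiseless harmonic tones the Yin track and an independent
    autocorrelation-peak oracle agree within +-2 cents on >=99% of
    voiced frames."""
    agree = total = 0
    for f0 in (196.0, 294.0, 440.0, 660.0):
        t = np.arange(int(1.0 * SR)) / SR
        n_h = int(rng.integers(1, 9))
        x = sum(np.sin(2 * np.pi * k * f0 * t + k) / k for k in range(1, n_h + 1))
        x = 0.5 * x / np.max(np.abs(x))
        frames = frame_metrics(trial(x), hop_s=0.005)
        oracle = hz_to_cents(
            autocorr_f0_frames(x, SR, hop_s=0.005)[: len(frames)]
        )
        v = frames.voiced
        agree += int(np.sum(np.abs(frames.f0_cents[v] - oracle[v]) <= 2.0))
        total += int(v.sum())
    assert total > 0
    assert agree / total >= 0.99


def test_pitch_track_amplitude_invariance():
    """Scaling the waveform leaves f0 (cents) unchanged and scales power
    quadratically."""
    x = sine(440.0) + 0.1 * sine(880.0)
    a = frame_metrics(trial(x))
    b = frame_metrics(trial(0.25 * x))
    assert np.allclose(a.f0_cents, b.f0_cents, atol=1.0, equal_nan=True)
    assert np.allclose(b.power, a.power * 0.0625, rtol=0.01)


# ---------------------------------------------------------------------------
# trial descriptors
# ---------------------------------------------------------------------------


def make_frames(powers, cents, aper=None):
    n = len(powers)
    return FrameSeries(
        np.arange(n) * 0.01,
        np.asarray(cents, dtype=float),
        np.asarray(powers, dtype=float),
        np.zeros(n) if aper is None else np.asarray(aper, dtype=float),
    )


def test_constant_series_has_zero_instability():
    d = trial_descriptors(make_frames([2, 2, 2, 2], [0, 0, 0, 0]))
    assert d.dynamic_instability == 0.0
    assert d.pitch_instability == 0.0


def test_population_sd_hand_values():
    d = trial_descriptors(make_frames([0, 2, 0, 2], [-3, -1, 1, 3]))
    assert d.dynamic_instability == pytest.approx(1.0, abs=1e-12)
    assert d.pitch_instability == pytest.approx(math.sqrt(5.0), abs=1e-12)


def test_all_unvoiced_trial_is_degenerate():
    frames = make_frames([1, 1, 1], [np.nan] * 3, [1, 1, 1])
    with pytest.raises(DegenerateTrialError, match="unvoiced"):
        trial_descriptors(frames, voiced_only=True)


def test_pitch_sd_uses_voiced_frames_only():
    frames = make_frames([1, 1, 1, 1], [5.0, np.nan, 5.0, np.nan])
    d = trial_descriptors(frames)
    assert d.pitch_instability == 0.0


# ---------------------------------------------------------------------------
# sound instability composite
# ---------------------------------------------------------------------------


def toy_cohort(values):
    return [
        TrialSoundDescriptors("s01", "BF", i + 1, dyn, pit, ap)
        for i, (dyn, pit, ap) in enumerate(values)
    ]


TOY = [(0.5, 10.0, 0.30), (0.3, 6.0, 0.20), (0.8, 20.0, 0.55),
       (0.2, 4.0, 0.10), (0.6, 15.0, 0.40)]


@pytest.mark.parametrize("scale", ["center_only", "zscore"])
def test_composite_matches_spreadsheet_oracle(scale):
    """The composite equals a hand-rolled center(/scale)/average computed
    with plain Python arithmetic, to double precision."""
    scored = sound_instability(toy_cohort(TOY), scale=scale)
    cols = list(zip(*TOY))
    centered = []
    for col in cols:
        m = sum(col) / len(col)
        c = [v - m for v in col]
        if scale == "zscore":
            sd = math.sqrt(sum(v * v for v in c) / len(c))
            c = [v / sd for v in c]
        centered.append(c)
    expected = [sum(vals) / 3 for vals in zip(*centered)]
    got = [d.sound_instability for d in scored]
    assert np.allclose(got, expected, atol=1e-12)


def test_composite_cohort_mean_is_zero():
    scored = sound_instability(toy_cohort(TOY))
    assert abs(np.mean([d.sound_instability for d in scored])) < 1e-9


def test_composite_monotone_in_raw_components():
    cohort = toy_cohort([(0.9, 20.0, 0.6), (0.1, 2.0, 0.05)])
    a, b = sound_instability(cohort, scale="center_only")
    assert a.sound_instability > b.sound_instability


def test_identical_trials_center_to_zero():
    cohort = toy_cohort([(0.5, 10.0, 0.3)] * 4)
    scored = sound_instability(cohort, scale="center_only")
    assert all(d.sound_instability == pytest.approx(0.0, abs=1e-12) for d in scored)


def test_zero_variance_component_rejected_under_zscore():
    cohort = toy_cohort([(0.5, 10.0, 0.3), (0.5, 12.0, 0.4)])
    with pytest.raises(ValueError, match="dynamic_instability"):
        sound_instability(cohort, scale="zscore")


def test_cohort_of_one_rejected():
    with pytest.raises(ValueError):
        sound_instability(toy_cohort(TOY[:1]))


@given(
    st.lists(
        st.tuples(
            st.floats(0.01, 10.0), st.floats(0.01, 100.0), st.floats(0.0, 1.0)
        ),
        min_size=3,
        max_size=12,
    )
)
@settings(deadline=None, max_examples=60, derandomize=True)
def test_composite_centering_property(values):
    try:
        scored = sound_instability(toy_cohort(values))
    except ValueError:
        return  # zero-variance cohorts are rejected, not mis-scored
    assert abs(np.mean([d.sound_instability for d in scored])) < 1e-9


# ---------------------------------------------------------------------------
# block design and percent change
# ---------------------------------------------------------------------------


def test_block_design_partitions_20_trials():
    design = BlockDesign()
    seen = [design.block_of(t) for t in range(1, 21)]
    assert seen == ["baseline"] * 5 + ["early"] * 5 + ["middle"] * 5 + ["late"] * 5


def test_overlapping_blocks_rejected():
    with pytest.raises(ValueError):
        BlockDesign(late=(15, 20))


@pytest.mark.parametrize(
    "base, other, expected",
    [(2.0, 2.0, 0.0), (2.0, 1.0, 50.0), (1.0, 2.0, -100.0)],
)
def test_percent_change_substitutions(base, other, expected):
    scores = {t: base for t in range(1, 6)}
    scores.update({t: other for t in range(6, 11)})
    change = block_percent_change(scores)
    assert change.per_block["early"] == pytest.approx(expected)


def test_percent_change_zero_baseline_is_undefined():
    scores = {t: 0.0 for t in range(1, 6)}
    scores.update({t: 1.0 for t in range(6, 11)})
    with pytest.raises(ZeroDivisionError):
        block_percent_change(scores)


def test_percent_change_records_sign_convention():
    scores = {t: 2.0 for t in range(1, 11)}
    assert "decreased" in block_percent_change(scores).convention


# ---------------------------------------------------------------------------
# feedback payload
# ---------------------------------------------------------------------------


def descriptor_session(n, offset=0.0):
    return {
        t: TrialSoundDescriptors("s01", "BF", t, 0.1 * t + offset, t + offset, 0.1)
        for t in range(1, n + 1)
    }


def test_payload_truncates_at_current_trial():
    payload = feedback_payload(descriptor_session(9), descriptor_session(20, 1.0), 9)
    assert all(len(v) == 9 for v in payload.descriptors.values())
    assert all(len(v) == 20 for v in payload.expert.values())


def test_payload_first_trial():
    payload = feedback_payload(descriptor_session(1), descriptor_session(20), 1)
    assert all(len(v) == 1 for v in payload.descriptors.values())


def test_payload_missing_trial_reports_gap():
    learner = descriptor_session(9)
    del learner[5]
    with pytest.raises(ValueError, match=r"\[5\]"):
        feedback_payload(learner, descriptor_session(20), 9)


def test_payload_json_round_trip():
    payload = feedback_payload(descriptor_session(9), descriptor_session(20), 9)
    again = FeedbackPayload.from_json(payload.to_json())
    assert again == payload
    assert json.loads(payload.to_json())["current_trial"] == 9
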