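"""Sound-quality descriptors for bowed violin trials.

A practice session is 20 bowing trials on the open A string. Each trial's
mono recording is analysed frame-by-frame with the Yin fundamental-frequency
estimator, and the frame series is reduced to three per-trial descriptors:

* ``dynamic_instability`` — population SD of frame power,
* ``pitch_instability``  — population SD of frame f0 in cents (re 440 Hz),
* ``aperiodicity``       — mean fraction of frame power not explained by the
  best periodic model.

Standardizing the descriptors across a cohort of trials and averaging them
yields the *sound instability* composite, the scalar a learner sees as
feedback and the quantity tracked across practice blocks.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.io import wavfile

__all__ = [
    "TrialAudio",
    "FrameSeries",
    "TrialSoundDescriptors",
    "BlockDesign",
    "BlockPercentChange",
    "FeedbackPayload",
    "DegenerateTrialError",
    "hz_to_cents",
    "frame_metrics",
    "trial_descriptors",
    "sound_instability",
    "block_percent_change",
    "feedback_payload",
    "read_trial_audio",
    "descriptor_table",
]

GROUPS = ("EG", "BF", "BNF")

DESCRIPTOR_NAMES = ("dynamic_instability", "pitch_instability", "aperiodicity")


class DegenerateTrialError(ValueError):
    """A trial whose frame series cannot support the requested descriptor."""


def hz_to_cents(frequency: float, reference: float = 440.0) -> float:
    """Convert a frequency to cents relative to ``reference`` (A4 by default).

    1200 cents = 1 octave, so 880 Hz maps to +1200 re 440 Hz.
    """
    frequency = np.asarray(frequency, dtype=float)
    if np.any(frequency <= 0) or reference <= 0:
        raise ValueError("frequencies must be strictly positive")
    out = 1200.0 * np.log2(frequency / reference)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class TrialAudio:
    """One bowing trial's mono waveform plus its identity in the session."""

    subject_id: str
    group: str
    trial_index: int
    samples: np.ndarray
    sample_rate: float = 44100.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if not 1 <= int(self.trial_index) <= 20:
            raise ValueError(f"trial_index must be in [1, 20], got {self.trial_index}")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if samples.ndim != 1:
            raise ValueError("samples must be mono (1-D)")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate


@dataclass(frozen=True)
class FrameSeries:
    """Per-frame Yin metrics for one trial.

    ``f0_cents`` uses NaN as the unvoiced marker; ``power`` is the linear
    mean-square amplitude of the frame; ``aperiodicity`` is
    aperiodic power / total power in [0, 1].
    """

    frame_start_times: np.ndarray
    f0_cents: np.ndarray
    power: np.ndarray
    aperiodicity: np.ndarray

    def __post_init__(self) -> None:
        arrays = {
            name: np.asarray(getattr(self, name), dtype=np.float64)
            for name in ("frame_start_times", "f0_cents", "power", "aperiodicity")
        }
        lengths = {len(a) for a in arrays.values()}
        if len(lengths) != 1:
            raise ValueError("all frame series must have equal length")
        if np.any(arrays["power"] < 0):
            raise ValueError("frame power must be non-negative")
        ap = arrays["aperiodicity"]
        if np.any((ap < 0) | (ap > 1)):
            raise ValueError("aperiodicity must lie in [0, 1]")
        for name, a in arrays.items():
            object.__setattr__(self, name, a)

    def __len__(self) -> int:
        return len(self.frame_start_times)

    @property
    def voiced(self) -> np.ndarray:
        return ~np.isnan(self.f0_cents)


@dataclass
class TrialSoundDescriptors:
    """Per-trial descriptor values; the composite is set only within a cohort."""

    subject_id: str
    group: str
    trial_index: int
    dynamic_instability: float
    pitch_instability: float
    aperiodicity: float
    sound_instability: float | None = None
    includes_aperiodicity: bool | None = None

    def __post_init__(self) -> None:
        if self.dynamic_instability < 0 or self.pitch_instability < 0:
            raise ValueError("instability descriptors must be non-negative")


@dataclass(frozen=True)
class BlockDesign:
    """The session's four named five-trial blocks.

    Trials 1–5 form the baseline block (no external feedback yet); early,
    middle and late blocks partition trials 6–20.
    """

    baseline: tuple[int, int] = (1, 5)
    early: tuple[int, int] = (6, 10)
    middle: tuple[int, int] = (11, 15)
    late: tuple[int, int] = (16, 20)

    def __post_init__(self) -> None:
        covered: set[int] = set()
        for name in self.block_names:
            lo, hi = getattr(self, name)
            trials = set(range(lo, hi + 1))
            if covered & trials:
                raise ValueError(f"block {name!r} overlaps another block")
            covered |= trials
        if covered != set(range(1, 21)):
            raise ValueError("blocks must partition trials 1..20")

    @property
    def block_names(self) -> tuple[str, ...]:
        return ("baseline", "early", "middle", "late")

    @property
    def test_blocks(self) -> tuple[str, ...]:
        return ("early", "middle", "late")

    def trials(self, block: str) -> range:
        lo, hi = getattr(self, block)
        return range(lo, hi + 1)

    def block_of(self, trial_index: int) -> str:
        for name in self.block_names:
            if trial_index in self.trials(name):
                return name
        raise ValueError(f"trial {trial_index} outside the 20-trial design")


# ---------------------------------------------------------------------------
# Yin frame analysis
# ---------------------------------------------------------------------------


def _next_pow2(n: int) -> int:
    return 1 << (int(n) - 1).bit_length()


def frame_metrics(
    audio: TrialAudio,
    window_s: float = 0.033,
    hop_s: float = 0.0007,
    yin_threshold: float = 0.15,
    f0_min: float = 80.0,
    f0_max: float = 1200.0,
) -> FrameSeries:
    """Run the Yin procedure over sliding windows of one trial.

    For each frame of ``window_s`` seconds (hop ``hop_s``) the difference
    function d(tau) is evaluated for lags up to one window, normalised to the
    cumulative-mean-normalised difference d'(tau), and the first dip of d'
    below ``yin_threshold`` is refined by parabolic interpolation to give the
    frame's period.  Outputs per frame:

    * f0 in cents relative to 440 Hz (NaN where no dip falls below the
      threshold — the unvoiced marker),
    * power: mean of squared samples in the window,
    * aperiodicity: d(tau*) normalised by the total power of the two
      windows it compares, i.e. the fraction of power the best periodic
      model leaves unexplained (near 0 for a clean tone, near 1 for noise).
    """
    sr = float(audio.sample_rate)
    x = audio.samples
    W = int(round(window_s * sr))
    hop = max(1, int(round(hop_s * sr)))
    if W < 2:
        raise ValueError("window too short: fewer than 2 samples")
    span = 2 * W  # each frame compares two adjacent windows
    if len(x) < span:
        raise ValueError(
            f"audio too short: {len(x)} samples < {span} (2 windows of {W})"
        )
    if not 0 < yin_threshold < 1:
        raise ValueError("yin_threshold must be in (0, 1)")

    tau_min = max(2, int(sr / f0_max))
    tau_max = min(W, int(math.ceil(sr / f0_min)))
    if tau_max <= tau_min + 2:
        raise ValueError("f0 search range too narrow for this window")

    frames = sliding_window_view(x, span)[::hop]
    n_frames = len(frames)
    starts = np.arange(n_frames) * hop / sr

    nfft = _next_pow2(span + W)
    f0_cents = np.full(n_frames, np.nan)
    power = np.empty(n_frames)
    aperiod = np.empty(n_frames)

    chunk = max(1, int(2**24 // nfft))  # bound FFT workspace to ~hundreds of MB
    taus = np.arange(tau_max + 1)
    for lo in range(0, n_frames, chunk):
        seg = np.ascontiguousarray(frames[lo : lo + chunk])
        sq = seg**2
        cs = np.concatenate(
            [np.zeros((len(seg), 1)), np.cumsum(sq, axis=1)], axis=1
        )
        e_win = cs[:, W]  # energy of the anchor window
        e_lag = cs[:, taus + W] - cs[:, taus]  # energy of the lagged window
        spec = np.fft.rfft(seg, nfft, axis=1)
        spec_win = np.fft.rfft(seg[:, :W], nfft, axis=1)
        corr = np.fft.irfft(spec * spec_win.conj(), nfft, axis=1)[:, : tau_max + 1]
        d = e_win[:, None] + e_lag - 2.0 * corr
        np.maximum(d, 0.0, out=d)

        # cumulative-mean normalisation: d'(0) = 1, d'(t) = d(t)*t / sum_{1..t} d
        csum = np.cumsum(d[:, 1:], axis=1)
        dprime = np.ones_like(d)
        with np.errstate(divide="ignore", invalid="ignore"):
            dprime[:, 1:] = d[:, 1:] * taus[1:] / csum
        dprime[~np.isfinite(dprime)] = 1.0

        power[lo : lo + len(seg)] = e_win / W

        for i in range(len(seg)):
            dp = dprime[i]
            below = dp[tau_min : tau_max + 1] < yin_threshold
            if below.any():
                t = tau_min + int(np.argmax(below))
                while t + 1 <= tau_max and dp[t + 1] < dp[t]:
                    t += 1
                voiced = True
            else:
                t = tau_min + int(np.argmin(dp[tau_min : tau_max + 1]))
                voiced = False
            # parabolic refinement of the dip on d'
            if tau_min < t < tau_max:
                a, b, c = dp[t - 1], dp[t], dp[t + 1]
                denom = a - 2 * b + c
                shift = 0.5 * (a - c) / denom if denom > 0 else 0.0
                shift = float(np.clip(shift, -0.5, 0.5))
            else:
                shift = 0.0
            j = lo + i
            tot = e_win[i] + e_lag[i, t]
            aperiod[j] = float(np.clip(d[i, t] / tot, 0.0, 1.0)) if tot > 0 else 1.0
            if voiced:
                f0_cents[j] = hz_to_cents(sr / (t + shift))

    return FrameSeries(starts, f0_cents, power, aperiod)


# ---------------------------------------------------------------------------
# Per-trial descriptors and the cohort composite
# ---------------------------------------------------------------------------


def trial_descriptors(
    frames: FrameSeries,
    subject_id: str = "",
    group: str = "EG",
    trial_index: int = 1,
    voiced_only: bool = True,
) -> TrialSoundDescriptors:
    """Reduce a frame series to the three per-trial descriptors.

    The instabilities are *population* standard deviations (1/N inside the
    root) of frame power and frame f0; per-trial aperiodicity is the mean
    over all frames.  Pitch SD uses voiced frames only when ``voiced_only``
    is set (unvoiced frames carry no f0); power and aperiodicity always use
    every frame — a scratchy unvoiced frame is part of the bad-sound signal.
    """
    if len(frames) < 2:
        raise ValueError("need at least 2 frames to compute descriptors")
    voiced = frames.voiced
    if voiced_only:
        if not voiced.any():
            raise DegenerateTrialError(
                f"trial {subject_id}/{trial_index}: all {len(frames)} frames "
                "unvoiced; no pitch track available"
            )
        f0 = frames.f0_cents[voiced]
    else:
        f0 = np.nan_to_num(frames.f0_cents, nan=0.0)
    return TrialSoundDescriptors(
        subject_id=subject_id,
        group=group,
        trial_index=trial_index,
        dynamic_instability=float(np.std(frames.power)),
        pitch_instability=float(np.std(f0)),
        aperiodicity=float(np.mean(frames.aperiodicity)),
    )


def sound_instability(
    cohort: Sequence[TrialSoundDescriptors],
    include_aperiodicity: bool = True,
    scale: Literal["zscore", "center_only"] = "zscore",
) -> list[TrialSoundDescriptors]:
    """Standardize descriptors across a cohort and average into the composite.

    Each included component (dynamic instability, pitch instability and —
    unless disabled — aperiodicity) is standardized over all trials in the
    cohort, then the per-trial composite is the mean of the standardized
    components.  ``scale='zscore'`` (default) divides by the population SD so
    components in different physical units contribute comparably;
    ``scale='center_only'`` subtracts the mean only.  Either way the cohort
    mean of the composite is zero by construction.
    """
    if len(cohort) < 2:
        raise ValueError("cohort must contain at least 2 trials")
    if scale not in ("zscore", "center_only"):
        raise ValueError(f"unknown scale mode {scale!r}")
    names = DESCRIPTOR_NAMES if include_aperiodicity else DESCRIPTOR_NAMES[:2]
    cols = []
    for name in names:
        v = np.array([getattr(d, name) for d in cohort], dtype=float)
        v = v - v.mean()
        if scale == "zscore":
            sd = v.std()
            if sd == 0:
                raise ValueError(
                    f"component {name!r} has zero variance; cannot z-score"
                )
            v = v / sd
        cols.append(v)
    composite = np.mean(cols, axis=0)
    return [
        replace(d, sound_instability=float(c), includes_aperiodicity=include_aperiodicity)
        for d, c in zip(cohort, composite)
    ]


@dataclass(frozen=True)
class BlockPercentChange:
    """Per-block percent change of a score relative to the baseline block.

    ``convention`` records the sign orientation so no consumer must guess:
    the change is 100*(mean(baseline) - mean(block)) / |mean(baseline)|,
    hence positive means the score *decreased* relative to baseline — an
    improvement when the score is an instability.
    """

    per_block: dict[str, float]
    baseline_mean: float
    convention: str = "positive_means_score_decreased_vs_baseline"


def block_percent_change(
    per_trial_scores: Mapping[int, float], design: BlockDesign | None = None
) -> BlockPercentChange:
    """Percent change of a per-trial score for each post-baseline block."""
    design = design or BlockDesign()
    base_vals = [per_trial_scores[t] for t in design.trials("baseline") if t in per_trial_scores]
    if not base_vals:
        raise ValueError("no baseline trials present in scores")
    base_mean = float(np.mean(base_vals))
    if base_mean == 0:
        raise ZeroDivisionError("baseline mean is 0; percent change undefined")
    out: dict[str, float] = {}
    for block in design.test_blocks:
        vals = [per_trial_scores[t] for t in design.trials(block) if t in per_trial_scores]
        if not vals:
            continue
        out[block] = 100.0 * (base_mean - float(np.mean(vals))) / abs(base_mean)
    if not out:
        raise ValueError("scores cover no post-baseline block")
    return BlockPercentChange(per_block=out, baseline_mean=base_mean)


# ---------------------------------------------------------------------------
# Offline feedback payload
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeedbackPayload:
    """What a learner sees right after finishing trial ``current_trial``:
    their own descriptor series so far, against an expert's full session."""

    current_trial: int
    descriptors: dict[str, list[float]]
    expert: dict[str, list[float]]

    def to_json(self) -> str:
        return json.dumps(
            {
                "current_trial": self.current_trial,
                "descriptors": self.descriptors,
                "expert": self.expert,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "FeedbackPayload":
        obj = json.loads(text)
        return cls(
            current_trial=obj["current_trial"],
            descriptors={k: list(map(float, v)) for k, v in obj["descriptors"].items()},
            expert={k: list(map(float, v)) for k, v in obj["expert"].items()},
        )


def feedback_payload(
    learner: Mapping[int, TrialSoundDescriptors],
    expert: Mapping[int, TrialSoundDescriptors],
    current_trial: int,
) -> FeedbackPayload:
    """Assemble the offline feedback shown after ``current_trial``."""
    missing = [t for t in range(1, current_trial + 1) if t not in learner]
    if missing:
        raise ValueError(f"learner scores missing for trials {missing}")
    missing_e = [t for t in range(1, 21) if t not in expert]
    if missing_e:
        raise ValueError(f"expert reference missing for trials {missing_e}")

    def series(source: Mapping[int, TrialSoundDescriptors], upto: int) -> dict[str, list[float]]:
        return {
            name: [float(getattr(source[t], name)) for t in range(1, upto + 1)]
            for name in DESCRIPTOR_NAMES
        }

    return FeedbackPayload(
        current_trial=current_trial,
        descriptors=series(learner, current_trial),
        expert=series(expert, 20),
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_trial_audio(
    path: str, subject_id: str, group: str, trial_index: int
) -> TrialAudio:
    """Read one trial's mono PCM WAV; integer samples map to [-1, 1]."""
    sr, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono audio, got {data.shape[1]} channels")
    if data.dtype.kind == "i":
        scale = float(np.iinfo(data.dtype).max) + 1.0
        samples = data.astype(np.float64) / scale
    elif data.dtype.kind == "u":  # 8-bit WAV is unsigned
        samples = (data.astype(np.float64) - 128.0) / 128.0
    else:
        samples = data.astype(np.float64)
    return TrialAudio(subject_id, group, trial_index, samples, float(sr))


def descriptor_table(cohort: Sequence[TrialSoundDescriptors]) -> pd.DataFrame:
    """Tabulate a scored cohort, one row per trial."""
    return pd.DataFrame(
        {
            "subject_id": [d.subject_id for d in cohort],
            "group": [d.group for d in cohort],
            "trial_index": [d.trial_index for d in cohort],
            "dynamic_instability": [d.dynamic_instability for d in cohort],
            "pitch_instability": [d.pitch_instability for d in cohort],
            "aperiodicity": [d.aperiodicity for d in cohort],
            "sound_instability": [d.sound_instability for d in cohort],
        }
    )
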