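"""Synthetic practice cohort: audio trials and EEG with programmed structure.

The generator emulates the study design the analysis expects — three groups
(EG experts, BF beginners with feedback, BNF beginners without), 20 trials
per subject in four five-trial blocks — with controllable ground truth:

* audio: a harmonic ~440 Hz tone with an 8-stroke bow envelope, pitch
  modelled as a mean-reverting (Ornstein-Uhlenbeck) random walk with a
  stationary SD in cents, a slow relative power jitter, and additive white
  noise at a chosen SNR.  Mean reversion keeps pitch locally coherent so a
  33 ms analysis window reads it as pitch instability, not aperiodicity;
* EEG: per-channel Gaussian noise synthesized in the frequency domain so
  the one-sided spectral density inside each analysis band equals a target
  (uV^2/Hz) for the channel's scalp region, with per-block multipliers —
  e.g. a gamma decrease after the baseline block for beginner groups.

Everything is reproducible bit-for-bit from the cohort seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal
from scipy.io import wavfile

from .audio_features import BlockDesign, TrialAudio
from .eeg_features import DEFAULT_BANDS, MONTAGE_14, EEGRecording

__all__ = [
    "REGIONS",
    "GroupAudioParams",
    "GroupEEGParams",
    "SyntheticCohortSpec",
    "synth_violin_trial",
    "synth_eeg_trial",
    "synth_cohort",
]

# Disjoint scalp regions used to assign per-channel synthesis targets;
# every named analysis cluster is a subset of exactly one region.
REGIONS: dict[str, tuple[str, ...]] = {
    "frontal": ("AF3", "F7", "F3", "FC5", "FC6", "F4", "F8", "AF4"),
    "posterior": ("P7", "O1", "O2", "P8"),
    "temporal": ("T7", "T8"),
}

_REGION_OF = {ch: region for region, chans in REGIONS.items() for ch in chans}


def _ou_process(n: int, dt: float, sd: float, tau_c: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck samples: SD ``sd``, correlation time
    ``tau_c`` seconds."""
    if sd == 0:
        return np.zeros(n)
    a = math.exp(-dt / tau_c)
    w = rng.normal(0.0, sd * math.sqrt(1.0 - a * a), n)
    w[0] = rng.normal(0.0, sd)  # stationary start
    return signal.lfilter([1.0], [1.0, -a], w)


def synth_violin_trial(
    subject_id: str = "synth",
    group: str = "EG",
    trial_index: int = 1,
    f0: float = 440.0,
    duration_s: float = 30.0,
    pitch_jitter_sd: float = 0.0,
    power_jitter_sd: float = 0.0,
    noise_snr: float = math.inf,
    strokes: int = 8,
    sample_rate: float = 44100.0,
    seed: int | np.random.Generator = 0,
) -> TrialAudio:
    """Synthesize one bowing trial on the open A string.

    ``pitch_jitter_sd`` is the stationary SD of the pitch track in cents,
    ``power_jitter_sd`` the relative SD of slow power fluctuation, and
    ``noise_snr`` the signal-to-noise ratio in dB of the added white noise
    (``inf`` for a clean tone).  Eight harmonics with 1/k rolloff and a
    smooth ``strokes``-cycle amplitude envelope mimic the bowing exercise.
    """
    if duration_s < 1.0:
        raise ValueError("duration must be at least 1 s")
    if pitch_jitter_sd < 0 or power_jitter_sd < 0:
        raise ValueError("jitter SDs must be non-negative")
    if math.isnan(noise_snr):
        raise ValueError("noise_snr must be a number or inf")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate))
    dt = 1.0 / sample_rate
    t = np.arange(n) * dt

    cents = _ou_process(n, dt, pitch_jitter_sd, tau_c=0.5, rng=rng)
    freq = f0 * np.exp2(cents / 1200.0)
    phase = 2.0 * np.pi * np.cumsum(freq) * dt

    tone = np.zeros(n)
    for k in range(1, 9):
        tone += np.sin(k * phase) / k

    # bow strokes: amplitude dips at each bow change, never reaching zero
    stroke_env = 0.65 + 0.35 * np.sin(np.pi * strokes * t / duration_s) ** 2
    # slow relative power jitter; power ~ gain^2, so gain SD is half the
    # requested relative power SD (small-jitter approximation)
    gain = 1.0 + _ou_process(n, dt, power_jitter_sd / 2.0, tau_c=1.0, rng=rng)
    x = tone * stroke_env * np.clip(gain, 0.05, None)

    if math.isfinite(noise_snr):
        sig_power = float(np.mean(x**2))
        noise_power = sig_power * 10.0 ** (-noise_snr / 10.0)
        x = x + rng.normal(0.0, math.sqrt(noise_power), n)

    peak = float(np.max(np.abs(x)))
    if peak > 0:
        x = 0.5 * x / peak
    return TrialAudio(subject_id, group, trial_index, x, sample_rate)


def synth_eeg_trial(
    band_density_targets: dict[str, dict[str, float]],
    subject_id: str = "synth",
    group: str = "EG",
    trial_index: int = 1,
    duration_s: float = 30.0,
    sample_rate: float = 128.0,
    bands: dict[str, tuple[float, float]] | None = None,
    background_density: float = 0.25,
    seed: int | np.random.Generator = 0,
) -> EEGRecording:
    """Synthesize one trial of 14-channel EEG with programmed band density.

    ``band_density_targets`` maps scalp region (frontal/posterior/temporal)
    to {band: one-sided density in uV^2/Hz}; each channel is Gaussian noise
    shaped in the frequency domain so its Welch density inside each band
    matches its region's target.  A small flat ``background_density`` fills
    the spectrum outside the analysis bands so band-power contrasts are
    unaffected by it.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    bands = dict(bands or DEFAULT_BANDS)
    nyquist = sample_rate / 2.0
    for b, (lo, hi) in bands.items():
        if not 0 < lo < hi < nyquist:
            raise ValueError(f"band {b!r} [{lo}, {hi}) outside (0, Nyquist)")
    missing = set(REGIONS) - set(band_density_targets)
    if missing:
        raise ValueError(f"missing region targets: {sorted(missing)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n = int(round(duration_s * sample_rate))
    if n < 2:
        raise ValueError("duration too short at this sample rate")
    freqs = np.fft.rfftfreq(n, 1.0 / sample_rate)
    in_band = np.zeros(len(freqs), dtype=bool)

    data = np.empty((len(MONTAGE_14), n))
    for ci, ch in enumerate(MONTAGE_14):
        targets = band_density_targets[_REGION_OF[ch]]
        density = np.full(len(freqs), background_density)
        density[0] = 0.0
        # guard bands: extend each band's density ~0.75 Hz into spectral
        # gaps so the Welch taper's leakage does not bias band-edge bins
        # toward the background level
        guard = 0.75
        for b, (lo, hi) in bands.items():
            if b not in targets:
                raise ValueError(f"region target for {_REGION_OF[ch]!r} missing band {b!r}")
            if targets[b] < 0:
                raise ValueError("band density targets must be non-negative")
            density[(freqs >= lo - guard) & (freqs < hi + guard)] = targets[b]
        for b, (lo, hi) in bands.items():
            sel = (freqs >= lo) & (freqs < hi)
            density[sel] = targets[b]
            in_band |= sel
        # E|X_k|^2 = S(f_k) * n * fs / 2 gives one-sided density S
        sigma = np.sqrt(density * n * sample_rate / 4.0)
        spec = rng.normal(0, sigma) + 1j * rng.normal(0, sigma)
        spec[0] = 0.0
        if n % 2 == 0:
            spec[-1] = spec[-1].real * math.sqrt(2.0)
        data[ci] = np.fft.irfft(spec, n)

    return EEGRecording(
        subject_id, group, trial_index, MONTAGE_14, data, sample_rate
    )


# ---------------------------------------------------------------------------
# Cohort-level generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupAudioParams:
    """Audio ground truth for one group; block multipliers scale both
    jitter SDs in post-baseline blocks (values < 1 mean improvement)."""

    pitch_jitter_sd: float
    power_jitter_sd: float
    noise_snr_db: float
    block_multipliers: dict[str, float] = field(
        default_factory=lambda: {"early": 1.0, "middle": 1.0, "late": 1.0}
    )


@dataclass(frozen=True)
class GroupEEGParams:
    """EEG ground truth for one group: per-region baseline band densities
    (uV^2/Hz) and per-block multipliers keyed (region-or-'all', band)."""

    band_density: dict[str, dict[str, float]]
    block_multipliers: dict[str, dict[tuple[str, str], float]] = field(default_factory=dict)

    def densities_for_block(self, block: str) -> dict[str, dict[str, float]]:
        out = {r: dict(b) for r, b in self.band_density.items()}
        for (region, band), mult in self.block_multipliers.get(block, {}).items():
            targets = REGIONS if region == "all" else {region: None}
            for r in targets:
                out[r][band] *= mult
        return out


def _default_audio_params() -> dict[str, GroupAudioParams]:
    improve_bf = {"early": 0.75, "middle": 0.55, "late": 0.40}
    improve_bnf = {"early": 0.75, "middle": 0.70, "late": 0.68}
    return {
        "EG": GroupAudioParams(3.0, 0.05, 35.0),
        "BF": GroupAudioParams(15.0, 0.25, 18.0, improve_bf),
        "BNF": GroupAudioParams(15.0, 0.25, 18.0, improve_bnf),
    }


def _default_eeg_params() -> dict[str, GroupEEGParams]:
    expert_density = {
        "frontal": {"theta": 5.0, "alpha": 6.0, "beta": 1.0, "gamma": 1.0},
        "posterior": {"theta": 5.0, "alpha": 7.0, "beta": 1.2, "gamma": 0.9},
        "temporal": {"theta": 5.0, "alpha": 6.0, "beta": 1.2, "gamma": 0.9},
    }
    # beginners carry 190% more frontal beta and 16% more frontal gamma at
    # baseline, and their gamma density drops to 0.7x after the baseline
    beginner_density = {
        "frontal": {"theta": 5.0, "alpha": 6.0, "beta": 2.9, "gamma": 1.16},
        "posterior": dict(expert_density["posterior"]),
        "temporal": dict(expert_density["temporal"]),
    }
    beginner_mult = {
        blk: {("all", "gamma"): 0.7} for blk in ("early", "middle", "late")
    }
    expert_mult = {
        blk: {
            ("posterior", "gamma"): 0.75,
            ("temporal", "gamma"): 0.75,
            ("temporal", "beta"): 1.3,
        }
        for blk in ("early", "middle", "late")
    }
    return {
        "EG": GroupEEGParams(expert_density, expert_mult),
        "BF": GroupEEGParams(beginner_density, beginner_mult),
        "BNF": GroupEEGParams(beginner_density, beginner_mult),
    }


def _default_behavior_means() -> dict[str, dict[str, float]]:
    # Poisson request-count means; the feedback group consults the
    # reference video more often and additionally requests its score
    return {
        "BF": {"instructional_video": 4.0, "reference_video": 10.0, "score": 9.0},
        "BNF": {"instructional_video": 4.0, "reference_video": 8.0},
    }


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Full description of a synthetic cohort; the seed fixes everything."""

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"EG": 7, "BF": 9, "BNF": 9}
    )
    trials_per_subject: int = 20
    audio_duration_s: float = 30.0
    eeg_duration_s: float = 30.0
    audio_sample_rate: float = 44100.0
    eeg_sample_rate: float = 128.0
    audio_params: dict[str, GroupAudioParams] = field(default_factory=_default_audio_params)
    eeg_params: dict[str, GroupEEGParams] = field(default_factory=_default_eeg_params)
    behavior_means: dict[str, dict[str, float]] = field(default_factory=_default_behavior_means)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 1")
        if self.trials_per_subject != 20:
            raise ValueError("the session design is 20 trials per subject")

    def subjects(self) -> list[tuple[str, str]]:
        out = []
        for group in ("EG", "BF", "BNF"):
            for i in range(self.group_sizes.get(group, 0)):
                out.append((f"{group}{i + 1:02d}", group))
        return out


def _trial_rng(
    root: np.random.SeedSequence, subject_i: int, trial: int, stream: int
) -> np.random.Generator:
    """Independent, reproducible stream per (subject, trial, purpose)."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=root.entropy, spawn_key=(subject_i, trial, stream))
    )


def synth_cohort(spec: SyntheticCohortSpec, out_dir: str | Path) -> Path:
    """Write a full cohort to disk and return the manifest path.

    Layout: ``audio/<subject>_t<k>.wav`` (16-bit PCM),
    ``eeg/<subject>_t<k>.csv`` (time_s + 14 channel columns),
    ``events.csv``, ``behavior.csv`` and ``manifest.csv`` at the root.
    """
    out = Path(out_dir)
    (out / "audio").mkdir(parents=True, exist_ok=True)
    (out / "eeg").mkdir(parents=True, exist_ok=True)
    design = BlockDesign()
    root = np.random.SeedSequence(spec.seed)

    manifest_rows, event_rows = [], []
    for si, (subject, group) in enumerate(spec.subjects()):
        ap = spec.audio_params[group]
        ep = spec.eeg_params[group]
        for trial in range(1, spec.trials_per_subject + 1):
            block = design.block_of(trial)
            mult = 1.0 if block == "baseline" else ap.block_multipliers.get(block, 1.0)
            audio = synth_violin_trial(
                subject_id=subject,
                group=group,
                trial_index=trial,
                duration_s=spec.audio_duration_s,
                pitch_jitter_sd=ap.pitch_jitter_sd * mult,
                power_jitter_sd=ap.power_jitter_sd * mult,
                noise_snr=ap.noise_snr_db,
                sample_rate=spec.audio_sample_rate,
                seed=_trial_rng(root, si, trial, 0),
            )
            eeg = synth_eeg_trial(
                ep.densities_for_block(block),
                subject_id=subject,
                group=group,
                trial_index=trial,
                duration_s=spec.eeg_duration_s,
                sample_rate=spec.eeg_sample_rate,
                seed=_trial_rng(root, si, trial, 1),
            )
            wav_path = out / "audio" / f"{subject}_t{trial:02d}.wav"
            eeg_path = out / "eeg" / f"{subject}_t{trial:02d}.csv"
            wavfile.write(
                wav_path,
                int(audio.sample_rate),
                np.clip(audio.samples * 32767.0, -32768, 32767).astype(np.int16),
            )
            t = np.arange(eeg.data.shape[1]) / eeg.sample_rate
            eeg_df = pd.DataFrame({"time_s": t})
            for ci, ch in enumerate(eeg.channel_names):
                eeg_df[ch] = eeg.data[ci]
            eeg_df.to_csv(eeg_path, index=False, float_format="%.6f")
            manifest_rows.append(
                {
                    "subject_id": subject,
                    "group": group,
                    "trial_index": trial,
                    "audio_path": str(wav_path.relative_to(out)),
                    "eeg_path": str(eeg_path.relative_to(out)),
                }
            )
            event_rows.append(
                {
                    "subject_id": subject,
                    "trial_index": trial,
                    "start_s": 0.0,
                    "end_s": spec.eeg_duration_s,
                }
            )

    behavior_rows = []
    for si, (subject, group) in enumerate(spec.subjects()):
        means = spec.behavior_means.get(group)
        if not means:
            continue
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=root.entropy, spawn_key=(si, 99, 2))
        )
        for material in sorted(means):
            behavior_rows.append(
                {
                    "subject_id": subject,
                    "group": group,
                    "material_type": material,
                    "request_count": int(rng.poisson(means[material])),
                }
            )

    pd.DataFrame(event_rows).to_csv(out / "events.csv", index=False, float_format="%.3f")
    pd.DataFrame(behavior_rows).to_csv(out / "behavior.csv", index=False)
    manifest = out / "manifest.csv"
    pd.DataFrame(manifest_rows).to_csv(manifest, index=False)
    return manifest
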