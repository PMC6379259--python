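"""Clustered EEG band power and ERD/ERS for the bowing-practice session.

Fourteen channels of a consumer 10-20 headset (128 Hz) are reduced, per
trial, to Welch power spectral density; mean density over four canonical
bands is averaged within named electrode clusters.  Aberrant trial values
are masked with the modified Z-score (MAD) rule, and each post-baseline
block's power is contrasted with the baseline block (trials 1-5) as
event-related desynchronization / synchronization::

    ERD/ERS(%) = 100 * (baseline_power - test_power) / test_power

so a positive value is a power *decrease* (desynchronization) relative to
baseline.  The denominator is the test-interval power, not the classical
baseline-power form; ``erd_ers`` exposes the classical form behind a
clearly non-default switch.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .audio_features import GROUPS, BlockDesign

__all__ = [
    "MONTAGE_14",
    "DEFAULT_CLUSTERS",
    "DEFAULT_BANDS",
    "EEGRecording",
    "BandPowerRecord",
    "ERDRecord",
    "welch_psd",
    "band_power",
    "cluster_band_table",
    "modified_zscore",
    "modified_zscore_mask",
    "mask_outliers",
    "erd_ers",
    "block_erd_table",
    "read_eeg_csv",
]

logger = logging.getLogger(__name__)

MONTAGE_14 = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)

# 13 named electrode clusters over the 14-channel montage
DEFAULT_CLUSTERS: dict[str, tuple[str, ...]] = {
    "frontal": ("AF3", "F7", "F3", "FC5", "FC6", "F4", "F8", "AF4"),
    "midfrontal": ("F3", "F4"),
    "left_frontal": ("AF3", "F7", "F3", "FC5"),
    "right_frontal": ("FC6", "F4", "F8", "AF4"),
    "posterior": ("P7", "O1", "O2", "P8"),
    "left_posterior": ("P7", "O1"),
    "right_posterior": ("O2", "P8"),
    "occipital": ("O1", "O2"),
    "left_parietal": ("P7",),
    "right_parietal": ("P8",),
    "temporal": ("T7", "T8"),
    "left_temporal": ("T7",),
    "right_temporal": ("T8",),
}

# band name -> (low Hz, high Hz); half-open [low, high) at aggregation
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 24.0),
    "gamma": (30.0, 50.0),
}


@dataclass(frozen=True)
class EEGRecording:
    """One trial's multichannel EEG segment (channels x time, microvolts)."""

    subject_id: str
    group: str
    trial_index: int
    channel_names: tuple[str, ...]
    data: np.ndarray
    sample_rate: float = 128.0

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        names = self.channel_names
        if len(set(names)) != len(names):
            raise ValueError("duplicate channel names")
        unknown = set(names) - set(MONTAGE_14)
        if unknown:
            raise ValueError(f"channels not in the 14-electrode montage: {sorted(unknown)}")
        if data.ndim != 2 or data.shape[0] != len(names):
            raise ValueError("data must be channels x time with one row per channel name")
        if not np.all(np.isfinite(data)):
            raise ValueError("EEG data contains non-finite values")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.data[self.channel_names.index(name)]
        except ValueError:
            raise KeyError(f"channel {name!r} absent from recording") from None


@dataclass(frozen=True)
class BandPowerRecord:
    subject_id: str
    group: str
    trial_index: int
    cluster: str
    band: str
    power: float  # mean spectral density over the band, uV^2/Hz
    outlier_flag: bool = False

    def __post_init__(self) -> None:
        if self.power < 0:
            raise ValueError("band power must be non-negative")


@dataclass(frozen=True)
class ERDRecord:
    subject_id: str
    group: str
    block: str
    cluster: str
    band: str
    erd_percent: float


def welch_psd(
    samples: np.ndarray,
    sample_rate: float,
    window_s: float = 2.0,
    overlap_fraction: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch PSD with Hann-tapered overlapping segments.

    Frequency resolution is 1/window_s.  The returned density integrates
    (trapezoid-free, bin-sum x df) to the signal variance for stationary
    input, the usual discrete Parseval property of the estimator.
    """
    samples = np.asarray(samples, dtype=np.float64)
    nperseg = int(round(window_s * sample_rate))
    if len(samples) < nperseg:
        raise ValueError(
            f"signal of {len(samples)} samples shorter than one {nperseg}-sample segment"
        )
    if not 0 <= overlap_fraction < 1:
        raise ValueError("overlap_fraction must lie in [0, 1)")
    freqs, density = signal.welch(
        samples,
        fs=sample_rate,
        window="hann",
        nperseg=nperseg,
        noverlap=int(round(overlap_fraction * nperseg)),
        detrend="constant",
        scaling="density",
    )
    return freqs, density


def band_power(
    freqs: np.ndarray,
    density: np.ndarray,
    band: tuple[float, float],
    aggregate: Literal["mean", "integral"] = "mean",
) -> float:
    """Aggregate a PSD over ``band`` = (low, high), bins low <= f < high.

    Mean density (default) keeps bands of different widths comparable in
    uV^2/Hz; ``aggregate='integral'`` returns total band power in uV^2.
    """
    low, high = band
    freqs = np.asarray(freqs)
    sel = (freqs >= low) & (freqs < high)
    if not sel.any():
        raise ValueError(f"no frequency bins inside band [{low}, {high})")
    vals = np.asarray(density)[sel]
    if aggregate == "mean":
        return float(vals.mean())
    if aggregate == "integral":
        df = float(freqs[1] - freqs[0])
        return float(vals.sum() * df)
    raise ValueError(f"unknown aggregate {aggregate!r}")


def cluster_band_table(
    recordings: Iterable[EEGRecording],
    clusters: Mapping[str, Sequence[str]] | None = None,
    bands: Mapping[str, tuple[float, float]] | None = None,
    window_s: float = 2.0,
    overlap_fraction: float = 0.5,
    aggregate: Literal["mean", "integral"] = "mean",
) -> list[BandPowerRecord]:
    """Per trial, per cluster, per band: mean over member electrodes of the
    electrode's band power."""
    clusters = dict(clusters or DEFAULT_CLUSTERS)
    bands = dict(bands or DEFAULT_BANDS)
    records: list[BandPowerRecord] = []
    for rec in recordings:
        needed = {e for members in clusters.values() for e in members}
        missing = needed - set(rec.channel_names)
        if missing:
            raise ValueError(
                f"{rec.subject_id} trial {rec.trial_index}: missing electrode(s) "
                f"{sorted(missing)}"
            )
        per_electrode: dict[str, dict[str, float]] = {}
        for name in rec.channel_names:
            freqs, density = welch_psd(
                rec.channel(name), rec.sample_rate, window_s, overlap_fraction
            )
            per_electrode[name] = {
                b: band_power(freqs, density, edges, aggregate)
                for b, edges in bands.items()
            }
        for cluster, members in clusters.items():
            for b in bands:
                value = float(np.mean([per_electrode[e][b] for e in members]))
                records.append(
                    BandPowerRecord(
                        rec.subject_id, rec.group, rec.trial_index, cluster, b, value
                    )
                )
    return records


def modified_zscore(values: Sequence[float]) -> np.ndarray:
    """Iglewicz-Hoaglin modified Z-scores, 0.6745*(x - median)/MAD."""
    x = np.asarray(values, dtype=np.float64)
    if len(x) < 3:
        raise ValueError("need at least 3 values for the modified Z-score")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        warnings.warn(
            "MAD is zero (degenerate spread); no outliers can be flagged",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.zeros_like(x)
    return 0.6745 * (x - med) / mad


def modified_zscore_mask(values: Sequence[float], threshold: float = 3.5) -> np.ndarray:
    """Boolean outlier flags: |modified Z| > threshold."""
    return np.abs(modified_zscore(values)) > threshold


def mask_outliers(
    records: Sequence[BandPowerRecord],
    threshold: float = 3.5,
    scope: Literal["block", "session"] = "block",
    design: BlockDesign | None = None,
) -> list[BandPowerRecord]:
    """Flag outlier trials by modified Z-score; flagged records are excluded
    from block averages.

    ``scope='block'`` (default) scores each value against the other trials
    of the *same block* for that subject/cluster/band, so genuine
    between-block power shifts — the very signal ERD measures — are never
    mistaken for artifacts.  ``scope='session'`` scores against all of the
    subject's trials instead.
    """
    design = design or BlockDesign()
    df = pd.DataFrame(
        {
            "subject": [r.subject_id for r in records],
            "cluster": [r.cluster for r in records],
            "band": [r.band for r in records],
            "power": [r.power for r in records],
        }
    )
    keys = ["subject", "cluster", "band"]
    if scope == "block":
        df["block"] = [design.block_of(r.trial_index) for r in records]
        keys.append("block")
    elif scope != "session":
        raise ValueError(f"unknown masking scope {scope!r}")
    flags = np.zeros(len(records), dtype=bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # constant groups: no flags
        for _, idx in df.groupby(keys).groups.items():
            vals = df.loc[idx, "power"].to_numpy()
            if len(vals) >= 3:
                flags[np.asarray(idx)] = modified_zscore_mask(vals, threshold)
    return [
        BandPowerRecord(
            r.subject_id, r.group, r.trial_index, r.cluster, r.band, r.power, bool(f)
        )
        for r, f in zip(records, flags)
    ]


def erd_ers(
    baseline_power: float,
    test_power: float,
    denominator: Literal["test", "baseline"] = "test",
) -> float:
    """Signed percent band-power change between baseline and test intervals.

    Default form: 100*(baseline - test)/test.  Positive = desynchronization
    (power fell below baseline).  ``denominator='baseline'`` selects the
    classical normalisation instead; it is not the default here.
    """
    if baseline_power <= 0 or test_power <= 0:
        raise ValueError("band powers must be strictly positive")
    denom = test_power if denominator == "test" else baseline_power
    return 100.0 * (baseline_power - test_power) / denom


def block_erd_table(
    records: Sequence[BandPowerRecord],
    design: BlockDesign | None = None,
    denominator: Literal["test", "baseline"] = "test",
) -> list[ERDRecord]:
    """Block-wise ERD/ERS per subject/cluster/band vs. the baseline block.

    Baseline power is the mean over unmasked trials 1-5; each test block's
    power the mean over its unmasked trials.  Combinations whose baseline or
    test block is fully masked are omitted with a logged reason.
    """
    design = design or BlockDesign()
    df = pd.DataFrame(
        {
            "subject": [r.subject_id for r in records],
            "group": [r.group for r in records],
            "trial": [r.trial_index for r in records],
            "cluster": [r.cluster for r in records],
            "band": [r.band for r in records],
            "power": [r.power for r in records],
            "outlier": [r.outlier_flag for r in records],
        }
    )
    df = df[~df["outlier"]]
    df["block"] = df["trial"].map(design.block_of)
    out: list[ERDRecord] = []
    grouped = df.groupby(["subject", "group", "cluster", "band"])
    for (subject, group, cluster, band), sub in grouped:
        means = sub.groupby("block")["power"].mean()
        if "baseline" not in means:
            logger.warning(
                "%s %s/%s: baseline block fully masked; ERD omitted",
                subject, cluster, band,
            )
            continue
        base = float(means["baseline"])
        for block in design.test_blocks:
            if block not in means:
                logger.warning(
                    "%s %s/%s: block %s fully masked; ERD omitted",
                    subject, cluster, band, block,
                )
                continue
            out.append(
                ERDRecord(
                    subject, group, block, cluster, band,
                    erd_ers(base, float(means[block]), denominator),
                )
            )
    return out


def read_eeg_csv(
    path: str,
    subject_id: str,
    group: str,
    trial_index: int,
    sample_rate: float = 128.0,
    start_s: float | None = None,
    end_s: float | None = None,
) -> EEGRecording:
    """Read one trial's EEG CSV: ``time_s`` column then one column per
    montage channel.  ``start_s``/``end_s`` crop a trial out of a longer
    continuous recording (events-CSV alignment)."""
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: missing required 'time_s' column")
    if start_s is not None or end_s is not None:
        t = df["time_s"]
        lo = start_s if start_s is not None else -np.inf
        hi = end_s if end_s is not None else np.inf
        df = df[(t >= lo) & (t < hi)]
    channels = tuple(c for c in df.columns if c != "time_s")
    return EEGRecording(
        subject_id, group, trial_index, channels,
        df[list(channels)].to_numpy().T, sample_rate,
    )


def band_power_table(records: Sequence[BandPowerRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "group": [r.group for r in records],
            "trial_index": [r.trial_index for r in records],
            "cluster": [r.cluster for r in records],
            "band": [r.band for r in records],
            "power": [r.power for r in records],
            "outlier_flag": [r.outlier_flag for r in records],
        }
    )


def erd_table(records: Sequence[ERDRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "group": [r.group for r in records],
            "block": [r.block for r in records],
            "cluster": [r.cluster for r in records],
            "band": [r.band for r in records],
            "erd_percent": [r.erd_percent for r in records],
        }
    )
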