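"""Manifest-driven end-to-end analysis runs.

``run_analysis`` executes the three stages in order — audio descriptors,
EEG band power / ERD, then the statistical battery — on a session manifest
(subject, group, trial, audio path, EEG path), using trials 1-5 as the
shared baseline for both the sound-quality percent change and ERD/ERS, and
ranking features by information gain over the first block only (before any
external feedback).  Results are written as a TSV set plus a JSON summary
with enough provenance to re-run the identical analysis.
"""

from __future__ import annotations

import hashlib
import json
import logging
import wave
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from . import __version__
from .audio_features import (
    GROUPS,
    BlockDesign,
    block_percent_change,
    descriptor_table,
    frame_metrics,
    read_trial_audio,
    sound_instability,
    trial_descriptors,
)
from .eeg_features import (
    DEFAULT_BANDS,
    DEFAULT_CLUSTERS,
    band_power_table,
    block_erd_table,
    cluster_band_table,
    erd_table,
    mask_outliers,
    read_eeg_csv,
)
from . import stats as st

__all__ = ["RunConfig", "AnalysisReport", "validate_manifest", "run_analysis"]

logger = logging.getLogger(__name__)

BEGINNER_GROUPS = ("BF", "BNF")


@dataclass
class RunConfig:
    """Everything an end-to-end run depends on."""

    manifest: str
    out_dir: str = "sqvfs_out"
    # audio stage
    window_ms: float = 33.0
    hop_ms: float = 0.7
    yin_threshold: float = 0.15
    include_aperiodicity: bool = True
    scale: Literal["zscore", "center_only"] = "zscore"
    # EEG stage
    eeg_window_s: float = 2.0
    eeg_overlap: float = 0.5
    mask_threshold: float = 3.5
    mask_scope: Literal["block", "session"] = "block"
    erd_denominator: Literal["test", "baseline"] = "test"
    # stats stage
    family_alpha: float = 0.05
    discretizer: Literal["mdl", "equal_width_k"] = "mdl"
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        import yaml  # local import: config files are optional

        with open(path) as fh:
            obj = yaml.safe_load(fh) or {}
        obj.update(overrides)
        return cls(**obj)

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


class ManifestError(ValueError):
    """Raised with an itemized report when a session manifest is invalid."""


def validate_manifest(manifest_path: str | Path) -> pd.DataFrame:
    """Validate a session manifest and return the session index.

    Checks: required columns, known group labels, exactly trials 1..20 per
    subject, referenced files present with parseable headers.  Paths in the
    manifest are resolved relative to the manifest's directory.
    """
    path = Path(manifest_path)
    df = pd.read_csv(path)
    problems: list[str] = []
    required = {"subject_id", "group", "trial_index", "audio_path", "eeg_path"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ManifestError(f"manifest missing column(s): {sorted(missing_cols)}")

    for label in sorted(set(df["group"]) - set(GROUPS)):
        problems.append(f"unknown group label {label!r}")
    for subject, sub in df.groupby("subject_id"):
        trials = sorted(sub["trial_index"])
        if trials != list(range(1, 21)):
            absent = sorted(set(range(1, 21)) - set(trials))
            extra = sorted(set(trials) - set(range(1, 21)))
            if absent:
                problems.append(f"subject {subject}: missing trial(s) {absent}")
            if extra:
                problems.append(f"subject {subject}: unexpected trial index(es) {extra}")

    base = path.parent
    for _, row in df.iterrows():
        wav_path = base / row["audio_path"]
        eeg_path = base / row["eeg_path"]
        tag = f"subject {row['subject_id']} trial {row['trial_index']}"
        if not wav_path.is_file():
            problems.append(f"{tag}: audio file missing: {wav_path}")
        else:
            try:
                with wave.open(str(wav_path)) as wf:
                    wf.getframerate()
            except wave.Error as exc:
                problems.append(f"{tag}: unreadable WAV header ({exc})")
        if not eeg_path.is_file():
            problems.append(f"{tag}: EEG file missing: {eeg_path}")
        else:
            header = eeg_path.read_text().splitlines()[0] if eeg_path.stat().st_size else ""
            if "time_s" not in header.split(","):
                problems.append(f"{tag}: EEG CSV lacks a 'time_s' header column")

    if problems:
        raise ManifestError("manifest validation failed:\n  " + "\n  ".join(problems))
    df = df.copy()
    df["audio_path"] = [str(base / p) for p in df["audio_path"]]
    df["eeg_path"] = [str(base / p) for p in df["eeg_path"]]
    return df.sort_values(["subject_id", "trial_index"]).reset_index(drop=True)


@dataclass
class AnalysisReport:
    """All tables of one end-to-end run, plus provenance."""

    descriptors: pd.DataFrame
    percent_change: pd.DataFrame
    band_power: pd.DataFrame
    erd: pd.DataFrame
    ig_ranking: pd.DataFrame
    stats_report: pd.DataFrame
    correlation: pd.DataFrame
    behavior: pd.DataFrame
    skipped: dict[str, str]
    provenance: dict

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tables = {
            "descriptors": self.descriptors,
            "percent_change": self.percent_change,
            "band_power": self.band_power,
            "erd": self.erd,
            "ig_ranking": self.ig_ranking,
            "stats_report": self.stats_report,
            "correlation": self.correlation,
            "behavior": self.behavior,
        }
        summary: dict = {"provenance": self.provenance, "skipped": self.skipped, "tables": {}}
        for name, df in tables.items():
            df.to_csv(out / f"{name}.tsv", sep="\t", index=False, float_format="%.6g")
            summary["tables"][name] = {"rows": int(len(df)), "columns": list(df.columns)}
        report_path = out / "report.json"
        report_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
        return report_path


def _audio_stage(index: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    cohort = []
    for _, row in index.iterrows():
        logger.info("audio: subject %s trial %d", row["subject_id"], row["trial_index"])
        audio = read_trial_audio(
            row["audio_path"], row["subject_id"], row["group"], int(row["trial_index"])
        )
        frames = frame_metrics(
            audio,
            window_s=config.window_ms / 1000.0,
            hop_s=config.hop_ms / 1000.0,
            yin_threshold=config.yin_threshold,
        )
        cohort.append(
            trial_descriptors(
                frames, row["subject_id"], row["group"], int(row["trial_index"])
            )
        )
    with_ap = sound_instability(cohort, include_aperiodicity=True, scale=config.scale)
    without_ap = sound_instability(cohort, include_aperiodicity=False, scale=config.scale)
    table = descriptor_table(
        with_ap if config.include_aperiodicity else without_ap
    )
    table["sound_instability_with_ap"] = [d.sound_instability for d in with_ap]
    table["sound_instability_no_ap"] = [d.sound_instability for d in without_ap]
    return table


def _percent_change_stage(desc: pd.DataFrame, design: BlockDesign) -> pd.DataFrame:
    rows = []
    for group, sub in desc.groupby("group"):
        per_trial = sub.groupby("trial_index")["sound_instability"].mean()
        try:
            change = block_percent_change(per_trial.to_dict(), design)
        except (ValueError, ZeroDivisionError) as exc:
            logger.warning("percent change skipped for group %s: %s", group, exc)
            continue
        for block, pct in change.per_block.items():
            rows.append(
                {
                    "group": group,
                    "block": block,
                    "percent_change": pct,
                    "baseline_mean": change.baseline_mean,
                    "convention": change.convention,
                }
            )
    return pd.DataFrame(rows)


def _first_block_features(
    desc: pd.DataFrame, bp: pd.DataFrame, design: BlockDesign
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-row (subject x first-block-trial) feature tables with a
    beginner/expert class label, for IG ranking."""
    first = list(design.trials("baseline"))
    label = lambda g: "expert" if g == "EG" else "beginner"

    a = desc[desc["trial_index"].isin(first)].copy()
    audio = pd.DataFrame(
        {
            "dynamic_instability": a["dynamic_instability"],
            "pitch_instability": a["pitch_instability"],
            "aperiodicity": a["aperiodicity"],
            "sound_instability_with_ap": a["sound_instability_with_ap"],
            "sound_instability_no_ap": a["sound_instability_no_ap"],
            "label": a["group"].map(label),
        }
    )

    b = bp[bp["trial_index"].isin(first)]
    wide = b.pivot_table(
        index=["subject_id", "group", "trial_index"],
        columns=["cluster", "band"],
        values="power",
    )
    wide.columns = [f"{c}_{band}" for c, band in wide.columns]
    wide = wide.reset_index()
    eeg = wide.drop(columns=["subject_id", "trial_index"])
    eeg["label"] = wide["group"].map(label)
    eeg = eeg.drop(columns=["group"])
    return audio, eeg


def _stats_stage(
    desc: pd.DataFrame,
    bp: pd.DataFrame,
    erd: pd.DataFrame,
    behavior: pd.DataFrame | None,
    design: BlockDesign,
    config: RunConfig,
    skipped: dict[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    results: list[st.StatResult] = []
    ig_rows = []

    has_both_classes = set(desc["group"]) - {"EG"} and "EG" in set(desc["group"])
    audio_feats, eeg_feats = _first_block_features(desc, bp, design)

    if has_both_classes:
        for domain, table in (("audio", audio_feats), ("eeg", eeg_feats)):
            ranking = st.rank_features(table, discretizer=config.discretizer)
            for rank, (name, ig) in enumerate(ranking, start=1):
                ig_rows.append(
                    {"domain": domain, "feature": name,
                     "information_gain_bits": ig, "rank": rank}
                )
        # beginner-vs-expert contrasts: every audio descriptor; the 8
        # top-ranked EEG cluster-band features
        audio_cols = [c for c in audio_feats.columns if c != "label"]
        alpha_a = st.bonferroni_alpha(config.family_alpha, len(audio_cols))
        for col in audio_cols:
            results.append(
                st.nonparametric_test(
                    "rank_sum",
                    {
                        "beginner": audio_feats.loc[audio_feats["label"] == "beginner", col],
                        "expert": audio_feats.loc[audio_feats["label"] == "expert", col],
                    },
                    comparison=f"audio {col}: beginners vs experts (first block)",
                    adjusted_alpha=alpha_a,
                )
            )
        eeg_rank = [r for r in ig_rows if r["domain"] == "eeg"][:8]
        alpha_e = st.bonferroni_alpha(config.family_alpha, len(eeg_rank))
        for row in eeg_rank:
            col = row["feature"]
            results.append(
                st.nonparametric_test(
                    "rank_sum",
                    {
                        "beginner": eeg_feats.loc[eeg_feats["label"] == "beginner", col],
                        "expert": eeg_feats.loc[eeg_feats["label"] == "expert", col],
                    },
                    comparison=f"eeg {col}: beginners vs experts (first block)",
                    adjusted_alpha=alpha_e,
                )
            )
    else:
        skipped["beginner_vs_expert"] = (
            "both beginner and expert rows are required; only one class present"
        )

    # within-group learning: baseline vs post-baseline signed-rank and a
    # Friedman test across the three post blocks, one per group
    groups_present = sorted(set(desc["group"]))
    alpha_block = st.bonferroni_alpha(config.family_alpha, max(1, len(groups_present)))
    for group in groups_present:
        sub = desc[desc["group"] == group]
        per_subject = sub.assign(block=sub["trial_index"].map(design.block_of))
        means = per_subject.pivot_table(
            index="subject_id", columns="block", values="sound_instability"
        )
        if means.shape[0] < 2 or means.isna().any().any():
            skipped[f"block_tests_{group}"] = "insufficient per-subject block coverage"
            continue
        post = means[list(design.test_blocks)].mean(axis=1)
        results.append(
            st.nonparametric_test(
                "signed_rank",
                {"baseline": means["baseline"], "post": post},
                comparison=f"{group}: sound instability, baseline vs post-baseline",
                adjusted_alpha=alpha_block,
            )
        )
        results.append(
            st.nonparametric_test(
                "friedman",
                {b: means[b] for b in design.test_blocks},
                comparison=f"{group}: sound instability across post blocks",
                adjusted_alpha=alpha_block,
            )
        )

    # end-of-session contrast between the beginner groups
    if set(BEGINNER_GROUPS) <= set(groups_present):
        late = desc[desc["trial_index"].isin(design.trials("late"))]
        late_means = late.groupby(["group", "subject_id"])["sound_instability"].mean()
        results.append(
            st.nonparametric_test(
                "rank_sum",
                {g: late_means[g].to_numpy() for g in BEGINNER_GROUPS},
                comparison="late-block sound instability: BF vs BNF",
                adjusted_alpha=config.family_alpha,
            )
        )

    # ERD: signed-rank vs zero per group x cluster x band x block; the
    # Bonferroni family is the number of tests actually performed
    erd_cells = [
        (group, cluster, band, block, sub["erd_percent"].to_numpy())
        for (group, cluster, band, block), sub in erd.groupby(
            ["group", "cluster", "band", "block"]
        )
        if len(sub) >= 2
    ]
    if erd_cells:
        alpha_erd = st.bonferroni_alpha(config.family_alpha, len(erd_cells))
        for group, cluster, band, block, vals in erd_cells:
            results.append(
                st.nonparametric_test(
                    "signed_rank",
                    {"erd": vals, "zero": np.zeros_like(vals)},
                    comparison=f"{group} {cluster} {band} {block}: ERD vs 0",
                    adjusted_alpha=alpha_erd,
                )
            )
    # between-group frontal gamma desynchronization contrasts
    fg = erd[(erd["cluster"] == "frontal") & (erd["band"] == "gamma")]
    fg_means = fg.groupby(["group", "subject_id"])["erd_percent"].mean()
    for a, b in (("BNF", "BF"), ("BNF", "EG")):
        if {a, b} <= set(fg_means.index.get_level_values(0)):
            results.append(
                st.nonparametric_test(
                    "rank_sum",
                    {a: fg_means[a].to_numpy(), b: fg_means[b].to_numpy()},
                    comparison=f"frontal gamma ERD: {a} vs {b}",
                    adjusted_alpha=st.bonferroni_alpha(config.family_alpha, 2),
                )
            )

    # trialwise correlation of frontal band power with sound instability,
    # averaged over beginner subjects per trial
    beginners = desc[desc["group"].isin(BEGINNER_GROUPS)]
    corr = pd.DataFrame()
    if not beginners.empty:
        score_series = beginners.groupby("trial_index")["sound_instability"].mean()
        fb = bp[
            bp["group"].isin(BEGINNER_GROUPS)
            & (bp["cluster"] == "frontal")
            & ~bp["outlier_flag"]
        ]
        band_series = {
            band: sub.groupby("trial_index")["power"].mean().reindex(score_series.index)
            for band, sub in fb.groupby("band")
        }
        if all(s.notna().all() for s in band_series.values()):
            corr = st.trialwise_correlation(
                band_series, score_series.to_numpy(), config.family_alpha
            )
        else:
            skipped["correlation"] = "incomplete trial coverage after outlier masking"
    else:
        skipped["correlation"] = "no beginner trials present"

    if behavior is not None and not behavior.empty:
        try:
            results.extend(st.behavioral_comparison(behavior, config.family_alpha))
        except ValueError as exc:
            skipped["behavior"] = str(exc)
    else:
        skipped["behavior"] = "no behavior table provided"

    return pd.DataFrame(ig_rows), st.stat_results_table(results), corr


def run_analysis(config: RunConfig) -> AnalysisReport:
    """Execute audio -> EEG -> stats on a validated manifest and return the
    full report (also written to ``config.out_dir``)."""
    index = validate_manifest(config.manifest)
    design = BlockDesign()
    skipped: dict[str, str] = {}

    desc = _audio_stage(index, config)
    pct = _percent_change_stage(desc, design)

    recordings = (
        read_eeg_csv(
            row["eeg_path"], row["subject_id"], row["group"], int(row["trial_index"])
        )
        for _, row in index.iterrows()
    )
    bp_records = mask_outliers(
        cluster_band_table(
            recordings,
            DEFAULT_CLUSTERS,
            DEFAULT_BANDS,
            window_s=config.eeg_window_s,
            overlap_fraction=config.eeg_overlap,
        ),
        threshold=config.mask_threshold,
        scope=config.mask_scope,
        design=design,
    )
    bp = band_power_table(bp_records)
    erd = erd_table(
        block_erd_table(bp_records, design, denominator=config.erd_denominator)
    )

    behavior_path = Path(config.manifest).parent / "behavior.csv"
    behavior = pd.read_csv(behavior_path) if behavior_path.is_file() else None

    ig, stats_report, corr = _stats_stage(
        desc, bp, erd, behavior, design, config, skipped
    )

    provenance = {
        "package_version": __version__,
        "config": asdict(config),
        "config_hash": config.content_hash(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
    }
    report = AnalysisReport(
        descriptors=desc,
        percent_change=pct,
        band_power=bp,
        erd=erd,
        ig_ranking=ig,
        stats_report=stats_report,
        correlation=corr,
        behavior=behavior if behavior is not None else pd.DataFrame(),
        skipped=skipped,
        provenance=provenance,
    )
    report.write(config.out_dir)
    return report
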