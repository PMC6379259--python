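"""Feature ranking and the session's hypothesis-test battery.

Information gain over MDL-discretized numeric features ranks audio
descriptors and cluster-band powers by how well they separate beginners
from experts.  Group and block contrasts use a Shapiro-Wilk normality gate
followed by nonparametric tests (Wilcoxon rank-sum / signed-rank, Friedman,
Mann-Whitney U) with Bonferroni family-wise control; frontal band power is
correlated trial-by-trial with the sound-instability composite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatResult",
    "entropy_bits",
    "mdl_discretize",
    "information_gain",
    "rank_features",
    "normality_gate",
    "nonparametric_test",
    "bonferroni_alpha",
    "trialwise_correlation",
    "behavioral_comparison",
]


@dataclass(frozen=True)
class StatResult:
    """One hypothesis test's outcome; ``significant`` is p < adjusted_alpha
    by construction."""

    test_name: str
    comparison: str
    statistic: float
    p_value: float
    adjusted_alpha: float
    effect_summary: dict[str, float]
    note: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < self.adjusted_alpha


# ---------------------------------------------------------------------------
# Information gain with supervised MDL discretization
# ---------------------------------------------------------------------------


def entropy_bits(labels: Sequence) -> float:
    """Shannon entropy of a label sample, in bits."""
    _, counts = np.unique(np.asarray(labels), return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _split_entropy(y: np.ndarray, left: np.ndarray) -> float:
    n = len(y)
    nl = int(left.sum())
    hl = entropy_bits(y[left]) if nl else 0.0
    hr = entropy_bits(y[~left]) if nl < n else 0.0
    return (nl * hl + (n - nl) * hr) / n


def _mdl_accepts(y: np.ndarray, left: np.ndarray) -> bool:
    # Fayyad-Irani MDLP stopping rule for a binary cut
    n = len(y)
    k = len(np.unique(y))
    kl = len(np.unique(y[left]))
    kr = len(np.unique(y[~left]))
    ent = entropy_bits(y)
    ent_l = entropy_bits(y[left]) if left.any() else 0.0
    ent_r = entropy_bits(y[~left]) if (~left).any() else 0.0
    gain = ent - _split_entropy(y, left)
    delta = math.log2(3**k - 2) - (k * ent - kl * ent_l - kr * ent_r)
    return gain > (math.log2(n - 1) + delta) / n


def _best_cut(x: np.ndarray, y: np.ndarray) -> float | None:
    """Best boundary cut point by class-entropy, or None if no candidate."""
    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y[order]
    # candidate cuts: midpoints between adjacent distinct values
    # (boundary points suffice for optimality, but distinct-value midpoints
    #  are simpler and equivalent in result)
    distinct = np.nonzero(np.diff(xs) > 0)[0]
    best, best_h = None, np.inf
    for i in distinct:
        cut = 0.5 * (xs[i] + xs[i + 1])
        h = _split_entropy(y, x <= cut)
        if h < best_h:
            best_h, best = h, cut
    return best


def mdl_discretize(x: np.ndarray, y: np.ndarray) -> list[float]:
    """Fayyad-Irani recursive entropy discretization; returns sorted cut
    points (possibly empty when no cut passes the MDL criterion)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    cuts: list[float] = []

    def recurse(mask: np.ndarray) -> None:
        xs, ys = x[mask], y[mask]
        if len(xs) < 2 or len(np.unique(ys)) < 2:
            return
        cut = _best_cut(xs, ys)
        if cut is None:
            return
        if not _mdl_accepts(ys, xs <= cut):
            return
        cuts.append(cut)
        recurse(mask & (x <= cut))
        recurse(mask & (x > cut))

    recurse(np.ones(len(x), dtype=bool))
    return sorted(cuts)


def _equal_width_cuts(x: np.ndarray, k: int) -> list[float]:
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        return []
    return list(np.linspace(lo, hi, k + 1)[1:-1])


def information_gain(
    feature: Sequence[float],
    labels: Sequence,
    discretizer: Literal["mdl", "equal_width_k"] = "mdl",
    k: int = 10,
) -> float:
    """Class-entropy reduction (bits) from partitioning on the discretized
    feature: IG = H(labels) - sum_bins P(bin) H(labels | bin).

    The default supervised MDL discretization mirrors the common
    attribute-evaluation practice; an unsupervised equal-width fallback is
    available for oracle comparisons.  A constant feature has IG = 0.
    """
    x = np.asarray(feature, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("labels must contain at least 2 classes")
    if np.min(counts) < 2:
        raise ValueError("each class needs at least 2 rows")
    if discretizer == "mdl":
        cuts = mdl_discretize(x, y)
    elif discretizer == "equal_width_k":
        cuts = _equal_width_cuts(x, k)
    else:
        raise ValueError(f"unknown discretizer {discretizer!r}")
    bins = np.digitize(x, cuts) if cuts else np.zeros(len(x), dtype=int)
    h = entropy_bits(y)
    cond = 0.0
    for b in np.unique(bins):
        sel = bins == b
        cond += sel.mean() * entropy_bits(y[sel])
    return max(0.0, h - cond)


def rank_features(
    table: pd.DataFrame,
    label_column: str = "label",
    discretizer: Literal["mdl", "equal_width_k"] = "mdl",
) -> list[tuple[str, float]]:
    """Rank numeric feature columns by information gain, descending; ties
    broken by feature name for determinism."""
    features = [c for c in table.columns if c != label_column]
    if not features:
        raise ValueError("table has no feature columns")
    scored = [
        (name, information_gain(table[name].to_numpy(), table[label_column], discretizer))
        for name in features
    ]
    return sorted(scored, key=lambda item: (-item[1], item[0]))


# ---------------------------------------------------------------------------
# Test battery
# ---------------------------------------------------------------------------


def normality_gate(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> tuple[bool, dict[str, float]]:
    """Shapiro-Wilk per group; returns (any group rejects normality at
    ``alpha``, per-group p-values).  A rejection steers downstream analysis
    to nonparametric tests.  Constant samples are degenerate and routed
    nonparametric (p-value reported as 0)."""
    pvals: dict[str, float] = {}
    for name, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        if len(v) < 3:
            raise ValueError(f"group {name!r} has n < 3")
        if np.ptp(v) == 0:
            pvals[name] = 0.0
            continue
        pvals[name] = float(sps.shapiro(v).pvalue)
    return any(p < alpha for p in pvals.values()), pvals


def bonferroni_alpha(family_alpha: float = 0.05, m: int = 1) -> float:
    """Per-test significance level under Bonferroni control of ``m`` tests."""
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    return family_alpha / m


def _summary(name_vals: Mapping[str, Sequence[float]]) -> dict[str, float]:
    return {
        f"median_{k}": float(np.median(np.asarray(v, dtype=float)))
        for k, v in name_vals.items()
    }


def nonparametric_test(
    kind: Literal["rank_sum", "signed_rank", "friedman", "mann_whitney", "paired_t"],
    data: Mapping[str, Sequence[float]] | Sequence[Sequence[float]],
    comparison: str = "",
    adjusted_alpha: float = 0.05,
) -> StatResult:
    """Dispatch one test of the battery, two-sided.

    ``data`` maps sample names to values (two entries for two-sample and
    paired kinds; >= 3 related blocks for Friedman).  Rank-based two-sample
    tests use exact enumeration when both samples are small (n <= 10) and
    tie-free, mid-rank normal approximation otherwise; signed-rank drops
    zero differences, noting how many were dropped.
    """
    if isinstance(data, Mapping):
        names = list(data)
        samples = [np.asarray(data[k], dtype=float) for k in names]
    else:
        samples = [np.asarray(s, dtype=float) for s in data]
        names = [f"sample{i+1}" for i in range(len(samples))]
    note = ""

    if kind in ("rank_sum", "mann_whitney"):
        if len(samples) != 2:
            raise ValueError(f"{kind} needs exactly 2 samples")
        a, b = samples
        exact = (
            len(a) <= 10
            and len(b) <= 10
            and len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
        )
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
        )
        stat, p = float(res.statistic), float(res.pvalue)
        note = "exact enumeration" if exact else "mid-rank normal approximation"
    elif kind == "signed_rank":
        if len(samples) != 2 or len(samples[0]) != len(samples[1]):
            raise ValueError("signed_rank needs 2 equal-length samples")
        diff = samples[0] - samples[1]
        nz = diff != 0
        if not nz.any():
            stat, p = 0.0, 1.0
            note = "all pairwise differences zero"
        else:
            if (~nz).any():
                note = f"{int((~nz).sum())} zero difference(s) excluded"
            res = sps.wilcoxon(
                samples[0][nz], samples[1][nz], alternative="two-sided"
            )
            stat, p = float(res.statistic), float(res.pvalue)
    elif kind == "friedman":
        if len(samples) < 3:
            raise ValueError("friedman needs >= 3 related blocks")
        if len({len(s) for s in samples}) != 1:
            raise ValueError("friedman blocks must have equal length")
        if all(np.array_equal(samples[0], s) for s in samples[1:]):
            stat, p = 0.0, 1.0
            note = "identical blocks"
        else:
            res = sps.friedmanchisquare(*samples)
            stat, p = float(res.statistic), float(res.pvalue)
    elif kind == "paired_t":
        if len(samples) != 2 or len(samples[0]) != len(samples[1]):
            raise ValueError("paired_t needs 2 equal-length samples")
        if len(samples[0]) < 2:
            raise ValueError("paired_t needs at least 2 pairs")
        res = sps.ttest_rel(samples[0], samples[1])
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown test kind {kind!r}")

    return StatResult(
        test_name=kind,
        comparison=comparison or " vs ".join(names),
        statistic=stat,
        p_value=min(1.0, p),
        adjusted_alpha=adjusted_alpha,
        effect_summary=_summary(dict(zip(names, samples))),
        note=note,
    )


def trialwise_correlation(
    band_series: Mapping[str, Sequence[float]],
    score_series: Sequence[float],
    family_alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlation, per band, of trial-averaged frontal band power
    against trial-averaged sound instability.

    Returns one row per band with r, R^2, p and a Bonferroni-adjusted
    significance flag over the number of bands tested.
    """
    scores = np.asarray(score_series, dtype=float)
    if len(scores) < 3:
        raise ValueError("need >= 3 trials for correlation")
    if np.ptp(scores) == 0:
        raise ValueError("score series has zero variance; correlation undefined")
    alpha = bonferroni_alpha(family_alpha, len(band_series))
    rows = []
    for band, series in band_series.items():
        v = np.asarray(series, dtype=float)
        if len(v) != len(scores):
            raise ValueError(f"band {band!r} series length mismatch")
        if np.ptp(v) == 0:
            raise ValueError(f"band {band!r} series has zero variance")
        r, p = sps.pearsonr(v, scores)
        rows.append(
            {
                "band": band,
                "r": float(r),
                "r_squared": float(r) ** 2,
                "p_value": float(p),
                "adjusted_alpha": alpha,
                "significant": float(p) < alpha,
            }
        )
    return pd.DataFrame(rows)


def behavioral_comparison(
    requests: pd.DataFrame,
    family_alpha: float = 0.05,
) -> list[StatResult]:
    """Compare learning-material request counts between the two beginner
    groups, plus the feedback group's internal reference-video vs
    score-request contrast.

    ``requests`` columns: subject_id, group, material_type, request_count.
    Mann-Whitney per material type shared by BF and BNF, Bonferroni over the
    number of such types; paired t within BF between 'reference_video' and
    'score' counts when both are present.
    """
    required = {"subject_id", "group", "material_type", "request_count"}
    if not required <= set(requests.columns):
        raise ValueError(f"behavior table needs columns {sorted(required)}")
    if (requests["request_count"] < 0).any():
        raise ValueError("request counts must be non-negative")

    results: list[StatResult] = []
    bf = requests[requests["group"] == "BF"]
    bnf = requests[requests["group"] == "BNF"]
    shared = sorted(
        set(bf["material_type"]) & set(bnf["material_type"])
    )
    if not shared or bf.empty or bnf.empty:
        raise ValueError("both beginner groups must have request counts")
    alpha = bonferroni_alpha(family_alpha, len(shared))
    for material in shared:
        a = bf.loc[bf["material_type"] == material, "request_count"].to_numpy(float)
        b = bnf.loc[bnf["material_type"] == material, "request_count"].to_numpy(float)
        results.append(
            nonparametric_test(
                "mann_whitney",
                {"BF": a, "BNF": b},
                comparison=f"{material}: BF vs BNF",
                adjusted_alpha=alpha,
            )
        )
    bf_types = set(bf["material_type"])
    if {"reference_video", "score"} <= bf_types:
        ref = bf[bf["material_type"] == "reference_video"].sort_values("subject_id")
        sco = bf[bf["material_type"] == "score"].sort_values("subject_id")
        if len(ref) >= 2 and list(ref["subject_id"]) == list(sco["subject_id"]):
            results.append(
                nonparametric_test(
                    "paired_t",
                    {
                        "reference_video": ref["request_count"].to_numpy(float),
                        "score": sco["request_count"].to_numpy(float),
                    },
                    comparison="BF: reference_video vs score requests",
                    adjusted_alpha=family_alpha,
                )
            )
    return results


def stat_results_table(results: Sequence[StatResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "test_name": [r.test_name for r in results],
            "comparison": [r.comparison for r in results],
            "statistic": [r.statistic for r in results],
            "p_value": [r.p_value for r in results],
            "adjusted_alpha": [r.adjusted_alpha for r in results],
            "significant": [r.significant for r in results],
            "note": [r.note for r in results],
        }
    )
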