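"""Staging statistics for spleen perfusion parameters.

Given per-observation METAVIR fibrosis stages (0–4) and the four perfusion
parameters, this module provides the analyses used to assess a staging
biomarker: Spearman rank correlation with stage, pairwise and grouped-stage
Mann–Whitney tests with Bonferroni correction, ROC analysis with
Youden-index cutoff selection for the four clinically relevant stage splits
(>=1, >=2, >=3, 4), and observer/histology agreement statistics (ICC,
Pearson, Cohen's kappa with the Kundel interpretation bands).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StagedMeasurements",
    "TestResult",
    "RocResult",
    "AgreementResult",
    "PARAMETERS",
    "SPLITS",
    "GROUPED_SPLITS",
    "spearman_stage_correlation",
    "mann_whitney",
    "grouped_stage_tests",
    "rank_auc",
    "roc_analysis",
    "icc_interobserver",
    "pearson_intraobserver",
    "cohen_kappa",
    "kappa_band",
    "staging_report",
]

PARAMETERS = ("ttp", "pei", "msi", "msd")

#: ROC stage splits: label -> minimum stage of the positive class.
SPLITS: dict[str, int] = {">=1": 1, ">=2": 2, ">=3": 3, "4": 4}

#: grouped Mann-Whitney splits: label -> stages on the low side.
GROUPED_SPLITS: dict[str, tuple[int, ...]] = {
    "S0 vs S1-4": (0,),
    "S0-1 vs S2-4": (0, 1),
    "S0-2 vs S3-4": (0, 1, 2),
    "S0-3 vs S4": (0, 1, 2, 3),
}


@dataclass(frozen=True)
class StagedMeasurements:
    """Stage labels and parameter values, one row per observation."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        if "stage" not in df.columns:
            raise ValueError("missing 'stage' column")
        stages = df["stage"].to_numpy()
        if not np.isin(stages, range(5)).all():
            raise ValueError("stages must be integers in 0..4")

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   dedup: bool = True) -> "StagedMeasurements":
        """Build from a cohort table, dropping repeat-stage observations
        (the published group sizes count each animal once per stage)."""
        if dedup and "is_repeat_stage" in df.columns:
            df = df.loc[~df["is_repeat_stage"].astype(bool)]
        return cls(df.reset_index(drop=True))

    def values(self, parameter: str) -> np.ndarray:
        if parameter not in self.frame.columns:
            raise ValueError(f"missing parameter column '{parameter}'")
        return self.frame[parameter].to_numpy(dtype=float)

    @property
    def stages(self) -> np.ndarray:
        return self.frame["stage"].to_numpy(dtype=int)


@dataclass(frozen=True)
class TestResult:
    """One two-sample test with its Bonferroni-corrected p-value."""

    statistic: float
    p_raw: float
    p_bonferroni: float
    n1: int
    n2: int
    family_size: int


@dataclass(frozen=True)
class RocResult:
    """ROC summary for one stage split of one parameter.

    ``polarity`` records which direction flags disease: for
    "higher-is-positive" a value >= cutoff predicts the higher-stage class,
    for "lower-is-positive" a value <= cutoff does.
    """

    split: str
    auc: float
    cutoff: float
    sensitivity: float  # percent
    specificity: float  # percent
    polarity: str
    n_positive: int
    n_negative: int


@dataclass(frozen=True)
class AgreementResult:
    """Observer/histology agreement statistics (whichever were computed)."""

    kappa: float | None = None
    kappa_ci: tuple[float, float] | None = None
    icc: float | None = None
    icc_ci: tuple[float, float] | None = None
    pearson_r: float | None = None
    pearson_p: float | None = None
    band: str | None = None


def spearman_stage_correlation(data: StagedMeasurements, parameter: str
                               ) -> tuple[float, float]:
    """Spearman rank correlation of a parameter with fibrosis stage.

    Average-rank tie handling; p from the t approximation with n-2 df.
    """
    x = data.values(parameter)
    y = data.stages
    if len(x) < 3 or len(np.unique(y)) < 2:
        raise ValueError("need >= 3 observations over >= 2 stages")
    if np.ptp(x) == 0:
        raise ValueError("parameter is constant; correlation undefined")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def mann_whitney(group_a, group_b, family_size: int = 1) -> TestResult:
    """Two-sided Mann–Whitney U test with Bonferroni correction.

    The p-value is exact (full enumeration) when n1*n2 <= 400 and the
    pooled sample is tie-free — which covers every group pair at the
    published group sizes — and otherwise uses the normal approximation
    with tie and continuity corrections.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    pooled = np.concatenate([a, b])
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(a) * len(b) <= 400 and tie_free) \
        else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    p_raw = float(res.pvalue)
    return TestResult(
        statistic=float(res.statistic), p_raw=p_raw,
        p_bonferroni=min(1.0, p_raw * family_size),
        n1=len(a), n2=len(b), family_size=family_size)


def grouped_stage_tests(data: StagedMeasurements, parameter: str,
                        family_size: int = 4) -> dict[str, TestResult]:
    """Mann–Whitney tests for the four grouped-stage splits.

    ``family_size`` is the Bonferroni family (default: the 4 splits of one
    parameter; widen it when several parameters are tested jointly).
    """
    x = data.values(parameter)
    s = data.stages
    out: dict[str, TestResult] = {}
    for label, low_stages in GROUPED_SPLITS.items():
        low = x[np.isin(s, low_stages)]
        high = x[~np.isin(s, low_stages)]
        if len(low) == 0 or len(high) == 0:
            raise ValueError(f"split '{label}' has an empty side")
        out[label] = mann_whitney(low, high, family_size=family_size)
    return out


def rank_auc(negatives, positives) -> float:
    """Empirical AUC by the rank (Mann–Whitney) method, ties count 1/2."""
    neg = np.asarray(negatives, dtype=float)
    pos = np.asarray(positives, dtype=float)
    if len(neg) == 0 or len(pos) == 0:
        raise ValueError("both classes must be non-empty")
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[:len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def roc_analysis(data: StagedMeasurements, parameter: str,
                 split: str) -> RocResult:
    """ROC analysis of one parameter for one stage split.

    The positive class is the higher-stage side.  The AUC is oriented to
    >= 0.5 and the orientation recorded as the polarity.  The cutoff
    maximizes the Youden index (sensitivity + specificity - 1) over the
    observed values, ties broken toward higher specificity.
    """
    if split not in SPLITS:
        raise ValueError(f"unknown split '{split}'")
    x = data.values(parameter)
    s = data.stages
    pos = x[s >= SPLITS[split]]
    neg = x[s < SPLITS[split]]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("single-class input")
    auc = rank_auc(neg, pos)
    if auc >= 0.5:
        polarity, scores_pos, scores_neg = "higher-is-positive", pos, neg
    else:
        polarity, scores_pos, scores_neg = "lower-is-positive", -pos, -neg
        auc = 1.0 - auc

    best = None
    for c in np.unique(np.concatenate([scores_pos, scores_neg])):
        sens = float(np.mean(scores_pos >= c))
        spec = float(np.mean(scores_neg < c))
        key = (sens + spec - 1.0, spec)
        if best is None or key > best[0]:
            best = (key, c, sens, spec)
    _, cut, sens, spec = best
    cutoff = -cut if polarity == "lower-is-positive" else cut
    return RocResult(split=split, auc=auc, cutoff=float(cutoff),
                     sensitivity=100.0 * sens, specificity=100.0 * spec,
                     polarity=polarity,
                     n_positive=len(pos), n_negative=len(neg))


def apply_cutoff(values, roc: RocResult) -> np.ndarray:
    """Predicted positive-class labels from a RocResult's cutoff rule."""
    v = np.asarray(values, dtype=float)
    if roc.polarity == "higher-is-positive":
        return v >= roc.cutoff
    return v <= roc.cutoff


def icc_interobserver(obs1, obs2) -> AgreementResult:
    """Inter-observer agreement: two-way random-effects, absolute-agreement,
    single-measure ICC (ICC2 / ICC(A,1)) with a 95% CI from F bounds."""
    a = np.asarray(obs1, dtype=float)
    b = np.asarray(obs2, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need paired 1-D samples with n >= 3")
    if np.ptp(np.concatenate([a, b])) == 0:
        raise ValueError("zero total variance; ICC undefined")
    import pingouin as pg

    n = len(a)
    df = pd.DataFrame({
        "target": np.tile(np.arange(n), 2),
        "rater": np.repeat(["A", "B"], n),
        "score": np.concatenate([a, b]),
    })
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = pg.intraclass_corr(df, targets="target", raters="rater",
                                   ratings="score")
    row = table.loc[table["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
    ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
    lo, hi = (float(v) for v in row[ci_col])
    return AgreementResult(icc=float(row["ICC"]), icc_ci=(lo, hi))


def pearson_intraobserver(meas1, meas2) -> tuple[float, float]:
    """Intra-observer agreement: Pearson r with t-based p (n-2 df)."""
    a = np.asarray(meas1, dtype=float)
    b = np.asarray(meas2, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need paired 1-D samples with n >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance; correlation undefined")
    res = sps.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)


def kappa_band(kappa: float) -> str:
    """Kundel interpretation band for a kappa value.

    Bands partition [-1, 1] with closed upper bounds: poor < 0.41,
    moderate 0.41–0.60, good 0.61–0.80 (i.e. (0.60, 0.80]),
    excellent (0.80, 1.00].
    """
    if not -1.0 <= kappa <= 1.0:
        raise ValueError("kappa must lie in [-1, 1]")
    if kappa < 0.41:
        return "poor"
    if kappa <= 0.60:
        return "moderate"
    if kappa <= 0.80:
        return "good"
    return "excellent"


def cohen_kappa(labels_a, labels_b) -> AgreementResult:
    """Unweighted Cohen's kappa with an asymptotic 95% CI and Kundel band."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need paired 1-D label vectors")
    cats = np.unique(np.concatenate([a, b]))
    if len(cats) < 2:
        raise ValueError("only one category present; "
                         "expected agreement is 1 and kappa undefined")
    table = pd.crosstab(pd.Categorical(a, categories=cats),
                        pd.Categorical(b, categories=cats),
                        dropna=False).to_numpy()
    from statsmodels.stats.inter_rater import cohens_kappa

    res = cohens_kappa(table, return_results=True)
    k = float(res.kappa)
    lo, hi = float(res.kappa_low), float(res.kappa_upp)
    band = kappa_band(max(-1.0, min(1.0, k)))
    return AgreementResult(kappa=k, kappa_ci=(lo, hi), band=band)


# ---------------------------------------------------------------------------
# report

def staging_report(cohort: pd.DataFrame,
                   parameters: tuple[str, ...] = PARAMETERS,
                   grouped_family_size: int = 4,
                   dedup: bool = True) -> dict:
    """Full staging analysis of a cohort table as a structured report.

    Sections: per-stage group means +/- SD with deduplicated group sizes,
    Spearman correlation per parameter, grouped-stage Mann–Whitney p-values
    (raw and Bonferroni), and the four ROC splits per parameter.  Constant
    parameters are flagged uninformative (AUC 0.5, no correlation).
    """
    required = {"stage", *parameters}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    data = StagedMeasurements.from_frame(cohort, dedup=dedup)

    group_stats = []
    for stage in range(5):
        sel = data.frame.loc[data.stages == stage]
        row = {"stage": stage, "n": int(len(sel))}
        for p in parameters:
            vals = sel[p].to_numpy(dtype=float)
            row[f"{p}_mean"] = float(vals.mean()) if len(vals) else None
            row[f"{p}_sd"] = float(vals.std(ddof=1)) \
                if len(vals) > 1 else None
        group_stats.append(row)

    correlations = {}
    grouped = {}
    roc = {}
    for p in parameters:
        uninformative = np.ptp(data.values(p)) == 0
        if uninformative:
            correlations[p] = {"rho": None, "p": None,
                               "uninformative": True}
        else:
            rho, pval = spearman_stage_correlation(data, p)
            correlations[p] = {"rho": rho, "p": pval,
                               "uninformative": False}
        grouped[p] = {
            label: {"U": r.statistic, "p_raw": r.p_raw,
                    "p_bonferroni": r.p_bonferroni,
                    "n1": r.n1, "n2": r.n2}
            for label, r in grouped_stage_tests(
                data, p, family_size=grouped_family_size).items()}
        roc[p] = {}
        for split in SPLITS:
            r = roc_analysis(data, p, split)
            roc[p][split] = {
                "auc": r.auc, "cutoff": r.cutoff,
                "sensitivity_pct": r.sensitivity,
                "specificity_pct": r.specificity,
                "polarity": r.polarity,
                "n_positive": r.n_positive, "n_negative": r.n_negative,
                "uninformative": bool(uninformative)}

    return {
        "n_observations": int(len(data.frame)),
        "group_sizes": [row["n"] for row in group_stats],
        "group_stats": group_stats,
        "spearman": correlations,
        "grouped_tests": grouped,
        "roc": roc,
    }
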