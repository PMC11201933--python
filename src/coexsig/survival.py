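"""Group comparisons of enrichment scores and median-split survival.

Test choice is gated on Shapiro–Wilk normality (alpha 0.05): two groups
get a t-test or a Wilcoxon rank-sum; three or more get ANOVA or
Kruskal–Wallis plus all pairwise two-group tests. Survival stratifies each
signature's scores at the cohort median and compares high vs. low with
Kaplan–Meier curves, the log-rank test and the median survival difference
(MSD = median(high) − median(low)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

log = logging.getLogger(__name__)

ALPHA_NORMALITY = 0.05
EXACT_WILCOXON_MAX_N = 25


@dataclass
class GroupComparison:
    grouping: str
    test: str                       # "t" | "wilcoxon" | "anova" | "kruskal"
    statistic: float
    p: float
    summary: pd.DataFrame           # per-group n / mean / sd / median / iqr
    pairwise: pd.DataFrame | None = None
    alpha_normality: float = ALPHA_NORMALITY

    @property
    def significant(self) -> bool:
        return self.p < 0.05


@dataclass
class SurvivalResult:
    signature: str
    threshold: float
    n_high: int
    n_low: int
    median_high: float | None
    median_low: float | None
    logrank_statistic: float
    p: float

    @property
    def msd(self) -> float | None:
        """Median survival difference, high − low; None if either KM
        median is undefined (survival never drops to 0.5)."""
        if self.median_high is None or self.median_low is None:
            return None
        return self.median_high - self.median_low


def split_cohort(sample_ids: Sequence[str], proportion: float = 0.5,
                 seed: int = 17) -> tuple[list[str], list[str]]:
    """Random disjoint exhaustive split; with an odd count the extra
    sample goes to the first (training) partition."""
    ids = list(sample_ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 samples to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_train = int(np.ceil(len(ids) * proportion))
    train = [ids[i] for i in sorted(order[:n_train])]
    valid = [ids[i] for i in sorted(order[n_train:])]
    return train, valid


def _all_normal(groups: Sequence[np.ndarray], alpha: float) -> bool:
    """Every group passes Shapiro–Wilk. Groups too small or constant are
    treated as non-normal (the nonparametric branch is the safe one)."""
    for g in groups:
        if len(g) < 3 or np.ptp(g) == 0:
            return False
        if stats.shapiro(g).pvalue <= alpha:
            return False
    return True


def _two_group(x: np.ndarray, y: np.ndarray, normal: bool) -> tuple[str, float, float]:
    if normal:
        res = stats.ttest_ind(x, y)
        return "t", float(res.statistic), float(res.pvalue)
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (max(len(x), len(y)) <= EXACT_WILCOXON_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return "wilcoxon", float(res.statistic), float(res.pvalue)


def compare_groups(scores: Mapping[str, float] | pd.Series,
                   labels: Mapping[str, str] | pd.Series,
                   grouping: str = "group",
                   alpha_normality: float = ALPHA_NORMALITY) -> GroupComparison:
    """Compare one signature's scores across labeled sample groups.

    The test is a pure function of the group count and the Shapiro–Wilk
    gate; with >= 3 groups every pairwise comparison is also reported.
    """
    s = pd.Series(scores, dtype=float)
    lab = pd.Series(labels)
    common = s.index.intersection(lab.index)
    if len(common) < len(s):
        log.info("compare_groups: %d sample(s) without a label dropped", len(s) - len(common))
    s, lab = s.loc[common], lab.loc[common]
    names = sorted(lab.dropna().unique().tolist())
    groups = [s[lab == name].to_numpy() for name in names]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need at least 2 non-empty groups")

    summary = pd.DataFrame({
        "group": names,
        "n": [len(g) for g in groups],
        "mean": [float(np.mean(g)) for g in groups],
        "sd": [float(np.std(g, ddof=1)) if len(g) > 1 else np.nan for g in groups],
        "median": [float(np.median(g)) for g in groups],
        "iqr": [float(np.subtract(*np.percentile(g, [75, 25]))) for g in groups],
    }).set_index("group")

    normal = _all_normal(groups, alpha_normality)
    if len(groups) == 2:
        test, stat, p = _two_group(groups[0], groups[1], normal)
        pairwise = None
    else:
        if normal:
            res = stats.f_oneway(*groups)
            test = "anova"
        else:
            res = stats.kruskal(*groups)
            test = "kruskal"
        stat, p = float(res.statistic), float(res.pvalue)
        rows = []
        for (i, a), (j, b) in combinations(enumerate(names), 2):
            pw_normal = _all_normal([groups[i], groups[j]], alpha_normality)
            pw_test, pw_stat, pw_p = _two_group(groups[i], groups[j], pw_normal)
            rows.append({"group_a": a, "group_b": b, "test": pw_test,
                         "statistic": pw_stat, "p": pw_p})
        pairwise = pd.DataFrame(rows)
    return GroupComparison(grouping=grouping, test=test, statistic=stat, p=p,
                           summary=summary, pairwise=pairwise,
                           alpha_normality=alpha_normality)


def km_estimate(times: Sequence[float], events: Sequence[int]
                ) -> tuple[pd.DataFrame, float | None]:
    """Kaplan–Meier product-limit estimate and median survival.

    Median = smallest time with S(t) <= 0.5; ``None`` when the curve never
    reaches 0.5 (heavy censoring).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if (times <= 0).any():
        raise ValueError("survival times must be > 0")
    if not np.isin(events, [0, 1]).all():
        raise ValueError("events must be 0 or 1")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    curve = kmf.survival_function_.rename(columns={"KM_estimate": "survival"})
    med = kmf.median_survival_time_
    return curve, (None if np.isinf(med) else float(med))


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and its upper-tail p-value."""
    res = _ll_logrank(times_a, times_b, event_observed_A=events_a,
                      event_observed_B=events_b)
    return float(res.test_statistic), float(res.p_value)


def median_split_survival(scores: Mapping[str, float] | pd.Series,
                          clinical: pd.DataFrame,
                          signature: str = "signature") -> SurvivalResult:
    """Stratify samples at the median score and compare survival.

    High = score strictly above the median; scores exactly at the median
    go to the low group. Samples lacking survival data are dropped with a
    logged count.
    """
    s = pd.Series(scores, dtype=float)
    clin = clinical.loc[clinical.index.intersection(s.index)]
    clin = clin.dropna(subset=["survival_time", "event"])
    dropped = len(s) - len(clin)
    if dropped:
        log.info("median_split_survival: %d sample(s) without survival data dropped", dropped)
    s = s.loc[clin.index]
    if len(s) < 2:
        raise ValueError("need at least 2 samples with survival data")
    threshold = float(s.median())
    high = s.index[s > threshold]
    low = s.index[s <= threshold]
    if len(high) == 0 or len(low) == 0:
        raise ValueError("median split produced an empty group (constant scores?)")
    t_hi, e_hi = clin.loc[high, "survival_time"], clin.loc[high, "event"]
    t_lo, e_lo = clin.loc[low, "survival_time"], clin.loc[low, "event"]
    _, med_hi = km_estimate(t_hi, e_hi)
    _, med_lo = km_estimate(t_lo, e_lo)
    stat, p = logrank_test(t_hi, e_hi, t_lo, e_lo)
    return SurvivalResult(signature=signature, threshold=threshold,
                          n_high=len(high), n_low=len(low),
                          median_high=med_hi, median_low=med_lo,
                          logrank_statistic=stat, p=p)


def survival_screen(scores: pd.DataFrame, clinical: pd.DataFrame,
                    adjust: bool = False) -> pd.DataFrame:
    """Median-split survival for every signature row of a score matrix.

    Raw log-rank p-values by default; ``adjust=True`` adds a BH column.
    """
    rows = []
    for sig, s in scores.iterrows():
        res = median_split_survival(s, clinical, signature=str(sig))
        rows.append({
            "signature": res.signature, "threshold": res.threshold,
            "n_high": res.n_high, "n_low": res.n_low,
            "median_high": res.median_high, "median_low": res.median_low,
            "msd": res.msd, "logrank_statistic": res.logrank_statistic,
            "p": res.p,
        })
    out = pd.DataFrame(rows).set_index("signature")
    if adjust and not out.empty:
        from statsmodels.stats.multitest import multipletests
        out["p_adj"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out


def paired_tumor_normal(scores: pd.DataFrame, clinical: pd.DataFrame) -> pd.DataFrame:
    """Paired tumor vs. non-tumor comparison per signature.

    Uses the ``paired_nontumor_id`` column to link each tumor sample to
    its patient-matched non-tumor sample; unpaired samples are excluded
    with a logged count. Reports the Wilcoxon signed-rank p per signature.
    """
    if "paired_nontumor_id" not in clinical.columns:
        raise ValueError("clinical table lacks a 'paired_nontumor_id' column")
    links = clinical["paired_nontumor_id"].dropna()
    pairs = [(t, n) for t, n in links.items()
             if t in scores.columns and n in scores.columns]
    n_unpaired = clinical.shape[0] - len(pairs)
    if n_unpaired:
        log.info("paired_tumor_normal: %d sample(s) without a usable pair excluded", n_unpaired)
    if not pairs:
        log.warning("paired_tumor_normal: no tumor/non-tumor pairs found")
        return pd.DataFrame(columns=["n_pairs", "mean_diff", "statistic", "p"])
    rows = []
    for sig, s in scores.iterrows():
        tumor = np.array([s[t] for t, _ in pairs], dtype=float)
        normal = np.array([s[n] for _, n in pairs], dtype=float)
        diff = tumor - normal
        if np.all(diff == 0):
            stat, p = 0.0, 1.0
        else:
            res = stats.wilcoxon(tumor, normal)
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append({"signature": str(sig), "n_pairs": len(pairs),
                     "mean_diff": float(diff.mean()), "statistic": stat, "p": p})
    return pd.DataFrame(rows).set_index("signature")
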