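"""Lesion correlation and progressive-IFTA analysis.

Group-comparison statistics (Welch t, Mann-Whitney U, Kruskal-Wallis),
Pearson/Spearman correlation of the tCRM score with Banff lesion grades,
exhaustive best-subset linear regression of the progressor indicator on
log2 fold changes scored by adjusted R^2, and the paired 6- vs 24-month
longitudinal comparison.

The "influence" analysis regresses the binary progressor indicator on gene
log2 fold changes by ordinary least squares for every non-empty subset of
the 11 genes (2047 models) and ranks subsets by adjusted
R^2 = 1 - (1 - R^2)(n - 1)/(n - p - 1).  Exhaustive search is exact and
cheap at this scale and avoids stepwise path dependence.  No
multiple-testing correction is applied anywhere; significance is read at
p < 0.05.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import Phenotype

__all__ = [
    "GroupTest",
    "CorrelationMethod",
    "GroupComparison",
    "CorrelationResult",
    "SubsetSelectionResult",
    "compare_groups",
    "correlate",
    "adjusted_r2",
    "best_subset_by_adjusted_r2",
    "longitudinal_compare",
]


class GroupTest(str, enum.Enum):
    WELCH_T = "WELCH_T"
    MANN_WHITNEY = "MANN_WHITNEY"
    KRUSKAL_WALLIS = "KRUSKAL_WALLIS"


class CorrelationMethod(str, enum.Enum):
    PEARSON = "PEARSON"
    SPEARMAN = "SPEARMAN"


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    test: GroupTest
    statistic: float
    p_value: float
    exact_separation: bool = False  # both groups constant but unequal


@dataclass
class CorrelationResult:
    method: CorrelationMethod
    r: float
    p_value: float
    n: int


@dataclass
class SubsetSelectionResult:
    best_subset: tuple[str, ...]
    best_adjusted_r2: float
    per_gene_single_r2: dict[str, float]
    search_log: pd.DataFrame  # one row per evaluated subset


def _sem(x: np.ndarray) -> float:
    if x.size < 2:
        return float("nan")
    return float(np.std(x, ddof=1) / np.sqrt(x.size))


def compare_groups(
    values_a,
    values_b,
    test: GroupTest = GroupTest.MANN_WHITNEY,
    label_a: str = "A",
    label_b: str = "B",
) -> GroupComparison:
    """Two-sided comparison of two independent groups.

    Reports means +- SEM and the requested test's statistic and p-value
    (delegated to scipy).  Degenerate inputs: two constant, unequal groups
    are reported as exact separation (no finite test statistic); identical
    constant groups give p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    test = GroupTest(test)
    mean_a, mean_b = float(a.mean()), float(b.mean())
    exact_sep = False
    if a.std() == 0 and b.std() == 0:
        if mean_a == mean_b:
            stat, p = 0.0, 1.0
        else:
            stat, p = float("inf"), float("nan")
            exact_sep = True
    elif test is GroupTest.WELCH_T:
        stat, p = stats.ttest_ind(a, b, equal_var=False)
    elif test is GroupTest.MANN_WHITNEY:
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        stat, p = stats.kruskal(a, b)
    return GroupComparison(
        group_a=label_a,
        group_b=label_b,
        n_a=a.size,
        n_b=b.size,
        mean_a=mean_a,
        sem_a=_sem(a),
        mean_b=mean_b,
        sem_b=_sem(b),
        test=test,
        statistic=float(stat),
        p_value=float(p),
        exact_separation=exact_sep,
    )


def correlate(
    x, y, method: CorrelationMethod = CorrelationMethod.PEARSON
) -> CorrelationResult:
    """Bivariate correlation with two-sided p-value.

    Spearman uses midranks for ties, appropriate for ordinal Banff grades
    (treated as numeric 0-3).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if x.size < 3:
        raise ValueError("correlation requires n >= 3")
    method = CorrelationMethod(method)
    if method is CorrelationMethod.PEARSON:
        r, p = stats.pearsonr(x, y)
    else:
        r, p = stats.spearmanr(x, y)
    return CorrelationResult(method=method, r=float(r), p_value=float(p),
                             n=int(x.size))


def adjusted_r2(outcome, predictors) -> float:
    """Adjusted R^2 of an OLS fit (intercept included implicitly).

    ``outcome`` is typically the 0/1 progressor indicator; ``predictors`` a
    (n, p) matrix of log2 fold changes.  Undefined when n - p - 1 <= 0.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.atleast_2d(np.asarray(predictors, dtype=float))
    if x.shape[0] != y.shape[0]:
        x = x.T
    n, p = x.shape
    if n - p - 1 <= 0:
        raise ValueError(f"adjusted R^2 undefined for n={n}, p={p}")
    yc = y - y.mean()
    xc = x - x.mean(axis=0)
    sst = float(yc @ yc)
    if sst == 0:
        raise ValueError("constant outcome")
    coef, *_ = np.linalg.lstsq(xc, yc, rcond=None)
    resid = yc - xc @ coef
    r2 = 1.0 - float(resid @ resid) / sst
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def best_subset_by_adjusted_r2(
    log2_fc: pd.DataFrame, outcome
) -> SubsetSelectionResult:
    """Exhaustive adjusted-R^2 best-subset search over gene columns.

    Evaluates all 2^G - 1 non-empty subsets of the columns of ``log2_fc``
    against the binary ``outcome``; ties are broken toward the smaller
    subset, then lexicographically.  ``per_gene_single_r2`` ranks single-gene
    influence (the top entry is the "maximal influence" gene).
    """
    y = np.asarray(outcome, dtype=float)
    genes = list(log2_fc.columns)
    x_all = log2_fc.to_numpy(dtype=float)
    if x_all.shape[0] != y.shape[0]:
        raise ValueError("outcome length must match number of samples")
    yc = y - y.mean()
    xc = x_all - x_all.mean(axis=0)
    sst = float(yc @ yc)
    n = y.size
    records = []
    best_subset: tuple[str, ...] = ()
    best_value = -np.inf
    for size in range(1, len(genes) + 1):
        for combo in itertools.combinations(range(len(genes)), size):
            xs = xc[:, combo]
            coef, *_ = np.linalg.lstsq(xs, yc, rcond=None)
            resid = yc - xs @ coef
            r2 = 1.0 - float(resid @ resid) / sst
            adj = 1.0 - (1.0 - r2) * (n - 1) / (n - size - 1)
            subset = tuple(genes[i] for i in combo)
            records.append({"subset": subset, "size": size,
                            "adjusted_r2": adj})
            # argmax; ties -> smaller subset, then lexicographic
            if adj > best_value or (
                adj == best_value
                and (size, subset) < (len(best_subset), best_subset)
            ):
                best_value = adj
                best_subset = subset
    log = pd.DataFrame(records)
    singles = {
        rec["subset"][0]: rec["adjusted_r2"]
        for rec in records
        if rec["size"] == 1
    }
    singles = dict(sorted(singles.items(), key=lambda kv: -kv[1]))
    return SubsetSelectionResult(
        best_subset=best_subset,
        best_adjusted_r2=float(best_value),
        per_gene_single_r2=singles,
        search_log=log,
    )


def longitudinal_compare(
    scores: pd.DataFrame, samples: pd.DataFrame
) -> dict[str, GroupComparison | dict]:
    """Progressor-vs-non-progressor comparison of the paired protocol arm.

    Expects one 6-month and one 24-month biopsy per patient.  Reports the
    cross-sectional P-vs-NP Mann-Whitney comparison at each timepoint plus
    the within-arm paired 6->24-month Wilcoxon signed-rank test.
    """
    meta = samples[
        samples["phenotype"].isin(
            (Phenotype.PIFTA_P.value, Phenotype.PIFTA_NP.value)
        )
    ]
    merged = meta.merge(scores, on="sample_id", how="left")
    if merged["tcrm"].isna().any():
        missing = merged.loc[merged["tcrm"].isna(), "sample_id"].tolist()
        raise ValueError(f"missing scores for longitudinal samples: {missing}")
    for patient, group in merged.groupby("patient_id"):
        tps = sorted(group["timepoint_months"].tolist())
        if tps != [6.0, 24.0]:
            raise ValueError(
                f"patient {patient} lacks a complete 6/24-month pair "
                f"(timepoints {tps})"
            )

    def cell(phen: str, tp: float) -> pd.DataFrame:
        sel = merged[(merged["phenotype"] == phen)
                     & (merged["timepoint_months"] == tp)]
        return sel.sort_values("patient_id")

    out: dict[str, GroupComparison | dict] = {}
    for tp in (6.0, 24.0):
        p_scores = cell(Phenotype.PIFTA_P.value, tp)["tcrm"].to_numpy()
        np_scores = cell(Phenotype.PIFTA_NP.value, tp)["tcrm"].to_numpy()
        out[f"p_vs_np_{int(tp)}m"] = compare_groups(
            p_scores, np_scores, GroupTest.MANN_WHITNEY,
            label_a="PIFTA_P", label_b="PIFTA_NP",
        )
    for phen, name in ((Phenotype.PIFTA_P.value, "progressor"),
                       (Phenotype.PIFTA_NP.value, "non_progressor")):
        s6 = cell(phen, 6.0).set_index("patient_id")["tcrm"]
        s24 = cell(phen, 24.0).set_index("patient_id")["tcrm"]
        diff = (s24 - s6.reindex(s24.index)).to_numpy()
        if np.allclose(diff, 0.0):
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.wilcoxon(diff)
        out[f"paired_6_to_24_{name}"] = {
            "n": int(diff.size),
            "statistic": float(stat),
            "p_value": float(p),
            "mean_6m": float(s6.mean()),
            "mean_24m": float(s24.mean()),
        }
    return out
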