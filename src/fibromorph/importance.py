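"""Feature-importance analysis for the disease task on engineered features.

Per (model architecture, fold) rankings — impurity importance for forests,
absolute coefficients for linear models — are intersected at a top-K
threshold chosen as the smallest multiple of 20 whose cross-validated AUC
stays within one cross-fold SD of the full-feature AUC.  The common set is
then pruned greedily at a Pearson |r| threshold of 0.75 over line-level
values, grouped semantically by measurement family and compartment/channel,
and tested for control-vs-PD-subgroup differences with two-sided
Mann-Whitney U tests, Bonferroni adjusted for the 2 comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, pearsonr

from .features import FeatureName


@dataclass
class RankedFeatureList:
    """Features of one (model, fold), most important first."""

    model_kind: str
    fold: int
    features: list
    scores: np.ndarray

    def __post_init__(self):
        if len(self.features) != len(self.scores):
            raise ValueError("features and scores must have equal length")
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("scores must be nonincreasing")

    def top(self, k: int) -> set:
        return set(self.features[:k])


def rank_features(estimator, feature_names, model_kind: str,
                  fold: int) -> RankedFeatureList:
    """Rank features of a fitted model: impurity importance for forests,
    |coefficient| (summed over classes) for linear models."""
    if hasattr(estimator, "feature_importances_"):
        scores = np.asarray(estimator.feature_importances_, dtype=float)
    elif hasattr(estimator, "coef_"):
        coef = np.atleast_2d(estimator.coef_)
        scores = np.abs(coef).sum(axis=0)
    else:
        raise ValueError("estimator is not fitted or exposes no importances")
    if len(scores) != len(feature_names):
        raise ValueError("feature_names length does not match the model")
    order = np.argsort(-scores, kind="stable")
    return RankedFeatureList(model_kind, fold,
                             [feature_names[i] for i in order], scores[order])


def topk_threshold(ranked: RankedFeatureList, evaluator, step: int = 20,
                   full_performance: tuple[float, float] | None = None):
    """Smallest K (multiple of ``step``) whose cross-validated AUC is within
    one cross-fold SD of the all-features AUC.

    ``evaluator(features)`` returns ``(mean_auc, sd_auc)`` over folds.  If no
    K reaches the band, returns the full feature count with ``reached=False``.
    """
    n = len(ranked.features)
    full_mean, full_sd = (full_performance if full_performance is not None
                          else evaluator(ranked.features))
    for k in range(step, n, step):
        mean_k, _ = evaluator(ranked.features[:k])
        if mean_k >= full_mean - full_sd:
            return k, True
    # only the full set maintains performance: no reduced K exists
    return n, False


def intersect_top(lists: list[RankedFeatureList], k: int) -> set:
    """Features present in the top K of every (model, fold) list."""
    if not lists:
        raise ValueError("need at least one ranked list")
    common = lists[0].top(k)
    for lst in lists[1:]:
        common &= lst.top(k)
    return common


def prune_correlated(features: list, values: pd.DataFrame,
                     threshold: float = 0.75) -> tuple[list, list]:
    """Greedy pass in rank order over line-level values: drop a feature whose
    |Pearson r| with any already-kept feature exceeds the threshold.

    Constant features (undefined correlation) are dropped and flagged.
    Returns ``(kept, dropped_constant)``.
    """
    kept: list = []
    constant: list = []
    for f in features:
        x = values[f].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            constant.append(f)
            continue
        ok = True
        for g in kept:
            r = pearsonr(x, values[g].to_numpy(dtype=float)).statistic
            if abs(r) > threshold:
                ok = False
                break
        if ok:
            kept.append(f)
    return kept, constant


def group_features(names) -> tuple[pd.DataFrame, list]:
    """Counts per (family, compartment-or-channel) group.

    Channel-scoped features group by channel; channel-free ones by
    compartment.  Unparseable names are returned separately, never dropped
    silently."""
    counts: dict = {}
    bad = []
    for name in names:
        try:
            fn = FeatureName.parse(name)
        except ValueError:
            bad.append(name)
            continue
        origin = fn.channel if fn.channel != "none" else fn.compartment
        key = (fn.family, origin)
        counts[key] = counts.get(key, 0) + 1
    table = pd.DataFrame(
        [{"family": k[0], "origin": k[1], "count": v} for k, v in sorted(counts.items())]
    )
    return table, bad


def group_difference_tests(line_values: pd.DataFrame, groups: pd.Series,
                           features=None) -> pd.DataFrame:
    """Two-sided Mann-Whitney U per feature for control vs sporadic and
    control vs LRRK2, Bonferroni adjusted for the 2 comparisons; exact P for
    group sizes <= 10, normal approximation with tie correction otherwise."""
    features = list(features) if features is not None else [
        c for c in line_values.columns if c != "line_id"]
    groups = groups.astype(str)
    ctrl = line_values[groups == "none"]
    rows = []
    for comparison in ("sporadic", "LRRK2"):
        other = line_values[groups == comparison]
        if len(ctrl) < 2 or len(other) < 2:
            raise ValueError(f"group of size < 2 in comparison {comparison!r}")
        method = "exact" if max(len(ctrl), len(other)) <= 10 else "asymptotic"
        for f in features:
            res = mannwhitneyu(ctrl[f], other[f], alternative="two-sided",
                               method=method)
            p_adj = min(1.0, 2.0 * float(res.pvalue))
            rows.append({
                "feature": f, "comparison": f"control_vs_{comparison}",
                "U": float(res.statistic), "p_raw": float(res.pvalue),
                "p_bonferroni": p_adj, "stars": _stars(p_adj),
            })
    return pd.DataFrame(rows)


def _stars(p: float) -> str:
    if p <= 1e-4:
        return "****"
    if p <= 1e-3:
        return "***"
    if p <= 1e-2:
        return "**"
    if p <= 5e-2:
        return "*"
    return "ns"


@dataclass
class ImportanceReport:
    selected_k: int
    reached_band: bool
    common: set
    kept: list
    dropped_constant: list
    group_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    unparseable: list = field(default_factory=list)
    tests: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_dict(self) -> dict:
        return {
            "selected_k": self.selected_k,
            "reached_band": self.reached_band,
            "n_common": len(self.common),
            "common": sorted(self.common),
            "kept": list(self.kept),
            "dropped_constant": list(self.dropped_constant),
            "groups": self.group_table.to_dict(orient="records"),
            "unparseable": list(self.unparseable),
        }


def importance_report(lists: list[RankedFeatureList], k: int,
                      line_values: pd.DataFrame,
                      groups: pd.Series | None = None,
                      threshold: float = 0.75,
                      reached_band: bool = True) -> ImportanceReport:
    """Intersection + pruning + grouping (+ group tests when disease-group
    labels are provided) in one pass; the pruning order is the mean rank of
    each common feature across the lists."""
    common = intersect_top(lists, k)
    mean_rank = {
        f: np.mean([lst.features.index(f) for lst in lists]) for f in common
    }
    ordered = sorted(common, key=lambda f: (mean_rank[f], f))
    kept, constant = prune_correlated(ordered, line_values, threshold)
    table, bad = group_features(kept)
    report = ImportanceReport(k, reached_band, common, kept, constant, table, bad)
    if groups is not None and len(kept):
        report.tests = group_difference_tests(line_values, groups, kept)
    return report
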