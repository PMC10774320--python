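"""Cohort-level utilities: set overlap, outlier screening, stratification, survival.

These are the downstream validation helpers of the pipeline: compositional
overlap of gene sets (to show an activity association is not a set-overlap
artifact), Cook's-distance screening before activity-activity regressions,
two-group stratification of patients on a (pathway NES, TR NES) plane with
threshold transfer to sibling cohorts, and thin wrappers around log-rank /
Cox proportional-hazards evaluation of the resulting groups.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test
from sklearn.base import BaseEstimator
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.metrics import roc_auc_score

from .datatypes import GeneSet, OverlapReport, StratificationResult, SurvivalEvaluation

logger = logging.getLogger(__name__)

__all__ = ["jaccard_index", "cooks_outliers", "stratify_two_groups",
           "apply_thresholds", "evaluate_stratification", "binary_response_auc",
           "TwoGroupStratifier"]


def jaccard_index(set_a: GeneSet, set_b: GeneSet,
                  denominator: str = "sum") -> OverlapReport:
    """Compositional overlap of two gene collections.

    ``denominator='sum'`` divides the intersection by ``|A| + |B|`` (the
    convention used throughout this package); ``'union'`` gives the classical
    Jaccard ``|A ∩ B| / |A ∪ B|``. Note the sum convention caps at 0.5 for
    identical sets.
    """
    if denominator not in ("sum", "union"):
        raise ValueError(f"unknown denominator convention {denominator!r}")
    a, b = set(set_a.genes), set(set_b.genes)
    common = len(a & b)
    denom = len(a) + len(b) if denominator == "sum" else len(a | b)
    return OverlapReport(size_a=len(a), size_b=len(b), n_common=common,
                         jaccard=common / denom, denominator=denominator)


def cooks_outliers(x, y, threshold_rule: str = "four_over_n",
                   threshold: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Cook's distances of a simple linear fit of ``y`` on ``x``.

    Returns ``(outlier_indices, distances)``; points are flagged when their
    distance exceeds ``4/n`` (default rule) or an ``absolute`` cutoff passed
    via ``threshold``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 4:
        raise ValueError("Cook's distance screen needs >= 4 points")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: degenerate fit")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    if fit.mse_resid <= 1e-12 * max(float(np.var(y)), 1e-12):
        # (near-)exact fit: Cook's D is 0/0, so no point is influential
        distances = np.zeros(n)
    else:
        distances = fit.get_influence().cooks_distance[0]
    if threshold_rule == "four_over_n":
        cut = 4.0 / n
    elif threshold_rule == "absolute":
        if threshold is None:
            raise ValueError("absolute rule needs an explicit threshold")
        cut = float(threshold)
    else:
        raise ValueError(f"unknown threshold rule {threshold_rule!r}")
    return np.where(distances > cut)[0], distances


def _as_pairs(activity_pairs) -> pd.DataFrame:
    pairs = pd.DataFrame(activity_pairs)
    if pairs.shape[1] != 2:
        raise ValueError("activity_pairs must have exactly two columns "
                         "(pathway NES, TR NES)")
    if not np.all(np.isfinite(pairs.to_numpy(dtype=float))):
        raise ValueError("activity_pairs must be finite")
    return pairs


def stratify_two_groups(activity_pairs, rng_seed: int = 0) -> StratificationResult:
    """Split samples into ``high_high`` vs ``other`` on the activity plane.

    K-means (k=2, seeded) supplies the labels; complete-linkage hierarchical
    clustering cut at two is run alongside and the fraction of identically
    assigned samples is reported as ``method_agreement``. The ``high_high``
    cluster is the one with the larger centroid coordinate sum, and the
    implied per-axis thresholds are the minima of each coordinate within it.
    """
    pairs = _as_pairs(activity_pairs)
    X = pairs.to_numpy(dtype=float)
    n = len(pairs)
    if n < 4:
        raise ValueError("stratification needs >= 4 samples")
    if np.ptp(X[:, 0]) == 0 or np.ptp(X[:, 1]) == 0:
        raise ValueError("degenerate spread: an axis is constant")
    km = KMeans(n_clusters=2, random_state=int(rng_seed), n_init=10).fit(X)
    hier = AgglomerativeClustering(n_clusters=2, linkage="complete").fit_predict(X)
    km_labels = km.labels_
    agreement = max(float(np.mean(km_labels == hier)),
                    float(np.mean(km_labels == 1 - hier)))
    high_cluster = int(np.argmax(km.cluster_centers_.sum(axis=1)))
    labels = pd.Series(np.where(km_labels == high_cluster, "high_high", "other"),
                       index=pairs.index, name="label")
    hh = X[km_labels == high_cluster]
    thresholds = (float(hh[:, 0].min()), float(hh[:, 1].min()))
    return StratificationResult(labels=labels, centroids=km.cluster_centers_,
                                method_agreement=agreement, thresholds=thresholds)


def apply_thresholds(activity_pairs, thresholds: tuple[float, float]) -> pd.Series:
    """Label samples ``high_high`` iff both coordinates reach their thresholds.

    The comparison is inclusive, so a point exactly at both cutoffs is
    ``high_high``; this is the transfer rule for scoring a sibling cohort with
    thresholds learned elsewhere.
    """
    pairs = _as_pairs(activity_pairs)
    t0, t1 = float(thresholds[0]), float(thresholds[1])
    hh = (pairs.iloc[:, 0] >= t0) & (pairs.iloc[:, 1] >= t1)
    return pd.Series(np.where(hh, "high_high", "other"), index=pairs.index, name="label")


def evaluate_stratification(labels, times, events, covariates=None) -> SurvivalEvaluation:
    """Log-rank test and Cox PH hazard ratio for ``high_high`` vs ``other``.

    ``covariates`` (optional samples x covariates frame) enters the Cox model
    as adjustment terms. A group without observed events is reported with a
    warning rather than an error.
    """
    labels = pd.Series(labels)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if np.any(times <= 0):
        raise ValueError("survival times must be positive")
    if not set(np.unique(events)).issubset({0, 1, False, True}):
        raise ValueError("events must be binary")
    groups = set(labels)
    if groups != {"high_high", "other"}:
        raise ValueError(f"labels must contain both groups, got {sorted(groups)}")
    events = events.astype(int)
    hh = (labels == "high_high").to_numpy()
    notes = []
    for name, mask in (("high_high", hh), ("other", ~hh)):
        if events[mask].sum() == 0:
            notes.append(f"group {name} has no observed events")
            logger.warning("evaluate_stratification: %s", notes[-1])
    lr = logrank_test(times[hh], times[~hh], event_observed_A=events[hh],
                      event_observed_B=events[~hh])
    df = pd.DataFrame({"time": times, "event": events,
                       "high_high": hh.astype(int)})
    covariate_names: list[str] = []
    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True)
        covariate_names = [str(c) for c in cov.columns]
        df = pd.concat([df, cov.set_axis(covariate_names, axis=1)], axis=1)
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event")
    row = cph.summary.loc["high_high"]
    return SurvivalEvaluation(logrank_p=float(lr.p_value),
                              hazard_ratio=float(row["exp(coef)"]),
                              ci_low=float(row["exp(coef) lower 95%"]),
                              ci_high=float(row["exp(coef) upper 95%"]),
                              covariates=covariate_names,
                              warnings=notes)


def binary_response_auc(activity_pairs, response) -> float:
    """AUROC of the product of the two activities against a binary response.

    The predictor is the elementwise product of pathway and TR activity (the
    multiplicative-model contract for binary-outcome cohorts).
    """
    pairs = _as_pairs(activity_pairs)
    response = np.asarray(response).astype(int)
    product = pairs.iloc[:, 0].to_numpy() * pairs.iloc[:, 1].to_numpy()
    return float(roc_auc_score(response, product))


class TwoGroupStratifier(BaseEstimator):
    """Estimator wrapper: fit k-means/hierarchical stratification, predict by threshold.

    ``fit(X)`` on a samples x 2 frame learns labels and per-axis thresholds;
    ``predict(X)`` applies the learned thresholds (inclusive) to new samples.
    """

    def __init__(self, random_state: int = 0):
        self.random_state = random_state

    def fit(self, X, y=None):
        res = stratify_two_groups(X, rng_seed=self.random_state)
        self.result_ = res
        self.labels_ = res.labels
        self.thresholds_ = res.thresholds
        self.method_agreement_ = res.method_agreement
        return self

    def predict(self, X) -> pd.Series:
        if not hasattr(self, "thresholds_"):
            raise AttributeError("TwoGroupStratifier is not fitted")
        return apply_thresholds(X, self.thresholds_)
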