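"""Prioritizing TR programs upstream of a pathway under multi-collinearity.

TR activity vectors upstream of one pathway are often strongly collinear
(shared targets, co-regulation), which makes their individual multivariable
regression coefficients uninterpretable. The strategy here:

1. *VIF screen* — quantify collinearity of each TR against the rest
   (VIF = 1/(1-R^2); VIF > 10 flags multi-collinearity) but keep all TRs.
2. *Latent variables* — build successive PLS-style latent variables: per
   component, each TR's weight is the univariate OLS slope of the (deflated)
   pathway vector on that (deflated) TR vector (weights normalized to unit
   norm), the component score is the weight-combined TR block, loadings are
   the multivariable OLS coefficients of the score on the TR block, and both
   block and response are deflated on the score before the next component.
   Successive scores are exactly uncorrelated.
3. *Circle of correlation* — place each TR and the pathway at the Pearson
   correlations of its activity vector with the first two component scores;
   angular proximity to the pathway arrow encodes similarity of effect.
4. *Grouping and effect scores* — cluster TRs on their angular closeness to
   the pathway, then rank groups on mean closeness, mean |r| with the latent
   axes, and mean bootstrap edge weight; the geometric mean of the three ranks
   is the group's effect score (lower = stronger prioritization).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.cluster import AgglomerativeClustering
from sklearn.linear_model import Ridge
from sklearn.metrics import silhouette_score

from ._utils import validate_expression
from .datatypes import CirclePoint, MechanismNetwork, TRGroup

logger = logging.getLogger(__name__)

__all__ = ["vif", "LatentComponent", "LatentModel", "pls_fit", "correlation_circle",
           "closeness_and_cluster", "effect_scores", "prioritize_trs",
           "PLSLatentRegression", "TRPrioritizer"]

_VAR_TOL = 1e-12


# ---------------------------------------------------------------------------
# VIF


def vif(tr_acts: pd.DataFrame) -> pd.DataFrame:
    """Variance inflation factor of each TR activity vector against the rest.

    Returns a frame indexed by TR with columns ``r_squared``, ``vif`` and
    ``method`` (``ols``, or ``ridge`` when there are not more samples than
    TRs and a small-ridge fallback is used). Perfectly collinear TRs get
    ``vif = inf`` with a warning.
    """
    validate_expression(tr_acts, min_samples=2, name="TR activities")
    m, n = tr_acts.shape
    if m < 2:
        raise ValueError("VIF needs at least 2 TRs")
    X = tr_acts.to_numpy(dtype=float).T  # samples x TRs
    exact = n > m
    if not exact:
        logger.warning("vif: %d TRs >= %d samples; using ridge fallback", m, n)
    rows = []
    for i, tr in enumerate(tr_acts.index):
        y = X[:, i]
        others = np.delete(X, i, axis=1)
        ss_tot = np.sum((y - y.mean()) ** 2)
        if ss_tot <= _VAR_TOL:
            raise ValueError(f"constant TR activity vector {tr!r}")
        if exact:
            design = np.column_stack([np.ones(n), others])
            coef, *_ = np.linalg.lstsq(design, y, rcond=None)
            resid = y - design @ coef
        else:
            model = Ridge(alpha=1e-3).fit(others, y)
            resid = y - model.predict(others)
        r2 = 1.0 - np.sum(resid**2) / ss_tot
        r2 = min(max(r2, 0.0), 1.0)
        if r2 >= 1.0 - 1e-12:
            warnings.warn(f"vif: TR {tr!r} is perfectly collinear with the rest")
            v = np.inf
        else:
            v = 1.0 / (1.0 - r2)
        rows.append((tr, r2, v, "ols" if exact else "ridge"))
    return pd.DataFrame(rows, columns=["tr", "r_squared", "vif", "method"]).set_index("tr")


# ---------------------------------------------------------------------------
# latent variables


@dataclass
class LatentComponent:
    """One latent variable: per-TR weights/loadings and per-sample scores."""

    weights: np.ndarray
    scores: np.ndarray
    loadings: np.ndarray
    r_with_pathway: float


@dataclass
class LatentModel:
    """Ordered latent components over a TR activity block."""

    tr_ids: list[str]
    components: list[LatentComponent]
    stop_reason: str | None = None
    sample_ids: list[str] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return len(self.components)

    def scores_matrix(self) -> np.ndarray:
        return np.column_stack([c.scores for c in self.components])


def _center(v: np.ndarray) -> np.ndarray:
    return v - v.mean(axis=0, keepdims=True) if v.ndim > 1 else v - v.mean()


def _deflate_on(v: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Residual of ``v`` (column(s)) after OLS on ``scores`` with intercept."""
    sc = scores - scores.mean()
    denom = np.sum(sc**2)
    vc = v - v.mean(axis=0, keepdims=True) if v.ndim > 1 else v - v.mean()
    b = (sc @ vc) / denom
    return vc - np.outer(sc, np.atleast_1d(b)) if v.ndim > 1 else vc - b * sc


def pls_fit(tr_acts: pd.DataFrame, pathway_vec, n_components: int = 2,
            stop_rule: str | None = None, min_incremental: float = 0.01) -> LatentModel:
    """Fit PLS-style latent variables of a TR block against one pathway vector.

    Per component the TR weights are univariate slopes of the deflated pathway
    on each deflated TR (unit-norm normalized), scores are the weighted TR
    combination, loadings the multivariable OLS coefficients of the score on
    the TR block, and deflation keeps the residuals of every TR vector and the
    pathway vector on the score. With ``stop_rule='explained_variance'``
    fitting stops once a component explains less than ``min_incremental`` of
    the original pathway variance.
    """
    validate_expression(tr_acts, min_samples=3, name="TR activities")
    y0 = np.asarray(pathway_vec, dtype=float)
    if y0.ndim != 1 or len(y0) != tr_acts.shape[1]:
        raise ValueError("pathway vector must be 1-D over the same samples")
    m, n = tr_acts.shape
    if n_components > min(m, n - 1):
        raise ValueError(f"n_components={n_components} exceeds min(#TRs, #samples-1)")
    Xd = tr_acts.to_numpy(dtype=float).T.copy()  # samples x TRs
    yd = y0.copy()
    var_y0 = y0.var()
    if var_y0 <= _VAR_TOL:
        raise ValueError("constant pathway activity vector")
    components: list[LatentComponent] = []
    stop_reason = None
    for _ in range(n_components):
        var_x = Xd.var(axis=0)
        if np.all(var_x <= _VAR_TOL):
            stop_reason = "deflated TR block has no variance left"
            break
        if yd.var() <= _VAR_TOL:
            stop_reason = "deflated pathway vector has no variance left"
            break
        xc = _center(Xd)
        yc = _center(yd)
        ssx = np.sum(xc**2, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            w = np.where(ssx > _VAR_TOL, (xc.T @ yc) / ssx, 0.0)
        norm = np.linalg.norm(w)
        if norm <= _VAR_TOL:
            stop_reason = "all TR slopes vanished"
            break
        w = w / norm
        scores = Xd @ w
        if scores.var() <= _VAR_TOL:
            stop_reason = "latent scores are constant"
            break
        design = np.column_stack([np.ones(n), Xd])
        coef, *_ = np.linalg.lstsq(design, scores, rcond=None)
        loadings = coef[1:]
        r = float(stats.pearsonr(scores, y0).statistic)
        if stop_rule == "explained_variance":
            explained = (yd.var() - _deflate_on(yd, scores).var()) / var_y0
            if components and explained < min_incremental:
                stop_reason = f"incremental explained variance {explained:.4f} < {min_incremental}"
                break
        components.append(LatentComponent(weights=w, scores=scores,
                                          loadings=loadings, r_with_pathway=r))
        Xd = _deflate_on(Xd, scores)
        yd = _deflate_on(yd, scores)
    if not components:
        raise ValueError(f"no latent component could be fitted: {stop_reason}")
    if stop_reason:
        logger.info("pls_fit: stopped at %d component(s): %s", len(components), stop_reason)
    return LatentModel(tr_ids=list(tr_acts.index), components=components,
                       stop_reason=stop_reason, sample_ids=list(tr_acts.columns))


class PLSLatentRegression(BaseEstimator):
    """sklearn-style wrapper around :func:`pls_fit`.

    ``fit(X, y)`` takes a samples x TRs matrix and the pathway activity
    vector; fitted attributes are ``x_weights_`` (TRs x components),
    ``x_scores_`` (samples x components), ``x_loadings_`` and
    ``r_with_response_``.
    """

    def __init__(self, n_components: int = 2, stop_rule: str | None = None,
                 min_incremental: float = 0.01):
        self.n_components = n_components
        self.stop_rule = stop_rule
        self.min_incremental = min_incremental

    def fit(self, X, y):
        X = pd.DataFrame(X)
        acts = X.T  # to TRs x samples
        acts.index = [str(i) for i in acts.index]
        model = pls_fit(acts, np.asarray(y, dtype=float),
                        n_components=self.n_components, stop_rule=self.stop_rule,
                        min_incremental=self.min_incremental)
        self.model_ = model
        self.x_weights_ = np.column_stack([c.weights for c in model.components])
        self.x_scores_ = model.scores_matrix()
        self.x_loadings_ = np.column_stack([c.loadings for c in model.components])
        self.r_with_response_ = np.array([c.r_with_pathway for c in model.components])
        return self


# ---------------------------------------------------------------------------
# circle of correlation and grouping


def correlation_circle(model: LatentModel, tr_acts: pd.DataFrame,
                       pathway_vec, pathway_id: str = "pathway"
                       ) -> tuple[list[CirclePoint], CirclePoint]:
    """Project TRs and the pathway onto the first two latent axes.

    Coordinates are Pearson correlations of each activity vector with the
    component-1 and component-2 scores; returns the TR points and the pathway
    point separately.
    """
    if model.n_components < 2:
        raise ValueError("correlation circle needs at least 2 latent components")
    s1 = model.components[0].scores
    s2 = model.components[1].scores

    def _point(name, vec) -> CirclePoint:
        vec = np.asarray(vec, dtype=float)
        if vec.var() <= _VAR_TOL:
            raise ValueError(f"constant activity vector {name!r}: correlation undefined")
        return CirclePoint(mechanism_id=name,
                           x=float(stats.pearsonr(vec, s1).statistic),
                           y=float(stats.pearsonr(vec, s2).statistic))

    points = [_point(tr, tr_acts.loc[tr].to_numpy()) for tr in model.tr_ids]
    return points, _point(pathway_id, pathway_vec)


def _circular_distance_deg(a: float, b: float) -> float:
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def closeness_and_cluster(points: list[CirclePoint], pathway_point: CirclePoint,
                          n_groups: int | str = "auto") -> list[TRGroup]:
    """Group TRs by angular closeness to the pathway arrow.

    Closeness is the wrapped absolute angle difference in degrees (range
    [0, 180]); complete-linkage agglomerative clustering on the 1-D closeness
    values is cut into ``n_groups`` clusters (``'auto'``: maximum silhouette
    over 2..min(10, #TRs-1)). Singleton groups are allowed.
    """
    if not points:
        raise ValueError("no TR points to cluster")
    closeness = np.array([_circular_distance_deg(p.angle_deg, pathway_point.angle_deg)
                          for p in points])
    n = len(points)
    if n == 1:
        labels = np.zeros(1, dtype=int)
    else:
        if n_groups == "auto":
            k = _auto_k(closeness)
        else:
            k = int(n_groups)
            if not 1 <= k <= n:
                raise ValueError(f"n_groups={k} outside [1, {n}]")
        if k == 1:
            labels = np.zeros(n, dtype=int)
        else:
            labels = AgglomerativeClustering(n_clusters=k, linkage="complete") \
                .fit_predict(closeness.reshape(-1, 1))
    groups = []
    for lab in np.unique(labels):
        idx = np.where(labels == lab)[0]
        members = sorted(points[i].mechanism_id for i in idx)
        groups.append(TRGroup(members=members,
                              mean_closeness_deg=float(closeness[idx].mean())))
    groups.sort(key=lambda g: (g.mean_closeness_deg, g.members))
    return groups


def _auto_k(closeness: np.ndarray) -> int:
    n = len(closeness)
    if n <= 2:
        return n
    X = closeness.reshape(-1, 1)
    best_k, best_s = 2, -np.inf
    for k in range(2, min(10, n - 1) + 1):
        labels = AgglomerativeClustering(n_clusters=k, linkage="complete").fit_predict(X)
        if len(np.unique(labels)) < 2:
            continue
        s = silhouette_score(X, labels)
        if s > best_s + 1e-12:
            best_k, best_s = k, s
    return best_k


def effect_scores(groups: list[TRGroup], points: list[CirclePoint],
                  model: LatentModel, network: MechanismNetwork,
                  pathway_id: str) -> list[TRGroup]:
    """Rank TR groups and combine the ranks into geometric-mean effect scores.

    Per group: (i) mean angular closeness to the pathway (smaller = better),
    (ii) mean |r| of its members with the two evaluated latent axes
    (larger = better), (iii) mean bootstrap edge weight to the pathway
    (larger = better). Each criterion ranks the groups (1 = best, ties get
    average ranks); the effect score is the geometric mean of the three ranks
    and ``final_rank`` orders groups by ascending effect score.
    """
    point_by_id = {p.mechanism_id: p for p in points}
    closeness_vals, corr_vals, weight_vals = [], [], []
    for g in groups:
        corrs, weights = [], []
        for tr in g.members:
            p = point_by_id[tr]
            corrs.append((abs(p.x) + abs(p.y)) / 2.0)
            edge = network.edge(tr, pathway_id)  # raises if the contract is broken
            w = edge["weight"]
            if not np.isfinite(w):
                raise ValueError(f"edge {tr!r} -> {pathway_id!r} has no bootstrap weight")
            weights.append(float(w))
        closeness_vals.append(g.mean_closeness_deg)
        corr_vals.append(float(np.mean(corrs)))
        weight_vals.append(float(np.mean(weights)))
    rank_close = stats.rankdata(closeness_vals)          # small closeness = rank 1
    rank_corr = stats.rankdata([-v for v in corr_vals])  # large |r| = rank 1
    rank_weight = stats.rankdata([-v for v in weight_vals])
    effects = stats.gmean(np.column_stack([rank_close, rank_corr, rank_weight]), axis=1)
    final = stats.rankdata(effects)
    out = []
    for i, g in enumerate(groups):
        out.append(TRGroup(members=list(g.members),
                           mean_closeness_deg=closeness_vals[i],
                           mean_lv_correlation=corr_vals[i],
                           mean_edge_weight=weight_vals[i],
                           ranks=(float(rank_close[i]), float(rank_corr[i]),
                                  float(rank_weight[i])),
                           effect_score=float(effects[i]),
                           final_rank=float(final[i])))
    out.sort(key=lambda g: (g.final_rank, g.members))
    return out


# ---------------------------------------------------------------------------
# orchestration


def prioritize_trs(network: MechanismNetwork, tr_acts: pd.DataFrame,
                   pathway_vec, pathway_id: str, n_components: int = 2,
                   n_groups: int | str = "auto", stop_rule: str | None = None):
    """Full prioritization of the TRs upstream of one pathway.

    ``tr_acts`` rows are restricted to the network neighbours of
    ``pathway_id``. Returns ``(groups, model, points, pathway_point,
    vif_report)``.
    """
    candidates = [t for t in network.neighbors(pathway_id) if t in tr_acts.index]
    if not candidates:
        raise ValueError(f"pathway {pathway_id!r} has no upstream TRs with activities")
    acts = tr_acts.loc[candidates]
    vif_report = vif(acts) if len(candidates) >= 2 else None
    n_comp = min(n_components, len(candidates), acts.shape[1] - 1)
    model = pls_fit(acts, pathway_vec, n_components=n_comp, stop_rule=stop_rule)
    points, pathway_point = correlation_circle(model, acts, pathway_vec, pathway_id)
    groups = closeness_and_cluster(points, pathway_point, n_groups=n_groups)
    groups = effect_scores(groups, points, model, network, pathway_id)
    return groups, model, points, pathway_point, vif_report


class TRPrioritizer(BaseEstimator):
    """Estimator wrapper: fit = prioritize the TRs upstream of one pathway.

    ``fit(X, y)`` takes the TR activity matrix (TRs x samples, superset of the
    pathway's network neighbours allowed) and the pathway activity vector.
    Fitted attributes: ``groups_``, ``model_``, ``points_``,
    ``pathway_point_``, ``vif_report_`` and ``report_`` (a tidy frame).
    """

    def __init__(self, network: MechanismNetwork | None = None, pathway_id: str = "",
                 n_components: int = 2, n_groups: int | str = "auto",
                 stop_rule: str | None = None):
        self.network = network
        self.pathway_id = pathway_id
        self.n_components = n_components
        self.n_groups = n_groups
        self.stop_rule = stop_rule

    def fit(self, X: pd.DataFrame, y):
        if self.network is None:
            raise ValueError("network is required")
        (self.groups_, self.model_, self.points_, self.pathway_point_,
         self.vif_report_) = prioritize_trs(self.network, X, np.asarray(y, dtype=float),
                                            self.pathway_id, self.n_components,
                                            self.n_groups, self.stop_rule)
        self.report_ = pd.DataFrame(
            [{"group": i + 1, "members": ",".join(g.members),
              "mean_closeness_deg": g.mean_closeness_deg,
              "mean_lv_correlation": g.mean_lv_correlation,
              "mean_edge_weight": g.mean_edge_weight,
              "rank_closeness": g.ranks[0], "rank_lv_correlation": g.ranks[1],
              "rank_edge_weight": g.ranks[2], "effect_score": g.effect_score,
              "final_rank": g.final_rank}
             for i, g in enumerate(self.groups_)])
        return self
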