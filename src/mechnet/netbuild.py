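"""Bipartite TR -> pathway network by pairwise regression with bootstrap weights.

Every TR activity vector is regressed against every pathway activity vector
(ordinary least squares, TR as predictor). Within each pathway the slope
p-values are Benjamini-Hochberg adjusted across TRs, and pairs with FDR below
threshold become signed edges. Bootstrap resampling of the cohort then scores
each retained edge by the percentage of resampled networks that recover it
with the same sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from ._utils import validate_expression
from .datatypes import BootstrapConfig, MechanismNetwork

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300  # avoids log-domain trouble downstream

__all__ = ["EdgeStats", "regress_edge", "build_network", "bootstrap_weights",
           "MechanismNetworkBuilder"]


@dataclass
class EdgeStats:
    """OLS statistics of one candidate TR -> pathway edge."""

    tr_id: str
    pathway_id: str
    alpha: float
    beta: float
    pvalue: float
    fdr: float = np.nan
    sign: int = 0

    def __post_init__(self) -> None:
        self.sign = int(np.sign(self.beta))


def regress_edge(tr_vec, pathway_vec, tr_id: str = "tr", pathway_id: str = "pathway") -> EdgeStats:
    """OLS of pathway activity on TR activity with a two-sided slope t-test."""
    x = np.asarray(tr_vec, dtype=float)
    y = np.asarray(pathway_vec, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("activity vectors must be 1-D and equal length")
    if len(x) < 3:
        raise ValueError("regression needs >= 3 samples")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("activity vectors must be finite")
    if np.ptp(x) == 0:
        raise ValueError(f"constant predictor for TR {tr_id!r}: degenerate fit")
    fit = stats.linregress(x, y)
    p = fit.pvalue if np.isfinite(fit.pvalue) else 0.0
    return EdgeStats(tr_id=tr_id, pathway_id=pathway_id, alpha=float(fit.intercept),
                     beta=float(fit.slope), pvalue=float(max(p, P_FLOOR)))


def _pairwise_edges(tr_values: np.ndarray, pw_values: np.ndarray,
                    tr_ids, pathway_ids, fdr_threshold: float) -> pd.DataFrame:
    """Vectorized all-pairs OLS + per-pathway BH; returns the retained edges."""
    n = tr_values.shape[1]
    if n < 3:
        raise ValueError("network regression needs >= 3 samples")
    tc = tr_values - tr_values.mean(axis=1, keepdims=True)
    pc = pw_values - pw_values.mean(axis=1, keepdims=True)
    sxx = np.sum(tc * tc, axis=1)
    if np.any(sxx == 0):
        bad = [tr_ids[i] for i in np.where(sxx == 0)[0][:5]]
        raise ValueError(f"constant TR activity vector(s): {bad}")
    if np.any(np.ptp(pw_values, axis=1) == 0):
        bad = [pathway_ids[i] for i in np.where(np.ptp(pw_values, axis=1) == 0)[0][:5]]
        raise ValueError(f"constant pathway activity vector(s): {bad}")
    sxy = pc @ tc.T                      # (n_pathways, n_trs)
    beta = sxy / sxx[None, :]
    alpha = pw_values.mean(axis=1)[:, None] - beta * tr_values.mean(axis=1)[None, :]
    rss = np.clip(np.sum(pc * pc, axis=1)[:, None] - beta * sxy, 0.0, None)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / df / sxx[None, :])
        tstat = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = np.clip(2.0 * stats.t.sf(np.abs(tstat), df), P_FLOOR, 1.0)
    rows = []
    for i, pw in enumerate(pathway_ids):
        _, fdr, _, _ = multipletests(pvals[i], method="fdr_bh")
        keep = np.where(fdr < fdr_threshold)[0]
        for t in keep:
            rows.append((tr_ids[t], pw, alpha[i, t], beta[i, t], pvals[i, t],
                         fdr[t], int(np.sign(beta[i, t]))))
    edges = pd.DataFrame(rows, columns=["tr", "pathway", "alpha", "beta",
                                        "pvalue", "fdr", "sign"])
    return edges.sort_values(["pathway", "tr"], kind="stable").reset_index(drop=True)


def build_network(tr_acts: pd.DataFrame, path_acts: pd.DataFrame,
                  fdr_threshold: float = 0.05) -> MechanismNetwork:
    """All-pairs TR -> pathway regression network at a per-pathway FDR.

    Both activity matrices must share sample ids in identical order; both
    positive and negative significant slopes are kept as signed edges.
    """
    validate_expression(tr_acts, min_samples=3, name="TR activities")
    validate_expression(path_acts, min_samples=3, name="pathway activities")
    if list(tr_acts.columns) != list(path_acts.columns):
        raise ValueError("TR and pathway activity matrices must share sample ids and order")
    edges = _pairwise_edges(tr_acts.to_numpy(dtype=float), path_acts.to_numpy(dtype=float),
                            list(tr_acts.index), list(path_acts.index), fdr_threshold)
    return MechanismNetwork(edges=edges, tr_ids=list(tr_acts.index),
                            pathway_ids=list(path_acts.index))


def _resample_columns(rng: np.random.Generator, n: int, tr_values: np.ndarray,
                      pw_values: np.ndarray, max_tries: int = 100) -> np.ndarray:
    """Bootstrap column indices; redraw degenerate resamples (logged)."""
    for attempt in range(max_tries):
        idx = rng.integers(0, n, size=n)
        if len(np.unique(idx)) < 3:
            logger.info("bootstrap: redraw (fewer than 3 distinct samples)")
            continue
        if np.any(np.ptp(tr_values[:, idx], axis=1) == 0) or \
           np.any(np.ptp(pw_values[:, idx], axis=1) == 0):
            logger.info("bootstrap: redraw (constant activity vector in resample)")
            continue
        return idx
    raise RuntimeError("bootstrap: could not draw a non-degenerate resample")


def bootstrap_weights(base: MechanismNetwork, config: BootstrapConfig,
                      fdr_threshold: float = 0.05, *,
                      tr_acts: pd.DataFrame | None = None,
                      path_acts: pd.DataFrame | None = None,
                      expr: pd.DataFrame | None = None,
                      genesets=None, regulons=None,
                      n_perm: int = 1000, weight_exponent: float = 1.0,
                      min_overlap: int = 5) -> MechanismNetwork:
    """Attach bootstrap recovery weights (percent, 0-100) to a base network.

    ``resample_activities`` (default) resamples cohort columns of the
    precomputed activity matrices and rebuilds the regression network on each
    resample. ``full_recompute`` resamples the expression columns and redoes
    z-scoring and enrichment before rebuilding — faithful to cohort-level
    standardization, but far slower. Weights qualify the base edges only;
    edges absent from the base network are never added.
    """
    if config.recompute_mode == "resample_activities":
        if tr_acts is None or path_acts is None:
            raise ValueError("resample_activities mode needs tr_acts and path_acts")
        tr_ids, pw_ids = list(tr_acts.index), list(path_acts.index)
        tv = tr_acts.to_numpy(dtype=float)
        pv = path_acts.to_numpy(dtype=float)
        n = tv.shape[1]

        def _edges_for(b: int) -> pd.DataFrame:
            rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, b]))
            idx = _resample_columns(rng, n, tv, pv)
            return _pairwise_edges(tv[:, idx], pv[:, idx], tr_ids, pw_ids, fdr_threshold)
    elif config.recompute_mode == "full_recompute":
        if expr is None or genesets is None or regulons is None:
            raise ValueError("full_recompute mode needs expr, genesets and regulons")
        from .activity import single_sample_activities

        ev = expr.to_numpy(dtype=float)
        n = ev.shape[1]

        def _edges_for(b: int) -> pd.DataFrame:
            rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, b]))
            for _ in range(100):
                idx = rng.integers(0, n, size=n)
                if len(np.unique(idx)) >= 3:
                    break
            else:  # pragma: no cover
                raise RuntimeError("bootstrap: degenerate resample")
            cols = [f"{expr.columns[i]}.b{b}.{j}" for j, i in enumerate(idx)]
            boot_expr = pd.DataFrame(ev[:, idx], index=expr.index, columns=cols)
            acts = single_sample_activities(boot_expr, genesets, regulons,
                                            n_perm=n_perm,
                                            rng_seed=int(np.random.SeedSequence(
                                                [config.rng_seed, b, 1]).generate_state(1)[0] % (2**31)),
                                            weight_exponent=weight_exponent,
                                            min_overlap=min_overlap)
            return _pairwise_edges(acts.trs.to_numpy(), acts.pathways.to_numpy(),
                                   list(acts.trs.index), list(acts.pathways.index),
                                   fdr_threshold)
    else:  # pragma: no cover - BootstrapConfig already validates
        raise ValueError(config.recompute_mode)

    counts: dict[tuple[str, str, int], int] = {}
    for b in range(config.k):
        boot_edges = _edges_for(b)
        for tr, pw, sign in zip(boot_edges["tr"], boot_edges["pathway"], boot_edges["sign"]):
            counts[(tr, pw, sign)] = counts.get((tr, pw, sign), 0) + 1
    edges = base.edges.copy()
    edges["weight"] = [
        100.0 * counts.get((tr, pw, int(sign)), 0) / config.k
        for tr, pw, sign in zip(edges["tr"], edges["pathway"], edges["sign"])
    ]
    return MechanismNetwork(edges=edges, tr_ids=base.tr_ids, pathway_ids=base.pathway_ids)


class MechanismNetworkBuilder(BaseEstimator):
    """Estimator wrapper: fit TR and pathway activities into a weighted network.

    ``fit(tr_acts, path_acts)`` builds the FDR-thresholded regression network
    and, when ``bootstrap_k > 0``, attaches bootstrap edge weights; the result
    is in ``network_`` (and ``edges_``).
    """

    def __init__(self, fdr_threshold: float = 0.05, bootstrap_k: int = 0,
                 recompute_mode: str = "resample_activities", random_state: int = 0):
        self.fdr_threshold = fdr_threshold
        self.bootstrap_k = bootstrap_k
        self.recompute_mode = recompute_mode
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y: pd.DataFrame):
        """X: TR activities (TRs x samples); y: pathway activities (pathways x samples)."""
        net = build_network(X, y, fdr_threshold=self.fdr_threshold)
        if self.bootstrap_k > 0:
            cfg = BootstrapConfig(k=self.bootstrap_k, rng_seed=self.random_state,
                                  recompute_mode=self.recompute_mode)
            net = bootstrap_weights(net, cfg, fdr_threshold=self.fdr_threshold,
                                    tr_acts=X, path_acts=y)
        self.network_ = net
        self.edges_ = net.edges
        return self
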