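"""Activity inference: z-scoring, weighted-KS enrichment, single-sample NES.

The activity of a mechanism (a molecular pathway or a transcriptional
regulatory program) in a sample or in a phenotype-contrast signature is its
normalized enrichment score (NES): the weighted Kolmogorov-Smirnov running-sum
statistic of the mechanism's genes in the ranked signature, scaled by the mean
magnitude of same-sign scores under a gene-permutation null. A row of the
resulting mechanisms x samples matrix is the mechanism's *activity vector*,
the unit of all downstream network regression.

Regulon (TR program) enrichment is mode-aware: targets the TR represses enter
with their signature score negated, so a positive NES always reads as
"the TR is active".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from ._utils import derived_rng, validate_expression
from .datatypes import EnrichmentResult, GeneSet, Regulon, Signature

logger = logging.getLogger(__name__)

__all__ = [
    "zscore_genes",
    "gsea_enrichment",
    "regulon_enrichment",
    "single_sample_activities",
    "phenotype_signature",
    "ActivityResult",
    "SingleSampleActivity",
]


# ---------------------------------------------------------------------------
# z-scoring


def zscore_genes(expr: pd.DataFrame) -> pd.DataFrame:
    """Standardize each gene row to mean 0 and sample standard deviation 1.

    Constant rows carry no rank information and are mapped to all-zero rows
    (with a warning) instead of propagating NaNs.
    """
    validate_expression(expr, min_samples=2)
    values = expr.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    flat = sd[:, 0] == 0
    if flat.any():
        logger.warning("zscore_genes: %d constant gene row(s) set to zero", int(flat.sum()))
        sd[flat] = 1.0
    out = (values - mean) / sd
    out[flat] = 0.0
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


# ---------------------------------------------------------------------------
# weighted-KS running-sum machinery


def _ks_extremum(positions: np.ndarray, increments: np.ndarray, n_genes: int,
                 return_extremum_index: bool = False):
    """Extremum of the weighted KS running sum for each row of ``positions``.

    ``positions`` (draws x k) holds 0-based hit positions in the ranked list,
    ``increments`` the matching non-negative hit magnitudes. Between hits the
    sum decreases by 1/(n_genes - k) per miss. Ties between the positive and
    negative extremum resolve to the positive one.
    """
    positions = np.atleast_2d(positions)
    increments = np.atleast_2d(increments).astype(float)
    d, k = positions.shape
    if k >= n_genes:
        raise ValueError("query set must be smaller than the signature")
    order = np.argsort(positions, axis=1)
    pos = np.take_along_axis(positions, order, axis=1)
    inc = np.take_along_axis(increments, order, axis=1)
    tot = inc.sum(axis=1, keepdims=True)
    degenerate = tot[:, 0] == 0
    if degenerate.any():
        # all-zero magnitudes (e.g. every member score exactly 0): rank-only steps
        inc[degenerate] = 1.0
        tot = inc.sum(axis=1, keepdims=True)
    hit = np.cumsum(inc, axis=1) / tot
    miss = (pos - np.arange(k)) / float(n_genes - k)
    es_after = hit - miss
    es_before = np.concatenate([np.zeros((d, 1)), hit[:, :-1]], axis=1) - miss
    j_max = np.argmax(es_after, axis=1)
    j_min = np.argmin(es_before, axis=1)
    max_dev = np.maximum(np.take_along_axis(es_after, j_max[:, None], 1)[:, 0], 0.0)
    min_dev = np.minimum(np.take_along_axis(es_before, j_min[:, None], 1)[:, 0], 0.0)
    # tolerance in the tie-break keeps the branch choice stable under
    # summation-order float noise (exact +/- extremum ties do occur)
    take_pos = max_dev >= -min_dev - 1e-12
    es = np.where(take_pos, max_dev, min_dev)
    if not return_extremum_index:
        return es
    # leading-edge boundary: position of the extremum in the ranked list
    boundary = np.where(take_pos,
                        np.take_along_axis(pos, j_max[:, None], 1)[:, 0],
                        np.take_along_axis(pos, j_min[:, None], 1)[:, 0])
    return es, boundary


def _null_positions(rng: np.random.Generator, n_perm: int, n_genes: int, k: int) -> np.ndarray:
    """``n_perm`` uniformly random k-subsets of positions 0..n_genes-1."""
    r = rng.random((n_perm, n_genes))
    return np.argpartition(r, k - 1, axis=1)[:, :k]


def _pvalue_and_nes(es: float, null_es: np.ndarray) -> tuple[float, float]:
    """One-sided permutation p (add-one smoothed) and sign-matched NES."""
    n = len(null_es)
    if es > 0:
        count = int(np.sum(null_es >= es))
        same_sign = null_es[null_es > 0]
    elif es < 0:
        count = int(np.sum(null_es <= es))
        same_sign = -null_es[null_es < 0]
    else:
        return 1.0, 0.0
    if len(same_sign) == 0:
        raise ValueError("degenerate permutation null: no same-sign null scores")
    pvalue = (1.0 + count) / (1.0 + n)
    nes = es / float(np.mean(same_sign))
    return pvalue, nes


def _weighted_ks_enrichment(signature: Signature, member_ids: np.ndarray,
                            member_weights: np.ndarray, n_perm: int,
                            weight_exponent: float,
                            rng: np.random.Generator) -> EnrichmentResult:
    """Core enrichment of a weighted member set in a ranked signature."""
    n = len(signature)
    order = signature.rank_order()
    ranked_ids = signature.gene_ids[order]
    ranked_abs = np.abs(signature.scores[order]) ** weight_exponent
    pos_of = {g: i for i, g in enumerate(ranked_ids)}
    positions = np.array([pos_of[g] for g in member_ids], dtype=int)
    k = len(positions)
    inc = ranked_abs[positions] * member_weights
    es_arr, boundary = _ks_extremum(positions[None, :], inc[None, :], n,
                                    return_extremum_index=True)
    es = float(es_arr[0])
    b = int(boundary[0])
    if es >= 0:
        leading = [g for g, p in zip(member_ids, positions) if p <= b]
    else:
        leading = [g for g, p in zip(member_ids, positions) if p >= b]
    null_pos = _null_positions(rng, n_perm, n, k)
    null_inc = ranked_abs[null_pos] * member_weights[None, :]
    null_es = _ks_extremum(null_pos, null_inc, n)
    pvalue, nes = _pvalue_and_nes(es, null_es)
    return EnrichmentResult(es=es, nes=nes, pvalue=pvalue, n_perm=n_perm,
                            leading_edge=sorted(map(str, leading)), n_overlap=k)


def gsea_enrichment(signature: Signature, geneset: GeneSet, n_perm: int = 1000,
                    weight_exponent: float = 1.0, rng_seed: int = 0,
                    min_overlap: int = 5) -> EnrichmentResult:
    """Weighted-KS enrichment of a gene set in a ranked signature.

    The enrichment score (ES) is the signed extremum of the running sum over
    the signature ranked by descending score; in-set steps are weighted by
    ``|score|**weight_exponent``. NES divides ES by the mean magnitude of
    same-sign scores from ``n_perm`` random placements of an equally sized set
    (gene-label permutation); the p-value is the one-sided tail of that null,
    floored at ``1/(n_perm + 1)``.

    Sets overlapping the signature by fewer than ``min_overlap`` genes return
    a skipped result rather than an estimate.
    """
    present = np.array([g for g in sorted(geneset.genes) if g in set(signature.gene_ids)],
                       dtype=object)
    n_dropped = len(geneset) - len(present)
    if n_dropped:
        logger.info("gsea_enrichment: %s: %d/%d genes absent from signature",
                    geneset.name, n_dropped, len(geneset))
    if len(present) < min_overlap:
        return EnrichmentResult(es=np.nan, nes=np.nan, pvalue=np.nan, n_perm=n_perm,
                                n_overlap=len(present),
                                skipped_reason=f"overlap {len(present)} < floor {min_overlap}")
    rng = np.random.default_rng(rng_seed)
    return _weighted_ks_enrichment(signature, present, np.ones(len(present)),
                                   n_perm, weight_exponent, rng)


def regulon_enrichment(signature: Signature, regulon: Regulon, n_perm: int = 1000,
                       rng_seed: int = 0, weight_exponent: float = 1.0,
                       min_overlap: int = 5) -> EnrichmentResult:
    """Mode-aware enrichment of a TR program in a ranked signature.

    Targets with negative mode of regulation enter with their signature score
    negated (the signature is re-ranked after the flip), so over-expression of
    repressed targets counts as evidence *against* TR activity; each target's
    running-sum step is additionally weighted by ``|mode| * likelihood``.
    Positive NES means the TR program is inferred active in the signature.
    """
    weights = np.abs(regulon.modes) * regulon.likelihoods
    keep = weights > 0
    universe = set(signature.gene_ids)
    present = np.array([t in universe for t in regulon.targets]) & keep
    idx = np.where(present)[0]
    idx = idx[np.argsort(regulon.targets[idx].astype(str))]
    if len(idx) < min_overlap:
        return EnrichmentResult(es=np.nan, nes=np.nan, pvalue=np.nan, n_perm=n_perm,
                                n_overlap=len(idx),
                                skipped_reason=f"overlap {len(idx)} < floor {min_overlap}")
    member_ids = regulon.targets[idx]
    member_weights = weights[idx]
    neg_targets = set(regulon.targets[idx[regulon.modes[idx] < 0]])
    flipped = signature.scores.copy()
    for i, g in enumerate(signature.gene_ids):
        if g in neg_targets:
            flipped[i] = -flipped[i]
    flipped_sig = Signature(signature.gene_ids, flipped, dict(signature.metadata))
    rng = np.random.default_rng(rng_seed)
    return _weighted_ks_enrichment(flipped_sig, member_ids, member_weights,
                                   n_perm, weight_exponent, rng)


# ---------------------------------------------------------------------------
# single-sample activities


@dataclass
class ActivityResult:
    """Mechanism x sample NES matrices (and permutation p-values) for one cohort."""

    pathways: pd.DataFrame
    trs: pd.DataFrame
    pathway_pvalues: pd.DataFrame
    tr_pvalues: pd.DataFrame


def single_sample_activities(expr: pd.DataFrame, genesets: list[GeneSet],
                             regulons: list[Regulon], n_perm: int = 1000,
                             rng_seed: int = 0, weight_exponent: float = 1.0,
                             min_overlap: int = 5,
                             assume_scaled: bool = False) -> ActivityResult:
    """NES of every pathway and TR program in every sample.

    Expression is z-scored gene-wise first (unless ``assume_scaled``); the
    single-sample signature of sample *j* is the vector of its gene z-scores.
    Mechanisms whose overlap with the gene universe is below ``min_overlap``
    are dropped (logged). Per-sample randomness is derived from
    ``(rng_seed, sample id)``, so reordering samples permutes the output
    columns without changing any value.
    """
    if not genesets or not regulons:
        raise ValueError("need at least one gene set and one regulon")
    validate_expression(expr, min_samples=2)
    z = expr if assume_scaled else zscore_genes(expr)
    n_genes = z.shape[0]
    gene_index = pd.Index(z.index)
    row_of = {g: i for i, g in enumerate(gene_index)}
    ids_str = np.array([str(g) for g in gene_index])

    def _prepare_set(name, members, weights, neg_members):
        rows = np.array([row_of[g] for g in members if g in row_of], dtype=int)
        kept = [g for g in members if g in row_of]
        w = np.array([wt for g, wt in zip(members, weights) if g in row_of])
        if len(rows) < min_overlap:
            logger.info("single_sample_activities: dropping %s (overlap %d < %d)",
                        name, len(rows), min_overlap)
            return None
        neg_rows = np.array([row_of[g] for g in neg_members if g in row_of], dtype=int)
        return name, rows, w, neg_rows

    prepared_sets = []
    for gs in genesets:
        p = _prepare_set(gs.name, sorted(gs.genes), np.ones(len(gs)), [])
        if p is not None:
            prepared_sets.append(("pathway", p))
    for reg in regulons:
        w_all = np.abs(reg.modes) * reg.likelihoods
        keep = w_all > 0
        order = np.argsort(reg.targets[keep].astype(str))
        members = list(reg.targets[keep][order])
        weights = list(w_all[keep][order])
        neg = list(reg.targets[keep & (reg.modes < 0)])
        p = _prepare_set(reg.tr_id, members, weights, neg)
        if p is not None:
            prepared_sets.append(("tr", p))
    if not any(kind == "pathway" for kind, _ in prepared_sets):
        raise ValueError("no gene set passed the overlap floor")
    if not any(kind == "tr" for kind, _ in prepared_sets):
        raise ValueError("no regulon passed the overlap floor")

    values = z.to_numpy(dtype=float)
    out = {"pathway": ({}, {}), "tr": ({}, {})}
    for kind, (name, *_rest) in prepared_sets:
        out[kind][0][name] = np.empty(z.shape[1])
        out[kind][1][name] = np.empty(z.shape[1])

    for j, sample in enumerate(z.columns):
        scores = values[:, j]
        abs_sp = np.abs(scores) ** weight_exponent
        order = np.lexsort((ids_str, -scores))
        pos_in_rank = np.empty(n_genes, dtype=int)
        pos_in_rank[order] = np.arange(n_genes)
        ranked_abs = abs_sp[order]
        # one permutation-position draw per (mechanism kind, set size): sets of
        # equal size share a null within a kind (marginally identical), but
        # pathway and TR nulls stay independent so the shared null-normalization
        # noise cannot correlate TR with pathway estimates across samples
        null_pos_by_k: dict[tuple[str, int], np.ndarray] = {}
        null_ranked_by_k: dict[tuple[str, int], np.ndarray] = {}
        for kind_key in ("pathway", "tr"):
            ks = sorted({len(p[1]) for kd, p in prepared_sets if kd == kind_key})
            if not ks:
                continue
            rng = derived_rng(rng_seed, f"{sample}:{kind_key}")
            r = rng.random((n_perm, n_genes))
            for k in ks:
                pos = np.argpartition(r, k - 1, axis=1)[:, :k]
                null_pos_by_k[(kind_key, k)] = pos
                null_ranked_by_k[(kind_key, k)] = ranked_abs[pos]
        for kind, (name, rows, w, neg_rows) in prepared_sets:
            if kind == "tr" and len(neg_rows):
                s2 = scores.copy()
                s2[neg_rows] = -s2[neg_rows]
                order2 = np.lexsort((ids_str, -s2))
                pir = np.empty(n_genes, dtype=int)
                pir[order2] = np.arange(n_genes)
                positions = pir[rows]
            else:
                positions = pos_in_rank[rows]
            k = len(rows)
            inc = abs_sp[rows] * w
            es = float(_ks_extremum(positions[None, :], inc[None, :], n_genes)[0])
            null_es = _ks_extremum(null_pos_by_k[(kind, k)],
                                   null_ranked_by_k[(kind, k)] * w[None, :], n_genes)
            pvalue, nes = _pvalue_and_nes(es, null_es)
            out[kind][0][name][j] = nes
            out[kind][1][name][j] = pvalue

    def _frame(d):
        return pd.DataFrame(d, index=z.columns).T

    return ActivityResult(pathways=_frame(out["pathway"][0]),
                          trs=_frame(out["tr"][0]),
                          pathway_pvalues=_frame(out["pathway"][1]),
                          tr_pvalues=_frame(out["tr"][1]))


# ---------------------------------------------------------------------------
# phenotype-contrast signatures


def phenotype_signature(expr_a: pd.DataFrame, expr_b: pd.DataFrame) -> Signature:
    """Per-gene two-tailed Welch t contrast of group b versus group a.

    Positive scores mean the gene is up in ``expr_b``. Welch p-values are kept
    in ``metadata['pvalues']``.
    """
    validate_expression(expr_a, min_samples=2, name="group a")
    validate_expression(expr_b, min_samples=2, name="group b")
    shared = expr_a.index.intersection(expr_b.index)
    if len(shared) == 0:
        raise ValueError("gene universes of the two groups are disjoint")
    a = expr_a.loc[shared].to_numpy(dtype=float)
    b = expr_b.loc[shared].to_numpy(dtype=float)
    t, p = stats.ttest_ind(b, a, axis=1, equal_var=False)
    t = np.where(np.isfinite(t), t, 0.0)  # zero-variance genes carry no contrast
    p = np.where(np.isfinite(p), p, 1.0)
    return Signature(np.asarray(shared, dtype=object), t,
                     metadata={"pvalues": p, "n_a": expr_a.shape[1], "n_b": expr_b.shape[1]})


# ---------------------------------------------------------------------------
# sklearn-style transformer


class SingleSampleActivity(TransformerMixin, BaseEstimator):
    """Transformer mapping a genes x samples frame to mechanism activities.

    ``transform`` returns the stacked (pathways then TRs) mechanisms x samples
    NES frame; the split matrices and permutation p-values of the last
    transform are kept in ``result_``.

    Parameters
    ----------
    genesets, regulons:
        Pathway gene sets and TR programs to score.
    n_perm:
        Gene permutations for the NES null (default 1000).
    weight_exponent:
        Exponent on ``|score|`` in the running sum (0 = rank-only).
    min_overlap:
        Minimum genes a mechanism must share with the matrix.
    assume_scaled:
        Skip gene-wise z-scoring when the input is already standardized.
    random_state:
        Base seed for the permutation null.
    """

    def __init__(self, genesets=None, regulons=None, n_perm: int = 1000,
                 weight_exponent: float = 1.0, min_overlap: int = 5,
                 assume_scaled: bool = False, random_state: int = 0):
        self.genesets = genesets
        self.regulons = regulons
        self.n_perm = n_perm
        self.weight_exponent = weight_exponent
        self.min_overlap = min_overlap
        self.assume_scaled = assume_scaled
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None):
        validate_expression(X, min_samples=2)
        if not self.genesets or not self.regulons:
            raise ValueError("genesets and regulons must both be non-empty")
        self.n_features_in_ = X.shape[0]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self.result_ = single_sample_activities(
            X, self.genesets, self.regulons, n_perm=self.n_perm,
            rng_seed=self.random_state, weight_exponent=self.weight_exponent,
            min_overlap=self.min_overlap, assume_scaled=self.assume_scaled)
        return pd.concat([self.result_.pathways, self.result_.trs], axis=0)
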