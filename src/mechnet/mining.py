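"""Network mining: TR programs reactivated under treatment resistance.

Given three phenotypes — untreated (intact), treatment-sensitive and
treatment-resistant — two Welch contrast signatures are formed
(intact -> sensitive, sensitive -> resistant). A mechanism shows "up-down-up"
behaviour when it is significantly repressed in the first contrast
(NES < 0) and significantly reactivated in the second (NES > 0), both at a
permutation p below threshold. Candidates are restricted to the network
neighbourhood of the queried pathway, so the result is a sub-network of the
mechanism-centric graph, not a free gene-set screen.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._utils import derived_rng
from .activity import gsea_enrichment, phenotype_signature, regulon_enrichment
from .datatypes import GeneSet, MechanismNetwork, MiningResult, PhenotypeSeries, Regulon, Signature

logger = logging.getLogger(__name__)

__all__ = ["contrast_signatures", "find_up_down_up", "UpDownUpMiner"]


def contrast_signatures(series: PhenotypeSeries) -> tuple[Signature, Signature]:
    """Welch contrasts along the treatment course.

    Returns ``(sig1, sig2)``: intact -> sensitive and sensitive -> resistant,
    with positive scores meaning up-regulation in the later phenotype.
    """
    sig1 = phenotype_signature(series.intact, series.sensitive)
    sig2 = phenotype_signature(series.sensitive, series.resistant)
    sig1.metadata["contrast"] = "intact->sensitive"
    sig2.metadata["contrast"] = "sensitive->resistant"
    return sig1, sig2


def find_up_down_up(network: MechanismNetwork, pathway_id: str,
                    sig1: Signature, sig2: Signature,
                    genesets: list[GeneSet], regulons: list[Regulon],
                    p_threshold: float = 0.001, n_perm: int = 1000,
                    rng_seed: int = 0, weight_exponent: float = 1.0,
                    min_overlap: int = 5) -> MiningResult:
    """TR programs upstream of ``pathway_id`` with the up-down-up pattern.

    Each network neighbour of the pathway (and the pathway itself) is
    enrichment-scored in both contrast signatures; a mechanism passes when
    ``nes_sig1 < 0`` and ``nes_sig2 > 0`` with both permutation p-values below
    ``p_threshold``. The pathway must itself pass for the sub-network to be
    flagged coherent (``pathway_passes``); if it does not, passing TRs are
    still reported. ``n_perm`` must satisfy ``1/(n_perm+1) < p_threshold``,
    otherwise the threshold is unreachable by construction.
    """
    if not (1.0 / (n_perm + 1) < p_threshold):
        raise ValueError(f"n_perm={n_perm} cannot resolve p_threshold={p_threshold}; "
                         "need 1/(n_perm+1) < p_threshold")
    geneset_by_name = {g.name: g for g in genesets}
    regulon_by_id = {r.tr_id: r for r in regulons}
    if pathway_id not in geneset_by_name:
        raise KeyError(f"no gene set for pathway {pathway_id!r}")
    candidates = network.neighbors(pathway_id)
    columns = ["mechanism", "kind", "nes_sig1", "p_sig1", "nes_sig2", "p_sig2", "passed"]
    if not candidates:
        return MiningResult(pathway_id=pathway_id, passing_trs=set(),
                            records=pd.DataFrame(columns=columns),
                            p_threshold=p_threshold, pathway_passes=False,
                            reason=f"pathway {pathway_id!r} has no incident edges")

    def _passes(r1, r2) -> bool:
        if r1.skipped or r2.skipped:
            return False
        return (r1.nes < 0 and r1.pvalue < p_threshold
                and r2.nes > 0 and r2.pvalue < p_threshold)

    rows = []
    gs = geneset_by_name[pathway_id]
    pw1 = gsea_enrichment(sig1, gs, n_perm=n_perm, weight_exponent=weight_exponent,
                          rng_seed=_seed(rng_seed, pathway_id, 1), min_overlap=min_overlap)
    pw2 = gsea_enrichment(sig2, gs, n_perm=n_perm, weight_exponent=weight_exponent,
                          rng_seed=_seed(rng_seed, pathway_id, 2), min_overlap=min_overlap)
    pathway_passes = _passes(pw1, pw2)
    rows.append((pathway_id, "pathway", pw1.nes, pw1.pvalue, pw2.nes, pw2.pvalue, pathway_passes))

    passing: set[str] = set()
    for tr in candidates:
        if tr not in regulon_by_id:
            logger.warning("find_up_down_up: no regulon for network TR %r; skipped", tr)
            continue
        reg = regulon_by_id[tr]
        r1 = regulon_enrichment(sig1, reg, n_perm=n_perm, rng_seed=_seed(rng_seed, tr, 1),
                                weight_exponent=weight_exponent, min_overlap=min_overlap)
        r2 = regulon_enrichment(sig2, reg, n_perm=n_perm, rng_seed=_seed(rng_seed, tr, 2),
                                weight_exponent=weight_exponent, min_overlap=min_overlap)
        ok = _passes(r1, r2)
        if ok:
            passing.add(tr)
        rows.append((tr, "tr", r1.nes, r1.pvalue, r2.nes, r2.pvalue, ok))

    records = pd.DataFrame(rows, columns=columns)
    return MiningResult(pathway_id=pathway_id, passing_trs=passing, records=records,
                        p_threshold=p_threshold, pathway_passes=bool(pathway_passes))


def _seed(base: int, mechanism: str, which: int) -> int:
    """Stable per-(mechanism, signature) seed, independent of evaluation order."""
    return int(derived_rng(base, f"{mechanism}:{which}").integers(0, 2**31))


class UpDownUpMiner(BaseEstimator):
    """Estimator wrapper around the up-down-up sub-network search.

    ``fit(series)`` builds the two contrast signatures and scores the network
    neighbourhood of ``pathway_id``; results land in ``result_`` and
    ``passing_trs_``.
    """

    def __init__(self, network: MechanismNetwork | None = None, pathway_id: str = "",
                 genesets=None, regulons=None, p_threshold: float = 0.001,
                 n_perm: int = 1000, random_state: int = 0):
        self.network = network
        self.pathway_id = pathway_id
        self.genesets = genesets
        self.regulons = regulons
        self.p_threshold = p_threshold
        self.n_perm = n_perm
        self.random_state = random_state

    def fit(self, X: PhenotypeSeries, y=None):
        if self.network is None:
            raise ValueError("network is required")
        sig1, sig2 = contrast_signatures(X)
        self.signatures_ = (sig1, sig2)
        self.result_ = find_up_down_up(self.network, self.pathway_id, sig1, sig2,
                                       self.genesets, self.regulons,
                                       p_threshold=self.p_threshold,
                                       n_perm=self.n_perm, rng_seed=self.random_state)
        self.passing_trs_ = self.result_.passing_trs
        return self
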