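"""Shared containers for mechanism-centric network inference.

Expression and activity matrices are plain :class:`pandas.DataFrame` objects
(genes x samples and mechanisms x samples respectively); the dataclasses here
hold everything that is not naturally a rectangular table: gene sets, regulons,
ranked signatures, enrichment results, the bipartite network, mining and
prioritization outputs, and simulation ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneSet",
    "Regulon",
    "Signature",
    "EnrichmentResult",
    "MechanismNetwork",
    "BootstrapConfig",
    "PhenotypeSeries",
    "MiningResult",
    "CirclePoint",
    "TRGroup",
    "OverlapReport",
    "StratificationResult",
    "SurvivalEvaluation",
    "SimulationTruth",
]


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene identifiers (one GMT line)."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set requires a non-empty name")
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        object.__setattr__(self, "genes", frozenset(self.genes))

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class Regulon:
    """A transcriptional regulatory program: a TR and its inferred targets.

    Parameters
    ----------
    tr_id:
        Identifier of the transcriptional regulator (TF or co-factor).
    targets:
        Target gene identifiers, unique within the regulon.
    modes:
        Mode of regulation per target in ``[-1, 1]``; positive values mean the
        TR activates the target, negative that it represses it.
    likelihoods:
        Confidence weight per target in ``(0, 1]``; defaults to 1.
    """

    tr_id: str
    targets: np.ndarray
    modes: np.ndarray
    likelihoods: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.targets = np.asarray(self.targets, dtype=object)
        self.modes = np.asarray(self.modes, dtype=float)
        if self.likelihoods is None:
            self.likelihoods = np.ones(len(self.targets))
        self.likelihoods = np.asarray(self.likelihoods, dtype=float)
        if not (len(self.targets) == len(self.modes) == len(self.likelihoods)):
            raise ValueError(f"regulon {self.tr_id!r}: ragged target/mode/likelihood arrays")
        if len(set(self.targets)) != len(self.targets):
            raise ValueError(f"regulon {self.tr_id!r}: duplicate targets")
        if not np.all(np.isfinite(self.modes)) or np.any(np.abs(self.modes) > 1):
            raise ValueError(f"regulon {self.tr_id!r}: modes must be finite and in [-1, 1]")
        if np.any(self.likelihoods <= 0) or np.any(self.likelihoods > 1):
            raise ValueError(f"regulon {self.tr_id!r}: likelihoods must lie in (0, 1]")

    def __len__(self) -> int:
        return len(self.targets)


@dataclass
class Signature:
    """Genes with one real score each (single-sample z-scores or Welch t-values).

    Ranking is always by descending score with ties broken by ascending gene
    identifier, so the ordering is deterministic across runs.
    """

    gene_ids: np.ndarray
    scores: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.gene_ids) != len(self.scores):
            raise ValueError("signature: one score per gene required")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("signature: duplicate gene ids")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("signature: scores must be finite")

    def rank_order(self) -> np.ndarray:
        """Indices that sort genes by descending score, gene id ascending on ties."""
        ids = np.array([str(g) for g in self.gene_ids])
        return np.lexsort((ids, -self.scores))

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class EnrichmentResult:
    """Outcome of one weighted-KS enrichment of a query set in a signature."""

    es: float
    nes: float
    pvalue: float
    n_perm: int
    leading_edge: list[str] = field(default_factory=list)
    n_overlap: int = 0
    skipped_reason: str | None = None

    @property
    def skipped(self) -> bool:
        return self.skipped_reason is not None


#: columns of the network edge table, in serialization order
EDGE_COLUMNS = ["tr", "pathway", "alpha", "beta", "pvalue", "fdr", "sign", "weight"]


@dataclass
class MechanismNetwork:
    """Bipartite TR -> pathway network with regression statistics.

    ``edges`` has columns ``tr, pathway, alpha, beta, pvalue, fdr, sign`` and,
    once bootstrap analysis has run, ``weight`` (percent recovery in
    ``[0, 100]``). At most one edge per (tr, pathway) pair.
    """

    edges: pd.DataFrame
    tr_ids: list[str]
    pathway_ids: list[str]

    def __post_init__(self) -> None:
        self.edges = self.edges.reset_index(drop=True)
        if "weight" not in self.edges.columns:
            self.edges["weight"] = np.nan
        dup = self.edges.duplicated(subset=["tr", "pathway"])
        if dup.any():
            raise ValueError("duplicate (tr, pathway) edges")
        overlap = set(self.tr_ids) & set(self.pathway_ids)
        if overlap:
            raise ValueError(f"network must be bipartite; shared ids: {sorted(overlap)[:5]}")
        bad_tr = set(self.edges["tr"]) - set(self.tr_ids)
        bad_pw = set(self.edges["pathway"]) - set(self.pathway_ids)
        if bad_tr or bad_pw:
            raise ValueError("edge endpoints missing from node lists")

    @property
    def has_weights(self) -> bool:
        return bool(self.edges["weight"].notna().all()) and len(self.edges) > 0

    def neighbors(self, pathway_id: str) -> list[str]:
        """TRs with an edge into ``pathway_id``, in sorted order."""
        if pathway_id not in self.pathway_ids:
            raise KeyError(f"unknown pathway {pathway_id!r}")
        return sorted(self.edges.loc[self.edges["pathway"] == pathway_id, "tr"])

    def edge(self, tr_id: str, pathway_id: str) -> pd.Series:
        m = (self.edges["tr"] == tr_id) & (self.edges["pathway"] == pathway_id)
        if not m.any():
            raise KeyError(f"no edge {tr_id!r} -> {pathway_id!r}")
        return self.edges.loc[m].iloc[0]

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class BootstrapConfig:
    """Bootstrap resampling settings for edge-weight estimation."""

    k: int = 100
    rng_seed: int = 0
    recompute_mode: str = "resample_activities"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("bootstrap requires k >= 1")
        if self.recompute_mode not in ("resample_activities", "full_recompute"):
            raise ValueError(f"unknown recompute_mode {self.recompute_mode!r}")


@dataclass
class PhenotypeSeries:
    """Expression for the three treatment phenotypes (untreated, sensitive, resistant)."""

    intact: pd.DataFrame
    sensitive: pd.DataFrame
    resistant: pd.DataFrame

    def __post_init__(self) -> None:
        for name, df in self.groups().items():
            if df.shape[1] < 2:
                raise ValueError(f"phenotype group {name!r} needs >= 2 samples")
        g0 = set(self.intact.index)
        if not (g0 == set(self.sensitive.index) == set(self.resistant.index)):
            raise ValueError("phenotype groups must share one gene universe")

    def groups(self) -> dict[str, pd.DataFrame]:
        return {"intact": self.intact, "sensitive": self.sensitive, "resistant": self.resistant}


@dataclass
class MiningResult:
    """TRs upstream of one pathway passing the up-down-up pattern.

    ``records`` has one row per evaluated mechanism with columns
    ``mechanism, kind, nes_sig1, p_sig1, nes_sig2, p_sig2, passed``.
    """

    pathway_id: str
    passing_trs: set[str]
    records: pd.DataFrame
    p_threshold: float
    pathway_passes: bool
    reason: str | None = None


@dataclass
class CirclePoint:
    """Position of one mechanism on the circle of correlation."""

    mechanism_id: str
    x: float
    y: float

    @property
    def radius(self) -> float:
        return float(np.hypot(self.x, self.y))

    @property
    def angle_deg(self) -> float:
        """Full-circle inclination angle of (x, y) in degrees, in [0, 360)."""
        a = float(np.degrees(np.arctan2(self.y, self.x)) % 360.0)
        return 0.0 if a >= 360.0 else a  # -tiny % 360 rounds to exactly 360.0


@dataclass
class TRGroup:
    """A cluster of TRs with its prioritization statistics."""

    members: list[str]
    mean_closeness_deg: float
    mean_lv_correlation: float = np.nan
    mean_edge_weight: float = np.nan
    ranks: tuple[float, float, float] | None = None
    effect_score: float = np.nan
    final_rank: float = np.nan


@dataclass
class OverlapReport:
    """Set overlap between two gene collections."""

    size_a: int
    size_b: int
    n_common: int
    jaccard: float
    denominator: str = "sum"


@dataclass
class StratificationResult:
    """Two-way clustering of samples on a (pathway NES, TR NES) plane."""

    labels: pd.Series
    centroids: np.ndarray
    method_agreement: float
    thresholds: tuple[float, float]


@dataclass
class SurvivalEvaluation:
    """Log-rank and Cox proportional-hazards summary for a two-group stratification."""

    logrank_p: float
    hazard_ratio: float
    ci_low: float
    ci_high: float
    covariates: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


@dataclass
class SimulationTruth:
    """Ground truth of a simulated cohort.

    ``planted_edges`` are (tr_id, pathway_id, beta) triples; ``tr_activities``
    is the latent TR x sample activity matrix the expression was generated
    from; ``regulon_modes`` maps each TR to its target modes so downstream
    checks can reason about signs.
    """

    planted_edges: list[tuple[str, str, float]]
    tr_activities: pd.DataFrame
    up_down_up_trs: list[str] = field(default_factory=list)
    group_labels: pd.Series | None = None
    hazards: dict[str, float] = field(default_factory=dict)
    rng_seed: int = 0
    #: generative blueprint (gene assignments, modes, betas); not serialized
    design: object | None = None

    def planted_pairs(self) -> set[tuple[str, str]]:
        return {(t, p) for t, p, _ in self.planted_edges}

    def to_json(self) -> str:
        payload = {
            "planted_edges": [[t, p, float(b)] for t, p, b in self.planted_edges],
            "tr_activities": {
                "index": list(self.tr_activities.index),
                "columns": list(self.tr_activities.columns),
                "values": self.tr_activities.to_numpy().tolist(),
            },
            "up_down_up_trs": list(self.up_down_up_trs),
            "group_labels": None
            if self.group_labels is None
            else {"index": list(self.group_labels.index), "values": list(self.group_labels)},
            "hazards": self.hazards,
            "rng_seed": self.rng_seed,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SimulationTruth":
        d = json.loads(text)
        acts = pd.DataFrame(
            d["tr_activities"]["values"],
            index=d["tr_activities"]["index"],
            columns=d["tr_activities"]["columns"],
        )
        labels = None
        if d["group_labels"] is not None:
            labels = pd.Series(d["group_labels"]["values"], index=d["group_labels"]["index"])
        return cls(
            planted_edges=[(t, p, float(b)) for t, p, b in d["planted_edges"]],
            tr_activities=acts,
            up_down_up_trs=list(d["up_down_up_trs"]),
            group_labels=labels,
            hazards={k: float(v) for k, v in d["hazards"].items()},
            rng_seed=int(d["rng_seed"]),
        )
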