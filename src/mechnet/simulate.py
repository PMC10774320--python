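"""Synthetic cohorts with planted TR -> pathway regulatory structure.

The generator emulates the statistical skeleton the whole pipeline assumes:
latent per-sample TR activities, target genes linearly coupled to their TR
(with activating/repressing modes), pathway genes driven by a linear
combination of parent-TR activities (the planted edges), everything under
Gaussian noise. It also produces the three-phenotype treatment series with a
planted "up-down-up" TR trajectory, deliberately collinear TR activity
blocks, and group-dependent exponential survival times — each matching the
assumptions of the stage it feeds.

Default study conditions: 80 samples, 1200 genes, 30 TRs with 25 targets
each, 10 pathways with 25 genes each, unit effect size and gene-level noise
standard deviation 0.5. All outputs are fully determined by ``rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import GeneSet, PhenotypeSeries, Regulon, SimulationTruth

__all__ = ["CohortDesign", "make_cohort", "make_phenotype_series",
           "make_collinear_block", "make_survival", "make_prioritization_scenario"]


@dataclass
class CohortDesign:
    """Generative blueprint of a simulated cohort (gene wiring and noise)."""

    gene_ids: list[str]
    #: tr_id -> (target gene row indices, modes)
    tr_targets: dict[str, tuple[np.ndarray, np.ndarray]]
    #: pathway_id -> (member gene row indices, parent tr ids, parent betas)
    pathway_genes: dict[str, tuple[np.ndarray, list[str], np.ndarray]]
    effect: float
    noise_sd: float
    n_genes: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_genes = len(self.gene_ids)


def _expression_from_latents(design: CohortDesign, Z: pd.DataFrame,
                             rng: np.random.Generator) -> pd.DataFrame:
    """Expression matrix implied by latent TR activities ``Z`` (TRs x samples)."""
    n = Z.shape[1]
    expr = rng.normal(0.0, 1.0, size=(design.n_genes, n))  # background noise genes
    zv = Z.to_numpy(dtype=float)
    tr_row = {t: i for i, t in enumerate(Z.index)}
    for tr, (rows, modes) in design.tr_targets.items():
        noise = rng.normal(0.0, design.noise_sd, size=(len(rows), n))
        expr[rows] = modes[:, None] * design.effect * zv[tr_row[tr]][None, :] + noise
    for pw, (rows, parents, betas) in design.pathway_genes.items():
        drive = betas @ zv[[tr_row[t] for t in parents]]
        noise = rng.normal(0.0, design.noise_sd, size=(len(rows), n))
        expr[rows] = design.effect * drive[None, :] + noise
    return pd.DataFrame(expr, index=design.gene_ids, columns=Z.columns)


def make_cohort(n_samples: int = 80, n_genes: int = 1200, n_trs: int = 30,
                n_pathways: int = 10, targets_per_tr: int = 25,
                genes_per_pathway: int = 25, planted_edges=None,
                effect: float = 1.0, noise_sd: float = 0.5, rng_seed: int = 0
                ) -> tuple[pd.DataFrame, list[GeneSet], list[Regulon], SimulationTruth]:
    """Simulate an expression cohort with known TR -> pathway edges.

    Returns ``(expression, genesets, regulons, truth)``. Gene blocks (TR
    targets, pathway members, pure-noise genes) are disjoint. When
    ``planted_edges`` is None each pathway receives one or two parent TRs
    (sampled without replacement across pathways) with slopes of magnitude 1
    and random sign. Modes of regulation are ±1 with 70% activating.
    """
    for name, v in [("n_samples", n_samples), ("n_genes", n_genes), ("n_trs", n_trs),
                    ("n_pathways", n_pathways), ("targets_per_tr", targets_per_tr),
                    ("genes_per_pathway", genes_per_pathway)]:
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    needed = n_trs * targets_per_tr + n_pathways * genes_per_pathway
    if needed > n_genes:
        raise ValueError(f"gene pool too small: need {needed}, have {n_genes}")
    rng = np.random.default_rng(rng_seed)
    width = len(str(n_genes))
    gene_ids = [f"g{i + 1:0{width}d}" for i in range(n_genes)]
    tr_ids = [f"TR{i + 1:02d}" for i in range(n_trs)]
    pathway_ids = [f"PW{i + 1:02d}" for i in range(n_pathways)]
    sample_ids = [f"s{j + 1:03d}" for j in range(n_samples)]

    if planted_edges is None:
        parents_per_pw = [1 if i % 2 == 0 else 2 for i in range(n_pathways)]
        if sum(parents_per_pw) > n_trs:
            raise ValueError("not enough TRs for the default edge plan")
        pool = list(rng.permutation(tr_ids))
        planted_edges = []
        for pw, npar in zip(pathway_ids, parents_per_pw):
            for _ in range(npar):
                tr = pool.pop()
                beta = float(rng.choice([-1.0, 1.0]))
                planted_edges.append((tr, pw, beta))
    else:
        planted_edges = [(str(t), str(p), float(b)) for t, p, b in planted_edges]
        for t, p, _ in planted_edges:
            if t not in tr_ids or p not in pathway_ids:
                raise ValueError(f"planted edge references unknown ids ({t}, {p})")

    cursor = 0
    tr_targets: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for tr in tr_ids:
        rows = np.arange(cursor, cursor + targets_per_tr)
        cursor += targets_per_tr
        modes = rng.choice([1.0, -1.0], size=targets_per_tr, p=[0.7, 0.3])
        tr_targets[tr] = (rows, modes)
    pathway_genes: dict[str, tuple[np.ndarray, list[str], np.ndarray]] = {}
    for pw in pathway_ids:
        rows = np.arange(cursor, cursor + genes_per_pathway)
        cursor += genes_per_pathway
        parents = [t for t, p, _ in planted_edges if p == pw]
        betas = np.array([b for t, p, b in planted_edges if p == pw])
        pathway_genes[pw] = (rows, parents, betas)

    design = CohortDesign(gene_ids=gene_ids, tr_targets=tr_targets,
                          pathway_genes=pathway_genes, effect=effect, noise_sd=noise_sd)
    zv = rng.normal(0.0, 1.0, size=(n_trs, n_samples))
    if n_samples > n_trs:
        # whiten across TRs: in-sample latent correlations become exactly zero,
        # so the planted edges are the complete ground truth (no chance
        # latent-latent correlation masquerading as an unplanted edge)
        zc = zv - zv.mean(axis=1, keepdims=True)
        gram = zc @ zc.T / (n_samples - 1)
        zv = np.linalg.solve(np.linalg.cholesky(gram), zc)
    Z = pd.DataFrame(zv, index=tr_ids, columns=sample_ids)
    expr = _expression_from_latents(design, Z, rng)

    genesets = [GeneSet(pw, frozenset(gene_ids[r] for r in rows))
                for pw, (rows, _, _) in pathway_genes.items()]
    regulons = [Regulon(tr_id=tr,
                        targets=np.array([gene_ids[r] for r in rows], dtype=object),
                        modes=modes.copy())
                for tr, (rows, modes) in tr_targets.items()]
    truth = SimulationTruth(planted_edges=planted_edges, tr_activities=Z,
                            rng_seed=rng_seed, design=design)
    return expr, genesets, regulons, truth


def make_phenotype_series(truth: SimulationTruth, up_down_up_trs,
                          effect_size: float = 2.0, n_per_group: int = 4,
                          rng_seed: int = 0) -> PhenotypeSeries:
    """Three-phenotype series with a planted up-down-up TR trajectory.

    The listed TRs have latent activity ``+effect_size`` in the intact group,
    ``-effect_size`` in the treatment-sensitive group and ``+effect_size``
    again in the resistant group; every other TR keeps standard-normal latent
    activity, so all remaining structure is phenotype-independent.
    """
    if truth.design is None:
        raise ValueError("truth must carry its cohort design (as built by make_cohort)")
    design: CohortDesign = truth.design
    tr_ids = list(truth.tr_activities.index)
    up_down_up_trs = [str(t) for t in up_down_up_trs]
    unknown = set(up_down_up_trs) - set(tr_ids)
    if unknown:
        raise ValueError(f"unknown TRs in up_down_up_trs: {sorted(unknown)}")
    if n_per_group < 2:
        raise ValueError("each phenotype group needs >= 2 samples")
    rng = np.random.default_rng(rng_seed)
    planted = np.array([t in up_down_up_trs for t in tr_ids])
    level = {"intact": +effect_size, "sensitive": -effect_size, "resistant": +effect_size}
    frames = {}
    for group, lv in level.items():
        Z = rng.normal(0.0, 1.0, size=(len(tr_ids), n_per_group))
        Z[planted] = lv
        Zf = pd.DataFrame(Z, index=tr_ids,
                          columns=[f"{group}_{j + 1}" for j in range(n_per_group)])
        frames[group] = _expression_from_latents(design, Zf, rng)
    return PhenotypeSeries(intact=frames["intact"], sensitive=frames["sensitive"],
                           resistant=frames["resistant"])


def make_collinear_block(n_samples: int = 60, n_trs: int = 12, latent_dim: int = 1,
                         noise_sd: float = 0.1, rng_seed: int = 0) -> pd.DataFrame:
    """TR activity block driven by few shared factors (multi-collinear by design).

    Each TR vector is a mixture of ``latent_dim`` shared standard-normal
    factors (mixture coefficients of magnitude in [0.8, 1.2]) plus
    ``noise_sd`` Gaussian noise; at the default noise level every TR has
    VIF > 10. Larger ``noise_sd`` drives the VIFs toward 1.
    """
    if latent_dim >= n_trs:
        raise ValueError("latent_dim must be smaller than n_trs")
    rng = np.random.default_rng(rng_seed)
    F = rng.normal(0.0, 1.0, size=(latent_dim, n_samples))
    signs = rng.choice([-1.0, 1.0], size=(n_trs, latent_dim))
    A = signs * rng.uniform(0.8, 1.2, size=(n_trs, latent_dim))
    X = A @ F + rng.normal(0.0, noise_sd, size=(n_trs, n_samples))
    return pd.DataFrame(X, index=[f"TR{i + 1:02d}" for i in range(n_trs)],
                        columns=[f"s{j + 1:03d}" for j in range(n_samples)])


def make_survival(labels, hazard_high: float = 0.4, hazard_other: float = 0.1,
                  censor_rate: float = 0.0, rng_seed: int = 0
                  ) -> tuple[pd.Series, pd.Series]:
    """Exponential survival times with group-specific hazards.

    ``labels`` assigns each sample to ``high_high`` (hazard ``hazard_high``)
    or any other value (hazard ``hazard_other``). Censoring is independent
    exponential, calibrated so the expected censored fraction is
    ``censor_rate``; at 0 every event is observed.
    """
    if hazard_high <= 0 or hazard_other <= 0:
        raise ValueError("hazard rates must be positive")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must be in [0, 1)")
    labels = pd.Series(labels)
    rng = np.random.default_rng(rng_seed)
    hazards = np.where(labels.to_numpy() == "high_high", hazard_high, hazard_other)
    event_times = rng.exponential(1.0 / hazards)
    if censor_rate == 0:
        return (pd.Series(event_times, index=labels.index, name="time"),
                pd.Series(np.ones(len(labels), dtype=int), index=labels.index, name="event"))
    c = censor_rate / (1.0 - censor_rate)
    censor_times = rng.exponential(1.0 / (c * hazards))
    times = np.minimum(event_times, censor_times)
    events = (event_times <= censor_times).astype(int)
    return (pd.Series(times, index=labels.index, name="time"),
            pd.Series(events, index=labels.index, name="event"))


def make_prioritization_scenario(n_decoys: int = 10, n_samples: int = 60,
                                 bootstrap_k: int = 50, rng_seed: int = 0):
    """One dominant TR among collinear decoys, with a weighted one-pathway network.

    The dominant TR alone generates the pathway signal (unit slope plus 0.3-sd
    noise); the decoys are a mutually collinear block (one shared latent
    factor) that is independent of the pathway. So that every decoy is a
    network neighbour of the pathway — the situation prioritization is for —
    the base network keeps all candidate edges (permissive FDR cut) while the
    bootstrap weights are computed at the working FDR of 0.05, leaving decoy
    edges with near-zero stability and the dominant edge at 100. Returns
    ``(tr_acts, pathway_vec, network, dominant_id)``.
    """
    from .netbuild import bootstrap_weights, build_network
    from .datatypes import BootstrapConfig

    rng = np.random.default_rng(rng_seed)
    decoys = make_collinear_block(n_samples=n_samples, n_trs=n_decoys, latent_dim=1,
                                  noise_sd=0.1, rng_seed=int(rng.integers(2**31)))
    dominant = rng.normal(0.0, 1.0, size=n_samples)
    pathway = dominant + 0.3 * rng.normal(0.0, 1.0, size=n_samples)
    dominant_id = "TR_DOM"
    tr_acts = pd.concat([pd.DataFrame([dominant], index=[dominant_id],
                                      columns=decoys.columns), decoys])
    path_acts = pd.DataFrame([pathway], index=["PW01"], columns=decoys.columns)
    net = build_network(tr_acts, path_acts, fdr_threshold=1.01)  # keep all edges
    cfg = BootstrapConfig(k=bootstrap_k, rng_seed=rng_seed)
    net = bootstrap_weights(net, cfg, fdr_threshold=0.05,
                            tr_acts=tr_acts, path_acts=path_acts)
    return tr_acts, pd.Series(pathway, index=decoys.columns), net, dominant_id
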