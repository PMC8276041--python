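"""End-to-end pipeline: inputs -> heterogeneous network -> features ->
initial scores -> transition matrix -> propagation -> ranking."""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from . import features as ft
from .config import KFPMConfig
from .io import (DomainAnnotation, EssentialSet, ExpressionMatrix,
                 OrthologyTable, PPIGraph, RankedList, SubcellTable)
from .network import HeteroNetwork, build_hetero_network
from .propagation import (PropagationResult, TransitionMatrix, build_ndpm,
                          propagate, rank)

logger = logging.getLogger("kfpm")


@dataclasses.dataclass
class PipelineResult:
    """Ranking plus all intermediate artefacts, for inspection and dumps."""

    ranking: RankedList
    network: HeteroNetwork
    feature_table: np.ndarray
    critic: ft.CriticWeights
    bio: np.ndarray
    top: np.ndarray
    initial: ft.InitialScores
    ndpm: TransitionMatrix
    propagation: PropagationResult


def run_pipeline(ppi: PPIGraph, domains: DomainAnnotation,
                 expression: ExpressionMatrix, orthology: OrthologyTable,
                 subcellular: SubcellTable,
                 essential: EssentialSet | None = None,
                 config: KFPMConfig | None = None) -> PipelineResult:
    """Run the full ranking method on typed inputs.

    Auxiliary tables may cover proteins outside the PPI node set; those
    entries are ignored (the method operates on the PPI node set), and a
    PPI protein missing from a table contributes 0 for that feature.
    """
    cfg = config or KFPMConfig()
    het = build_hetero_network(ppi, domains, cfg)

    bio_i = ft.orthology_score(orthology, ppi.proteins)
    bio_exp = ft.expression_score(expression, ppi)
    bio_sub = ft.subcellular_score(subcellular, ppi.proteins)
    table = ft.feature_table(bio_i, bio_exp, bio_sub)

    critic = ft.critic_weights(table, raw=cfg.critic_raw)
    logger.info("CRITIC weights (%s): %s",
                "/".join(ft.FEATURE_NAMES),
                np.array2string(critic.weights, precision=4))
    bio = ft.bio_score(table, critic, raw=cfg.critic_raw)
    top = ft.topology_score(het, on_ppi_only=cfg.top_on_ppi_only)
    initial = ft.initial_scores(bio, top, cfg.theta, het.wpd)

    ndpm = build_ndpm(het, initial, cfg)
    prop = propagate(ndpm, initial, alpha=cfg.alpha, eps=cfg.eps,
                     max_iter=cfg.max_iter)
    logger.info("propagation converged in %d iterations (residual %.3e)",
                prop.iterations, prop.residual)
    ranking = rank(prop, ppi.proteins, essential=essential)
    return PipelineResult(ranking=ranking, network=het, feature_table=table,
                          critic=critic, bio=bio, top=top, initial=initial,
                          ndpm=ndpm, propagation=prop)


def degree_ranking(ppi: PPIGraph,
                   essential: EssentialSet | None = None) -> RankedList:
    """Baseline: rank proteins by PPI degree (the classic degree-centrality
    predictor); used for ablation comparisons."""
    deg = np.zeros(ppi.n)
    for i, j in ppi.edges:
        deg[i] += 1
        deg[j] += 1
    order = sorted(range(ppi.n), key=lambda i: (-deg[i], ppi.proteins[i]))
    ids = [ppi.proteins[i] for i in order]
    flags = None
    if essential is not None:
        ess = essential.proteins if hasattr(essential, "proteins") \
            else essential
        flags = np.array([p in ess for p in ids])
    return RankedList(proteins=ids, scores=deg[order], essential=flags)
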