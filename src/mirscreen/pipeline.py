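"""End-to-end screening: evidence → reference network → DE → candidates.

Chains the stages exactly as the screening workflow prescribes: assemble
the reference network under the evidence filters, screen DE miRNAs
(t test) and DE genes (best-of-six statistic by cross-study overlap),
induce the two condition-specific networks (miRNA-seeded Net1,
gene-seeded Net2), score NOD/TFP against the rewiring null in each, and
intersect the significant miRNAs into the candidate list.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .descreen import (
    DeMethod,
    DeResult,
    ExpressionStudy,
    de_genes,
    de_mirnas,
    select_method_by_overlap,
)
from .netbuild import (
    InteractionEvidence,
    RegulatoryNetwork,
    build_reference_network,
    filter_predictions,
    PredictionFilterConfig,
)
from .netstat import (
    BiomarkerCandidate,
    ConditionNetworkSpec,
    MirnaNetworkStats,
    induce_network,
    network_stats,
    select_candidates,
)

__all__ = ["ScreenResult", "screen_biomarkers"]


@dataclass
class ScreenResult:
    reference: RegulatoryNetwork
    net1: RegulatoryNetwork
    net2: RegulatoryNetwork
    de_mirnas: list[DeResult]
    de_gene_list: list[str]
    best_method: DeMethod
    stats_net1: list[MirnaNetworkStats]
    stats_net2: list[MirnaNetworkStats]
    candidates: list[BiomarkerCandidate]


def screen_biomarkers(
    evidence: Sequence[InteractionEvidence],
    mirna_study: ExpressionStudy,
    mrna_studies: Sequence[ExpressionStudy],
    tf_genes: Sequence[str],
    alpha: float = 0.05,
    top_fraction: float = 0.4,
    n_null: int = 1000,
    seed: int = 0,
    mode: str = "rewire",
    filter_config: PredictionFilterConfig | None = None,
    methods: Sequence[DeMethod] = tuple(DeMethod),
) -> ScreenResult:
    """Run the full network-based biomarker screen.

    DE genes come from the first mRNA study's top-fraction list under the
    statistic with the best cross-study overlap; DE miRNAs from the t test
    at ``alpha``. Candidate miRNAs have significantly high NOD and TFP
    (p < alpha, one-sided rewiring null with ``n_null`` replicates) in
    both condition-specific networks.
    """
    predicted = filter_predictions(evidence, filter_config)
    reference = build_reference_network(evidence, predicted)

    de_mir = de_mirnas(mirna_study, alpha=alpha)

    lists_by_method = {
        m: de_genes(mrna_studies, m, top_fraction=top_fraction) for m in methods
    }
    best_method, _ = select_method_by_overlap(lists_by_method)
    de_gene_list = list(lists_by_method[best_method][0])

    net1 = induce_network(
        reference,
        ConditionNetworkSpec(mirna_seed=frozenset(r.feature_id for r in de_mir)),
    )
    net2 = induce_network(
        reference, ConditionNetworkSpec(gene_seed=frozenset(de_gene_list))
    )
    stats1 = network_stats(net1, tf_genes, n_null=n_null, seed=seed, mode=mode)
    stats2 = network_stats(net2, tf_genes, n_null=n_null, seed=seed + 1, mode=mode)
    candidates = select_candidates(stats1, stats2, de_mir, alpha=alpha)
    return ScreenResult(
        reference=reference,
        net1=net1,
        net2=net2,
        de_mirnas=de_mir,
        de_gene_list=de_gene_list,
        best_method=best_method,
        stats_net1=stats1,
        stats_net2=stats2,
        candidates=candidates,
    )
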