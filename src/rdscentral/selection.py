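"""Central-node selection: top-k nodes from each of the m largest components.

Distributing the selection across components (rather than taking a single
city-wide top list) prevents the largest component from monopolising the
central set and yields a more diverse sample: with k=5 and m=3 the full set
holds 15 nodes per city and measure.  Score ties at the selection boundary
are broken by ascending node id so that selection is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from rdscentral.centrality import component_scores
from rdscentral.errors import EmptySelectionError
from rdscentral.network import ComponentRanking, ReferralForest, rank_components


@dataclass(frozen=True)
class SelectedNode:
    node_id: str
    component_id: str
    rank: int  # 1-based within the component
    score: float


@dataclass(frozen=True)
class CentralNodeSet:
    """The per-city, per-measure central set ``c`` used as the score denominator."""

    city: str
    measure: str
    members: tuple[SelectedNode, ...]
    k_per_component: int
    m_components: int
    shortfall: bool = False

    @property
    def set_size(self) -> int:
        return len(self.members)

    @property
    def node_ids(self) -> tuple[str, ...]:
        return tuple(m.node_id for m in self.members)


def select_central(
    scores: Mapping[str, Mapping],
    ranking: ComponentRanking,
    k: int,
    m: int,
    measure: str = "",
) -> CentralNodeSet:
    """Take the k highest-scoring nodes from each of the m top-ranked components.

    Parameters
    ----------
    scores:
        Mapping of component id (smallest node id in the component) to a
        node -> score mapping for one measure.
    ranking:
        Output of :func:`rdscentral.network.rank_components` for the city.
    k, m:
        Nodes per component and number of components.  A component smaller
        than k contributes all its nodes and the shortfall flag is set; the
        realized ``set_size`` (not k*m) is the exceptionality denominator.
    """
    if k < 1 or m < 1:
        raise ValueError("k and m must be >= 1")
    if not ranking.components:
        raise EmptySelectionError(f"no components to select from in {ranking.city!r}")
    members = []
    for cid, comp in zip(ranking.component_ids, ranking.components):
        if cid not in scores:
            raise KeyError(f"no scores for component {cid!r}")
        comp_scores = scores[cid]
        ordered = sorted(comp_scores, key=lambda v: (-comp_scores[v], v))
        for rank, node in enumerate(ordered[:k], start=1):
            members.append(SelectedNode(node, cid, rank, float(comp_scores[node])))
    return CentralNodeSet(
        city=ranking.city,
        measure=measure,
        members=tuple(members),
        k_per_component=k,
        m_components=m,
        shortfall=ranking.shortfall or len(members) < k * m,
    )


def central_nodes(
    forest: ReferralForest,
    city: str,
    measure: str,
    k: int = 5,
    m: int = 3,
    closeness_numerator: str = "N",
) -> CentralNodeSet:
    """Convenience: rank components, score them, and select in one call."""
    ranking = rank_components(forest, city, m)
    g = forest.graph(city)
    scores = {}
    for cid, comp in zip(ranking.component_ids, ranking.components):
        sub = g.subgraph(comp)
        scores[cid] = component_scores(
            sub, measures=(measure,), closeness_numerator=closeness_numerator
        )[measure]
    return select_central(scores, ranking, k=k, m=m, measure=measure)
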