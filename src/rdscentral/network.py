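"""Construction of the per-city referral forest from recruiter links.

Every respondent is a node; an undirected edge joins each recruiter to each
of their recruits.  Because a participant cannot recruit someone already in
the study, the result is a forest: within each city,
``|edges| = |nodes| - |components|``.  Recruitment direction is retained as
edge metadata only; all centrality computations treat edges as undirected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from rdscentral.errors import CrossCityError, CycleError, OrphanRecruiterError

#: Columns of a respondent table that are structural, not survey features.
ID_COLUMNS = ("respondent_id", "city", "recruiter_id")


def _is_missing(value) -> bool:
    return value is None or value == "" or pd.isna(value)


class ReferralForest:
    """Per-city forests of recruitment trees.

    Parameters
    ----------
    graphs:
        Mapping of city label to an undirected :class:`networkx.Graph` whose
        nodes are respondent ids.  Each edge carries a ``recruiter`` attribute
        naming the endpoint that did the recruiting; seed nodes carry a
        ``seed=True`` node attribute.
    """

    def __init__(self, graphs: dict[str, nx.Graph]):
        self.graphs = graphs

    @property
    def cities(self) -> list[str]:
        return sorted(self.graphs)

    def graph(self, city: str) -> nx.Graph:
        if city not in self.graphs:
            raise KeyError(f"city {city!r} not present in forest")
        return self.graphs[city]

    def components(self, city: str) -> list[set]:
        """Connected components of one city, as node sets.

        Ordered by decreasing size; ties broken by the lexicographically
        smallest contained respondent id, so the order is deterministic.
        """
        comps = [set(c) for c in nx.connected_components(self.graph(city))]
        return sorted(comps, key=lambda c: (-len(c), min(c)))

    def n_nodes(self, city: str | None = None) -> int:
        cities = [city] if city else self.cities
        return sum(self.graphs[c].number_of_nodes() for c in cities)

    def n_edges(self, city: str | None = None) -> int:
        cities = [city] if city else self.cities
        return sum(self.graphs[c].number_of_edges() for c in cities)

    def n_components(self, city: str | None = None) -> int:
        cities = [city] if city else self.cities
        return sum(nx.number_connected_components(self.graphs[c]) for c in cities)

    def is_forest(self) -> bool:
        """Acyclicity check via the tree identity |E| = |V| - #components."""
        return all(
            self.graphs[c].number_of_edges()
            == self.graphs[c].number_of_nodes()
            - nx.number_connected_components(self.graphs[c])
            for c in self.cities
        )

    def component_of(self, city: str, node) -> set:
        return set(nx.node_connected_component(self.graph(city), node))

    def edge_table(self) -> pd.DataFrame:
        """All edges as a (city, recruiter_id, recruit_id) table, sorted."""
        rows = []
        for city in self.cities:
            g = self.graphs[city]
            for u, v, attrs in g.edges(data=True):
                recruiter = attrs.get("recruiter", u)
                recruit = v if recruiter == u else u
                rows.append((city, recruiter, recruit))
        return pd.DataFrame(
            rows, columns=["city", "recruiter_id", "recruit_id"]
        ).sort_values(["city", "recruiter_id", "recruit_id"], ignore_index=True)

    def write_edge_list(self, path) -> None:
        self.edge_table().to_csv(path, index=False)

    def write_graphml(self, path, city: str) -> None:
        g = self.graph(city).copy()
        comps = self.components(city)
        for cid, comp in enumerate(comps):
            for n in comp:
                g.nodes[n]["component"] = min(comp)
                g.nodes[n]["city"] = city
                g.nodes[n].setdefault("seed", False)
        nx.write_graphml(g, path)


@dataclass(frozen=True)
class ComponentRanking:
    """The ``m`` largest components of one city, largest first."""

    city: str
    components: tuple[frozenset, ...]
    shortfall: bool = False

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(len(c) for c in self.components)

    @property
    def component_ids(self) -> tuple[str, ...]:
        """Stable component identifier: the smallest contained respondent id."""
        return tuple(min(c) for c in self.components)


def build_forest(table: pd.DataFrame) -> ReferralForest:
    """Build the referral forest from a respondent table.

    Parameters
    ----------
    table:
        One row per respondent with columns ``respondent_id``, ``city`` and
        ``recruiter_id`` (empty/NaN for seeds).  Extra columns are ignored.

    Raises
    ------
    OrphanRecruiterError
        If a recruiter id does not match any respondent id.
    CrossCityError
        If a recruitment link crosses cities.
    CycleError
        If an edge would close a cycle (including self-recruitment).
    """
    if table.empty:
        raise ValueError("respondent table is empty")
    ids = table["respondent_id"]
    if ids.duplicated().any():
        dupes = ids[ids.duplicated()].tolist()
        raise ValueError(f"duplicate respondent ids: {dupes[:10]}")
    city_of = dict(zip(ids, table["city"]))

    orphans = []
    edges = []
    for rid, city, recruiter in zip(ids, table["city"], table["recruiter_id"]):
        if _is_missing(recruiter):
            continue
        if recruiter not in city_of:
            orphans.append((rid, recruiter))
            continue
        if city_of[recruiter] != city:
            raise CrossCityError(
                f"recruit {rid!r} (city {city!r}) was recruited by "
                f"{recruiter!r} from city {city_of[recruiter]!r}"
            )
        edges.append((recruiter, rid))
    if orphans:
        raise OrphanRecruiterError(orphans)

    graphs: dict[str, nx.Graph] = {}
    parent: dict = {}  # union-find over respondent ids

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for rid, city in city_of.items():
        g = graphs.setdefault(city, nx.Graph())
        g.add_node(rid)
        parent[rid] = rid
    # Seeds are rows without a recruiter; mark them before edges are added.
    recruits = {r for _, r in edges}
    for rid, city in city_of.items():
        graphs[city].nodes[rid]["seed"] = rid not in recruits

    for recruiter, recruit in edges:
        ru, rv = find(recruiter), find(recruit)
        if ru == rv:
            raise CycleError(
                f"edge {recruiter!r} -> {recruit!r} would close a cycle; "
                "a participant cannot recruit someone already recruited"
            )
        parent[ru] = rv
        graphs[city_of[recruit]].add_edge(recruiter, recruit, recruiter=recruiter)
    return ReferralForest(graphs)


def rank_components(forest: ReferralForest, city: str, m: int) -> ComponentRanking:
    """Return the ``m`` largest components of ``city``.

    Ties in size are broken by the lexicographically smallest respondent id in
    the component.  If fewer than ``m`` components exist, all are returned and
    ``shortfall`` is flagged.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    comps = forest.components(city)
    top = comps[:m]
    return ComponentRanking(
        city=city,
        components=tuple(frozenset(c) for c in top),
        shortfall=len(top) < m,
    )
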