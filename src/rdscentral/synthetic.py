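"""Synthetic RDS cohort generator with plantable central-node signals.

The real survey data are restricted-access, so validation runs on synthetic
cohorts that emulate their statistical structure: a forest of recruitment
trees per city grown by a branching process (each participant independently
draws how many of their 6 coupons convert into recruits), plus an attribute
table with configurable per-city prevalences and missingness.  Under the
default settings the offspring mean sits near 1 (critical branching), which
reproduces the qualitative shape of coupon-based recruitment: a majority of
components of size 1-2 (seeds who recruited nobody or one person) alongside
occasional chains of tens to hundreds of nodes.

``plant_signal`` creates exact ground truth for recovery testing: it runs the
central-node selection stage, then re-draws one binary attribute at an
elevated rate among the selected central nodes and at the background city
prevalence elsewhere.  Because planting happens *after* selection, recovery
tests exercise the scoring stage in isolation; planting by topological
position before selection (end-to-end mode) is available via
``plant_signal(..., nodes=...)`` with a caller-chosen node set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from rdscentral.centrality import MEASURES
from rdscentral.errors import ConfigurationError
from rdscentral.network import ReferralForest
from rdscentral.selection import central_nodes

KINDS = ("binary", "ordinal", "numeric")


@dataclass(frozen=True)
class AttributeSpec:
    """One synthetic survey attribute.

    ``city_param`` is the Bernoulli prevalence (binary), the mean level
    (ordinal, on 0..n_levels-1) or the mean (numeric); it may be a scalar
    applied to every city or a mapping of city label to value.  ``planted``
    attributes are re-drawn among selected central nodes at
    ``planted_central_rate`` by :func:`plant_signal`.
    """

    name: str
    kind: str
    city_param: float | Mapping[str, float]
    sd: float | None = None
    n_levels: int = 5
    planted: bool = False
    planted_central_rate: float | None = None

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ConfigurationError(f"unknown attribute kind {self.kind!r}")
        params = (
            self.city_param.values()
            if isinstance(self.city_param, Mapping)
            else [self.city_param]
        )
        if self.kind == "binary" and not all(0 <= p <= 1 for p in params):
            raise ConfigurationError(f"binary prevalence outside [0,1] for {self.name!r}")
        if self.kind == "numeric" and self.sd is None:
            raise ConfigurationError(f"numeric attribute {self.name!r} needs sd")
        if self.planted and self.planted_central_rate is None:
            raise ConfigurationError(
                f"planted attribute {self.name!r} needs planted_central_rate"
            )

    def param_for(self, city: str) -> float:
        if isinstance(self.city_param, Mapping):
            return float(self.city_param[city])
        return float(self.city_param)


def default_attribute_specs() -> list[AttributeSpec]:
    """Survey-like defaults: low-prevalence risk markers, an ordinal and a numeric."""
    return [
        AttributeSpec("walks_transport", "binary", 0.06),
        AttributeSpec("divorced", "binary", 0.12),
        AttributeSpec("separated", "binary", 0.08),
        AttributeSpec("hotel_residence", "binary", 0.07),
        AttributeSpec("shelter_residence", "binary", 0.05),
        AttributeSpec("drug_other", "binary", 0.10),
        AttributeSpec("used_heroin", "binary", 0.15),
        AttributeSpec("race_other", "binary", 0.04),
        AttributeSpec("income_level", "ordinal", 1.5, n_levels=4),
        AttributeSpec("age", "numeric", 40.0, sd=11.0),
    ]


#: Coupon-conversion distribution over 0..6 recruits; mean 0.90 (slightly
#: subcritical), giving expected component size ~10 — so ~411 seeds yield a
#: cohort near the real study's 4688 participants, a majority of components
#: of size 1-2, and occasional chains running to hundreds of nodes.
DEFAULT_RECRUIT_DIST = (0.55, 0.22, 0.11, 0.06, 0.03, 0.02, 0.01)


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings; defaults emulate the three-city study's structure."""

    n_cities: int = 3
    seeds_per_city: int = 137
    coupon_max: int = 6
    recruit_count_dist: Sequence[float] = DEFAULT_RECRUIT_DIST
    max_waves: int = 30
    attribute_specs: Sequence[AttributeSpec] = field(
        default_factory=default_attribute_specs
    )
    missing_rate: float = 0.03
    rng_seed: int = 0
    city_names: Sequence[str] | None = None

    def __post_init__(self):
        if self.n_cities < 1 or self.seeds_per_city < 1:
            raise ConfigurationError("n_cities and seeds_per_city must be >= 1")
        if self.coupon_max < 1:
            raise ConfigurationError("coupon_max must be >= 1")
        dist = np.asarray(self.recruit_count_dist, dtype=float)
        if dist.shape != (self.coupon_max + 1,):
            raise ConfigurationError(
                f"recruit_count_dist must have {self.coupon_max + 1} entries "
                f"(counts 0..{self.coupon_max}), got {dist.size}"
            )
        if (dist < 0).any() or abs(dist.sum() - 1.0) > 1e-9:
            raise ConfigurationError("recruit_count_dist must be a probability vector")
        if not 0 <= self.missing_rate <= 1:
            raise ConfigurationError("missing_rate must be in [0,1]")
        if self.max_waves < 1:
            raise ConfigurationError("max_waves must be >= 1")
        if self.city_names is not None and len(self.city_names) != self.n_cities:
            raise ConfigurationError("city_names length must equal n_cities")

    @property
    def cities(self) -> list[str]:
        if self.city_names is not None:
            return list(self.city_names)
        return [f"city{i + 1}" for i in range(self.n_cities)]

    @classmethod
    def from_dict(cls, data: dict) -> "CohortConfig":
        data = dict(data)
        if "attribute_specs" in data:
            data["attribute_specs"] = [
                spec if isinstance(spec, AttributeSpec) else AttributeSpec(**spec)
                for spec in data["attribute_specs"]
            ]
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class SyntheticCohort:
    table: pd.DataFrame
    truth: frozenset
    forest: ReferralForest
    config: CohortConfig

    def write_table(self, path) -> None:
        out = self.table.copy()
        out = out.where(out.notna(), "")
        out.to_csv(path, index=False)


def _node_id(city: str, component: int, index: int) -> str:
    # zero-padded so lexicographic order matches creation order and the seed
    # (index 0) is always the smallest id in its component
    return f"{city}-{component:04d}-{index:04d}"


def simulate_forest(
    config: CohortConfig, rng: np.random.Generator | None = None
) -> ReferralForest:
    """Grow the referral forest: one branching-process tree per seed.

    Each participant draws a recruit count from ``recruit_count_dist``;
    growth stops after ``max_waves`` recruitment waves or when a wave
    produces no recruits.  Node degree is therefore bounded by
    ``coupon_max + 1`` (own recruiter plus a full book of coupons).
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    dist = np.asarray(config.recruit_count_dist, dtype=float)
    counts = np.arange(config.coupon_max + 1)
    graphs: dict[str, nx.Graph] = {}
    for city in config.cities:
        g = nx.Graph()
        for comp in range(config.seeds_per_city):
            seed = _node_id(city, comp, 0)
            g.add_node(seed, seed=True)
            next_index = 1
            frontier = [seed]
            for _ in range(config.max_waves):
                new_frontier = []
                for node in frontier:
                    k = int(rng.choice(counts, p=dist))
                    for _ in range(k):
                        child = _node_id(city, comp, next_index)
                        next_index += 1
                        g.add_node(child, seed=False, recruiter=node)
                        g.add_edge(node, child, recruiter=node)
                        new_frontier.append(child)
                frontier = new_frontier
                if not frontier:
                    break
        graphs[city] = g
    return ReferralForest(graphs)


def _draw(spec: AttributeSpec, city: str, n: int, rng: np.random.Generator):
    p = spec.param_for(city)
    if spec.kind == "binary":
        return (rng.random(n) < p).astype(float)
    if spec.kind == "ordinal":
        top = spec.n_levels - 1
        if not 0 <= p <= top:
            raise ConfigurationError(
                f"ordinal mean {p} outside [0, {top}] for {spec.name!r}"
            )
        return rng.binomial(top, p / top, size=n).astype(float)
    return rng.normal(p, spec.sd, size=n)


def simulate_attributes(
    forest: ReferralForest,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw the respondent table over the forest's nodes.

    Attributes follow their :class:`AttributeSpec`; every cell is
    independently blanked with probability ``missing_rate``.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    rows = []
    for city in forest.cities:
        g = forest.graph(city)
        for node in sorted(g.nodes):
            rows.append((node, city, g.nodes[node].get("recruiter", "")))
    table = pd.DataFrame(rows, columns=["respondent_id", "city", "recruiter_id"])
    for spec in config.attribute_specs:
        col = np.empty(len(table))
        for city in forest.cities:
            idx = np.flatnonzero((table["city"] == city).to_numpy())
            values = _draw(spec, city, idx.size, rng)
            if config.missing_rate > 0:
                values = np.where(
                    rng.random(idx.size) < config.missing_rate, np.nan, values
                )
            col[idx] = values
        table[spec.name] = col
    return table


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Forest plus attribute table from a single seeded generator."""
    rng = np.random.default_rng(config.rng_seed)
    forest = simulate_forest(config, rng)
    table = simulate_attributes(forest, config, rng)
    return SyntheticCohort(
        table=table, truth=frozenset(), forest=forest, config=config
    )


def plant_signal(
    cohort: SyntheticCohort,
    measure: str,
    spec: AttributeSpec,
    k: int = 5,
    m: int = 3,
    rng: np.random.Generator | None = None,
    nodes: Sequence[str] | None = None,
) -> SyntheticCohort:
    """Re-draw one binary attribute with an elevated rate among central nodes.

    Runs the selection stage (top ``k`` per component over the ``m`` largest
    components, per city) for ``measure``, then re-draws ``spec.name``:
    Bernoulli(``planted_central_rate``) on the selected nodes — always
    observed, so the ground truth is exact — and Bernoulli(city prevalence)
    elsewhere, with the configured missing rate.  ``nodes`` overrides the
    selection with an explicit node set (end-to-end planting mode).
    The forest topology is untouched; ``spec.name`` is recorded in ``truth``.
    """
    if not spec.planted:
        raise ConfigurationError(f"attribute {spec.name!r} is not marked planted")
    if spec.kind != "binary":
        raise ConfigurationError("only binary attributes can be planted")
    if measure not in MEASURES:
        raise ConfigurationError(f"unknown measure {measure!r}")
    if rng is None:
        rng = np.random.default_rng(cohort.config.rng_seed)

    if nodes is None:
        selected: set[str] = set()
        for city in cohort.forest.cities:
            central = central_nodes(cohort.forest, city, measure, k=k, m=m)
            selected.update(central.node_ids)
    else:
        selected = set(nodes)

    table = cohort.table.copy()
    n = len(table)
    is_central = table["respondent_id"].isin(selected).to_numpy()
    values = np.empty(n)
    for city in cohort.forest.cities:
        idx = np.flatnonzero((table["city"] == city).to_numpy())
        values[idx] = (rng.random(idx.size) < spec.param_for(city)).astype(float)
        if cohort.config.missing_rate > 0:
            values[idx] = np.where(
                rng.random(idx.size) < cohort.config.missing_rate,
                np.nan,
                values[idx],
            )
    values[is_central] = (
        rng.random(int(is_central.sum())) < spec.planted_central_rate
    ).astype(float)
    table[spec.name] = values
    return replace(
        cohort, table=table, truth=cohort.truth | frozenset([spec.name])
    )
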