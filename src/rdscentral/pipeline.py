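"""End-to-end orchestration: prep -> forest -> centrality -> selection -> scoring.

Every stage writes its intermediate table under the output directory, and a
run manifest records the configuration, seed and per-stage row counts, so a
run is reproducible bit-for-bit from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from rdscentral.centrality import MEASURES, component_scores
from rdscentral.exceptionality import compute_baseline, records_table, score_attributes
from rdscentral.network import build_forest, rank_components
from rdscentral.prep import filter_features, one_hot_encode
from rdscentral.selection import select_central
from rdscentral.synthetic import CohortConfig, simulate_cohort


@dataclass(frozen=True)
class PipelineConfig:
    """Full pipeline settings; defaults quote the published methodology."""

    input_table: str | None = None
    simulate: CohortConfig | None = None
    min_completeness: float = 0.94
    ordinal_features: Sequence[str] = ()
    metadata_exclusions: Sequence[str] = ()
    decline_codes: Sequence = ()
    k_per_component: int = 5
    m_components: int = 3
    measures: Sequence[str] = MEASURES
    min_count: int = 4
    closeness_numerator: str = "N"
    sd_form: str = "population"
    code_labels: Mapping[str, str] = field(default_factory=dict)
    rng_seed: int = 0
    out_dir: str = "rdscentral_out"

    def __post_init__(self):
        if self.input_table is None and self.simulate is None:
            raise ValueError("either input_table or simulate must be given")
        unknown = set(self.measures) - set(MEASURES)
        if unknown:
            raise ValueError(f"unknown measures: {sorted(unknown)}")
        if min(self.k_per_component, self.m_components, self.min_count) < 1:
            raise ValueError("k_per_component, m_components, min_count must be >= 1")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if isinstance(data.get("simulate"), dict):
            data["simulate"] = CohortConfig.from_dict(data["simulate"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def read_respondents(path) -> pd.DataFrame:
    """Read a respondent CSV; empty strings are missing values."""
    table = pd.read_csv(
        path, dtype={"respondent_id": str, "city": str, "recruiter_id": str}
    )
    return table


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    return obj


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage and return the path of the final report CSV."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    # --- input ---------------------------------------------------------
    if config.simulate is not None:
        sim_config = dataclasses.replace(config.simulate, rng_seed=config.rng_seed)
        cohort = simulate_cohort(sim_config)
        table = cohort.table
        cohort.write_table(out / "respondents.csv")
        table = read_respondents(out / "respondents.csv")  # same path as file input
    else:
        table = read_respondents(config.input_table)
    counts["respondents"] = len(table)

    # --- prep ----------------------------------------------------------
    filtered = filter_features(
        table,
        min_completeness=config.min_completeness,
        exclude=config.metadata_exclusions,
        decline_codes=config.decline_codes,
    )
    features = one_hot_encode(
        filtered,
        ordinal_features=config.ordinal_features,
        code_labels=dict(config.code_labels),
    )
    features.write(out / "features.csv", out / "features_meta.json")
    counts["features"] = len(features.feature_names)

    # --- forest --------------------------------------------------------
    forest = build_forest(table)
    forest.write_edge_list(out / "edges.csv")
    counts["edges"] = forest.n_edges()
    counts["components"] = forest.n_components()

    # --- centrality + selection over the analysed components -----------
    score_rows, member_rows, report_records = [], [], []
    n_tested = len(features.feature_names)
    for city in forest.cities:
        ranking = rank_components(forest, city, config.m_components)
        baseline = compute_baseline(features, city, sd_form=config.sd_form)
        g = forest.graph(city)
        per_measure_scores: dict[str, dict] = {meas: {} for meas in config.measures}
        for cid, comp in zip(ranking.component_ids, ranking.components):
            sub = g.subgraph(comp)
            all_scores = component_scores(
                sub,
                measures=config.measures,
                closeness_numerator=config.closeness_numerator,
            )
            for meas, node_scores in all_scores.items():
                per_measure_scores[meas][cid] = node_scores
                for node in sorted(node_scores):
                    score_rows.append((city, cid, node, meas, node_scores[node]))
        for meas in config.measures:
            central = select_central(
                per_measure_scores[meas],
                ranking,
                k=config.k_per_component,
                m=config.m_components,
                measure=meas,
            )
            for member in central.members:
                member_rows.append(
                    (
                        city,
                        meas,
                        member.component_id,
                        member.node_id,
                        member.rank,
                        member.score,
                    )
                )
            report_records.extend(
                score_attributes(
                    central, features, baseline, min_count=config.min_count
                )
            )

    pd.DataFrame(
        score_rows, columns=["city", "component_id", "node_id", "measure", "score"]
    ).to_csv(out / "centrality.csv", index=False)
    pd.DataFrame(
        member_rows,
        columns=["city", "measure", "component_id", "node_id", "rank", "score"],
    ).to_csv(out / "central_nodes.csv", index=False)
    counts["central_nodes"] = len(member_rows)

    # --- report --------------------------------------------------------
    report = records_table(report_records, n_attributes_tested=n_tested)
    report = report.sort_values(
        ["city", "centrality_type", "exceptionality", "attribute_code"],
        ascending=[True, True, False, True],
        ignore_index=True,
    )
    report_path = out / "report.csv"
    report.to_csv(report_path, index=False)
    with open(out / "report.json", "w") as fh:
        json.dump(
            {
                "n_attributes_tested": n_tested,
                "records": json.loads(report.to_json(orient="records")),
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    counts["report_records"] = len(report)

    with open(out / "manifest.json", "w") as fh:
        json.dump(
            {
                "config": _jsonable(config),
                "rng_seed": config.rng_seed,
                "stage_counts": counts,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    return report_path
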