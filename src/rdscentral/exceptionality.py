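"""Attribute exceptionality among central nodes.

Each central node's attribute values are compared with that attribute's city
baseline (mean and standard deviation over the observed values of all the
city's respondents).  A value more than two standard deviations from the
city mean is *deviant*.  An attribute deviant in at least ``min_count``
central nodes (default 4 of 15) is *exceptional*, scored
``deviant_count / set_size`` — the fraction of the central set sharing the
deviation.  For a binary attribute with city prevalence p this reduces to:
a 1 is deviant iff p < 0.2 and a 0 is deviant iff p > 0.8 (with the
population-form standard deviation sqrt(p(1-p))).

The standard deviation defaults to the population form (divide by n); at
realistic city sizes the sample/population distinction is negligible, and
the population form makes the binary p < 0.2 boundary exact.  Missing values
never count as deviant.  No multiple-testing correction is applied; the
record set carries ``n_attributes_tested`` so users can post-correct.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from rdscentral.prep import FeatureMatrix
from rdscentral.selection import CentralNodeSet


@dataclass(frozen=True)
class BaselineEntry:
    mean: float
    sd: float
    n_observed: int


@dataclass
class CityBaseline:
    """Per-attribute mean/sd over a city's observed values."""

    city: str
    entries: dict[str, BaselineEntry] = field(default_factory=dict)
    sd_form: str = "population"

    def available(self, attribute: str) -> bool:
        return attribute in self.entries

    def __getitem__(self, attribute: str) -> BaselineEntry:
        return self.entries[attribute]


@dataclass(frozen=True)
class ExceptionalityRecord:
    city: str
    measure: str
    attribute: str
    deviant_count: int
    set_size: int
    plaintext: str = ""

    @property
    def score(self) -> float:
        return self.deviant_count / self.set_size

    @property
    def score_4dp(self) -> float:
        """Score rounded to 4 decimal places, the report precision."""
        return round(self.score, 4)


def compute_baseline(
    features: FeatureMatrix, city: str, sd_form: str = "population"
) -> CityBaseline:
    """Mean and standard deviation per attribute over one city's observed values.

    Attributes with zero observed values in the city are omitted (marked
    unavailable) and skipped downstream.  ``sd_form`` selects divide-by-n
    ("population", default) or divide-by-(n-1) ("sample").
    """
    if sd_form not in ("population", "sample"):
        raise ValueError("sd_form must be 'population' or 'sample'")
    in_city = features.city_of() == city
    if int(in_city.sum()) < 2:
        raise ValueError(f"city {city!r} has fewer than 2 respondents")
    block = features.values.loc[in_city]
    ddof = 0 if sd_form == "population" else 1
    baseline = CityBaseline(city=city, sd_form=sd_form)
    n_obs = block.notna().sum()
    means = block.mean()
    sds = block.std(ddof=ddof)
    for attr in block.columns:
        n = int(n_obs[attr])
        if n == 0:
            continue
        sd = float(sds[attr]) if n > ddof else 0.0
        baseline.entries[attr] = BaselineEntry(float(means[attr]), sd, n)
    return baseline


def flag_deviant(value: float, entry: BaselineEntry) -> bool:
    """True iff the observed value lies more than two SDs from the city mean.

    With sd = 0 any value different from the mean counts as deviant.
    """
    if entry.sd == 0.0:
        return value != entry.mean
    return abs(value - entry.mean) > 2.0 * entry.sd


def score_attributes(
    central: CentralNodeSet,
    features: FeatureMatrix,
    baseline: CityBaseline,
    min_count: int = 4,
    code_labels: dict[str, str] | None = None,
) -> list[ExceptionalityRecord]:
    """Exceptionality records for every attribute meeting the report threshold.

    For each attribute, ``deviant_count`` is the number of central members
    whose *observed* value is deviant (missing values cannot contribute).
    Records with ``deviant_count >= min_count`` are returned sorted by
    descending score, then attribute name.
    """
    if not central.members:
        raise ValueError("central node set is empty")
    labels = {**features.code_labels, **(code_labels or {})}
    member_ids = [m.node_id for m in central.members]
    block = features.values.loc[member_ids]
    records = []
    for attr in block.columns:
        if not baseline.available(attr):
            continue
        entry = baseline[attr]
        count = sum(
            flag_deviant(v, entry) for v in block[attr] if not math.isnan(v)
        )
        if count >= min_count:
            records.append(
                ExceptionalityRecord(
                    city=central.city,
                    measure=central.measure,
                    attribute=attr,
                    deviant_count=count,
                    set_size=central.set_size,
                    plaintext=labels.get(attr, ""),
                )
            )
    records.sort(key=lambda r: (-r.score, r.attribute))
    return records


def records_table(records, n_attributes_tested: int | None = None) -> pd.DataFrame:
    """Records as the report table mirroring the published result layout."""
    df = pd.DataFrame(
        [
            {
                "city": r.city,
                "centrality_type": r.measure,
                "attribute_code": r.attribute,
                "attribute_plaintext": r.plaintext,
                "deviant_count": r.deviant_count,
                "set_size": r.set_size,
                "exceptionality": r.score_4dp,
            }
            for r in records
        ],
        columns=[
            "city",
            "centrality_type",
            "attribute_code",
            "attribute_plaintext",
            "deviant_count",
            "set_size",
            "exceptionality",
        ],
    )
    if n_attributes_tested is not None:
        df.attrs["n_attributes_tested"] = n_attributes_tested
    return df
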