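"""Feature filtering and one-hot encoding of the respondent table.

Survey answers arrive as mixed categorical/ordinal/numeric columns with
substantial missingness (respondents may decline any question).  Cleaning is
one global pass pooled across cities: features observed in at least a given
fraction of respondents (default 94%) are retained, metadata columns are
dropped regardless, and declined-answer codes are treated as missing.
Categorical features without an ordinal relationship are then one-hot
encoded: a k-level feature becomes k binary indicator columns named
``{feature}-{level}`` (the income high/medium/low example becomes three
yes/no questions).  Two-level features collapse to a single 0/1 indicator to
avoid a pair of perfectly anti-correlated columns that would double-count
deviance downstream.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from rdscentral.network import ID_COLUMNS


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in ID_COLUMNS]


def completeness(table: pd.DataFrame) -> pd.Series:
    """Observed (non-missing) fraction per feature column, pooled over cities."""
    feats = table[feature_columns(table)]
    obs = feats.notna() & (feats.astype(object) != "")
    return obs.mean()


def filter_features(
    table: pd.DataFrame,
    min_completeness: float = 0.94,
    exclude: Iterable[str] = (),
    decline_codes: Iterable = (),
) -> pd.DataFrame:
    """Drop features observed in fewer than ``min_completeness`` of rows.

    ``exclude`` lists metadata features dropped regardless of completeness.
    Values in ``decline_codes`` (declined/refused answer codes) are converted
    to missing before completeness is computed.  The row set is unchanged.
    """
    if not 0 < min_completeness <= 1:
        raise ValueError("min_completeness must be in (0, 1]")
    if table.empty:
        raise ValueError("respondent table is empty")
    table = table.copy()
    feats = feature_columns(table)
    decline = set(decline_codes)
    if decline:
        table[feats] = table[feats].where(~table[feats].isin(decline), np.nan)
    frac = completeness(table)
    keep = [c for c in feats if frac[c] >= min_completeness and c not in set(exclude)]
    if not keep:
        warnings.warn("all features dropped by completeness filter", stacklevel=2)
    return table[list(ID_COLUMNS) + keep]


@dataclass
class FeatureMatrix:
    """Respondents x post-encoding features.

    ``values`` is a float frame indexed by respondent id; NaN marks missing.
    ``feature_kind`` maps each column to ``"binary"`` or ``"numeric"``;
    ``groups`` maps each raw feature to the derived columns it produced.
    """

    values: pd.DataFrame
    feature_kind: dict[str, str]
    groups: dict[str, list[str]]
    meta: pd.DataFrame
    ordinal_features: tuple[str, ...] = ()
    code_labels: dict[str, str] = field(default_factory=dict)

    @property
    def respondent_ids(self):
        return self.values.index

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def mask(self) -> pd.DataFrame:
        """Boolean frame, True exactly where the value is missing."""
        return self.values.isna()

    def city_of(self) -> pd.Series:
        return self.meta["city"]

    def decode(self, raw_feature: str) -> pd.Series:
        """Recover the raw categorical value from its one-hot group (argmax)."""
        cols = self.groups[raw_feature]
        block = self.values[cols]
        if len(cols) == 1:
            return block[cols[0]]
        levels = [c[len(raw_feature) + 1 :] for c in cols]
        observed = block.notna().any(axis=1)
        out = pd.Series(np.nan, index=block.index, dtype=object)
        out[observed] = block.loc[observed].idxmax(axis=1)
        return out.map(dict(zip(cols, levels)), na_action="ignore")

    def sidecar(self) -> dict:
        return {
            "feature_kind": self.feature_kind,
            "groups": self.groups,
            "ordinal_features": sorted(self.ordinal_features),
            "code_labels": self.code_labels,
        }

    def write(self, values_path, sidecar_path) -> None:
        self.values.join(self.meta).to_csv(values_path)
        with open(sidecar_path, "w") as fh:
            json.dump(self.sidecar(), fh, indent=2, sort_keys=True)


def _observed(series: pd.Series) -> pd.Series:
    return series.notna() & (series.astype(object) != "")


def one_hot_encode(
    table: pd.DataFrame,
    ordinal_features: Iterable[str] = (),
    code_labels: dict[str, str] | None = None,
) -> FeatureMatrix:
    """Encode a respondent table into the analysis-ready feature matrix.

    Ordinal and numeric features pass through unchanged; non-ordinal
    categorical features with k observed levels expand into k binary
    indicators (k=2 collapses to one, coded 1 for the lexicographically
    larger level).  A missing raw value leaves every derived column missing
    for that respondent.
    """
    ordinal = set(ordinal_features)
    unknown = ordinal - set(feature_columns(table))
    if unknown:
        raise ValueError(f"ordinal features not in table: {sorted(unknown)}")
    index = pd.Index(table["respondent_id"], name="respondent_id")
    columns: dict[str, pd.Series] = {}
    kinds: dict[str, str] = {}
    groups: dict[str, list[str]] = {}

    for feat in feature_columns(table):
        raw = table[feat].mask(~_observed(table[feat]))
        numeric = pd.to_numeric(raw, errors="coerce")
        coercible = (numeric.notna() | raw.isna()).all()
        if feat in ordinal:
            if not coercible:
                bad = sorted(set(raw[numeric.isna() & raw.notna()].astype(str)))
                raise ValueError(
                    f"ordinal feature {feat!r} has non-orderable values: {bad[:5]}"
                )
            columns[feat] = numeric.set_axis(index)
            observed = numeric.dropna().unique()
            kinds[feat] = "binary" if set(observed) <= {0.0, 1.0} else "numeric"
            groups[feat] = [feat]
        elif coercible:
            columns[feat] = numeric.set_axis(index)
            observed = numeric.dropna().unique()
            kinds[feat] = "binary" if set(observed) <= {0.0, 1.0} else "numeric"
            groups[feat] = [feat]
        else:
            levels = sorted(raw.dropna().astype(str).unique())
            str_raw = raw.astype(object).where(raw.isna(), raw.astype(str))
            if len(levels) <= 2:
                # single indicator: 1 codes the lexicographically larger level
                positive = levels[-1]
                col = (str_raw == positive).astype(float).where(raw.notna())
                columns[feat] = col.set_axis(index)
                kinds[feat] = "binary"
                groups[feat] = [feat]
            else:
                groups[feat] = []
                for level in levels:
                    name = f"{feat}-{level}"
                    col = (str_raw == level).astype(float).where(raw.notna())
                    columns[name] = col.set_axis(index)
                    kinds[name] = "binary"
                    groups[feat].append(name)

    values = pd.DataFrame(columns, index=index, dtype=float)
    meta = table.set_index(pd.Index(table["respondent_id"], name="respondent_id"))[
        ["city", "recruiter_id"]
    ]
    return FeatureMatrix(
        values=values,
        feature_kind=kinds,
        groups=groups,
        meta=meta,
        ordinal_features=tuple(sorted(ordinal)),
        code_labels=dict(code_labels or {}),
    )
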