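"""Comparison of median-height percentile curves against external references.

External reference tables (KIGGS/OLAF/CHNS-style) are user-supplied CSV
with columns ``source, sex, measure, age, P50, P90`` giving the reference
P50/P90 at median height; none are bundled.  Differences are computed on
the exact age intersection only (no interpolation across ages), with the
sign convention positive = ours higher.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["ReferenceTable", "load_reference_table", "compare", "ComparisonCurve"]

_REF_COLUMNS = ["source", "sex", "measure", "age", "P50", "P90"]


@dataclass(frozen=True)
class ReferenceTable:
    source: str
    sex: str
    measure: str
    df: pd.DataFrame  # columns: age, P50, P90

    def __post_init__(self):
        ages = self.df["age"].to_numpy()
        if not (len(ages) and (ages[1:] > ages[:-1]).all()):
            raise ValueError("reference ages must be strictly increasing")
        if not (self.df["P90"] > self.df["P50"]).all():
            raise ValueError("reference must satisfy P90 > P50 rowwise")


def load_reference_table(path, source=None, sex=None, measure=None) -> list:
    """Read reference tables from CSV; returns one ReferenceTable per
    (source, sex, measure) present, optionally filtered."""
    df = pd.read_csv(path)
    missing = set(_REF_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"reference CSV missing columns {sorted(missing)}")
    out = []
    for (src, sx, ms), g in df.groupby(["source", "sex", "measure"]):
        if source and src != source or sex and sx != sex or measure and ms != measure:
            continue
        out.append(ReferenceTable(src, sx, ms, g.sort_values("age")[["age", "P50", "P90"]]
                                  .reset_index(drop=True)))
    return out


@dataclass(frozen=True)
class ComparisonCurve:
    """Per-age difference (ours - reference) in mmHg at median height."""

    source: str
    sex: str
    measure: str
    percentile: int
    df: pd.DataFrame  # columns: age, ours, reference, difference


def compare(ours: pd.DataFrame, ref: ReferenceTable, percentile: int = 50) -> ComparisonCurve:
    """Difference of our median-height percentile minus the reference.

    ``ours`` is a threshold table in the long emission format; rows are
    matched on exact integer age within the common range.
    """
    if percentile not in (50, 90):
        raise ValueError("percentile must be 50 or 90")
    col = f"P{percentile}"
    mine = ours[(ours["sex"] == ref.sex) & (ours["measure"] == ref.measure)
                & (ours["height_pct"] == "50th")][["age", col]]
    merged = mine.merge(ref.df[["age", col]], on="age", suffixes=("_ours", "_ref"))
    if merged.empty:
        raise ValueError("no overlapping ages between table and reference")
    out = pd.DataFrame(dict(
        age=merged["age"],
        ours=merged[f"{col}_ours"].astype(float),
        reference=merged[f"{col}_ref"].astype(float),
    ))
    out["difference"] = out["ours"] - out["reference"]
    return ComparisonCurve(ref.source, ref.sex, ref.measure, percentile,
                           out.sort_values("age").reset_index(drop=True))
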