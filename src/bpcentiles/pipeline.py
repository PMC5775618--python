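"""Deterministic cohort preparation for reference-centile construction.

Exclusion accounting, IOTF weight-status classification, reduction of the
triplicate oscillometric readings to the analysis value (mean of readings
2 and 3), baseline summary tables and the survey sample-size utility.

Cohorts are plain pandas DataFrames with columns::

    id, sex, age, height_cm, weight_kg, sbp1, sbp2, sbp3, dbp1, dbp2, dbp3

``sex`` is "M"/"F" and ``age`` is decimal years.  Missing values are NaN.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "IOTFCutoffTable",
    "load_iotf_cutoffs",
    "classify_iotf",
    "reduce_readings",
    "OutlierLimits",
    "ExclusionReport",
    "apply_exclusions",
    "summarize_baseline",
    "sample_size",
    "participation_rate",
    "READING_COLUMNS",
    "COHORT_COLUMNS",
]

READING_COLUMNS = ["sbp1", "sbp2", "sbp3", "dbp1", "dbp2", "dbp3"]
COHORT_COLUMNS = ["id", "sex", "age", "height_cm", "weight_kg"] + READING_COLUMNS

#: ordered exclusion rules; each record is counted under the first it violates
EXCLUSION_ORDER = ["age_below_min", "age_above_max", "missing_or_outlying", "overweight", "obese"]


@dataclass(frozen=True)
class IOTFCutoffTable:
    """IOTF (Cole et al., 2000) sex- and age-specific BMI cut-offs.

    Half-year grid from age 2 to 18; the cut-offs pass through adult BMI
    25 (overweight) and 30 (obesity) at age 18.  Classification linearly
    interpolates between grid ages.
    """

    age: np.ndarray
    cutoff_25: dict  # sex -> np.ndarray
    cutoff_30: dict

    @property
    def age_min(self) -> float:
        return float(self.age[0])

    @property
    def age_max(self) -> float:
        return float(self.age[-1])


def load_iotf_cutoffs() -> IOTFCutoffTable:
    """Load the packaged IOTF BMI cut-off fixture."""
    with resources.files("bpcentiles.data").joinpath("iotf_bmi_cutoffs.csv").open() as fh:
        df = pd.read_csv(fh)
    return IOTFCutoffTable(
        age=df["age"].to_numpy(),
        cutoff_25={"M": df["boys_25"].to_numpy(), "F": df["girls_25"].to_numpy()},
        cutoff_30={"M": df["boys_30"].to_numpy(), "F": df["girls_30"].to_numpy()},
    )


def classify_iotf(sex, age, bmi, table: IOTFCutoffTable | None = None):
    """Weight status ("normal" / "overweight" / "obese") by IOTF cut-offs.

    A BMI exactly on a cut-off counts as the heavier class.  Vectorised:
    scalar or array ``sex``/``age``/``bmi`` are accepted.
    """
    if table is None:
        table = load_iotf_cutoffs()
    sex_arr = np.atleast_1d(np.asarray(sex, dtype=object))
    age_arr = np.atleast_1d(np.asarray(age, dtype=float))
    bmi_arr = np.atleast_1d(np.asarray(bmi, dtype=float))
    sex_arr, age_arr, bmi_arr = np.broadcast_arrays(sex_arr, age_arr, bmi_arr)
    if np.any((age_arr < table.age_min) | (age_arr > table.age_max)):
        raise ValueError(
            f"age outside the IOTF cut-off range [{table.age_min}, {table.age_max}]; "
            "age-filter the cohort first"
        )
    if np.any(bmi_arr <= 0):
        raise ValueError("bmi must be > 0")
    out = np.full(sex_arr.shape, "normal", dtype=object)
    for s in ("M", "F"):
        m = sex_arr == s
        if not np.any(m):
            continue
        c25 = np.interp(age_arr[m], table.age, table.cutoff_25[s])
        c30 = np.interp(age_arr[m], table.age, table.cutoff_30[s])
        cls = np.where(bmi_arr[m] >= c30, "obese", np.where(bmi_arr[m] >= c25, "overweight", "normal"))
        out[m] = cls
    if np.ndim(sex) == 0 and np.ndim(age) == 0 and np.ndim(bmi) == 0:
        return str(out[0])
    return out


def reduce_readings(record):
    """Analysis BP of one child: mean of readings 2 and 3 (reading 1 ignored).

    ``record`` is any mapping with keys sbp2, sbp3, dbp2, dbp3.  Raises if
    either of the used readings is missing; callers flag such records as
    missing under the exclusion rules.
    """
    vals = [record[k] for k in ("sbp2", "sbp3", "dbp2", "dbp3")]
    if any(v is None or (isinstance(v, float) and np.isnan(v)) for v in vals):
        raise ValueError("readings 2 and 3 are required for the analysis BP")
    return (vals[0] + vals[1]) / 2.0, (vals[2] + vals[3]) / 2.0


@dataclass(frozen=True)
class OutlierLimits:
    """Physiologically-impossible-value screen (the survey did not publish
    its operational outlier rule; these bounds are a declared default)."""

    height_cm: tuple = (80.0, 210.0)
    weight_kg: tuple = (8.0, 150.0)
    sbp: tuple = (40.0, 250.0)
    dbp: tuple = (20.0, 150.0)


@dataclass
class ExclusionReport:
    """Per-rule removal counts with application order, plus accounting."""

    consented: int
    counts: dict = field(default_factory=dict)  # rule -> count, EXCLUSION_ORDER
    analysis_n: int = 0
    by_sex: dict = field(default_factory=dict)  # sex -> analysis count
    invited: int | None = None

    @property
    def total_excluded(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def participation_rate(self) -> float | None:
        if self.invited is None:
            return None
        return participation_rate(self.invited, self.consented)

    def validate(self) -> None:
        if self.consented - self.total_excluded != self.analysis_n:
            raise ValueError("exclusion accounting does not conserve records")

    @classmethod
    def from_counts(cls, consented, age_below_min=0, age_above_max=0,
                    missing_or_outlying=0, overweight=0, obese=0, invited=None,
                    by_sex=None):
        """Build a report from component counts (e.g. published numbers)."""
        counts = {
            "age_below_min": int(age_below_min),
            "age_above_max": int(age_above_max),
            "missing_or_outlying": int(missing_or_outlying),
            "overweight": int(overweight),
            "obese": int(obese),
        }
        rep = cls(consented=int(consented), counts=counts,
                  analysis_n=int(consented) - int(sum(counts.values())),
                  by_sex=by_sex or {}, invited=invited)
        rep.validate()
        return rep

    def to_json(self) -> str:
        d = dict(consented=self.consented, invited=self.invited,
                 exclusions=self.counts, total_excluded=self.total_excluded,
                 analysis_n=self.analysis_n, by_sex=self.by_sex,
                 participation_rate=self.participation_rate,
                 order=EXCLUSION_ORDER)
        return json.dumps(d, indent=2)


def participation_rate(invited: int, consented: int) -> float:
    """Participation as a percentage, one decimal (e.g. 74.2)."""
    return round(100.0 * consented / invited, 1)


def _missing_or_outlying_mask(df: pd.DataFrame, limits: OutlierLimits) -> pd.Series:
    required = ["sex", "age", "height_cm", "weight_kg", "sbp2", "sbp3", "dbp2", "dbp3"]
    bad = df[required].isna().any(axis=1)
    h, w = df["height_cm"], df["weight_kg"]
    bad |= (h < limits.height_cm[0]) | (h > limits.height_cm[1])
    bad |= (w < limits.weight_kg[0]) | (w > limits.weight_kg[1])
    for c in ("sbp1", "sbp2", "sbp3"):
        if c in df:
            bad |= (df[c] < limits.sbp[0]) | (df[c] > limits.sbp[1])
    for c in ("dbp1", "dbp2", "dbp3"):
        if c in df:
            bad |= (df[c] < limits.dbp[0]) | (df[c] > limits.dbp[1])
    return bad.fillna(False) | df[required].isna().any(axis=1)


def apply_exclusions(cohort: pd.DataFrame, iotf: IOTFCutoffTable | None = None,
                     age_min: float = 3.0, age_max: float = 17.0,
                     limits: OutlierLimits = OutlierLimits(),
                     invited: int | None = None):
    """Sequential exclusions with full accounting.

    Order (each record counted under the first rule it violates):
    age below ``age_min`` -> age ``>= age_max + 1`` (completed years above
    the window) -> missing/outlying fields -> IOTF overweight -> IOTF obese.

    Returns the analysis cohort (with derived ``bmi``, ``sbp``, ``dbp``
    columns; all weight-normal, in the age window) and an ExclusionReport.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    if iotf is None:
        iotf = load_iotf_cutoffs()
    df = cohort.reset_index(drop=True)
    n = len(df)
    rule = np.full(n, "", dtype=object)

    age = df["age"].to_numpy(dtype=float)
    below = np.isnan(age) | (age < age_min)
    # treat missing age as missing data, not as under-age
    below &= ~np.isnan(age)
    above = ~np.isnan(age) & (age >= age_max + 1.0)
    rule[below] = "age_below_min"
    rule[(rule == "") & above] = "age_above_max"

    missing = _missing_or_outlying_mask(df, limits).to_numpy()
    rule[(rule == "") & missing] = "missing_or_outlying"

    ok = rule == ""
    bmi = df["weight_kg"].to_numpy(dtype=float) / (df["height_cm"].to_numpy(dtype=float) / 100.0) ** 2
    status = np.full(n, "normal", dtype=object)
    if np.any(ok):
        status[ok] = classify_iotf(df.loc[ok, "sex"].to_numpy(),
                                   age[ok], bmi[ok], iotf)
    rule[(rule == "") & (status == "overweight")] = "overweight"
    rule[(rule == "") & (status == "obese")] = "obese"

    keep = rule == ""
    out = df.loc[keep].copy()
    out["bmi"] = bmi[keep]
    out["sbp"] = (out["sbp2"] + out["sbp3"]) / 2.0
    out["dbp"] = (out["dbp2"] + out["dbp3"]) / 2.0

    counts = {r: int(np.sum(rule == r)) for r in EXCLUSION_ORDER}
    by_sex = out.groupby("sex").size().to_dict()
    report = ExclusionReport(consented=n, counts=counts, analysis_n=int(keep.sum()),
                             by_sex={k: int(v) for k, v in by_sex.items()},
                             invited=invited)
    report.validate()
    return out.reset_index(drop=True), report


_DEFAULT_BANDS = ((3, 6), (7, 10), (11, 13), (14, 17))

_SUMMARY_VARS = [
    ("weight_kg", "Weight, kg"),
    ("height_cm", "Height, cm"),
    ("bmi", "BMI, kg/m2"),
    ("sbp1", "First SBP, mmHg"),
    ("sbp2", "Second SBP, mmHg"),
    ("sbp3", "Third SBP, mmHg"),
    ("sbp_mean12", "Mean of first and second SBP, mmHg"),
    ("sbp", "Mean of second and third SBP, mmHg"),
    ("dbp1", "First DBP, mmHg"),
    ("dbp2", "Second DBP, mmHg"),
    ("dbp3", "Third DBP, mmHg"),
    ("dbp_mean12", "Mean of first and second DBP, mmHg"),
    ("dbp", "Mean of second and third DBP, mmHg"),
]


def summarize_baseline(cohort: pd.DataFrame, age_bands=_DEFAULT_BANDS) -> pd.DataFrame:
    """Baseline characteristics per sex and completed-years age band.

    One row per sex x band x variable with n, %, mean and SD; bands are
    closed integer-age bands on completed years (age 6.9 falls in 3-6).
    SD is NaN for single-record cells, as are all statistics for empty ones.
    """
    df = cohort.copy()
    if "bmi" not in df:
        df["bmi"] = df["weight_kg"] / (df["height_cm"] / 100.0) ** 2
    if "sbp" not in df:
        df["sbp"] = (df["sbp2"] + df["sbp3"]) / 2.0
        df["dbp"] = (df["dbp2"] + df["dbp3"]) / 2.0
    df["sbp_mean12"] = (df["sbp1"] + df["sbp2"]) / 2.0
    df["dbp_mean12"] = (df["dbp1"] + df["dbp2"]) / 2.0
    years = np.floor(df["age"].to_numpy(dtype=float)).astype(int)

    rows = []
    for sex in ("M", "F"):
        sex_mask = (df["sex"] == sex).to_numpy()
        n_sex = int(sex_mask.sum())
        for lo, hi in age_bands:
            m = sex_mask & (years >= lo) & (years <= hi)
            sub = df.loc[m]
            n = int(m.sum())
            pct = 100.0 * n / n_sex if n_sex else np.nan
            for col, label in _SUMMARY_VARS:
                x = sub[col].to_numpy(dtype=float) if n else np.array([])
                mean = float(np.mean(x)) if n else np.nan
                sd = float(np.std(x, ddof=1)) if n > 1 else np.nan
                rows.append(dict(sex=sex, band=f"{lo}-{hi}", n=n, pct=round(pct, 1),
                                 variable=label, mean=mean, sd=sd))
    return pd.DataFrame(rows)


def sample_size(z: float = 1.96, p: float = 0.5, e: float = 0.05, factors=()) -> float:
    """Survey sample size per stratum, n = z^2 p(1-p) / e^2.

    ``factors`` multiply the base size (design effect, estimation inflation,
    non-response adjustment ...).
    """
    if not (0 <= p <= 1):
        raise ValueError("p must lie in [0, 1]")
    if e <= 0:
        raise ValueError("e must be > 0")
    n = z**2 * p * (1.0 - p) / e**2
    for f in factors:
        n *= f
    return n
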