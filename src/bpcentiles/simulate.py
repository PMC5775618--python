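"""Synthetic school-survey cohorts with known blood-pressure truth.

The generator emulates the statistical structure the centile pipeline
assumes: children with sex, continuous age, height from sex-specific
growth curves, BMI calibrated to an IOTF overweight/obese prevalence, and
three oscillometric BP readings per child.  Each child's "true" BP is
drawn from a BCCG/BCPE law whose parameters vary smoothly with age and
height (the truth surfaces); the recorded readings add a first- and
second-reading elevation (white-coat-style decline across the triplet)
plus within-child measurement noise:

    reading_k = true BP + delta_k + eps_k,   delta_3 = 0,  eps ~ N(0, sd)

so the analysis value (mean of readings 2 and 3) is the true BP plus
delta_2/2 plus noise with sd/sqrt(2).  Because the truth surfaces are
known, fitted centiles can be judged against exact targets
(``true_centile``), which no field survey permits.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .distributions import _z_to_y, _pe_scale
from .pipeline import COHORT_COLUMNS, load_iotf_cutoffs
from .tables import load_reference_thresholds

__all__ = [
    "TrueSurfaces",
    "SimulationConfig",
    "default_truth",
    "simulate_cohort",
    "true_centile",
]

AGE_DOMAIN = (3.0, 17.0)

# sex-specific growth knots: band-median heights of the reference cohort at
# band midpoints, extended with plausible anchors at ages 2 and 19
_H_KNOT_AGES = np.array([2.0, 4.5, 8.5, 12.0, 15.5, 19.0])
_H_MEAN = {"M": np.array([87.0, 111.1, 130.5, 142.3, 162.3, 170.0]),
           "F": np.array([86.0, 111.3, 131.2, 148.0, 159.0, 160.5])}
_H_SD = {"M": np.array([3.5, 8.8, 9.0, 9.4, 10.2, 10.2]),
         "F": np.array([3.5, 10.2, 9.9, 9.6, 7.4, 7.4])}
# normal-weight BMI median curve (kg/m2) at the same knots
_BMI_MEAN = {"M": np.array([16.2, 15.1, 15.6, 16.9, 19.2, 20.0]),
             "F": np.array([16.2, 14.9, 15.6, 17.7, 19.9, 20.5])}
_BMI_LOG_SD = 0.09


class _MuSurface:
    """Smooth median surface exp(cubic(age) + b * log(height/140)),
    least-squares calibrated to a reference table; monotone non-decreasing
    in both covariates over the calibration domain."""

    def __init__(self, age, height, p50):
        X = _mu_design(age, height)
        self.coef, *_ = np.linalg.lstsq(X, np.log(p50), rcond=None)

    def __call__(self, age, height):
        age = np.clip(np.asarray(age, dtype=float), *AGE_DOMAIN)
        height = np.clip(np.asarray(height, dtype=float), 60.0, 220.0)
        age, height = np.broadcast_arrays(age, height)
        out = np.exp(_mu_design(age.ravel(), height.ravel()) @ self.coef)
        return out.reshape(age.shape)


def _mu_design(age, height):
    a = np.asarray(age, dtype=float) - 10.0
    return np.column_stack([np.ones_like(a), a, a**2, a**3,
                            np.log(np.asarray(height, dtype=float) / 140.0)])


class _SigmaLine:
    """Coefficient of variation linear in age, clamped to [0.05, 0.2]."""

    def __init__(self, age, s):
        self.coef = np.polyfit(np.asarray(age, dtype=float), np.asarray(s, dtype=float), 1)

    def __call__(self, age, height):
        age = np.clip(np.asarray(age, dtype=float), *AGE_DOMAIN)
        out = np.polyval(self.coef, age)
        return np.clip(np.broadcast_arrays(out, np.asarray(height, dtype=float))[0],
                       0.05, 0.2)


class _Const:
    def __init__(self, value):
        self.value = float(value)

    def __call__(self, age, height):
        return np.broadcast_arrays(np.asarray(age, dtype=float),
                                   np.asarray(height, dtype=float))[0] * 0.0 + self.value


@dataclass(frozen=True)
class TrueSurfaces:
    """Known BP parameter surfaces per (sex, measure).

    ``mu_fn``/``sigma_fn``/``nu_fn`` map (age in years, height in cm) to
    the BCCG/BCPE parameters; ``family`` is "BCCG" or "BCPE" and ``tau``
    the constant kurtosis power for BCPE entries.
    """

    mu_fn: dict
    sigma_fn: dict
    nu_fn: dict
    family: dict
    tau: dict
    age_domain: tuple = AGE_DOMAIN


def default_truth() -> TrueSurfaces:
    """Smooth truth surfaces calibrated to the bundled reference table.

    The median surface per (sex, measure) is exp(cubic(age) + b*log(height))
    least-squares fitted to the 75 printed P50 cells (residuals below 0.8
    mmHg, i.e. inside the table's own integer rounding); sigma is linear in
    age through the printed S column; nu is constant at the value the BCCG
    row-consistency relation recovers from the printed rows (about 0.27 for
    SBP, about 1 for girls' DBP).  The boys' DBP surface is BCPE
    (tau = 1.5); its sigma is calibrated to the girls' DBP S column, which
    is consistent with the observed age-band SDs, whereas the printed boys'
    DBP S column is not variance-consistent with a CV reading.
    """
    ref = load_reference_thresholds()
    mu_fn, sigma_fn, nu_fn, family, tau = {}, {}, {}, {}, {}

    def cells(sex, measure):
        g = ref[(ref.sex == sex) & (ref.measure == measure)]
        return (g["age"].to_numpy(dtype=float), g["height_cm"].to_numpy(dtype=float),
                g["P50"].to_numpy(dtype=float), g["S"].to_numpy(dtype=float))

    for sex in ("M", "F"):
        for measure in ("SBP", "DBP"):
            key = (sex, measure)
            a, h, p50, s = cells(sex, measure)
            mu_fn[key] = _MuSurface(a, h, p50)
            if key == ("M", "DBP"):
                a_g, _, _, s_g = cells("F", "DBP")
                sigma_fn[key] = _SigmaLine(a_g, s_g)
                nu_fn[key] = _Const(1.0)
                family[key] = "BCPE"
                tau[key] = 1.5
            else:
                sigma_fn[key] = _SigmaLine(a, s)
                nu_fn[key] = _Const(0.27 if measure == "SBP" else 1.0)
                family[key] = "BCCG"
                tau[key] = None
    return TrueSurfaces(mu_fn=mu_fn, sigma_fn=sigma_fn, nu_fn=nu_fn,
                        family=family, tau=tau)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition defaults for the synthetic survey.

    Defaults emulate the reference survey: 8371 consenting children,
    ages spanning past both ends of the 3-17 analysis window, about 8.5%
    overweight/obese by IOTF, three BP readings whose means decline from
    first to third, and a small missing-data rate.
    """

    n: int = 8371
    seed: int = 0
    sex_ratio: float = 0.49          # fraction of boys
    age_range: tuple = (2.0, 19.0)
    overweight_rate: float = 548 / 7523   # prevalence among the measured
    obese_rate: float = 92 / 7523
    delta1: float = 2.2              # first-reading elevation, mmHg
    delta2: float = 1.0              # second-reading elevation, mmHg
    reading_sd: float = 3.0          # within-child measurement sd, mmHg
    missing_rate: float = 53 / 8371
    truth: TrueSurfaces | None = None

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not (self.delta1 > self.delta2 >= 0):
            raise ValueError("need delta1 > delta2 >= 0 (declining reading means)")
        for r in (self.sex_ratio, self.overweight_rate, self.obese_rate, self.missing_rate):
            if not (0 <= r <= 1):
                raise ValueError("rates must lie in [0, 1]")
        if self.reading_sd < 0:
            raise ValueError("reading_sd must be >= 0")
        if not (self.age_range[0] < self.age_range[1]):
            raise ValueError("empty age range")


def _interp_knots(age, values):
    return np.interp(age, _H_KNOT_AGES, values)


def _draw_true_bp(truth, sex, measure, age, height, u):
    key = (sex, measure)
    mu = truth.mu_fn[key](age, height)
    sigma = truth.sigma_fn[key](age, height)
    nu = truth.nu_fn[key](age, height)
    u = np.clip(u, 1e-9, 1 - 1e-9)
    if truth.family[key] == "BCPE":
        tau = truth.tau[key]
        z = stats.gennorm.ppf(u, tau, scale=_pe_scale(tau))
    else:
        z = stats.norm.ppf(u)
    return _z_to_y(z, mu, sigma, nu)


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Generate one survey cohort; fully reproducible under ``config.seed``."""
    truth = config.truth if config.truth is not None else default_truth()
    rng = np.random.default_rng(config.seed)
    n = config.n
    sex = np.where(rng.uniform(size=n) < config.sex_ratio, "M", "F")
    age = rng.uniform(*config.age_range, size=n)

    height = np.empty(n)
    bmi = np.empty(n)
    iotf = load_iotf_cutoffs()
    age_iotf = np.clip(age, iotf.age_min, iotf.age_max)
    ucls = rng.uniform(size=n)
    for s in ("M", "F"):
        m = sex == s
        height[m] = (_interp_knots(age[m], _H_MEAN[s])
                     + rng.normal(size=m.sum()) * _interp_knots(age[m], _H_SD[s]))
        c25 = np.interp(age_iotf[m], iotf.age, iotf.cutoff_25[s])
        c30 = np.interp(age_iotf[m], iotf.age, iotf.cutoff_30[s])
        k = int(m.sum())
        b = _interp_knots(age[m], _BMI_MEAN[s]) * np.exp(rng.normal(0, _BMI_LOG_SD, size=k))
        # margins of >= 0.15 kg/m2 around each cut-off keep the intended
        # class stable under the 0.1-unit rounding of height and weight
        b = np.minimum(b, c25 - rng.uniform(0.15, 0.9, size=k))
        ow = ucls[m] < config.obese_rate + config.overweight_rate
        ob = ucls[m] < config.obese_rate
        b = np.where(ow, c25 + rng.uniform(0.08, 0.92, size=k) * (c30 - c25), b)
        b = np.where(ob, c30 * np.exp(rng.uniform(0.008, 0.15, size=k)), b)
        bmi[m] = b
    height = np.round(height, 1)
    weight = np.round(bmi * (height / 100.0) ** 2, 1)

    age_bp = np.clip(age, *AGE_DOMAIN)
    readings = {}
    deltas = (config.delta1, config.delta2, 0.0)
    for measure, prefix in (("SBP", "sbp"), ("DBP", "dbp")):
        true_bp = np.empty(n)
        u = rng.uniform(size=n)
        for s in ("M", "F"):
            m = sex == s
            true_bp[m] = _draw_true_bp(truth, s, measure, age_bp[m], height[m], u[m])
        for k, d in enumerate(deltas, start=1):
            readings[f"{prefix}{k}"] = true_bp + d + rng.normal(0, config.reading_sd, size=n)

    df = pd.DataFrame(dict(id=np.arange(1, n + 1), sex=sex, age=age,
                           height_cm=height, weight_kg=weight, **readings))
    df["bmi"] = df["weight_kg"] / (df["height_cm"] / 100.0) ** 2

    if config.missing_rate > 0:
        hit = rng.uniform(size=n) < config.missing_rate
        fields = np.array(["height_cm", "weight_kg", "sbp1", "sbp2", "sbp3",
                           "dbp1", "dbp2", "dbp3"])
        which = rng.integers(0, len(fields), size=n)
        for i in np.flatnonzero(hit):
            df.loc[i, fields[which[i]]] = np.nan
        df.loc[hit & df[["height_cm", "weight_kg"]].isna().any(axis=1), "bmi"] = np.nan
    return df[COHORT_COLUMNS + ["bmi"]]


def true_centile(truth: TrueSurfaces, sex: str, measure: str, age, height, alpha):
    """Exact percentile of the configured law at the true parameters.

    This is the target against which fitted centiles are judged.  Raises
    for covariates outside the truth's age domain.
    """
    age_arr = np.atleast_1d(np.asarray(age, dtype=float))
    if np.any((age_arr < truth.age_domain[0]) | (age_arr > truth.age_domain[1])):
        raise ValueError(f"age outside the truth domain {truth.age_domain}")
    key = (sex, measure)
    mu = truth.mu_fn[key](age, height)
    sigma = truth.sigma_fn[key](age, height)
    nu = truth.nu_fn[key](age, height)
    if truth.family[key] == "BCPE":
        tau = truth.tau[key]
        z = stats.gennorm.ppf(alpha, tau, scale=_pe_scale(tau))
    else:
        z = stats.norm.ppf(alpha)
    out = _z_to_y(z, mu, sigma, nu)
    if np.ndim(age) == 0 and np.ndim(height) == 0 and np.ndim(alpha) == 0:
        return float(np.asarray(out).reshape(-1)[0])
    return out
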