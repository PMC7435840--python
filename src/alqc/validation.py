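"""HPLC-side quantitative computations.

Covers the whole quantitative arm of the tablet QC workflow:

* per-day single-level calibration (a through-origin response factor, since
  one concentration level cannot estimate an intercept) and back-calculation
  of validation concentrations;
* total-error accuracy-profile statistics per level: relative bias, one-way
  random-effects variance components (repeatability and intermediate
  precision), and beta-expectation tolerance intervals;
* linearity of back-calculated versus introduced concentrations, profile
  verdict against acceptance limits and the quantification range
  (LLOQ/ULOQ);
* tablet assay content from the two-dilution sample preparation and an
  API-presence verdict for falsification confirmation;
* chromatographic figures of merit (retention factor, pharmacopoeial
  symmetry factor at 5% height, half-height resolution).

The beta-expectation tolerance interval at probability level beta for a
balanced p-day x n-replicate design uses the one-way random ANOVA
decomposition with Satterthwaite degrees of freedom:

    MS_B = n * sum_j (xbar_j - xbar)^2 / (p - 1)
    MS_W = sum_jk (x_jk - xbar_j)^2 / (p (n - 1))
    sigma_W^2 = MS_W,  sigma_B^2 = max(0, (MS_B - MS_W) / n)
    R = sigma_B^2 / sigma_W^2,  B^2 = (R + 1) / (n R + 1)
    nu = (R + 1)^2 / [ (R + 1/n)^2 / (p - 1) + (1 - 1/n) / (p n) ]
    k = t_{nu, (1+beta)/2} * sqrt(1 + 1 / (p n B^2))
    limits(%) = bias(%) +/- k * 100 * sigma_IP / mu_T
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


# ------------------------------------------------------------- calibration
@dataclass
class CalibrationModel:
    """Per-day response factors (area per mg/mL) for one compound."""

    compound: str
    factors: dict[int, float]  # day -> b_j

    def factor(self, day: int) -> float:
        try:
            return self.factors[day]
        except KeyError:
            raise KeyError(f"no calibration factor for day {day}") from None


def fit_calibration(areas: pd.DataFrame, nominal_100: float, compound: str = "") -> CalibrationModel:
    """Through-origin response factor per day from the 100%-level standards.

    ``areas`` needs columns ``day`` and ``area``; rows with a ``role`` column
    are filtered to ``role == "calibration"`` first.
    """
    if nominal_100 <= 0:
        raise ValueError("nominal concentration must be > 0")
    df = areas
    if "role" in df.columns:
        df = df[df["role"] == "calibration"]
    if df.empty:
        raise ValueError("no calibration rows")
    if (df["area"] <= 0).any():
        raise ValueError("non-positive calibration areas")
    factors = {
        int(day): float(group["area"].mean()) / nominal_100
        for day, group in df.groupby("day")
    }
    return CalibrationModel(compound=compound, factors=factors)


def back_calculate(areas: pd.DataFrame, calibration: CalibrationModel) -> pd.DataFrame:
    """Add a ``conc`` column: area divided by that day's response factor."""
    df = areas
    if "role" in df.columns:
        df = df[df["role"] == "validation"]
    df = df.copy()
    df["conc"] = [
        area / calibration.factor(int(day)) for day, area in zip(df["day"], df["area"])
    ]
    return df


# ------------------------------------------------------------ level stats
@dataclass
class LevelStats:
    level: object
    mu_T: float
    grand_mean: float
    relative_bias_pct: float
    sigma_W2: float
    sigma_B2: float
    sigma_IP2: float
    rsd_repeatability_pct: float
    rsd_intermediate_pct: float
    R: float
    B2: float
    nu: float
    beta: float
    tolerance_low_pct: float
    tolerance_high_pct: float


def level_statistics(
    x: np.ndarray, mu_T: float, beta: float = 0.90, level: object = None
) -> LevelStats:
    """Accuracy-profile statistics of one concentration level.

    ``x`` is the (p, n) matrix of back-calculated concentrations — p days by
    n replicates, balanced.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("x must be a (days, replicates) matrix (balanced design)")
    p, n = x.shape
    if p < 2 or n < 2:
        raise ValueError("need at least 2 days and 2 replicates")
    if mu_T <= 0:
        raise ValueError("mu_T must be > 0")
    if not (0 < beta < 1):
        raise ValueError("beta must be in (0, 1)")

    day_means = x.mean(axis=1)
    grand = x.mean()
    ms_b = n * np.sum((day_means - grand) ** 2) / (p - 1)
    ms_w = np.sum((x - day_means[:, None]) ** 2) / (p * (n - 1))
    sigma_w2 = ms_w
    sigma_b2 = max(0.0, (ms_b - ms_w) / n)
    sigma_ip2 = sigma_w2 + sigma_b2
    R = sigma_b2 / sigma_w2 if sigma_w2 > 0 else 0.0
    B2 = (R + 1.0) / (n * R + 1.0)
    nu = (R + 1.0) ** 2 / ((R + 1.0 / n) ** 2 / (p - 1) + (1.0 - 1.0 / n) / (p * n))
    bias_pct = 100.0 * (grand - mu_T) / mu_T
    sigma_ip = math.sqrt(sigma_ip2)
    if sigma_ip > 0:
        k = stats.t.ppf((1.0 + beta) / 2.0, nu) * math.sqrt(1.0 + 1.0 / (p * n * B2))
        half_width = k * 100.0 * sigma_ip / mu_T
    else:
        half_width = 0.0
    return LevelStats(
        level=level,
        mu_T=mu_T,
        grand_mean=grand,
        relative_bias_pct=bias_pct,
        sigma_W2=sigma_w2,
        sigma_B2=sigma_b2,
        sigma_IP2=sigma_ip2,
        rsd_repeatability_pct=100.0 * math.sqrt(sigma_w2) / mu_T,
        rsd_intermediate_pct=100.0 * sigma_ip / mu_T,
        R=R,
        B2=B2,
        nu=nu,
        beta=beta,
        tolerance_low_pct=bias_pct - half_width,
        tolerance_high_pct=bias_pct + half_width,
    )


def level_matrix(back_calcs: pd.DataFrame, level) -> np.ndarray:
    """Pivot one level's back-calculated concentrations to a (p, n) matrix."""
    df = back_calcs[back_calcs["level"] == level]
    pivot = df.pivot_table(index="day", columns="replicate", values="conc")
    if pivot.isna().any().any():
        raise ValueError(f"unbalanced design at level {level!r}")
    return pivot.to_numpy()


def linearity_fit(back_calcs: pd.DataFrame) -> tuple[float, float, float]:
    """OLS of back-calculated on introduced concentration, pooled over the design.

    Returns (slope, intercept, R^2).
    """
    x = back_calcs["nominal_mgml"].to_numpy(dtype=float)
    y = back_calcs["conc"].to_numpy(dtype=float)
    if x.size < 3 or np.unique(x).size < 2:
        raise ValueError("need at least 3 points with at least 2 distinct concentrations")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), float(r2)


# ----------------------------------------------------------------- profile
@dataclass
class AccuracyProfile:
    compound: str
    levels: list[LevelStats]
    acceptance_limit_pct: float
    slope: float
    intercept: float
    r2: float
    valid: bool
    lloq: float | None
    uloq: float | None
    beta: float = 0.90


def _crossing(conc0, bound0, conc1, bound1, limit) -> float | None:
    """Concentration where a linear tolerance-bound segment crosses a limit."""
    if bound0 == bound1:
        return None
    frac = (limit - bound0) / (bound1 - bound0)
    if 0.0 <= frac <= 1.0:
        return conc0 + frac * (conc1 - conc0)
    return None


def _level_ok(ls: LevelStats, limit: float) -> bool:
    return ls.tolerance_low_pct >= -limit and ls.tolerance_high_pct <= limit


def build_profile(
    level_stats: list[LevelStats],
    acceptance_limit_pct: float = 10.0,
    linearity: tuple[float, float, float] = (float("nan"),) * 3,
    compound: str = "",
) -> AccuracyProfile:
    """Assemble the profile verdict and quantification range.

    The method is valid iff every level's tolerance interval lies within
    +/- the acceptance limit; then LLOQ/ULOQ are the dosing-range endpoints.
    When a terminal level fails, the corresponding limit of quantification
    is the interpolated concentration where a tolerance bound crosses the
    acceptance limit between adjacent levels.
    """
    if len(level_stats) < 2:
        raise ValueError("need at least two levels")
    ls = sorted(level_stats, key=lambda s: s.mu_T)
    limit = acceptance_limit_pct
    ok = [_level_ok(s, limit) for s in ls]
    valid = all(ok)
    lloq = uloq = None
    if valid:
        lloq, uloq = ls[0].mu_T, ls[-1].mu_T
    else:
        if ok[-1] and not ok[0]:
            uloq = ls[-1].mu_T
        if ok[0] and not ok[-1]:
            lloq = ls[0].mu_T
        # interpolate a failing terminal level toward its valid neighbour
        if not ok[0] and ok[1]:
            cands = []
            for bound, lim in (("tolerance_low_pct", -limit), ("tolerance_high_pct", limit)):
                c = _crossing(ls[0].mu_T, getattr(ls[0], bound), ls[1].mu_T, getattr(ls[1], bound), lim)
                if c is not None:
                    cands.append(c)
            if cands:
                lloq = max(cands)
        if not ok[-1] and ok[-2]:
            cands = []
            for bound, lim in (("tolerance_low_pct", -limit), ("tolerance_high_pct", limit)):
                c = _crossing(ls[-2].mu_T, getattr(ls[-2], bound), ls[-1].mu_T, getattr(ls[-1], bound), lim)
                if c is not None:
                    cands.append(c)
            if cands:
                uloq = min(cands)
    slope, intercept, r2 = linearity
    return AccuracyProfile(
        compound=compound,
        levels=ls,
        acceptance_limit_pct=limit,
        slope=slope,
        intercept=intercept,
        r2=r2,
        valid=valid,
        lloq=lloq,
        uloq=uloq,
        beta=ls[0].beta,
    )


def accuracy_profile_from_areas(
    areas: pd.DataFrame,
    nominal_100: float,
    beta: float = 0.90,
    acceptance_limit_pct: float = 10.0,
    compound: str = "",
) -> AccuracyProfile:
    """Full per-compound validation from a tidy area table.

    Expects calibration and validation rows (``role`` column) with day,
    level, replicate, ``nominal_mgml`` and area; fits the per-day response
    factors, back-calculates, and assembles the accuracy profile.
    """
    calib = fit_calibration(areas, nominal_100, compound=compound)
    back = back_calculate(areas, calib)
    stats_per_level = []
    for level in sorted(back["level"].unique()):
        mu = float(back.loc[back["level"] == level, "nominal_mgml"].iloc[0])
        stats_per_level.append(level_statistics(level_matrix(back, level), mu, beta, level))
    lin = linearity_fit(back)
    return build_profile(stats_per_level, acceptance_limit_pct, lin, compound=compound)


def profile_table(profile: AccuracyProfile) -> pd.DataFrame:
    rows = []
    for s in profile.levels:
        rows.append(
            {
                "compound": profile.compound,
                "level": s.level,
                "concentration_mgml": s.mu_T,
                "relative_bias_pct": s.relative_bias_pct,
                "repeatability_rsd_pct": s.rsd_repeatability_pct,
                "intermediate_precision_rsd_pct": s.rsd_intermediate_pct,
                "tolerance_low_pct": s.tolerance_low_pct,
                "tolerance_high_pct": s.tolerance_high_pct,
            }
        )
    return pd.DataFrame(rows)


# ------------------------------------------------------------ tablet assay
def tablet_content(
    assay_areas: pd.DataFrame,
    response_factors: dict[str, float],
    scheme=None,
) -> dict[str, float]:
    """Tablet content (% of label claim) per compound from assay areas.

    ``response_factors`` maps compound -> area per (mg/mL) (e.g. the mean of
    the per-day calibration factors).  The injected concentration is
    back-calculated, multiplied by the dilution factor of that compound's
    path and referenced to the nominal stock concentration.
    """
    from .synthetic import AssayScheme

    scheme = scheme or AssayScheme()
    contents = {}
    for compound, group in assay_areas.groupby("compound"):
        if compound not in response_factors:
            raise KeyError(f"no calibration for {compound!r}")
        b = response_factors[compound]
        conc = group["area"].mean() / b
        stock = conc * scheme.dilution_factor[compound]
        contents[str(compound)] = 100.0 * stock / scheme.stock_nominal_mgml[compound]
    return contents


def detect_api(contents: dict[str, float], threshold_pct: float = 1.0) -> dict[str, str]:
    """Presence verdict per compound: below the threshold -> "not_detected".

    The rule is closed at the boundary: a content exactly equal to the
    threshold counts as present.
    """
    return {
        compound: ("present" if content >= threshold_pct else "not_detected")
        for compound, content in contents.items()
    }


# --------------------------------------------------- chromatographic merit
@dataclass(frozen=True)
class PeakDescriptor:
    """Geometry of one chromatographic peak (times in minutes)."""

    t0: float        # dead time
    tR: float        # retention time
    w_half: float    # full width at half height
    f_5: float       # leading-edge half width at 5% height
    w_5: float       # full width at 5% height

    def __post_init__(self) -> None:
        if not (self.tR > self.t0 > 0):
            raise ValueError("need tR > t0 > 0")
        if min(self.w_half, self.f_5, self.w_5) <= 0:
            raise ValueError("peak widths must be > 0")


@dataclass(frozen=True)
class ChromatographicParams:
    k: float                  # retention factor
    As: float                 # symmetry (tailing) factor at 5% height
    Rs: float | None = None   # resolution vs the neighbour peak


def chromatographic_params(
    peak: PeakDescriptor, neighbor: PeakDescriptor | None = None
) -> ChromatographicParams:
    """Retention factor, symmetry factor and (optionally) resolution.

    ``k = (tR - t0) / t0``; ``As = w_5 / (2 f_5)`` (pharmacopoeial tailing
    factor at 5% height); ``Rs = 1.18 (tR2 - tR1) / (w_half,1 + w_half,2)``
    when a neighbouring peak is given.
    """
    k = (peak.tR - peak.t0) / peak.t0
    As = peak.w_5 / (2.0 * peak.f_5)
    Rs = None
    if neighbor is not None:
        first, second = sorted((peak, neighbor), key=lambda p: p.tR)
        Rs = 1.18 * (second.tR - first.tR) / (first.w_half + second.w_half)
    return ChromatographicParams(k=k, As=As, Rs=Rs)
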