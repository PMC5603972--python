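"""Body-mass prediction from talar articular facet surface areas.

Species mass regressions are ordinary least squares of log10(body mass)
on log10(facet area), one regression per facet (ectal, trochlear,
navicular, sustentacular).  Back-transformation from the log scale uses
the quasi-maximum-likelihood (log-normal smearing) correction

    QMLE = exp(0.5 * SEE**2 * ln(10)**2),       %SEE = 100 * (10**SEE - 1),

with SEE the residual standard error in log10 units.  Fossil specimens
rarely preserve all four facets, so the final estimate is the arithmetic
mean of the point estimates from the intact facets, rounded half away
from zero to integer grams.  Species with reported sexual dimorphism
above a threshold (20% by default) enter the calibration as separate male
and female points rather than a single species average.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "FACETS",
    "MassRegression",
    "MassPrediction",
    "collapse_dimorphism",
    "fit_mass_regression",
    "predict_facet",
    "average_facets",
    "qmle_from_see",
    "qmle_from_percent_see",
    "percent_see",
]

FACETS = ("ectal", "trochlear", "navicular", "sustentacular")
LN10 = math.log(10.0)


def qmle_from_see(see: float) -> float:
    """Log-normal detransformation correction from SEE in log10 units."""
    return math.exp(0.5 * see * see * LN10 * LN10)


def percent_see(see: float) -> float:
    """Percent standard error of estimate: ``100 * (10^SEE - 1)``."""
    return 100.0 * (10.0 ** see - 1.0)


def qmle_from_percent_see(psee: float) -> float:
    """QMLE recovered from a printed %SEE value."""
    return qmle_from_see(math.log10(1.0 + psee / 100.0))


# ---------------------------------------------------------------------------
# Calibration sample assembly
# ---------------------------------------------------------------------------

def collapse_dimorphism(rows: pd.DataFrame, threshold: float = 20.0) -> pd.DataFrame:
    """Collapse individuals to species (or species-sex) calibration points.

    ``rows`` needs columns ``species, sex, dimorphism, mass_g`` plus any
    facet-area columns.  Species at or below the dimorphism threshold (in
    percent) are averaged into one point; species above it contribute one
    male and one female point.
    """
    required = {"species", "sex", "dimorphism", "mass_g"}
    if not required.issubset(rows.columns):
        raise ValueError(f"need columns {sorted(required)}")
    value_cols = [c for c in rows.columns
                  if c not in ("species", "sex") and rows[c].dtype.kind in "fi"]
    out = []
    for sp, grp in rows.groupby("species", sort=True):
        dim = float(grp["dimorphism"].iloc[0])
        if dim > threshold:
            for sex, sub in grp.groupby("sex", sort=True):
                rec = {"species": sp, "sex": sex}
                rec.update(sub[value_cols].mean())
                out.append(rec)
        else:
            rec = {"species": sp, "sex": "averaged"}
            rec.update(grp[value_cols].mean())
            out.append(rec)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Regression
# ---------------------------------------------------------------------------

@dataclass
class MassRegression:
    facet: str
    slope: float
    intercept: float
    r_squared: float
    see: float                   # residual standard error, log10 units
    percent_see: float
    qmle: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    n: int
    dof: int
    # centroid of the calibration data in log10 space (for intervals)
    _x_mean: float = 0.0
    _sxx: float = 1.0


def fit_mass_regression(areas: np.ndarray, masses: np.ndarray,
                        facet: str = "ectal") -> MassRegression:
    """OLS of log10(mass in g) on log10(facet area).

    Requires at least three positive (area, mass) pairs.  SEE is the
    residual standard error with ``n - 2`` degrees of freedom; %SEE and
    QMLE follow from it.
    """
    areas = np.asarray(areas, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if len(areas) != len(masses):
        raise ValueError("areas and masses must have equal length")
    if len(areas) < 3:
        raise ValueError("need >= 3 calibration points")
    if np.any(areas <= 0) or np.any(masses <= 0):
        raise ValueError("areas and masses must be strictly positive")
    x = np.log10(areas)
    y = np.log10(masses)
    n = len(x)
    res = scipy.stats.linregress(x, y)
    yhat = res.intercept + res.slope * x
    dof = n - 2
    sse = float(((y - yhat) ** 2).sum())
    see = math.sqrt(sse / dof)
    tcrit = scipy.stats.t.ppf(0.975, dof)
    sxx = float(((x - x.mean()) ** 2).sum())
    slope_se = see / math.sqrt(sxx)
    int_se = see * math.sqrt(1.0 / n + x.mean() ** 2 / sxx)
    return MassRegression(
        facet=facet,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2),
        see=see,
        percent_see=percent_see(see),
        qmle=qmle_from_see(see),
        slope_ci=(res.slope - tcrit * slope_se, res.slope + tcrit * slope_se),
        intercept_ci=(res.intercept - tcrit * int_se, res.intercept + tcrit * int_se),
        n=n,
        dof=dof,
        _x_mean=float(x.mean()),
        _sxx=sxx,
    )


def predict_facet(reg: MassRegression, area: float) -> tuple[float, tuple[float, float]]:
    """Point estimate (g) and 95% interval for one facet area.

    The point estimate applies the QMLE correction to the back-transformed
    OLS prediction; the interval back-transforms the t-based log-scale
    prediction interval at the new area (QMLE applied to the point
    estimate only, so the interval brackets the uncorrected prediction).
    """
    if area <= 0:
        raise ValueError("area must be positive")
    x0 = math.log10(area)
    yhat = reg.intercept + reg.slope * x0
    est = reg.qmle * 10.0 ** yhat
    tcrit = scipy.stats.t.ppf(0.975, reg.dof)
    half = tcrit * reg.see * math.sqrt(
        1.0 + 1.0 / reg.n + (x0 - reg._x_mean) ** 2 / reg._sxx)
    lo, hi = 10.0 ** (yhat - half), 10.0 ** (yhat + half)
    return est, (lo, hi)


# ---------------------------------------------------------------------------
# Fossil predictions
# ---------------------------------------------------------------------------

@dataclass
class MassPrediction:
    specimen_id: str
    facet_estimates: dict[str, float]           # facet -> grams
    facet_ci: dict[str, tuple[float, float]]
    intact: list[str]
    average: int                                # grams, integer


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def average_facets(estimates: dict[str, float],
                   intact: list[str] | None = None) -> int:
    """Arithmetic mean of intact-facet point estimates, in integer grams.

    Rounding is half away from zero.  At least one intact facet required.
    """
    if intact is None:
        intact = list(estimates)
    vals = [estimates[f] for f in intact]
    if not vals:
        raise ValueError("no intact facets to average")
    return _round_half_away(sum(vals) / len(vals))


def predict_specimen(specimen_id: str, areas: dict[str, float],
                     regressions: dict[str, MassRegression]) -> MassPrediction:
    """Per-facet estimates for one fossil specimen from its intact facets.

    ``areas`` maps facet name to measured area for every intact facet
    (absent facets are simply not predicted).
    """
    ests: dict[str, float] = {}
    cis: dict[str, tuple[float, float]] = {}
    for facet, area in areas.items():
        if facet not in regressions:
            raise ValueError(f"no regression for facet {facet!r}")
        est, ci = predict_facet(regressions[facet], area)
        ests[facet] = est
        cis[facet] = ci
    intact = sorted(ests)
    return MassPrediction(specimen_id, ests, cis, intact,
                          average_facets(ests, intact))
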