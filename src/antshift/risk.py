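"""Extinction-risk classification under decadal warming.

A species' maximum air temperature tolerance is the sum of its optimum
(WA) and tolerance (TOL). If that sum is smaller than the lowest air
temperature available in the assessed area for a decade — the 1st
percentile of temperatures in 100-m lateral buffers around the sampling
sites, minimised over sites — no suitable thermal habitat remains and
the species is classified at risk. Risk rates are the percentage of
assessed species at risk, overall and per altitude band, and the
altitude-risk relationship is summarised by a logistic regression of the
species-level risk indicator on optimal altitude.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .climate import ClimateGrid, WarmingScenario, apply_warming, lowest_air_temperature
from .errors import UndefinedEstimateError
from .niche import NicheEstimate
from .synth import band_label

logger = logging.getLogger(__name__)

FREQ_CLASSES = {"all": 0.0, ">1%": 0.01, ">5%": 0.05, ">10%": 0.10}


@dataclass(frozen=True)
class RiskAssessment:
    """Per-decade risk classification of a species set."""

    decade_label: str
    at_risk: dict[str, bool]
    risk_rate_pct: float
    band_rates: dict[str, float] = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class AltitudeRiskCurve:
    """Logistic fit of species risk indicator vs optimal altitude."""

    freq_class: str
    intercept: float
    slope: float
    slope_p: float
    separation: bool = False


def classify_risk(estimate: NicheEstimate, lowest_temp: float) -> bool:
    """True iff the species' upper thermal limit (WA + TOL) is strictly
    below the lowest available air temperature."""
    return (estimate.wa + estimate.tol) < lowest_temp


def risk_rate(assessments) -> float:
    """Percentage of at-risk species among those assessed."""
    flags = list(assessments)
    if len(flags) == 0:
        raise UndefinedEstimateError("no species assessed")
    return 100.0 * float(np.mean([bool(f) for f in flags]))


def site_lowest_temperatures(
    grid: ClimateGrid, sites: pd.DataFrame, buffer_m: float = 100.0
) -> np.ndarray:
    """Per-site 1st-percentile buffer temperature."""
    return np.array(
        [lowest_air_temperature(grid, (x, y), buffer_m) for x, y in zip(sites["x"], sites["y"])]
    )


def study_area_lowest_temperature(
    grid: ClimateGrid, sites: pd.DataFrame, buffer_m: float = 100.0
) -> float:
    """Lowest air temperature in the study area: the minimum over sites
    of the per-site 1st-percentile buffer temperatures."""
    return float(site_lowest_temperatures(grid, sites, buffer_m).min())


def assess_decade(
    estimates: list[NicheEstimate],
    baseline: ClimateGrid,
    scenario: WarmingScenario,
    decade: str,
    sites: pd.DataFrame,
    buffer_m: float = 100.0,
) -> RiskAssessment:
    """Classify every species against the decade's study-area threshold."""
    grid = apply_warming(baseline, scenario, decade)
    threshold = study_area_lowest_temperature(grid, sites, buffer_m)
    at_risk = {e.species_id: classify_risk(e, threshold) for e in estimates}
    return RiskAssessment(
        decade_label=decade,
        at_risk=at_risk,
        risk_rate_pct=risk_rate(at_risk.values()),
        thresholds={"study_area": threshold},
    )


def band_risk_rates(
    sites: pd.DataFrame,
    abundance: pd.DataFrame,
    estimates: list[NicheEstimate],
    grid: ClimateGrid,
    band_edges,
    buffer_m: float = 100.0,
    threshold_scope: str = "study_area",
) -> dict[str, float]:
    """Risk rate per altitude band for one decade's grid.

    A species is "recorded" in a band if it has positive abundance at at
    least one member site. With ``threshold_scope="study_area"`` (default)
    every species is classified against the single study-area-wide lowest
    temperature and band rates aggregate that status over each band's
    recorded species; ``"band"`` instead assesses each band's species
    against the band's own lowest temperature (minimum over member sites
    of the per-site 1st-percentile values). Empty bands are reported as
    NaN.
    """
    if threshold_scope not in ("study_area", "band"):
        raise ValueError("threshold_scope must be 'study_area' or 'band'")
    site_low = site_lowest_temperatures(grid, sites, buffer_m)
    global_threshold = float(site_low.min())
    est_by_id = {e.species_id: e for e in estimates}
    rates: dict[str, float] = {}
    for i in range(len(band_edges) - 1):
        lo, hi = band_edges[i], band_edges[i + 1]
        label = band_label((lo, hi))
        member = (sites["altitude"] >= lo) & (sites["altitude"] < hi)
        if not member.any():
            rates[label] = np.nan
            continue
        member_ids = sites.loc[member, "site_id"]
        recorded = [
            sp for sp in abundance.columns
            if sp in est_by_id and (abundance.loc[member_ids, sp] > 0).any()
        ]
        if not recorded:
            rates[label] = np.nan
            continue
        threshold = (
            global_threshold if threshold_scope == "study_area"
            else float(site_low[member.to_numpy()].min())
        )
        flags = [classify_risk(est_by_id[sp], threshold) for sp in recorded]
        rates[label] = risk_rate(flags)
    return rates


def altitude_risk_logistic(
    niche_table: pd.DataFrame,
    at_risk: dict[str, bool],
    freq_class: str = "all",
) -> AltitudeRiskCurve:
    """Logistic regression of species risk status on optimal altitude.

    ``niche_table`` must carry ``wa_alt`` (optimal altitude) and
    ``occurrence_freq``; species below the frequency class cut-off are
    excluded. Complete separation is flagged and the (diverging)
    coefficients reported with a warning rather than raised.
    """
    if freq_class not in FREQ_CLASSES:
        raise ValueError(f"freq_class must be one of {sorted(FREQ_CLASSES)}")
    cut = FREQ_CLASSES[freq_class]
    tab = niche_table[niche_table["occurrence_freq"] > cut]
    alt = tab["wa_alt"].to_numpy(dtype=float)
    y = np.array([bool(at_risk[sp]) for sp in tab.index], dtype=float)
    if len(np.unique(alt)) < 2:
        raise ValueError("need at least 2 distinct altitude values")
    if y.min() == y.max():
        raise ValueError("both risk outcomes must be present")
    exog = sm.add_constant(alt)
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, exog).fit(disp=0, maxiter=200)
        except Exception:
            separation = True
            res = sm.Logit(y, exog).fit_regularized(disp=0, alpha=1e-4, maxiter=500)
    fitted = res.predict(exog)
    if np.all((fitted < 1e-6) | (fitted > 1 - 1e-6)):
        separation = True
    if separation:
        logger.warning("complete separation in altitude-risk logistic (%s)", freq_class)
    params = np.asarray(res.params)
    try:
        pvals = np.asarray(res.pvalues)
        slope_p = float(pvals[1])
    except Exception:
        slope_p = np.nan
    return AltitudeRiskCurve(
        freq_class=freq_class,
        intercept=float(params[0]),
        slope=float(params[1]),
        slope_p=slope_p,
        separation=separation,
    )


def risk_table(
    assessments: list[RiskAssessment], estimates: list[NicheEstimate]
) -> pd.DataFrame:
    """Long-format per-decade, per-species risk table."""
    est_by_id = {e.species_id: e for e in estimates}
    rows = []
    for a in assessments:
        thr = a.thresholds.get("study_area", np.nan)
        for sp, flag in a.at_risk.items():
            e = est_by_id[sp]
            rows.append(
                {
                    "decade": a.decade_label,
                    "species_id": sp,
                    "wa": e.wa,
                    "tol": e.tol,
                    "threshold": thr,
                    "at_risk": bool(flag),
                }
            )
    return pd.DataFrame(rows)
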