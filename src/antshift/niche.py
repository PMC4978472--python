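"""Weighted-averaging regression (WARM): thermal optima and tolerances.

For species *j* with abundance :math:`y_{ij}` at sites with temperature
:math:`x_i`, the optimum is the abundance-weighted mean

.. math:: WA_j = \\frac{\\sum_i x_i y_{ij}}{\\sum_i y_{ij}}

and the tolerance is the abundance-weighted standard deviation

.. math:: TOL_j = \\sqrt{\\frac{\\sum_i (x_i - WA_j)^2 y_{ij}}{\\sum_i y_{ij}}}.

Standard errors come from bootstrapping sites (rows) with replacement.
Whole-model diagnostics use weighted-averaging calibration with inverse
deshrinking: site temperature is inferred from the community as the
abundance-weighted mean of species optima, then linearly deshrunk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UndefinedEstimateError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NicheEstimate:
    """Estimated thermal niche of one species."""

    species_id: str
    wa: float
    tol: float
    wa_boot_se: float = np.nan
    tol_boot_se: float = np.nan
    n_sites_present: int = 0
    occurrence_freq: float = np.nan

    @property
    def upper_limit(self) -> float:
        """Maximum air temperature tolerance: optimum plus tolerance."""
        return self.wa + self.tol


@dataclass(frozen=True)
class WarmDiagnostics:
    """Whole-model accuracy of the weighted-averaging calibration."""

    r2: float
    mean_bias: float
    rmse: float
    n_boot: int
    r2_boot: float = np.nan


def _validated(temps, abundances):
    x = np.asarray(temps, dtype=float)
    y = np.asarray(abundances, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("temps and abundances must be equal-length vectors")
    if np.any(y < 0):
        raise ValueError("abundances must be non-negative")
    if y.sum() <= 0:
        raise UndefinedEstimateError("zero total abundance: estimate undefined")
    return x, y


def weighted_average(temps, abundances) -> float:
    """Abundance-weighted mean temperature (the species optimum)."""
    x, y = _validated(temps, abundances)
    return float(np.sum(x * y) / np.sum(y))


def weighted_tolerance(temps, abundances) -> float:
    """Abundance-weighted standard deviation of temperature.

    The radicand form is an abundance-weighted variance; the square root
    is applied so the tolerance is in degC and comparable with (and
    addable to) the optimum.
    """
    x, y = _validated(temps, abundances)
    wa = np.sum(x * y) / np.sum(y)
    return float(np.sqrt(np.sum((x - wa) ** 2 * y) / np.sum(y)))


def bootstrap_niche(
    temps, abundances, n_boot: int = 1000, seed: int | np.random.SeedSequence = 0
) -> tuple[float, float]:
    """Bootstrap standard errors of (WA, TOL).

    Sites are resampled with replacement, abundance travelling with its
    temperature. Resamples with zero total abundance are redrawn.
    """
    x, y = _validated(temps, abundances)
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    n = len(x)
    was = np.empty(n_boot)
    tols = np.empty(n_boot)
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            yb = y[idx]
            if yb.sum() > 0:
                break
        xb = x[idx]
        wa = np.sum(xb * yb) / np.sum(yb)
        was[b] = wa
        tols[b] = np.sqrt(np.sum((xb - wa) ** 2 * yb) / np.sum(yb))
    return float(was.std(ddof=1)), float(tols.std(ddof=1))


def estimate_niches(
    abundance: pd.DataFrame,
    temps,
    altitudes=None,
    n_boot: int = 1000,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Per-species niche table from a site x species abundance matrix.

    Species absent everywhere are dropped with a warning. If site
    altitudes are given, optimal/tolerance altitudes are estimated by the
    same weighted-averaging operations with altitude in place of
    temperature (columns ``wa_alt``, ``tol_alt``).
    """
    x = np.asarray(temps, dtype=float)
    if len(x) != len(abundance):
        raise ValueError("temps length must match number of sites")
    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    rows = []
    for sp, child in zip(abundance.columns, ss.spawn(abundance.shape[1])):
        y = abundance[sp].to_numpy(dtype=float)
        if y.sum() <= 0:
            logger.warning("species %s absent everywhere; skipped", sp)
            continue
        wa = weighted_average(x, y)
        tol = weighted_tolerance(x, y)
        wa_se, tol_se = bootstrap_niche(x, y, n_boot=n_boot, seed=child)
        row = {
            "species_id": sp,
            "wa": wa,
            "tol": tol,
            "wa_boot_se": wa_se,
            "tol_boot_se": tol_se,
            "n_sites_present": int((y > 0).sum()),
            "occurrence_freq": float((y > 0).mean()),
        }
        if altitudes is not None:
            alt = np.asarray(altitudes, dtype=float)
            row["wa_alt"] = weighted_average(alt, y)
            row["tol_alt"] = weighted_tolerance(alt, y)
        rows.append(row)
    return pd.DataFrame(rows).set_index("species_id")


def _wa_calibrate(abund: np.ndarray, x: np.ndarray):
    """Species optima and raw community-inferred site temperatures."""
    col_tot = abund.sum(axis=0)
    was = (x @ abund) / col_tot
    row_tot = abund.sum(axis=1)
    inferred = (abund @ was) / row_tot
    return was, inferred


def warm_diagnostics(
    abundance: pd.DataFrame,
    temps,
    n_boot: int = 1000,
    seed: int | np.random.SeedSequence = 0,
) -> WarmDiagnostics:
    """Whole-model diagnostics of the weighted-averaging calibration.

    ``r2`` is the apparent squared Pearson correlation between observed
    and community-inferred (inverse-deshrunk) site temperatures.
    ``mean_bias`` and ``rmse`` are computed from bootstrap out-of-bag
    predictions (sites resampled with replacement; each site's held-out
    predictions averaged over the cycles that exclude it); ``r2_boot`` is
    the corresponding out-of-bag r-squared.
    """
    x = np.asarray(temps, dtype=float)
    ab = abundance.to_numpy(dtype=float)
    if ab.shape[0] < 2 or ab.shape[1] < 2:
        raise ValueError("need at least 2 sites and 2 species")
    keep = ab.sum(axis=1) > 0
    if not keep.all():
        logger.warning("%d sites with zero total abundance excluded", (~keep).sum())
        ab, x = ab[keep], x[keep]
    present = ab.sum(axis=0) > 0
    ab = ab[:, present]
    n = len(x)

    _, inferred = _wa_calibrate(ab, x)
    r2 = float(np.corrcoef(inferred, x)[0, 1] ** 2)

    rng = np.random.default_rng(seed)
    pred_sum = np.zeros(n)
    pred_cnt = np.zeros(n)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), idx)
        if oob.size == 0:
            continue
        ab_in = ab[idx]
        cols = ab_in.sum(axis=0) > 0
        if cols.sum() < 2:
            continue
        was, inf_in = _wa_calibrate(ab_in[:, cols], x[idx])
        # inverse deshrinking fitted on the in-bag sites
        b, a = np.polyfit(x[idx], inf_in, 1)
        if abs(b) < 1e-12:
            continue
        ab_oob = ab[oob][:, cols]
        ok = ab_oob.sum(axis=1) > 0
        raw = (ab_oob[ok] @ was) / ab_oob[ok].sum(axis=1)
        pred = (raw - a) / b
        pred_sum[oob[ok]] += pred
        pred_cnt[oob[ok]] += 1
    got = pred_cnt > 0
    pred_mean = pred_sum[got] / pred_cnt[got]
    err = pred_mean - x[got]
    r2_boot = float(np.corrcoef(pred_mean, x[got])[0, 1] ** 2) if got.sum() > 2 else np.nan
    return WarmDiagnostics(
        r2=r2,
        mean_bias=float(err.mean()),
        rmse=float(np.sqrt(np.mean(err**2))),
        n_boot=n_boot,
        r2_boot=r2_boot,
    )
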