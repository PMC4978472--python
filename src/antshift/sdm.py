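"""Spatially corrected species distribution models.

Occurrence (presence/absence of positive abundance) is modelled with an
additive logistic regression: one penalised smoothing-spline term per
temperature predictor plus a linear autocovariate term correcting for
spatial autocorrelation,

.. math:: g(\\mu) = \\alpha + \\sum_i f_i(x_i),

with a logit link. The nine predictors are the annual, January and July
maximum / mean / minimum air temperatures. The autocovariate is the
distance-weighted mean of neighbouring sites' responses; spatial
structure is screened beforehand with Moran's I. Discrimination is
assessed on a stratified 70/30 split by AUC, and by sensitivity and
specificity at the threshold maximising Youden's J on the training set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import train_test_split
from statsmodels.gam.api import BSplines, GLMGam
import statsmodels.api as sm

from .climate import PREDICTOR_NAMES

logger = logging.getLogger(__name__)

#: Paper's acceptability bar for discrimination.
AUC_ACCEPTABLE = 0.7


def check_predictors(predictors: pd.DataFrame) -> pd.DataFrame:
    """Validate a nine-variable predictor table.

    Requires all of :data:`antshift.climate.PREDICTOR_NAMES`, finite
    values, and warns (without failing) if the seasonal ordering
    January mean <= annual mean <= July mean is violated anywhere.
    """
    missing = set(PREDICTOR_NAMES) - set(predictors.columns)
    if missing:
        raise ValueError(f"missing predictors: {sorted(missing)}")
    tab = predictors[list(PREDICTOR_NAMES)]
    if not np.all(np.isfinite(tab.to_numpy())):
        raise ValueError("predictors must be finite")
    bad = (tab["jan_mean"] > tab["annual_mean"]) | (tab["annual_mean"] > tab["jul_mean"])
    if bad.any():
        logger.warning("seasonal ordering Jan <= annual <= Jul violated at %d rows", bad.sum())
    return tab


def morans_i(values, coords, neighbourhood_m: float) -> tuple[float, float]:
    """Moran's I with inverse-distance weights and an analytical z-test.

    Weights are 1/distance for pairs closer than ``neighbourhood_m``,
    zero otherwise, row-standardised. The p-value is two-sided under the
    normality assumption. Requires at least 8 sites; a constant input
    has no defined I and returns ``(nan, nan)``.
    """
    x = np.asarray(values, dtype=float)
    xy = np.asarray(coords, dtype=float)
    n = len(x)
    if n < 8:
        raise ValueError("Moran's I needs at least 8 sites")
    z = x - x.mean()
    if np.allclose(z, 0):
        logger.warning("all values identical; Moran's I undefined")
        return np.nan, np.nan
    d = cdist(xy, xy)
    with np.errstate(divide="ignore"):
        w = np.where((d > 0) & (d <= neighbourhood_m), 1.0 / d, 0.0)
    rs = w.sum(axis=1, keepdims=True)
    rs[rs == 0] = 1.0
    w = w / rs
    s0 = w.sum()
    i_stat = (n / s0) * (z @ w @ z) / (z @ z)
    s1 = 0.5 * ((w + w.T) ** 2).sum()
    s2 = ((w.sum(axis=1) + w.sum(axis=0)) ** 2).sum()
    e_i = -1.0 / (n - 1)
    var_i = (n**2 * s1 - n * s2 + 3 * s0**2) / ((n**2 - 1) * s0**2) - e_i**2
    zscore = (i_stat - e_i) / np.sqrt(var_i)
    p = 2.0 * stats.norm.sf(abs(zscore))
    return float(i_stat), float(p)


def build_autocovariate(
    response, coords, radius_m: float, decay: str = "inverse"
) -> np.ndarray:
    """Distance-weighted mean of neighbours' responses within a radius.

    ``decay="inverse"`` weights neighbours by 1/distance, ``"none"``
    equally. Sites with no neighbour inside the radius receive the
    global mean response (logged).
    """
    if radius_m <= 0:
        raise ValueError("radius_m must be > 0")
    if decay not in ("inverse", "none"):
        raise ValueError("decay must be 'inverse' or 'none'")
    y = np.asarray(response, dtype=float)
    xy = np.asarray(coords, dtype=float)
    d = cdist(xy, xy)
    within = (d > 0) & (d <= radius_m)
    with np.errstate(divide="ignore"):
        w = np.where(within, 1.0 / d if decay == "inverse" else 1.0, 0.0)
    if decay == "none":
        w = within.astype(float)
    totals = w.sum(axis=1)
    auto = np.where(totals > 0, (w @ y) / np.where(totals > 0, totals, 1.0), np.nan)
    orphans = ~np.isfinite(auto)
    if orphans.any():
        logger.info("%d isolated sites imputed with the global mean response", orphans.sum())
        auto[orphans] = y.mean()
    return auto


def moran_eigenvectors(coords, radius_m: float, k: int = 5) -> np.ndarray:
    """Leading Moran eigenvector maps (MEM) as spatial predictors.

    Eigenvectors of the doubly centred inverse-distance weight matrix
    associated with the ``k`` largest positive eigenvalues; an
    alternative spatial correction that can be passed to
    :func:`fit_sdm` in place of (or besides) the autocovariate.
    """
    if radius_m <= 0 or k < 1:
        raise ValueError("radius_m must be > 0 and k >= 1")
    xy = np.asarray(coords, dtype=float)
    n = len(xy)
    d = cdist(xy, xy)
    with np.errstate(divide="ignore"):
        w = np.where((d > 0) & (d <= radius_m), 1.0 / d, 0.0)
    w = (w + w.T) / 2.0
    h = np.eye(n) - np.ones((n, n)) / n
    eigval, eigvec = np.linalg.eigh(h @ w @ h)
    order = np.argsort(eigval)[::-1]
    positive = [i for i in order if eigval[i] > 1e-10]
    return eigvec[:, positive[:k]]


def default_autocov_radius(coords) -> float:
    """Default neighbourhood radius: 3x the median nearest-neighbour distance."""
    xy = np.asarray(coords, dtype=float)
    d = cdist(xy, xy)
    np.fill_diagonal(d, np.inf)
    return 3.0 * float(np.median(d.min(axis=1)))


@dataclass
class SDMModel:
    """Fitted smooth-additive occurrence model for one species."""

    species_id: str
    result: object  # GLMGamResults
    smoother: object  # BSplines
    predictor_names: tuple[str, ...]
    train_min: np.ndarray
    train_max: np.ndarray
    autocov_mean: np.ndarray
    youden_threshold: float
    prevalence: float
    converged: bool
    smooth_df: int
    link: str = "logit"

    def predict(self, predictors: pd.DataFrame, autocov=None, clip: bool = True) -> np.ndarray:
        """Occurrence probability for new predictor rows.

        ``autocov`` defaults to the training-mean autocovariate (the
        convention for projecting to unsurveyed cells). Predictor values
        outside the training range are clipped to it, with a warning
        counting the affected rows (climate-envelope extrapolation).
        """
        x = predictors[list(self.predictor_names)].to_numpy(dtype=float)
        if clip:
            outside = (x < self.train_min) | (x > self.train_max)
            n_out = int(outside.any(axis=1).sum())
            if n_out:
                logger.warning(
                    "%s: %d cells outside the training predictor range; "
                    "values clipped to the range edge", self.species_id, n_out,
                )
            x = np.clip(x, self.train_min, self.train_max)
        if autocov is None:
            auto = np.tile(self.autocov_mean, (len(x), 1))
        else:
            auto = np.asarray(autocov, dtype=float)
            if auto.ndim == 1:
                auto = auto[:, None]
        exog = np.column_stack([np.ones(len(x)), auto])
        return np.asarray(self.result.predict(exog=exog, exog_smooth=x))


def auc_score(y_true, scores) -> float:
    """Area under the ROC curve (rank / concordance statistic).

    Equals the fraction of (presence, absence) pairs in which the
    presence receives the higher score, ties counting one half.
    """
    return float(roc_auc_score(np.asarray(y_true), np.asarray(scores)))


def _youden_threshold(y_true, scores) -> float:
    fpr, tpr, thresholds = roc_curve(y_true, scores)
    j = tpr - fpr
    return float(thresholds[np.argmax(j)])


def fit_sdm(
    presence,
    predictors: pd.DataFrame,
    autocov,
    smooth_df: int = 4,
    alpha: float = 1.0,
    species_id: str = "species",
) -> SDMModel:
    """Fit the additive logistic occurrence model.

    One B-spline smooth (``smooth_df`` basis functions, penalty weight
    ``alpha``) per predictor plus linear spatial terms: ``autocov`` may
    be the 1-D autocovariate (default correction) or a 2-D column stack
    of spatial predictors such as Moran eigenvector maps (see
    :func:`moran_eigenvectors`). Deterministic given the data.
    Non-convergence is flagged on the returned model; a single-class
    response is an error.
    """
    y = np.asarray(presence, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("presence must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("both presence and absence must occur")
    if len(y) < 30:
        logger.warning("fewer than 30 sites; smooth-additive fit may be unstable")
    tab = check_predictors(predictors)
    x = tab.to_numpy(dtype=float)
    auto = np.asarray(autocov, dtype=float)
    if auto.ndim == 1:
        auto = auto[:, None]
    k = x.shape[1]
    smoother = BSplines(x, df=[smooth_df] * k, degree=[3] * k, include_intercept=False)
    exog = np.column_stack([np.ones(len(y)), auto])
    converged = True
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # quasi-separable responses (e.g. noise-free step functions) abort
        # penalised IRLS; escalate the penalty until the fit stabilises
        for factor in (1.0, 1e2, 1e4, 1e6, 1e8):
            model = GLMGam(y, exog=exog, smoother=smoother,
                           alpha=[alpha * factor] * k, family=sm.families.Binomial())
            try:
                res = model.fit(maxiter=100)
                converged = bool(getattr(res, "converged", True)) and factor == 1.0
                break
            except Exception as exc:
                last_exc = exc
                continue
    if res is None:
        raise RuntimeError(f"{species_id}: GAM fit failed at every penalty ({last_exc})")
    if not converged:
        logger.warning("%s: penalised IRLS needed a stronger penalty or did not "
                       "fully converge", species_id)
    fitted = np.asarray(res.predict())
    return SDMModel(
        species_id=species_id,
        result=res,
        smoother=smoother,
        predictor_names=tuple(tab.columns),
        train_min=x.min(axis=0),
        train_max=x.max(axis=0),
        autocov_mean=auto.mean(axis=0),
        youden_threshold=_youden_threshold(y, fitted),
        prevalence=float(y.mean()),
        converged=converged,
        smooth_df=smooth_df,
    )


@dataclass(frozen=True)
class ValidationMetrics:
    """Discrimination of a fitted model on a held-out split."""

    auc: float
    sensitivity: float
    specificity: float
    threshold_used: float
    split_seed: int

    @property
    def acceptable(self) -> bool:
        """Paper's acceptability flag: AUC >= 0.7."""
        return self.auc >= AUC_ACCEPTABLE


def cross_validate(
    presence,
    predictors: pd.DataFrame,
    autocov,
    train_frac: float = 0.7,
    seed: int = 0,
    smooth_df: int = 4,
    alpha: float = 1.0,
    max_retries: int = 10,
    species_id: str = "species",
) -> ValidationMetrics:
    """70/30 stratified split validation of the occurrence model.

    AUC is the rank (concordance) statistic on the test split;
    sensitivity and specificity are evaluated at the Youden-optimal
    threshold chosen on the training split. A test split that loses one
    class is resampled with a new seed (logged).
    """
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    y = np.asarray(presence, dtype=float)
    tab = check_predictors(predictors)
    auto = np.asarray(autocov, dtype=float)
    idx = np.arange(len(y))
    split_seed = seed
    for attempt in range(max_retries):
        tr, te = train_test_split(
            idx, train_size=train_frac, random_state=split_seed, stratify=y
        )
        if len(np.unique(y[tr])) == 2 and len(np.unique(y[te])) == 2:
            break
        logger.info("single-class split with seed %d; resampling", split_seed)
        split_seed += 1
    else:
        raise ValueError("could not obtain a two-class train/test split")
    model = fit_sdm(y[tr], tab.iloc[tr], auto[tr],
                    smooth_df=smooth_df, alpha=alpha, species_id=species_id)
    train_scores = model.predict(tab.iloc[tr], autocov=auto[tr], clip=False)
    threshold = _youden_threshold(y[tr], train_scores)
    test_scores = model.predict(tab.iloc[te], autocov=auto[te])
    auc = auc_score(y[te], test_scores)
    pred = test_scores >= threshold
    pos, neg = y[te] == 1, y[te] == 0
    sensitivity = float(pred[pos].mean())
    specificity = float((~pred[neg]).mean())
    return ValidationMetrics(
        auc=auc,
        sensitivity=sensitivity,
        specificity=specificity,
        threshold_used=threshold,
        split_seed=split_seed,
    )


def uncertainty_bounds(metrics: pd.DataFrame | list[ValidationMetrics]) -> tuple[float, float]:
    """Model-uncertainty range (1 - predictive accuracy).

    Returns ``(1 - mean AUC, 1 - mean sensitivity)``: the lower and upper
    bounds of the fraction of projected distribution that may be
    misestimated.
    """
    if isinstance(metrics, pd.DataFrame):
        auc = metrics["auc"].mean()
        sens = metrics["sensitivity"].mean()
    else:
        auc = float(np.mean([m.auc for m in metrics]))
        sens = float(np.mean([m.sensitivity for m in metrics]))
    return 1.0 - auc, 1.0 - sens
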