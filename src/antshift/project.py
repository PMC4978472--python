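"""Projection of fitted occurrence models onto decadal climate grids.

Each species' model is evaluated on the nine predictor surfaces of every
decade; cells at or above the species' stored Youden threshold count as
predicted presence. The per-decade fraction of presence cells (the
proportion of suitable geographic area) is regressed on decade index to
classify species as decreased / increased / stable. Summing presences
over species gives a richness surface per decade, from which the
altitude of peak richness, its upward displacement rate, and the shape
of the richness-altitude curve are derived.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .climate import AltitudeGrid, SeasonalClimate, WarmingScenario
from .sdm import SDMModel

logger = logging.getLogger(__name__)

SHAPE_LABELS = ("monotonic-decrease", "bell-shaped", "monotonic-increase", "flat")


@dataclass(frozen=True)
class ProjectionResult:
    """Per-decade probability/presence surfaces for one species."""

    species_id: str
    decades: tuple[str, ...]
    probability: dict[str, np.ndarray]
    presence: dict[str, np.ndarray]
    suitable_area_prop: dict[str, float]
    threshold: float


@dataclass(frozen=True)
class TrendClass:
    """Linear trend of suitable-area proportion over decades."""

    species_id: str
    slope: float
    p_value: float
    label: str


@dataclass(frozen=True)
class ShapeFit:
    """Quadratic fit of richness against altitude."""

    label: str
    a: float
    b: float
    c: float
    p_a: float

    @property
    def vertex(self) -> float:
        return -self.b / (2.0 * self.a) if self.a != 0 else np.inf


@dataclass(frozen=True)
class RichnessSummary:
    """Richness surface and altitudinal pattern for one decade."""

    decade_label: str
    richness: np.ndarray
    peak_altitude: float
    shape: ShapeFit
    bin_centres: np.ndarray = field(repr=False, default=None)
    bin_means: np.ndarray = field(repr=False, default=None)


def project_species(
    model: SDMModel,
    seasonal: SeasonalClimate,
    scenario: WarmingScenario,
    threshold: float | None = None,
) -> ProjectionResult:
    """Project one species onto every decade of a warming scenario.

    Per-cell probabilities use the model with the autocovariate held at
    its training mean; presence is probability >= threshold (the model's
    stored Youden threshold unless overridden).
    """
    thr = model.youden_threshold if threshold is None else float(threshold)
    shape = seasonal.baseline.shape
    probability, presence, props = {}, {}, {}
    for decade in scenario.decades:
        vals = seasonal.predictor_values(scenario.offset(decade))
        frame = pd.DataFrame({k: v.ravel() for k, v in vals.items()})
        p = model.predict(frame).reshape(shape)
        probability[decade] = p
        pres = p >= thr
        presence[decade] = pres
        props[decade] = float(pres.mean())
    return ProjectionResult(
        species_id=model.species_id,
        decades=tuple(scenario.decades),
        probability=probability,
        presence=presence,
        suitable_area_prop=props,
        threshold=thr,
    )


def classify_trend(result: ProjectionResult, alpha: float = 0.05) -> TrendClass:
    """OLS of suitable-area proportion on decade index (0, 1, ...).

    decreased / increased if the slope is significant at ``alpha``,
    stable otherwise.
    """
    props = [result.suitable_area_prop[d] for d in result.decades]
    if len(props) < 3:
        raise ValueError("need at least 3 decades to classify a trend")
    t = np.arange(len(props), dtype=float)
    fit = stats.linregress(t, props)
    slope, p = float(fit.slope), float(fit.pvalue)
    if np.isnan(p):  # zero-variance proportions: exactly stable
        p = 1.0
    if slope < 0 and p < alpha:
        label = "decreased"
    elif slope > 0 and p < alpha:
        label = "increased"
    else:
        label = "stable"
    return TrendClass(species_id=result.species_id, slope=slope, p_value=p, label=label)


def richness_surface(results: list[ProjectionResult], decade: str) -> np.ndarray:
    """Per-cell count of species predicted present in a decade."""
    grids = []
    for r in results:
        if decade not in r.presence:
            logger.warning("species %s lacks decade %s; excluded", r.species_id, decade)
            continue
        grids.append(r.presence[decade].astype(int))
    if not grids:
        raise ValueError(f"no projections available for decade {decade}")
    shapes = {g.shape for g in grids}
    if len(shapes) > 1:
        raise ValueError("projections do not share one grid")
    return np.sum(grids, axis=0)


def richness_by_altitude(
    richness: np.ndarray, altitude: AltitudeGrid, band_width_m: float = 50.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean richness in altitude bins: (bin centres, means, cell counts).

    Empty bins are skipped.
    """
    if band_width_m <= 0:
        raise ValueError("band_width_m must be > 0")
    alt = altitude.values.ravel()
    rich = np.asarray(richness, dtype=float).ravel()
    if alt.shape != rich.shape:
        raise ValueError("richness and altitude grids must be congruent")
    edges = np.arange(0.0, alt.max() + band_width_m, band_width_m)
    idx = np.digitize(alt, edges) - 1
    centres, means, counts = [], [], []
    for b in range(len(edges)):
        sel = idx == b
        if not sel.any():
            continue
        centres.append(edges[b] + band_width_m / 2.0)
        means.append(rich[sel].mean())
        counts.append(int(sel.sum()))
    return np.array(centres), np.array(means), np.array(counts)


def peak_altitude(
    richness: np.ndarray, altitude: AltitudeGrid, band_width_m: float = 50.0
) -> float:
    """Centre of the altitude bin with maximal mean richness.

    Ties break toward the lower altitude.
    """
    centres, means, _ = richness_by_altitude(richness, altitude, band_width_m)
    return float(centres[np.argmax(means)])  # argmax takes the first (lowest) maximum


def upward_rate(peaks: dict[str, float], years_per_decade: float = 10.0) -> float:
    """Upward displacement rate (m per year) of the richness peak.

    ``(peak_last - peak_first)`` divided by the years between the first
    and last decade midpoints; decade labels like ``"2000s"`` are parsed
    for ordering, otherwise insertion order with ``years_per_decade``
    spacing is used.
    """
    if len(peaks) < 2:
        raise ValueError("need at least 2 decades")
    labels = list(peaks)
    try:
        years = [float(lab.rstrip("s")) for lab in labels]
    except ValueError:
        years = [i * years_per_decade for i in range(len(labels))]
    order = np.argsort(years)
    first, last = labels[order[0]], labels[order[-1]]
    span = years[order[-1]] - years[order[0]]
    if span <= 0:
        raise ValueError("decades span zero years")
    return (peaks[last] - peaks[first]) / span


def curve_shape(
    bin_centres,
    richness,
    weights=None,
    alpha: float = 0.05,
) -> ShapeFit:
    """Classify the richness-altitude curve from a quadratic fit.

    Fits ``richness = a*alt^2 + b*alt + c`` by (optionally weighted)
    least squares. Labels:

    - ``bell-shaped``: a < 0 significantly and the vertex lies strictly
      inside the observed altitude range;
    - ``monotonic-decrease`` / ``monotonic-increase``: the fitted curve
      is monotone (with a strictly non-zero total change) over the
      whole observed range;
    - ``flat`` otherwise (including degenerate/singular fits and
      curves whose fitted extremum lies inside the range without
      significant curvature).

    Weights (e.g. cells per bin) keep sparsely represented summit bins
    from dominating the curvature.
    """
    x = np.asarray(bin_centres, dtype=float)
    y = np.asarray(richness, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 altitude bins")
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    design = np.column_stack([x**2, x, np.ones_like(x)])
    sw = np.sqrt(w)
    try:
        coef, res_ss, rank, _ = np.linalg.lstsq(design * sw[:, None], y * sw, rcond=None)
    except np.linalg.LinAlgError:
        rank = 0
    if rank < 3:
        logger.warning("singular quadratic design; shape reported as flat")
        return ShapeFit("flat", np.nan, np.nan, np.nan, np.nan)
    a, b, c = (float(v) for v in coef)
    # t-test of the quadratic coefficient from the weighted normal equations
    n, k = len(x), 3
    resid = y - design @ coef
    dof = n - k
    s2 = float((w * resid**2).sum() / dof) if dof > 0 else 0.0
    xtx_inv = np.linalg.inv((design * w[:, None]).T @ design)
    se_a = np.sqrt(max(s2 * xtx_inv[0, 0], 0.0))
    if se_a == 0.0:
        p_a = 0.0 if a != 0 else 1.0
    else:
        p_a = float(2.0 * stats.t.sf(abs(a) / se_a, dof))
    lo, hi = x.min(), x.max()
    vertex = -b / (2.0 * a) if a != 0 else np.nan

    if a < 0 and p_a < alpha and lo < vertex < hi:
        return ShapeFit("bell-shaped", a, b, c, p_a)

    # monotonicity of the fitted parabola over [lo, hi]
    d_lo, d_hi = 2 * a * lo + b, 2 * a * hi + b
    f = np.polyval([a, b, c], [lo, hi])
    total_change = f[1] - f[0]
    if d_lo <= 0 and d_hi <= 0 and total_change < 0:
        return ShapeFit("monotonic-decrease", a, b, c, p_a)
    if d_lo >= 0 and d_hi >= 0 and total_change > 0:
        return ShapeFit("monotonic-increase", a, b, c, p_a)
    return ShapeFit("flat", a, b, c, p_a)


def summarise_decade(
    results: list[ProjectionResult],
    decade: str,
    altitude: AltitudeGrid,
    band_width_m: float = 50.0,
    alpha: float = 0.05,
) -> RichnessSummary:
    """Richness surface, peak altitude and curve shape for one decade."""
    rich = richness_surface(results, decade)
    centres, means, counts = richness_by_altitude(rich, altitude, band_width_m)
    return RichnessSummary(
        decade_label=decade,
        richness=rich,
        peak_altitude=float(centres[np.argmax(means)]),
        shape=curve_shape(centres, means, weights=counts, alpha=alpha),
        bin_centres=centres,
        bin_means=means,
    )


def plot_richness_profiles(summaries: dict[str, "RichnessSummary"], path) -> None:
    """Quick-look plot of binned richness vs altitude per decade.

    Requires matplotlib (optional dependency).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for decade, summ in summaries.items():
        ax.plot(summ.bin_centres, summ.bin_means, marker="o", ms=3,
                label=f"{decade} (peak {summ.peak_altitude:.0f} m, {summ.shape.label})")
        ax.axvline(summ.peak_altitude, ls=":", lw=0.6, color="grey")
    ax.set_xlabel("altitude (m)")
    ax.set_ylabel("mean predicted richness")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def band_richness_change(
    baseline_richness: np.ndarray,
    future_richness: np.ndarray,
    altitude: AltitudeGrid,
    band_edges,
) -> pd.DataFrame:
    """Percent richness loss per altitude band between two decades."""
    alt = altitude.values.ravel()
    r0 = np.asarray(baseline_richness, dtype=float).ravel()
    r1 = np.asarray(future_richness, dtype=float).ravel()
    rows = []
    for i in range(len(band_edges) - 1):
        lo, hi = band_edges[i], band_edges[i + 1]
        sel = (alt >= lo) & (alt < hi)
        if not sel.any():
            continue
        base, fut = r0[sel].mean(), r1[sel].mean()
        loss = 100.0 * (base - fut) / base if base > 0 else np.nan
        rows.append({"band_low_m": lo, "band_high_m": hi,
                     "baseline_richness": base, "future_richness": fut,
                     "loss_pct": loss})
    return pd.DataFrame(rows)
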