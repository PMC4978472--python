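"""End-to-end pipeline: synth (or load) -> niche -> risk -> sdm -> project.

A :class:`PipelineConfig` fully determines a run; the resolved config is
serialised next to every output set so each run is reproducible
bit-for-bit from its own artefacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import climate as climate_mod
from . import niche as niche_mod
from . import project as project_mod
from . import risk as risk_mod
from . import sdm as sdm_mod
from . import synth as synth_mod
from .errors import StageError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of one pipeline run."""

    synth: synth_mod.SyntheticStudyConfig = field(
        default_factory=synth_mod.SyntheticStudyConfig
    )
    warming: dict[str, float] = field(default_factory=lambda: dict(climate_mod.A1B_OFFSETS))
    n_boot: int = 1000
    buffer_m: float = 100.0
    train_frac: float = 0.7
    smooth_df: int = 4
    penalty: float = 1.0
    autocov_radius_m: float | None = None
    band_width_m: float = 50.0
    alpha: float = 0.05
    min_presences: int = 10
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must be in (0, 1)")
        if self.n_boot < 2 or self.buffer_m <= 0 or self.band_width_m <= 0:
            raise ValueError("n_boot, buffer_m and band_width_m out of range")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["synth"]["band_edges"] = [
            "inf" if np.isinf(e) else float(e) for e in data["synth"]["band_edges"]
        ]
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        synth_data = data.pop("synth", {})
        for key in ("band_edges", "band_counts", "optimum_range", "tolerance_range"):
            if key in synth_data:
                synth_data[key] = tuple(
                    np.inf if v == "inf" else v for v in synth_data[key]
                )
        return cls(synth=synth_mod.SyntheticStudyConfig(**synth_data), **data)


def validate_inputs(
    sites: pd.DataFrame, abundance: pd.DataFrame, grid: climate_mod.ClimateGrid
) -> dict:
    """Consistency report for externally supplied inputs.

    Checks duplicate site ids, dimensional agreement, negative counts
    and sites outside the grid; returns ``{"passed": bool, "problems":
    [...]}`` with line-level diagnostics.
    """
    problems: list[str] = []
    dupes = sites["site_id"][sites["site_id"].duplicated()].tolist()
    if dupes:
        problems.append(f"duplicate site ids: {dupes}")
    if len(sites) != len(abundance):
        problems.append(
            f"site table has {len(sites)} rows but abundance has {len(abundance)}"
        )
    neg = np.argwhere(abundance.to_numpy() < 0)
    for r, c in neg[:20]:
        problems.append(
            f"negative count at site {abundance.index[r]!r}, species {abundance.columns[c]!r}"
        )
    for _, row in sites.iterrows():
        if not grid.contains(row["x"], row["y"]):
            problems.append(f"site {row['site_id']!r} outside grid bounds")
    return {"passed": not problems, "problems": problems}


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(name, str(exc)) from exc
        return inner
    return wrap


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every stage and write all outputs under ``outdir``.

    Returns the machine-readable summary (also written as
    ``summary.json``). Partial outputs are retained on stage failure.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    master = np.random.SeedSequence(config.seed)
    s_synth, s_niche, s_cv = (s.generate_state(1)[0] % 2**31 for s in master.spawn(3))
    scenario = climate_mod.WarmingScenario(dict(config.warming))
    baseline_decade = scenario.decades[0]

    # ---- synth ------------------------------------------------------------
    study = _stage("synth")(synth_mod.make_study)(config.synth, seed=int(s_synth))
    synth_mod.write_study(study, outdir)
    climate_mod.write_asc(study.climate, outdir / f"temperature_{baseline_decade}.asc")
    climate_mod.write_asc(study.altitude, outdir / "altitude.asc")
    site_temps = study.site_temps
    site_alts = study.sites["altitude"].to_numpy()

    # ---- niche ------------------------------------------------------------
    @_stage("niche")
    def niche_stage():
        table = niche_mod.estimate_niches(
            study.abundance, site_temps, altitudes=site_alts,
            n_boot=config.n_boot, seed=int(s_niche),
        )
        diag = niche_mod.warm_diagnostics(
            study.abundance, site_temps, n_boot=config.n_boot, seed=int(s_niche)
        )
        return table, diag

    niche_table, diagnostics = niche_stage()
    niche_table.to_csv(outdir / "niche_table.csv")
    estimates = [
        niche_mod.NicheEstimate(
            species_id=sp, wa=row["wa"], tol=row["tol"],
            wa_boot_se=row["wa_boot_se"], tol_boot_se=row["tol_boot_se"],
            n_sites_present=int(row["n_sites_present"]),
            occurrence_freq=row["occurrence_freq"],
        )
        for sp, row in niche_table.iterrows()
    ]

    # ---- risk -------------------------------------------------------------
    @_stage("risk")
    def risk_stage():
        assessments, band_rows = [], []
        for decade in scenario.decades:
            assessment = risk_mod.assess_decade(
                estimates, study.climate, scenario, decade, study.sites, config.buffer_m
            )
            grid = climate_mod.apply_warming(study.climate, scenario, decade)
            band = risk_mod.band_risk_rates(
                study.sites, study.abundance, estimates, grid,
                config.synth.band_edges, config.buffer_m,
            )
            assessments.append(dataclasses.replace(assessment, band_rates=band))
            for label, rate in band.items():
                band_rows.append(
                    {"decade": decade, "band": label, "rate_pct": rate}
                )
        return assessments, pd.DataFrame(band_rows)

    assessments, band_table = risk_stage()
    risk_mod.risk_table(assessments, estimates).to_csv(outdir / "risk_table.csv", index=False)
    band_table.to_csv(outdir / "band_risk_rates.csv", index=False)

    # ---- sdm --------------------------------------------------------------
    coords = study.sites[["x", "y"]].to_numpy()
    radius = config.autocov_radius_m or sdm_mod.default_autocov_radius(coords)
    predictors = study.seasonal.site_predictors(study.sites["x"], study.sites["y"])

    @_stage("sdm")
    def sdm_stage():
        total = study.abundance.sum(axis=1).to_numpy(dtype=float)
        moran = sdm_mod.morans_i(total, coords, radius)
        models, metric_rows = [], []
        rng = np.random.default_rng(int(s_cv))
        for sp in study.abundance.columns:
            presence = (study.abundance[sp] > 0).astype(int).to_numpy()
            n_pres = presence.sum()
            if n_pres < config.min_presences or n_pres > len(presence) - config.min_presences:
                logger.warning("species %s skipped: %d presences", sp, n_pres)
                continue
            auto = sdm_mod.build_autocovariate(presence, coords, radius)
            model = sdm_mod.fit_sdm(
                presence, predictors, auto,
                smooth_df=config.smooth_df, alpha=config.penalty, species_id=sp,
            )
            metrics = sdm_mod.cross_validate(
                presence, predictors, auto,
                train_frac=config.train_frac, seed=int(rng.integers(2**31)),
                smooth_df=config.smooth_df, alpha=config.penalty, species_id=sp,
            )
            models.append(model)
            metric_rows.append(
                {"species_id": sp, "auc": metrics.auc,
                 "sensitivity": metrics.sensitivity, "specificity": metrics.specificity,
                 "threshold": metrics.threshold_used, "split_seed": metrics.split_seed}
            )
        return moran, models, pd.DataFrame(metric_rows)

    moran, models, metrics_table = sdm_stage()
    metrics_table.to_csv(outdir / "sdm_metrics.csv", index=False)

    # ---- project ----------------------------------------------------------
    @_stage("project")
    def project_stage():
        results = [
            project_mod.project_species(m, study.seasonal, scenario) for m in models
        ]
        trends = [project_mod.classify_trend(r, alpha=config.alpha) for r in results]
        summaries = {
            d: project_mod.summarise_decade(
                results, d, study.altitude, config.band_width_m, config.alpha
            )
            for d in scenario.decades
        }
        return results, trends, summaries

    results, trends, summaries = project_stage()
    pd.DataFrame(
        [
            {"species_id": t.species_id, "slope_per_decade": t.slope,
             "p_value": t.p_value, "label": t.label,
             **{f"prop_{d}": r.suitable_area_prop[d] for d in scenario.decades}}
            for t, r in zip(trends, results)
        ]
    ).to_csv(outdir / "species_trends.csv", index=False)
    for d, summ in summaries.items():
        grid = climate_mod.ClimateGrid(
            values=summ.richness.astype(float), cell_size=study.climate.cell_size,
            origin=study.climate.origin, decade_label=d, kind="mean",
        )
        climate_mod.write_asc(grid, outdir / f"richness_{d}.asc")
    pd.DataFrame(
        [
            {"decade": d, "peak_altitude_m": s.peak_altitude, "shape": s.shape.label,
             "a": s.shape.a, "b": s.shape.b, "c": s.shape.c}
            for d, s in summaries.items()
        ]
    ).to_csv(outdir / "richness_summary.csv", index=False)

    peaks = {d: s.peak_altitude for d, s in summaries.items()}
    unc_low, unc_high = sdm_mod.uncertainty_bounds(metrics_table) if len(metrics_table) else (np.nan, np.nan)
    summary = {
        "seed": config.seed,
        "n_sites": int(len(study.sites)),
        "n_species_modelled": int(len(models)),
        "warm_r2": diagnostics.r2,
        "warm_rmse": diagnostics.rmse,
        "warm_mean_bias": diagnostics.mean_bias,
        "morans_i": moran[0],
        "morans_i_p": moran[1],
        "risk_rate_pct": {a.decade_label: a.risk_rate_pct for a in assessments},
        "band_risk_rates_pct": {
            a.decade_label: {k: (None if pd.isna(v) else v) for k, v in a.band_rates.items()}
            for a in assessments
        },
        "mean_auc": float(metrics_table["auc"].mean()) if len(metrics_table) else None,
        "uncertainty_bounds": [unc_low, unc_high],
        "trend_counts": {
            lab: int(sum(t.label == lab for t in trends))
            for lab in ("decreased", "increased", "stable")
        },
        "peak_altitude_m": peaks,
        "shape_labels": {d: s.shape.label for d, s in summaries.items()},
        "upward_rate_m_per_yr": project_mod.upward_rate(peaks),
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
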