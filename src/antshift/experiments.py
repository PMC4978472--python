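"""Replicate validation suites over synthetic studies.

These functions define the package's standard validation protocol:
fixed replicate seed sets over the named study presets, shared by the
test suite and the acceptance script so both evaluate the identical
computation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import climate as climate_mod
from . import niche as niche_mod
from . import project as project_mod
from . import risk as risk_mod
from . import sdm as sdm_mod
from . import synth as synth_mod

logger = logging.getLogger(__name__)

#: Replicate seeds of the standard validation protocol.
REPLICATE_SEEDS = tuple(range(1, 21))


def recovery_errors(seeds=REPLICATE_SEEDS) -> pd.DataFrame:
    """Weighted-averaging parameter recovery on the calibration preset.

    For each seed, generates a study and returns the mean absolute
    difference between each species' estimated optimum (WA) and its true
    niche optimum.
    """
    rows = []
    for seed in seeds:
        study = synth_mod.make_study(synth_mod.SyntheticStudyConfig.calibration(seed=seed))
        temps = study.site_temps
        errs = []
        for sp in study.niches:
            y = study.abundance[sp.species_id].to_numpy(dtype=float)
            if y.sum() <= 0:
                continue
            wa = niche_mod.weighted_average(temps, y)
            errs.append(abs(wa - sp.true_optimum))
        rows.append({"seed": seed, "mean_abs_error": float(np.mean(errs)),
                     "n_species": len(errs)})
    return pd.DataFrame(rows)


def risk_nesting(seeds=REPLICATE_SEEDS, scenario: climate_mod.WarmingScenario | None = None) -> pd.DataFrame:
    """Nestedness of at-risk sets across increasing warming offsets.

    For each seed (default preset), classifies every species in every
    decade and checks that the at-risk set under a smaller offset is a
    subset of the set under any larger offset.
    """
    scenario = scenario or climate_mod.WarmingScenario()
    rows = []
    for seed in seeds:
        study = synth_mod.make_study(synth_mod.SyntheticStudyConfig(seed=seed))
        temps = study.site_temps
        table = niche_mod.estimate_niches(study.abundance, temps, n_boot=2, seed=seed)
        estimates = [
            niche_mod.NicheEstimate(species_id=sp, wa=row["wa"], tol=row["tol"])
            for sp, row in table.iterrows()
        ]
        sets = []
        for decade in scenario.decades:
            a = risk_mod.assess_decade(estimates, study.climate, scenario, decade, study.sites)
            sets.append({sp for sp, flag in a.at_risk.items() if flag})
        nested = all(sets[i] <= sets[i + 1] for i in range(len(sets) - 1))
        rows.append({"seed": seed, "nested": nested,
                     "n_at_risk_final": len(sets[-1])})
    return pd.DataFrame(rows)


def _fit_study_models(study, min_presences: int = 10):
    coords = study.sites[["x", "y"]].to_numpy()
    radius = sdm_mod.default_autocov_radius(coords)
    predictors = study.seasonal.site_predictors(study.sites["x"], study.sites["y"])
    models = []
    for sp in study.abundance.columns:
        presence = (study.abundance[sp] > 0).astype(int).to_numpy()
        n_pres = int(presence.sum())
        if n_pres < min_presences or n_pres > len(presence) - min_presences:
            continue
        auto = sdm_mod.build_autocovariate(presence, coords, radius)
        models.append(sdm_mod.fit_sdm(presence, predictors, auto, species_id=sp))
    return models, predictors, coords, radius


def null_auc(seeds=REPLICATE_SEEDS) -> pd.DataFrame:
    """Cross-validated AUC with labels shuffled: discrimination should
    collapse to chance.

    For each seed, generates the default study, picks the species with
    prevalence closest to 0.5, permutes its presence labels and
    cross-validates the occurrence model.
    """
    rows = []
    for seed in seeds:
        study = synth_mod.make_study(synth_mod.SyntheticStudyConfig(seed=seed))
        coords = study.sites[["x", "y"]].to_numpy()
        radius = sdm_mod.default_autocov_radius(coords)
        predictors = study.seasonal.site_predictors(study.sites["x"], study.sites["y"])
        presence_all = (study.abundance > 0).astype(int)
        prev = presence_all.mean(axis=0)
        sp = (prev - 0.5).abs().idxmin()
        rng = np.random.default_rng(seed)
        shuffled = rng.permutation(presence_all[sp].to_numpy())
        auto = sdm_mod.build_autocovariate(shuffled, coords, radius)
        metrics = sdm_mod.cross_validate(
            shuffled, predictors, auto, seed=seed, species_id=f"{sp}-shuffled"
        )
        rows.append({"seed": seed, "species_id": sp, "auc": metrics.auc})
    return pd.DataFrame(rows)


def sdm_discrimination(seed: int = 1) -> pd.DataFrame:
    """Cross-validated discrimination of every modelled species on one
    default study."""
    study = synth_mod.make_study(synth_mod.SyntheticStudyConfig(seed=seed))
    coords = study.sites[["x", "y"]].to_numpy()
    radius = sdm_mod.default_autocov_radius(coords)
    predictors = study.seasonal.site_predictors(study.sites["x"], study.sites["y"])
    rows = []
    rng = np.random.default_rng(seed)
    for sp in study.abundance.columns:
        presence = (study.abundance[sp] > 0).astype(int).to_numpy()
        n_pres = int(presence.sum())
        if n_pres < 10 or n_pres > len(presence) - 10:
            continue
        auto = sdm_mod.build_autocovariate(presence, coords, radius)
        m = sdm_mod.cross_validate(
            presence, predictors, auto, seed=int(rng.integers(2**31)), species_id=sp
        )
        rows.append({"species_id": sp, "auc": m.auc, "sensitivity": m.sensitivity,
                     "specificity": m.specificity})
    return pd.DataFrame(rows)


def rangeshift_replicates(
    seeds=REPLICATE_SEEDS, scenario: climate_mod.WarmingScenario | None = None
) -> pd.DataFrame:
    """Peak-altitude trajectory and curve-shape labels per decade on the
    range-shift preset.

    Returns one row per seed with the per-decade richness-peak altitudes
    and shape labels, whether peaks are non-decreasing over decades,
    whether the shape transitions from monotonic-decrease (baseline) to
    bell-shaped (final decade), and the upward displacement rate.
    """
    scenario = scenario or climate_mod.WarmingScenario()
    rows = []
    for seed in seeds:
        study = synth_mod.make_study(synth_mod.SyntheticStudyConfig.rangeshift(seed=seed))
        models, _, _, _ = _fit_study_models(study)
        results = [
            project_mod.project_species(m, study.seasonal, scenario) for m in models
        ]
        summaries = {
            d: project_mod.summarise_decade(results, d, study.altitude)
            for d in scenario.decades
        }
        peaks = [summaries[d].peak_altitude for d in scenario.decades]
        shapes = [summaries[d].shape.label for d in scenario.decades]
        row = {"seed": seed}
        for d, p, s in zip(scenario.decades, peaks, shapes):
            row[f"peak_{d}"] = p
            row[f"shape_{d}"] = s
        row["peaks_non_decreasing"] = all(b >= a for a, b in zip(peaks, peaks[1:]))
        row["md_to_bell"] = (
            shapes[0] == "monotonic-decrease" and shapes[-1] == "bell-shaped"
        )
        row["upward_rate_m_per_yr"] = project_mod.upward_rate(
            dict(zip(scenario.decades, peaks))
        )
        rows.append(row)
    return pd.DataFrame(rows)


def band_rate_gradient(seeds=REPLICATE_SEEDS) -> pd.DataFrame:
    """Highest- vs lowest-band risk rates under the strongest offset.

    For each seed (default preset), compares the risk rate of the
    highest occupied altitude band with the lowest band in the final
    decade; under warming the top band's rate should not fall below the
    bottom band's.
    """
    scenario = climate_mod.WarmingScenario()
    final = scenario.decades[-1]
    rows = []
    for seed in seeds:
        study = synth_mod.make_study(synth_mod.SyntheticStudyConfig(seed=seed))
        temps = study.site_temps
        table = niche_mod.estimate_niches(study.abundance, temps, n_boot=2, seed=seed)
        estimates = [
            niche_mod.NicheEstimate(species_id=sp, wa=row["wa"], tol=row["tol"])
            for sp, row in table.iterrows()
        ]
        grid = climate_mod.apply_warming(study.climate, scenario, final)
        band = risk_mod.band_risk_rates(
            study.sites, study.abundance, estimates, grid, study.config.band_edges
        )
        rates = [v for v in band.values() if not pd.isna(v)]
        rows.append({
            "seed": seed,
            "lowest_band_rate": rates[0],
            "highest_band_rate": rates[-1],
            "top_ge_bottom": rates[-1] >= rates[0],
        })
    return pd.DataFrame(rows)
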