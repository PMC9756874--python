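"""End-to-end orchestration of the rewilding analysis.

``run_pipeline`` executes the full chain on a synthetic study system:
landscape generation, survey design, detection simulation, independence
filtering, REM estimation, IDW interpolation, suitability levels,
land-cover change classification, the association statistics, and the
population projection.  All randomness flows from one root seed; stage
outputs are written as plain-text artifacts (ASCII grids, CSV, YAML) plus
a machine-readable results dictionary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import yaml

from . import landcover_change as lcc
from . import pva as pva_mod
from . import rem, spatial_stats, suitability
from . import synthetic_data as synth

__all__ = [
    "PipelineConfig",
    "population_density",
    "mean_cell_density",
    "run_pipeline",
]


class InvalidAreaError(ValueError):
    pass


class NoDataError(ValueError):
    pass


class DependencyError(RuntimeError):
    """A stage needed the output of a stage that was toggled off."""


def population_density(n_individuals: float, area_km2: float) -> float:
    """Equilibrium density (ind/km^2) of a projected population over an area.

    Dividing the PVA population size by the highly suitable habitat extent
    gives the study's headline expected densities.
    """
    if area_km2 <= 0:
        raise InvalidAreaError("area must be positive")
    if n_individuals < 0:
        raise ValueError("population size must be >= 0")
    return n_individuals / area_km2


def mean_cell_density(densities) -> tuple[float, float]:
    """Unweighted mean and SE (SD/sqrt n) over per-cell density estimates.

    Accepts a list of numbers or of :class:`rem.CellDensityEstimate`;
    zero-density cells count.
    """
    vals = np.asarray(
        [d.density if hasattr(d, "density") else float(d) for d in densities],
        dtype=float,
    )
    if vals.size == 0:
        raise NoDataError("no cell estimates")
    mean = float(vals.mean())
    se = float(vals.std(ddof=1) / math.sqrt(vals.size)) if vals.size > 1 else 0.0
    return mean, se


@dataclass
class PipelineConfig:
    """Settings for a synthetic end-to-end run.

    ``abundances`` are the true numbers of individuals planted per species;
    ``decay_per_km`` the exponential distance-decay of density from the
    release point.  Succession in epoch 2 responds to cumulative grazer
    density through ``succession_params``.
    """

    seed: int = 0
    extent_m: tuple[float, float] = (20_000.0, 20_000.0)
    resolution_m: float = 100.0
    n_quadrats: int = 4
    trap_days: float = 100.0
    abundances: dict[str, float] = field(
        default_factory=lambda: {"roe_deer": 600.0, "red_deer": 250.0, "livestock": 700.0}
    )
    decay_per_km: float = 0.25
    suitability_threshold: float = 0.5
    idw_power: float = 2.0
    glm_families: dict[str, str] = field(
        default_factory=lambda: {"roe_deer": "inverse-gaussian", "red_deer": "gamma"}
    )
    succession_params: synth.SuccessionChangeParams = field(
        default_factory=lambda: synth.SuccessionChangeParams(
            advance_intercept=1.5,
            advance_slope=1.2,
            revert_intercept=-3.0,
            revert_slope=0.8,
        )
    )
    bootstrap_B: int = 200
    pva_config: pva_mod.PVAConfig | None = None
    stages: dict[str, bool] = field(
        default_factory=lambda: {
            "simulate": True,
            "rem": True,
            "interpolate": True,
            "suitability": True,
            "change": True,
            "stats": True,
            "pva": True,
        }
    )
    out_dir: Path | None = None


def _camera_catalog() -> list[rem.CameraSpec]:
    """Camera models and detection-zone geometry used in the survey."""
    return [
        rem.CameraSpec("ScoutGuard SG-2060-X", 20.0, 0.87),
        rem.CameraSpec("LTL Acorn 5310", 20.0, 2.09),
        rem.CameraSpec("Browning Recon Force 4K", 20.0, 0.77),
        rem.CameraSpec("Stealth Cam DS4K", 20.0, 0.79),
        rem.CameraSpec("Victure HC300", 20.0, 1.57),
        rem.CameraSpec("Uovision UV575", 12.0, 1.75),
    ]


def _make_deployments(
    cells: list[rem.SurveyCell], trap_days: float, rng: np.random.Generator
) -> list[rem.Deployment]:
    catalog = _camera_catalog()
    start = datetime(2021, 4, 1)
    end = start + timedelta(days=trap_days)
    deployments = []
    for cell in cells:
        for k, (x, y) in enumerate(cell.corner_points):
            spec = catalog[int(rng.integers(len(catalog)))]
            deployments.append(
                rem.Deployment(
                    camera_id=f"{cell.cell_id}{k}",
                    spec=spec,
                    location=(x, y),
                    cell_id=cell.cell_id,
                    start=start,
                    end=end,
                )
            )
    return deployments


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the analysis chain on synthetic data; returns the results dict.

    Artifacts (rasters, CSVs, results.yaml) are written when
    ``config.out_dir`` is set.  Deterministic given ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed)
    sub = {name: s for name, s in zip(
        ["landscape", "density", "detections", "design", "rem", "change", "pva",
         "thresholds"],
        ss.spawn(8),
    )}
    results: dict = {"seed": config.seed}
    art: dict = {}
    stages = config.stages

    def _need(stage: str, key: str):
        if key not in art:
            raise DependencyError(
                f"stage {stage!r} requires output of a stage that did not run: {key}"
            )
        return art[key]

    # --- synthetic study system ---------------------------------------
    if stages.get("simulate", True):
        lconf = synth.LandscapeConfig(
            extent_m=config.extent_m,
            resolution_m=config.resolution_m,
            seed=int(np.random.default_rng(sub["landscape"]).integers(2**31)),
        )
        bundle = synth.generate_landscape(lconf)
        art["bundle"] = bundle
        fields = {}
        for species, n in config.abundances.items():
            fields[species] = synth.simulate_density_field(
                bundle, species, n, config.decay_per_km,
                suitability_threshold=config.suitability_threshold,
            )
        art["true_fields"] = fields

    # --- survey design + detections + REM ------------------------------
    if stages.get("rem", True):
        bundle = _need("rem", "bundle")
        fields = _need("rem", "true_fields")
        deer_mask = (
            (bundle.suitability["roe_deer"].data >= config.suitability_threshold)
            | (bundle.suitability["red_deer"].data >= config.suitability_threshold)
        )
        mask_raster = bundle.grid().like(deer_mask.astype(float))
        cells = rem.build_survey_design(
            bundle.grid().extent, mask_raster, config.n_quadrats,
            seed=int(np.random.default_rng(sub["design"]).integers(2**31)),
        )
        dep_rng = np.random.default_rng(sub["design"])
        deployments = _make_deployments(cells, config.trap_days, dep_rng)
        art["cells"], art["deployments"] = cells, deployments

        det_seed_root = np.random.default_rng(sub["detections"])
        estimates: dict[str, list[rem.CellDensityEstimate]] = {}
        all_records: list[rem.DetectionRecord] = []
        for species, fld in fields.items():
            v = rem.SPEED_KM_PER_DAY.get(species, 4.0)
            records = synth.simulate_detections(
                fld, deployments, v, seed=int(det_seed_root.integers(2**31))
            )
            records = rem.filter_independent(records)
            all_records.extend(records)
            sp = rem.SpeciesParams(species, v)
            est = []
            boot_rng = np.random.default_rng(sub["rem"])
            for cell in cells:
                deps = [d for d in deployments if d.cell_id == cell.cell_id]
                recs = [r for r in records if r.camera_id in {d.camera_id for d in deps}]
                est.append(
                    rem.estimate_cell(
                        recs, deps, sp, bootstrap_B=config.bootstrap_B,
                        seed=int(boot_rng.integers(2**31)),
                    )
                )
            estimates[species] = est
        art["estimates"], art["records"] = estimates, all_records
        results["rem"] = {
            sp: {
                "mean_density": mean_cell_density(est)[0],
                "se": mean_cell_density(est)[1],
                "cells": {e.cell_id: round(e.density, 4) for e in est},
            }
            for sp, est in estimates.items()
        }

    # --- suitability levels --------------------------------------------
    if stages.get("suitability", True):
        bundle = _need("suitability", "bundle")
        levels = {}
        thr_rng = np.random.default_rng(sub["thresholds"])
        for species in ("roe_deer", "red_deer"):
            scores = np.asarray(bundle.suitability[species].data, dtype=float).ravel()
            # presence records concentrate where habitat quality is high
            p = scores**2
            presence = thr_rng.choice(scores, size=300, p=p / p.sum())
            background = thr_rng.choice(scores, size=1000)
            thr = suitability.SuitabilityThresholds(
                p10=suitability.percentile_threshold(presence, 10),
                maxsss=suitability.max_sss_threshold(presence, background),
            )
            levels[species] = suitability.classify_levels(bundle.suitability[species], thr)
        art["levels"] = levels
        results["suitability"] = {
            sp: {k: round(v, 2) for k, v in lv.area_km2.items()}
            for sp, lv in levels.items()
        }

    # --- density surfaces ----------------------------------------------
    if stages.get("interpolate", True):
        bundle = _need("interpolate", "bundle")
        estimates = _need("interpolate", "estimates")
        cells = _need("interpolate", "cells")
        centers = np.array(
            [
                (
                    (c.cell_bounds[0] + c.cell_bounds[2]) / 2,
                    (c.cell_bounds[1] + c.cell_bounds[3]) / 2,
                )
                for c in cells
            ]
        )
        surfaces = {}
        for species, est in estimates.items():
            suit_layer = bundle.suitability.get(species)
            mask = (
                suit_layer.data >= config.suitability_threshold
                if suit_layer is not None
                else np.ones(bundle.grid().shape, dtype=bool)
            )
            vals = np.array([e.density for e in est])
            surfaces[species] = spatial_stats.idw_interpolate(
                centers, vals, bundle.grid(), power=config.idw_power,
                mask=np.asarray(mask, dtype=bool), label=species,
            )
        cumulative = spatial_stats.merge_densities(list(surfaces.values()))
        art["surfaces"], art["cumulative"] = surfaces, cumulative

    # --- land-cover change ---------------------------------------------
    if stages.get("change", True):
        bundle = _need("change", "bundle")
        # true cumulative grazer density drives succession in epoch 2
        fields = _need("change", "true_fields")
        true_cum = sum(f.surface.data for f in fields.values())
        epoch2 = synth.simulate_landcover_change(
            bundle,
            bundle.grid().like(true_cum),
            config.succession_params,
            seed=int(np.random.default_rng(sub["change"]).integers(2**31)),
        )
        pieces = lcc.overlay_epochs(bundle.landcover_epoch1, epoch2)
        pieces = lcc.clean_small(pieces, 0.25)
        change_raster, change_areas = lcc.rasterize_changes(pieces, bundle.grid())
        art["epoch2"], art["change_raster"] = epoch2, change_raster
        results["change_areas_km2"] = {k: round(v, 2) for k, v in change_areas.items()}

    # --- statistics ----------------------------------------------------
    if stages.get("stats", True):
        bundle = _need("stats", "bundle")
        cumulative = _need("stats", "cumulative")
        change_raster = _need("stats", "change_raster")
        surfaces = _need("stats", "surfaces")
        levels = _need("stats", "levels")

        dist_km = bundle.grid().like(
            synth.distance_from_release_km(bundle.grid(), bundle.release_point)
        )
        glms = {}
        for species, family in config.glm_families.items():
            if species in surfaces:
                try:
                    glms[species] = spatial_stats.fit_density_distance_glm(
                        surfaces[species], dist_km, family=family
                    )
                except spatial_stats.InsufficientDataError:
                    continue
        results["glm"] = {
            sp: {
                "family": g.family,
                "intercept": round(g.intercept, 4),
                "slope": round(g.slope, 4),
                "slope_p": g.slope_p,
                "pseudo_r2": round(g.pseudo_r2, 3),
                "n": g.n,
                "aic": round(g.aic, 2),
                "bic": round(g.bic, 2),
            }
            for sp, g in glms.items()
        }

        summary = spatial_stats.class_density_summary(cumulative, change_raster)
        results["class_density"] = summary
        if "SS" in summary and "IS" in summary:
            vals = np.asarray(cumulative.raster.data, dtype=float)
            cls = np.asarray(change_raster.data, dtype=int)
            sel = cumulative.mask & np.isfinite(vals)
            ss_vals = vals[sel & (cls == lcc.SS_VALUE)]
            is_vals = vals[sel & (cls == lcc.IS_VALUE)]
            if ss_vals.size >= 2 and is_vals.size >= 2:
                wt = spatial_stats.welch_t(ss_vals, is_vals)
                results["welch_ss_vs_is"] = {
                    "t": wt.statistic, "df": wt.df, "p": wt.p_value,
                    "means": wt.means, "ns": wt.ns,
                }

        suitable = (
            (levels["roe_deer"].raster.data >= suitability.MEDIUM)
            | (levels["red_deer"].raster.data >= suitability.MEDIUM)
        )
        cls = np.asarray(change_raster.data, dtype=int)
        table = [
            [
                int(((cls == lcc.IS_VALUE) & suitable).sum()),
                int(((cls == lcc.IS_VALUE) & ~suitable).sum()),
            ],
            [
                int(((cls == lcc.SS_VALUE) & suitable).sum()),
                int(((cls == lcc.SS_VALUE) & ~suitable).sum()),
            ],
        ]
        try:
            chi = spatial_stats.chi_square_2x2(table)
            results["chi2_inside_outside"] = {
                "table": table, "chi2": chi.statistic, "p": chi.p_value,
                "n": int(np.sum(table)),
            }
        except spatial_stats.DegenerateTableError:
            results["chi2_inside_outside"] = {"table": table, "chi2": None}

        try:
            elev = spatial_stats.elevation_by_class(
                bundle.elevation, change_raster, exclude_mask=suitable
            )
            results["elevation_ss_vs_is"] = {
                "t": elev.statistic, "p": elev.p_value,
                "means": elev.means, "ns": elev.ns,
            }
        except spatial_stats.InsufficientDataError as exc:
            results["elevation_ss_vs_is"] = {"error": str(exc)}

    # --- population projection ------------------------------------------
    if stages.get("pva", True):
        cfg = config.pva_config or default_pva_config()
        cfg.seed = int(np.random.default_rng(sub["pva"]).integers(2**31))
        traj = pva_mod.project(cfg)
        art["pva"] = traj
        results["pva"] = {
            "final_mean_n": round(traj.final_mean_n, 2),
            "final_se_n": round(traj.final_se_n, 2),
            "extinction_probability": traj.extinction_probability,
            "growth_rate_lambda": round(pva_mod.deterministic_lambda(cfg), 4),
        }

    # --- artifacts -----------------------------------------------------
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if "bundle" in art:
            art["bundle"].landcover_epoch1.write_ascii_grid(out / "landcover_epoch1.asc")
            art["bundle"].elevation.write_ascii_grid(out / "elevation.asc")
        if "epoch2" in art:
            art["epoch2"].write_ascii_grid(out / "landcover_epoch2.asc")
        if "change_raster" in art:
            art["change_raster"].write_ascii_grid(out / "succession_classes.asc")
        if "cumulative" in art:
            art["cumulative"].raster.write_ascii_grid(out / "cumulative_density.asc")
        if "records" in art:
            rem.write_detections_csv(art["records"], out / "detections.csv")
        if "deployments" in art:
            rem.write_deployments_csv(art["deployments"], out / "deployments.csv")
        if "estimates" in art:
            flat = [e for est in art["estimates"].values() for e in est]
            rem.write_estimates_csv(flat, out / "cell_densities.csv")
        with open(out / "results.yaml", "w") as fh:
            yaml.safe_dump(_plain(results), fh, sort_keys=False)
    results["_artifacts"] = art
    return results


def default_pva_config() -> pva_mod.PVAConfig:
    """Roe-deer-like demographic rates (literature-plausible, synthetic).

    Not the parameter set of any published projection — those values were
    never deposited; these rates are a documented stand-in with the right
    orders of magnitude for a mid-size temperate cervid.
    """
    return pva_mod.PVAConfig(
        initial_individuals=[(pva_mod.FEMALE, 2)] * 19 + [(pva_mod.MALE, 2)] * 18,
        age_classes=[
            pva_mod.AgeClass(0, 0, 0.65, 0.65),
            pva_mod.AgeClass(1, 1, 0.80, 0.75),
            pva_mod.AgeClass(2, 12, 0.88, 0.82),
        ],
        breeding_proportion=0.80,
        litter_distribution={1: 0.35, 2: 0.55, 3: 0.10},
        sex_ratio_at_birth=0.5,
        first_breeding_age=2,
        carrying_capacity=400,
        years=19,
        iterations=100,
        seed=0,
    )


def _plain(obj):
    """Recursively convert numpy scalars/arrays for YAML serialisation."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items() if not str(k).startswith("_")}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
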