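"""End-to-end orchestration of the sampling-design experiment.

One configured run simulates a scene, renders and preprocesses the cube
(Savitzky-Golay smoothing, MNF, first-k component selection), places the
reference-plot design, then executes the nine classification runs — Stage 0
(naive split), Stage 1 (five cover-range scenarios) and Stage 2 (three
sample sizes for the winning Stage-1 scenario) — scoring each with the
three-criteria evaluation.  All randomness derives from one master seed.
"""
from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import classify, evaluate, mnf, sampling, scenarios
from .geo import GeoTransform, polygons_to_geojson, write_geojson, write_raster
from .scene import (CoverScene, HyperCube, extract_truth_patches,
                    make_spectral_library, make_wavelength_grid, render_cube,
                    simulate_cover_field)

_SEED_ROLES = ("library", "scene", "noise", "sampling", "stage0_split",
               "validation", "scenario", "rf")


@dataclass
class ExperimentConfig:
    """All tunables of one experiment; sub-seeds derive from ``seed``."""

    # scene
    rows: int = 400
    cols: int = 400
    n_bands: int = 60
    correlation_length_m: float = 6.0
    prevalence: float = 0.045
    gsd: float = 1.0
    noise_sd: float = 0.01
    # spectral library
    n_background_endmembers: int = 5
    separability: float = 0.03
    # sampling design
    n_target: int = 110
    strata_counts: tuple[int, int, int] = (30, 30, 50)
    n_background: int = 200
    radius_m: float = 2.0
    min_spacing_m: float = 6.0
    # preprocessing
    sg_window: int = 13
    sg_polyorder: int = 2
    mnf_k: int = 30
    # evaluation
    control_area_size_m: float = 200.0
    # orchestration
    seed: int = 0

    def sub_seeds(self) -> dict[str, int]:
        ss = np.random.SeedSequence(self.seed)
        children = ss.spawn(len(_SEED_ROLES))
        return {name: int(c.generate_state(1)[0] % (2 ** 31))
                for name, c in zip(_SEED_ROLES, children)}

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        import yaml

        d = asdict(self)
        d["strata_counts"] = list(d["strata_counts"])
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        d = yaml.safe_load(Path(path).read_text())
        if "strata_counts" in d:
            d["strata_counts"] = tuple(d["strata_counts"])
        return cls(**d)


def survey_scale_config(seed: int = 0) -> ExperimentConfig:
    """Survey-scale settings: 430 bands, 10 ha control square, 10 m plot spacing."""
    return ExperimentConfig(rows=1000, cols=1000, n_bands=430,
                            control_area_size_m=316.0, min_spacing_m=10.0,
                            seed=seed)


def choose_control_area(scene: CoverScene, size_m: float):
    """Square control area placed where the species' cover is best represented.

    Scans a coarse grid of candidate squares and keeps the one with the most
    field-mappable species area, emulating the field protocol of choosing a
    control square spanning the full density range.
    """
    from shapely.geometry import box

    size_px = int(round(size_m / scene.gsd))
    rows, cols = scene.shape
    if size_px > rows or size_px > cols:
        raise ValueError("control area larger than the scene")
    from .scene import truth_mask

    mask = truth_mask(scene).astype(float)
    csum = mask.cumsum(0).cumsum(1)
    pad = np.zeros((rows + 1, cols + 1))
    pad[1:, 1:] = csum
    step = max(size_px // 10, 1)
    best, best_rc = -1.0, (0, 0)
    for r in range(0, rows - size_px + 1, step):
        for c in range(0, cols - size_px + 1, step):
            s = (pad[r + size_px, c + size_px] - pad[r, c + size_px]
                 - pad[r + size_px, c] + pad[r, c])
            if s > best:
                best, best_rc = s, (r, c)
    r, c = best_rc
    gt = scene.transform
    return box(gt.x0 + c * scene.gsd, gt.y0 - (r + size_px) * scene.gsd,
               gt.x0 + (c + size_px) * scene.gsd, gt.y0 - r * scene.gsd)


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    scene: CoverScene
    design: sampling.SampleDesign
    reports: dict[str, evaluate.EvaluationReport]
    stage1_winner: str
    stage1_winners_by_criterion: dict[str, str]
    stage2_winner: str
    stage2_winners_by_criterion: dict[str, str]
    manifest: dict = field(default_factory=dict)

    @property
    def stage1_reports(self) -> list[evaluate.EvaluationReport]:
        return [self.reports[n] for n in scenarios.STAGE1_RANGES]

    @property
    def stage2_reports(self) -> list[evaluate.EvaluationReport]:
        return [r for n, r in self.reports.items() if "_" in n]


def _evaluate_run(cmap, val_polys, truth_patches, control_poly, name,
                  full_map: bool):
    pix = np.array([px for p in val_polys for px in p.pixels])
    y_true = np.array([1 if p.klass == "target" else 0
                       for p in val_polys for _ in p.pixels])
    y_pred = (cmap.labels[pix[:, 0], pix[:, 1]] == classify.LABEL_TARGET)
    counts = evaluate.confusion_from_labels(y_true.astype(bool), y_pred)
    strata_tp, bg_fp = evaluate.stratum_tp_fraction(cmap, val_polys)
    areas = evaluate.confusion_percentages(
        evaluate.zonal_confusion(cmap, truth_patches, control_poly))
    return evaluate.EvaluationReport(
        scenario=name, kappa=evaluate.kappa(counts), f1=evaluate.f1(counts),
        stratum_tp_pct=strata_tp, background_fp_pct=bg_fp,
        confusion_areas=areas,
        map_area_pct=evaluate.map_area_percent(cmap) if full_map else None)


def run_experiment(config: ExperimentConfig, outdir=None,
                   predict_scope: str = "full") -> ExperimentResult:
    """Execute the full 9-run experiment from one config.

    ``predict_scope='evaluation'`` restricts map prediction to the pixels
    the three criteria actually score (validation plots and the control
    area), which leaves every reported number except the whole-map area
    percentage unchanged — prediction is pixel-independent.
    """
    if predict_scope not in ("full", "evaluation"):
        raise ValueError("predict_scope must be 'full' or 'evaluation'")
    t0 = time.time()
    seeds = config.sub_seeds()

    wl = make_wavelength_grid(config.n_bands)
    library = make_spectral_library(wl, config.n_background_endmembers,
                                    seed=seeds["library"],
                                    separability=config.separability)
    scene = simulate_cover_field(config.rows, config.cols,
                                 config.correlation_length_m,
                                 config.prevalence, gsd=config.gsd,
                                 n_background=config.n_background_endmembers,
                                 seed=seeds["scene"])
    cube = render_cube(scene, library, noise_sd=config.noise_sd,
                       seed=seeds["noise"])
    cube = mnf.savitzky_golay_smooth(cube, config.sg_window,
                                     config.sg_polyorder)
    mnf_result = mnf.mnf_transform(cube)
    features = mnf.select_components(mnf_result, k=config.mnf_k)

    truth_patches = extract_truth_patches(scene)
    control_poly = choose_control_area(scene, config.control_area_size_m)

    design = sampling.place_reference_polygons(
        scene, n_target=config.n_target, strata_counts=config.strata_counts,
        n_background=config.n_background, radius=config.radius_m,
        min_spacing_m=config.min_spacing_m, seed=seeds["sampling"])

    fixed_val = sampling.build_fixed_validation(design, seed=seeds["validation"])

    # pixels needed when prediction is restricted to the scored subset
    def scored_pixels(extra_polys):
        from shapely import contains_xy

        rr, cc = np.nonzero(~features.nodata_mask)
        x, y = features.transform.pixel_center(rr, cc)
        in_ctrl = contains_xy(control_poly, x, y)
        pix = {(int(r), int(c)) for r, c in zip(rr[in_ctrl], cc[in_ctrl])}
        for p in extra_polys:
            pix.update(p.pixels)
        return np.array(sorted(pix))

    reports: dict[str, evaluate.EvaluationReport] = {}
    full = predict_scope == "full"

    def classify_and_score(train_polys, val_polys, name, rf_seed):
        classify.assert_no_leakage(train_polys, val_polys)
        train_ds = classify.assemble_pixel_dataset(features, train_polys,
                                                   "train")
        model = classify.train_rf(train_ds, seed=rf_seed)
        pixels = None if full else scored_pixels(val_polys)
        cmap = classify.predict_map(model, features, pixels=pixels)
        reports[name] = _evaluate_run(cmap, val_polys, truth_patches,
                                      control_poly, name, full_map=full)
        return cmap

    # Stage 0 — naive 50/50 polygon split
    tr0, va0 = sampling.split_stage0(design, seed=seeds["stage0_split"])
    classify_and_score(tr0, va0, "STAGE0", seeds["rf"])

    # Stage 1 — cover-range scenarios against the fixed validation set
    for name, rng_ in scenarios.STAGE1_RANGES.items():
        spec = scenarios.ScenarioSpec(stage=1, name=name, cover_range=rng_,
                                      seed=seeds["scenario"])
        train = scenarios.build_stage1_training(design, fixed_val, spec)
        classify_and_score(train, fixed_val, name, seeds["rf"])

    stage1_reports = [reports[n] for n in scenarios.STAGE1_RANGES]
    stage1_winner, stage1_by_crit = evaluate.select_best_scenario(stage1_reports)

    # Stage 2 — sample-size scenarios for the winning cover range
    best_spec = scenarios.ScenarioSpec(
        stage=1, name=stage1_winner,
        cover_range=scenarios.STAGE1_RANGES[stage1_winner],
        seed=seeds["scenario"])
    for n in scenarios.STAGE2_SIZES:
        train = scenarios.build_stage2_training(design, fixed_val, best_spec,
                                                n_target=n)
        classify_and_score(train, fixed_val, f"{stage1_winner}_{n}",
                           seeds["rf"])

    stage2_reports = [reports[f"{stage1_winner}_{n}"]
                      for n in scenarios.STAGE2_SIZES]
    stage2_winner, stage2_by_crit = evaluate.select_best_scenario(stage2_reports)

    manifest = {
        "config_hash": config.config_hash(),
        "seeds": seeds,
        "n_runs": len(reports),
        "stage1_winner": stage1_winner,
        "stage2_winner": stage2_winner,
        "runtime_s": round(time.time() - t0, 2),
    }
    result = ExperimentResult(config=config, scene=scene, design=design,
                              reports=reports, stage1_winner=stage1_winner,
                              stage1_winners_by_criterion=stage1_by_crit,
                              stage2_winner=stage2_winner,
                              stage2_winners_by_criterion=stage2_by_crit,
                              manifest=manifest)
    if outdir is not None:
        _write_outputs(result, features, mnf_result, truth_patches,
                       control_poly, Path(outdir))
    return result


def _write_outputs(result, features: HyperCube, mnf_result, truth_patches,
                   control_poly, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    write_raster(outdir / "mnf_components.tif", features.data.astype("float32"),
                 features.transform, wavelengths=features.wavelengths)
    write_raster(outdir / "cover.tif", result.scene.cover.astype("float32"),
                 result.scene.transform)
    mnf.eigenvalues_to_csv(mnf_result, outdir / "mnf_eigenvalues.csv")
    write_geojson(outdir / "truth_patches.geojson", polygons_to_geojson(
        truth_patches,
        [{"area_m2": p.area} for p in truth_patches]))
    write_geojson(outdir / "control_area.geojson",
                  polygons_to_geojson([control_poly]))
    write_geojson(outdir / "reference_polygons.geojson",
                  result.design.to_geojson())
    result.design.to_dataframe().to_csv(outdir / "reference_polygons.csv",
                                        index=False)
    df = evaluate.reports_to_dataframe(list(result.reports.values()))
    df.to_csv(outdir / "scenario_reports.csv", index=False)
    winners = {
        "stage1": {"overall": result.stage1_winner,
                   **result.stage1_winners_by_criterion},
        "stage2": {"overall": result.stage2_winner,
                   **result.stage2_winners_by_criterion},
    }
    (outdir / "winners.json").write_text(json.dumps(winners, indent=1))
    (outdir / "manifest.json").write_text(json.dumps(
        {**result.manifest, "config": asdict(cfg)}, indent=1, default=list))


# --------------------------------------------------------------------------
# seeded end-to-end property replicates
# --------------------------------------------------------------------------

@dataclass
class ReplicateOutcome:
    """Per-seed records of the three qualitative sampling-design effects."""

    sc0_fp_pct: list[float]
    sc4_fp_pct: list[float]
    sc4_best_stratum: list[str]
    stage2_tp: list[dict[int, int]]

    @property
    def n(self) -> int:
        return len(self.sc0_fp_pct)

    def overestimation_holds(self) -> int:
        """Seeds where SC0 training overestimates relative to SC4 (zonal FP%)."""
        return sum(a > b for a, b in zip(self.sc0_fp_pct, self.sc4_fp_pct))

    def high_stratum_holds(self) -> int:
        """Seeds where SC4's best stratum TP fraction is the 80-100 class."""
        return sum(s == "80-100" for s in self.sc4_best_stratum)

    def sample_size_holds(self) -> int:
        """Seeds where 20 training plots underestimate vs both 30 and 40."""
        return sum(d[20] < d[30] and d[20] < d[40] for d in self.stage2_tp)


def run_property_replicates(base_seed: int = 0, n_replicates: int = 10,
                            config_factory=None) -> ReplicateOutcome:
    """Re-run the full experiment across seeds and record the design effects.

    Uses evaluation-scope prediction: the scored quantities are identical to
    a full-map run.
    """
    if config_factory is None:
        config_factory = lambda s: ExperimentConfig(seed=s)
    out = ReplicateOutcome([], [], [], [])
    for i in range(n_replicates):
        res = run_experiment(config_factory(base_seed + i),
                             predict_scope="evaluation")
        out.sc0_fp_pct.append(res.reports["SC0"].confusion_areas.fp_pct_1dp)
        out.sc4_fp_pct.append(res.reports["SC4"].confusion_areas.fp_pct_1dp)
        strata = res.reports["SC4"].stratum_tp_pct
        out.sc4_best_stratum.append(max(strata, key=strata.get))
        out.stage2_tp.append(
            {n: res.reports[f"{res.stage1_winner}_{n}"].confusion_areas.tp_pct
             for n in scenarios.STAGE2_SIZES})
    return out
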