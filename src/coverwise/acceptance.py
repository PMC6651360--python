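"""Built-in self-check suite: worked examples, oracle agreement, replicates.

Three groups of checks, each a pure function of the package itself:

* worked examples — the percentage columns of the bundled airborne-campaign
  control-area table recomputed from its m2 columns, cross-checked against
  the published integers and the 1-decimal in-text values;
* oracle agreement — the MNF rotation against a brute-force generalized
  eigensolver, Savitzky-Golay smoothing against an explicit sliding
  least-squares fit, Kappa/F1 against exhaustive enumeration, and circle
  rasterization against direct offset enumeration;
* seeded end-to-end replicates — the three qualitative sampling-design
  effects (low-cover training overestimates, high-cover training is most
  accurate in the 80-100 % stratum, 20 plots underestimate vs 30/40) across
  replicate experiments.

Failures are report entries, not exceptions, so the suite is idempotent.
"""
from __future__ import annotations

import numpy as np

from . import reference_data
from .evaluate import ConfusionCounts, f1, kappa
from .geo import GeoTransform
from .mnf import mnf_transform, savitzky_golay_smooth
from .pipeline import run_property_replicates
from .sampling import rasterize_circle
from .scene import HyperCube

# published integer percentage columns (tp, fp, tn, fn) per campaign row
PUBLISHED_PCT: dict[str, dict[str, tuple[int, int, int, int]]] = {
    "MC": {"STAGE0": (69, 14, 98, 31), "SC0": (76, 24, 96, 23),
           "SC1": (69, 13, 98, 31), "SC2": (53, 6, 99, 46),
           "SC3": (49, 5, 99, 51), "SC4": (36, 3, 99, 64),
           "SC1_20": (43, 3, 100, 57), "SC1_30": (69, 13, 98, 31),
           "SC1_40": (66, 12, 98, 34)},
    "FU": {"STAGE0": (75, 55, 93, 25), "SC0": (60, 41, 95, 40),
           "SC1": (66, 46, 94, 34), "SC2": (62, 43, 95, 38),
           "SC3": (58, 32, 96, 42), "SC4": (60, 29, 96, 40),
           "SC4_20": (43, 14, 98, 57), "SC4_30": (60, 29, 96, 40),
           "SC4_40": (60, 28, 96, 40)},
    "SG": {"STAGE0": (62, 30, 96, 38), "SC0": (37, 91, 88, 63),
           "SC1": (13, 36, 95, 87), "SC2": (17, 5, 99, 83),
           "SC3": (35, 6, 99, 65), "SC4": (22, 5, 99, 78),
           "SC3_20": (14, 2, 100, 86), "SC3_30": (35, 6, 99, 65),
           "SC3_40": (42, 6, 99, 58)},
    "PA": {"STAGE0": (74, 11, 95, 26), "SC0": (55, 10, 95, 45),
           "SC1": (47, 5, 97, 53), "SC2": (33, 2, 99, 67),
           "SC3": (26, 1, 99, 74), "SC4": (32, 1, 99, 68),
           "SC1_20": (12, 1, 99, 88), "SC1_30": (47, 5, 97, 53),
           "SC1_40": (50, 5, 97, 50)},
}

# 1-decimal values quoted in the campaign's running text
PUBLISHED_PCT_1DP: dict[tuple[str, str, str], float] = {
    ("PA", "STAGE0", "fp"): 10.7,
    ("FU", "STAGE0", "fp"): 54.7,
    ("MC", "SC0", "fp"): 24.3,
    ("SG", "SC0", "fp"): 90.9,
}


def check_worked_examples() -> dict:
    """Recompute every campaign percentage column from the printed areas."""
    mismatches = []
    for species, rows in PUBLISHED_PCT.items():
        for scenario, expected in rows.items():
            areas = reference_data.campaign_confusion_areas(species, scenario)
            got = (areas.tp_pct, areas.fp_pct, areas.tn_pct, areas.fn_pct)
            if got != expected:
                mismatches.append((species, scenario, got, expected))
    onedp = []
    for (species, scenario, which), expected in PUBLISHED_PCT_1DP.items():
        areas = reference_data.campaign_confusion_areas(species, scenario)
        got = getattr(areas, f"{which}_pct_1dp")
        if abs(got - expected) > 1e-9:
            onedp.append((species, scenario, which, got, expected))
    sg_sc4 = reference_data.campaign_confusion_areas("SG", "SC4").tp_pct
    return {
        "pass": not mismatches and not onedp and sg_sc4 == 22,
        "n_rows": sum(len(v) for v in PUBLISHED_PCT.values()),
        "integer_mismatches": mismatches,
        "onedecimal_mismatches": onedp,
        "sg_sc4_tp_pct": sg_sc4,
    }


def check_oracles(seed: int = 0) -> dict:
    """Independent small-scale oracles for the numerical operators."""
    rng = np.random.default_rng(seed)
    out = {}

    # MNF vs brute-force generalized eigensolver (5 bands, 100 pixels)
    X = rng.normal(size=(100, 5)) @ rng.normal(size=(5, 5))
    N = rng.normal(size=(5, 5))
    N = N @ N.T + 0.5 * np.eye(5)
    cube = HyperCube(data=X.T.reshape(5, 10, 10),
                     wavelengths=np.arange(5, dtype=float) + 1)
    res = mnf_transform(cube, noise_cov=N)
    Xc = X - X.mean(axis=0)
    T = Xc.T @ Xc / (X.shape[0] - 1)
    brute = np.sort(np.real(np.linalg.eigvals(np.linalg.inv(N) @ T)))[::-1]
    out["mnf_eigenvalues_max_abs_diff"] = float(
        np.max(np.abs(res.eigenvalues - brute)))
    out["mnf_whitening_max_dev"] = float(np.max(np.abs(
        res.forward_transform.T @ N @ res.forward_transform - np.eye(5))))

    # Savitzky-Golay vs explicit sliding least-squares fit (interior bands)
    spec = rng.uniform(0.0, 1.0, size=41)
    cube1 = HyperCube(data=spec.reshape(41, 1, 1),
                      wavelengths=np.arange(41, dtype=float) + 1)
    smoothed = savitzky_golay_smooth(cube1, window=13, polyorder=2)
    w = 13
    max_diff = 0.0
    for i in range(w // 2, 41 - w // 2):
        idx = np.arange(i - w // 2, i + w // 2 + 1)
        coeff = np.polyfit(idx - i, spec[idx], 2)
        max_diff = max(max_diff, abs(coeff[-1] - smoothed.data[i, 0, 0]))
    out["savgol_max_abs_diff"] = float(max_diff)

    # Kappa/F1 hand cases
    out["kappa_hand_case"] = kappa(ConfusionCounts(tp=40, fn=10, fp=20, tn=30))
    out["f1_hand_case"] = f1(ConfusionCounts(tp=40, fp=20, fn=10, tn=0))

    # circle rasterization vs offset enumeration (2 m radius, 1 m grid)
    gt = GeoTransform()
    pix = rasterize_circle(gt.pixel_center(10, 10), 2.0, gt, (21, 21))
    enum = sum(1 for dr in range(-2, 3) for dc in range(-2, 3)
               if dr * dr + dc * dc <= 4)
    out["circle_pixels"] = len(pix)
    out["circle_enumeration"] = enum

    out["pass"] = (out["mnf_eigenvalues_max_abs_diff"] < 1e-8
                   and out["mnf_whitening_max_dev"] < 1e-6
                   and out["savgol_max_abs_diff"] < 1e-10
                   and abs(out["kappa_hand_case"] - 0.4) < 1e-12
                   and abs(out["f1_hand_case"] - 80 / 110) < 1e-12
                   and out["circle_pixels"] == enum == 13)
    return out


def check_design_counts(seed: int = 0) -> dict:
    """Reference-design arithmetic: plot counts, strata, nominal pixels, runs."""
    from .sampling import NOMINAL_PIXELS_PER_POLYGON
    from .scenarios import enumerate_experiment

    specs = enumerate_experiment(seed=seed)
    return {
        "pass": (len(specs) == 9
                 and len({s.name for s in specs}) == 9
                 and 110 * NOMINAL_PIXELS_PER_POLYGON == 1650),
        "n_runs": len(specs),
        "nominal_target_pixels": 110 * NOMINAL_PIXELS_PER_POLYGON,
    }


def check_winner_logic() -> dict:
    """Majority-vote winner selection replayed on the published patterns."""
    from .evaluate import majority_winner

    got = {sp: majority_winner(pat)
           for sp, pat in reference_data.STAGE2_WINNER_PATTERNS.items()}
    return {"pass": got == reference_data.STAGE2_OVERALL_WINNERS,
            "winners": got}


def check_replicates(seed: int = 0, n_replicates: int = 10,
                     min_hold: int = 8) -> dict:
    """Seeded end-to-end property replication at desk scale."""
    out = run_property_replicates(base_seed=seed, n_replicates=n_replicates)
    res = {
        "n_replicates": out.n,
        "overestimation_sc0_gt_sc4": out.overestimation_holds(),
        "sc4_best_in_80_100": out.high_stratum_holds(),
        "n20_underestimates": out.sample_size_holds(),
    }
    res["pass"] = all(res[k] >= min_hold for k in
                      ("overestimation_sc0_gt_sc4", "sc4_best_in_80_100",
                       "n20_underestimates"))
    return res


def run_acceptance_suite(seed: int = 0, n_replicates: int = 10,
                         include_replicates: bool = True) -> dict:
    """All checks as one machine-readable pass/fail report."""
    report = {
        "worked_examples": check_worked_examples(),
        "oracles": check_oracles(seed=seed),
        "design_counts": check_design_counts(seed=seed),
        "winner_logic": check_winner_logic(),
    }
    if include_replicates:
        report["replicates"] = check_replicates(seed=seed,
                                                n_replicates=n_replicates)
    report["pass"] = all(v["pass"] for v in report.values()
                         if isinstance(v, dict))
    return report
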