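"""Bundled control-area results from an airborne mapping campaign.

Zonal confusion areas (m2) reported for four herbaceous target species —
FU (*Filipendula ulmaria*), MC (*Molinia caerulea*), PA (*Phragmites
australis*), SG (*Solidago gigantea*) — mapped from 1 m HySpex imagery and
assessed against field-mapped patches inside a 10 ha control square.  Each
entry gives the species/background zone areas of the control square and the
TP/FP/TN/FN pixel areas for every stage and training scenario.  These areas
are the inputs of the worked examples: the package's percentage convention
recomputes the published percentage columns from them.
"""
from __future__ import annotations

from .evaluate import ConfusionAreas, confusion_percentages

# species -> (control species m2, control background m2)
CONTROL_AREAS: dict[str, tuple[float, float]] = {
    "MC": (14189, 85667),
    "FU": (10797, 89203),
    "SG": (11477, 88523),
    "PA": (33106, 66894),
}

# species -> scenario -> (tp, fp, tn, fn) areas in m2
CAMPAIGN_CONFUSION_M2: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "MC": {
        "STAGE0": (9784, 1946, 83739, 4387),
        "SC0": (10840, 3449, 82236, 3331),
        "SC1": (9812, 1774, 83911, 4359),
        "SC2": (7578, 878, 84807, 6593),
        "SC3": (6953, 694, 84991, 7218),
        "SC4": (5102, 460, 85225, 9069),
        "SC1_20": (6123, 402, 85283, 8048),
        "SC1_30": (9812, 1774, 83911, 4359),
        "SC1_40": (9343, 1737, 83948, 4828),
    },
    "FU": {
        "STAGE0": (8134, 5910, 83149, 2663),
        "SC0": (6486, 4406, 84653, 4311),
        "SC1": (7102, 5006, 84053, 3695),
        "SC2": (6679, 4590, 84469, 4118),
        "SC3": (6287, 3454, 85605, 4510),
        "SC4": (6457, 3126, 85933, 4340),
        "SC4_20": (4684, 1482, 87577, 6113),
        "SC4_30": (6457, 3126, 85933, 4340),
        "SC4_40": (6453, 3057, 86002, 4344),
    },
    "SG": {
        "STAGE0": (7076, 3398, 84981, 4401),
        "SC0": (4208, 10431, 77948, 7269),
        "SC1": (1488, 4128, 84251, 9989),
        "SC2": (1916, 581, 87798, 9561),
        "SC3": (4061, 665, 87714, 7416),
        "SC4": (2575, 568, 87811, 8902),
        "SC3_20": (1636, 211, 88168, 9841),
        "SC3_30": (4061, 665, 87714, 7416),
        "SC3_40": (4770, 638, 87741, 6707),
    },
    "PA": {
        "STAGE0": (24417, 3534, 63216, 8689),
        "SC0": (18279, 3409, 63341, 14827),
        "SC1": (15426, 1700, 65050, 17680),
        "SC2": (10979, 657, 66093, 22127),
        "SC3": (8604, 356, 66394, 24502),
        "SC4": (10450, 473, 66277, 22656),
        "SC1_20": (3904, 315, 66435, 29202),
        "SC1_30": (15426, 1700, 65050, 17680),
        "SC1_40": (16393, 1532, 65218, 16713),
    },
}

# species -> per-criterion winner patterns reported for the Stage-2 comparison
# (accuracy measures, stratum-wise correct pixels, field-map compatibility)
STAGE2_WINNER_PATTERNS: dict[str, dict[str, str]] = {
    "MC": {"accuracy": "SC1_30", "stratum": "SC1_40", "field": "SC1_30"},
    "FU": {"accuracy": "SC4_40", "stratum": "SC4_40", "field": "SC4_40"},
    "SG": {"accuracy": "SC3_40", "stratum": "SC3_40", "field": "SC3_40"},
    "PA": {"accuracy": "SC1_30", "stratum": "SC1_40", "field": "SC1_40"},
}

STAGE2_OVERALL_WINNERS: dict[str, str] = {
    "MC": "SC1_30", "FU": "SC4_40", "SG": "SC3_40", "PA": "SC1_40",
}


def campaign_confusion_areas(species: str, scenario: str) -> ConfusionAreas:
    """ConfusionAreas for one campaign row, percentage columns recomputed."""
    sp, bg = CONTROL_AREAS[species]
    tp, fp, tn, fn = CAMPAIGN_CONFUSION_M2[species][scenario]
    areas = ConfusionAreas(control_species_area=sp, control_background_area=bg,
                           tp_area=tp, fp_area=fp, tn_area=tn, fn_area=fn)
    return confusion_percentages(areas)
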