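"""Published reference values from the mouse whole-body irradiation skin
time-course study this pipeline models.

These are the printed summary numbers of that study — per-dose/per-timepoint
SDTG union, common-to-all and TP-unique counts, the top time-point-unique
genes above the 3.5-fold reporting threshold, and the five-gene marker panel
fold-change grid — kept here so worked examples and consistency checks can
run from the printed inputs without the raw array deposition.  Percentages
in the published tables were rounded inconsistently (some cells half-up,
some truncated), so checks against them should allow one unit in the last
printed digit.
"""

from __future__ import annotations

import pandas as pd

TIMEPOINTS = ("2h", "d4", "d7", "d21", "d28")
SUBLETHAL_DOSES = (1.0, 3.0, 6.0)
LETHAL_DOSE = 20.0

# ---- global analysis: one partition across all (dose, TP) cells -----------
# union of all SDTGs in the study, common-to-everything count, and per-cell
# unique counts with the printed percentages
GLOBAL_UNION = 1665
GLOBAL_COMMON = 0
GLOBAL_UNIQUE = {
    (1.0, "2h"): (37, 2.22),
    (1.0, "d4"): (16, 0.96),
    (1.0, "d7"): (19, 1.14),
    (1.0, "d21"): (8, 0.48),
    (1.0, "d28"): (5, 0.3),
    (3.0, "2h"): (4, 0.24),
    (3.0, "d4"): (6, 0.36),
    (3.0, "d7"): (2, 0.12),
    (3.0, "d21"): (28, 1.68),
    (3.0, "d28"): (32, 1.92),
    (6.0, "2h"): (4, 0.24),
    (6.0, "d4"): (43, 2.58),
    (6.0, "d7"): (55, 3.3),
    (6.0, "d21"): (35, 2.1),
    (6.0, "d28"): (18, 1.08),
    (20.0, "2h"): (34, 2.04),
    (20.0, "d4"): (50, 3.0),
    (20.0, "d7"): (58, 3.48),
}

# ---- per-dose partitions across time points -------------------------------
# dose -> (union, common-to-all-TPs, {tp: (unique count, printed percent)})
PER_DOSE_PARTITION = {
    1.0: (
        619,
        1,
        {
            "2h": (125, 20.2),
            "d4": (101, 16.3),
            "d7": (26, 4.2),
            "d21": (51, 8.2),
            "d28": (62, 10.0),
        },
    ),
    3.0: (
        411,
        0,
        {
            "2h": (61, 14.8),
            "d4": (35, 8.5),
            "d7": (20, 4.9),
            "d21": (99, 24.1),
            "d28": (82, 20.0),
        },
    ),
    6.0: (
        765,
        4,
        {
            "2h": (47, 6.1),
            "d4": (84, 11.0),
            "d7": (173, 22.6),
            "d21": (52, 6.8),
            "d28": (88, 11.5),
        },
    ),
    20.0: (
        1038,
        609,
        {"2h": (57, 5.5), "d4": (80, 7.7), "d7": (89, 8.6)},
    ),
}
PER_DOSE_COMMON_PERCENT = {1.0: 0.16, 3.0: 0.0, 6.0: 0.52, 20.0: 58.6}

# ---- per-timepoint partitions across doses --------------------------------
# tp -> (union, common-to-all-doses, {dose: (unique count, printed percent)})
PER_TP_PARTITION = {
    "2h": (
        1096,
        17,
        {1.0: (83, 7.57), 3.0: (14, 1.27), 6.0: (36, 3.28), 20.0: (702, 64.05)},
    ),
    "d4": (
        1079,
        24,
        {1.0: (78, 7.22), 3.0: (15, 1.39), 6.0: (107, 9.91), 20.0: (620, 57.46)},
    ),
    "d7": (
        1121,
        16,
        {1.0: (34, 3.03), 3.0: (7, 0.62), 6.0: (179, 15.96), 20.0: (666, 59.41)},
    ),
    "d21": (
        314,
        5,
        {1.0: (47, 14.96), 3.0: (76, 24.20), 6.0: (118, 37.57)},
    ),
    "d28": (
        322,
        19,
        {1.0: (21, 6.52), 3.0: (66, 20.49), 6.0: (112, 34.78)},
    ),
}
PER_TP_COMMON_PERCENT = {"2h": 1.55, "d4": 2.22, "d7": 1.42}

# first-post-exposure-week comparison of lethal vs sublethal responses
FIRST_WEEK_UNION = 1499
FIRST_WEEK_COMMON = 5
LETHAL_COMMON_ALL_TPS = 609
LETHAL_UNIQUE_GENES = 390
SUBLETHAL_COMMON_ALL = 10
SUBLETHAL_UNIQUE_GENES = ("CSTA", "Cyp2b13/Cyp2b9", "Hrnr")

# ---- top time-point-unique genes at the |FC| > 3.5 reporting threshold ----
# (dose, timepoint) -> {gene symbol: signed linear fold change}
TOP_UNIQUE_FC = {
    (1.0, "2h"): {"TRIM63": 4.607, "MYLK4": 4.488, "MSTN": 3.841, "KRT31": -3.736},
    (1.0, "d4"): {"Stfa2/Stfa2l1": 5.821, "S100A9": 3.711},
    (1.0, "d7"): {
        "D030036P13Rik": 5.008,
        "4930556J24Rik": 4.293,
        "MKNK1": 4.078,
        "NET1": 4.051,
        "LIN7A": 3.728,
    },
    (1.0, "d21"): {"PRR9": 4.542},
    (1.0, "d28"): {"Kap": 4.359, "PPP1R3C": -3.856, "KRT71": -6.13},
    (3.0, "2h"): {"Defb8": 4.342},
    (3.0, "d7"): {"PON1": 3.654},
    (3.0, "d21"): {
        "NR4A1": 4.566,
        "FOSB": 3.909,
        "FOS": 3.734,
        "CCL4": 3.557,
        "MLANA": -3.711,
        "LGR5": -3.862,
    },
    (3.0, "d28"): {"GJB2": 5.18, "PPP1R3C": -3.942},
    (6.0, "d4"): {"PLAC8": 5.227, "CCL2": 4.079, "FCGR1A": 3.649},
    (6.0, "d7"): {
        "Stfa2/Stfa2l1": 11.053,
        "KLHL36": 5.555,
        "CKMT2": 4.435,
        "KLK6": 4.3,
        "KRT6B": 3.847,
        "Krtap16-3": -3.576,
        "1110025L11Rik": -3.597,
        "KRT34": -3.734,
        "FBP1": -3.755,
        "Krtap8-1": -3.864,
        "Krtap22-2": -3.938,
        "Gm10229": -4.033,
        "PRR9": -4.416,
        "Krtap19-1": -5.359,
        "KRT27": -5.532,
        "KRT25": -8.664,
    },
    (6.0, "d21"): {
        "CHRNA1": 5.57,
        "FOS": 5.228,
        "CHRNG": 4.627,
        "HSPB7": 4.321,
        "ANKRD1": 4.161,
        "MYH3": 3.54,
    },
    (6.0, "d28"): {"Fam25c": -3.683, "Krt10": -3.758, "PPP1R3C": -3.964},
    (20.0, "2h"): {"KRT28": -3.725},
    (20.0, "d4"): {"ENO3": -3.848, "PPP1R3C": -4.105},
}

# ---- five-gene marker panel: signed FC per (dose, timepoint) cell ---------
# up in every sublethal cell, down in every lethal cell, first three TPs
_PANEL_COLUMNS = [
    (d, tp) for d in (1.0, 3.0, 6.0, 20.0) for tp in ("2h", "d4", "d7")
]
_PANEL_ROWS = {
    "AADAC": [2.41, 3.89, 2.86, 2.86, 2.49, 2.31, 2.89, 2.43, 6.31, -7.09, -7.44, -8.54],
    "ELOVL4": [2.09, 3.48, 2.73, 2.10, 2.57, 2.32, 2.32, 3.05, 5.50, -7.36, -5.93, -6.79],
    "SEC14L4": [2.58, 3.46, 3.11, 2.38, 2.18, 2.17, 2.72, 2.88, 6.51, -6.28, -6.46, -6.50],
    "SLURP1": [2.29, 3.33, 3.01, 2.07, 3.10, 2.31, 2.21, 2.95, 4.33, -3.08, -2.52, -3.29],
    "TMPRSS4": [3.01, 4.94, 2.39, 3.30, 3.07, 3.11, 2.08, 2.05, 3.35, -2.67, -2.69, -2.77],
}
MARKER_PANEL_GENES = tuple(_PANEL_ROWS)


def marker_panel_fc_grid() -> pd.DataFrame:
    """The published five-gene marker-panel FC grid (genes x 12 cells)."""
    frame = pd.DataFrame.from_dict(_PANEL_ROWS, orient="index")
    frame.columns = pd.MultiIndex.from_tuples(_PANEL_COLUMNS, names=["dose_gy", "timepoint"])
    frame.index.name = "gene"
    return frame


def reconstruct_partition_sets(union: int, common: int, unique: dict, labels):
    """Synthetic gene sets realizing printed union/common/unique counts.

    Distinct genes beyond the common and unique blocks are placed in the
    all-but-last-label overlap block so the totals conserve the printed
    union.  Returns {label: set of synthetic gene ids}.
    """
    sets: dict = {lab: set() for lab in labels}
    gid = 0
    for lab in labels:
        for _ in range(unique[lab]):
            sets[lab].add(gid)
            gid += 1
    for _ in range(common):
        for lab in labels:
            sets[lab].add(gid)
        gid += 1
    remaining = union - gid
    if remaining < 0:
        raise ValueError("printed counts exceed the printed union")
    if remaining and len(labels) < 3:
        raise ValueError("cannot realize leftover genes without an overlap block")
    for _ in range(remaining):
        for lab in list(labels)[:-1]:
            sets[lab].add(gid)
        gid += 1
    return sets
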