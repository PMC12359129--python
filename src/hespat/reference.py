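"""Published reference results of the EU-27 health-security assessment.

These are the 3-decimal values reported by the published entropy-CoCoSo
evaluation of the 27 EU member states on the six GHSI pillars, for the
2019 and 2021 GHSI editions and the aggregated 2017-2021 series:
composite indices (Ci), ranks (Ri), performance tiers (Si, 1 = High,
3 = Dangerous), regional indicator weights, and the worked-example rows
of the intermediate pipeline stages.  They serve as regression anchors
for the pipeline and as the worked example shipped with the package —
they are *outputs* of the method, not inputs to it, except where a
check deliberately re-runs one stage on them (e.g. tier clustering of
the published Ci column).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "INDICATORS",
    "EU_COUNTRIES",
    "PERIODS",
    "eu_cocoso_table",
    "regional_weights",
    "regional_weight_shifts",
    "eu2019_entropy_sums",
    "eu2019_entropy_values",
    "eu2019_worked_rows",
    "cluster_memberships",
    "agreement_cocoso_row",
]

INDICATORS = (
    "Prevention",
    "Detection and reporting",
    "Rapid response",
    "Health system",
    "Compliance with norms",
    "Risk environment",
)

PERIODS = ("2019", "2021", "2017-2021")

# country: (Ci, Ri, Si) for 2019, 2021, 2017-2021, then (rank shift, tier shift)
_EU_TABLE = {
    "Austria":        ((6.123, 17, 2), (3.910, 15, 2), (4.969, 15, 2), (2, 0)),
    "Belgium":        ((7.979, 10, 1), (4.637, 12, 1), (6.210, 10, 1), (-2, 0)),
    "Bulgaria":       ((8.280, 8, 1), (4.886, 10, 1), (6.502, 9, 1), (-2, 0)),
    "Croatia":        ((4.894, 23, 2), (3.002, 23, 2), (3.881, 23, 2), (0, 0)),
    "Cyprus":         ((2.280, 26, 3), (1.864, 26, 3), (1.933, 26, 3), (0, 0)),
    "Czech Republic": ((5.963, 18, 2), (3.419, 22, 2), (4.711, 19, 2), (-4, 0)),
    "Denmark":        ((9.581, 3, 1), (5.489, 5, 1), (7.426, 3, 1), (-2, 0)),
    "Estonia":        ((6.157, 16, 2), (3.890, 16, 2), (4.932, 16, 2), (0, 0)),
    "Finland":        ((10.442, 1, 1), (6.275, 1, 1), (8.262, 1, 1), (0, 0)),
    "France":         ((7.745, 11, 1), (4.740, 11, 1), (6.189, 11, 1), (0, 0)),
    "Germany":        ((9.250, 5, 1), (5.571, 3, 1), (7.319, 4, 1), (2, 0)),
    "Greece":         ((5.617, 21, 2), (3.473, 21, 2), (4.483, 21, 2), (0, 0)),
    "Hungary":        ((6.169, 15, 2), (3.776, 18, 2), (4.887, 17, 2), (-3, 0)),
    "Ireland":        ((6.299, 14, 2), (4.037, 13, 2), (5.129, 14, 2), (1, 0)),
    "Italy":          ((5.841, 19, 2), (3.622, 20, 2), (4.644, 20, 2), (-1, 0)),
    "Latvia":         ((8.598, 7, 1), (5.502, 4, 1), (7.042, 6, 1), (3, 0)),
    "Lithuania":      ((6.912, 13, 2), (4.944, 9, 1), (5.969, 12, 1), (4, 1)),
    "Luxembourg":     ((3.935, 24, 3), (2.523, 25, 3), (3.148, 24, 3), (-1, 0)),
    "Malta":          ((1.025, 27, 3), (1.109, 27, 3), (1.085, 27, 3), (0, 0)),
    "Netherlands":    ((9.516, 4, 1), (5.360, 6, 1), (7.289, 5, 1), (-2, 0)),
    "Poland":         ((5.633, 20, 2), (3.951, 14, 2), (4.795, 18, 2), (6, 0)),
    "Portugal":       ((6.984, 12, 2), (3.801, 17, 2), (5.231, 13, 2), (-5, 0)),
    "Romania":        ((3.736, 25, 3), (2.587, 24, 3), (3.117, 25, 3), (1, 0)),
    "Slovakia":       ((5.083, 22, 2), (3.767, 19, 2), (4.473, 22, 2), (3, 0)),
    "Slovenia":       ((9.853, 2, 1), (6.140, 2, 1), (7.965, 2, 1), (0, 0)),
    "Spain":          ((8.116, 9, 1), (5.164, 8, 1), (6.603, 8, 1), (1, 0)),
    "Sweden":         ((8.953, 6, 1), (5.236, 7, 1), (6.999, 7, 1), (-1, 0)),
}

EU_COUNTRIES = tuple(_EU_TABLE)


def eu_cocoso_table() -> pd.DataFrame:
    """Published Ci/Ri/Si per period plus 2019→2021 rank/tier shifts.

    Columns: ``Ci_<period>``, ``Ri_<period>``, ``Si_<period>`` for each
    of the three periods, and ``rank_shift`` / ``tier_shift``.
    """
    rows = {}
    for country, (*cases, shifts) in _EU_TABLE.items():
        row = {}
        for period, (ci, ri, si) in zip(PERIODS, cases):
            row[f"Ci_{period}"] = ci
            row[f"Ri_{period}"] = ri
            row[f"Si_{period}"] = si
        row["rank_shift"], row["tier_shift"] = shifts
        rows[country] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "country"
    return frame


# (region, period) -> six published entropy weights
_REGIONAL_WEIGHTS = {
    ("European Union", "2019"): (0.168, 0.372, 0.210, 0.164, 0.044, 0.043),
    ("European Union", "2021"): (0.162, 0.360, 0.207, 0.182, 0.044, 0.045),
    ("European Union", "2017-2021"): (0.168, 0.371, 0.200, 0.176, 0.040, 0.044),
    ("African Region", "2019"): (0.330, 0.326, 0.060, 0.172, 0.057, 0.055),
    ("African Region", "2021"): (0.352, 0.294, 0.072, 0.169, 0.051, 0.063),
    ("African Region", "2017-2021"): (0.325, 0.322, 0.061, 0.175, 0.056, 0.061),
    ("Eastern Mediterranean", "2019"): (0.209, 0.217, 0.098, 0.322, 0.060, 0.095),
    ("Eastern Mediterranean", "2021"): (0.259, 0.221, 0.096, 0.261, 0.063, 0.099),
    ("Eastern Mediterranean", "2017-2021"): (0.228, 0.220, 0.092, 0.298, 0.063, 0.099),
}


def regional_weights() -> pd.DataFrame:
    """Published entropy weights per region and period (long format)."""
    rows = [
        {"region": region, "period": period, "indicator": ind, "weight": w}
        for (region, period), ws in _REGIONAL_WEIGHTS.items()
        for ind, w in zip(INDICATORS, ws)
    ]
    return pd.DataFrame(rows)


# published 2019→2021 weight shifts per region
_WEIGHT_SHIFTS = {
    "European Union": (-0.005, -0.013, -0.003, 0.018, 0.000, 0.003),
    "African Region": (0.023, -0.032, 0.011, -0.004, -0.006, 0.008),
    "Eastern Mediterranean": (0.051, 0.004, -0.003, -0.060, 0.004, 0.004),
}


def regional_weight_shifts() -> pd.DataFrame:
    frame = pd.DataFrame(_WEIGHT_SHIFTS, index=list(INDICATORS)).T
    frame.index.name = "region"
    return frame


# per-indicator Σ_i n_ij ln n_ij of the EU-2019 matrix, as published
def eu2019_entropy_sums() -> np.ndarray:
    return np.array([-3.27368, -3.24666, -3.26812, -3.27420, -3.29006, -3.29021])


# per-indicator entropy Ent_j of the EU-2019 matrix, as published
def eu2019_entropy_values() -> np.ndarray:
    return np.array([0.99328, 0.98508, 0.99159, 0.99344, 0.99825, 0.99829])


def eu2019_worked_rows() -> dict[str, pd.DataFrame]:
    """Published example rows of the EU-2019 pipeline stages.

    Five of the 27 country rows per stage: raw pillar scores, min-max
    normalized scores, the comparability sums CS and P, and the
    appraisal scores with the final Ci and rank.
    """
    countries = ["Austria", "Belgium", "Bulgaria", "Croatia", "Sweden"]
    raw = pd.DataFrame(
        [
            (53.3, 38.8, 47.9, 54.0, 63.9, 86.5),
            (57.5, 52.9, 57.5, 64.3, 60.6, 78.4),
            (66.7, 61.7, 49.0, 58.3, 69.4, 63.5),
            (51.3, 37.8, 37.0, 51.4, 55.0, 66.2),
            (80.6, 64.6, 46.1, 53.6, 69.4, 83.8),
        ],
        index=countries,
        columns=list(INDICATORS),
    )
    normalized = pd.DataFrame(
        [
            (0.45726, 0.35902, 0.32800, 0.67955, 0.45490, 1.00000),
            (0.54076, 0.62406, 0.52000, 0.91364, 0.32549, 0.74286),
            (0.72366, 0.78947, 0.35000, 0.77727, 0.67059, 0.26984),
            (0.41750, 0.34023, 0.11000, 0.62045, 0.10588, 0.35556),
            (1.00000, 0.84398, 0.29200, 0.67045, 0.67059, 0.91429),
        ],
        index=countries,
        columns=list(INDICATORS),
    )
    sums = pd.DataFrame(
        {
            "CS": (0.453, 0.628, 0.657, 0.341, 0.721),
            "P": (5.256, 5.538, 5.553, 4.951, 5.627),
        },
        index=countries,
    )
    appraisal = pd.DataFrame(
        {
            "ka": (0.038, 0.041, 0.041, 0.035, 0.042),
            "kb": (15.125, 20.247, 21.090, 11.798, 22.966),
            "kc": (0.851, 0.919, 0.926, 0.789, 0.946),
            "Ci": (6.123, 7.979, 8.280, 4.894, 8.953),
            "rank": (17, 10, 8, 23, 6),
        },
        index=countries,
    )
    return {
        "raw": raw,
        "normalized": normalized,
        "sums": sums,
        "appraisal": appraisal,
    }


# published k=3 tier memberships per period
_CLUSTERS = {
    "2019": {
        1: (
            "Belgium", "Bulgaria", "Denmark", "Finland", "France", "Germany",
            "Latvia", "Netherlands", "Slovenia", "Spain", "Sweden",
        ),
        2: (
            "Austria", "Croatia", "Czech Republic", "Estonia", "Greece",
            "Hungary", "Ireland", "Italy", "Lithuania", "Poland", "Portugal",
            "Slovakia",
        ),
        3: ("Cyprus", "Luxembourg", "Malta", "Romania"),
    },
    "2021": {
        1: (
            "Belgium", "Bulgaria", "Denmark", "Finland", "France", "Germany",
            "Latvia", "Netherlands", "Slovenia", "Spain", "Sweden",
            "Lithuania",
        ),
        2: (
            "Austria", "Croatia", "Czech Republic", "Estonia", "Greece",
            "Hungary", "Ireland", "Italy", "Poland", "Portugal", "Slovakia",
        ),
        3: ("Cyprus", "Luxembourg", "Malta", "Romania"),
    },
}
_CLUSTERS["2017-2021"] = _CLUSTERS["2021"]


def cluster_memberships(period: str) -> dict[int, tuple[str, ...]]:
    """Published tier memberships (1=High, 2=Intermediate, 3=Dangerous)."""
    return {k: tuple(v) for k, v in _CLUSTERS[period].items()}


def agreement_cocoso_row() -> pd.Series:
    """Published mean Spearman agreement of CoCoSo with each method."""
    return pd.Series(
        {
            "cocoso": 1.0,
            "topsis": 0.963777,
            "edas": 0.9866,
            "waspas": 0.9843305,
            "vikor": 0.96622,
        }
    )
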