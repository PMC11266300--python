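"""Published reference variance tables for canine hind-limb shape models.

Per-mode (column A) and cumulative (column B) percentages of total variance
reported for the canine femur / tibia / patella shape-model groups, by side,
at the original 3-significant-figure precision. These printed values serve
as arithmetic-consistency inputs: recomputing B by accumulating the printed
A values and re-rounding must reproduce the printed B column to within one
unit in the last printed place (the printed A values are themselves rounded,
so exact agreement is not attainable in every cell).
"""

from __future__ import annotations

import numpy as np

from .ssm import round_sig

__all__ = ["REFERENCE_VARIANCE_TABLES", "cumulative_discrepancy", "max_cumulative_discrepancy"]

# group -> side -> {"A": per-mode %, "B": cumulative %}, modes 1..5
REFERENCE_VARIANCE_TABLES = {
    "group1_whole_femur": {
        "left": {"A": [93.5, 5.62, 0.34, 0.17, 0.11], "B": [93.5, 99.1, 99.5, 99.6, 99.7]},
        "right": {"A": [96.4, 3.01, 0.2, 0.14, 0.07], "B": [96.4, 99.4, 99.6, 99.7, 99.8]},
    },
    "group2_0_10kg": {
        "left": {"A": [91.3, 6.06, 1.49, 0.39, 0.25], "B": [91.3, 97.3, 98.8, 99.2, 99.5]},
        "right": {"A": [74.2, 19.6, 3.53, 1.57, 0.5], "B": [74.2, 93.8, 97.3, 98.9, 99.4]},
    },
    "group3_10_25kg": {
        "left": {"A": [91.7, 7.6, 0.22, 0.15, 0.12], "B": [91.7, 99.3, 99.5, 99.6, 99.8]},
        "right": {"A": [92.9, 6.22, 0.29, 0.24, 0.09], "B": [92.9, 99.2, 99.5, 99.7, 99.8]},
    },
    "group4_over_25kg": {
        "left": {"A": [73.5, 23.6, 1.08, 0.82, 0.4], "B": [73.5, 97.1, 98.2, 99.0, 99.4]},
        "right": {"A": [77.1, 19.6, 1.53, 0.65, 0.35], "B": [77.1, 96.8, 98.3, 98.9, 99.3]},
    },
    "group5_chondrodystrophic": {
        "left": {"A": [93.8, 5.04, 0.35, 0.28, 0.13], "B": [93.8, 98.9, 99.2, 99.5, 99.6]},
        "right": {"A": [89.5, 6.72, 2.95, 0.28, 0.2], "B": [89.5, 96.2, 99.2, 99.5, 99.7]},
    },
    "group6_retrievers": {
        "left": {"A": [90.1, 8.54, 0.67, 0.36, 0.11], "B": [90.1, 98.6, 99.3, 99.6, 99.7]},
        "right": {"A": [87.3, 11.2, 0.8, 0.33, 0.14], "B": [87.3, 98.5, 99.3, 99.6, 99.7]},
    },
    "femur_condyles": {
        "left": {"A": [80.4, 7.46, 3.55, 3.05, 0.92], "B": [80.4, 87.9, 91.5, 94.5, 95.4]},
        "right": {"A": [67.3, 25.6, 2.66, 1.65, 0.81], "B": [67.3, 92.9, 95.5, 97.2, 98.0]},
    },
    "femoral_head": {
        "left": {"A": [85.2, 3.21, 2.09, 1.92, 1.46], "B": [85.2, 88.4, 90.5, 92.5, 93.9]},
        "right": {"A": [83.4, 5.12, 2.35, 1.87, 1.43], "B": [83.4, 88.5, 90.8, 92.7, 94.1]},
    },
    "tibia": {
        "left": {"A": [94.7, 4.18, 0.61, 0.15, 0.1], "B": [94.7, 98.9, 99.5, 99.7, 99.8]},
        "right": {"A": [97.6, 1.82, 0.2, 0.09, 0.07], "B": [97.6, 99.4, 99.6, 99.7, 99.8]},
    },
    "tibia_plateau": {
        "left": {"A": [78.9, 9.13, 4.79, 2.03, 1.22], "B": [78.9, 88.0, 92.8, 94.9, 96.1]},
        "right": {"A": [77.6, 11.3, 4.48, 1.72, 1.03], "B": [77.6, 88.8, 93.3, 95.0, 96.1]},
    },
    "patella": {
        "left": {"A": [73.3, 10.8, 5.93, 2.4, 1.39], "B": [73.3, 84.1, 90.0, 92.4, 93.8]},
        "right": {"A": [75.3, 9.07, 5.06, 2.47, 1.82], "B": [75.3, 84.4, 89.5, 91.9, 93.7]},
    },
}


def cumulative_discrepancy(a: np.ndarray, b_printed: np.ndarray, sig: int = 3) -> np.ndarray:
    """|cumsum(printed A), re-rounded to ``sig`` figures - printed B| per mode."""
    b_recomputed = round_sig(np.cumsum(np.asarray(a, dtype=float)), sig)
    return np.abs(b_recomputed - np.asarray(b_printed, dtype=float))


def max_cumulative_discrepancy(tables: dict | None = None) -> float:
    """Largest A-vs-B arithmetic discrepancy over every group, side and mode."""
    tables = REFERENCE_VARIANCE_TABLES if tables is None else tables
    worst = 0.0
    for sides in tables.values():
        for cols in sides.values():
            worst = max(worst, float(cumulative_discrepancy(cols["A"], cols["B"]).max()))
    return worst
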