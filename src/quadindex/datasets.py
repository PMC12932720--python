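"""Built-in benchmark tables for a ten-cycle simulated-maize selection study.

These are published per-cycle summaries of a recurrent-selection experiment
comparing the four indices (QPSI, QGSI, LPSI, LGSI) over ten simulated maize
selection cycles at 10% selected proportion, plus the per-cycle genomic
results of two real maize populations (two genomic cycles each). They serve
as worked-example inputs for the summary/report machinery — column layout,
Average-row arithmetic and headline relative-response computations — and as
regression fixtures; they are *inputs*, never outputs, of this package.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "load_maize_cycle_summaries",
    "load_maize_gain_table",
    "load_maize_real_summaries",
]

# per-cycle (R, SCor, SR-MSPE) for each index, cycles 1..10
_CYCLE_SUMMARIES = {
    "QPSI": [
        (163.4, 0.844, 40.0), (145.2, 0.823, 38.3), (122.9, 0.798, 35.2),
        (130.2, 0.801, 36.9), (121.6, 0.795, 35.2), (100.9, 0.761, 32.2),
        (87.9, 0.750, 28.9), (55.3, 0.903, 10.3), (46.7, 0.888, 9.5),
        (42.6, 0.882, 8.9),
    ],
    "QGSI": [
        (153.5, 0.745, 4.0), (158.0, 0.730, 4.0), (149.9, 0.670, 4.6),
        (171.5, 0.791, 3.6), (182.7, 0.796, 3.6), (157.3, 0.724, 4.3),
        (144.1, 0.695, 4.0), (82.8, 0.997, 1.4), (78.2, 0.998, 1.2),
        (80.7, 0.996, 1.3),
    ],
    "LPSI": [
        (19.1, 0.942, 2.7), (17.1, 0.928, 2.7), (15.7, 0.916, 2.7),
        (15.9, 0.917, 2.7), (15.2, 0.911, 2.7), (13.7, 0.893, 2.7),
        (13.2, 0.890, 2.6), (8.8, 0.942, 1.2), (7.3, 0.916, 1.3),
        (7.3, 0.920, 1.2),
    ],
    "LGSI": [
        (18.4, 0.874, 4.0), (18.0, 0.866, 4.0), (17.8, 0.832, 4.6),
        (19.2, 0.900, 3.6), (19.5, 0.907, 3.6), (17.5, 0.842, 4.3),
        (17.9, 0.866, 4.0), (9.6, 0.998, 1.4), (9.1, 0.996, 1.2),
        (9.5, 0.995, 1.3),
    ],
}

# per-cycle expected genetic gain for four traits, cycles 1..10
_GAIN_TABLE = {
    "LPSI": [
        (10.4, -5.5, 3.8, 2.0), (10.1, -4.4, 3.7, 2.0), (9.9, -4.1, 3.3, 1.7),
        (10.9, -4.3, 2.6, 1.4), (10.6, -3.5, 3.0, 1.5), (10.0, -3.5, 2.5, 1.4),
        (5.0, -2.0, 1.7, 1.4), (5.6, -1.6, 1.2, 1.6), (5.2, -1.5, 0.8, 1.4),
        (4.9, -1.6, 1.3, 1.0),
    ],
    "LGSI": [
        (8.6, -4.7, 3.3, 1.8), (8.8, -3.6, 3.4, 2.2), (8.3, -4.0, 2.9, 2.6),
        (9.7, -4.6, 3.1, 1.8), (9.8, -4.5, 3.3, 1.9), (9.0, -3.2, 3.2, 2.1),
        (7.9, -4.7, 2.9, 2.4), (6.5, -0.8, 0.8, 1.5), (6.5, -0.5, 0.9, 1.2),
        (7.1, -0.5, 1.0, 0.9),
    ],
}

# two real maize populations: per-genomic-cycle selection response R under
# maximum-likelihood (ML) and Gaussian-kernel GEBV estimation
_REAL_MAIZE = {
    "JDMexico": {
        "cycle": [1, 2],
        "QGSI": [35.8, 37.0],
        "LGSI": [3.9, 4.1],
        "G-QGSI": [67.0, 69.0],
        "G-LGSI": [8.4, 8.3],
    },
    "JDZimbabwe": {
        "cycle": [1, 2],
        "QGSI": [34.1, 37.1],
        "LGSI": [6.9, 7.3],
        "G-QGSI": [95.8, 90.8],
        "G-LGSI": [4.6, 4.5],
    },
}


def load_maize_cycle_summaries() -> pd.DataFrame:
    """Per-cycle R/SCor/SR-MSPE rows for QPSI, QGSI, LPSI and LGSI."""
    rows = []
    for kind, vals in _CYCLE_SUMMARIES.items():
        for cycle, (r, scor, mspe) in enumerate(vals, start=1):
            rows.append({"cycle": cycle, "index": kind, "R": r, "SCor": scor, "SR-MSPE": mspe})
    return pd.DataFrame(rows)


def load_maize_gain_table() -> pd.DataFrame:
    """Per-cycle expected genetic gain rows (traits T1..T4) for LPSI and LGSI."""
    rows = []
    for kind, vals in _GAIN_TABLE.items():
        for cycle, gains in enumerate(vals, start=1):
            row = {"cycle": cycle, "index": kind}
            row.update({f"T{i + 1}": g for i, g in enumerate(gains)})
            rows.append(row)
    return pd.DataFrame(rows)


def load_maize_real_summaries() -> pd.DataFrame:
    """Genomic-cycle selection responses for the two real maize populations."""
    rows = []
    for dataset, d in _REAL_MAIZE.items():
        for i, cycle in enumerate(d["cycle"]):
            rows.append(
                {
                    "dataset": dataset,
                    "cycle": cycle,
                    **{k: d[k][i] for k in ("QGSI", "LGSI", "G-QGSI", "G-LGSI")},
                }
            )
    return pd.DataFrame(rows)
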