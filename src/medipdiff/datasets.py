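"""Bundled small reference inputs.

Holds the printed clinical-characteristics table of the 4-vs-4
(h)MeDIP-seq discovery cohort (late-onset severe preeclampsia cases vs
normotensive controls) used to exercise the two-group statistics. Only
raw per-subject values are stored; every statistic is recomputed.
"""

from __future__ import annotations

import pandas as pd

# Columns: case subjects 7/14/15/40, control subjects 9/10/27/28.
_CLINICAL_ROWS = {
    "Maternal age (years)": [29, 26, 33, 23, 28, 25, 26, 26],
    "Gravidity (n)": [4, 1, 1, 1, 3, 2, 1, 1],
    "Parity (n)": [1, 0, 0, 0, 1, 0, 0, 0],
    "Gestation at delivery (weeks)": [38.3, 37.6, 37.7, 39.4, 37.9, 39.0, 38.4, 39.3],
    "Pregnancy BMI (kg/m2)": [30.4, 33.2, 26.0, 25.4, 27.7, 24.4, 29.2, 31.2],
    "Systolic BP (mmHg)": [160, 161, 166, 145, 96, 129, 122, 103],
    "Diastolic BP (mmHg)": [100, 110, 100, 94, 63, 87, 72, 71],
    "Hemoglobin (g/L)": [101, 116, 112, 122, 105, 142, 115, 125],
    "Platelets (x10^9/L)": [282, 166, 203, 149, 118, 181, 197, 172],
    "AST (U/L)": [14, 22, 13, 15, 12, 31, 16, 11],
    "ALT (U/L)": [10, 17, 22, 12, 17, 21, 14, 19],
    "LDH (U/L)": [204, 213, 432, 468, 393, 499, 451, 215],
    "Scr (umol/L)": [53, 38, 52, 56, 34, 47, 45, 47],
    "BUN (mmol/L)": [3.9, 3.2, 3.1, 2.7, 3.1, 4.2, 3.5, 4.0],
    "Proteinuria (g/24h)": [2.91, 0.95, 0.36, 1.44, 0.05, 0.04, 0.05, 0.06],
    "Infant birthweight (g)": [3580, 3510, 3265, 3140, 3490, 4215, 2590, 3270],
    "5-min Apgar score": [9, 9, 9, 9, 10, 9, 9, 9],
    "Umbilical artery S/D rate": [1.64, 2.03, 1.95, 2.13, 2.16, 2.29, 2.38, 2.05],
}

_SUBJECTS = ["case7", "case14", "case15", "case40",
             "ctrl9", "ctrl10", "ctrl27", "ctrl28"]


def clinical_table() -> pd.DataFrame:
    """Per-subject clinical characteristics, one row per characteristic."""
    return pd.DataFrame.from_dict(_CLINICAL_ROWS, orient="index", columns=_SUBJECTS)


def clinical_groups() -> dict[str, str]:
    """Subject -> group labels for :func:`clinical_table`."""
    return {s: ("case" if s.startswith("case") else "control") for s in _SUBJECTS}
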