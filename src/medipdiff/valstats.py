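"""Small-sample validation statistics.

The wet-lab side of a differential methylation study reduces to three
pieces of arithmetic, all implemented here:

* comparative-Ct qPCR enrichment, ``2**(Ct_input - Ct_IP)`` — the
  IP yield of a locus relative to its input;
* per-amplicon summarization of mass-spectrometry (EpiTYPER-style)
  CpG methylation ratios, with inapplicable readings dropped;
* two-group comparisons for 4-vs-4 (and larger) designs: the
  pooled-variance Student t-test and the Mann–Whitney U test, the
  latter both as an exact full-enumeration test (feasible for
  n1+n2 <= 12) and as the tie-corrected normal approximation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import ValidationError

TESTS = ("pooled-t", "welch-t", "mann-whitney-exact", "mann-whitney-asymptotic")


@dataclass(frozen=True)
class GroupComparison:
    statistic: float
    df: float | None
    p_value: float
    test: str


def qpcr_relative_enrichment(ct_input: float, ct_ip: float) -> float:
    """Comparative-Ct fold enrichment: ``2**(ct_input - ct_ip)``."""
    if not (math.isfinite(ct_input) and math.isfinite(ct_ip)):
        raise ValidationError("Ct values must be finite")
    return 2.0 ** (ct_input - ct_ip)


def pooled_t_test(x: Sequence[float], y: Sequence[float]) -> GroupComparison:
    """Two-sided pooled-variance (Student) two-sample t-test.

    Degenerate zero-variance inputs are resolved by the means: equal
    means give p = 1, unequal means p = 0, each with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs at least 2 values")
    df = n1 + n2 - 2
    s2p = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    if s2p == 0:
        if x.mean() == y.mean():
            warnings.warn("zero pooled variance with equal means; p set to 1")
            return GroupComparison(0.0, float(df), 1.0, "pooled-t")
        warnings.warn("zero pooled variance with unequal means; p set to 0")
        t = math.inf if x.mean() > y.mean() else -math.inf
        return GroupComparison(t, float(df), 0.0, "pooled-t")
    t = (x.mean() - y.mean()) / math.sqrt(s2p * (1 / n1 + 1 / n2))
    p = 2.0 * sps.t.sf(abs(t), df)
    return GroupComparison(float(t), float(df), float(p), "pooled-t")


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> GroupComparison:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("each group needs at least 2 values")
    res = sps.ttest_ind(x, y, equal_var=False)
    return GroupComparison(float(res.statistic), float(res.df), float(res.pvalue), "welch-t")


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def mann_whitney(
    x: Sequence[float], y: Sequence[float], mode: str = "exact"
) -> GroupComparison:
    """Two-sided Mann–Whitney U test.

    exact: full enumeration of all C(n1+n2, n1) group assignments with
    midrank ties; p = fraction of assignments whose U deviates from
    n1*n2/2 at least as much as observed. Limited to n1+n2 <= 12.

    asymptotic: normal approximation with tie-corrected variance and no
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValidationError("both groups need at least one value")
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    r1 = ranks[:n1].sum()
    u_obs = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0

    if mode == "exact":
        n = n1 + n2
        if n > 12:
            raise ValidationError(
                "exact enumeration limited to n1+n2 <= 12; use mode='asymptotic'"
            )
        dev_obs = abs(u_obs - mu)
        hits = total = 0
        for idx in combinations(range(n), n1):
            u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
            total += 1
            if abs(u - mu) >= dev_obs - 1e-9:
                hits += 1
        return GroupComparison(float(u_obs), None, hits / total, "mann-whitney-exact")

    if mode != "asymptotic":
        raise ValidationError(f"mode must be 'exact' or 'asymptotic', got {mode!r}")
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return GroupComparison(float(u_obs), None, 1.0, "mann-whitney-asymptotic")
    z = (u_obs - mu) / math.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return GroupComparison(float(z), None, float(p), "mann-whitney-asymptotic")


def clinical_table_compare(
    table: pd.DataFrame,
    groups: Mapping[str, str],
    overrides: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-characteristic case/control comparison of a clinical table.

    ``table`` has one row per characteristic and one column per subject;
    ``groups`` maps column name -> 'case'/'control'. The default test is
    the pooled-variance t; ``overrides`` may name a different test per
    characteristic ('welch-t', 'mann-whitney-exact',
    'mann-whitney-asymptotic'). Rows whose test raises are reported with
    NaN p and the error message in the diagnostic column.
    """
    overrides = dict(overrides or {})
    case_cols = [c for c in table.columns if groups.get(c) == "case"]
    ctrl_cols = [c for c in table.columns if groups.get(c) == "control"]
    if len(case_cols) < 2 or len(ctrl_cols) < 2:
        raise ValidationError("need >= 2 subjects per group")
    runners = {
        "pooled-t": pooled_t_test,
        "welch-t": welch_t_test,
        "mann-whitney-exact": lambda a, b: mann_whitney(a, b, "exact"),
        "mann-whitney-asymptotic": lambda a, b: mann_whitney(a, b, "asymptotic"),
    }
    rows = []
    for characteristic, row in table.iterrows():
        test = overrides.get(characteristic, "pooled-t")
        xs = row[case_cols].astype(float).to_numpy()
        ys = row[ctrl_cols].astype(float).to_numpy()
        rec = {
            "characteristic": characteristic,
            "mean_case": xs.mean(),
            "mean_control": ys.mean(),
            "test": test,
            "statistic": np.nan,
            "p_value": np.nan,
            "diagnostic": "",
        }
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cmp = runners[test](xs, ys)
            rec.update(statistic=cmp.statistic, p_value=cmp.p_value, test=cmp.test)
        except (ValidationError, KeyError) as exc:
            rec["diagnostic"] = str(exc)
        rows.append(rec)
    return pd.DataFrame(rows).set_index("characteristic")


def amplicon_methylation_summary(
    records: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summarize per-CpG methylation ratios from bisulfite amplicons.

    ``records`` is long-format with columns amplicon, cpg_unit, sample,
    group, ratio (NaN = inapplicable reading, dropped). Returns:

    * amplicon summary — per (amplicon, group): mean of per-sample
      amplicon means (each sample's mean over its non-missing CpG
      units), with sample counts; amplicons missing an entire group are
      skipped and flagged.
    * per-CpG tests — pooled-t comparison of case vs control ratios for
      each (amplicon, cpg_unit) with >= 2 values per group.
    """
    req = {"amplicon", "cpg_unit", "sample", "group", "ratio"}
    if not req.issubset(records.columns):
        raise ValidationError(f"records must have columns {sorted(req)}")
    clean = records.dropna(subset=["ratio"]).copy()
    if ((clean["ratio"] < 0) | (clean["ratio"] > 1)).any():
        raise ValidationError("methylation ratios must lie in [0, 1]")

    amp_rows = []
    for amp, sub in clean.groupby("amplicon"):
        sample_means = (
            sub.groupby(["group", "sample"])["ratio"].mean().rename("sample_mean")
        )
        present = set(sample_means.index.get_level_values("group"))
        if present != {"case", "control"}:
            amp_rows.append(
                {"amplicon": amp, "group": None, "mean_ratio": np.nan,
                 "n_samples": 0, "diagnostic": f"group(s) missing: {sorted({'case','control'} - present)}"}
            )
            continue
        for grp, grp_means in sample_means.groupby(level="group"):
            amp_rows.append(
                {"amplicon": amp, "group": grp, "mean_ratio": grp_means.mean(),
                 "n_samples": len(grp_means), "diagnostic": ""}
            )
    summary = pd.DataFrame(amp_rows)

    test_rows = []
    for (amp, unit), sub in clean.groupby(["amplicon", "cpg_unit"]):
        xs = sub.loc[sub["group"] == "case", "ratio"].to_numpy()
        ys = sub.loc[sub["group"] == "control", "ratio"].to_numpy()
        if len(xs) < 2 or len(ys) < 2:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cmp = pooled_t_test(xs, ys)
        test_rows.append(
            {"amplicon": amp, "cpg_unit": unit, "mean_case": xs.mean(),
             "mean_control": ys.mean(), "statistic": cmp.statistic,
             "p_value": cmp.p_value}
        )
    tests = pd.DataFrame(
        test_rows,
        columns=["amplicon", "cpg_unit", "mean_case", "mean_control",
                 "statistic", "p_value"],
    )
    return summary, tests
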