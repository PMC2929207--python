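"""Immunoassay validation statistics: group summaries and two-sample t-tests.

Candidate markers from the peak-profiling stage are validated on raw
immunoassay readouts (ELISA concentrations, western-blot photoluminescence)
with two-sample t-tests.  Both the pooled-variance and the Welch variant
are provided — published tables rarely state which was used — and a
summary-level test reconstructs t, df and p from printed means, SDs and
group sizes alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError

VARIANTS = ("pooled", "welch")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    variant: str


def read_immunoassay(path) -> pd.DataFrame:
    """Read a measurement table (sample_id, group, analyte, value)."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = ["sample_id", "group", "analyte", "value"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigurationError(f"immunoassay table: missing column(s) {missing}")
    df["value"] = df["value"].astype(float)
    if (df["value"] <= 0).any():
        raise ConfigurationError("immunoassay table: values must be positive")
    if df.duplicated(subset=["sample_id", "analyte"]).any():
        raise ConfigurationError("immunoassay table: duplicate (sample, analyte) rows")
    return df[required]


def group_summary(t: pd.DataFrame, analyte: str) -> pd.DataFrame:
    """Per-group n, mean and sample SD (n-1) for one analyte, raw scale."""
    sub = t.loc[t["analyte"] == analyte]
    if sub.empty:
        raise ConfigurationError(f"analyte: no rows for {analyte!r}")
    out = (
        sub.groupby("group")["value"]
        .agg(n="count", mean="mean", sd=lambda v: v.std(ddof=1))
        .reset_index()
    )
    if (out["n"] < 2).any():
        small = out.loc[out["n"] < 2, "group"].tolist()
        raise ConfigurationError(f"group(s) {small} have fewer than 2 values")
    return out


def _check_variant(variant: str) -> None:
    if variant not in VARIANTS:
        raise ConfigurationError(f"variant: must be one of {VARIANTS}, got {variant!r}")


def two_sample_t(
    a: Sequence[float], b: Sequence[float], variant: str = "welch"
) -> TTestResult:
    """Two-sided two-sample t-test on raw values.

    ``variant="pooled"`` assumes equal variances; ``"welch"`` does not.
    If every value in both groups is identical the test is degenerate and
    p = 1 is returned with a warning.
    """
    _check_variant(variant)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ConfigurationError("groups: need at least 2 values per group")
    if np.ptp(np.concatenate([a, b])) == 0:
        warnings.warn("degenerate t-test: all values identical; p = 1", stacklevel=2)
        df = a.size + b.size - 2 if variant == "pooled" else float("nan")
        return TTestResult(t=0.0, df=float(df), p=1.0, variant=variant)
    res = sps.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return TTestResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue), variant=variant)


def summary_t_test(
    mean_a: float,
    sd_a: float,
    n_a: int,
    mean_b: float,
    sd_b: float,
    n_b: int,
    variant: str = "welch",
) -> TTestResult:
    """Two-sample t-test reconstructed from group summaries.

    Pooled variant is algebraically identical to :func:`two_sample_t` on
    any raw data with these summaries; Welch uses the Welch–Satterthwaite
    degrees of freedom.
    """
    _check_variant(variant)
    if n_a < 2 or n_b < 2:
        raise ConfigurationError("n: need at least 2 per group")
    if sd_a <= 0 or sd_b <= 0:
        raise ConfigurationError("sd: must be positive")
    res = sps.ttest_ind_from_stats(
        mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=(variant == "pooled")
    )
    if variant == "pooled":
        df = float(n_a + n_b - 2)
    else:
        va, vb = sd_a**2 / n_a, sd_b**2 / n_b
        df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    return TTestResult(t=float(res.statistic), df=float(df), p=float(res.pvalue), variant=variant)


def validation_report(t: pd.DataFrame, analyte: str, group_a: str, group_b: str) -> pd.DataFrame:
    """Table-style report: per-group mean/SD plus p-values of both variants."""
    summary = group_summary(t, analyte).set_index("group")
    for g in (group_a, group_b):
        if g not in summary.index:
            raise ConfigurationError(f"group: no rows for {g!r} and analyte {analyte!r}")
    sub = t.loc[t["analyte"] == analyte]
    va = sub.loc[sub["group"] == group_a, "value"].to_numpy()
    vb = sub.loc[sub["group"] == group_b, "value"].to_numpy()
    rows = {
        "analyte": analyte,
        f"mean_{group_a}": summary.loc[group_a, "mean"],
        f"sd_{group_a}": summary.loc[group_a, "sd"],
        f"n_{group_a}": summary.loc[group_a, "n"],
        f"mean_{group_b}": summary.loc[group_b, "mean"],
        f"sd_{group_b}": summary.loc[group_b, "sd"],
        f"n_{group_b}": summary.loc[group_b, "n"],
        "p_pooled": two_sample_t(va, vb, "pooled").p,
        "p_welch": two_sample_t(va, vb, "welch").p,
    }
    return pd.DataFrame([rows])
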