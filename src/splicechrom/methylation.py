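"""Per-CpG methylation levels and two-condition comparison.

The beta value of a CpG is the methylated fraction m/(m+u) from
bisulfite-converted read counts; CpGs below a minimum coverage get no
beta. Two conditions are compared CpG-by-CpG (paired by position by
default, since the same amplicon CpGs are measured in both) with a
two-sided t-test across CpGs; a Wilcoxon signed-rank alternative and an
unpaired mode are available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class MethylationComparison:
    per_cpg: pd.DataFrame  # chrom, pos, beta_a, beta_b, diff
    mean_diff: float
    ci_low: float
    ci_high: float
    statistic: float
    p_value: float
    test: str
    n_shared: int
    n_dropped: int  # CpGs present/covered in only one condition


def compute_betas(records: pd.DataFrame, min_coverage: int = 1) -> pd.DataFrame:
    """Add a beta = m/(m+u) column; NaN below the coverage floor."""
    df = records.copy()
    if (df["m_count"] < 0).any() or (df["u_count"] < 0).any():
        raise ValueError("methylation counts must be non-negative")
    cov = df["m_count"] + df["u_count"]
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = df["m_count"] / cov
    df["coverage"] = cov
    df["beta"] = beta.where(cov >= max(1, min_coverage))
    return df


def compare_conditions(
    records: pd.DataFrame,
    cond_a: str,
    cond_b: str,
    paired_by_cpg: bool = True,
    min_coverage: int = 1,
    method: str = "t",
) -> MethylationComparison:
    """Per-CpG beta differences (A - B) and a summary test across CpGs.

    Paired mode matches CpGs by (chrom, pos) and drops CpGs covered in
    only one condition; unpaired mode compares the two beta samples.
    ``method`` is ``t`` or ``wilcoxon`` (signed-rank; paired only).
    """
    df = compute_betas(records, min_coverage=min_coverage)
    a = df[df["condition"] == cond_a].dropna(subset=["beta"])
    b = df[df["condition"] == cond_b].dropna(subset=["beta"])
    merged = a.merge(b, on=["chrom", "pos"], suffixes=("_a", "_b"))
    n_dropped = (len(a) - len(merged)) + (len(b) - len(merged))
    per_cpg = merged[["chrom", "pos"]].copy()
    per_cpg["beta_a"] = merged["beta_a"].to_numpy()
    per_cpg["beta_b"] = merged["beta_b"].to_numpy()
    per_cpg["diff"] = per_cpg["beta_a"] - per_cpg["beta_b"]

    if paired_by_cpg:
        if len(per_cpg) < 2:
            raise ValueError("need >= 2 CpGs shared between conditions")
        diffs = per_cpg["diff"].to_numpy()
        mean_diff = float(diffs.mean())
        sd = diffs.std(ddof=1)
        n = len(diffs)
        if sd < 1e-12:  # identical diffs up to float rounding
            sd = 0.0
            if abs(mean_diff) < 1e-12:
                stat, p = 0.0, 1.0
            else:
                raise ValueError("degenerate comparison: all per-CpG differences identical and nonzero")
        elif method == "t":
            res = sps.ttest_rel(per_cpg["beta_a"], per_cpg["beta_b"])
            stat, p = float(res.statistic), float(res.pvalue)
        elif method == "wilcoxon":
            res = sps.wilcoxon(diffs)
            stat, p = float(res.statistic), float(res.pvalue)
        else:
            raise ValueError(f"unknown method {method!r}")
        se = sd / np.sqrt(n) if sd > 0 else 0.0
        tcrit = sps.t.ppf(0.975, n - 1) if n > 1 else np.nan
        ci = (mean_diff - tcrit * se, mean_diff + tcrit * se)
        test = f"paired {method}"
    else:
        if method != "t":
            raise ValueError("unpaired mode supports the t-test only")
        xa = a["beta"].to_numpy()
        xb = b["beta"].to_numpy()
        if len(xa) < 2 or len(xb) < 2:
            raise ValueError("need >= 2 covered CpGs per condition")
        mean_diff = float(xa.mean() - xb.mean())
        if xa.std(ddof=1) == 0 and xb.std(ddof=1) == 0:
            if mean_diff == 0:
                stat, p = 0.0, 1.0
            else:
                raise ValueError("degenerate comparison: zero variance in both conditions")
        else:
            res = sps.ttest_ind(xa, xb)
            stat, p = float(res.statistic), float(res.pvalue)
        se = np.sqrt(xa.var(ddof=1) / len(xa) + xb.var(ddof=1) / len(xb))
        tcrit = sps.t.ppf(0.975, len(xa) + len(xb) - 2)
        ci = (mean_diff - tcrit * se, mean_diff + tcrit * se)
        test = "unpaired t"

    return MethylationComparison(
        per_cpg=per_cpg,
        mean_diff=mean_diff,
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        statistic=stat,
        p_value=p,
        test=test,
        n_shared=len(per_cpg),
        n_dropped=int(n_dropped),
    )
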