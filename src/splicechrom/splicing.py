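"""Differential cassette-exon splicing from junction counts.

PSI is the effective-length-normalized inclusion fraction

    psi = (I / l_I) / (I / l_I + S / l_S)

with I inclusion-supporting reads, S skipping-supporting reads and l_I,
l_S the effective lengths of the two isoform measurements (for a skipped
exon counted on junctions, l_I = 2 junctions vs l_S = 1).

Group differences are tested with a pooled-count binomial likelihood-
ratio test (group-specific vs shared inclusion fraction, chi-square with
one degree of freedom), followed by Benjamini-Hochberg correction across
all tested events jointly. An event is called significant when
FDR < 0.05, |dPSI| > 0.1 and the host gene is expressed (TPM > 1).

Note the LRT assumes binomial counts; overdispersed replicates inflate
its type-I error (see docs/methods.md).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust, fisher_exact_2x2

REQUIRED_COUNT_COLUMNS = [
    "event_id", "gene_id", "group", "replicate", "inc_reads", "skp_reads", "len_inc", "len_skp",
]


def compute_psi(inc_reads, skp_reads, len_inc, len_skp):
    """Effective-length-normalized PSI; NaN where no informative reads.

    Vectorized: accepts scalars or arrays. Invariant to scaling both
    effective lengths by a common factor.
    """
    inc = np.asarray(inc_reads, dtype=float)
    skp = np.asarray(skp_reads, dtype=float)
    li = np.asarray(len_inc, dtype=float)
    ls = np.asarray(len_skp, dtype=float)
    if np.any(inc < 0) or np.any(skp < 0):
        raise ValueError("read counts must be non-negative")
    if np.any(li < 1) or np.any(ls < 1):
        raise ValueError("effective lengths must be >= 1")
    num = inc / li
    den = num + skp / ls
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(den > 0, num / den, np.nan)
    return psi if psi.ndim else float(psi)


def _binom_ll(inc, tot, f):
    """Binomial log-likelihood terms without the combinatorial constant."""
    f = np.clip(f, 1e-12, 1 - 1e-12)
    return inc * np.log(f) + (tot - inc) * np.log1p(-f)


def lrt_binomial(inc1, tot1, inc2, tot2):
    """Vectorized two-group binomial LRT p-value (chi-square, 1 df).

    Tests H0: one shared inclusion fraction vs H1: group-specific
    fractions, on pooled counts per group. NaN where a group has no
    reads.
    """
    inc1 = np.asarray(inc1, dtype=float)
    tot1 = np.asarray(tot1, dtype=float)
    inc2 = np.asarray(inc2, dtype=float)
    tot2 = np.asarray(tot2, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = inc1 / tot1
        f2 = inc2 / tot2
        f0 = (inc1 + inc2) / (tot1 + tot2)
    stat = 2.0 * (
        _binom_ll(inc1, tot1, f1) + _binom_ll(inc2, tot2, f2)
        - _binom_ll(inc1, tot1, f0) - _binom_ll(inc2, tot2, f0)
    )
    stat = np.maximum(stat, 0.0)
    p = sps.chi2.sf(stat, df=1)
    p = np.where((tot1 > 0) & (tot2 > 0), p, np.nan)
    return p if p.ndim else float(p)


def test_event(counts: pd.DataFrame) -> float:
    """LRT p-value for one event's replicate table (long format).

    Replicates with zero informative reads are dropped; counts are pooled
    within group before testing.
    """
    groups = counts["group"].unique()
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    pooled = {}
    for g in groups:
        sub = counts[counts["group"] == g]
        informative = (sub["inc_reads"] + sub["skp_reads"]) > 0
        if informative.sum() < len(sub):
            warnings.warn(f"dropping {int((~informative).sum())} uninformative replicate(s) in group {g}")
        sub = sub[informative]
        pooled[g] = (sub["inc_reads"].sum(), (sub["inc_reads"] + sub["skp_reads"]).sum())
    (i1, t1), (i2, t2) = pooled.values()
    if t1 == 0 or t2 == 0:
        return float("nan")
    return float(lrt_binomial(i1, t1, i2, t2))


def event_table(counts: pd.DataFrame, expression: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-event PSI, dPSI and LRT p-value from a long count table.

    Pools counts within group (control / mutant); dPSI = mutant - control.
    Joins gene TPM when an expression table is supplied.
    """
    missing = [c for c in REQUIRED_COUNT_COLUMNS if c not in counts.columns]
    if missing:
        raise ValueError(f"count table missing columns: {missing}")
    gb = counts.groupby(["event_id", "group"], sort=False)[["inc_reads", "skp_reads"]].sum()
    meta_cols = [c for c in ("gene_id", "chrom", "start", "end", "strand", "event_type", "len_inc", "len_skp") if c in counts.columns]
    meta = counts.groupby("event_id", sort=False)[meta_cols].first()
    wide = gb.unstack("group")
    for g in ("control", "mutant"):
        if ("inc_reads", g) not in wide.columns:
            raise ValueError(f"count table lacks group {g!r}")
    out = meta.copy()
    li, ls = out["len_inc"], out["len_skp"]
    inc_c = wide[("inc_reads", "control")].reindex(out.index)
    skp_c = wide[("skp_reads", "control")].reindex(out.index)
    inc_m = wide[("inc_reads", "mutant")].reindex(out.index)
    skp_m = wide[("skp_reads", "mutant")].reindex(out.index)
    out["psi_control"] = compute_psi(inc_c, skp_c, li, ls)
    out["psi_mutant"] = compute_psi(inc_m, skp_m, li, ls)
    out["delta_psi"] = out["psi_mutant"] - out["psi_control"]
    out["p_value"] = lrt_binomial(inc_m, inc_m + skp_m, inc_c, inc_c + skp_c)
    out = out.reset_index()
    if expression is not None:
        out = out.merge(expression[["gene_id", "tpm"]], on="gene_id", how="left")
        out = out.rename(columns={"tpm": "gene_tpm"})
    else:
        out["gene_tpm"] = np.nan
    return out


def call_events(
    events: pd.DataFrame,
    fdr_threshold: float = 0.05,
    dpsi_threshold: float = 0.1,
    tpm_threshold: float = 1.0,
) -> pd.DataFrame:
    """Apply BH across all tested events and the significance filters.

    Adds ``fdr``, ``called`` and ``direction`` columns and returns the
    full table; significant events carry direction ``included-in-mutant``
    (dPSI > 0) or ``excluded-in-mutant``, all others ``ns``.
    """
    events = events.copy()
    if len(events) == 0:
        events["fdr"] = pd.Series(dtype=float)
        events["called"] = pd.Series(dtype=bool)
        events["direction"] = pd.Series(dtype=object)
        return events
    events["fdr"] = bh_adjust(events["p_value"].to_numpy())
    tpm = events["gene_tpm"].fillna(np.inf)  # absent expression: do not filter
    called = (
        (events["fdr"] < fdr_threshold)
        & (events["delta_psi"].abs() > dpsi_threshold)
        & (tpm > tpm_threshold)
    )
    events["called"] = called.fillna(False)
    events["direction"] = np.where(
        ~events["called"], "ns",
        np.where(events["delta_psi"] > 0, "included-in-mutant", "excluded-in-mutant"),
    )
    return events


def called_events(events: pd.DataFrame) -> pd.DataFrame:
    return events[events["called"]].copy()


def summarize_direction(events: pd.DataFrame) -> dict:
    """Fractions of called events by direction plus per-type counts."""
    called = events[events.get("called", False)] if "called" in events.columns else events
    n = len(called)
    if n == 0:
        return {"n_called": 0, "frac_included": np.nan, "frac_excluded": np.nan, "by_type": {}}
    inc = int((called["direction"] == "included-in-mutant").sum())
    exc = int((called["direction"] == "excluded-in-mutant").sum())
    by_type = called["event_type"].value_counts().to_dict() if "event_type" in called.columns else {}
    return {"n_called": n, "frac_included": inc / n, "frac_excluded": exc / n, "by_type": by_type}


def overlap_de_as(as_genes, de_genes, universe) -> dict:
    """Set overlap between alternatively spliced and DE genes + Fisher p."""
    universe = set(universe)
    as_set, de_set = set(as_genes), set(de_genes)
    if not as_set <= universe or not de_set <= universe:
        raise ValueError("gene sets must be subsets of the universe")
    overlap = as_set & de_set
    a = len(overlap)
    b = len(as_set) - a
    c = len(de_set) - a
    d = len(universe) - a - b - c
    return {
        "overlap": a,
        "n_as": len(as_set),
        "n_de": len(de_set),
        "n_universe": len(universe),
        "p_value": fisher_exact_2x2(a, b, c, d),
    }
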