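"""Peak-proximity enrichment at mis-spliced exons.

An exon counts as bound when any peak overlaps a symmetric window around
it by at least one base (half-open interval arithmetic). Enrichment of a
foreground exon set over a background set is summarized as the ratio of
bound proportions (relative risk) — the arithmetic that matches
"binds X-times more often" statements — with the odds ratio reported
alongside and a two-sided Fisher exact p-value. Directional occupancy
splits each exon's window into strand-aware upstream/downstream flanks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats as sps

from .io import GenomicInterval
from .stats import bh_adjust, fisher_exact_2x2, hypergeom_upper_tail, odds_ratio_2x2


@dataclass
class BindingComparison:
    window_bp: int
    n_fg_bound: int
    n_fg_total: int
    n_bg_bound: int
    n_bg_total: int
    ratio: float
    odds_ratio: float
    p_value: float

    @property
    def fg_proportion(self) -> float:
        return self.n_fg_bound / self.n_fg_total

    @property
    def bg_proportion(self) -> float:
        return self.n_bg_bound / self.n_bg_total


class PeakIndex:
    """Chromosome-indexed interval lookup over a peak set."""

    def __init__(self, peaks):
        self._trees: dict[str, IntervalTree] = {}
        for p in peaks:
            self._trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, p)

    def any_overlap(self, chrom: str, start: int, end: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree.overlap(start, end)) if tree is not None else False


def exon_window(exon: GenomicInterval, window_bp: int) -> GenomicInterval:
    """Symmetric window around the exon, clipped at the contig start."""
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    return exon.with_coords(max(0, exon.start - window_bp), exon.end + window_bp)


def is_bound(exon: GenomicInterval, peaks: PeakIndex, window_bp: int) -> bool:
    """True iff any peak overlaps the exon window by >= 1 bp."""
    w = exon_window(exon, window_bp)
    return peaks.any_overlap(w.chrom, w.start, w.end)


def nearest_peak_distance(exon: GenomicInterval, peaks) -> float:
    """Distance in bp from the exon to the nearest peak edge (0 if touching)."""
    best = np.inf
    for p in peaks:
        if p.chrom != exon.chrom:
            continue
        if p.start < exon.end and exon.start < p.end:
            return 0.0
        best = min(best, max(p.start - exon.end, exon.start - p.end))
    return float(best)


def _dedup(exons) -> list:
    seen = set()
    out = []
    for e in exons:
        key = (e.chrom, e.start, e.end)
        if key not in seen:
            seen.add(key)
            out.append(e)
    return out


def enrichment_vs_background(fg_exons, bg_exons, peaks, window_bp: int) -> BindingComparison:
    """Bound-proportion enrichment of foreground exons over background.

    Exons are deduplicated by coordinates so multi-gene exons count once.
    The background may be any caller-chosen exon set (all expressed
    exons, or the non-mis-spliced exons of the same genes).
    """
    fg = _dedup(fg_exons)
    bg = _dedup(bg_exons)
    if not fg or not bg:
        raise ValueError("foreground and background must be non-empty")
    idx = peaks if isinstance(peaks, PeakIndex) else PeakIndex(peaks)
    fg_bound = sum(is_bound(e, idx, window_bp) for e in fg)
    bg_bound = sum(is_bound(e, idx, window_bp) for e in bg)
    a, b = fg_bound, len(fg) - fg_bound
    c, d = bg_bound, len(bg) - bg_bound
    fg_prop = a / len(fg)
    bg_prop = c / len(bg)
    ratio = fg_prop / bg_prop if bg_prop > 0 else np.inf
    return BindingComparison(
        window_bp=window_bp,
        n_fg_bound=a, n_fg_total=len(fg),
        n_bg_bound=c, n_bg_total=len(bg),
        ratio=ratio,
        odds_ratio=odds_ratio_2x2(a, b, c, d),
        p_value=fisher_exact_2x2(a, b, c, d),
    )


def directional_occupancy(exons, peaks, window_bp: int) -> pd.DataFrame:
    """Strand-aware upstream/downstream bound flags per exon.

    The downstream flank is [end, end+window) on ``+`` and
    [start-window, start) on ``-``; upstream is mirrored. Peaks that
    overlap the exon body are ignored so the two flank flags partition
    flank-only binding.
    """
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, p)
    rows = []
    for e in exons:
        if e.strand not in ("+", "-"):
            raise ValueError(f"exon {e.name or e} lacks strand; directional logic needs orientation")
        left = (max(0, e.start - window_bp), e.start)
        right = (e.end, e.end + window_bp)
        flank_hits = {"left": False, "right": False}
        tree = trees.get(e.chrom, IntervalTree())
        nearby = tree.overlap(left[0], right[1]) if left[0] < right[1] else set()
        for hit in nearby:
            p = hit.data
            if p.start < e.end and e.start < p.end:
                continue  # overlaps the exon body: counts for neither flank
            if left[0] < left[1] and p.start < left[1] and left[0] < p.end:
                flank_hits["left"] = True
            if p.start < right[1] and right[0] < p.end:
                flank_hits["right"] = True
        if e.strand == "+":
            up, down = flank_hits["left"], flank_hits["right"]
        else:
            up, down = flank_hits["right"], flank_hits["left"]
        rows.append((e.name, e.chrom, e.start, e.end, e.strand, up, down))
    return pd.DataFrame(
        rows, columns=["name", "chrom", "start", "end", "strand", "upstream_bound", "downstream_bound"]
    )


def directional_test(occupancy: pd.DataFrame) -> dict:
    """Downstream-vs-upstream comparison over an exon set.

    Reports a two-sided Fisher exact p on the bound counts and a
    two-sided sign test restricted to exons bound on exactly one flank.
    """
    n = len(occupancy)
    n_down = int(occupancy["downstream_bound"].sum())
    n_up = int(occupancy["upstream_bound"].sum())
    fisher_p = fisher_exact_2x2(n_down, n - n_down, n_up, n - n_up)
    down_only = int((occupancy["downstream_bound"] & ~occupancy["upstream_bound"]).sum())
    up_only = int((~occupancy["downstream_bound"] & occupancy["upstream_bound"]).sum())
    discordant = down_only + up_only
    sign_p = (
        float(sps.binomtest(down_only, discordant, 0.5, alternative="two-sided").pvalue)
        if discordant > 0
        else 1.0
    )
    return {
        "n_exons": n,
        "n_downstream_bound": n_down,
        "n_upstream_bound": n_up,
        "fisher_p": fisher_p,
        "sign_test_p": sign_p,
    }


def geneset_enrichment(query_genes, gene_sets: dict, universe) -> pd.DataFrame:
    """Hypergeometric over-representation of each gene set in the query.

    Sets are intersected with the universe first; sets disjoint from the
    universe are skipped with a warning. One-sided upper-tail p per set,
    BH across sets.
    """
    universe = set(universe)
    query = set(query_genes)
    if not query <= universe:
        raise ValueError("query genes must be a subset of the universe")
    rows = []
    for name, members in gene_sets.items():
        members = set(members) & universe
        if not members:
            warnings.warn(f"gene set {name!r} is disjoint from the universe; skipped")
            continue
        overlap = len(query & members)
        p = hypergeom_upper_tail(overlap, len(universe), len(members), len(query))
        rows.append((name, overlap, len(members), p))
    df = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "p_value"])
    df["q_value"] = bh_adjust(df["p_value"].to_numpy()) if len(df) else pd.Series(dtype=float)
    return df
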