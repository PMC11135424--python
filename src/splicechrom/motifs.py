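"""PWM scanning of exon-flank windows and set-level motif enrichment.

RNA-binding-protein motifs (DNA-encoded PWMs, e.g. the Ray 2013
compendium in MEME format) are scanned on the sense (pre-mRNA) strand
only, with a log-odds score against a 0-order background and the common
hit rule score >= 0.8 * maximum attainable score. Enrichment of a motif
in a foreground window set over a background set is a window-level 2x2
Fisher test (windows with >= 1 hit vs without), BH-corrected across
motifs, with the hit-density ratio reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs
from pyfaidx import Fasta

from .io import GenomicInterval, SignalTrack
from .stats import bh_adjust, fisher_exact_2x2

_ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class Pwm:
    """Position probability matrix over A/C/G/T with a background model."""

    motif_id: str
    matrix: np.ndarray  # (length, 4), rows sum to 1
    background: np.ndarray | None = None  # length-4; uniform when None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("matrix must be (length, 4)")
        if self.matrix.shape[0] < 4:
            raise ValueError("PWM length must be >= 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("each PWM position must sum to 1")
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, dtype=float)

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def log_odds(self, pseudo: float = 1e-6) -> np.ndarray:
        return np.log2((self.matrix + pseudo) / (self.background + pseudo))

    @property
    def consensus(self) -> str:
        return "".join(_ALPHABET[i] for i in self.matrix.argmax(axis=1))

    def with_background(self, background) -> "Pwm":
        return Pwm(self.motif_id, self.matrix, np.asarray(background, dtype=float))


def read_meme(path) -> list[Pwm]:
    """Read PWMs from a MEME (minimal) motif file."""
    with open(path) as fh:
        records = bio_motifs.parse(fh, "minimal")
    out = []
    for m in records:
        mat = np.array([[m.pwm[b][i] for b in _ALPHABET] for i in range(m.length)])
        bg = np.array([m.background[b] for b in _ALPHABET]) if m.background else None
        out.append(Pwm(m.name or m.base_id, mat, bg))
    return out


def write_meme(pwms, path) -> None:
    """Write PWMs in MEME minimal format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: +\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for p in pwms:
            fh.write(f"MOTIF {p.motif_id}\n")
            # large nsites: readers that reconstruct probabilities through
            # integer counts then lose < 1e-6 per cell
            fh.write(f"letter-probability matrix: alength= 4 w= {len(p)} nsites= 1000000 E= 0\n")
            for row in p.matrix:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


def consensus_pwm(motif_id: str, consensus: str, sharpness: float = 0.97) -> Pwm:
    """Sharp PWM around a consensus (each position: ``sharpness`` on the
    consensus base, the remainder split over the other three)."""
    consensus = consensus.upper().replace("U", "T")
    mat = np.full((len(consensus), 4), (1.0 - sharpness) / 3.0)
    for i, b in enumerate(consensus):
        mat[i, _ALPHABET.index(b)] = sharpness
    return Pwm(motif_id, mat)


# ---------------------------------------------------------------------------
# sequence extraction
# ---------------------------------------------------------------------------

def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def extract_flank_sequences(exons, genome, flank_bp: int = 10000) -> list[dict]:
    """Exon-plus-flank sequences in sense (pre-mRNA) orientation.

    ``genome`` is a FASTA path, a ``pyfaidx.Fasta``, or a dict of
    chromosome sequences. Minus-strand regions are reverse-complemented.
    Regions running off a contig are clipped and flagged.
    """
    if isinstance(genome, (str,)) or hasattr(genome, "__fspath__"):
        genome = Fasta(str(genome))
    out = []
    for e in exons:
        if e.strand not in ("+", "-"):
            raise ValueError("flank extraction requires stranded exons")
        if isinstance(genome, dict):
            contig = genome[e.chrom]
            clen = len(contig)
        else:
            contig = genome[e.chrom]
            clen = len(contig)
        start = e.start - flank_bp
        end = e.end + flank_bp
        clipped = start < 0 or end > clen
        start = max(0, start)
        end = min(clen, end)
        seq = str(contig[start:end]).upper()
        if e.strand == "-":
            seq = reverse_complement(seq)
        out.append({"name": e.name, "seq": seq, "clipped": clipped, "strand": e.strand})
    return out


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3, anything else -> 4."""
    lut = np.full(256, 4, dtype=np.int8)
    for i, b in enumerate(_ALPHABET):
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    return lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def scan_pwm(seq: str, pwm: Pwm, threshold_frac: float = 0.8) -> pd.DataFrame:
    """Sense-strand log-odds scan; hits where score >= frac * max score.

    Windows containing a non-ACGT base are skipped. Returns a DataFrame
    of 0-based hit offsets and scores.
    """
    L = len(pwm)
    codes = _encode(seq)
    n = len(codes) - L + 1
    if n <= 0:
        return pd.DataFrame({"offset": [], "score": []})
    lo = pwm.log_odds()
    lo_ext = np.hstack([lo, np.full((L, 1), -np.inf)])  # column 4: N
    scores = np.zeros(n)
    for j in range(L):
        scores = scores + lo_ext[j, codes[j : j + n]]
    max_score = lo.max(axis=1).sum()
    thr = threshold_frac * max_score
    hit = scores >= thr
    return pd.DataFrame({"offset": np.nonzero(hit)[0], "score": scores[hit]})


@dataclass
class MotifEnrichment:
    motif_id: str
    fg_hits: int
    fg_bp: int
    fg_windows_hit: int
    n_fg: int
    bg_hits: int
    bg_bp: int
    bg_windows_hit: int
    n_bg: int
    enrichment_ratio: float
    p_value: float
    q_value: float = np.nan


def compare_motif_sets(fg_seqs, bg_seqs, pwms, threshold_frac: float = 0.8) -> list[MotifEnrichment]:
    """Per-PWM enrichment of foreground windows over background windows.

    The background base composition of the bg set is used as the 0-order
    background model for scoring both sets. p is a window-level two-sided
    Fisher exact test; q is BH across the supplied motifs;
    ``enrichment_ratio`` is the hit-density (hits per bp) ratio.
    """
    fg_seqs, bg_seqs = list(fg_seqs), list(bg_seqs)
    if not fg_seqs or not bg_seqs:
        raise ValueError("both sequence sets must be non-empty")
    comp = _base_composition(bg_seqs)
    results = []
    for pwm in pwms:
        pw = pwm.with_background(comp)
        fg_hits = [len(scan_pwm(s, pw, threshold_frac)) for s in fg_seqs]
        bg_hits = [len(scan_pwm(s, pw, threshold_frac)) for s in bg_seqs]
        fg_bp = sum(len(s) for s in fg_seqs)
        bg_bp = sum(len(s) for s in bg_seqs)
        a = sum(h > 0 for h in fg_hits)
        c = sum(h > 0 for h in bg_hits)
        fg_density = sum(fg_hits) / fg_bp
        bg_density = sum(bg_hits) / bg_bp
        ratio = fg_density / bg_density if bg_density > 0 else np.inf
        p = fisher_exact_2x2(a, len(fg_seqs) - a, c, len(bg_seqs) - c)
        results.append(
            MotifEnrichment(
                motif_id=pwm.motif_id,
                fg_hits=sum(fg_hits), fg_bp=fg_bp, fg_windows_hit=a, n_fg=len(fg_seqs),
                bg_hits=sum(bg_hits), bg_bp=bg_bp, bg_windows_hit=c, n_bg=len(bg_seqs),
                enrichment_ratio=ratio, p_value=p,
            )
        )
    qs = bh_adjust([r.p_value for r in results])
    for r, q in zip(results, qs):
        r.q_value = float(q)
    return results


def shared_motifs(results_a, results_b, q_threshold: float = 0.05) -> set:
    """Motifs significantly enriched (q < threshold, ratio > 1) in both runs."""
    def sig(results):
        return {r.motif_id for r in results if r.q_value < q_threshold and r.enrichment_ratio > 1}

    return sig(results_a) & sig(results_b)


def _base_composition(seqs) -> np.ndarray:
    counts = np.zeros(4)
    for s in seqs:
        codes = _encode(s)
        counts += np.bincount(codes[codes < 4], minlength=4)
    total = counts.sum()
    return counts / total if total > 0 else np.full(4, 0.25)


# ---------------------------------------------------------------------------
# paused-site definition
# ---------------------------------------------------------------------------

def find_paused_sites(
    exons,
    track: SignalTrack,
    half_size: int = 2500,
    quantile: float = 0.9,
    site_halfwidth: int = 150,
) -> list[GenomicInterval]:
    """Operational paused-polymerase sites near exons.

    For each exon, the position of maximum signal within the +/-
    ``half_size`` window qualifies as a paused site when its value
    exceeds the given quantile of all exon-window maxima. Returns one
    interval (+/- ``site_halfwidth``) per qualifying exon.
    """
    maxima = []
    for e in exons:
        lo, hi = max(0, e.center - half_size), e.center + half_size
        starts, ends, values = track.runs(e.chrom)
        sel = (ends > lo) & (starts < hi)
        if not sel.any():
            maxima.append((e, None, 0.0))
            continue
        vals = values[sel]
        mids = ((np.maximum(starts[sel], lo) + np.minimum(ends[sel], hi)) // 2).astype(int)
        k = int(np.argmax(vals))
        maxima.append((e, int(mids[k]), float(vals[k])))
    peak_vals = np.array([m[2] for m in maxima])
    cutoff = np.quantile(peak_vals, quantile)
    out = []
    for e, pos, val in maxima:
        if pos is not None and val >= cutoff and val > 0:
            out.append(
                GenomicInterval(
                    e.chrom, max(0, pos - site_halfwidth), pos + site_halfwidth, e.strand, name=e.name
                )
            )
    return out
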