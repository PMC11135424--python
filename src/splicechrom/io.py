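"""Genomic interval and signal-track containers plus BED/GTF/bedGraph I/O.

Every coordinate inside the package is 0-based half-open (BED-native);
GTF's 1-based closed coordinates are converted on read and restored on
write. Strand ``.`` is allowed for undirected features such as peaks but
callers that need transcription direction (flank logic, metaplots) reject
it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

import gffutils
import numpy as np

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded, named, optionally scored genomic interval.

    ``start`` is 0-based inclusive, ``end`` 0-based exclusive.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(f"start >= end ({self.start} >= {self.end})")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def with_coords(self, start: int, end: int) -> "GenomicInterval":
        return replace(self, start=start, end=end)


class SignalTrack:
    """Per-chromosome step function: sorted non-overlapping runs of signal.

    Bases outside any run read as 0. Supports point queries and fast
    interval means via a cumulative integral, which is what the metaplot
    binning uses.
    """

    def __init__(self, runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        # runs[chrom] = (starts, ends, values), each a 1-D array
        self._runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self._cum: dict[str, np.ndarray] = {}
        for chrom, (starts, ends, values) in runs.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            if not (np.all(np.isfinite(values))):
                raise ValueError(f"non-finite signal value on {chrom}")
            if np.any(starts >= ends):
                raise ValueError(f"empty or inverted run on {chrom}")
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping runs on {chrom}")
            self._runs[chrom] = (starts, ends, values)
            # cumulative integral up to the start of each run
            seg = values * (ends - starts)
            self._cum[chrom] = np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def chroms(self) -> list[str]:
        return list(self._runs)

    def runs(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self._runs[chrom]

    def value_at(self, chrom: str, pos: int) -> float:
        if chrom not in self._runs:
            return 0.0
        starts, ends, values = self._runs[chrom]
        i = np.searchsorted(starts, pos, side="right") - 1
        if i >= 0 and pos < ends[i]:
            return float(values[i])
        return 0.0

    def mean(self, chrom: str, start: int, end: int) -> float:
        """Mean signal over [start, end); off-track bases count as 0."""
        if start >= end:
            raise ValueError("start >= end")
        if chrom not in self._runs:
            return 0.0
        ints = self.integral_at(chrom, np.array([start, end], dtype=np.int64))
        return float((ints[1] - ints[0]) / (end - start))

    def integral_at(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Vectorized integral of the signal over [0, pos)."""
        starts, ends, values = self._runs[chrom]
        cum = self._cum[chrom]
        pos = np.asarray(pos, dtype=np.int64)
        pos = np.clip(pos, 0, None)
        i = np.searchsorted(starts, pos, side="right") - 1
        idx = np.clip(i, 0, None)
        full = cum[idx + 1]  # integral through the end of run i
        # subtract the part of run i beyond pos (if pos falls inside run i)
        trim = np.where(pos < ends[idx], (ends[idx] - np.maximum(pos, starts[idx])) * values[idx], 0.0)
        out = np.where(i >= 0, full - trim, 0.0)
        return out

    def bin_means(self, chrom: str, edges: np.ndarray) -> np.ndarray:
        """Mean signal in each [edges[i], edges[i+1]) bin.

        Edges below 0 are clipped; clipped bins average only in-range
        bases over the *requested* width (off-range bases read 0).
        """
        edges = np.asarray(edges, dtype=np.int64)
        widths = np.diff(edges)
        if np.any(widths <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if chrom not in self._runs:
            return np.zeros(len(edges) - 1)
        ints = self.integral_at(chrom, edges)
        return np.diff(ints) / widths

    def __eq__(self, other) -> bool:
        if not isinstance(other, SignalTrack):
            return NotImplemented
        if set(self._runs) != set(other._runs):
            return False
        return all(
            all(np.array_equal(a, b) for a, b in zip(self._runs[c], other._runs[c]))
            for c in self._runs
        )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path) -> list[GenomicInterval]:
    """Read BED3/BED6 into 0-based half-open intervals.

    Missing strand becomes ``.`` and missing score is left absent.
    Malformed lines raise with their 1-based line number.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 else "."
            try:
                out.append(GenomicInterval(chrom, start, end, strand, name, score))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    """Write BED6 (or BED3 when no interval carries name/score/strand)."""
    intervals = list(intervals)
    bed6 = any(iv.name is not None or iv.score is not None or iv.strand != "." for iv in intervals)
    with open(path, "w") as fh:
        for iv in intervals:
            if bed6:
                score = "." if iv.score is None else format(iv.score, "g")
                name = iv.name if iv.name is not None else "."
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def read_gtf_exons(path) -> dict[tuple[str, str], list[GenomicInterval]]:
    """Read exon features from a GTF, keyed by (gene_id, transcript_id).

    Coordinates are converted from GTF 1-based closed to 0-based
    half-open. Exons within a transcript are ordered by start. Non-exon
    features are skipped.
    """
    out: dict[tuple[str, str], list[GenomicInterval]] = {}
    for feat in gffutils.iterators.DataIterator(str(path)):
        if feat.featuretype != "exon":
            continue
        gene_ids = feat.attributes.get("gene_id", [])
        tx_ids = feat.attributes.get("transcript_id", [])
        if not gene_ids:
            raise ValueError(f"exon at {feat.seqid}:{feat.start} lacks gene_id")
        if feat.strand not in ("+", "-"):
            raise ValueError(
                f"exon at {feat.seqid}:{feat.start} has no usable strand "
                f"({feat.strand!r}); exons must be oriented"
            )
        tx = tx_ids[0] if tx_ids else gene_ids[0]
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand, name=gene_ids[0])
        out.setdefault((gene_ids[0], tx), []).append(iv)
    for key in out:
        out[key] = sorted(out[key], key=lambda iv: iv.start)
    return out


def write_gtf_exons(exons: dict[tuple[str, str], list[GenomicInterval]], path, source="splicechrom") -> None:
    """Write exon intervals back to GTF (restores 1-based closed coords)."""
    with open(path, "w") as fh:
        for (gene_id, tx_id), ivs in exons.items():
            for iv in ivs:
                attrs = f'gene_id "{gene_id}"; transcript_id "{tx_id}";'
                fh.write(
                    f"{iv.chrom}\t{source}\texon\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def read_bedgraph(path, scale_factor: float = 1.0) -> SignalTrack:
    """Read a 4-column bedGraph into a :class:`SignalTrack`.

    Values are taken as already normalized; ``scale_factor`` multiplies
    them uniformly. Overlapping runs are an error (tracks must be flat).
    """
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            try:
                start, end = int(fields[1]), int(fields[2])
                value = float(fields[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed bedGraph record") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            per_chrom.setdefault(fields[0], []).append((start, end, value * scale_factor))
    runs = {}
    for chrom, recs in per_chrom.items():
        recs.sort()
        starts = np.array([r[0] for r in recs], dtype=np.int64)
        ends = np.array([r[1] for r in recs], dtype=np.int64)
        values = np.array([r[2] for r in recs], dtype=float)
        if np.any(starts[1:] < ends[:-1]):
            bad = int(np.nonzero(starts[1:] < ends[:-1])[0][0])
            raise ValueError(f"{path}: overlapping runs on {chrom} near base {starts[bad + 1]}")
        runs[chrom] = (starts, ends, values)
    return SignalTrack(runs)


def write_bedgraph(track: SignalTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms:
            starts, ends, values = track.runs(chrom)
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    """Write sequences to FASTA with fixed line width."""
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
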