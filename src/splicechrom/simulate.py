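"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the statistical structure the downstream analyses
assume: group-wise cassette-exon PSI shifts measured by overdispersed
junction counts, chromatin-factor peaks planted downstream (in
transcription direction) of exons that are skipped in control cells,
an elongation-signal stalling bump over peak-bound exons, RNA-binding
protein motifs planted at different densities in foreground vs background
windows, a dual-readout qPCR knockdown screen with spiked hits, and
two-condition per-CpG bisulfite counts.

Everything is deterministic under ``SimConfig.seed``: each generator
draws from its own seed stream so adding or reordering calls never
perturbs another generator's output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import GenomicInterval, SignalTrack, write_bed, write_bedgraph, write_fasta, write_gtf_exons

# seed-stream ids, one per generator (never reuse)
_STREAM_ANNOT = 1
_STREAM_COUNTS = 2
_STREAM_PEAKS = 3
_STREAM_SIGNAL = 4
_STREAM_SCREEN = 5
_STREAM_METH = 6
_STREAM_GENOME = 7
_STREAM_MOTIF = 8


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with the study's default design.

    Replicate counts follow a 2-control vs 3-mutant design; the PSI effect
    size (0.3), sequencing depth, background peak rate (~7% of 5-kb exon
    windows hit by chance) and screen geometry (71-factor library, two
    controls, two biological replicates) mirror the scale of the kind of
    study this package analyzes.
    """

    seed: int = 0
    # annotation geometry
    n_genes: int = 200
    exons_per_gene: int = 3
    genome_len: int | None = None  # computed from geometry when None
    chrom: str = "chr1"
    exon_len_range: tuple[int, int] = (100, 200)
    intron_len_range: tuple[int, int] = (5000, 7000)
    gene_gap_range: tuple[int, int] = (8000, 12000)
    # splicing events
    n_reps_control: int = 2
    n_reps_mutant: int = 3
    psi_null_beta: tuple[float, float] = (2.0, 2.0)
    n_true_events: int | None = None  # default: 20% of genes
    frac_positive: float = 0.59  # fraction of true events more included in mutant
    delta_psi_effect: float = 0.3
    read_depth: float = 100.0
    dispersion: float = 0.0  # beta-binomial rho; 0 -> binomial
    len_inc: int = 2
    len_skp: int = 1
    tpm_low_frac: float = 0.1  # fraction of (non-true-event) genes with TPM < 1
    # peaks
    peak_bg_rate: float = 7.0  # background peaks per Mbp
    peak_fg_prob: float = 0.10  # P(planted downstream peak | excluded exon)
    peak_offset_range: int = 2000
    peak_len: int = 300
    # signal track
    stall_amplitude: float = 2.0
    stall_sd: float = 300.0
    # motifs
    motif_rate_fg: float = 1.0  # planted motifs per kb, foreground windows
    motif_rate_bg: float = 0.5
    # screen
    screen_n_factors: int = 71
    screen_n_hits: int = 5
    screen_effect: float = 0.5  # fold-change shift for spiked hits
    pos_control_effect: float = 0.25
    ct_noise_sd: float = 0.1  # per-well Ct noise (one technical replicate)
    screen_n_reps: int = 2  # biological replicates (independent experiments)
    screen_n_tech_reps: int = 3  # technical replicates averaged into each reported Ct
    detection_limit: float = 35.0
    screen_frac_undetected: float = 0.04
    # methylation
    n_cpgs: int = 200
    meth_coverage: float = 50.0
    meth_beta_params: tuple[tuple[float, float], tuple[float, float]] = (
        (30.0, 20.0),  # group A: mean 0.6
        (35.0, 15.0),  # group B: mean 0.7
    )

    def __post_init__(self):
        if self.n_true_events is None:
            self.n_true_events = max(1, round(0.2 * self.n_genes))
        if self.exons_per_gene < 3:
            raise ValueError("each gene needs >=3 exons (cassette + constitutive flanks)")
        if not 0 <= self.dispersion < 1:
            raise ValueError("dispersion must be in [0, 1)")
        if not 0 < self.delta_psi_effect < 1:
            raise ValueError("delta_psi_effect must be in (0, 1)")
        for p in (self.peak_fg_prob, self.frac_positive, self.tpm_low_frac, self.screen_frac_undetected):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_true_events > self.n_genes:
            raise ValueError("n_true_events exceeds n_genes")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), int(stream)]))


@dataclass
class GroundTruth:
    """Per-entity truth tables filled in by each generator."""

    events: pd.DataFrame | None = None  # event_id, gene_id, psi_control, psi_mutant, is_true, clamped
    exons: pd.DataFrame | None = None  # event_id, peak_planted, peak_offset
    screen: pd.DataFrame | None = None  # factor_id, spiked, undetected, true_fc
    cpgs: pd.DataFrame | None = None  # pos, theta_a, theta_b
    warnings: list = field(default_factory=list)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("events", "exons", "screen", "cpgs"):
            df = getattr(self, name)
            if df is not None:
                df.to_csv(outdir / f"truth_{name}.tsv", sep="\t", index=False)


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    exons: list  # list[GenomicInterval], ordered by start
    cassette_index: int  # index into exons of the cassette exon

    @property
    def cassette_exon(self) -> GenomicInterval:
        return self.exons[self.cassette_index]

    @property
    def event_id(self) -> str:
        return f"{self.gene_id}.SE"


@dataclass
class Annotation:
    genes: list  # list[Gene]
    chrom_lengths: dict

    def cassette_exons(self) -> dict[str, GenomicInterval]:
        return {g.event_id: g.cassette_exon for g in self.genes}

    def constitutive_exons(self) -> list[GenomicInterval]:
        out = []
        for g in self.genes:
            out.extend(e for i, e in enumerate(g.exons) if i != g.cassette_index)
        return out

    def all_exons(self) -> list[GenomicInterval]:
        return [e for g in self.genes for e in g.exons]

    def to_gtf(self, path) -> None:
        exons = {
            (g.gene_id, f"{g.gene_id}.t1"): list(g.exons) for g in self.genes
        }
        write_gtf_exons(exons, path)


# ---------------------------------------------------------------------------
# annotation & genome
# ---------------------------------------------------------------------------

def simulate_annotation(config: SimConfig) -> Annotation:
    """Lay out multi-exon genes on one chromosome, both strands.

    Each gene carries one cassette exon (the middle exon) flanked by
    constitutive exons. Genes never overlap; packing that cannot fit in a
    caller-supplied ``genome_len`` raises.
    """
    rng = config.rng(_STREAM_ANNOT)
    genes = []
    pos = int(rng.integers(*config.gene_gap_range))
    for i in range(config.n_genes):
        strand = "+" if rng.random() < 0.5 else "-"
        gene_id = f"g{i + 1:05d}"
        exons = []
        cur = pos
        for j in range(config.exons_per_gene):
            elen = int(rng.integers(*config.exon_len_range))
            exons.append(GenomicInterval(config.chrom, cur, cur + elen, strand, name=gene_id))
            cur += elen
            if j < config.exons_per_gene - 1:
                cur += int(rng.integers(*config.intron_len_range))
        genes.append(Gene(gene_id, config.chrom, strand, exons, config.exons_per_gene // 2))
        pos = cur + int(rng.integers(*config.gene_gap_range))
    needed = pos + 1000
    if config.genome_len is not None and config.genome_len < needed:
        raise ValueError(
            f"genome_len={config.genome_len} too small for {config.n_genes} genes (need >= {needed})"
        )
    glen = config.genome_len if config.genome_len is not None else needed
    return Annotation(genes, {config.chrom: glen})


def simulate_genome(config: SimConfig, annotation: Annotation) -> dict[str, str]:
    """IID random genome sequence for the annotated chromosome(s)."""
    rng = config.rng(_STREAM_GENOME)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    out = {}
    for chrom, length in annotation.chrom_lengths.items():
        idx = rng.integers(0, 4, size=length)
        out[chrom] = bases[idx].tobytes().decode("ascii")
    return out


# ---------------------------------------------------------------------------
# junction counts
# ---------------------------------------------------------------------------

def _beta_binomial(rng, n, p, rho):
    """Beta-binomial with mean n*p and overdispersion rho; rho=0 -> binomial."""
    n = np.asarray(n)
    p = np.asarray(p, dtype=float)
    if rho == 0:
        return rng.binomial(n, p)
    conc = (1.0 - rho) / rho
    a = np.maximum(p * conc, 1e-9)
    b = np.maximum((1.0 - p) * conc, 1e-9)
    theta = rng.beta(a, b)
    return rng.binomial(n, theta)


def simulate_junction_counts(
    config: SimConfig, annotation: Annotation, truth: GroundTruth | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw inclusion/skipping junction counts per event and replicate.

    Returns ``(counts, expression, truth)``: a long-format count table
    (one row per event x replicate), a per-gene TPM table with a
    configurable fraction of low-expressed genes, and the updated ground
    truth. ``n_true_events`` events receive a group PSI difference of
    ``delta_psi_effect`` (sign positive — more included in mutant — with
    probability ``frac_positive``); all others share one PSI.
    """
    if truth is None:
        truth = GroundTruth()
    rng = config.rng(_STREAM_COUNTS)
    genes = annotation.genes
    n = len(genes)

    psi_control = rng.beta(*config.psi_null_beta, size=n)
    true_idx = rng.choice(n, size=config.n_true_events, replace=False)
    is_true = np.zeros(n, dtype=bool)
    is_true[true_idx] = True
    sign = np.where(rng.random(n) < config.frac_positive, 1.0, -1.0)
    psi_mutant = psi_control.copy()
    raw = psi_control[true_idx] + sign[true_idx] * config.delta_psi_effect
    clamped_vals = np.clip(raw, 0.01, 0.99)
    clamped = np.zeros(n, dtype=bool)
    clamped[true_idx] = clamped_vals != raw
    psi_mutant[true_idx] = clamped_vals
    for i in np.nonzero(clamped)[0]:
        truth.warnings.append(f"event {genes[i].event_id}: mutant PSI clamped into (0,1)")

    # TPM: low-expression genes drawn only among null events so the
    # expression filter and the effect recovery stay separable truths
    tpm = np.exp(rng.normal(np.log(20.0), 1.0, size=n))
    tpm = np.maximum(tpm, 1.01)
    null_idx = np.nonzero(~is_true)[0]
    n_low = int(round(config.tpm_low_frac * n))
    n_low = min(n_low, len(null_idx))
    low_idx = rng.choice(null_idx, size=n_low, replace=False)
    tpm[low_idx] = rng.uniform(0.05, 0.95, size=n_low)

    rows = []
    groups = [("control", config.n_reps_control, psi_control), ("mutant", config.n_reps_mutant, psi_mutant)]
    for group, n_reps, psi in groups:
        for rep in range(1, n_reps + 1):
            totals = rng.poisson(config.read_depth, size=n)
            # inclusion-read fraction implied by PSI and effective lengths
            f = psi * config.len_inc / (psi * config.len_inc + (1 - psi) * config.len_skp)
            inc = _beta_binomial(rng, totals, f, config.dispersion)
            skp = totals - inc
            for i, g in enumerate(genes):
                ex = g.cassette_exon
                rows.append(
                    (
                        g.event_id, g.gene_id, ex.chrom, ex.start, ex.end, ex.strand,
                        "SE", group, f"{group}_{rep}", int(inc[i]), int(skp[i]),
                        config.len_inc, config.len_skp,
                    )
                )
    counts = pd.DataFrame(
        rows,
        columns=[
            "event_id", "gene_id", "chrom", "start", "end", "strand", "event_type",
            "group", "replicate", "inc_reads", "skp_reads", "len_inc", "len_skp",
        ],
    )
    expression = pd.DataFrame({"gene_id": [g.gene_id for g in genes], "tpm": tpm})
    truth.events = pd.DataFrame(
        {
            "event_id": [g.event_id for g in genes],
            "gene_id": [g.gene_id for g in genes],
            "psi_control": psi_control,
            "psi_mutant": psi_mutant,
            "is_true": is_true,
            "clamped": clamped,
            "tpm": tpm,
        }
    )
    return counts, expression, truth


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------

def excluded_exon_ids(truth: GroundTruth) -> list[str]:
    """Events whose exon is skipped in control but included in mutant.

    These are the "excluded exons" of the motivating biology — skipped in
    control cells, included in mutants: true events with a positive
    mutant-minus-control PSI difference.
    """
    ev = truth.events
    mask = ev["is_true"] & (ev["psi_mutant"] > ev["psi_control"])
    return ev.loc[mask, "event_id"].tolist()


def simulate_peaks(
    annotation: Annotation, truth: GroundTruth, config: SimConfig
) -> tuple[list, GroundTruth]:
    """Plant strand-aware downstream peaks plus uniform background peaks.

    A true excluded exon receives (with probability ``peak_fg_prob``) one
    peak whose near edge sits Uniform(0, peak_offset_range) bp past the
    exon 3' end in transcription direction. Background peaks arrive as a
    Poisson process at ``peak_bg_rate`` per Mbp.
    """
    if truth.events is None:
        raise ValueError("simulate_junction_counts must run first (truth.events missing)")
    rng = config.rng(_STREAM_PEAKS)
    excluded = set(excluded_exon_ids(truth))
    peaks = []
    recs = []
    k = 0
    for g in annotation.genes:
        ex = g.cassette_exon
        planted = False
        offset = np.nan
        if g.event_id in excluded and rng.random() < config.peak_fg_prob:
            planted = True
            offset = int(rng.integers(0, config.peak_offset_range))
            if g.strand == "+":
                s = ex.end + offset
                e = s + config.peak_len
            else:
                e = ex.start - offset
                s = e - config.peak_len
            if s >= 0:
                k += 1
                peaks.append(GenomicInterval(ex.chrom, s, e, ".", name=f"planted_{k}"))
            else:
                planted = False
                offset = np.nan
        recs.append((g.event_id, planted, offset))
    for chrom, length in annotation.chrom_lengths.items():
        n_bg = rng.poisson(config.peak_bg_rate * length / 1e6)
        starts = np.sort(rng.integers(0, max(1, length - config.peak_len), size=n_bg))
        for j, s in enumerate(starts):
            peaks.append(GenomicInterval(chrom, int(s), int(s) + config.peak_len, ".", name=f"bg_{j + 1}"))
    planted_df = pd.DataFrame(recs, columns=["event_id", "peak_planted", "peak_offset"])
    truth.exons = planted_df
    return peaks, truth


def peak_fg_prob_for_ratio(
    config: SimConfig, target_ratio: float, window_bp: int = 5000
) -> float:
    """Planted-peak probability giving an expected bound-proportion ratio.

    Background exons are hit by chance with probability
    ``1 - exp(-lambda * (2*window + exon_len))``; a foreground exon is
    bound if it gets its planted peak or a background one. Solves for the
    planting probability that makes E[fg proportion] / E[bg proportion]
    equal ``target_ratio``.
    """
    lam = config.peak_bg_rate / 1e6
    mean_exon = sum(config.exon_len_range) / 2
    span = 2 * window_bp + mean_exon + config.peak_len
    p_bg = 1.0 - math.exp(-lam * span)
    p_fg = target_ratio * p_bg
    if p_fg >= 1:
        raise ValueError("target ratio unattainable at this background rate")
    q = 1.0 - (1.0 - p_fg) / (1.0 - p_bg)
    if q < 0:
        raise ValueError("target ratio below background; cannot plant negatively")
    return q


# ---------------------------------------------------------------------------
# signal track
# ---------------------------------------------------------------------------

def simulate_signal_track(
    annotation: Annotation, truth: GroundTruth, config: SimConfig, resolution: int = 25
) -> SignalTrack:
    """Flat unit-background track with Gaussian stalling bumps.

    Bumps (amplitude ``stall_amplitude``, sd ``stall_sd``) are centered on
    the cassette exons flagged peak-planted in the ground truth,
    discretized at ``resolution`` bp out to 4 sd.
    """
    if truth.exons is None:
        raise ValueError("simulate_peaks must run first (truth.exons missing)")
    planted = set(truth.exons.loc[truth.exons["peak_planted"], "event_id"])
    centers_by_chrom: dict[str, list[int]] = {}
    for g in annotation.genes:
        if g.event_id in planted:
            centers_by_chrom.setdefault(g.chrom, []).append(g.cassette_exon.center)
    reach = int(4 * config.stall_sd)
    runs = {}
    for chrom, length in annotation.chrom_lengths.items():
        centers = np.array(sorted(centers_by_chrom.get(chrom, [])), dtype=np.int64)
        segments = []  # (start, end, value)
        cursor = 0
        # merge bump windows, then evaluate the summed bump on a fixed grid
        windows = []
        for c in centers:
            lo, hi = max(0, c - reach), min(length, c + reach)
            if windows and lo <= windows[-1][1]:
                windows[-1] = (windows[-1][0], max(hi, windows[-1][1]))
            else:
                windows.append((lo, hi))
        for lo, hi in windows:
            if lo > cursor:
                segments.append((cursor, lo, 1.0))
            edges = np.arange(lo, hi + resolution, resolution, dtype=np.int64)
            edges[-1] = min(edges[-1], hi)
            if edges[-1] <= edges[-2]:
                edges = edges[:-1]
            mids = (edges[:-1] + edges[1:]) / 2.0
            near = centers[(centers >= lo - reach) & (centers <= hi + reach)]
            bump = np.zeros_like(mids)
            for c in near:
                bump += config.stall_amplitude * np.exp(-((mids - c) ** 2) / (2 * config.stall_sd**2))
            for s, e, v in zip(edges[:-1], edges[1:], 1.0 + bump):
                segments.append((int(s), int(e), float(v)))
            cursor = hi
        if cursor < length:
            segments.append((cursor, length, 1.0))
        starts = np.array([s[0] for s in segments], dtype=np.int64)
        ends = np.array([s[1] for s in segments], dtype=np.int64)
        values = np.array([s[2] for s in segments], dtype=float)
        runs[chrom] = (starts, ends, values)
    return SignalTrack(runs)


# ---------------------------------------------------------------------------
# screen plate
# ---------------------------------------------------------------------------

SCREEN_AMPLICONS = ("exon5", "exon21", "total", "reference")
POSITIVE_CONTROL = "SMCHD1"
NEGATIVE_CONTROL = "GFP"


def simulate_screen_plate(
    config: SimConfig, truth: GroundTruth | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Ct table for a dual-readout knockdown screen with spiked hits.

    Library factors SF001..SFnnn plus a positive control (strong but
    sub-hit effect on both readouts) and a negative control. Spiked hits
    shift both exon readouts by ``screen_effect``; a configurable subset
    of library factors is rendered undetected (total-amplicon Ct at or
    beyond the detection limit). Each reported Ct is the mean of
    ``screen_n_tech_reps`` technical replicates, so its noise sd is
    ``ct_noise_sd / sqrt(screen_n_tech_reps)``.
    """
    if config.screen_n_factors < 3:
        raise ValueError("need >=3 factors including both controls")
    if truth is None:
        truth = GroundTruth()
    rng = config.rng(_STREAM_SCREEN)
    noise_sd = config.ct_noise_sd / math.sqrt(config.screen_n_tech_reps)
    library = [f"SF{i + 1:03d}" for i in range(config.screen_n_factors)]
    spiked = set(rng.choice(library, size=config.screen_n_hits, replace=False))
    rest = [f for f in library if f not in spiked]
    n_undet = int(round(config.screen_frac_undetected * config.screen_n_factors))
    undetected = set(rng.choice(rest, size=min(n_undet, len(rest)), replace=False))

    factors = [POSITIVE_CONTROL, NEGATIVE_CONTROL] + library
    ct_ref, ct_total = 20.0, 26.0
    incl_offset = {"exon5": 2.0, "exon21": 2.5}
    rows = []
    fc_true = {}
    for f in factors:
        if f == POSITIVE_CONTROL:
            fc = 1.0 + config.pos_control_effect
        elif f in spiked:
            fc = 1.0 + config.screen_effect
        else:
            fc = 1.0
        fc_true[f] = fc
        for rep in range(1, config.screen_n_reps + 1):
            noise = rng.normal(0.0, noise_sd, size=4)
            if f in undetected:
                base = config.detection_limit + rng.uniform(1.0, 4.0)
                cts = {
                    "exon5": base + 2.0, "exon21": base + 2.5,
                    "total": base, "reference": ct_ref + noise[3],
                }
            else:
                cts = {
                    "exon5": ct_total + incl_offset["exon5"] - math.log2(fc) + noise[0],
                    "exon21": ct_total + incl_offset["exon21"] - math.log2(fc) + noise[1],
                    "total": ct_total + noise[2],
                    "reference": ct_ref + noise[3],
                }
            for amp in SCREEN_AMPLICONS:
                rows.append((f, amp, rep, cts[amp]))
    plate = pd.DataFrame(rows, columns=["factor_id", "amplicon", "replicate", "ct"])
    truth.screen = pd.DataFrame(
        {
            "factor_id": factors,
            "spiked": [f in spiked for f in factors],
            "undetected": [f in undetected for f in factors],
            "true_fc": [fc_true[f] for f in factors],
        }
    )
    return plate, truth


# ---------------------------------------------------------------------------
# methylation
# ---------------------------------------------------------------------------

def simulate_methylation_counts(
    config: SimConfig, truth: GroundTruth | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Two-condition per-CpG methylated/unmethylated counts.

    Per CpG and condition, coverage is Poisson and the methylated count
    binomial with a Beta-distributed methylation level whose parameters
    differ between conditions.
    """
    if config.n_cpgs < 1:
        raise ValueError("n_cpgs must be >= 1")
    if truth is None:
        truth = GroundTruth()
    rng = config.rng(_STREAM_METH)
    pos = 1000 + 2 * np.arange(config.n_cpgs)
    rows = []
    thetas = {}
    for cond, (a, b) in zip(("groupA", "groupB"), config.meth_beta_params):
        theta = rng.beta(a, b, size=config.n_cpgs)
        thetas[cond] = theta
        cov = rng.poisson(config.meth_coverage, size=config.n_cpgs)
        m = rng.binomial(cov, theta)
        u = cov - m
        for p, mi, ui in zip(pos, m, u):
            rows.append(("amplicon1", int(p), cond, int(mi), int(ui)))
    table = pd.DataFrame(rows, columns=["chrom", "pos", "condition", "m_count", "u_count"])
    truth.cpgs = pd.DataFrame({"pos": pos, "theta_a": thetas["groupA"], "theta_b": thetas["groupB"]})
    return table, truth


# ---------------------------------------------------------------------------
# motif sequence sets
# ---------------------------------------------------------------------------

def simulate_motif_sequences(
    config: SimConfig,
    consensus: str,
    n_fg: int,
    n_bg: int,
    seq_len: int = 1000,
) -> tuple[list[str], list[str], GroundTruth]:
    """Random windows with a consensus motif planted at two densities.

    Foreground windows receive Poisson(motif_rate_fg * len/1kb) planted
    copies, background windows Poisson(motif_rate_bg * len/1kb), at
    uniform positions (later plants may overwrite earlier ones).
    """
    rng = config.rng(_STREAM_MOTIF)
    consensus = consensus.upper()
    k = len(consensus)
    bases = np.array(list("ACGT"))

    def make(n, rate):
        seqs = []
        planted = []
        for _ in range(n):
            arr = bases[rng.integers(0, 4, size=seq_len)]
            m = rng.poisson(rate * seq_len / 1000.0)
            for _ in range(m):
                p = int(rng.integers(0, seq_len - k + 1))
                arr[p : p + k] = list(consensus)
            seqs.append("".join(arr))
            planted.append(m)
        return seqs, planted

    fg, fg_n = make(n_fg, config.motif_rate_fg)
    bg, bg_n = make(n_bg, config.motif_rate_bg)
    truth = GroundTruth()
    truth.warnings.append(
        f"planted motifs: fg total {sum(fg_n)} in {n_fg} windows, bg total {sum(bg_n)} in {n_bg}"
    )
    return fg, bg, truth


# ---------------------------------------------------------------------------
# one-call full dataset
# ---------------------------------------------------------------------------

def simulate_all(config: SimConfig, outdir) -> GroundTruth:
    """Generate and write the complete synthetic dataset to ``outdir``.

    Writes genome.fa, annotation.gtf, junction_counts.tsv,
    expression.tsv, peaks.bed, signal.bedgraph, screen_plate.tsv,
    methylation.tsv and the ground-truth tables.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ann = simulate_annotation(config)
    counts, expr, truth = simulate_junction_counts(config, ann)
    peaks, truth = simulate_peaks(ann, truth, config)
    track = simulate_signal_track(ann, truth, config)
    plate, truth = simulate_screen_plate(config, truth)
    meth, truth = simulate_methylation_counts(config, truth)
    genome = simulate_genome(config, ann)

    write_fasta(genome, outdir / "genome.fa")
    ann.to_gtf(outdir / "annotation.gtf")
    counts.to_csv(outdir / "junction_counts.tsv", sep="\t", index=False)
    expr.to_csv(outdir / "expression.tsv", sep="\t", index=False)
    write_bed(peaks, outdir / "peaks.bed")
    write_bedgraph(track, outdir / "signal.bedgraph")
    plate.to_csv(outdir / "screen_plate.tsv", sep="\t", index=False)
    meth.to_csv(outdir / "methylation.tsv", sep="\t", index=False)
    truth.write(outdir)
    return truth
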