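import math

import numpy as np
import pandas as pd
import pytest

from splicechrom import simulate as sim
from splicechrom.splicing import compute_psi


class TestAnnotation:
    def test_determinism_and_counts(self, tmp_path):
        cfg = sim.SimConfig(seed=1, n_genes=10, exons_per_gene=3)
        a1 = sim.simulate_annotation(cfg)
        a2 = sim.simulate_annotation(cfg)
        p1, p2 = tmp_path / "a1.gtf", tmp_path / "a2.gtf"
        a1.to_gtf(p1)
        a2.to_gtf(p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert sum(len(g.exons) for g in a1.genes) == 30
        assert {g.strand for g in a1.genes} == {"+", "-"}

    def test_genes_do_not_overlap_and_cassette_is_internal(self):
        cfg = sim.SimConfig(seed=3, n_genes=40)
        ann = sim.simulate_annotation(cfg)
        ends = [g.exons[-1].end for g in ann.genes]
        starts = [g.exons[0].start for g in ann.genes]
        assert all(e < s for e, s in zip(ends[:-1], starts[1:]))
        for g in ann.genes:
            assert 0 < g.cassette_index < len(g.exons) - 1

    def test_infeasible_packing_rejected(self):
        cfg = sim.SimConfig(seed=1, n_genes=50, genome_len=10_000)
        with pytest.raises(ValueError, match="too small"):
            sim.simulate_annotation(cfg)

    def test_genome_matches_chrom_lengths(self):
        cfg = sim.SimConfig(seed=2, n_genes=5)
        ann = sim.simulate_annotation(cfg)
        genome = sim.simulate_genome(cfg, ann)
        assert set(genome) == set(ann.chrom_lengths)
        assert len(genome["chr1"]) == ann.chrom_lengths["chr1"]
        assert set(genome["chr1"]) <= set("ACGT")


class TestJunctionCounts:
    def test_psi_estimates_converge_to_truth_at_high_depth(self):
        # law of large numbers: dispersion 0, depth 1e5
        cfg = sim.SimConfig(seed=5, n_genes=50, n_true_events=0, read_depth=1e5, dispersion=0.0)
        ann = sim.simulate_annotation(cfg)
        counts, _, truth = sim.simulate_junction_counts(cfg, ann)
        pooled = counts.groupby("event_id")[["inc_reads", "skp_reads"]].sum()
        psi_hat = compute_psi(pooled["inc_reads"], pooled["skp_reads"], cfg.len_inc, cfg.len_skp)
        psi_true = truth.events.set_index("event_id").loc[pooled.index, "psi_control"]
        assert np.max(np.abs(psi_hat - psi_true.to_numpy())) < 0.01

    def test_null_config_shares_psi_across_groups(self):
        cfg = sim.SimConfig(seed=6, n_genes=20, n_true_events=0)
        ann = sim.simulate_annotation(cfg)
        _, _, truth = sim.simulate_junction_counts(cfg, ann)
        assert np.array_equal(truth.events["psi_control"], truth.events["psi_mutant"])

    def test_true_events_have_configured_effect(self):
        cfg = sim.SimConfig(seed=8, n_genes=50, n_true_events=10, delta_psi_effect=0.3)
        ann = sim.simulate_annotation(cfg)
        _, _, truth = sim.simulate_junction_counts(cfg, ann)
        ev = truth.events
        diff = (ev["psi_mutant"] - ev["psi_control"]).abs()
        assert (ev["is_true"].sum()) == 10
        ok = ev["is_true"] & ~ev["clamped"]
        assert np.allclose(diff[ok], 0.3)
        assert (diff[~ev["is_true"]] == 0).all()

    def test_determinism_and_truth_reconciliation(self):
        cfg = sim.SimConfig(seed=9, n_genes=30)
        ann = sim.simulate_annotation(cfg)
        c1, e1, t1 = sim.simulate_junction_counts(cfg, ann)
        c2, e2, t2 = sim.simulate_junction_counts(cfg, ann)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(e1, e2)
        # one truth record and one expression record per simulated event/gene
        assert len(t1.events) == 30 == len(e1)
        assert set(t1.events["event_id"]) == set(c1["event_id"])
        reps = c1.groupby("event_id").size()
        assert (reps == cfg.n_reps_control + cfg.n_reps_mutant).all()

    def test_low_tpm_fraction_exercises_expression_filter(self):
        cfg = sim.SimConfig(seed=10, n_genes=100, n_true_events=10, tpm_low_frac=0.2)
        ann = sim.simulate_annotation(cfg)
        _, expr, truth = sim.simulate_junction_counts(cfg, ann)
        assert (expr["tpm"] < 1).sum() == 20
        # low expression never lands on true events (truths stay separable)
        low_genes = set(expr.loc[expr["tpm"] < 1, "gene_id"])
        true_genes = set(truth.events.loc[truth.events["is_true"], "gene_id"])
        assert not (low_genes & true_genes)


class TestPeaks:
    def _dataset(self, **kw):
        cfg = sim.SimConfig(**kw)
        ann = sim.simulate_annotation(cfg)
        _, _, truth = sim.simulate_junction_counts(cfg, ann)
        return cfg, ann, truth

    def test_certain_planting_no_background(self):
        cfg, ann, truth = self._dataset(seed=11, n_genes=60, n_true_events=30, frac_positive=1.0,
                                        peak_fg_prob=1.0, peak_bg_rate=0.0)
        peaks, truth = sim.simulate_peaks(ann, truth, cfg)
        excluded = set(sim.excluded_exon_ids(truth))
        assert len(peaks) == len(excluded)
        assert truth.exons.set_index("event_id").loc[sorted(excluded), "peak_planted"].all()

    def test_strand_aware_downstream_placement(self):
        cfg, ann, truth = self._dataset(seed=12, n_genes=80, n_true_events=40, frac_positive=1.0,
                                        peak_fg_prob=1.0, peak_bg_rate=0.0)
        peaks, truth = sim.simulate_peaks(ann, truth, cfg)
        exon_by_event = ann.cassette_exons()
        strand_by_event = {g.event_id: g.strand for g in ann.genes}
        planted = truth.exons[truth.exons["peak_planted"]]
        by_pos = {}
        for p in peaks:
            by_pos[(p.start, p.end)] = p
        for rec in planted.itertuples():
            ex = exon_by_event[rec.event_id]
            if strand_by_event[rec.event_id] == "+":
                s = ex.end + int(rec.peak_offset)
                assert (s, s + cfg.peak_len) in by_pos
                assert s >= ex.end
            else:
                e = ex.start - int(rec.peak_offset)
                assert (e - cfg.peak_len, e) in by_pos
                assert e <= ex.start  # minus strand: peak left of exon

    def test_planted_count_within_binomial_envelope(self):
        cfg, ann, truth = self._dataset(seed=13, n_genes=400, n_true_events=200, frac_positive=1.0,
                                        peak_fg_prob=0.5, peak_bg_rate=0.0)
        _, truth = sim.simulate_peaks(ann, truth, cfg)
        n_planted = int(truth.exons["peak_planted"].sum())
        n_exc = len(sim.excluded_exon_ids(truth))
        # 99% central interval of Binomial(n_exc, 0.5)
        lo = 0.5 * n_exc - 2.576 * math.sqrt(n_exc * 0.25)
        hi = 0.5 * n_exc + 2.576 * math.sqrt(n_exc * 0.25)
        assert lo <= n_planted <= hi

    def test_fg_prob_solver_matches_target_ratio_in_expectation(self):
        cfg = sim.SimConfig(seed=1)
        q = sim.peak_fg_prob_for_ratio(cfg, 2.25, window_bp=5000)
        lam = cfg.peak_bg_rate / 1e6
        span = 2 * 5000 + sum(cfg.exon_len_range) / 2 + cfg.peak_len
        p_bg = 1 - math.exp(-lam * span)
        p_fg = 1 - (1 - q) * (1 - p_bg)
        assert p_fg / p_bg == pytest.approx(2.25, rel=1e-9)


class TestSignalTrack:
    def test_zero_amplitude_gives_flat_unit_track(self, small_dataset):
        cfg = sim.SimConfig(seed=14, n_genes=20, stall_amplitude=0.0, peak_fg_prob=1.0, frac_positive=1.0)
        ann = sim.simulate_annotation(cfg)
        _, _, truth = sim.simulate_junction_counts(cfg, ann)
        _, truth = sim.simulate_peaks(ann, truth, cfg)
        track = sim.simulate_signal_track(ann, truth, cfg)
        glen = ann.chrom_lengths["chr1"]
        for pos in (0, glen // 3, glen - 1):
            assert track.value_at("chr1", pos) == pytest.approx(1.0)

    def test_bump_center_exceeds_flank_and_matches_gaussian_mean(self):
        cfg = sim.SimConfig(seed=15, n_genes=40, n_true_events=20, frac_positive=1.0,
                            peak_fg_prob=1.0, peak_bg_rate=0.0, stall_amplitude=2.0)
        ann = sim.simulate_annotation(cfg)
        _, _, truth = sim.simulate_junction_counts(cfg, ann)
        _, truth = sim.simulate_peaks(ann, truth, cfg)
        track = sim.simulate_signal_track(ann, truth, cfg)
        bump_ids = set(truth.exons.loc[truth.exons["peak_planted"], "event_id"])
        exons = ann.cassette_exons()
        diffs = []
        for g in ann.genes:
            c = exons[g.event_id].center
            if g.event_id in bump_ids:
                assert track.value_at(g.chrom, c) > track.value_at(g.chrom, c + 2400)
                diffs.append(track.mean(g.chrom, c - 2500, c + 2500) - 1.0)
        # analytic mean of A*exp(-x^2/2sd^2) over +/-2500 bp
        expected = cfg.stall_amplitude * cfg.stall_sd * math.sqrt(2 * math.pi) / 5000
        assert np.mean(diffs) == pytest.approx(expected, rel=0.05)


class TestScreenPlate:
    def test_noise_free_null_plate_gives_unit_fold_changes(self):
        from splicechrom.screen import score_plate

        cfg = sim.SimConfig(seed=16, ct_noise_sd=0.0, screen_effect=0.0, pos_control_effect=0.0,
                            screen_n_hits=0, screen_frac_undetected=0.0)
        plate, _ = sim.simulate_screen_plate(cfg)
        fc = score_plate(plate)
        lib = fc[~(fc["is_positive_control"] | fc["is_negative_control"])]
        assert np.allclose(lib[["fc_exon5", "fc_exon21"]], 1.0)

    def test_plate_is_deterministic_and_truth_reconciles(self):
        cfg = sim.SimConfig(seed=17)
        p1, t1 = sim.simulate_screen_plate(cfg)
        p2, t2 = sim.simulate_screen_plate(cfg)
        pd.testing.assert_frame_equal(p1, p2)
        assert len(t1.screen) == cfg.screen_n_factors + 2
        assert t1.screen["spiked"].sum() == cfg.screen_n_hits
        # spiked and undetected sets are disjoint
        assert not (t1.screen["spiked"] & t1.screen["undetected"]).any()


class TestMethylation:
    def test_identical_group_params_give_null_difference(self):
        cfg = sim.SimConfig(seed=18, n_cpgs=500, meth_coverage=100,
                            meth_beta_params=((30.0, 20.0), (30.0, 20.0)))
        table, _ = sim.simulate_methylation_counts(cfg)
        beta = table.assign(beta=lambda d: d.m_count / (d.m_count + d.u_count))
        means = beta.groupby("condition")["beta"].mean()
        assert abs(means["groupA"] - means["groupB"]) < 0.02

    def test_deterministic_table(self):
        cfg = sim.SimConfig(seed=19)
        t1, _ = sim.simulate_methylation_counts(cfg)
        t2, _ = sim.simulate_methylation_counts(cfg)
        pd.testing.assert_frame_equal(t1, t2)


def test_simulate_all_outputs_are_byte_identical_across_runs(tmp_path):
    cfg = sim.SimConfig(seed=20, n_genes=25, n_true_events=5)
    d1, d2 = tmp_path / "run1", tmp_path / "run2"
    sim.simulate_all(cfg, d1)
    sim.simulate_all(cfg, d2)
    files = sorted(p.name for p in d1.iterdir())
    assert files == sorted(p.name for p in d2.iterdir()) and files
    for name in files:
        assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name
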