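import dataclasses

import numpy as np
import pytest
from scipy.signal import argrelmax

from regland.atac_core import consensus_peaks
from regland.chromatin_states import MARKS
from regland.expression_link import gene_has_nfr
from regland.genome_io import Peak, merge_pairs
from regland.synthetic_data import (
    SimConfig,
    generate_genome,
    planted_edges,
    read_manifest,
    simulate_chip_peaks,
    simulate_expression,
    simulate_fragments,
    write_dataset,
    write_manifest,
)
from tests.conftest import SMALL_SIM


class TestGenerateGenome:
    def test_deterministic_outputs(self, tmp_path):
        ds1 = generate_genome(SMALL_SIM, seed=5)
        ds2 = generate_genome(SMALL_SIM, seed=5)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_dataset(ds1, d1)
        write_dataset(ds2, d2)
        for f1 in sorted(d1.iterdir()):
            assert f1.read_bytes() == (d2 / f1.name).read_bytes()

    def test_different_seed_changes_genome(self):
        a = generate_genome(SMALL_SIM, seed=1)
        b = generate_genome(SMALL_SIM, seed=2)
        assert a.sequences["chr1"] != b.sequences["chr1"]

    def test_zero_genes_all_intergenic(self):
        cfg = dataclasses.replace(SMALL_SIM, n_genes=0, n_nfrs=10, n_motifs=2)
        ds = generate_genome(cfg, seed=3)
        assert ds.annotation.genes == {}
        assert len(ds.manifest.nfrs) == 10
        assert ds.manifest.edges == []

    def test_too_small_genome_rejected(self):
        cfg = dataclasses.replace(SMALL_SIM, genome_size=50_000)
        with pytest.raises(ValueError, match="too small"):
            generate_genome(cfg, seed=1)

    def test_manifest_inside_genome_and_sites_in_nfrs(self, small_dataset):
        ds = small_dataset
        sizes = ds.annotation.chrom_sizes
        for iv, _ in ds.manifest.nfrs + ds.manifest.states:
            assert 0 <= iv.start < iv.end <= sizes[iv.chrom]
        nfr_spans = {(iv.chrom, iv.start, iv.end) for iv, _ in ds.manifest.nfrs}
        for s in ds.manifest.sites:
            if s.bound_in:
                assert any(
                    c == s.interval.chrom and a <= s.interval.start and s.interval.end <= b
                    for c, a, b in nfr_spans
                )

    def test_intronic_share_of_non_tss_nfrs(self, default_dataset):
        from collections import Counter

        from regland.chromatin_states import annotate_feature

        ds = default_dataset
        labels = Counter(
            annotate_feature(iv, ds.annotation) for iv, _ in ds.manifest.nfrs
        )
        # TSS-planted NFRs are centered on the TSS (midpoint in promoter/5'UTR)
        non_tss = sum(n for f, n in labels.items()
                      if f not in ("promoter", "five_prime_utr"))
        assert labels["intron"] / non_tss >= 0.6

    def test_planted_site_sequences_written(self, small_dataset):
        ds = small_dataset
        from regland.synthetic_data import reverse_complement

        by_id = {m.id: m for m in ds.motifs}
        for s in ds.manifest.sites:
            seq = ds.sequences[s.interval.chrom][s.interval.start : s.interval.end]
            cons = by_id[s.motif_id].consensus
            assert seq == (cons if s.interval.strand == "+" else reverse_complement(cons))


class TestSimulateFragments:
    def test_nfr_class_fraction_matches_mixture_weight(self, small_dataset):
        frags = simulate_fragments(small_dataset, "Q", 1)
        lens = np.array([f.length for f in frags])
        w = small_dataset.config.mixture_weights[0]
        assert abs((lens <= 100).mean() - w) <= 0.02

    def test_planted_nfr_rate_ratio(self, small_dataset):
        ds = small_dataset
        frags = [f for f in simulate_fragments(ds, "Q", 1) if f.length <= 100]
        active = ds.manifest.nfrs_active_in("Q")
        nfr_bp = sum(len(iv) for iv in active)
        genome_bp = sum(ds.annotation.chrom_sizes.values())
        spans = {}
        for iv in active:
            spans.setdefault(iv.chrom, []).append((iv.start, iv.end))
        inside = 0
        for f in frags:
            mid = (f.start + f.end) // 2
            if any(s <= mid < e for s, e in spans.get(f.chrom, [])):
                inside += 1
        rate_in = inside / nfr_bp
        rate_out = (len(frags) - inside) / (genome_bp - nfr_bp)
        assert rate_in / rate_out >= 8

    def test_replicates_differ_but_share_signal(self, small_dataset):
        r1 = simulate_fragments(small_dataset, "Q", 1)
        r2 = simulate_fragments(small_dataset, "Q", 2)
        assert r1 != r2
        assert len(r1) == len(r2)

    def test_unknown_phenotype_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="phenotype"):
            simulate_fragments(small_dataset, "X", 1)

    def test_trimodal_length_histogram(self, default_dataset):
        frags = simulate_fragments(default_dataset, "W", 1)
        lens = np.array([f.length for f in frags])
        hist, edges = np.histogram(lens, bins=np.arange(0, 520, 10))
        smooth = np.convolve(hist, np.ones(3) / 3, mode="same")
        (peaks,) = argrelmax(smooth, order=4)
        centers = edges[peaks] + 5
        means = default_dataset.config.mixture_means
        for mu in means:
            assert (np.abs(centers - mu) <= 25).any(), f"no mode near {mu}"

    def test_bound_core_cut_depletion(self, default_dataset):
        ds = default_dataset
        from regland.atac_core import classify_fragments, cut_site_track

        frags = classify_fragments(simulate_fragments(ds, "Q", 1))["nfr"]
        track = cut_site_track(frags, ds.annotation.chrom_sizes)
        core = flank = core_bp = flank_bp = 0.0
        for s in ds.manifest.sites:
            iv = s.interval
            arr = track[iv.chrom]
            if "Q" in s.bound_in:
                core += arr[iv.start : iv.end].sum()
                core_bp += len(iv)
                flank += arr[iv.start - 20 : iv.start].sum() + arr[iv.end : iv.end + 20].sum()
                flank_bp += 40
        depletion = (core / core_bp) / (flank / flank_bp)
        assert depletion <= 0.5  # configured 0.25x plus background leakage


class TestSimulateChipPeaks:
    def test_noiseless_equals_planted(self, small_dataset):
        cfg = dataclasses.replace(SMALL_SIM, chip_jitter=0, chip_false_rate=0.0)
        ds = generate_genome(cfg, seed=11)
        for mark in MARKS:
            r1, r2 = simulate_chip_peaks(ds, mark, "Q")
            planted = sorted(
                (iv.start, iv.end) for iv, marks in ds.manifest.states if mark in marks
            )
            for peaks in (r1, r2):
                assert sorted((p.start, p.end) for p in peaks) == planted

    def test_false_peaks_removed_by_consensus(self):
        cfg = dataclasses.replace(SMALL_SIM, chip_jitter=0, chip_false_rate=0.5)
        ds = generate_genome(cfg, seed=4)
        r1, r2 = simulate_chip_peaks(ds, "H3K27ac", "Q")
        planted = {(iv.start, iv.end) for iv, m in ds.manifest.states if "H3K27ac" in m}
        assert {(p.start, p.end) for p in r1} != planted or {
            (p.start, p.end) for p in r2
        } != planted  # false peaks present somewhere
        cons = consensus_peaks(r1, r2)
        assert {(p.start, p.end) for p in cons} == planted

    def test_multi_mark_state_in_both_mark_files(self, small_dataset):
        ds = small_dataset
        multi = [(iv, m) for iv, m in ds.manifest.states if len(m) >= 2]
        assert multi
        iv, marks = multi[0]
        for mark in marks:
            r1, _ = simulate_chip_peaks(ds, mark, "W")
            assert any(p.start < iv.end and iv.start < p.end for p in r1)

    def test_unknown_mark_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="mark"):
            simulate_chip_peaks(small_dataset, "H3K9me3", "Q")


class TestSimulateExpression:
    def test_deterministic(self, small_dataset):
        a = simulate_expression(small_dataset, seed=2)
        b = simulate_expression(small_dataset, seed=2)
        assert a.equals(b)

    def test_null_effect_means_equal(self):
        cfg = dataclasses.replace(SimConfig(), expression_effect=0.0)
        ds = generate_genome(cfg, seed=6)
        counts = simulate_expression(ds)
        flags = gene_has_nfr(ds.annotation, [Peak(iv) for iv, _ in ds.manifest.nfrs])
        log = np.log1p(counts).mean(axis=1)
        g1 = log[[g for g in log.index if flags[g]]]
        g2 = log[[g for g in log.index if not flags[g]]]
        assert abs(g1.mean() - g2.mean()) < 0.35

    def test_planted_effect_shifts_nfr_genes(self, default_dataset):
        counts = simulate_expression(default_dataset)
        flags = gene_has_nfr(
            default_dataset.annotation,
            [Peak(iv) for iv, _ in default_dataset.manifest.nfrs],
        )
        log = np.log(counts + 1).mean(axis=1)
        g1 = log[[g for g in log.index if flags[g]]]
        g2 = log[[g for g in log.index if not flags[g]]]
        # +1 log2 unit = log(2) natural-log units, within sampling noise
        assert g1.mean() - g2.mean() == pytest.approx(np.log(2), abs=0.4)


class TestExpressionTestPower:
    def test_planted_effect_detected_with_high_power(self):
        """A +1 log2 planted shift with 100 genes per group is detected by
        the downstream rank-sum test at alpha = 0.01 in >= 95% of 500
        simulations (negative-binomial counts, dispersion 0.1)."""
        import pandas as pd

        from regland.expression_link import nfr_expression_test

        n_runs = 500
        rejections = 0
        nb_n = 1 / 0.1
        for run in range(n_runs):
            rng = np.random.default_rng(40_000 + run)
            base = 150 * np.exp(rng.normal(0, 0.6, 200))
            mu = base * np.where(np.arange(200) < 100, 2.0, 1.0)
            counts = rng.negative_binomial(nb_n, nb_n / (nb_n + mu[:, None]), (200, 6))
            df = pd.DataFrame(counts, index=[f"g{i}" for i in range(200)],
                              columns=[f"s{i}_rep1" for i in range(6)])
            has = {f"g{i}": i < 100 for i in range(200)}
            _, p, _ = nfr_expression_test(df, has)
            rejections += p <= 0.01
        assert rejections >= round(0.95 * n_runs)


class TestManifestRoundTrip:
    def test_read_back_equals_written(self, small_dataset, tmp_path):
        path = tmp_path / "manifest.tsv"
        write_manifest(small_dataset.manifest, path)
        back = read_manifest(path)
        m = small_dataset.manifest
        assert back.seed == m.seed
        assert back.nfrs == m.nfrs
        assert back.states == m.states
        assert back.sites == m.sites
        assert back.edges == m.edges
        assert back.tf_gene_map == m.tf_gene_map


class TestPlantedEdges:
    def test_edges_follow_window_rule(self, small_dataset):
        ds = small_dataset
        edges = planted_edges(ds.manifest.sites, ds.annotation, ds.manifest.tf_gene_map)
        assert edges == ds.manifest.edges
        gene_to_tf = {g: m for m, g in ds.manifest.tf_gene_map.items()}
        # every edge must trace back to >= 1 bound site in the target gene region
        for src, tgt, cls, phenos in edges:
            target_gene = ds.manifest.tf_gene_map[tgt]
            g = ds.annotation.genes[target_gene]
            tss = ds.annotation.tss(target_gene)
            found = False
            for s in ds.manifest.sites:
                if s.motif_id != src or not s.bound_in or s.interval.chrom != g.chrom:
                    continue
                mid = s.interval.midpoint
                if g.strand == "-":
                    in_win = tss - 200 <= mid < tss + 2001
                else:
                    in_win = tss - 2000 <= mid < tss + 201
                if in_win or g.start <= mid < g.end:
                    found = True
            assert found
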