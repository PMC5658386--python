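"""Synthetic epigenome generator: truth consistency, noise model, determinism."""

import filecmp

import numpy as np
import pytest

from lincscreen import (
    SimConfig,
    classify_intergenic,
    promoter_window,
    simulate,
    window_density,
    write_fixture,
)
from lincscreen.simulate import TruthManifest, generate_annotation


class TestSimConfigValidation:
    def test_infeasible_planted_counts_rejected(self):
        with pytest.raises(ValueError, match="planted"):
            SimConfig(n_lnc=10, frac_intergenic=0.5, n_planted_marks=6,
                      n_planted_tf=2)
        with pytest.raises(ValueError, match="planted"):
            SimConfig(n_planted_marks=4, n_planted_tf=5)

    def test_enrich_fold_below_one_rejected(self):
        with pytest.raises(ValueError, match="enrich_fold"):
            SimConfig(enrich_fold=0.5)

    def test_overcrowded_genome_fails_with_advice(self):
        cfg = SimConfig(chrom_lengths={"chr1": 60_000}, n_genes=5,
                        n_lnc=4, frac_intergenic=0.5,
                        n_planted_marks=1, n_planted_tf=1)
        with pytest.raises(RuntimeError, match="larger genome"):
            simulate(cfg)


class TestGenerateAnnotation:
    def test_manifest_counts_match_config(self):
        cfg = SimConfig(seed=1)
        genes, lncs, manifest = generate_annotation(
            cfg, np.random.default_rng(cfg.seed)
        )
        assert len(genes) == cfg.n_genes
        assert len(lncs) == cfg.n_lnc
        assert len(manifest.intergenic_ids) == 30
        assert len(manifest.overlapping_ids) == 20
        assert len(manifest.planted_mark_ids) == 10
        assert len(manifest.planted_tf_ids) == 4
        assert manifest.planted_tf_ids <= manifest.planted_mark_ids
        assert manifest.planted_mark_ids <= manifest.intergenic_ids

    def test_classifier_reproduces_manifest_exactly(self):
        cfg = SimConfig(seed=1)
        genes, lncs, manifest = generate_annotation(
            cfg, np.random.default_rng(cfg.seed)
        )
        part = classify_intergenic(list(lncs), list(genes))
        assert part.intergenic_ids == manifest.intergenic_ids
        assert part.overlapping_ids == manifest.overlapping_ids

    def test_overlapping_lncs_intersect_a_gene_by_100bp(self):
        cfg = SimConfig(seed=3)
        genes, lncs, manifest = generate_annotation(
            cfg, np.random.default_rng(cfg.seed)
        )
        spans = [g.interval for g in genes]
        for t in lncs:
            if t.transcript_id in manifest.overlapping_ids:
                assert max(t.interval.overlap_bp(g) for g in spans) >= 100

    def test_empty_catalogue(self):
        cfg = SimConfig(n_lnc=0, frac_intergenic=0.0, n_planted_marks=0,
                        n_planted_tf=0)
        _, lncs, manifest = generate_annotation(
            cfg, np.random.default_rng(0)
        )
        assert lncs == []
        assert manifest.records == {}


class TestTracks:
    def test_planted_ratio_concentrates_near_fold_over_enrich_span(self):
        """Over the enrichment span itself, the post/pre density ratio of a
        planted promoter lands in [6, 10] for >= 95% of promoters at
        fold 8, depth 30 (count-noise sampling bound)."""
        inside, total = 0, 0
        for seed in range(10):
            fix = simulate(SimConfig(seed=seed))
            chrom_len = fix.cfg.chrom_lengths["chr1"]
            half = fix.cfg.enrich_span // 2
            by_id = {t.transcript_id: t for t in fix.lncs}
            for tid in fix.manifest.planted_mark_ids:
                win = promoter_window(by_id[tid], half, chrom_len)
                for mark in fix.cfg.marks:
                    d_pre = window_density(fix.tracks[(mark, "pre")], win)
                    d_post = window_density(fix.tracks[(mark, "post")], win)
                    total += 1
                    if 6.0 <= d_post / d_pre <= 10.0:
                        inside += 1
        assert inside / total >= 0.95

    def test_unplanted_ratio_concentrates_at_one(self):
        fix = simulate(SimConfig(seed=2))
        chrom_len = fix.cfg.chrom_lengths["chr1"]
        by_id = {t.transcript_id: t for t in fix.lncs}
        unplanted = sorted(
            fix.manifest.intergenic_ids - fix.manifest.planted_mark_ids
        )
        ratios = []
        for tid in unplanted:
            win = promoter_window(by_id[tid], fix.cfg.window_half_width,
                                  chrom_len)
            for mark in fix.cfg.marks:
                d_pre = window_density(fix.tracks[(mark, "pre")], win)
                d_post = window_density(fix.tracks[(mark, "post")], win)
                ratios.append(d_post / d_pre)
        assert abs(float(np.median(ratios)) - 1.0) < 0.1
        assert max(ratios) < 2.0

    def test_tf_peaks_cover_planted_tss_only(self):
        fix = simulate(SimConfig(seed=4))
        w = fix.cfg.window_half_width
        from lincscreen import IntervalIndex, tf_overlap_bp

        index = IntervalIndex((p, i) for i, p in enumerate(fix.tf_peaks))
        chrom_len = fix.cfg.chrom_lengths["chr1"]
        for t in fix.lncs:
            win = promoter_window(t, w, chrom_len)
            bp = tf_overlap_bp(win, index)
            if t.transcript_id in fix.manifest.planted_tf_ids:
                assert bp >= fix.cfg.tf_peak_width // 2
            else:
                assert bp == 0

    def test_overdispersed_noise_inflates_variance(self):
        base = simulate(SimConfig(seed=5, n_planted_marks=0, n_planted_tf=0))
        od = simulate(SimConfig(seed=5, n_planted_marks=0, n_planted_tf=0,
                                overdispersion=2.0))

        def values(fix):
            return np.array(
                [v for _, _, v in fix.tracks[("H3K4me3", "pre")].runs("chr1")]
            )

        assert values(od).var() > 1.5 * values(base).var()


class TestFixtureFiles:
    def test_file_inventory_and_round_trip(self, small_sim_config, tmp_path):
        from lincscreen import read_bed, read_bedgraph, read_gtf
        from lincscreen.io import read_bed_intervals

        fix = simulate(small_sim_config)
        paths = write_fixture(fix, tmp_path / "fx")
        names = {p.name for p in paths.values()}
        assert names == {
            "genes.gtf", "lncs.bed", "tf_peaks.bed", "truth.tsv",
            "simconfig.json",
            "H3K4me3_pre.bedGraph", "H3K4me3_post.bedGraph",
            "H3K27ac_pre.bedGraph", "H3K27ac_post.bedGraph",
        }
        lncs = read_bed(paths["lncs"])
        assert tuple(
            (t.transcript_id, t.interval, t.exons) for t in lncs
        ) == tuple((t.transcript_id, t.interval, t.exons) for t in fix.lncs)
        genes = read_gtf(paths["genes"], biotype="protein_coding")
        assert tuple(t.interval for t in genes) == tuple(
            t.interval for t in fix.genes
        )
        assert read_bedgraph(paths["track:H3K4me3:post"]) == (
            fix.tracks[("H3K4me3", "post")]
        )
        peaks = read_bed_intervals(paths["tf_peaks"])
        assert [(p.chrom, p.start, p.end) for p in peaks] == [
            (p.chrom, p.start, p.end) for p in fix.tf_peaks
        ]
        manifest = TruthManifest.read_tsv(paths["truth"])
        assert manifest == fix.manifest

    def test_same_seed_identical_bytes(self, small_sim_config, tmp_path):
        p1 = write_fixture(simulate(small_sim_config), tmp_path / "a")
        p2 = write_fixture(simulate(small_sim_config), tmp_path / "b")
        for key in p1:
            assert filecmp.cmp(p1[key], p2[key], shallow=False), key

    def test_different_seeds_differ(self, small_sim_config, tmp_path):
        import dataclasses

        cfg2 = dataclasses.replace(small_sim_config, seed=8)
        p1 = write_fixture(simulate(small_sim_config), tmp_path / "a")
        p2 = write_fixture(simulate(cfg2), tmp_path / "b")
        assert not filecmp.cmp(p1["truth"], p2["truth"], shallow=False)
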