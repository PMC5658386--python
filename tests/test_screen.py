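"""Venn accounting, ranking, TF overlap and the cascade orchestrator."""

import numpy as np
import pytest

from lincscreen import (
    CoverageTrack,
    GenomicInterval,
    IntervalIndex,
    PromoterWindow,
    ScreenConfig,
    rank_candidates,
    run_screen,
    tf_overlap_bp,
    venn_counts,
)

from conftest import make_tx


class TestVennCounts:
    def test_nested_three_sets(self):
        counts = venn_counts(
            {"A": {"a", "b", "c"}, "B": {"b", "c"}, "C": {"c"}}
        )
        assert counts[("A",)] == 1
        assert counts[("A", "B")] == 1
        assert counts[("A", "B", "C")] == 1
        assert all(
            v == 0
            for k, v in counts.items()
            if k not in {("A",), ("A", "B"), ("A", "B", "C")}
        )

    def test_disjoint_pair(self):
        counts = venn_counts({"A": {"x", "y"}, "B": {"z"}})
        assert counts == {("A",): 2, ("B",): 1, ("A", "B"): 0}

    def test_identical_sets_all_in_intersection(self):
        counts = venn_counts({"A": {"x", "y"}, "B": {"x", "y"}})
        assert counts == {("A",): 0, ("B",): 0, ("A", "B"): 2}

    @pytest.mark.parametrize("n_sets", [1, 4])
    def test_set_count_contract(self, n_sets):
        sets = {f"S{i}": {"x"} for i in range(n_sets)}
        with pytest.raises(ValueError, match="2 or 3"):
            venn_counts(sets)

    @pytest.mark.parametrize("seed", range(10))
    def test_regions_match_brute_force_algebra(self, seed):
        rng = np.random.default_rng(seed)
        universe = [f"e{i}" for i in range(int(rng.integers(5, 101)))]
        sets = {
            label: {e for e in universe if rng.random() < p}
            for label, p in (("A", 0.5), ("B", 0.35), ("C", 0.2))
        }
        counts = venn_counts(sets)
        # disjoint regions sum to the union
        assert sum(counts.values()) == len(sets["A"] | sets["B"] | sets["C"])
        # each region independently, by direct set algebra
        labels = list(sets)
        for region, n in counts.items():
            inside = set.intersection(*(sets[lb] for lb in region))
            outside = set.union(
                *(sets[lb] for lb in labels if lb not in region), set()
            )
            assert n == len(inside - outside)


class TestRankCandidates:
    DENS = {
        ("x", "H3K4me3", "post"): 5.0,
        ("y", "H3K4me3", "post"): 9.0,
        ("z", "H3K4me3", "post"): 2.0,
    }

    def test_descending_by_density(self):
        assert rank_candidates(["x", "y", "z"], self.DENS, "H3K4me3") == [
            "y", "x", "z",
        ]

    def test_ties_break_lexicographically(self):
        dens = {("x", "m", "post"): 5.0, ("y", "m", "post"): 5.0}
        assert rank_candidates(["y", "x"], dens, "m") == ["x", "y"]

    def test_single_survivor(self):
        assert rank_candidates(["x"], self.DENS, "H3K4me3") == ["x"]

    def test_missing_density_is_error(self):
        with pytest.raises(KeyError, match="H3K27ac"):
            rank_candidates(["x"], self.DENS, "H3K27ac")


class TestTfOverlapBp:
    def win(self, start=0, end=5_000):
        return PromoterWindow("t", GenomicInterval("chr1", start, end))

    def peaks(self, *spans):
        return IntervalIndex(
            (GenomicInterval("chr1", s, e), i) for i, (s, e) in enumerate(spans)
        )

    def test_overlapping_peaks_union_not_double_counted(self):
        assert tf_overlap_bp(self.win(), self.peaks((100, 200), (150, 300))) == 200

    def test_no_overlap_is_zero(self):
        assert tf_overlap_bp(self.win(), self.peaks((9_000, 9_500))) == 0

    def test_containing_peak_clipped_to_window_length(self):
        assert tf_overlap_bp(
            self.win(1_000, 2_000), self.peaks((0, 10_000))
        ) == 1_000


def two_mark_tracks(chrom_len=100_000, value=1.0):
    runs = {"chr1": [(0, chrom_len, value)]}
    return {
        (mark, cond): CoverageTrack.from_runs(runs)
        for mark in ("H3K4me3", "H3K27ac")
        for cond in ("pre", "post")
    }


class TestRunScreenValidation:
    def lncs(self):
        return [make_tx("l1", start=10_000, end=12_000)]

    def test_missing_track_names_the_pair(self):
        tracks = two_mark_tracks()
        del tracks[("H3K27ac", "post")]
        with pytest.raises(ValueError, match=r"H3K27ac.*post"):
            run_screen(self.lncs(), [], tracks, [], ScreenConfig())

    def test_disjoint_chromosome_namespaces_fail_loud(self):
        tracks = {
            key: CoverageTrack.from_runs({"1": [(0, 100_000, 1.0)]})
            for key in two_mark_tracks()
        }
        with pytest.raises(ValueError, match="naming"):
            run_screen(self.lncs(), [], tracks, [], ScreenConfig())

    def test_all_zero_tracks_yield_empty_mark_stage(self):
        tracks = {
            key: CoverageTrack.from_runs({"chr1": [(0, 100_000, 0.0)]})
            for key in two_mark_tracks()
        }
        with pytest.warns(UserWarning):  # empty gene list
            result = run_screen(self.lncs(), [], tracks, [], ScreenConfig())
        assert [n for _, n in result.stage_counts] == [1, 1, 0, 0]

    def test_huge_tau_empties_mark_stage(self, default_fixture):
        fix = default_fixture
        result = run_screen(
            fix.lncs, fix.genes, fix.tracks, fix.tf_peaks,
            ScreenConfig(tau=1e12),
        )
        counts = dict(result.stage_counts)
        assert counts["marks_increased"] == 0
        assert counts["tf_bound"] == 0

    @pytest.mark.parametrize(
        "kwargs", [{"w": 0}, {"tau": 1.0}, {"eps": 0.0}, {"marks": ()},
                   {"tf_min_overlap": 0}, {"key_mark": "missing"}]
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ScreenConfig(**kwargs)


class TestRunScreenCascade:
    def test_fixture_ground_truth_recovered(self, default_fixture):
        fix = default_fixture
        result = run_screen(
            fix.lncs, fix.genes, fix.tracks, fix.tf_peaks, ScreenConfig()
        )
        assert [n for _, n in result.stage_counts] == [50, 30, 10, 4]
        assert set(result.candidate_ids) == fix.manifest.planted_tf_ids
        assert set(result.survivors["marks_increased"]) == (
            fix.manifest.planted_mark_ids
        )

    def test_counts_non_increasing_and_consistent(self, default_fixture):
        fix = default_fixture
        result = run_screen(
            fix.lncs, fix.genes, fix.tracks, fix.tf_peaks, ScreenConfig()
        )
        counts = [n for _, n in result.stage_counts]
        assert counts == sorted(counts, reverse=True)
        for stage, n in result.stage_counts:
            assert len(result.survivors[stage]) == n

    def test_venn_regions_sum_to_union(self, default_fixture):
        fix = default_fixture
        result = run_screen(
            fix.lncs, fix.genes, fix.tracks, fix.tf_peaks, ScreenConfig()
        )
        union = set()
        for call in result.calls:
            if call.increased:
                union.add(call.transcript_id)
        union |= {
            tid for tid, bp in result.tf_overlap.items() if bp >= 1
        }
        assert sum(result.venn.values()) == len(union)

    def test_candidates_ranked_descending_by_key_mark(self, default_fixture):
        fix = default_fixture
        result = run_screen(
            fix.lncs, fix.genes, fix.tracks, fix.tf_peaks, ScreenConfig()
        )
        key_densities = [
            c.post_densities["H3K4me3"] for c in result.candidates
        ]
        assert key_densities == sorted(key_densities, reverse=True)

    def test_any_mark_mode_is_superset_of_all_mark_mode(self, default_fixture):
        fix = default_fixture
        strict = run_screen(
            fix.lncs, fix.genes, fix.tracks, fix.tf_peaks,
            ScreenConfig(require_all_marks=True),
        )
        loose = run_screen(
            fix.lncs, fix.genes, fix.tracks, fix.tf_peaks,
            ScreenConfig(require_all_marks=False),
        )
        assert set(strict.survivors["marks_increased"]) <= set(
            loose.survivors["marks_increased"]
        )

    def test_coding_filter_stage_drops_long_orf_transcripts(self, default_fixture):
        fix = default_fixture
        # give every transcript a harmless sequence, one survivor a 150 aa ORF
        baseline = run_screen(
            fix.lncs, fix.genes, fix.tracks, fix.tf_peaks, ScreenConfig()
        )
        victim = baseline.candidate_ids[0]
        seqs = {t.transcript_id: "CCCACC" * 200 for t in fix.lncs}
        seqs[victim] = "ATG" + "GCT" * 150 + "TAA"
        result = run_screen(
            fix.lncs, fix.genes, fix.tracks, fix.tf_peaks,
            ScreenConfig(coding_max_orf_aa=100),
            sequences=seqs,
        )
        stages = dict(result.stage_counts)
        assert stages["noncoding"] == stages["intergenic"] - 1
        assert victim not in result.candidate_ids
        assert len(result.orf_reports) == stages["intergenic"]

    def test_determinism_identical_results(self, default_fixture):
        fix = default_fixture
        r1 = run_screen(
            fix.lncs, fix.genes, fix.tracks, fix.tf_peaks, ScreenConfig()
        )
        r2 = run_screen(
            fix.lncs, fix.genes, fix.tracks, fix.tf_peaks, ScreenConfig()
        )
        assert r1.stage_counts == r2.stage_counts
        assert r1.candidates == r2.candidates
        assert r1.venn == r2.venn
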