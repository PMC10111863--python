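"""Interval algebra against brute-force oracles and format round-trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pioneerlink import intervals as gi

CHROMS = ("chr1", "chr2", "chr3")


def random_intervals(rng, n, span=100_000, max_width=2_000, chroms=CHROMS):
    start = rng.integers(0, span, n)
    width = rng.integers(1, max_width, n)
    return pd.DataFrame(
        {
            "chrom": rng.choice(chroms, n),
            "start": start,
            "end": start + width,
            "name": [f"iv{i:05d}" for i in range(n)],
        }
    )


def brute_force_overlap(query, reference):
    flags = np.zeros(len(query), dtype=bool)
    for i, q in enumerate(query.itertuples()):
        for r in reference.itertuples():
            if q.chrom == r.chrom and q.start < r.end and r.start < q.end:
                flags[i] = True
                break
    return flags


class TestIntersectAny:
    @pytest.mark.parametrize(
        "q, r, expected",
        [
            ((0, 10), (9, 20), True),  # shares base 9
            ((0, 10), (10, 20), False),  # half-open adjacency
            ((5, 6), (0, 100), True),
            ((0, 100), (5, 6), True),
        ],
    )
    def test_single_pair(self, q, r, expected):
        query = pd.DataFrame({"chrom": ["chr1"], "start": [q[0]], "end": [q[1]]})
        ref = pd.DataFrame({"chrom": ["chr1"], "start": [r[0]], "end": [r[1]]})
        assert gi.intersect_any(query, ref)[0] == expected

    def test_different_chromosomes_never_overlap(self):
        query = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100]})
        ref = pd.DataFrame({"chrom": ["chr2"], "start": [0], "end": [100]})
        assert not gi.intersect_any(query, ref)[0]

    def test_matches_bruteforce_on_random_intervals(self):
        rng = np.random.default_rng(42)
        query = random_intervals(rng, 500)
        ref = random_intervals(rng, 500)
        got = gi.intersect_any(query, ref)
        assert np.array_equal(got, brute_force_overlap(query, ref))

    def test_overlap_relation_symmetric_on_singletons(self):
        rng = np.random.default_rng(3)
        a = random_intervals(rng, 50, span=1_000)
        b = random_intervals(rng, 50, span=1_000)
        for i in range(len(a)):
            fa = gi.intersect_any(a.iloc[[i]], b.iloc[[i]])[0]
            fb = gi.intersect_any(b.iloc[[i]], a.iloc[[i]])[0]
            assert fa == fb

    def test_malformed_interval_raises_with_record_name(self):
        bad = pd.DataFrame(
            {"chrom": ["chr1"], "start": [10], "end": [10], "name": ["broken"]}
        )
        ok = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [5]})
        with pytest.raises(ValueError, match="broken"):
            gi.intersect_any(bad, ok)


class TestMergeOverlapping:
    def test_overlapping_pair_collapses(self):
        peaks = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [0, 5], "end": [10, 15]}
        )
        out = gi.merge_overlapping(peaks)
        assert out[["start", "end"]].to_numpy().tolist() == [[0, 15]]

    def test_disjoint_unchanged(self):
        peaks = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [0, 20], "end": [10, 30]}
        )
        out = gi.merge_overlapping(peaks)
        assert out[["start", "end"]].to_numpy().tolist() == [[0, 10], [20, 30]]

    def test_same_coordinates_on_different_chromosomes_stay_separate(self):
        peaks = pd.DataFrame(
            {"chrom": ["chr1", "chr2"], "start": [0, 5], "end": [10, 15]}
        )
        assert len(gi.merge_overlapping(peaks)) == 2

    def test_covered_bases_match_bruteforce_union(self):
        rng = np.random.default_rng(7)
        peaks = random_intervals(rng, 1_000, span=3_000, max_width=50)
        merged = gi.merge_overlapping(peaks)
        for chrom in CHROMS:
            cover = np.zeros(4_000, dtype=bool)
            for p in peaks[peaks["chrom"] == chrom].itertuples():
                cover[p.start : p.end] = True
            got = np.zeros(4_000, dtype=bool)
            sub = merged[merged["chrom"] == chrom]
            for p in sub.itertuples():
                assert not got[p.start : p.end].any(), "merged intervals overlap"
            for p in sub.itertuples():
                got[p.start : p.end] = True
            assert np.array_equal(cover, got)

    def test_idempotent(self):
        rng = np.random.default_rng(9)
        peaks = random_intervals(rng, 300, span=5_000, max_width=100)
        once = gi.merge_overlapping(peaks)
        twice = gi.merge_overlapping(once)
        pd.testing.assert_frame_equal(
            once.reset_index(drop=True), twice.reset_index(drop=True)
        )

    def test_merged_peak_keeps_highest_score_summit(self):
        peaks = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "start": [0, 5],
                "end": [10, 15],
                "score": [1.0, 9.0],
                "summit": [3, 12],
                "name": ["lo", "hi"],
            }
        )
        out = gi.merge_overlapping(peaks)
        assert out["summit"].iloc[0] == 12 and out["name"].iloc[0] == "hi"

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.integers(0, 200), st.integers(1, 40)), min_size=1, max_size=40
        )
    )
    def test_merge_idempotent_property(self, pairs):
        peaks = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": [s for s, _ in pairs],
                "end": [s + w for s, w in pairs],
            }
        )
        once = gi.merge_overlapping(peaks)
        twice = gi.merge_overlapping(once)
        assert once[["start", "end"]].to_numpy().tolist() == twice[
            ["start", "end"]
        ].to_numpy().tolist()


def tss_table(rows):
    return pd.DataFrame(
        rows, columns=["gene_id", "symbol", "chrom", "strand", "tss", "gene_start", "gene_end"]
    )


class TestNearestTss:
    def test_exact_hit_distance_zero(self):
        sites = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200]})
        tss = tss_table([("gA", "A", "chr1", "+", 150, 100, 5_000)])
        out = gi.nearest_tss(sites, tss)
        assert out["gene_id"].iloc[0] == "gA" and out["distance"].iloc[0] == 0

    def test_smallest_distance_wins(self):
        sites = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200]})
        tss = tss_table(
            [
                ("gA", "A", "chr1", "+", 1_150, 1_000, 2_000),
                ("gB", "B", "chr1", "+", 5_000, 5_000, 9_000),
            ]
        )
        out = gi.nearest_tss(sites, tss)
        assert out["gene_id"].iloc[0] == "gA" and out["distance"].iloc[0] == 1_000

    def test_tie_broken_by_smaller_gene_id(self):
        sites = pd.DataFrame({"chrom": ["chr1"], "start": [90], "end": [110]})  # center 100
        tss = tss_table(
            [
                ("gZ", "Z", "chr1", "+", 90, 0, 1_000),
                ("gA", "A", "chr1", "+", 110, 0, 1_000),
            ]
        )
        out = gi.nearest_tss(sites, tss)
        assert out["gene_id"].iloc[0] == "gA"

    def test_chromosome_without_tss_reports_missing(self):
        sites = pd.DataFrame({"chrom": ["chrM"], "start": [0], "end": [10]})
        tss = tss_table([("gA", "A", "chr1", "+", 150, 100, 5_000)])
        out = gi.nearest_tss(sites, tss)
        assert out["gene_id"].iloc[0] is None and np.isnan(out["distance"].iloc[0])

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(21)
        sites = random_intervals(rng, 500, span=50_000)
        tss = tss_table(
            [
                (f"g{i:03d}", f"S{i}", rng.choice(CHROMS), "+", int(rng.integers(0, 50_000)), 0, 1)
                for i in range(50)
            ]
        )
        out = gi.nearest_tss(sites, tss)
        centers = gi.interval_centers(sites)
        for i in range(len(sites)):
            cand = tss[tss["chrom"] == sites["chrom"].iloc[i]]
            if cand.empty:
                assert out["gene_id"].iloc[i] is None
                continue
            d = np.abs(cand["tss"].to_numpy() - centers[i])
            dmin = d.min()
            best = sorted(cand.loc[d == dmin, "gene_id"])[0]
            assert out["distance"].iloc[i] == dmin
            assert out["gene_id"].iloc[i] == best


class TestAnnotateSite:
    TSS = tss_table(
        [
            ("gA", "A", "chr1", "+", 10_000, 10_000, 60_000),
            ("gB", "B", "chr1", "-", 200_000, 150_000, 200_000),
        ]
    )

    @pytest.mark.parametrize(
        "start, end, expected",
        [
            (9_950, 10_050, "promoter_proximal"),  # center at the TSS
            (14_950, 15_050, "genic"),  # 5 kb into the gene body
            (500_000, 500_200, "intergenic"),
        ],
    )
    def test_labels(self, start, end, expected):
        sites = pd.DataFrame({"chrom": ["chr1"], "start": [start], "end": [end]})
        assert gi.annotate_site(sites, self.TSS)[0] == expected

    def test_gene_free_chromosome_is_intergenic(self):
        sites = pd.DataFrame({"chrom": ["chr9"], "start": [0], "end": [100]})
        assert gi.annotate_site(sites, self.TSS)[0] == "intergenic"

    def test_labels_partition_site_set(self):
        rng = np.random.default_rng(5)
        sites = random_intervals(rng, 300, span=300_000, chroms=("chr1",))
        labels = gi.annotate_site(sites, self.TSS)
        assert set(labels) <= {"promoter_proximal", "genic", "intergenic"}
        assert len(labels) == len(sites)


class TestFileFormats:
    def test_narrowpeak_roundtrip_preserves_absolute_summits(self, tmp_path):
        peaks = pd.DataFrame(
            {
                "chrom": ["chr1", "chr2"],
                "start": [100, 500],
                "end": [300, 900],
                "name": ["p1", "p2"],
                "score": [5, 7],
                "strand": [".", "."],
                "summit": [150, 700],
            }
        )
        path = tmp_path / "peaks.bed"
        gi.write_bed(peaks, path)
        back = gi.read_bed(path)
        assert back["summit"].tolist() == [150, 700]
        assert back["start"].tolist() == [100, 500]

    def test_bedgraph_roundtrip_and_signal(self, tmp_path):
        bumps = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1", "chr2"],
                "start": [0, 50, 10],
                "end": [100, 150, 20],
                "value": [2.0, 3.0, 7.0],
            }
        )
        track = gi.step_track(bumps)
        # steps non-overlapping and sorted per chromosome
        for _, grp in track.groupby("chrom"):
            assert (grp["start"].to_numpy()[1:] >= grp["end"].to_numpy()[:-1]).all()
        path = tmp_path / "cov.bedGraph"
        gi.write_bedgraph(track, path)
        back = gi.read_bedgraph(path)
        query = pd.DataFrame(
            {"chrom": ["chr1", "chr1", "chr2"], "start": [0, 40, 0], "end": [100, 120, 30]}
        )
        got = gi.interval_signal(back, query, how="sum")
        # brute force: per-base accumulation
        expected = []
        for q in query.itertuples():
            total = 0.0
            for b in bumps.itertuples():
                if b.chrom == q.chrom:
                    ov = max(0, min(q.end, b.end) - max(q.start, b.start))
                    total += ov * b.value
            expected.append(total)
        assert np.allclose(got, expected)
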