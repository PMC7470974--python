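import numpy as np
import pandas as pd
import pytest

import _oracles as oracles
from promoterome.clustering import (
    TagCluster, annotate_cc, build_consensus_clusters, call_tag_clusters,
    dominant_position, filter_supported_ctss, interquantile_bounds,
    merge_intervals, reduce_to_representative, tag_clusters_frame,
    trim_cluster,
)


def ctss_table(positions, tpms, chrom="chr1", strand="+"):
    return pd.DataFrame({
        "chrom": chrom, "pos": positions, "strand": strand,
        "count": np.maximum(np.round(tpms).astype(int), 1), "tpm": tpms})


class TestSupportFilter:
    def test_supported_in_one_sample_retained_in_all(self):
        a = ctss_table([100], [0.6])
        b = ctss_table([100], [0.1])
        out = filter_supported_ctss({"a": a, "b": b}, min_tpm=0.5)
        assert len(out["a"]) == 1 and len(out["b"]) == 1

    def test_unsupported_everywhere_dropped(self):
        a = ctss_table([100], [0.4])
        b = ctss_table([100], [0.4])
        out = filter_supported_ctss({"a": a, "b": b}, min_tpm=0.5)
        assert len(out["a"]) == 0 and len(out["b"]) == 0

    def test_zero_threshold_is_identity(self):
        a = ctss_table([100, 105], [0.01, 0.02])
        out = filter_supported_ctss({"a": a}, min_tpm=0.0)
        pd.testing.assert_frame_equal(out["a"], a)


class TestTagClusters:
    def test_gap_chaining_example(self):
        t = ctss_table([100, 115, 140], [10.0, 10.0, 10.0])
        tcs = call_tag_clusters(t, max_gap=20, min_cluster_tpm=5)
        spans = sorted((tc.start, tc.end) for tc in tcs)
        assert spans == [(100, 115), (140, 140)]

    def test_strands_never_merge(self):
        t = pd.concat([ctss_table([100], [10.0], strand="+"),
                       ctss_table([100], [10.0], strand="-")],
                      ignore_index=True)
        tcs = call_tag_clusters(t)
        assert len(tcs) == 2
        assert {tc.strand for tc in tcs} == {"+", "-"}

    def test_total_exactly_five_tpm_discarded(self):
        t = ctss_table([100], [5.0])
        assert call_tag_clusters(t, min_cluster_tpm=5) == []
        t2 = ctss_table([100], [5.01])
        assert len(call_tag_clusters(t2, min_cluster_tpm=5)) == 1

    def test_boundary_gap_exactly_max_merges(self):
        t = ctss_table([100, 120, 141], [10.0, 10.0, 10.0])
        tcs = call_tag_clusters(t, max_gap=20)
        spans = sorted((tc.start, tc.end) for tc in tcs)
        # gaps: 20 (inclusive, merges), 21 (splits)
        assert spans == [(100, 120), (141, 141)]

    def test_equals_bruteforce_chaining_on_random_instances(self, rng):
        """Chained clusters match a naive transitive single-linkage oracle on
        many random small instances."""
        for _ in range(300):
            n = rng.integers(1, 12)
            positions = np.sort(rng.choice(np.arange(1, 200), size=n,
                                           replace=False))
            max_gap = int(rng.integers(1, 40))
            t = ctss_table(positions, np.full(n, 10.0))
            tcs = call_tag_clusters(t, max_gap=max_gap, min_cluster_tpm=0,
                                    trim=False)
            got = sorted(sorted(tc.positions.tolist()) for tc in tcs)
            assert got == oracles.chain_merge(list(positions), max_gap)


class TestTrim:
    def test_cumulative_example(self):
        tc = TagCluster("s", "chr1", "+", [100, 105, 110], [10.0, 80.0, 10.0])
        out = trim_cluster(tc)
        assert (out.q_low, out.q_high, out.iq_width) == (100, 105, 6)
        assert list(out.positions) == [100, 105]

    def test_single_ctss(self):
        tc = trim_cluster(TagCluster("s", "chr1", "+", [500], [7.0]))
        assert (tc.q_low, tc.q_high, tc.iq_width) == (500, 500, 1)

    def test_uniform_ten_positions(self):
        pos = np.arange(50, 60)
        tc = trim_cluster(TagCluster("s", "chr1", "+", pos, np.full(10, 2.0)))
        assert (tc.q_low, tc.q_high, tc.iq_width) == (50, 58, 9)

    def test_idempotent_and_never_widens(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 15))
            pos = np.sort(rng.choice(np.arange(1, 500), size=n, replace=False))
            tpm = rng.uniform(0.1, 50, size=n)
            tc = TagCluster("s", "chr1", "+", pos, tpm)
            once = trim_cluster(tc)
            twice = trim_cluster(once)
            assert once.iq_width <= (tc.end - tc.start + 1)
            assert list(twice.positions) == list(once.positions)

    def test_bounds_match_scanning_oracle(self, rng):
        for _ in range(300):
            n = int(rng.integers(1, 20))
            pos = np.sort(rng.choice(np.arange(1, 300), size=n, replace=False))
            tpm = rng.uniform(0.1, 20, size=n)
            assert (interquantile_bounds(pos, tpm)
                    == oracles.quantile_bounds(pos, tpm))


class TestDominant:
    def test_tie_break_is_most_five_prime(self):
        pos = np.array([100, 110])
        tpm = np.array([5.0, 5.0])
        assert dominant_position(pos, tpm, "+") == 100
        assert dominant_position(pos, tpm, "-") == 110


class TestConsensus:
    def test_interval_merge_examples(self):
        assert merge_intervals(np.array([100, 180]), np.array([120, 200]),
                               max_gap=100) == [(100, 200)]
        assert merge_intervals(np.array([100, 221]), np.array([120, 240]),
                               max_gap=100) == [(100, 120), (221, 240)]
        # transitive chain spanning more than max_gap end to end
        assert merge_intervals(np.array([0, 90, 180]),
                               np.array([10, 100, 260]),
                               max_gap=100) == [(0, 260)]

    def test_equals_bruteforce_interval_oracle(self, rng):
        for _ in range(300):
            k = int(rng.integers(1, 8))
            starts = rng.integers(0, 400, size=k)
            ends = starts + rng.integers(0, 60, size=k)
            max_gap = int(rng.integers(0, 120))
            got = merge_intervals(starts, ends, max_gap=max_gap)
            exp = oracles.interval_merge(
                [(int(s), int(e)) for s, e in zip(starts, ends)],
                max_gap=max_gap)
            assert got == exp

    def test_expression_conservation(self):
        """Per-sample CC expression sums equal the member CTSS tpm sums."""
        a = ctss_table([100, 105, 300], [10.0, 20.0, 30.0])
        b = ctss_table([102, 305, 900], [5.0, 6.0, 50.0])
        tcs = {s: call_tag_clusters(t, min_cluster_tpm=0)
               for s, t in {"a": a, "b": b}.items()}
        ccs = build_consensus_clusters(tcs, {"a": a, "b": b})
        assert ccs["tpm_a"].sum() == pytest.approx(60.0)
        assert ccs["tpm_b"].sum() == pytest.approx(61.0)

    def test_sample_without_expression_gets_zero(self):
        a = ctss_table([100], [10.0])
        b = ctss_table([5000], [10.0])
        tcs = {s: call_tag_clusters(t, min_cluster_tpm=0)
               for s, t in {"a": a, "b": b}.items()}
        ccs = build_consensus_clusters(tcs, {"a": a, "b": b})
        assert len(ccs) == 2
        row = ccs[ccs["start"] == 100].iloc[0]
        assert row["tpm_b"] == 0.0 and row["tpm_a"] == 10.0
        assert row["tc_support_a"] and not row["tc_support_b"]


ANNOTATION = pd.DataFrame([{
    "gene_id": "g1", "chrom": "chr1", "strand": "+", "tss": 10_000,
    "gene_start": 9_999, "gene_end": 10_999,
    "utr5_start": 9_999, "utr5_end": 10_149,
    "utr3_start": 10_849, "utr3_end": 10_999,
    "exon_blocks": "9999-10299,10499-10799",
}])


def one_cc(dominant, strand="+"):
    return pd.DataFrame([{
        "cc_id": "cc1", "chrom": "chr1", "strand": strand,
        "start": dominant - 5, "end": dominant + 5,
        "dominant_pos": float(dominant), "tpm_a": 10.0,
    }])


class TestAnnotate:
    @pytest.mark.parametrize("dominant,feature,in_set", [
        (9_500, "Promoter(<=1kb)", True),     # 500 bp upstream
        (8_500, "Promoter(1-3kb)", False),    # 1500 bp upstream
        (10_100, "5'UTR", True),              # inside annotated 5'UTR
        (10_600, "Exon", False),
        (10_400, "Intron", False),
        (10_900, "3'UTR", False),
        (12_000, "Downstream(<3kb)", False),
        (90_000, "Distal intergenic", False),
    ])
    def test_feature_classes(self, dominant, feature, in_set):
        out = annotate_cc(one_cc(dominant), ANNOTATION)
        assert out["feature"].item() == feature
        assert out["promoter_set"].item() == in_set

    def test_empty_annotation_warns_distal(self):
        with pytest.warns(UserWarning, match="empty annotation"):
            out = annotate_cc(one_cc(9_500), ANNOTATION.iloc[:0])
        assert out["feature"].item() == "Distal intergenic"

    def test_representative_reduction_keeps_top_expressed(self):
        ccs = pd.DataFrame({
            "cc_id": ["c1", "c2", "c3"],
            "gene_id": ["g1", "g1", "g2"],
            "tpm_a": [5.0, 50.0, 1.0],
        })
        kept = reduce_to_representative(ccs)
        assert set(kept["cc_id"]) == {"c2", "c3"}


def test_tag_clusters_frame_columns():
    t = ctss_table([100, 105], [10.0, 30.0])
    frame = tag_clusters_frame(call_tag_clusters(t))
    assert frame.loc[0, "dominant_pos"] == 105
    assert frame.loc[0, "iq_width"] == 6
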