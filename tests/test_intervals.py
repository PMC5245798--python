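import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cobind3d.intervals import (
    AnalysisParams,
    FeatureClass,
    GenomicInterval,
    PeakSet,
    annotate_peaks,
    flanking_enhancer_density,
    match_tss_to_peaks,
    overlap_peak_sets,
)


def brute_force_classify(mid, genes, params):
    """Exhaustive per-peak scan over all gene features (oracle)."""
    prom = any(abs(mid - g.tss) <= params.promoter_window for g in genes.itertuples())
    if prom:
        return "promoter"
    for g in genes.itertuples():
        tts = g.tx_start if g.strand == "-" else g.tx_end
        if g.strand == "-":
            lo, hi = tts - params.tts_downstream, tts + params.tts_upstream
        else:
            lo, hi = tts - params.tts_upstream, tts + params.tts_downstream
        if lo <= mid <= hi:
            return "TTS"
    for g in genes.itertuples():
        if g.tx_start <= mid <= g.tx_end:
            return "intron"
    return "intergenic"


class TestGenomicInterval:
    def test_valid(self):
        iv = GenomicInterval("chr1", 10, 20, "+")
        assert len(iv) == 10
        assert iv.midpoint == 15

    @pytest.mark.parametrize("start,end", [(-1, 5), (5, 5), (9, 3)])
    def test_invalid_coords(self, start, end):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", start, end)

    def test_empty_chrom(self):
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 10)


class TestPeakSet:
    def test_sorted_and_unique(self):
        df = pd.DataFrame(
            {"chrom": ["chr2", "chr1", "chr1"], "start": [5, 100, 3], "end": [15, 150, 9]}
        )
        ps = PeakSet("x", df)
        assert ps.df["chrom"].tolist() == ["chr1", "chr1", "chr2"]
        assert ps.df["start"].tolist() == [3, 100, 5]

    def test_duplicate_ids_rejected(self):
        df = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [0, 10], "end": [5, 15], "peak_id": ["a", "a"]}
        )
        with pytest.raises(ValueError, match="duplicate"):
            PeakSet("x", df)

    def test_bed_round_trip(self, tmp_path, rng, make_peaks):
        ps = make_peaks(rng, "t", 20)
        ps.to_bed(tmp_path / "t.bed")
        back = PeakSet.from_bed(tmp_path / "t.bed", "t")
        pd.testing.assert_frame_equal(ps.df, back.df, check_dtype=False)


class TestAnnotatePeaks:
    def test_promoter_hit(self, toy_genes):
        # peak [1000,1200) and a TSS at 1100: midpoint inside +/- 1 kb
        genes = toy_genes.copy()
        genes.loc[0, ["tss", "tx_start", "tx_end"]] = [1_100, 1_100, 9_100]
        ps = PeakSet("p", pd.DataFrame({"chrom": ["chr1"], "start": [1_000], "end": [1_200]}))
        classes, _ = annotate_peaks(ps, genes)
        assert classes.iloc[0] == FeatureClass.PROMOTER.value

    def test_tts_window_downstream(self, toy_genes):
        # g2 (+ strand) ends at 126,000; 500 bp past it is in -100/+1kb window
        ps = PeakSet(
            "p", pd.DataFrame({"chrom": ["chr1"], "start": [126_400], "end": [126_600]})
        )
        classes, _ = annotate_peaks(ps, toy_genes)
        assert classes.iloc[0] == FeatureClass.TTS.value

    def test_no_genes_on_chrom_is_na(self, toy_genes):
        genes = toy_genes[toy_genes["chrom"] == "chr1"]
        ps = PeakSet(
            "p",
            pd.DataFrame(
                {"chrom": ["chr1", "chr2"], "start": [10_000, 500], "end": [10_200, 700]}
            ),
        )
        classes, fractions = annotate_peaks(ps, genes)
        by_id = dict(zip(ps.df["peak_id"], classes.to_numpy()))
        assert sorted(classes.to_numpy()) == sorted(by_id.values())
        assert (classes == FeatureClass.NA.value).sum() == 1

    def test_chrom_mismatch_errors(self, toy_genes):
        ps = PeakSet("p", pd.DataFrame({"chrom": ["1"], "start": [0], "end": [100]}))
        with pytest.raises(ValueError, match="naming mismatch"):
            annotate_peaks(ps, toy_genes)

    def test_matches_brute_force_oracle(self, rng, toy_genes):
        params = AnalysisParams()
        starts = rng.integers(0, 320_000, size=200)
        ps = PeakSet(
            "p", pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 200})
        )
        classes, fractions = annotate_peaks(ps, toy_genes, params)
        genes1 = toy_genes[toy_genes["chrom"] == "chr1"]
        mids = ps.midpoints
        expected = [brute_force_classify(m, genes1, params) for m in mids]
        assert list(classes.to_numpy()) == expected
        non_na = [c for c in expected if c != "NA"]
        assert sum(v for k, v in fractions.items() if k != "NA") == pytest.approx(1.0)

    def test_order_invariance(self, rng, toy_genes):
        starts = rng.integers(0, 320_000, size=50)
        df = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": starts,
                "end": starts + 200,
                "peak_id": [f"p{i}" for i in range(50)],
            }
        )
        a, _ = annotate_peaks(PeakSet("p", df), toy_genes)
        b, _ = annotate_peaks(PeakSet("p", df.sample(frac=1, random_state=0)), toy_genes)
        assert a.sort_index().equals(b.sort_index())


class TestOverlapPeakSets:
    def test_disjoint_chromosomes(self, rng, make_peaks):
        a = make_peaks(rng, "a", 10, chrom="chr1")
        b = make_peaks(rng, "b", 10, chrom="chr2")
        part = overlap_peak_sets(a, b)
        assert part.a_both == 0 and part.b_both == 0
        assert part.cobound_merged_sites == 0

    def test_matches_all_pairs_oracle(self, rng, make_peaks):
        a = make_peaks(rng, "a", 50, span=1_000_000, width=2_000)
        b = make_peaks(rng, "b", 50, span=1_000_000, width=2_000)
        part = overlap_peak_sets(a, b)

        def hits(q, s):
            return [
                any(qs < se and qe > ss for ss, se in zip(s.df["start"], s.df["end"]))
                for qs, qe in zip(q.df["start"], q.df["end"])
            ]

        a_hits, b_hits = hits(a, b), hits(b, a)
        assert part.a_both == sum(a_hits)
        assert part.b_only == len(b) - sum(b_hits)
        assert part.a_only + part.a_both == len(a)

    def test_merged_count_symmetric(self, rng, make_peaks):
        a = make_peaks(rng, "a", 40, width=1_500)
        b = make_peaks(rng, "b", 40, width=1_500)
        ab, ba = overlap_peak_sets(a, b), overlap_peak_sets(b, a)
        assert ab.merged_sites == ba.merged_sites
        assert ab.cobound_merged_sites == ba.cobound_merged_sites

    def test_empty_sets(self):
        empty = PeakSet("e", pd.DataFrame(columns=["chrom", "start", "end"]))
        part = overlap_peak_sets(empty, empty)
        assert part.a_only == part.b_both == 0


class TestFlankingDensity:
    def test_single_gene_gets_all(self, toy_genes, rng, make_peaks):
        genes = toy_genes.iloc[[0]]
        peaks = make_peaks(rng, "p", 5, chrom="chr1")
        counts, means = flanking_enhancer_density(genes, peaks)
        assert counts["g0"] == 5
        assert means["__all__"] == 5.0

    def test_matches_argmin_oracle(self, rng):
        genes = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(10)],
                "chrom": "chr1",
                "strand": "+",
                "tss": np.sort(rng.choice(np.arange(1_000, 999_000), 10, replace=False)),
            }
        )
        genes["tx_start"] = genes["tss"]
        genes["tx_end"] = genes["tss"] + 1_000
        starts = rng.integers(0, 999_000, size=30)
        peaks = PeakSet("p", pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 200}))
        counts, _ = flanking_enhancer_density(genes, peaks)
        oracle = {g: 0 for g in genes["gene_id"]}
        for m in peaks.midpoints:
            d = np.abs(m - genes["tss"].to_numpy())
            cands = np.flatnonzero(d == d.min())
            # tie -> smaller TSS coordinate
            win = cands[np.argmin(genes["tss"].to_numpy()[cands])]
            oracle[genes["gene_id"].iloc[win]] += 1
        assert counts.to_dict() == oracle

    def test_conserves_peaks(self, toy_genes, rng, make_peaks):
        peaks = make_peaks(rng, "p", 25, chrom="chr1")
        counts, _ = flanking_enhancer_density(toy_genes, peaks)
        assert counts.sum() == 25  # all peaks on a chromosome bearing genes


class TestMatchTss:
    def test_exact_center_matches(self, toy_genes):
        ps = PeakSet("p", pd.DataFrame({"chrom": ["chr1"], "start": [9_900], "end": [10_100]}))
        res = match_tss_to_peaks(toy_genes, ps)
        assert "g0" in res.matched

    def test_window_boundary_exclusive(self, toy_genes):
        # center 2,001 bp from the g0 TSS at 10,000
        ps = PeakSet("p", pd.DataFrame({"chrom": ["chr1"], "start": [11_901], "end": [12_101]}))
        res = match_tss_to_peaks(toy_genes.iloc[[0]], ps, AnalysisParams(tss_match_window=2_000))
        assert res.matched == []
        # at exactly 2,000 it matches
        ps2 = PeakSet("p", pd.DataFrame({"chrom": ["chr1"], "start": [11_900], "end": [12_100]}))
        assert match_tss_to_peaks(toy_genes.iloc[[0]], ps2).matched == ["g0"]

    def test_matches_window_scan_oracle(self, rng, toy_genes):
        starts = rng.integers(0, 320_000, size=60)
        ps = PeakSet("p", pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 200}))
        res = match_tss_to_peaks(toy_genes, ps)
        mids = ps.midpoints
        for g in toy_genes.itertuples():
            if g.chrom != "chr1":
                expect = False
            else:
                expect = bool(np.any(np.abs(mids - g.tss) <= 2_000))
            assert (g.gene_id in res.matched) == expect


@settings(max_examples=50, deadline=None)
@given(
    st.lists(
        st.tuples(st.integers(0, 10_000), st.integers(1, 500)), min_size=1, max_size=30
    )
)
def test_overlap_partition_exhaustive_property(raw):
    """a_only + a_both == |a| for arbitrary interval sets."""
    df = pd.DataFrame(
        {"chrom": "chr1", "start": [s for s, _ in raw], "end": [s + w for s, w in raw]}
    )
    a = PeakSet("a", df)
    b = PeakSet("b", df.iloc[: len(df) // 2 + 1])
    part = overlap_peak_sets(a, b)
    assert part.a_only + part.a_both == len(a)
    assert part.b_only + part.b_both == len(b)
    assert part.cobound_merged_sites <= part.merged_sites
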