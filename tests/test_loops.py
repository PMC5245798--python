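from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cobind3d import contacts, loops
from cobind3d.contacts import bin_pairs, fit_background
from cobind3d.intervals import PeakSet
from cobind3d.loops import (
    AnchorEnrichmentEdge,
    anchor_enrichment,
    call_interactions,
    export_network,
    read_network,
    score_differential,
)
from cobind3d.synth import LoopSpec, SimulationConfig, simulate_contact_reads


def binom_upper_tail_exact(n, p_num, p_den, o):
    """P(X >= o) for X ~ Binomial(n, p_num/p_den), rational arithmetic."""
    from math import comb

    p = Fraction(p_num, p_den)
    return float(
        sum(Fraction(comb(n, k)) * p**k * (1 - p) ** (n - k) for k in range(o, n + 1))
    )


@pytest.fixture(scope="module")
def loop_sim():
    """20 loops planted at 5x background, depth 1e6, 25 kb bins."""
    rng = np.random.default_rng(0)
    n_bins = 400
    loop_list, used = [], []
    while len(loop_list) < 20:
        b1 = int(rng.integers(5, n_bins - 60))
        d = int(rng.integers(5, 51))
        b2 = b1 + d
        if any(abs(b1 - a) < 3 and abs(b2 - c) < 3 for a, c in used):
            continue
        used.append((b1, b2))
        loop_list.append(LoopSpec(b1 * 25_000 + 100, b2 * 25_000 + 100, 5.0, 1.0))
    cfg = SimulationConfig(
        seed=11, chrom_length=10_000_000, bin_size=25_000, depth=1_000_000, loops=loop_list
    )
    pairs, truth = simulate_contact_reads(cfg)
    out = {}
    for cond in ("cond1", "cond2"):
        mats, _ = bin_pairs(pairs[cond], cfg.bin_size, cfg.chrom_sizes)
        out[cond] = (mats["chr1"], fit_background(mats["chr1"]))
    out["planted"] = {tuple(sorted((b1, b2))) for b1, b2 in used}
    out["config"] = cfg
    return out


class TestBinomialTail:
    def test_worked_value(self):
        # Binom(20, 0.1), P(X >= 5) by direct rational summation
        want = binom_upper_tail_exact(20, 1, 10, 5)
        assert want == pytest.approx(0.0432, abs=5e-5)
        got = float(stats.binom.sf(4, 20, 0.1))
        assert got == pytest.approx(want, abs=1e-12)

    def test_matches_exhaustive_summation(self):
        for n in (1, 7, 23, 50):
            for p_num, p_den in ((1, 10), (1, 3), (9, 10)):
                for o in range(0, n + 1, max(1, n // 5)):
                    want = binom_upper_tail_exact(n, p_num, p_den, o)
                    got = float(stats.binom.sf(o - 1, n, p_num / p_den))
                    assert abs(got - want) < 1e-12

    def test_monotone_in_observed(self):
        p = stats.binom.sf(np.arange(0, 30) - 1, 30, 0.2)
        assert np.all(np.diff(p) <= 0)


class TestCallInteractions:
    def test_zero_observed_p_one(self, loop_sim):
        m, bg = loop_sim["cond1"]
        calls = call_interactions(m, bg, max_distance=60)
        # every tested pair with o = 0 must have p = 1; check via the caller's
        # own p-value vector against a recomputation
        i, j = np.triu_indices(m.n_bins, k=2)
        keep = ((j - i) <= 60) & ~(bg.mask[i] | bg.mask[j])
        o = m.counts[i, j][keep]
        assert np.all(calls.all_p_values[o == 0] == 1.0)

    def test_planted_recovery(self, loop_sim):
        m, bg = loop_sim["cond1"]
        calls = call_interactions(m, bg, min_separation=2, max_distance=100)
        called = set(zip(calls.df["bin1"], calls.df["bin2"]))
        planted = loop_sim["planted"]
        tp = len(called & planted)
        assert tp / len(planted) >= 0.9
        assert (len(called) - tp) / max(len(called), 1) <= 0.15

    def test_calls_sorted_by_p(self, loop_sim):
        m, bg = loop_sim["cond1"]
        calls = call_interactions(m, bg, max_distance=100)
        p = calls.df["p_value"].dropna().to_numpy()
        assert np.all(np.diff(p) >= 0)
        assert (calls.df["q_value"].dropna() >= calls.df["p_value"].dropna()).all()

    def test_mismatched_background_errors(self, loop_sim):
        m, _ = loop_sim["cond1"]
        other = contacts.ContactMatrix("chr1", 25_000, np.zeros((10, 10)))
        bg_small = fit_background(
            contacts.ContactMatrix("chr1", 25_000, np.ones((10, 10)))
        )
        with pytest.raises(ValueError, match="binning"):
            call_interactions(m, bg_small)

    def test_bedpe_export(self, loop_sim, tmp_path):
        m, bg = loop_sim["cond1"]
        calls = call_interactions(m, bg, max_distance=100)
        calls.to_bedpe(tmp_path / "calls.bedpe")
        out = pd.read_csv(tmp_path / "calls.bedpe", sep="\t", header=None)
        assert len(out) == len(calls)
        assert (out[0] == "chr1").all()


class TestScoreDifferential:
    def test_identical_conditions_score_zero(self, loop_sim):
        m, bg = loop_sim["cond1"]
        calls = call_interactions(m, bg, max_distance=100)
        scored = score_differential(calls, m, bg)
        assert np.allclose(scored["diff_score"].dropna(), 0.0)
        assert (scored["category"].isin(["unchanged", "unscored"])).all()

    def test_planted_asymmetry_scored(self, loop_sim):
        # loops are 5x in condition 1 and 1x in condition 2
        m1, bg1 = loop_sim["cond1"]
        m2, bg2 = loop_sim["cond2"]
        calls = call_interactions(m1, bg1, max_distance=100)
        scored = score_differential(calls, m2, bg2)
        planted = loop_sim["planted"]
        rows = scored[[tuple(p) in planted for p in zip(scored["bin1"], scored["bin2"])]]
        assert len(rows) >= 18
        # expect roughly log2(5) ~ 2.3; accept a generous band
        assert rows["diff_score"].median() == pytest.approx(np.log2(5), abs=0.8)
        assert (rows["category"] == "stronger_in_1").mean() >= 0.9


def _toy_calls(n=30):
    rng = np.random.default_rng(5)
    b1 = rng.integers(0, 50, size=n)
    b2 = b1 + rng.integers(3, 20, size=n)
    bs = 10_000
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "bin1": b1,
            "bin2": b2,
            "start1": b1 * bs,
            "end1": (b1 + 1) * bs,
            "start2": b2 * bs,
            "end2": (b2 + 1) * bs,
        }
    )


class TestAnchorEnrichment:
    def test_saturated_marginal(self):
        calls = _toy_calls()
        everything = PeakSet(
            "all", pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [800_000]})
        )
        sparse = PeakSet(
            "some",
            pd.DataFrame({"chrom": "chr1", "start": [5_000, 105_000], "end": [6_000, 106_000]}),
        )
        edge = anchor_enrichment(calls, everything, sparse)
        assert edge.k_source == edge.n_loops
        assert edge.observed == edge.n_target
        assert edge.fold == pytest.approx(1.0)
        assert edge.p_value == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        calls = _toy_calls()
        rng = np.random.default_rng(9)
        fa = rng.integers(0, 600_000, size=15)
        fb = rng.integers(0, 600_000, size=15)
        a = PeakSet("a", pd.DataFrame({"chrom": "chr1", "start": fa, "end": fa + 500}))
        b = PeakSet("b", pd.DataFrame({"chrom": "chr1", "start": fb, "end": fb + 500}))
        edge = anchor_enrichment(calls, a, b)

        def touches(row_s, row_e, fs):
            return any(row_s < e and row_e > s for s, e in zip(fs.df["start"], fs.df["end"]))

        k = K = n = 0
        for r in calls.itertuples():
            a1 = touches(r.start1, r.end1, a)
            a2 = touches(r.start2, r.end2, a)
            b1 = touches(r.start1, r.end1, b)
            b2 = touches(r.start2, r.end2, b)
            K += a1 or a2
            n += b1 or b2
            k += (a1 and b2) or (a2 and b1)
        assert (edge.k_source, edge.n_target, edge.observed) == (K, n, k)

    def test_self_pair_requires_both_ends(self):
        calls = _toy_calls()
        f = PeakSet(
            "f",
            pd.DataFrame(
                {
                    "chrom": "chr1",
                    "start": calls["start1"].to_numpy()[:10] + 100,
                    "end": calls["start1"].to_numpy()[:10] + 400,
                }
            ),
        )
        edge = anchor_enrichment(calls, f, f)
        both = 0
        for r in calls.itertuples():
            t1 = any(r.start1 < e and r.end1 > s for s, e in zip(f.df["start"], f.df["end"]))
            t2 = any(r.start2 < e and r.end2 > s for s, e in zip(f.df["start"], f.df["end"]))
            both += t1 and t2
        assert edge.observed == both

    def test_different_assembly_errors(self):
        calls = _toy_calls()
        f = PeakSet("f", pd.DataFrame({"chrom": ["scaffold_9"], "start": [0], "end": [100]}))
        with pytest.raises(ValueError, match="assembly"):
            anchor_enrichment(calls, f, f)

    def test_random_features_never_anticonservative(self):
        # The opposite-ends statistic is conservative against marginals that
        # count either end, so under random features p-values are
        # stochastically >= uniform: the nominal error rate is an upper
        # bound, and p must not pile up near zero.
        calls = _toy_calls(60)
        rng = np.random.default_rng(77)
        ps = []
        for _ in range(200):
            fa = rng.integers(0, 700_000, size=12)
            fb = rng.integers(0, 700_000, size=12)
            a = PeakSet("a", pd.DataFrame({"chrom": "chr1", "start": fa, "end": fa + 2_000}))
            b = PeakSet("b", pd.DataFrame({"chrom": "chr1", "start": fb, "end": fb + 2_000}))
            ps.append(anchor_enrichment(calls, a, b).p_value)
        ps = np.asarray(ps)
        assert (ps < 0.05).mean() <= 0.075  # nominal + 3 binomial SE
        assert ps.mean() >= 0.4


class TestNetworkExport:
    def _edges(self):
        return [
            AnchorEnrichmentEdge("tfA", "tfB", 100, 40, 30, 20, 1.2e-5),
            AnchorEnrichmentEdge("tfA", "tfA", 100, 40, 40, 25, 3.3e-8),
            AnchorEnrichmentEdge("tfB", "tfC", 100, 30, 10, 2, 0.7),
        ]

    def test_empty_edge_list(self, tmp_path):
        export_network([], tmp_path / "net.tsv")
        df = pd.read_csv(tmp_path / "net.tsv", sep="\t")
        assert len(df) == 0
        assert "neg_log10_p" in df.columns

    def test_rows_and_columns(self, tmp_path):
        export_network(self._edges(), tmp_path / "net.tsv")
        df = pd.read_csv(tmp_path / "net.tsv", sep="\t")
        assert len(df) == 3
        assert not df.isna().any().any()

    def test_round_trip(self, tmp_path):
        edges = self._edges()
        export_network(edges, tmp_path / "net.tsv")
        back = read_network(tmp_path / "net.tsv")
        assert back == edges
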