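"""Significant-interaction (loop) calling, differential scoring, and anchor
feature enrichment.

Calls are carried as a DataFrame (one row per anchor-bin pair) inside an
:class:`InteractionCalls` wrapper; BEDPE and full-TSV exports are provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from cobind3d.cobinding import hypergeometric_overlap
from cobind3d.contacts import BackgroundModel, ContactMatrix
from cobind3d.intervals import PeakSet, intersects_any

__all__ = [
    "InteractionCalls",
    "AnchorEnrichmentEdge",
    "call_interactions",
    "score_differential",
    "anchor_enrichment",
    "export_network",
    "read_network",
]

CALL_COLUMNS = [
    "chrom",
    "bin1",
    "bin2",
    "start1",
    "end1",
    "start2",
    "end2",
    "observed",
    "trials",
    "success_prob",
    "p_value",
    "q_value",
    "strength1",
    "flagged",
]


@dataclass
class InteractionCalls:
    """Significant interaction calls plus test-wide context.

    ``df`` holds the significant calls (q < q_cutoff, sorted by p);
    ``all_p_values`` the p-values of every tested pair (for calibration);
    ``n_tested`` the number of tested pairs.
    """

    df: pd.DataFrame
    n_tested: int
    q_cutoff: float
    all_p_values: np.ndarray

    def __len__(self) -> int:
        return len(self.df)

    def to_bedpe(self, path: str | Path) -> None:
        d = self.df
        out = pd.DataFrame(
            {
                "chrom1": d["chrom"],
                "start1": d["start1"],
                "end1": d["end1"],
                "chrom2": d["chrom"],
                "start2": d["start2"],
                "end2": d["end2"],
                "name": [f"loop_{i}" for i in range(len(d))],
                "score": -np.log10(np.maximum(d["q_value"], 1e-300)),
            }
        )
        out.to_csv(path, sep="\t", header=False, index=False)

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def call_interactions(
    matrix: ContactMatrix,
    background: BackgroundModel,
    min_separation: int = 2,
    max_distance: int | None = None,
    q_cutoff: float = 0.05,
) -> InteractionCalls:
    """Cumulative-binomial interaction caller.

    For each candidate bin pair (i, j) with |i - j| >= min_separation (and
    <= max_distance if given), both bins unmasked: trials n = total contacts
    with an end in bin i plus total with an end in bin j; success probability
    p_s = expected(i, j) / n; p = P(X >= observed) for X ~ Binomial(n, p_s).
    Benjamini-Hochberg q-values are computed over all tested pairs; pairs
    with zero expectation but nonzero observation are flagged (p/q NaN) and
    kept out of the correction.
    """
    if background.n_bins != matrix.n_bins:
        raise ValueError("background was not fitted on this matrix binning")
    n = matrix.n_bins
    i, j = np.triu_indices(n, k=max(int(min_separation), 1))
    if max_distance is not None:
        keep = (j - i) <= max_distance
        i, j = i[keep], j[keep]
    unmasked = ~(background.mask[i] | background.mask[j])
    i, j = i[unmasked], j[unmasked]

    o = matrix.counts[i, j]
    e = background.expected[i, j]
    T = matrix.bin_totals
    trials = (T[i] + T[j]).astype(np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_s = np.where(trials > 0, e / trials, 0.0)
    p_s = np.clip(p_s, 0.0, 1.0)

    flagged = (e <= 0) & (o > 0)
    testable = ~flagged & (trials > 0)
    p = np.full(len(i), np.nan)
    p[testable] = stats.binom.sf(o[testable] - 1, trials[testable], p_s[testable])
    p[testable & (o == 0)] = 1.0

    q = np.full(len(i), np.nan)
    if testable.any():
        q[testable] = stats.false_discovery_control(p[testable], method="bh")

    sig = flagged | (testable & (q < q_cutoff))
    bs = matrix.bin_size
    df = pd.DataFrame(
        {
            "chrom": matrix.chrom,
            "bin1": i[sig],
            "bin2": j[sig],
            "start1": i[sig] * bs,
            "end1": (i[sig] + 1) * bs,
            "start2": j[sig] * bs,
            "end2": (j[sig] + 1) * bs,
            "observed": o[sig].astype(np.int64),
            "trials": trials[sig],
            "success_prob": p_s[sig],
            "p_value": p[sig],
            "q_value": q[sig],
            "strength1": np.where(e[sig] > 0, o[sig] / np.where(e[sig] > 0, e[sig], 1.0), np.inf),
            "flagged": flagged[sig],
        }
    )
    df = df.sort_values("p_value", kind="mergesort", na_position="last").reset_index(drop=True)
    return InteractionCalls(
        df=df, n_tested=int(testable.sum()), q_cutoff=q_cutoff, all_p_values=p[testable]
    )


def score_differential(
    calls: InteractionCalls,
    other_matrix: ContactMatrix,
    other_background: BackgroundModel,
    pseudocount: float = 0.1,
    unchanged_band: float = 0.58,
) -> pd.DataFrame:
    """Score calls against the other condition's reads.

    score = log2((o1/e1 + psi) / (o2/e2 + psi)); |score| < ``unchanged_band``
    (default 0.58 ~ 1.5-fold) is "unchanged", otherwise stronger_in_1 /
    stronger_in_2.  Returns a copy of the call table with columns observed2,
    strength2, diff_score, category.
    """
    d = calls.df
    if len(d) and (
        other_matrix.bin_size != other_background.bin_size
        or other_matrix.n_bins != other_background.n_bins
    ):
        raise ValueError("other condition matrix/background binning mismatch")
    if len(d) and (d["bin2"].max() >= other_matrix.n_bins):
        raise ValueError("calls fall outside the other condition's binning")
    out = d.copy()
    b1 = d["bin1"].to_numpy()
    b2 = d["bin2"].to_numpy()
    o2 = other_matrix.counts[b1, b2]
    e2 = other_background.expected[b1, b2]
    with np.errstate(invalid="ignore", divide="ignore"):
        s2 = np.where(e2 > 0, o2 / np.where(e2 > 0, e2, 1.0), np.nan)
    s1 = d["strength1"].to_numpy()
    score = np.log2((s1 + pseudocount) / (s2 + pseudocount))
    cat = np.where(
        np.isnan(score),
        "unscored",
        np.where(
            score >= unchanged_band,
            "stronger_in_1",
            np.where(score <= -unchanged_band, "stronger_in_2", "unchanged"),
        ),
    )
    out["observed2"] = o2.astype(np.int64)
    out["strength2"] = s2
    out["diff_score"] = score
    out["category"] = cat
    return out


@dataclass
class AnchorEnrichmentEdge:
    """Hypergeometric enrichment of a feature pair at opposite loop ends."""

    source: str
    target: str
    n_loops: int  # N: universe
    k_source: int  # K: loops touching the source set (either end)
    n_target: int  # n: loops touching the target set (either end)
    observed: int  # k: loops with opposite ends touching source and target
    p_value: float

    @property
    def expected(self) -> float:
        return self.k_source * self.n_target / self.n_loops if self.n_loops else float("nan")

    @property
    def fold(self) -> float:
        e = self.expected
        return self.observed / e if e and e > 0 else float("nan")


def _touch_masks(calls_df: pd.DataFrame, features: PeakSet) -> tuple[np.ndarray, np.ndarray]:
    """(end1 touches, end2 touches) for each call row (>=1 bp anchor overlap)."""
    t1 = np.zeros(len(calls_df), dtype=bool)
    t2 = np.zeros(len(calls_df), dtype=bool)
    fdf = features.df
    for chrom, sub in calls_df.groupby("chrom"):
        fsub = fdf[fdf["chrom"] == chrom]
        fs, fe = fsub["start"].to_numpy(), fsub["end"].to_numpy()
        idx = sub.index.to_numpy()
        t1[idx] = intersects_any(sub["start1"].to_numpy(), sub["end1"].to_numpy(), fs, fe)
        t2[idx] = intersects_any(sub["start2"].to_numpy(), sub["end2"].to_numpy(), fs, fe)
    return t1, t2


def anchor_enrichment(
    calls: InteractionCalls | pd.DataFrame,
    features_a: PeakSet,
    features_b: PeakSet,
) -> AnchorEnrichmentEdge:
    """Do loops connect features_a at one end to features_b at the other
    more often than chance?

    Universe N = all calls; K = calls touching a (either end); n = calls
    touching b; k = calls whose opposite ends touch a and b (either
    orientation).  For a single set tested against itself, k requires both
    ends to touch.  p from the upper-tail hypergeometric.
    """
    d = calls.df if isinstance(calls, InteractionCalls) else calls
    if len(d) == 0:
        raise ValueError("no interaction calls provided")
    call_chroms = set(d["chrom"].unique())
    for fs in (features_a, features_b):
        if fs.chroms and not (fs.chroms & call_chroms):
            raise ValueError(
                f"feature set {fs.name!r} shares no chromosome with the calls; "
                "different assembly?"
            )
    d = d.reset_index(drop=True)
    a1, a2 = _touch_masks(d, features_a)
    same_set = features_a is features_b or (
        features_a.name == features_b.name and features_a.df.equals(features_b.df)
    )
    if same_set:
        b1, b2 = a1, a2
        k = int((a1 & a2).sum())
    else:
        b1, b2 = _touch_masks(d, features_b)
        k = int(((a1 & b2) | (a2 & b1)).sum())
    N = len(d)
    K = int((a1 | a2).sum())
    n = int((b1 | b2).sum())
    res = hypergeometric_overlap(N, K, n, min(k, min(K, n)))
    return AnchorEnrichmentEdge(
        source=features_a.name,
        target=features_b.name,
        n_loops=N,
        k_source=K,
        n_target=n,
        observed=k,
        p_value=res.p_value,
    )


_NETWORK_COLUMNS = [
    "source",
    "target",
    "n_loops",
    "k_source",
    "n_target",
    "observed",
    "expected",
    "fold",
    "p_value",
    "neg_log10_p",
]


def export_network(edges: list[AnchorEnrichmentEdge], path: str | Path) -> None:
    """Write an edge table loadable by standard network tools (Cytoscape etc.)."""
    rows = [
        (
            e.source,
            e.target,
            e.n_loops,
            e.k_source,
            e.n_target,
            e.observed,
            e.expected,
            e.fold,
            e.p_value,
            -np.log10(max(e.p_value, 1e-300)),
        )
        for e in edges
    ]
    pd.DataFrame(rows, columns=_NETWORK_COLUMNS).to_csv(path, sep="\t", index=False)


def read_network(path: str | Path) -> list[AnchorEnrichmentEdge]:
    df = pd.read_csv(path, sep="\t")
    return [
        AnchorEnrichmentEdge(
            source=r.source,
            target=r.target,
            n_loops=int(r.n_loops),
            k_source=int(r.k_source),
            n_target=int(r.n_target),
            observed=int(r.observed),
            p_value=float(r.p_value),
        )
        for r in df.itertuples()
    ]
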