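"""Genomic interval model, annotation, overlap partitioning and TSS assignment.

Coordinates are 0-based, half-open throughout ([start, end)); BED files are
read and written without shifting. A peak's "position" for all windowed tests
is its integer midpoint, floor((start + end) / 2).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AnalysisParams",
    "FeatureClass",
    "GenomicInterval",
    "GeneAnnotation",
    "PeakSet",
    "OverlapPartition",
    "TssMatchResult",
    "annotate_peaks",
    "overlap_peak_sets",
    "flanking_enhancer_density",
    "match_tss_to_peaks",
    "read_gene_table",
    "write_gene_table",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval with optional strand and score."""

    chrom: str
    start: int
    end: int
    strand: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"strand must be '+', '-' or None, got {self.strand!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene with a TSS and transcript extent (tx_start <= tss <= tx_end)."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tx_start: int
    tx_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (self.tx_start <= self.tss <= self.tx_end):
            raise ValueError(
                f"{self.gene_id}: require tx_start <= tss <= tx_end, got "
                f"{self.tx_start}, {self.tss}, {self.tx_end}"
            )


class FeatureClass(str, enum.Enum):
    """Mutually exclusive peak annotation classes (priority order)."""

    PROMOTER = "promoter"
    TTS = "TTS"
    EXON = "exon"
    INTRON = "intron"
    INTERGENIC = "intergenic"
    NA = "NA"


@dataclass
class AnalysisParams:
    """Shared analysis constants.

    Defaults: promoters are TSS +/- 1 kb; TSS matching uses a 2 kb window;
    TTS windows run -100 bp/+1 kb past the transcript end (strand-oriented);
    permutation nulls use 1,000 iterations; tag counts are normalized to a
    10M-read library; knockdown classes at 3- and 10-fold; metagene profiles
    use 200 kb flanks with 175 bins per quartile.
    """

    promoter_window: int = 1_000
    tss_match_window: int = 2_000
    tts_upstream: int = 100
    tts_downstream: int = 1_000
    n_permutations: int = 1_000
    norm_depth: float = 10_000_000.0
    fold_thresholds: tuple[float, float] = (3.0, 10.0)
    padj_cutoff: float = 0.05
    correlation_cutoff: float = 0.5
    metagene_flank: int = 200_000
    bins_per_quartile: int = 175
    tad_bin_size: int = 25_000

    def __post_init__(self) -> None:
        for name in (
            "promoter_window",
            "tss_match_window",
            "tts_downstream",
            "n_permutations",
            "norm_depth",
            "padj_cutoff",
            "metagene_flank",
            "tad_bin_size",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.bins_per_quartile < 1:
            raise ValueError("bins_per_quartile must be >= 1")


_PEAK_COLUMNS = ["chrom", "start", "end", "peak_id", "score", "strand"]


class PeakSet:
    """A named, coordinate-sorted collection of peaks with unique ids.

    Backed by a DataFrame with columns ``chrom, start, end, peak_id, score,
    strand``.  Optional per-peak tag counts (one column per condition, indexed
    by peak_id) and per-condition library totals support normalization.
    """

    def __init__(
        self,
        name: str,
        df: pd.DataFrame,
        tag_counts: pd.DataFrame | None = None,
        library_totals: Mapping[str, float] | None = None,
    ) -> None:
        df = df.copy()
        for col in ("chrom", "start", "end"):
            if col not in df.columns:
                raise ValueError(f"peak table missing column {col!r}")
        if "peak_id" not in df.columns:
            df["peak_id"] = [f"{name}_{i}" for i in range(len(df))]
        if "score" not in df.columns:
            df["score"] = 0.0
        if "strand" not in df.columns:
            df["strand"] = "."
        df = df[_PEAK_COLUMNS]
        if (df["start"] < 0).any() or (df["start"] >= df["end"]).any():
            raise ValueError("peaks must satisfy 0 <= start < end")
        if df["peak_id"].duplicated().any():
            dup = df.loc[df["peak_id"].duplicated(), "peak_id"].iloc[0]
            raise ValueError(f"duplicate peak id {dup!r}")
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
        df = df.reset_index(drop=True)
        self.name = name
        self.df = df
        self.tag_counts = None
        self.library_totals = dict(library_totals) if library_totals else None
        if tag_counts is not None:
            tag_counts = tag_counts.reindex(df["peak_id"])
            if tag_counts.isna().any().any():
                raise ValueError("tag_counts missing entries for some peak ids")
            if (tag_counts < 0).any().any():
                raise ValueError("tag counts must be >= 0")
            self.tag_counts = tag_counts

    def __len__(self) -> int:
        return len(self.df)

    @property
    def midpoints(self) -> np.ndarray:
        return ((self.df["start"].to_numpy() + self.df["end"].to_numpy()) // 2)

    @property
    def chroms(self) -> set[str]:
        return set(self.df["chrom"].unique())

    @classmethod
    def from_intervals(cls, name: str, intervals: Iterable[GenomicInterval]) -> "PeakSet":
        rows = [
            (iv.chrom, iv.start, iv.end, f"{name}_{i}", iv.score or 0.0, iv.strand or ".")
            for i, iv in enumerate(intervals)
        ]
        return cls(name, pd.DataFrame(rows, columns=_PEAK_COLUMNS))

    @classmethod
    def from_bed(cls, path: str | Path, name: str | None = None) -> "PeakSet":
        """Read a BED/narrowPeak file (first 6 columns used, extras ignored)."""
        path = Path(path)
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        df = df.iloc[:, : min(6, df.shape[1])]
        df.columns = _PEAK_COLUMNS[: df.shape[1]]
        return cls(name or path.stem, df)

    def to_bed(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", header=False, index=False)

    def subset(self, peak_ids: Sequence[str]) -> "PeakSet":
        wanted = set(peak_ids)
        mask = self.df["peak_id"].isin(wanted)
        tags = self.tag_counts.loc[self.df.loc[mask, "peak_id"]] if self.tag_counts is not None else None
        return PeakSet(self.name, self.df[mask], tags, self.library_totals)


# ---------------------------------------------------------------------------
# gene table I/O

_GENE_COLUMNS = ["gene_id", "chrom", "strand", "tss", "tx_start", "tx_end"]


def genes_to_frame(genes) -> pd.DataFrame:
    """Normalize a gene list (GeneAnnotation sequence or DataFrame)."""
    if isinstance(genes, pd.DataFrame):
        missing = [c for c in _GENE_COLUMNS if c not in genes.columns]
        if missing:
            raise ValueError(f"gene table missing columns {missing}")
        return genes
    rows = [(g.gene_id, g.chrom, g.strand, g.tss, g.tx_start, g.tx_end) for g in genes]
    return pd.DataFrame(rows, columns=_GENE_COLUMNS)


def read_gene_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _GENE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gene table {path} missing columns {missing}")
    return df


def write_gene_table(df: pd.DataFrame, path: str | Path) -> None:
    df[_GENE_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# interval machinery


def _merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge overlapping (>=1 bp shared) intervals; inputs need not be sorted."""
    if len(starts) == 0:
        return starts, ends
    order = np.argsort(starts, kind="mergesort")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s < out_e[-1]:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.asarray(out_s), np.asarray(out_e)


def _points_in_intervals(points: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Membership of each point in a merged, sorted interval set."""
    if len(starts) == 0:
        return np.zeros(len(points), dtype=bool)
    idx = np.searchsorted(starts, points, side="right") - 1
    ok = idx >= 0
    hit = np.zeros(len(points), dtype=bool)
    hit[ok] = points[ok] < ends[idx[ok]]
    return hit


def intersects_any(
    q_starts: np.ndarray, q_ends: np.ndarray, s_starts: np.ndarray, s_ends: np.ndarray
) -> np.ndarray:
    """For each query interval, whether it shares >= 1 bp with any subject.

    Subjects need not be disjoint.  O((n+m) log m) via prefix max of ends.
    """
    if len(s_starts) == 0 or len(q_starts) == 0:
        return np.zeros(len(q_starts), dtype=bool)
    order = np.argsort(s_starts, kind="mergesort")
    s_starts, s_ends = s_starts[order], s_ends[order]
    cummax_end = np.maximum.accumulate(s_ends)
    # candidates: subjects with start < q_end; overlap iff max end among them > q_start
    n_cand = np.searchsorted(s_starts, q_ends, side="left")
    hit = np.zeros(len(q_starts), dtype=bool)
    nz = n_cand > 0
    hit[nz] = cummax_end[n_cand[nz] - 1] > q_starts[nz]
    return hit


def _check_chrom_compat(peak_chroms: set[str], gene_chroms: set[str]) -> None:
    if peak_chroms and gene_chroms and not (peak_chroms & gene_chroms):
        raise ValueError(
            "no chromosome shared between peaks and genes; naming mismatch? "
            f"peaks use {sorted(peak_chroms)[:5]}, genes use {sorted(gene_chroms)[:5]}"
        )


# ---------------------------------------------------------------------------
# operations


def annotate_peaks(
    peaks: PeakSet,
    genes,
    params: AnalysisParams | None = None,
) -> tuple[pd.Series, dict[str, float]]:
    """Classify each peak midpoint against gene features.

    Priority: promoter > TTS > exon > intron > intergenic.  The promoter is
    TSS +/- ``promoter_window``; the TTS window runs ``-tts_upstream`` /
    ``+tts_downstream`` around the strand-appropriate transcript end.  When
    exon structure is absent from the gene table, midpoints inside a
    transcript body fall in the intron class.  Peaks on chromosomes carrying
    no genes are NA.

    Returns a Series of FeatureClass values indexed by peak_id and a dict of
    class fractions (over non-NA peaks fractions sum to 1 when any exist).
    """
    params = params or AnalysisParams()
    gdf = genes_to_frame(genes)
    if len(gdf) == 0:
        raise ValueError("gene list is empty")
    _check_chrom_compat(peaks.chroms, set(gdf["chrom"].unique()))

    classes = np.full(len(peaks), FeatureClass.NA.value, dtype=object)
    pdf = peaks.df
    mids = peaks.midpoints
    has_exons = {"exon_starts", "exon_ends"} <= set(gdf.columns)

    for chrom, gsub in gdf.groupby("chrom"):
        sel = (pdf["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        pts = mids[sel]
        tss = gsub["tss"].to_numpy()
        minus = (gsub["strand"] == "-").to_numpy()
        # promoter: symmetric window around TSS
        prom_s = tss - params.promoter_window
        prom_e = tss + params.promoter_window + 1
        # TTS: strand-oriented window around the transcript 3' end
        tts = np.where(minus, gsub["tx_start"].to_numpy(), gsub["tx_end"].to_numpy())
        tts_s = np.where(minus, tts - params.tts_downstream, tts - params.tts_upstream)
        tts_e = np.where(minus, tts + params.tts_upstream + 1, tts + params.tts_downstream + 1)
        body_s = gsub["tx_start"].to_numpy()
        body_e = gsub["tx_end"].to_numpy() + 1

        layers: list[tuple[str, np.ndarray, np.ndarray]] = [
            (FeatureClass.PROMOTER.value, prom_s, prom_e),
            (FeatureClass.TTS.value, tts_s, tts_e),
        ]
        if has_exons:
            ex_s, ex_e = [], []
            for ss, ee in zip(gsub["exon_starts"], gsub["exon_ends"]):
                ex_s.extend(int(x) for x in str(ss).split(",") if x)
                ex_e.extend(int(x) for x in str(ee).split(",") if x)
            layers.append((FeatureClass.EXON.value, np.asarray(ex_s), np.asarray(ex_e)))
        layers.append((FeatureClass.INTRON.value, body_s, body_e))

        chrom_cls = np.full(len(pts), FeatureClass.INTERGENIC.value, dtype=object)
        undecided = np.ones(len(pts), dtype=bool)
        for label, ls, le in layers:
            ms, me = _merge_intervals(np.asarray(ls), np.asarray(le))
            hit = _points_in_intervals(pts, ms, me) & undecided
            chrom_cls[hit] = label
            undecided &= ~hit
        classes[sel] = chrom_cls

    result = pd.Series(classes, index=pdf["peak_id"].to_numpy(), name="feature_class")
    non_na = result[result != FeatureClass.NA.value]
    fractions = {c.value: 0.0 for c in FeatureClass if c != FeatureClass.NA}
    if len(non_na):
        for label, n in non_na.value_counts().items():
            fractions[label] = n / len(non_na)
    fractions["NA"] = float((result == FeatureClass.NA.value).mean()) if len(result) else 0.0
    return result, fractions


@dataclass
class OverlapPartition:
    """Exhaustive, disjoint overlap partition of two peak sets."""

    a_name: str
    b_name: str
    a_only: int
    a_both: int
    b_only: int
    b_both: int
    merged_sites: int
    cobound_merged_sites: int
    a_both_ids: list[str] = field(default_factory=list, repr=False)
    b_both_ids: list[str] = field(default_factory=list, repr=False)


def overlap_peak_sets(a: PeakSet, b: PeakSet) -> OverlapPartition:
    """Partition peaks of two sets by >= 1 bp intersection with the other.

    Counts are reported from each set's perspective; ``cobound_merged_sites``
    is the number of merged (union) intervals containing at least one peak
    from each set, the symmetric co-bound site count.
    """
    adf, bdf = a.df, b.df

    def _both_mask(qdf: pd.DataFrame, sdf: pd.DataFrame) -> np.ndarray:
        mask = np.zeros(len(qdf), dtype=bool)
        for chrom, qsub in qdf.groupby("chrom"):
            ssub = sdf[sdf["chrom"] == chrom]
            hit = intersects_any(
                qsub["start"].to_numpy(),
                qsub["end"].to_numpy(),
                ssub["start"].to_numpy(),
                ssub["end"].to_numpy(),
            )
            mask[qsub.index.to_numpy()] = hit
        return mask

    a_both = _both_mask(adf, bdf)
    b_both = _both_mask(bdf, adf)

    # merged union sites and those containing both labels
    merged_total = 0
    cobound = 0
    all_chroms = sorted(a.chroms | b.chroms)
    for chrom in all_chroms:
        asub = adf[adf["chrom"] == chrom]
        bsub = bdf[bdf["chrom"] == chrom]
        starts = np.concatenate([asub["start"].to_numpy(), bsub["start"].to_numpy()])
        ends = np.concatenate([asub["end"].to_numpy(), bsub["end"].to_numpy()])
        labels = np.concatenate([np.zeros(len(asub), int), np.ones(len(bsub), int)])
        if len(starts) == 0:
            continue
        order = np.argsort(starts, kind="mergesort")
        starts, ends, labels = starts[order], ends[order], labels[order]
        cur_end = -1
        has = [False, False]
        for s, e, lab in zip(starts, ends, labels):
            if s < cur_end:
                cur_end = max(cur_end, e)
                has[lab] = True
            else:
                if cur_end >= 0:
                    merged_total += 1
                    cobound += has[0] and has[1]
                cur_end = e
                has = [False, False]
                has[lab] = True
        merged_total += 1
        cobound += has[0] and has[1]

    return OverlapPartition(
        a_name=a.name,
        b_name=b.name,
        a_only=int((~a_both).sum()),
        a_both=int(a_both.sum()),
        b_only=int((~b_both).sum()),
        b_both=int(b_both.sum()),
        merged_sites=merged_total,
        cobound_merged_sites=cobound,
        a_both_ids=adf.loc[a_both, "peak_id"].tolist(),
        b_both_ids=bdf.loc[b_both, "peak_id"].tolist(),
    )


def flanking_enhancer_density(
    genes,
    active_peaks: PeakSet,
    gene_groups: Mapping[str, Sequence[str]] | None = None,
) -> tuple[pd.Series, dict[str, float]]:
    """Assign each peak to the gene with the nearest TSS; count per gene.

    Distance is from the peak midpoint to the TSS; equidistant ties go to the
    gene with the smaller TSS coordinate.  Peaks on chromosomes without genes
    are not assigned.  Returns per-gene counts (all genes, zero-filled) and
    the mean count for each requested gene group (key ``"__all__"`` is always
    included).
    """
    gdf = genes_to_frame(genes)
    counts = pd.Series(0, index=gdf["gene_id"].to_numpy(), name="n_flanking_peaks")
    pdf = active_peaks.df
    mids = active_peaks.midpoints
    for chrom, gsub in gdf.groupby("chrom"):
        sel = (pdf["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        pts = mids[sel]
        # sort genes by TSS; among equal TSS keep first (smaller coordinate rule
        # is vacuous for exact duplicates, kept deterministic by stable sort)
        gsub = gsub.sort_values("tss", kind="mergesort")
        tss = gsub["tss"].to_numpy()
        ids = gsub["gene_id"].to_numpy()
        right = np.searchsorted(tss, pts, side="left")
        left = np.clip(right - 1, 0, len(tss) - 1)
        right = np.clip(right, 0, len(tss) - 1)
        d_left = np.abs(pts - tss[left])
        d_right = np.abs(pts - tss[right])
        # tie -> smaller TSS coordinate, i.e. the left candidate
        choose_left = d_left <= d_right
        nearest = np.where(choose_left, left, right)
        for gi in nearest:
            counts[ids[gi]] += 1
    means: dict[str, float] = {"__all__": float(counts.mean())}
    if gene_groups:
        for name, members in gene_groups.items():
            members = [m for m in members if m in counts.index]
            means[name] = float(counts.loc[members].mean()) if members else float("nan")
    return counts, means


@dataclass
class TssMatchResult:
    matched: list[str]
    unmatched: list[str]

    @property
    def match_rate(self) -> float:
        total = len(self.matched) + len(self.unmatched)
        return len(self.matched) / total if total else 0.0


def match_tss_to_peaks(
    genes,
    promoter_peaks: PeakSet,
    params: AnalysisParams | None = None,
) -> TssMatchResult:
    """A TSS is matched iff some peak center lies within the match window.

    The window is inclusive: |center - tss| <= ``tss_match_window``.
    """
    params = params or AnalysisParams()
    gdf = genes_to_frame(genes)
    pdf = promoter_peaks.df
    mids = promoter_peaks.midpoints
    matched, unmatched = [], []
    for chrom, gsub in gdf.groupby("chrom"):
        sel = (pdf["chrom"] == chrom).to_numpy()
        centers = np.sort(mids[sel]) if sel.any() else np.array([], dtype=int)
        for gid, tss in zip(gsub["gene_id"], gsub["tss"]):
            if len(centers) == 0:
                unmatched.append(gid)
                continue
            i = np.searchsorted(centers, tss)
            best = min(
                abs(tss - centers[j]) for j in (max(i - 1, 0), min(i, len(centers) - 1))
            )
            (matched if best <= params.tss_match_window else unmatched).append(gid)
    return TssMatchResult(matched=matched, unmatched=unmatched)
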