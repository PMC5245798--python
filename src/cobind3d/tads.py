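"""Directionality index, domain calling, and boundary-relative metagene
profiles."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from cobind3d.contacts import ContactMatrix
from cobind3d.intervals import PeakSet

__all__ = [
    "DirectionalityTrack",
    "DomainSet",
    "MetageneProfile",
    "directionality_index",
    "call_domains",
    "metagene_profile",
]


@dataclass
class DirectionalityTrack:
    """Signed per-bin directionality statistic.

    For bin i with upstream contact sum A and downstream sum B over the
    window, E = (A + B) / 2 and DI = sign(B - A) * ((A-E)^2/E + (B-E)^2/E);
    DI = 0 when A = B or E = 0.  Bins whose window is truncated by a
    chromosome edge are flagged.
    """

    chrom: str
    bin_size: int
    window: int  # in bins
    values: np.ndarray = field(repr=False)
    truncated: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return len(self.values)

    def to_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for b, v in enumerate(self.values):
                fh.write(
                    f"{self.chrom}\t{b * self.bin_size}\t{(b + 1) * self.bin_size}\t{v:.6f}\n"
                )


def directionality_index(matrix: ContactMatrix, window: int) -> DirectionalityTrack:
    """Per-bin upstream/downstream contact asymmetry (chi-square signed)."""
    n = matrix.n_bins
    if window < 1:
        raise ValueError("window must be >= 1 bin")
    if window >= n:
        raise ValueError(f"window of {window} bins exceeds chromosome ({n} bins)")
    C = matrix.counts
    A = np.zeros(n)
    B = np.zeros(n)
    for dlt in range(1, window + 1):
        idx = np.arange(n)
        up = idx - dlt
        ok = up >= 0
        A[ok] += C[idx[ok], up[ok]]
        dn = idx + dlt
        ok = dn < n
        B[ok] += C[idx[ok], dn[ok]]
    E = (A + B) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        chi = np.where(E > 0, (A - E) ** 2 / E + (B - E) ** 2 / E, 0.0)
    di = np.sign(B - A) * chi
    truncated = np.zeros(n, dtype=bool)
    truncated[:window] = True
    truncated[n - window :] = True
    return DirectionalityTrack(
        chrom=matrix.chrom, bin_size=matrix.bin_size, window=window, values=di, truncated=truncated
    )


@dataclass
class DomainSet:
    """Sorted, non-overlapping called domains (bin and bp coordinates)."""

    chrom: str
    bin_size: int
    df: pd.DataFrame  # columns: start_bin, end_bin (exclusive), start, end

    def __len__(self) -> int:
        return len(self.df)

    @property
    def boundaries(self) -> np.ndarray:
        """All domain ends, in bp, sorted."""
        return np.sort(
            np.concatenate([self.df["start"].to_numpy(), self.df["end"].to_numpy()])
        )

    def to_bed(self, path: str | Path) -> None:
        out = self.df.copy()
        out.insert(0, "chrom", self.chrom)
        out["name"] = [f"domain_{i}" for i in range(len(out))]
        out[["chrom", "start", "end", "name"]].to_csv(path, sep="\t", header=False, index=False)


def call_domains(
    track: DirectionalityTrack,
    pos_threshold: float | None = None,
    neg_threshold: float | None = None,
    min_run: int = 3,
) -> DomainSet:
    """Threshold/run-length domain caller on a directionality track.

    A domain opens at the start of a sustained run (>= min_run bins) of
    DI > pos_threshold and closes at the end of the subsequent sustained run
    of DI < -neg_threshold.  Thresholds default to the 90th percentile of
    |DI| over non-truncated bins.  Truncated edge bins are treated as DI = 0.
    Domains shorter than 3 bins are dropped.
    """
    di = track.values.copy()
    di[track.truncated] = 0.0
    interior = np.abs(track.values[~track.truncated])
    if pos_threshold is None or neg_threshold is None:
        q = float(np.percentile(interior, 90)) if len(interior) else 0.0
        pos_threshold = pos_threshold if pos_threshold is not None else q
        neg_threshold = neg_threshold if neg_threshold is not None else q
    if pos_threshold <= 0 or neg_threshold <= 0:
        raise ValueError("thresholds must be positive")

    def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
        """Maximal runs of True, as (start, end) half-open, length >= min_run."""
        out = []
        start = None
        for b, m in enumerate(mask):
            if m and start is None:
                start = b
            elif not m and start is not None:
                if b - start >= min_run:
                    out.append((start, b))
                start = None
        if start is not None and len(mask) - start >= min_run:
            out.append((start, len(mask)))
        return out

    pos_runs = _runs(di > pos_threshold)
    neg_runs = _runs(di < -neg_threshold)
    domains = []
    ni = 0
    for ps, _pe in pos_runs:
        while ni < len(neg_runs) and neg_runs[ni][0] < ps:
            ni += 1
        if ni >= len(neg_runs):
            break
        # the closing run must come after this open and before the next open
        close = neg_runs[ni][1]
        if domains and ps < domains[-1][1]:
            continue  # positive run inside the previous domain
        if close - ps >= 3:
            domains.append((ps, close))
            ni += 1
    bs = track.bin_size
    df = pd.DataFrame(domains, columns=["start_bin", "end_bin"])
    df["start"] = df["start_bin"] * bs
    df["end"] = df["end_bin"] * bs
    return DomainSet(chrom=track.chrom, bin_size=bs, df=df)


@dataclass
class MetageneProfile:
    """Feature density over size-normalized domains plus fixed flanks.

    Four segments (upstream flank, first and second domain halves,
    downstream flank), each split into ``bins_per_quartile`` bins; profile
    length is 4 x bins_per_quartile.  ``densities`` is mean per-bp density
    over domains; ``counts`` the raw per-bin feature totals (summed over
    domains), kept for conservation checks.
    """

    bins_per_quartile: int
    n_domains: int
    densities: np.ndarray = field(repr=False)
    counts: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return len(self.densities)

    @property
    def segment_means(self) -> dict[str, float]:
        B = self.bins_per_quartile
        segs = ["upstream_flank", "domain_first_half", "domain_second_half", "downstream_flank"]
        return {
            s: float(self.densities[i * B : (i + 1) * B].mean()) for i, s in enumerate(segs)
        }

    def to_tsv(self, path: str | Path) -> None:
        B = self.bins_per_quartile
        segs = ["upstream_flank", "domain_first_half", "domain_second_half", "downstream_flank"]
        pd.DataFrame(
            {
                "segment": np.repeat(segs, B),
                "bin_index": np.arange(4 * B),
                "density": self.densities,
                "count": self.counts,
            }
        ).to_csv(path, sep="\t", index=False)


def metagene_profile(
    features,
    domains: DomainSet,
    flank: int = 200_000,
    bins_per_quartile: int = 175,
) -> MetageneProfile:
    """Boundary-relative feature density averaged over domains.

    ``features`` is a PeakSet (midpoints used) or an array of positions on
    the domain chromosome.  Each domain contributes four equal-bin segments:
    [start - flank, start), [start, mid), [mid, end), [end, end + flank),
    the midpoint being floor((start + end) / 2).
    """
    if len(domains) == 0:
        raise ValueError("domain set is empty")
    if isinstance(features, PeakSet):
        pdf = features.df
        pos = np.sort(
            features.midpoints[(pdf["chrom"] == domains.chrom).to_numpy()]
        ).astype(float)
    else:
        pos = np.sort(np.asarray(features, dtype=float))
    B = bins_per_quartile
    counts = np.zeros(4 * B)
    dens_sum = np.zeros(4 * B)
    for _, row in domains.df.iterrows():
        start, end = float(row["start"]), float(row["end"])
        mid = float((int(start) + int(end)) // 2)
        spans = [
            (start - flank, start),
            (start, mid),
            (mid, end),
            (end, end + flank),
        ]
        for si, (lo, hi) in enumerate(spans):
            if hi <= lo:
                continue
            width = (hi - lo) / B
            inside = pos[(pos >= lo) & (pos < hi)]
            idx = np.minimum(((inside - lo) / width).astype(int), B - 1)
            c = np.bincount(idx, minlength=B).astype(float)
            counts[si * B : (si + 1) * B] += c
            dens_sum[si * B : (si + 1) * B] += c / width
    return MetageneProfile(
        bins_per_quartile=B,
        n_domains=len(domains),
        densities=dens_sum / len(domains),
        counts=counts,
    )
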