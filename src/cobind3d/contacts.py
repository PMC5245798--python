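"""Contact matrices, the distance-decay background model, and
cross-condition per-bin correlation.

Pairs files are a cis-oriented 4-column TSV dialect: chrom1, pos1, chrom2,
pos2 (0-based positions).  Matrices are symmetric per-chromosome dense arrays
with a sparse TSV + JSON sidecar on disk.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ContactMatrix",
    "BackgroundModel",
    "CorrelationTrack",
    "bin_pairs",
    "fit_background",
    "condition_correlation",
    "read_pairs",
    "write_pairs",
]

PAIR_COLUMNS = ["chrom1", "pos1", "chrom2", "pos2"]


@dataclass
class ContactMatrix:
    """Symmetric binned cis contact counts for one chromosome."""

    chrom: str
    bin_size: int
    counts: np.ndarray = field(repr=False)
    total_pairs: int = 0  # all pairs in the source file (incl. trans)

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.float64)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("counts must be a square matrix")
        if not np.array_equal(c, c.T):
            raise ValueError("counts must be symmetric")
        if (c < 0).any():
            raise ValueError("counts must be nonnegative")
        self.counts = c

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def total_cis_pairs(self) -> int:
        return int(np.triu(self.counts).sum())

    @property
    def bin_totals(self) -> np.ndarray:
        """Per-bin contact totals (each pair contributes to both its bins)."""
        return self.counts.sum(axis=1)

    def __add__(self, other: "ContactMatrix") -> "ContactMatrix":
        if (self.chrom, self.bin_size, self.n_bins) != (
            other.chrom,
            other.bin_size,
            other.n_bins,
        ):
            raise ValueError("matrices are not on the same binning")
        return ContactMatrix(
            self.chrom,
            self.bin_size,
            self.counts + other.counts,
            self.total_pairs + other.total_pairs,
        )

    def to_tsv(self, path: str | Path) -> None:
        """Write upper-triangle sparse triples plus a JSON header sidecar."""
        path = Path(path)
        iu = np.triu_indices(self.n_bins)
        vals = self.counts[iu]
        nz = vals > 0
        pd.DataFrame(
            {"bin1": iu[0][nz], "bin2": iu[1][nz], "count": vals[nz].astype(np.int64)}
        ).to_csv(path, sep="\t", index=False)
        meta = {
            "chrom": self.chrom,
            "bin_size": self.bin_size,
            "n_bins": self.n_bins,
            "total_cis_pairs": self.total_cis_pairs,
            "total_pairs": self.total_pairs,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ContactMatrix":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        df = pd.read_csv(path, sep="\t")
        n = meta["n_bins"]
        counts = np.zeros((n, n))
        counts[df["bin1"], df["bin2"]] = df["count"]
        counts[df["bin2"], df["bin1"]] = df["count"]
        return cls(meta["chrom"], meta["bin_size"], counts, meta.get("total_pairs", 0))


def read_pairs(path: str | Path, drop_duplicates: bool = False) -> pd.DataFrame:
    """Read a 4-column pairs TSV; raises with the line number on bad records."""
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            names=PAIR_COLUMNS,
            dtype={"chrom1": str, "pos1": np.int64, "chrom2": str, "pos2": np.int64},
        )
    except (ValueError, pd.errors.ParserError):
        # locate the first offending line for the error message
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if line.startswith("#") or not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                ok = len(parts) == 4 and parts[1].lstrip("-").isdigit() and parts[3].lstrip("-").isdigit()
                if not ok:
                    raise ValueError(f"{path}: malformed pair record at line {lineno}: {line!r}")
        raise
    if drop_duplicates:
        df = df.drop_duplicates(ignore_index=True)
    return df


def write_pairs(df: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(PAIR_COLUMNS) + "\n")
        df[PAIR_COLUMNS].to_csv(fh, sep="\t", header=False, index=False)


def bin_pairs(
    pairs,
    bin_size: int,
    chrom_sizes: dict[str, int],
    drop_duplicates: bool = False,
) -> tuple[dict[str, ContactMatrix], dict]:
    """Bin read pairs into per-chromosome symmetric contact matrices.

    ``pairs`` is a DataFrame or a path to a pairs TSV.  Trans pairs are
    tallied in the summary only.  Returns (matrices by chrom, summary) with
    summary keys total_pairs, cis_pairs, trans_pairs, cis_fraction.
    """
    if not isinstance(pairs, pd.DataFrame):
        pairs = read_pairs(pairs, drop_duplicates=drop_duplicates)
    elif drop_duplicates:
        pairs = pairs.drop_duplicates(ignore_index=True)

    for col in ("pos1", "pos2"):
        bad = ~np.isin(pairs["chrom1" if col == "pos1" else "chrom2"], list(chrom_sizes))
        if bad.any():
            raise ValueError(
                f"pairs reference unknown chromosomes: "
                f"{sorted(set(pairs.loc[bad, 'chrom1' if col == 'pos1' else 'chrom2']))}"
            )
    sizes1 = pairs["chrom1"].map(chrom_sizes).to_numpy()
    sizes2 = pairs["chrom2"].map(chrom_sizes).to_numpy()
    if (
        (pairs["pos1"].to_numpy() < 0).any()
        or (pairs["pos2"].to_numpy() < 0).any()
        or (pairs["pos1"].to_numpy() >= sizes1).any()
        or (pairs["pos2"].to_numpy() >= sizes2).any()
    ):
        raise ValueError("pair positions outside chromosome bounds")

    total = len(pairs)
    cis_mask = (pairs["chrom1"] == pairs["chrom2"]).to_numpy()
    cis = pairs[cis_mask]
    matrices: dict[str, ContactMatrix] = {}
    for chrom, size in chrom_sizes.items():
        n = -(-size // bin_size)
        counts = np.zeros((n, n))
        sub = cis[cis["chrom1"] == chrom]
        if len(sub):
            b1 = sub["pos1"].to_numpy() // bin_size
            b2 = sub["pos2"].to_numpy() // bin_size
            np.add.at(counts, (b1, b2), 1.0)
            np.add.at(counts, (b2, b1), 1.0)
            # diagonal entries were incremented twice
            diag = b1 == b2
            np.add.at(counts, (b1[diag], b2[diag]), -1.0)
        matrices[chrom] = ContactMatrix(chrom, bin_size, counts, total_pairs=total)
    n_cis = int(cis_mask.sum())
    summary = {
        "total_pairs": total,
        "cis_pairs": n_cis,
        "trans_pairs": total - n_cis,
        "cis_fraction": n_cis / total if total else float("nan"),
    }
    return matrices, summary


@dataclass
class BackgroundModel:
    """Distance-decay + coverage background for one contact matrix.

    ``f`` is the expected count per bin pair at each bin distance (pooled in
    log-spaced strata beyond ``max_single_stratum``); ``w`` is the per-bin
    coverage weight (mean ~1 over unmasked bins); ``v`` the empirical
    within-stratum variance of observed counts.  ``expected`` conserves the
    observed total within every distance stratum over unmasked pairs.
    """

    chrom: str
    bin_size: int
    f: np.ndarray = field(repr=False)  # per bin-distance
    v: np.ndarray = field(repr=False)  # per bin-distance
    w: np.ndarray = field(repr=False)  # per bin
    mask: np.ndarray = field(repr=False)  # True = bin masked out
    expected: np.ndarray = field(repr=False)  # dense symmetric matrix
    stratum_of_distance: np.ndarray = field(repr=False)

    @property
    def n_bins(self) -> int:
        return len(self.w)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"distance_bins": np.arange(len(self.f)), "f": self.f, "v": self.v}
        ).to_csv(path, sep="\t", index=False)


def _strata(n_bins: int, max_single: int, pool_factor: float = 1.25) -> np.ndarray:
    """Map bin distance -> stratum id: unit strata then log-pooled."""
    strat = np.arange(n_bins)
    d = max_single
    sid = max_single
    while d < n_bins:
        width = max(1, int(d * (pool_factor - 1)))
        strat[d : min(d + width, n_bins)] = sid
        d += width
        sid += 1
    # compress ids to consecutive
    _, strat = np.unique(strat, return_inverse=True)
    return strat


def fit_background(
    matrix: ContactMatrix,
    window: int = 2,
    coverage_floor: float = 0.2,
    max_single_stratum: int = 100,
) -> BackgroundModel:
    """Fit the distance-decay / coverage background of a contact matrix.

    Coverage weights come from per-bin totals relative to the distance-decay
    expectation available to each bin (so uniform matrices get w = 1 even at
    chromosome edges); bins with relative total below ``coverage_floor`` are
    masked.  ``window`` > 1 applies a sliding-window sum (window x window,
    step 1) before estimating the reported decay curve ``f``; the expected
    matrix itself is rescaled so every distance stratum conserves its raw
    observed total over unmasked pairs.
    """
    if matrix.total_cis_pairs <= 0:
        raise ValueError("matrix has no cis pairs")
    C = matrix.counts
    n = matrix.n_bins
    strat = _strata(n, max_single_stratum)
    n_strata = strat.max() + 1

    i, j = np.triu_indices(n)
    d = j - i
    sid = strat[d]

    # raw per-distance mean (all pairs) for the edge-aware coverage weights
    sums = np.bincount(sid, weights=C[i, j], minlength=n_strata)
    npairs = np.bincount(sid, minlength=n_strata)
    f_raw_stratum = np.divide(sums, npairs, out=np.zeros(n_strata), where=npairs > 0)
    f_raw = f_raw_stratum[strat]  # per bin-distance

    # expected per-bin total under pure decay; weight = observed / that
    dist_mat = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    decay_mat = f_raw[dist_mat]
    decay_tot = decay_mat.sum(axis=1)
    bin_tot = C.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(decay_tot > 0, bin_tot / decay_tot, 0.0)
    pos = w[w > 0]
    if len(pos) == 0:
        raise ValueError("all bins have zero coverage")
    w = w / pos.mean()
    mask = w < coverage_floor
    if mask.all():
        raise ValueError("all bins masked by the coverage floor")
    # renormalize to mean 1 over unmasked bins
    w = w / w[~mask].mean()

    # reported decay curve, optionally from the sliding-window-summed matrix
    if window > 1:
        from scipy.ndimage import uniform_filter

        S = uniform_filter(C, size=window, mode="constant") * window**2
    else:
        S = C
    ok = ~(mask[i] | mask[j])
    sums_s = np.bincount(sid[ok], weights=S[i, j][ok], minlength=n_strata)
    npairs_ok = np.bincount(sid[ok], minlength=n_strata)
    f_stratum = np.divide(sums_s, npairs_ok, out=np.zeros(n_strata), where=npairs_ok > 0)
    if window > 1:
        f_stratum = f_stratum / window**2
    f = f_stratum[strat]

    # empirical variance of raw observed counts within each stratum (unmasked)
    obs_ok = C[i, j][ok]
    sums_o = np.bincount(sid[ok], weights=obs_ok, minlength=n_strata)
    sums_o2 = np.bincount(sid[ok], weights=obs_ok**2, minlength=n_strata)
    with np.errstate(invalid="ignore"):
        mean_o = np.divide(sums_o, npairs_ok, out=np.zeros(n_strata), where=npairs_ok > 0)
        v_stratum = np.divide(
            sums_o2, npairs_ok, out=np.zeros(n_strata), where=npairs_ok > 0
        ) - mean_o**2
    v = np.clip(v_stratum, 0.0, None)[strat]

    # expected(i,j) = f(d) * w_i * w_j, rescaled so each stratum conserves the
    # raw observed total over unmasked pairs
    E = f_raw[dist_mat] * np.outer(w, w)
    E[mask, :] = 0.0
    E[:, mask] = 0.0
    exp_sums = np.bincount(sid[ok], weights=E[i, j][ok], minlength=n_strata)
    scale = np.divide(sums_o, exp_sums, out=np.zeros(n_strata), where=exp_sums > 0)
    E = E * scale[strat[dist_mat]]

    return BackgroundModel(
        chrom=matrix.chrom,
        bin_size=matrix.bin_size,
        f=f,
        v=v,
        w=w,
        mask=mask,
        expected=E,
        stratum_of_distance=strat,
    )


@dataclass
class CorrelationTrack:
    """Per-bin cross-condition Pearson correlation of obs/exp profiles."""

    chrom: str
    bin_size: int
    values: np.ndarray = field(repr=False)
    valid: np.ndarray = field(repr=False)

    def n_below(self, cutoff: float) -> int:
        return int((self.values[self.valid] < cutoff).sum())

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def to_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for b in np.flatnonzero(self.valid):
                fh.write(
                    f"{self.chrom}\t{b * self.bin_size}\t{(b + 1) * self.bin_size}"
                    f"\t{self.values[b]:.6f}\n"
                )


def condition_correlation(
    matrix_a: ContactMatrix,
    matrix_b: ContactMatrix,
    background_a: BackgroundModel,
    background_b: BackgroundModel,
    max_distance: int = 100,
    correlation_cutoff: float = 0.5,
) -> tuple[CorrelationTrack, int]:
    """Per-bin Pearson r between obs/exp profiles of two conditions.

    For bin i the profile is obs/exp against all bins within ``max_distance``
    (entries where either condition is masked or has zero expectation are
    dropped).  Bins masked in either condition, or with fewer than 3 usable
    entries, or with a constant profile, are invalid.  Also returns the count
    of valid bins with r below ``correlation_cutoff``.
    """
    if (matrix_a.chrom, matrix_a.bin_size, matrix_a.n_bins) != (
        matrix_b.chrom,
        matrix_b.bin_size,
        matrix_b.n_bins,
    ):
        raise ValueError("matrices are not on the same binning")
    n = matrix_a.n_bins
    with np.errstate(invalid="ignore", divide="ignore"):
        Ra = np.where(background_a.expected > 0, matrix_a.counts / background_a.expected, np.nan)
        Rb = np.where(background_b.expected > 0, matrix_b.counts / background_b.expected, np.nan)
    values = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    bad_bin = background_a.mask | background_b.mask
    for b in range(n):
        if bad_bin[b]:
            continue
        lo, hi = max(0, b - max_distance), min(n, b + max_distance + 1)
        x, y = Ra[b, lo:hi], Rb[b, lo:hi]
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < 3:
            continue
        x, y = x[ok], y[ok]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        r = np.corrcoef(x, y)[0, 1]
        if np.isnan(r):
            continue
        values[b] = r
        valid[b] = True
    track = CorrelationTrack(matrix_a.chrom, matrix_a.bin_size, values, valid)
    return track, track.n_below(correlation_cutoff)
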