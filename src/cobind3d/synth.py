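"""Synthetic regulatory-genome and contact-read generator with planted truth.

Every artifact (genes, open chromatin, each factor's peaks, each condition's
read pairs) is driven by its own RNG stream derived from the master seed, so
adding outputs never perturbs existing ones.  Identical configs produce
byte-identical outputs.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from cobind3d.contacts import write_pairs
from cobind3d.intervals import PeakSet, write_gene_table

__all__ = [
    "FactorSpec",
    "TadSpec",
    "LoopSpec",
    "SimulationConfig",
    "SyntheticTruth",
    "RegulatoryData",
    "simulate_regulatory_genome",
    "simulate_contact_reads",
    "write_simulation",
]


@dataclass(frozen=True)
class FactorSpec:
    name: str
    n_peaks: int
    promoter_fraction: float = 0.0


@dataclass(frozen=True)
class TadSpec:
    start: int  # bp
    end: int  # bp
    enrichment: float = 1.0
    chrom: str = "chr1"


@dataclass(frozen=True)
class LoopSpec:
    anchor1: int  # bp
    anchor2: int  # bp
    intensity1: float = 1.0
    intensity2: float = 1.0
    chrom: str = "chr1"


@dataclass
class SimulationConfig:
    """Parameters of the synthetic regulatory genome and contact libraries.

    Planted TADs and loops carry their own chromosome (default chr1).
    ``cobinding_rate``
    is the per-peak probability that a peak of the second factor lands on a
    site already bound by the first.  ``knockdown_fold`` reduces tag counts
    at co-bound peaks (floor division, so the realized fold is always >= the
    configured fold).
    """

    seed: int = 1007
    n_chroms: int = 1
    chrom_length: int = 10_000_000
    bin_size: int = 25_000
    n_genes: int = 100
    n_open_sites: int = 500
    factors: list[FactorSpec] = field(default_factory=list)
    cobinding_rate: float = 0.0
    knockdown_fold: float = 1.0
    decay_exponent: float = 1.0
    tad_layout: list[TadSpec] = field(default_factory=list)
    loops: list[LoopSpec] = field(default_factory=list)
    depth: int = 0
    open_site_width: int = 500
    peak_width: int = 200
    promoter_site_fraction: float = 0.5

    def __post_init__(self) -> None:
        self.factors = [f if isinstance(f, FactorSpec) else FactorSpec(*f) for f in self.factors]
        self.tad_layout = [t if isinstance(t, TadSpec) else TadSpec(*t) for t in self.tad_layout]
        self.loops = [l if isinstance(l, LoopSpec) else LoopSpec(*l) for l in self.loops]
        if self.chrom_length % self.bin_size != 0:
            raise ValueError("bin_size must divide chrom_length")
        if not (0.0 <= self.cobinding_rate <= 1.0):
            raise ValueError("cobinding_rate must be in [0, 1]")
        if not (0.0 <= self.promoter_site_fraction <= 1.0):
            raise ValueError("promoter_site_fraction must be in [0, 1]")
        for fspec in self.factors:
            if not (0.0 <= fspec.promoter_fraction <= 1.0):
                raise ValueError(f"promoter_fraction of {fspec.name!r} must be in [0, 1]")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.knockdown_fold < 1.0:
            raise ValueError("knockdown_fold must be >= 1")
        names = set(self.chrom_names)
        for t in self.tad_layout:
            if t.chrom not in names:
                raise ValueError(f"planted TAD on unknown chromosome {t.chrom!r}")
            if not (0 <= t.start < t.end <= self.chrom_length):
                raise ValueError(f"planted TAD [{t.start}, {t.end}) outside chromosome")
        for l in self.loops:
            if l.chrom not in names:
                raise ValueError(f"planted loop on unknown chromosome {l.chrom!r}")
            for a in (l.anchor1, l.anchor2):
                if not (0 <= a < self.chrom_length):
                    raise ValueError(f"planted loop anchor {a} outside chromosome")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: self.chrom_length for c in self.chrom_names}

    def rng(self, stream: str) -> np.random.Generator:
        """A reproducible RNG stream named per output artifact."""
        return np.random.default_rng([self.seed, zlib.crc32(stream.encode())])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        raw = json.loads(Path(path).read_text())
        raw["factors"] = [FactorSpec(**f) for f in raw.get("factors", [])]
        raw["tad_layout"] = [TadSpec(**t) for t in raw.get("tad_layout", [])]
        raw["loops"] = [LoopSpec(**l) for l in raw.get("loops", [])]
        return cls(**raw)


@dataclass
class SyntheticTruth:
    """Planted ground truth, recoverable from the emitted files."""

    boundaries: list[int] = field(default_factory=list)  # bp, on chr1
    tads: list[dict] = field(default_factory=list)
    loops: list[dict] = field(default_factory=list)
    cobound_sites: list[str] = field(default_factory=list)
    cobound_peaks: dict[str, list[str]] = field(default_factory=dict)
    knockdown_affected: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


class RegulatoryData(NamedTuple):
    genes: pd.DataFrame
    open_sites: PeakSet
    factor_peaks: dict[str, PeakSet]
    truth: SyntheticTruth


def _place_genes(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    per_chrom = np.full(config.n_chroms, config.n_genes // config.n_chroms)
    per_chrom[: config.n_genes % config.n_chroms] += 1
    gi = 0
    for chrom, g in zip(config.chrom_names, per_chrom):
        if g == 0:
            continue
        spacing = config.chrom_length // (g + 1)
        jitter = rng.integers(-spacing // 4, spacing // 4 + 1, size=g)
        tss = (np.arange(1, g + 1) * spacing + jitter).astype(int)
        strands = rng.choice(["+", "-"], size=g)
        lengths = rng.integers(2_000, 10_001, size=g)
        for t, s, L in zip(tss, strands, lengths):
            t = int(np.clip(t, 1_500, config.chrom_length - 1_501))
            if s == "+":
                tx_start, tx_end = t, min(t + int(L), config.chrom_length - 1)
            else:
                tx_start, tx_end = max(t - int(L), 0), t
            rows.append((f"gene_{gi}", chrom, s, t, tx_start, tx_end))
            gi += 1
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss", "tx_start", "tx_end"])
    # unique TSSs per chromosome (jitter collisions are vanishingly rare but
    # would break downstream assumptions)
    for chrom in config.chrom_names:
        sel = df["chrom"] == chrom
        tss = df.loc[sel, "tss"]
        while tss.duplicated().any():
            dupes = tss.duplicated()
            df.loc[tss.index[dupes], "tss"] += 1
            tss = df.loc[sel, "tss"]
    return df


def _place_open_sites(
    config: SimulationConfig, genes: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Non-overlapping open-chromatin sites; a fraction promoter-proximal."""
    w = config.open_site_width
    half = w // 2
    per_chrom = np.full(config.n_chroms, config.n_open_sites // config.n_chroms)
    per_chrom[: config.n_open_sites % config.n_chroms] += 1
    rows = []
    si = 0
    for chrom, n_sites in zip(config.chrom_names, per_chrom):
        if n_sites == 0:
            continue
        gsub = genes[genes["chrom"] == chrom]
        # one promoter site per gene at most, so windows never need to pack
        n_prom = min(int(round(config.promoter_site_fraction * n_sites)), len(gsub))
        tss = gsub["tss"].to_numpy()
        prom_genes = rng.choice(len(tss), size=n_prom, replace=False) if n_prom else np.array([], dtype=int)
        prom_centers = tss[prom_genes] + rng.integers(-1_000, 1_001, size=n_prom)
        prom_centers = np.clip(prom_centers, half, config.chrom_length - half - 1)

        def _draw_bg(k: int) -> np.ndarray:
            c = rng.integers(half, config.chrom_length - half, size=k)
            return np.clip(c, half, config.chrom_length - half - 1)

        centers = np.concatenate([prom_centers, _draw_bg(n_sites - n_prom)])
        is_prom = np.concatenate([np.ones(n_prom, bool), np.zeros(n_sites - n_prom, bool)])
        gene_of_site = np.concatenate(
            [prom_genes, np.full(n_sites - n_prom, -1, dtype=int)]
        )
        for _ in range(500):
            order = np.argsort(centers, kind="mergesort")
            sc = centers[order]
            too_close = np.zeros(n_sites, dtype=bool)
            gaps = np.flatnonzero(np.diff(sc) < w)
            for g in gaps:
                # redraw a background member of the clash if there is one
                lo_i, hi_i = order[g], order[g + 1]
                if is_prom[lo_i] and is_prom[hi_i]:
                    too_close[hi_i] = True
                else:
                    too_close[hi_i if not is_prom[hi_i] else lo_i] = True
            if not too_close.any():
                break
            redraw_p = np.flatnonzero(too_close & is_prom)
            redraw_b = too_close & ~is_prom
            if len(redraw_p):
                jitter = rng.integers(-1_000, 1_001, size=len(redraw_p))
                centers[redraw_p] = np.clip(
                    tss[gene_of_site[redraw_p]] + jitter, half, config.chrom_length - half - 1
                )
            if redraw_b.any():
                centers[redraw_b] = _draw_bg(int(redraw_b.sum()))
        else:
            raise ValueError(
                f"could not place {n_sites} non-overlapping open sites on {chrom}; "
                "reduce n_open_sites or open_site_width"
            )
        order = np.argsort(centers, kind="mergesort")
        for c, p in zip(centers[order], is_prom[order]):
            rows.append((chrom, int(c) - half, int(c) + half, f"site_{si}", p))
            si += 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "site_id", "is_promoter"])


def simulate_regulatory_genome(config: SimulationConfig) -> RegulatoryData:
    """Generate genes, open chromatin, and per-factor peak sets.

    All peaks are fixed-width, centered on open-chromatin site centers, so
    they lie inside their sites.  The second factor shares the first factor's
    sites at per-peak probability ``cobinding_rate``; co-bound peaks carry
    knockdown tag counts reduced by ``knockdown_fold``.  Library totals for
    the two tag conditions are equal.
    """
    config.__post_init__()  # re-coerce/validate in case fields were mutated
    genes = _place_genes(config, config.rng("genes"))
    sites = _place_open_sites(config, genes, config.rng("open_sites"))
    truth = SyntheticTruth()
    factor_peaks: dict[str, PeakSet] = {}

    half_peak = config.peak_width // 2
    site_centers = ((sites["start"] + sites["end"]) // 2).to_numpy()
    prom_sites = np.flatnonzero(sites["is_promoter"].to_numpy())
    bg_sites = np.flatnonzero(~sites["is_promoter"].to_numpy())

    chosen: dict[str, np.ndarray] = {}  # factor -> site indices, aligned to peaks
    for fi, fspec in enumerate(config.factors):
        rng = config.rng(f"factor:{fspec.name}")
        if fspec.n_peaks > len(sites):
            raise ValueError(
                f"factor {fspec.name!r} requests {fspec.n_peaks} peaks but only "
                f"{len(sites)} open sites exist"
            )
        if fi == 1 and config.factors[0].name in chosen:
            a_sites = chosen[config.factors[0].name]
            shared_mask = rng.random(fspec.n_peaks) < config.cobinding_rate
            n_shared = int(shared_mask.sum())
            if n_shared > len(a_sites):
                n_shared = len(a_sites)
                shared_mask[np.flatnonzero(shared_mask)[n_shared:]] = False
            shared = rng.choice(a_sites, size=n_shared, replace=False)
            n_rest = fspec.n_peaks - n_shared
            a_set = set(a_sites.tolist())
            free_prom = np.array([s for s in prom_sites if s not in a_set], dtype=int)
            free_bg = np.array([s for s in bg_sites if s not in a_set], dtype=int)
            n_prom = min(int(round(fspec.promoter_fraction * n_rest)), len(free_prom))
            if n_rest - n_prom > len(free_bg):
                raise ValueError(
                    f"factor {fspec.name!r} requests {fspec.n_peaks} peaks but only "
                    f"{len(free_prom) + len(free_bg)} unshared open sites remain"
                )
            rest = np.concatenate(
                [
                    rng.choice(free_prom, size=n_prom, replace=False) if n_prom else [],
                    rng.choice(free_bg, size=n_rest - n_prom, replace=False) if n_rest - n_prom else [],
                ]
            ).astype(int)
            site_idx = np.concatenate([shared, rest]).astype(int)
        else:
            n_prom = min(int(round(fspec.promoter_fraction * fspec.n_peaks)), len(prom_sites))
            n_bg = fspec.n_peaks - n_prom
            if n_bg > len(bg_sites):
                raise ValueError(
                    f"factor {fspec.name!r} requests {fspec.n_peaks} peaks but only "
                    f"{len(prom_sites)} promoter and {len(bg_sites)} background sites exist"
                )
            site_idx = np.concatenate(
                [
                    rng.choice(prom_sites, size=n_prom, replace=False) if n_prom else [],
                    rng.choice(bg_sites, size=n_bg, replace=False) if n_bg else [],
                ]
            ).astype(int)
        chosen[fspec.name] = site_idx

    cobound_site_idx: set[int] = set()
    if len(config.factors) >= 2:
        a = set(chosen[config.factors[0].name].tolist())
        b = set(chosen[config.factors[1].name].tolist())
        cobound_site_idx = a & b
    truth.cobound_sites = sorted(sites["site_id"].iloc[sorted(cobound_site_idx)].tolist())

    for fspec in config.factors:
        rng = config.rng(f"tags:{fspec.name}")
        site_idx = chosen[fspec.name]
        centers = site_centers[site_idx]
        df = pd.DataFrame(
            {
                "chrom": sites["chrom"].iloc[site_idx].to_numpy(),
                "start": centers - half_peak,
                "end": centers + half_peak,
                "peak_id": [f"{fspec.name}_{sites['site_id'].iloc[s]}" for s in site_idx],
            }
        )
        control = rng.integers(50, 501, size=len(df)).astype(np.int64)
        affected = np.array([s in cobound_site_idx for s in site_idx])
        knock = control.copy()
        if config.knockdown_fold > 1.0:
            knock[affected] = (control[affected] / config.knockdown_fold).astype(np.int64)
        df["score"] = control
        tags = pd.DataFrame(
            {"control": control, "knockdown": knock}, index=pd.Index(df["peak_id"], name="peak_id")
        )
        ps = PeakSet(
            fspec.name,
            df,
            tag_counts=tags,
            library_totals={"control": 1_000_000, "knockdown": 1_000_000},
        )
        factor_peaks[fspec.name] = ps
        cob = df.loc[affected, "peak_id"].tolist()
        truth.cobound_peaks[fspec.name] = sorted(cob)
        if config.knockdown_fold > 1.0:
            truth.knockdown_affected.extend(sorted(cob))

    truth.boundaries = sorted({t.start for t in config.tad_layout} | {t.end for t in config.tad_layout})
    truth.tads = [asdict(t) for t in config.tad_layout]
    truth.loops = [asdict(l) for l in config.loops]

    open_peaks = PeakSet(
        "open_chromatin",
        sites.rename(columns={"site_id": "peak_id"})[["chrom", "start", "end", "peak_id"]],
    )
    return RegulatoryData(genes=genes, open_sites=open_peaks, factor_peaks=factor_peaks, truth=truth)


def _bin_pair_weights(config: SimulationConfig, condition: int, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upper-triangle (i, j, weight) arrays for one chromosome/condition."""
    n = config.chrom_length // config.bin_size
    i, j = np.triu_indices(n)
    d = (j - i).astype(float)
    w = np.power(np.maximum(d, 1.0), -config.decay_exponent)
    bs = config.bin_size
    for t in config.tad_layout:
        if t.chrom != chrom:
            continue
        lo, hi = t.start // bs, -(-t.end // bs)
        inside = (i >= lo) & (j < hi)
        w[inside] *= t.enrichment
    for l in config.loops:
        if l.chrom != chrom:
            continue
        b1, b2 = sorted((l.anchor1 // bs, l.anchor2 // bs))
        at = (i == b1) & (j == b2)
        w[at] *= l.intensity1 if condition == 1 else l.intensity2
    return i, j, w


def simulate_contact_reads(config: SimulationConfig) -> tuple[dict[str, pd.DataFrame], SyntheticTruth]:
    """Sample cis read pairs for two conditions.

    Bin-pair linking probability follows distance^(-decay_exponent),
    multiplied by planted TAD enrichments (both ends inside) and per-condition
    loop intensities; pair counts are multinomial at the configured depth and
    positions uniform within bins.  Returns {"cond1": df, "cond2": df} plus
    the planted truth.
    """
    if config.depth > 0 and config.n_chroms == 0:
        raise ValueError("depth > 0 requires at least one chromosome")
    config.__post_init__()  # re-coerce/validate in case fields were mutated
    truth = SyntheticTruth(
        boundaries=sorted({t.start for t in config.tad_layout} | {t.end for t in config.tad_layout}),
        tads=[asdict(t) for t in config.tad_layout],
        loops=[asdict(l) for l in config.loops],
    )
    out: dict[str, pd.DataFrame] = {}
    bs = config.bin_size
    for condition in (1, 2):
        rng = config.rng(f"contacts:cond{condition}")
        frames = []
        per_chrom = [
            _bin_pair_weights(config, condition, chrom) for chrom in config.chrom_names
        ]
        totals = np.array([w.sum() for _, _, w in per_chrom])
        if config.depth > 0 and totals.sum() > 0:
            depth_per = rng.multinomial(config.depth, totals / totals.sum())
        else:
            depth_per = np.zeros(len(per_chrom), dtype=int)
        for (i, j, w), chrom, depth in zip(per_chrom, config.chrom_names, depth_per):
            if depth == 0:
                continue
            counts = rng.multinomial(depth, w / w.sum())
            nz = counts > 0
            b1 = np.repeat(i[nz], counts[nz])
            b2 = np.repeat(j[nz], counts[nz])
            pos1 = b1 * bs + rng.integers(0, bs, size=len(b1))
            pos2 = b2 * bs + rng.integers(0, bs, size=len(b2))
            lo = np.minimum(pos1, pos2)
            hi = np.maximum(pos1, pos2)
            frames.append(
                pd.DataFrame({"chrom1": chrom, "pos1": lo, "chrom2": chrom, "pos2": hi})
            )
        out[f"cond{condition}"] = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=["chrom1", "pos1", "chrom2", "pos2"])
        )
    return out, truth


def write_simulation(config: SimulationConfig, outdir: str | Path) -> None:
    """Emit all synthetic artifacts to a directory.

    Files: genes.tsv, open_chromatin.bed, <factor>.bed + <factor>_tags.tsv,
    pairs_cond1.tsv / pairs_cond2.tsv, chrom_sizes.tsv, truth.json,
    config.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reg = simulate_regulatory_genome(config)
    pairs, contact_truth = simulate_contact_reads(config)

    write_gene_table(reg.genes, outdir / "genes.tsv")
    reg.open_sites.to_bed(outdir / "open_chromatin.bed")
    for name, ps in reg.factor_peaks.items():
        ps.to_bed(outdir / f"{name}.bed")
        tags = ps.tag_counts.copy()
        tags["library_total_control"] = ps.library_totals["control"]
        tags["library_total_knockdown"] = ps.library_totals["knockdown"]
        tags.to_csv(outdir / f"{name}_tags.tsv", sep="\t")
    for cond, df in pairs.items():
        write_pairs(df, outdir / f"pairs_{cond}.tsv")
    pd.DataFrame(
        list(config.chrom_sizes.items()), columns=["chrom", "size"]
    ).to_csv(outdir / "chrom_sizes.tsv", sep="\t", index=False, header=False)

    truth = reg.truth
    truth.boundaries = contact_truth.boundaries
    truth.tads = contact_truth.tads
    truth.loops = contact_truth.loops
    truth.to_json(outdir / "truth.json")
    config.to_json(outdir / "config.json")
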