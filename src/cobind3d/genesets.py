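"""Core gene list construction from differential-expression contrasts, and
expression summaries by promoter binding combination."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from cobind3d.intervals import AnalysisParams

__all__ = [
    "CoreGeneList",
    "core_gene_intersection",
    "binding_combination_expression",
    "read_contrast",
]

_CONTRAST_COLUMNS = ["gene_id", "log2fc", "padj"]


def read_contrast(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _CONTRAST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"contrast table {path} missing columns {missing}")
    return df


@dataclass
class CoreGeneList:
    """Genes passing every contrast, with per-contrast provenance."""

    genes: list[str]
    provenance: pd.DataFrame  # gene_id + log2fc_<contrast>, padj_<contrast>

    def __len__(self) -> int:
        return len(self.genes)

    def to_tsv(self, path) -> None:
        self.provenance.to_csv(path, sep="\t", index=False)


def _validate_contrast(name: str, df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _CONTRAST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"contrast {name!r} missing columns {missing}")
    if ((df["padj"] < 0) | (df["padj"] > 1)).any():
        raise ValueError(f"contrast {name!r} has adjusted p outside [0, 1]")
    dup = df[df["gene_id"].duplicated(keep=False)]
    if len(dup):
        # duplicates are only an error when the records conflict
        if dup.groupby("gene_id")[["log2fc", "padj"]].nunique().gt(1).any().any():
            bad = dup.loc[
                dup.groupby("gene_id")[["log2fc", "padj"]].transform("nunique").gt(1).any(axis=1),
                "gene_id",
            ].unique()
            raise ValueError(
                f"contrast {name!r} has conflicting duplicate records for genes {list(bad)[:5]}"
            )
        df = df.drop_duplicates("gene_id")
    return df


def core_gene_intersection(
    contrasts: Mapping[str, pd.DataFrame] | Sequence[tuple[str, pd.DataFrame]],
    params: AnalysisParams | None = None,
    require_direction: bool = True,
) -> CoreGeneList:
    """Genes significant (padj < cutoff) in every contrast.

    With ``require_direction`` (default) log2fc must additionally be > 0 in
    every contrast — the orientation convention being positive = higher in
    the condition of interest.  Provenance records each contrast's log2fc and
    padj for every member.
    """
    params = params or AnalysisParams()
    items = list(contrasts.items()) if isinstance(contrasts, Mapping) else list(contrasts)
    if not items:
        return CoreGeneList(genes=[], provenance=pd.DataFrame(columns=["gene_id"]))
    merged: pd.DataFrame | None = None
    for name, df in items:
        df = _validate_contrast(name, df)
        passing = df["padj"] < params.padj_cutoff
        if require_direction:
            passing &= df["log2fc"] > 0
        sub = df.loc[passing, _CONTRAST_COLUMNS].rename(
            columns={"log2fc": f"log2fc_{name}", "padj": f"padj_{name}"}
        )
        merged = sub if merged is None else merged.merge(sub, on="gene_id", how="inner")
    merged = merged.sort_values("gene_id").reset_index(drop=True)
    return CoreGeneList(genes=merged["gene_id"].tolist(), provenance=merged)


def binding_combination_expression(
    binding: pd.DataFrame,
    foldchanges: pd.Series | Mapping[str, float],
) -> pd.DataFrame:
    """Summarize expression change by exact promoter-binding combination.

    ``binding`` is a gene x factor 0/1 table (gene_id column plus one column
    per factor); ``foldchanges`` maps gene_id -> log2FC.  Genes are grouped
    by their exact factor combination ("none" for all-zero rows); per-group
    n, median and quartiles of log2FC are returned, empty groups omitted.
    """
    if "gene_id" not in binding.columns:
        raise ValueError("binding table must carry a gene_id column")
    factors = [c for c in binding.columns if c != "gene_id"]
    if not factors:
        raise ValueError("binding table has no factor columns")
    if binding["gene_id"].duplicated().any():
        raise ValueError("binding table has duplicate gene ids")
    fc = pd.Series(foldchanges, dtype=float) if not isinstance(foldchanges, pd.Series) else foldchanges
    missing = [g for g in binding["gene_id"] if g not in fc.index]
    if missing:
        raise ValueError(f"genes missing from foldchanges: {missing[:10]}")

    bvals = binding[factors].astype(bool)
    combo = bvals.apply(lambda r: "+".join([f for f in factors if r[f]]) or "none", axis=1)
    lfc = fc.loc[binding["gene_id"]].to_numpy()
    out = (
        pd.DataFrame({"combination": combo.to_numpy(), "log2fc": lfc})
        .groupby("combination")["log2fc"]
        .agg(
            n="size",
            median="median",
            q1=lambda x: float(np.percentile(x, 25)),
            q3=lambda x: float(np.percentile(x, 75)),
        )
        .reset_index()
        .sort_values("median", ascending=False)
        .reset_index(drop=True)
    )
    return out
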