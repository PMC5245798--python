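"""Co-binding statistics: permutation nulls, hypergeometric overlap,
knockdown fold-change classes.

All stochastic operations take an explicit integer seed (default
``DEFAULT_SEED``), recorded on the returned object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from cobind3d.intervals import AnalysisParams, FeatureClass, PeakSet, annotate_peaks

DEFAULT_SEED = 1007

__all__ = [
    "DEFAULT_SEED",
    "NullDistribution",
    "OverlapTestResult",
    "open_chromatin_permutation",
    "promoter_preference_permutation",
    "hypergeometric_overlap",
    "knockdown_response",
]


@dataclass
class NullDistribution:
    """An empirical null: per-iteration statistic values vs an observed value.

    ``empirical_p`` uses the (r + 1) / (n + 1) estimator for the upper tail,
    so it is never exactly zero.
    """

    n_iter: int
    samples: np.ndarray = field(repr=False)
    observed: float
    seed: int | None = None

    @property
    def mean(self) -> float:
        return float(np.mean(self.samples))

    @property
    def sd(self) -> float:
        return float(np.std(self.samples, ddof=1)) if self.n_iter > 1 else 0.0

    @property
    def empirical_p(self) -> float:
        r = int(np.sum(self.samples >= self.observed))
        return (r + 1) / (self.n_iter + 1)

    def to_dict(self) -> dict:
        return {
            "n_iter": self.n_iter,
            "observed": self.observed,
            "mean": self.mean,
            "sd": self.sd,
            "empirical_p": self.empirical_p,
            "seed": self.seed,
        }


@dataclass
class OverlapTestResult:
    """Upper-tail hypergeometric overlap test.

    ``log10_p`` carries the tail on a log scale so that extreme enrichments
    (p far below float underflow) remain distinguishable; ``p_value`` is
    clamped to the smallest positive float in that regime.
    """

    universe_size: int
    n_a: int
    n_b: int
    observed: int
    p_value: float
    log10_p: float = 0.0

    @property
    def expected(self) -> float:
        return self.n_a * self.n_b / self.universe_size

    @property
    def fold(self) -> float:
        return self.observed / self.expected if self.expected > 0 else float("nan")

    def to_dict(self) -> dict:
        return {
            "universe_size": self.universe_size,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "observed": self.observed,
            "expected": self.expected,
            "fold": self.fold,
            "p_value": self.p_value,
            "log10_p": self.log10_p,
        }


def _universe_size(universe) -> int:
    if isinstance(universe, PeakSet):
        return len(universe)
    return int(universe)


def open_chromatin_permutation(
    open_sites,
    n_a: int,
    n_b: int,
    observed: int,
    n_iter: int = 1000,
    seed: int = DEFAULT_SEED,
) -> NullDistribution:
    """Null distribution of co-binding over an open-chromatin universe.

    Each iteration draws ``n_a`` and ``n_b`` whole sites without replacement
    (two independent draws) from the universe and records the number of sites
    present in both draws.  ``open_sites`` may be a PeakSet or a plain count.
    """
    N = _universe_size(open_sites)
    if n_a > N or n_b > N:
        raise ValueError(f"draw sizes ({n_a}, {n_b}) exceed universe size {N}")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    samples = np.empty(n_iter, dtype=np.int64)
    mask = np.zeros(N, dtype=bool)
    for it in range(n_iter):
        idx_a = rng.choice(N, size=n_a, replace=False)
        idx_b = rng.choice(N, size=n_b, replace=False)
        mask[idx_a] = True
        samples[it] = int(mask[idx_b].sum())
        mask[idx_a] = False
    return NullDistribution(n_iter=n_iter, samples=samples, observed=observed, seed=seed)


def promoter_preference_permutation(
    peaks_a: PeakSet,
    peaks_b: PeakSet,
    k: int,
    observed: int,
    genes,
    params: AnalysisParams | None = None,
    n_iter: int = 1000,
    seed: int = DEFAULT_SEED,
) -> NullDistribution:
    """Null promoter count from mixed draws of k peaks, half from each set.

    Each iteration draws ceil(k/2) peaks from set a and floor(k/2) from set b
    without replacement and counts how many are promoter-classified; compared
    against the observed promoter count of the co-bound set.
    """
    params = params or AnalysisParams()
    k_a, k_b = (k + 1) // 2, k // 2
    if k_a > len(peaks_a) or k_b > len(peaks_b):
        raise ValueError(
            f"half-draws ({k_a}, {k_b}) exceed set sizes ({len(peaks_a)}, {len(peaks_b)})"
        )
    prom_a = (
        annotate_peaks(peaks_a, genes, params)[0] == FeatureClass.PROMOTER.value
    ).to_numpy()
    prom_b = (
        annotate_peaks(peaks_b, genes, params)[0] == FeatureClass.PROMOTER.value
    ).to_numpy()
    rng = np.random.default_rng(seed)
    samples = np.empty(n_iter, dtype=np.int64)
    for it in range(n_iter):
        s = 0
        if k_a:
            s += int(prom_a[rng.choice(len(prom_a), size=k_a, replace=False)].sum())
        if k_b:
            s += int(prom_b[rng.choice(len(prom_b), size=k_b, replace=False)].sum())
        samples[it] = s
    return NullDistribution(n_iter=n_iter, samples=samples, observed=observed, seed=seed)


def hypergeometric_overlap(N: int, n_a: int, n_b: int, k: int) -> OverlapTestResult:
    """P(X >= k) for X ~ Hypergeometric(N, n_a, n_b).

    Stable for universes up to ~1e7 (delegates to scipy's log-space tails).
    """
    if n_a > N or n_b > N:
        raise ValueError(f"marginals ({n_a}, {n_b}) exceed universe {N}")
    if not (0 <= k <= min(n_a, n_b)):
        raise ValueError(f"observed overlap {k} outside [0, min({n_a}, {n_b})]")
    if k == 0:
        logp = 0.0  # upper tail from zero is the whole distribution
    else:
        # sum the tail in log space so extreme tails stay finite on log scale
        support = np.arange(k, min(n_a, n_b) + 1)
        logp = float(
            min(special.logsumexp(stats.hypergeom.logpmf(support, N, n_a, n_b)), 0.0)
        )
    p = float(np.exp(logp))
    if p == 0.0:
        p = np.nextafter(0.0, 1.0)
    return OverlapTestResult(
        universe_size=N,
        n_a=n_a,
        n_b=n_b,
        observed=k,
        p_value=p,
        log10_p=logp / np.log(10.0),
    )


def knockdown_response(
    peaks: PeakSet,
    params: AnalysisParams | None = None,
    control: str = "control",
    knockdown: str = "knockdown",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Depth-normalized fold change of per-peak tags and reduction classes.

    Tags are scaled by norm_depth / library_total per condition; fold =
    scaled_control / max(scaled_knockdown, 1) (one scaled tag as pseudocount).
    Classes are nested: every ">=10-fold reduced" peak is also ">=3-fold
    reduced"; class counts report {ge3, ge10, other}.
    """
    params = params or AnalysisParams()
    if peaks.tag_counts is None:
        raise ValueError("peak set carries no tag counts")
    for col in (control, knockdown):
        if col not in peaks.tag_counts.columns:
            raise ValueError(f"missing tag column {col!r}")
    if not peaks.library_totals:
        raise ValueError("peak set carries no library totals")
    for col in (control, knockdown):
        if peaks.library_totals.get(col, 0) <= 0:
            raise ValueError(f"library total for {col!r} must be > 0")

    t3, t10 = params.fold_thresholds
    sc = peaks.tag_counts[control].to_numpy(float) * (
        params.norm_depth / peaks.library_totals[control]
    )
    sk = peaks.tag_counts[knockdown].to_numpy(float) * (
        params.norm_depth / peaks.library_totals[knockdown]
    )
    fold = sc / np.maximum(sk, 1.0)
    cls = np.where(fold >= t10, "ge10", np.where(fold >= t3, "ge3", "other"))
    out = pd.DataFrame(
        {
            "peak_id": peaks.tag_counts.index,
            "tags_control": peaks.tag_counts[control].to_numpy(),
            "tags_knockdown": peaks.tag_counts[knockdown].to_numpy(),
            "scaled_control": sc,
            "scaled_knockdown": sk,
            "fold_change": fold,
            "reduction_class": cls,
        }
    )
    counts = {
        "ge3": int((fold >= t3).sum()),
        "ge10": int((fold >= t10).sum()),
        "other": int((fold < t3).sum()),
    }
    return out, counts
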