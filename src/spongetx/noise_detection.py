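"""Depth normalization, the k*sqrt(N) sampling-noise model, and detection.

Technical replicates of a count library differ by sampling noise that scales
as sqrt(N) for a count N; the variation between replicates stays below an
envelope of k*sqrt(N) with k = 5 (a conservative >5-sigma bound for Poisson
counting at the depths where detection thresholds live). The relative error
k*sqrt(N)/N shrinks with expression, so a single detection threshold —
calibrated as the smallest count above which replicates always co-detect a
transcript — separates reliably observed transcripts from sampling artifacts.

The envelope is a bound to verify, not a distribution to sample: replicate
simulation uses Poisson by default (negative binomial when a dispersion is
configured).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .io_models import CountTable, ValidationError

__all__ = [
    "NoiseModel",
    "DetectionResult",
    "normalize_depth",
    "envelope",
    "calibrate_detection_threshold",
    "fold_cutoff_for_false_calling",
    "detect_genes",
]


@dataclass(frozen=True)
class NoiseModel:
    """Sampling-error envelope coefficient and replicate distribution.

    ``dispersion`` is the negative-binomial overdispersion alpha in the
    var = mu + alpha * mu^2 parameterization; 0 means Poisson.
    """

    k: float = 5.0
    dispersion: float = 0.0

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError("envelope coefficient k must be > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")

    def sample_replicates(self, means, rng: np.random.Generator,
                          n_reps: int = 2) -> np.ndarray:
        """Draw ``n_reps`` independent replicate count vectors at ``means``."""
        means = np.asarray(means, dtype=float)
        if (means < 0).any():
            raise ValueError("replicate means must be >= 0")
        shape = (n_reps,) + means.shape
        if self.dispersion == 0:
            return rng.poisson(np.broadcast_to(means, shape))
        # NB as gamma-Poisson mixture
        r = 1.0 / self.dispersion
        lam = rng.gamma(r, np.broadcast_to(means, shape) / r)
        return rng.poisson(lam)


def envelope(noise: NoiseModel, n) -> tuple[np.ndarray | float, np.ndarray | float]:
    """(absolute bound k*sqrt(n), relative error k*sqrt(n)/n).

    The relative error is infinite at n = 0 (an undetected transcript has no
    meaningful relative precision).
    """
    n_arr = np.asarray(n, dtype=float)
    if (n_arr < 0).any():
        raise ValueError("count must be >= 0")
    bound = noise.k * np.sqrt(n_arr)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(n_arr > 0, bound / n_arr, np.inf)
    if np.isscalar(n) or n_arr.ndim == 0:
        return float(bound), float(rel)
    return bound, rel


def normalize_depth(table: CountTable, reference: str) -> CountTable:
    """Rescale every sample to the reference sample's sequencing depth.

    Each column is multiplied by total_mapped(reference) / total_mapped(sample)
    — a single per-library proportionality constant, so within-sample ratios
    and rank order are untouched and the reference column is unchanged.
    """
    if table.normalized:
        raise ValidationError("table is already depth-normalized")
    if reference not in table.sample_ids:
        raise ValidationError(f"reference sample {reference!r} not in table")
    factors = table.total_mapped[reference] / table.total_mapped
    counts = table.counts * factors
    return CountTable(counts, table.total_mapped.to_dict(), normalized=True)


def calibrate_detection_threshold(rep1, rep2) -> int:
    """Replicate-concordance detection threshold.

    Returns the smallest integer c such that every gene with count >= c in
    either replicate is detected (count >= 1) in the other. Genes discordant
    at level m (zero in one replicate, m in the other) force c = m + 1, so the
    answer is one more than the largest discordant count; perfectly concordant
    columns give the vacuous threshold 1.
    """
    r1 = np.asarray(rep1, dtype=float)
    r2 = np.asarray(rep2, dtype=float)
    if r1.shape != r2.shape:
        raise ValueError("replicate columns must share gene order and length")
    mx = np.maximum(r1, r2)
    mn = np.minimum(r1, r2)
    discordant = (mn == 0) & (mx > 0)
    if not discordant.any():
        return 1
    return int(math.floor(mx[discordant].max())) + 1


def fold_cutoff_for_false_calling(noise: NoiseModel, n: float, alpha: float,
                                  reps: int = 100_000,
                                  seed: int | np.random.Generator | None = None) -> float:
    """Monte-Carlo fold-change cutoff at a target false-calling rate.

    Simulates technical replicate pairs (X1, X2) at mean ``n`` and returns the
    (1 - alpha) quantile of max/min (zero counts floored at 1): the fold change
    below which a fraction (1 - alpha) of pure-noise gene pairs fall. For
    Poisson noise at large n this approaches exp(z_{1-alpha/2} * sqrt(2/n)).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n <= 0:
        raise ValueError("expression level n must be > 0")
    if reps < 1000:
        raise ValueError("reps must be >= 1000")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = noise.sample_replicates(np.full(reps, float(n)), rng, n_reps=2).astype(float)
    x = np.maximum(x, 1.0)
    ratio = np.maximum(x[0], x[1]) / np.minimum(x[0], x[1])
    return float(np.quantile(ratio, 1.0 - alpha))


@dataclass
class DetectionResult:
    """Detection matrix plus stage-subset summary.

    ``per_subset_counts`` partitions genes detected in at least one stage by
    the exact combination of stages where they exceed the threshold (the
    Venn-diagram cells).
    """

    threshold: float
    detected: pd.DataFrame
    n_detected_any: int
    n_detected_all: int
    per_subset_counts: dict[tuple[str, ...], int]
    raw_threshold_lowest_depth: float | None = None

    def summary(self) -> dict:
        return {
            "threshold": self.threshold,
            "raw_threshold_lowest_depth": self.raw_threshold_lowest_depth,
            "n_detected_any": self.n_detected_any,
            "n_detected_all": self.n_detected_all,
            "per_subset_counts": {"+".join(k): v for k, v in
                                  sorted(self.per_subset_counts.items())},
        }


def detect_genes(table: CountTable, threshold: float,
                 raw_threshold_lowest_depth: float | None = None) -> DetectionResult:
    """Mark genes detected per stage at ``threshold`` (inclusive: >=)."""
    if threshold <= 0:
        raise ValueError("detection threshold must be > 0")
    if not table.normalized:
        raise ValidationError("detection requires a depth-normalized table")
    detected = table.counts >= threshold
    any_mask = detected.any(axis=1)
    subset_counts: dict[tuple[str, ...], int] = {}
    samples = table.sample_ids
    for r in range(1, len(samples) + 1):
        for combo in combinations(samples, r):
            subset_counts[combo] = 0
    patterns = detected[any_mask]
    for _, row in patterns.iterrows():
        combo = tuple(s for s in samples if row[s])
        subset_counts[combo] += 1
    return DetectionResult(
        threshold=float(threshold),
        detected=detected,
        n_detected_any=int(any_mask.sum()),
        n_detected_all=int(detected.all(axis=1).sum()),
        per_subset_counts=subset_counts,
        raw_threshold_lowest_depth=raw_threshold_lowest_depth,
    )
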