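"""Annotation transfer, resampling term enrichment, and stage enrichment.

Functional terms are transferred to genes from the single best surviving
sequence-similarity hit (e-value <= 1e-4 by default). Term enrichment in a
gene set is scored against the detected-gene universe by resampling: R random
draws of equal size without replacement, with the add-one estimator
p = (b + 1)/(R + 1) so no term gets an exact zero; Benjamini-Hochberg controls
the FDR across terms. The engine is vocabulary-agnostic — GO and PANTHER maps
are both just gene->term tables.

Stage enrichment of a gene family uses the at-peak rule: a gene counts toward
a stage when its expression there reaches the upper quarter of its own range
across development; Fisher's exact test compares the family's at-peak rate at
a stage with the remaining detected genes (both one-sided tails reported).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_models import AnnotationRecord, CountTable

__all__ = [
    "EnrichmentResult",
    "AtPeakMatrix",
    "transfer_annotations",
    "resampling_enrichment",
    "bh_adjust",
    "at_peak",
    "stage_family_enrichment",
]


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    universe_size: int
    set_size: int
    term_size: int
    overlap: int
    p_raw: float
    p_adj: float
    direction: str  # "enriched" | "depleted"


@dataclass
class AtPeakMatrix:
    """Gene x stage boolean matrix of the top-25%-of-range rule."""

    matrix: pd.DataFrame
    q: float

    @property
    def universe(self) -> list[str]:
        return list(self.matrix.index)


def transfer_annotations(records: Iterable[AnnotationRecord],
                         subject_terms: Mapping[str, Iterable[str]],
                         evalue_cutoff: float = 1e-4):
    """Assign each gene the terms of its best surviving similarity hit.

    Hits with e-value above the cutoff are discarded; among survivors the hit
    with the lowest e-value wins (ties to the lexicographically smaller
    subject id). Returns (gene -> frozenset of terms, gene -> (subject,
    e-value)); genes with no surviving hit appear in neither and are treated
    as non-annotated downstream.
    """
    best: dict[str, tuple[float, str]] = {}
    for rec in records:
        if rec.evalue > evalue_cutoff:
            continue
        key = (rec.evalue, rec.subject_id)
        if rec.gene_id not in best or key < best[rec.gene_id]:
            best[rec.gene_id] = key
    gene_terms = {g: frozenset(subject_terms.get(subj, ()))
                  for g, (_, subj) in best.items()}
    best_hits = {g: (subj, ev) for g, (ev, subj) in best.items()}
    return gene_terms, best_hits


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def resampling_enrichment(gene_set: Iterable[str],
                          gene_terms: Mapping[str, Iterable[str]],
                          universe: Iterable[str],
                          R: int = 10_000,
                          seed: int | np.random.Generator | None = None,
                          alpha: float = 0.05,
                          chunk: int = 1000) -> list[EnrichmentResult]:
    """Resampling over-representation p-values for every overlapping term.

    For each term present in the gene set, R samples of |gene_set| genes are
    drawn without replacement from the universe (detected annotated genes) and
    p_raw = (#{samples with term count >= observed} + 1)/(R + 1). Results are
    sorted by (adjusted p, raw p, -overlap, term). A seed is mandatory so runs
    are reproducible.
    """
    if seed is None:
        raise ValueError("a seed is required (no implicit randomness)")
    if R < 1000:
        raise ValueError("R must be >= 1000")
    universe = sorted(set(universe))
    gene_set = sorted(set(gene_set))
    if not set(gene_set) <= set(universe):
        raise ValueError("gene_set must be a subset of the universe")
    if not gene_set:
        return []
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    terms = sorted({t for g in universe for t in gene_terms.get(g, ())})
    term_idx = {t: j for j, t in enumerate(terms)}
    member = np.zeros((len(universe), len(terms)), dtype=np.uint8)
    for i, g in enumerate(universe):
        for t in gene_terms.get(g, ()):
            member[i, term_idx[t]] = 1

    set_rows = [universe.index(g) for g in gene_set]
    observed = member[set_rows].sum(axis=0)
    tested = np.flatnonzero(observed >= 1)
    if tested.size == 0:
        return []

    k = len(gene_set)
    exceed = np.zeros(tested.size, dtype=np.int64)
    done = 0
    while done < R:
        m = min(chunk, R - done)
        samples = np.empty((m, k), dtype=np.intp)
        for i in range(m):
            samples[i] = rng.choice(len(universe), size=k, replace=False)
        counts = member[samples][:, :, tested].sum(axis=1)
        exceed += (counts >= observed[tested]).sum(axis=0)
        done += m

    p_raw = (exceed + 1.0) / (R + 1.0)
    p_adj = bh_adjust(p_raw)
    term_sizes = member.sum(axis=0)
    results = [
        EnrichmentResult(
            term=terms[j], universe_size=len(universe), set_size=k,
            term_size=int(term_sizes[j]), overlap=int(observed[j]),
            p_raw=float(pr), p_adj=float(pa), direction="enriched",
        )
        for j, pr, pa in zip(tested, p_raw, p_adj)
    ]
    results.sort(key=lambda r: (r.p_adj, r.p_raw, -r.overlap, r.term))
    return results


def at_peak(table: CountTable, detected_genes: Iterable[str],
            q: float = 0.75, scale: str = "linear",
            pseudocount: float = 1.0) -> AtPeakMatrix:
    """Top-(1-q) of expression-range membership per stage.

    A gene is at-peak in a stage when its value there is >= min + q * range on
    the chosen scale (linear normalized counts by default; ``scale="log"``
    uses log2(count + pseudocount)). Constant genes are at-peak everywhere —
    the inequality holds vacuously when the range is zero.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    values = table.counts.loc[sorted(set(detected_genes))]
    if scale == "log":
        values = np.log2(values + pseudocount)
    elif scale != "linear":
        raise ValueError("scale must be 'linear' or 'log'")
    lo = values.min(axis=1)
    cutoff = lo + q * (values.max(axis=1) - lo)
    matrix = values.ge(cutoff, axis=0)
    return AtPeakMatrix(matrix=matrix, q=q)


def stage_family_enrichment(family: Iterable[str], peaks: AtPeakMatrix,
                            stage: str) -> tuple[EnrichmentResult, EnrichmentResult]:
    """Fisher's exact test of a family's at-peak rate at one stage.

    Builds the 2x2 table [family at-peak / not; non-family at-peak / not] and
    reports both one-sided tails: enrichment (upper) and depletion (lower).
    """
    family = sorted(set(family))
    if not family:
        raise ValueError("family must be non-empty")
    universe = set(peaks.universe)
    if not set(family) <= universe:
        missing = sorted(set(family) - universe)[:3]
        raise ValueError(f"family genes outside the at-peak universe: {missing}")
    col = peaks.matrix[stage]
    fam_mask = col.index.isin(family)
    a = int(col[fam_mask].sum())          # family, at peak
    b = len(family) - a                   # family, not
    c = int(col[~fam_mask].sum())         # background, at peak
    d = int((~fam_mask).sum()) - c        # background, not
    table = np.array([[a, b], [c, d]])
    p_enr = float(stats.fisher_exact(table, alternative="greater")[1])
    p_dep = float(stats.fisher_exact(table, alternative="less")[1])
    common = dict(term=stage, universe_size=len(universe), set_size=len(family),
                  term_size=a + c, overlap=a)
    return (
        EnrichmentResult(**common, p_raw=p_enr, p_adj=p_enr, direction="enriched"),
        EnrichmentResult(**common, p_raw=p_dep, p_adj=p_dep, direction="depleted"),
    )
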