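"""Attribute uniquely mapped reads to exons, introns, and intergenic space.

A read is exonic if at least half of its aligned length overlaps some gene's
exon union, intronic if at least half overlaps a gene span without meeting the
exon rule, and intergenic otherwise. The 50%-of-length rule is robust for
short (~50 nt) reads straddling feature edges. Gene assignment is
strand-agnostic; read strand matters only for the sense/antisense orientation
of intergenic reads relative to their nearest gene.

Intergenic reads are profiled by the distance from the read midpoint to the
nearest gene boundary (TSS or TTS, ties resolved toward the TSS), binned in
``bin_width`` segments out to ``max_distance``; reads farther than that are
counted as distal. Coverage tracks are exported as bedGraph scaled to a fixed
library size (reads per 10 million by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io_models import GeneModel, MappedRead

__all__ = [
    "ReadClass",
    "DistanceProfile",
    "GeneIndex",
    "classify_read",
    "classify_reads",
    "count_exonic_reads",
    "intergenic_profile",
    "export_track",
]

EXON, INTRON, INTERGENIC = "exon", "intron", "intergenic"


@dataclass(frozen=True)
class ReadClass:
    """Attribution outcome for one read.

    ``gene_id`` is set only for exon/intron reads; the boundary fields
    (``nearest_boundary``/``distance_bp``/``orientation``) only for intergenic
    reads with at least one gene on their contig.
    """

    read_id: str
    category: str
    gene_id: str | None = None
    nearest_boundary: str | None = None  # "TSS" | "TTS"
    distance_bp: int | None = None
    orientation: str | None = None  # "sense" | "antisense"

    def __post_init__(self):
        if self.category not in (EXON, INTRON, INTERGENIC):
            raise ValueError(f"bad category {self.category!r}")
        if (self.gene_id is not None) != (self.category != INTERGENIC):
            raise ValueError("gene_id must be set iff category is exon/intron")


@dataclass
class DistanceProfile:
    """Binned distances of intergenic reads from gene boundaries."""

    bin_width: int
    max_distance: int
    counts_by_bin_tss: np.ndarray
    counts_by_bin_tts: np.ndarray
    distal_count: int
    no_neighbor_count: int
    proximal_fraction: float
    sense_fraction: float
    total_intergenic: int

    def as_frame(self) -> pd.DataFrame:
        bins = np.arange(len(self.counts_by_bin_tss)) * self.bin_width
        return pd.DataFrame({
            "bin_start": bins,
            "bin_end": bins + self.bin_width,
            "tss_reads": self.counts_by_bin_tss,
            "tts_reads": self.counts_by_bin_tts,
        })


class GeneIndex:
    """Interval-tree index of gene spans plus per-gene exon unions."""

    def __init__(self, models: Sequence[GeneModel]):
        self.models = {m.gene_id: m for m in models}
        self.trees: dict[str, IntervalTree] = {}
        self.boundaries: dict[str, np.ndarray] = {}
        self._boundary_meta: dict[str, list[tuple[str, str, str]]] = {}
        per_contig: dict[str, list[GeneModel]] = {}
        for m in models:
            per_contig.setdefault(m.span.contig, []).append(m)
        for contig, ms in per_contig.items():
            tree = IntervalTree()
            bpos: list[float] = []
            bmeta: list[tuple[str, str, str]] = []
            for m in ms:
                tree[m.span.start:m.span.end] = m.gene_id
                for pos, kind in ((m.tss, "TSS"), (m.tts, "TTS")):
                    bpos.append(float(pos))
                    bmeta.append((kind, m.gene_id, m.span.strand))
            order = np.argsort(bpos, kind="stable")
            self.trees[contig] = tree
            self.boundaries[contig] = np.asarray(bpos, dtype=float)[order]
            self._boundary_meta[contig] = [bmeta[i] for i in order]

    def overlapping(self, contig: str, start: int, end: int) -> list[GeneModel]:
        tree = self.trees.get(contig)
        if tree is None:
            return []
        return [self.models[iv.data] for iv in tree.overlap(start, end)]

    def nearest_boundary(self, contig: str, midpoint: float):
        """(kind, gene_id, gene_strand, distance) of the closest boundary.

        Ties between a TSS and a TTS at equal distance resolve toward the TSS;
        remaining ties toward the smaller gene_id. Returns None when the
        contig carries no genes.
        """
        pos = self.boundaries.get(contig)
        if pos is None or len(pos) == 0:
            return None
        i = int(np.searchsorted(pos, midpoint))
        best = None
        for j in (i - 1, i, i + 1):
            if 0 <= j < len(pos):
                dist = abs(midpoint - pos[j])
                kind, gene_id, strand = self._boundary_meta[contig][j]
                key = (dist, 0 if kind == "TSS" else 1, gene_id)
                if best is None or key < best[0]:
                    best = (key, (kind, gene_id, strand, dist))
        return best[1]


def _exon_overlap(read: MappedRead, model: GeneModel) -> int:
    return sum(read.interval.overlap_length(e) for e in model.exons)


def classify_read(read: MappedRead, index: GeneIndex) -> ReadClass:
    """Classify one read as exon / intron / intergenic (50%-of-length rule)."""
    half = read.length / 2.0
    candidates = index.overlapping(read.interval.contig, read.interval.start,
                                   read.interval.end)
    exon_best: tuple[int, str] | None = None
    span_best: tuple[int, str] | None = None
    for m in sorted(candidates, key=lambda m: m.gene_id):
        ov_exon = _exon_overlap(read, m)
        ov_span = read.interval.overlap_length(m.span)
        if ov_exon >= half and (exon_best is None or ov_exon > exon_best[0]):
            exon_best = (ov_exon, m.gene_id)
        if ov_span >= half and (span_best is None or ov_span > span_best[0]):
            span_best = (ov_span, m.gene_id)
    if exon_best is not None:
        return ReadClass(read.read_id, EXON, gene_id=exon_best[1])
    if span_best is not None:
        return ReadClass(read.read_id, INTRON, gene_id=span_best[1])
    mid = (read.interval.start + read.interval.end) / 2.0
    nb = index.nearest_boundary(read.interval.contig, mid)
    if nb is None:
        return ReadClass(read.read_id, INTERGENIC)
    kind, gene_id, gene_strand, dist = nb
    orientation = "sense" if read.interval.strand == gene_strand else "antisense"
    return ReadClass(read.read_id, INTERGENIC, nearest_boundary=kind,
                     distance_bp=int(dist), orientation=orientation)


def classify_reads(reads: Iterable[MappedRead],
                   models: Sequence[GeneModel] | GeneIndex) -> list[ReadClass]:
    index = models if isinstance(models, GeneIndex) else GeneIndex(models)
    return [classify_read(r, index) for r in reads]


def count_exonic_reads(read_classes: Iterable[ReadClass],
                       gene_ids: Sequence[str]) -> pd.Series:
    """Per-gene exonic read count, ordered like ``gene_ids``."""
    counts = pd.Series(0, index=pd.Index(gene_ids, name="gene_id"), dtype=int)
    for rc in read_classes:
        if rc.category == EXON and rc.gene_id in counts.index:
            counts[rc.gene_id] += 1
    return counts


def intergenic_profile(read_classes: Iterable[ReadClass], bin_width: int = 1000,
                       max_distance: int = 10_000) -> DistanceProfile:
    """Distance/orientation profile of intergenic reads.

    Reads on geneless contigs have no neighbor; they are counted distal and
    reported separately, and excluded from the sense fraction.
    """
    n_bins = max_distance // bin_width
    tss = np.zeros(n_bins, dtype=int)
    tts = np.zeros(n_bins, dtype=int)
    distal = no_neighbor = total = sense = oriented = 0
    for rc in read_classes:
        if rc.category != INTERGENIC:
            continue
        total += 1
        if rc.orientation is not None:
            oriented += 1
            if rc.orientation == "sense":
                sense += 1
        if rc.distance_bp is None:
            no_neighbor += 1
            distal += 1
            continue
        if rc.distance_bp >= max_distance:
            distal += 1
            continue
        b = rc.distance_bp // bin_width
        (tss if rc.nearest_boundary == "TSS" else tts)[b] += 1
    proximal = total - distal
    return DistanceProfile(
        bin_width=bin_width, max_distance=max_distance,
        counts_by_bin_tss=tss, counts_by_bin_tts=tts,
        distal_count=distal, no_neighbor_count=no_neighbor,
        proximal_fraction=proximal / total if total else 0.0,
        sense_fraction=sense / oriented if oriented else float("nan"),
        total_intergenic=total,
    )


def _format_value(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else f"{v:g}"


def export_track(reads: Sequence[MappedRead], total_mapped: float, out,
                 scale_to: float = 10_000_000.0) -> None:
    """Write depth-scaled per-base coverage as bedGraph runs.

    Each covered base contributes ``scale_to / total_mapped`` so tracks from
    libraries of different depths are directly comparable.
    """
    if total_mapped <= 0:
        raise ValueError("total_mapped must be > 0")
    factor = scale_to / float(total_mapped)
    events: dict[str, dict[int, int]] = {}
    for r in reads:
        iv = r.interval
        d = events.setdefault(iv.contig, {})
        d[iv.start] = d.get(iv.start, 0) + 1
        d[iv.end] = d.get(iv.end, 0) - 1
    with open(out, "w") as fh:
        for contig in sorted(events):
            depth = 0
            prev = None
            for pos in sorted(events[contig]):
                if prev is not None and depth > 0 and pos > prev:
                    fh.write(f"{contig}\t{prev}\t{pos}\t{_format_value(depth * factor)}\n")
                depth += events[contig][pos]
                prev = pos
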