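"""Domain containers and file-format boundaries.

Everything downstream of this module works with 0-based half-open genomic
coordinates. GFF3 (1-based, inclusive) is converted at the boundary in both
directions; BED is native. The containers deliberately carry their own
invariants so that malformed data fails at parse time, not deep inside an
analysis step.

Formats handled here:

* GFF3 gene models (``gene`` features with ``exon`` children),
* BED6 read alignments (single-block; BED12 is rejected),
* the count-table TSV (gene x stage with ``#total_mapped:`` header lines),
* best-hit annotation TSV (``gene_id  subject_id  evalue``),
* gene->term TSV (``gene_id  TERM1,TERM2,...``),
* qPCR Ct TSV (``gene_id  stage  replicate  ct_target  ct_reference``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "ValidationError",
    "GenomicInterval",
    "GeneModel",
    "MappedRead",
    "CountTable",
    "AnnotationRecord",
    "QpcrRecord",
    "merge_intervals",
    "parse_gene_models",
    "write_gene_models",
    "dedup_locus_transcripts",
    "load_alignments",
    "write_alignments",
    "load_count_table",
    "write_count_table",
    "load_annotations",
    "load_terms",
    "write_terms",
    "load_qpcr",
    "load_tables",
]


class ParseError(ValueError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


class ValidationError(ValueError):
    """Structurally parseable input that violates a model invariant."""


_STRANDS = ("+", "-")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded interval on a contig, 0-based half-open."""

    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"interval requires 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in _STRANDS:
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.contig != other.contig:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.overlap_length(other) > 0


def merge_intervals(intervals: Sequence[GenomicInterval]) -> tuple[GenomicInterval, ...]:
    """Union-merge intervals on one contig/strand into disjoint sorted pieces."""
    if not intervals:
        return ()
    contigs = {iv.contig for iv in intervals}
    strands = {iv.strand for iv in intervals}
    if len(contigs) > 1 or len(strands) > 1:
        raise ValidationError("cannot merge intervals across contigs or strands")
    ordered = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    merged: list[GenomicInterval] = [ordered[0]]
    for iv in ordered[1:]:
        last = merged[-1]
        if iv.start <= last.end:
            if iv.end > last.end:
                merged[-1] = replace(last, end=iv.end)
        else:
            merged.append(iv)
    return tuple(merged)


@dataclass(frozen=True)
class GeneModel:
    """A stranded locus: a TSS..TTS span plus a merged exon set.

    ``is_annotated`` and ``terms`` are filled in by annotation transfer;
    parsing leaves them at their defaults.
    """

    gene_id: str
    span: GenomicInterval
    exons: tuple[GenomicInterval, ...]
    is_annotated: bool = False
    terms: frozenset[str] = frozenset()
    best_hit: tuple[str, float] | None = None

    def __post_init__(self):
        if not self.exons:
            raise ValidationError(f"gene {self.gene_id}: needs at least one exon")
        merged = merge_intervals(self.exons)
        if merged != tuple(self.exons):
            object.__setattr__(self, "exons", merged)
        for exon in self.exons:
            if exon.contig != self.span.contig or exon.strand != self.span.strand:
                raise ValidationError(
                    f"gene {self.gene_id}: exon on different contig/strand than span"
                )
            if exon.start < self.span.start or exon.end > self.span.end:
                raise ValidationError(f"gene {self.gene_id}: exon outside gene span")

    @property
    def tss(self) -> int:
        """Transcription start: span start on '+', span end on '-'."""
        return self.span.start if self.span.strand == "+" else self.span.end

    @property
    def tts(self) -> int:
        return self.span.end if self.span.strand == "+" else self.span.start

    @property
    def length(self) -> int:
        return self.span.length


@dataclass(frozen=True)
class MappedRead:
    """A uniquely mapped single-block read."""

    read_id: str
    interval: GenomicInterval

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class AnnotationRecord:
    gene_id: str
    subject_id: str
    evalue: float

    def __post_init__(self):
        if self.evalue < 0:
            raise ValidationError(
                f"gene {self.gene_id}: negative e-value {self.evalue}"
            )


@dataclass(frozen=True)
class QpcrRecord:
    gene_id: str
    stage_id: str
    replicate_index: int
    ct_target: float
    ct_reference: float

    def __post_init__(self):
        for name, ct in (("ct_target", self.ct_target), ("ct_reference", self.ct_reference)):
            if not math.isfinite(ct) or ct <= 0:
                raise ValidationError(
                    f"{self.gene_id}/{self.stage_id}: {name} must be finite and > 0"
                )


class CountTable:
    """Gene x sample read counts with per-sample total-mapped-read metadata.

    ``counts`` is a pandas DataFrame indexed by gene_id with one column per
    sample (stage). ``total_mapped`` is the per-sample library size used for
    depth normalization; ``normalized`` records whether normalization has
    already been applied (re-normalizing is an error upstream).
    """

    def __init__(self, counts: pd.DataFrame, total_mapped: Mapping[str, float],
                 normalized: bool = False):
        counts = counts.astype(float)
        if counts.index.has_duplicates:
            dup = counts.index[counts.index.duplicated()][0]
            raise ValidationError(f"duplicate gene_id in counts: {dup!r}")
        if (counts.to_numpy() < 0).any():
            raise ValidationError("negative read count in table")
        totals = pd.Series({s: float(total_mapped[s]) for s in counts.columns})
        missing = [s for s in counts.columns if s not in total_mapped]
        if missing:
            raise ValidationError(f"total_mapped missing for samples: {missing}")
        if (totals <= 0).any():
            raise ValidationError("total_mapped must be > 0 for every sample")
        self.counts = counts
        self.total_mapped = totals
        self.normalized = bool(normalized)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def subset(self, genes: Iterable[str]) -> "CountTable":
        return CountTable(self.counts.loc[list(genes)], self.total_mapped.to_dict(),
                          self.normalized)

    def __repr__(self):  # pragma: no cover
        return (f"CountTable({len(self.gene_ids)} genes x {len(self.sample_ids)} samples, "
                f"normalized={self.normalized})")


# ---------------------------------------------------------------------------
# GFF3 gene models


def _prevalidate_gff3(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(path, lineno, f"expected 9 tab-separated fields, got {len(fields)}")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise ParseError(path, lineno, "non-integer coordinates") from None
            if start < 1 or end < start:
                raise ParseError(path, lineno, f"bad 1-based coordinates {start}..{end}")
            if fields[6] not in _STRANDS:
                raise ValidationError(
                    f"{path}:{lineno}: unknown strand symbol {fields[6]!r}"
                )


def parse_gene_models(path) -> list[GeneModel]:
    """Parse gene/exon features from a GFF3 file into GeneModels.

    GFF3 coordinates (1-based, inclusive) are converted to internal 0-based
    half-open; exon records sharing a gene are union-merged; output is sorted
    by (contig, span start, gene_id).
    """
    import gffutils

    path = Path(path)
    _prevalidate_gff3(path)
    db = gffutils.create_db(str(path), ":memory:", keep_order=True,
                            merge_strategy="create_unique")
    models = []
    for gene in db.features_of_type("gene"):
        span = GenomicInterval(gene.seqid, gene.start - 1, gene.end, gene.strand)
        exons = []
        for exon in db.children(gene, featuretype="exon"):
            exons.append(GenomicInterval(exon.seqid, exon.start - 1, exon.end, exon.strand))
        if not exons:
            raise ValidationError(f"gene {gene.id}: no exon features")
        models.append(GeneModel(gene_id=gene.id, span=span, exons=tuple(exons)))
    models.sort(key=lambda m: (m.span.contig, m.span.start, m.gene_id))
    return models


def write_gene_models(models: Sequence[GeneModel], path) -> None:
    """Write models back to GFF3 (inverse of parse_gene_models)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in sorted(models, key=lambda m: (m.span.contig, m.span.start, m.gene_id)):
            s = m.span
            fh.write(f"{s.contig}\tspongetx\tgene\t{s.start + 1}\t{s.end}\t.\t"
                     f"{s.strand}\t.\tID={m.gene_id}\n")
            for i, e in enumerate(m.exons, start=1):
                fh.write(f"{e.contig}\tspongetx\texon\t{e.start + 1}\t{e.end}\t.\t"
                         f"{e.strand}\t.\tID={m.gene_id}.exon{i};Parent={m.gene_id}\n")


def dedup_locus_transcripts(models: Sequence[GeneModel]) -> list[GeneModel]:
    """Keep the longest transcript per locus.

    A locus is a connected component of pairwise span overlap among models on
    the same contig and strand. Within a component the model with the greatest
    span length survives; ties break toward the lexicographically smaller
    gene_id so the operation is deterministic.
    """
    kept: list[GeneModel] = []
    by_group: dict[tuple[str, str], list[GeneModel]] = {}
    for m in models:
        by_group.setdefault((m.span.contig, m.span.strand), []).append(m)
    for group in by_group.values():
        group.sort(key=lambda m: (m.span.start, m.span.end, m.gene_id))
        cluster: list[GeneModel] = []
        cluster_end = -1
        for m in group:
            if cluster and m.span.start >= cluster_end:
                kept.append(min(cluster, key=lambda x: (-x.length, x.gene_id)))
                cluster = []
            cluster.append(m)
            cluster_end = max(cluster_end, m.span.end)
        if cluster:
            kept.append(min(cluster, key=lambda x: (-x.length, x.gene_id)))
    kept.sort(key=lambda m: (m.span.contig, m.span.start, m.gene_id))
    return kept


# ---------------------------------------------------------------------------
# BED6 alignments


def load_alignments(path) -> list[MappedRead]:
    """Load single-block reads from BED6 (0-based half-open, strand col 6)."""
    reads: list[MappedRead] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 12:
                raise ParseError(path, lineno,
                                 "BED12 (multi-block) records are not supported")
            if len(fields) != 6:
                raise ParseError(path, lineno,
                                 f"expected 6 tab-separated fields, got {len(fields)}")
            contig, start_s, end_s, read_id, _score, strand = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(path, lineno, "non-integer coordinates") from None
            if start >= end:
                raise ParseError(path, lineno, f"start >= end ({start} >= {end})")
            if strand not in _STRANDS:
                raise ParseError(path, lineno, f"unknown strand symbol {strand!r}")
            reads.append(MappedRead(read_id, GenomicInterval(contig, start, end, strand)))
    return reads


def write_alignments(reads: Sequence[MappedRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            iv = r.interval
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{r.read_id}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# TSV tables


def load_count_table(path) -> CountTable:
    """Read the count-table TSV.

    Layout: one ``#total_mapped:<TAB>sample<TAB>total`` line per sample, an
    optional ``#normalized:<TAB>true`` line, then a header row
    ``gene_id<TAB>stage1<TAB>...`` followed by one row per gene.
    """
    totals: dict[str, float] = {}
    normalized = False
    header: list[str] | None = None
    rows: list[list[str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#total_mapped:"):
                parts = line.split("\t")
                if len(parts) != 3:
                    raise ParseError(path, lineno, "malformed #total_mapped: line")
                totals[parts[1]] = float(parts[2])
                continue
            if line.startswith("#normalized:"):
                normalized = line.split("\t")[-1].strip().lower() == "true"
                continue
            if line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                if header[0] != "gene_id":
                    raise ParseError(path, lineno, "first header column must be gene_id")
                continue
            rows.append(line.split("\t"))
    if header is None:
        raise ParseError(path, 0, "no header row")
    samples = header[1:]
    genes = [r[0] for r in rows]
    try:
        values = np.array([[float(v) for v in r[1:]] for r in rows], dtype=float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric count in {path}: {exc}") from None
    if values.size and values.shape[1] != len(samples):
        raise ValidationError(f"row width does not match header in {path}")
    counts = pd.DataFrame(values.reshape(len(genes), len(samples)),
                          index=pd.Index(genes, name="gene_id"), columns=samples)
    return CountTable(counts, totals, normalized=normalized)


def _format_count(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def write_count_table(table: CountTable, path) -> None:
    with open(path, "w") as fh:
        for sample in table.sample_ids:
            fh.write(f"#total_mapped:\t{sample}\t{_format_count(table.total_mapped[sample])}\n")
        if table.normalized:
            fh.write("#normalized:\ttrue\n")
        fh.write("gene_id\t" + "\t".join(table.sample_ids) + "\n")
        for gene, row in table.counts.iterrows():
            fh.write(gene + "\t" + "\t".join(_format_count(v) for v in row) + "\n")


def load_annotations(path) -> list[AnnotationRecord]:
    """Best-hit table: ``gene_id<TAB>subject_id<TAB>evalue`` with header."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or (lineno == 1 and line.startswith("gene_id")):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParseError(path, lineno, f"expected 3 fields, got {len(fields)}")
            try:
                ev = float(fields[2])
            except ValueError:
                raise ParseError(path, lineno, f"bad e-value {fields[2]!r}") from None
            records.append(AnnotationRecord(fields[0], fields[1], ev))
    return records


def load_terms(path) -> dict[str, frozenset[str]]:
    """Gene->terms map: ``gene_id<TAB>TERM1,TERM2,...``; empty second field ok."""
    terms: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or (lineno == 1 and line.startswith("gene_id")):
                continue
            fields = line.split("\t")
            if len(fields) not in (1, 2):
                raise ParseError(path, lineno, f"expected 1-2 fields, got {len(fields)}")
            gene = fields[0]
            raw = fields[1] if len(fields) == 2 else ""
            terms[gene] = frozenset(t for t in raw.split(",") if t)
    return terms


def write_terms(terms: Mapping[str, Iterable[str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tterms\n")
        for gene in sorted(terms):
            fh.write(f"{gene}\t{','.join(sorted(terms[gene]))}\n")


def load_qpcr(path, known_stages: Sequence[str] | None = None) -> list[QpcrRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or (lineno == 1 and line.startswith("gene_id")):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ParseError(path, lineno, f"expected 5 fields, got {len(fields)}")
            gene, stage, rep_s, ct_t_s, ct_r_s = fields
            if known_stages is not None and stage not in known_stages:
                raise ValidationError(
                    f"{path}:{lineno}: unknown stage {stage!r} (expected one of {list(known_stages)})"
                )
            try:
                rep = int(rep_s)
                ct_t, ct_r = float(ct_t_s), float(ct_r_s)
            except ValueError:
                raise ParseError(path, lineno, "bad numeric field") from None
            records.append(QpcrRecord(gene, stage, rep, ct_t, ct_r))
    return records


def load_tables(counts_path, annotation_path, terms_path, qpcr_path):
    """Load the four TSV inputs with cross-table consistency checks.

    Genes present in the count table but absent from the term map get empty
    term sets; qPCR stages are validated against the count-table samples.
    """
    table = load_count_table(counts_path)
    annotations = load_annotations(annotation_path)
    terms = load_terms(terms_path)
    for gene in table.gene_ids:
        terms.setdefault(gene, frozenset())
    qpcr = load_qpcr(qpcr_path, known_stages=table.sample_ids)
    return table, annotations, terms, qpcr
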