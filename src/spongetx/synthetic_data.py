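"""Synthetic developmental-transcriptome datasets with planted ground truth.

The generator emulates the statistical structure of a four-stage life-cycle
profiling experiment sequenced without biological replicates:

* a gene catalogue laid out on contigs (stranded spans with exon/intron
  structure and intergenic gaps, some of them wide enough to hold distal
  reads),
* per-stage expected counts depth_s * p(g, s) with Poisson sampling (negative
  binomial when a dispersion is configured), where p(g, s) is the true
  per-stage relative abundance; per-stage depths default to the study's
  relative library sizes scaled ~400x down for desk runtime,
* four planted expression classes — constant, stage-specific (one focal
  stage shifted by a log2 effect), transition (a step at one successive-stage
  boundary), and silent,
* an annotation layer (best-hit records with e-values straddling the 1e-4
  cutoff) and a term vocabulary in which a few terms per differential class
  are planted at elevated odds,
* uniquely mapped reads with exact placement labels (exon / intron /
  intergenic with intended nearest boundary, distance, and orientation),
* a qPCR panel whose Ct values are an affine function of log2 expected
  normalized counts plus Gaussian cycle noise.

Every random draw flows from the mandatory config seed, so a given config is
byte-reproducible. The truth record carries everything needed to score the
pipeline's calls against the planted structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io_models import (AnnotationRecord, CountTable, GeneModel, GenomicInterval,
                        MappedRead, QpcrRecord, write_alignments, write_count_table,
                        write_gene_models, write_terms)

__all__ = [
    "SynthConfig",
    "SynthTruth",
    "SynthDataset",
    "generate_dataset",
    "write_dataset",
    "generate_technical_replicates",
    "planted_stage_specific_table",
    "evaluate_calls",
]

STAGES = ("PRE", "COMP", "POST", "ADULT")


@dataclass
class SynthConfig:
    """Generator settings; defaults are the emulated study conditions."""

    seed: int
    n_genes: int = 2000
    n_contigs: int = 20
    stage_ids: tuple[str, ...] = STAGES
    # relative depths follow the study's per-stage mapped-read totals,
    # scaled ~400x down so the whole pipeline runs at desk scale
    depths: tuple[float, ...] = (112_500.0, 82_500.0, 50_000.0, 100_000.0)
    class_fractions: dict = field(default_factory=lambda: {
        "constant": 0.50, "stage_specific": 0.15, "transition": 0.15, "silent": 0.20,
    })
    effect_log2_range: tuple[float, float] = (2.0, 7.0)
    baseline_log2_mean: float = 4.0
    baseline_log2_sd: float = 1.5
    annotated_fraction: float = 0.64
    n_terms: int = 150
    planted_terms_per_class: int = 3
    planted_odds: float = 25.0
    background_term_prob: float = 0.02
    read_fractions: dict = field(default_factory=lambda: {
        "exon": 0.807, "intron": 0.057, "intergenic": 0.136,
    })
    n_reads: int = 50_000
    read_length: int = 50
    intergenic_proximal_fraction: float = 0.9
    intergenic_sense_fraction: float = 0.55
    proximal_max_distance: int = 10_000
    dispersion: float = 0.0
    ct_intercept: float = 30.0
    ct_reference_level: float = 15.0
    ct_noise_sd: float = 0.3
    n_qpcr_genes: int = 50
    n_qpcr_replicates: int = 3

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name, fracs in (("class_fractions", self.class_fractions),
                            ("read_fractions", self.read_fractions)):
            if abs(sum(fracs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        if len(self.depths) != len(self.stage_ids):
            raise ValueError("one depth per stage required")
        if any(d <= 0 for d in self.depths):
            raise ValueError("depths must be > 0")

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown synthetic-config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("stage_ids", "depths", "effect_log2_range"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SynthTruth:
    """Planted ground truth for one generated dataset."""

    genes: pd.DataFrame          # class_label, focal_stage, transition, direction, effect_log2
    expression: pd.DataFrame     # true relative abundance p(g, s), genes x stages
    read_labels: pd.DataFrame    # read_id, category, gene_id, distance_bp, orientation
    planted_terms: dict          # class label -> [term, ...]
    qpcr_true_folds: pd.DataFrame
    config: SynthConfig

    def to_json(self, path) -> None:
        payload = {
            "config": asdict(self.config),
            "genes": self.genes.reset_index().to_dict(orient="list"),
            "expression": {
                "gene_id": list(self.expression.index),
                "stages": list(self.expression.columns),
                "values": self.expression.to_numpy().tolist(),
            },
            "read_labels": self.read_labels.to_dict(orient="list"),
            "planted_terms": self.planted_terms,
            "qpcr_true_folds": {
                "gene_id": list(self.qpcr_true_folds.index),
                "stages": list(self.qpcr_true_folds.columns),
                "values": self.qpcr_true_folds.to_numpy().tolist(),
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, path) -> "SynthTruth":
        with open(path) as fh:
            payload = json.load(fh)
        genes = pd.DataFrame(payload["genes"]).set_index("gene_id")[
            ["class_label", "focal_stage", "transition", "direction", "effect_log2"]]
        expr = pd.DataFrame(payload["expression"]["values"],
                            index=pd.Index(payload["expression"]["gene_id"],
                                           name="gene_id"),
                            columns=payload["expression"]["stages"])
        folds = pd.DataFrame(payload["qpcr_true_folds"]["values"],
                             index=pd.Index(payload["qpcr_true_folds"]["gene_id"],
                                            name="gene_id"),
                             columns=payload["qpcr_true_folds"]["stages"])
        return cls(genes=genes, expression=expr,
                   read_labels=pd.DataFrame(payload["read_labels"]),
                   planted_terms=payload["planted_terms"],
                   qpcr_true_folds=folds,
                   config=SynthConfig.from_dict(payload["config"]))


@dataclass
class SynthDataset:
    models: list
    reads: list
    counts: CountTable
    annotations: list
    subject_terms: dict
    qpcr: list
    truth: SynthTruth


def _partition_classes(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Exact largest-remainder allocation of genes to classes, then shuffled."""
    names = sorted(cfg.class_fractions)
    raw = {c: cfg.class_fractions[c] * cfg.n_genes for c in names}
    counts = {c: int(np.floor(raw[c])) for c in names}
    short = cfg.n_genes - sum(counts.values())
    for c in sorted(names, key=lambda c: raw[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    labels = np.concatenate([np.full(counts[c], c, dtype=object) for c in names])
    rng.shuffle(labels)
    return labels


def _layout_genome(cfg: SynthConfig, rng: np.random.Generator) -> list[GeneModel]:
    """Place stranded multi-exon genes along contigs with mixed-size gaps."""
    gene_ids = [f"g{i:04d}" for i in range(cfg.n_genes)]
    per_contig = np.array_split(np.arange(cfg.n_genes), cfg.n_contigs)
    models = []
    for ci, idxs in enumerate(per_contig):
        contig = f"contig{ci:02d}"
        cursor = 0
        for gi in idxs:
            # ~15% of gaps are wide enough for distal intergenic placements
            if rng.random() < 0.15:
                gap = int(rng.integers(25_000, 40_000))
            else:
                gap = int(rng.integers(2_000, 9_000))
            cursor += gap
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(1, 6))
            exon_lens = rng.integers(150, 600, size=n_exons)
            intron_lens = rng.integers(200, 2000, size=max(0, n_exons - 1))
            exons = []
            pos = cursor
            for j in range(n_exons):
                exons.append(GenomicInterval(contig, pos, pos + int(exon_lens[j]), strand))
                pos += int(exon_lens[j])
                if j < n_exons - 1:
                    pos += int(intron_lens[j])
            span = GenomicInterval(contig, cursor, pos, strand)
            models.append(GeneModel(gene_ids[gi], span, tuple(exons)))
            cursor = pos
    return models


def _plant_expression(cfg: SynthConfig, labels: np.ndarray, rng: np.random.Generator):
    n, stages = cfg.n_genes, list(cfg.stage_ids)
    gene_ids = [f"g{i:04d}" for i in range(n)]
    baseline = 2.0 ** rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=n)
    expr = np.tile(baseline[:, None], (1, len(stages)))
    lo, hi = cfg.effect_log2_range
    info = {"class_label": labels, "focal_stage": np.full(n, "", dtype=object),
            "transition": np.full(n, "", dtype=object),
            "direction": np.full(n, "", dtype=object),
            "effect_log2": np.zeros(n)}
    for i in range(n):
        cls = labels[i]
        if cls == "silent":
            expr[i, :] = 0.0
            continue
        if cls == "constant":
            continue
        e = float(rng.uniform(lo, hi))
        up = rng.random() < 0.5
        info["direction"][i] = "up" if up else "down"
        info["effect_log2"][i] = e if up else -e
        factor = 2.0 ** e if up else 2.0 ** (-e)
        if cls == "stage_specific":
            s = int(rng.integers(len(stages)))
            info["focal_stage"][i] = stages[s]
            expr[i, s] *= factor
        elif cls == "transition":
            t = int(rng.integers(len(stages) - 1))
            info["transition"][i] = f"{stages[t]}->{stages[t + 1]}"
            expr[i, t + 1:] *= factor
    col_sums = expr.sum(axis=0)
    p = expr / col_sums
    genes = pd.DataFrame(info, index=pd.Index(gene_ids, name="gene_id"))
    return genes, pd.DataFrame(p, index=genes.index, columns=stages)


def _draw_counts(cfg: SynthConfig, p: pd.DataFrame, rng: np.random.Generator) -> CountTable:
    depths = np.asarray(cfg.depths, dtype=float)
    mu = p.to_numpy() * depths[None, :]
    if cfg.dispersion > 0:
        r = 1.0 / cfg.dispersion
        mu = rng.gamma(r, np.maximum(mu, 0) / r)
    counts = rng.poisson(mu).astype(float)
    totals = {s: max(1.0, counts[:, j].sum()) for j, s in enumerate(cfg.stage_ids)}
    frame = pd.DataFrame(counts, index=p.index, columns=list(cfg.stage_ids))
    return CountTable(frame, totals, normalized=False)


def _class_sets(genes: pd.DataFrame) -> dict[str, list[str]]:
    """Differential classes that receive planted terms."""
    sets: dict[str, list[str]] = {}
    ss = genes[genes["class_label"] == "stage_specific"]
    for stage, sub in ss[ss["direction"] == "up"].groupby("focal_stage"):
        sets[f"stage_specific:{stage}:up"] = list(sub.index)
    tr = genes[genes["class_label"] == "transition"]
    for (transition, direction), sub in tr.groupby(["transition", "direction"]):
        sets[f"transition:{transition}:{direction}"] = list(sub.index)
    return sets


def _plant_annotation(cfg: SynthConfig, genes: pd.DataFrame, rng: np.random.Generator):
    n = len(genes)
    gene_ids = list(genes.index)
    annotated = rng.random(n) < cfg.annotated_fraction
    subjects = {g: f"SP{i:05d}" for i, g in enumerate(gene_ids)}
    records = []
    for i, g in enumerate(gene_ids):
        if annotated[i]:
            ev = 10.0 ** (-rng.uniform(5.0, 50.0))
            records.append(AnnotationRecord(g, subjects[g], ev))
        elif rng.random() < 0.3:
            # weak hit above the cutoff: parsed, then discarded by transfer
            ev = 10.0 ** (-rng.uniform(0.0, 3.5))
            records.append(AnnotationRecord(g, subjects[g], ev))

    terms = [f"TERM{j:03d}" for j in range(cfg.n_terms)]
    class_sets = _class_sets(genes)
    planted: dict[str, list[str]] = {}
    cursor = 0
    for label in sorted(class_sets):
        take = terms[cursor:cursor + cfg.planted_terms_per_class]
        if len(take) < cfg.planted_terms_per_class:
            break
        planted[label] = take
        cursor += cfg.planted_terms_per_class

    q0 = cfg.background_term_prob
    odds0 = q0 / (1 - q0)
    odds1 = odds0 * cfg.planted_odds
    q1 = odds1 / (1 + odds1)

    gene_terms: dict[str, set[str]] = {g: set() for g in gene_ids}
    member = {label: set(gs) for label, gs in class_sets.items()}
    for j, term in enumerate(terms):
        owner = next((lab for lab, ts in planted.items() if term in ts), None)
        probs = np.full(n, q0)
        if owner is not None:
            in_class = np.fromiter((g in member[owner] for g in gene_ids),
                                   dtype=bool, count=n)
            probs[in_class] = q1
        hits = rng.random(n) < probs
        for g in np.asarray(gene_ids, dtype=object)[hits]:
            gene_terms[g].add(term)

    subject_terms = {subjects[g]: sorted(gene_terms[g])
                     for i, g in enumerate(gene_ids) if annotated[i]}
    return records, subject_terms, planted


def _intergenic_sides(cfg: SynthConfig, models: list[GeneModel]):
    """Candidate placement sides: (contig, boundary, sign, room, kind, gene, strand)."""
    per_contig: dict[str, list[GeneModel]] = {}
    for m in models:
        per_contig.setdefault(m.span.contig, []).append(m)
    L = cfg.read_length
    sides = []
    for contig, ms in per_contig.items():
        ms = sorted(ms, key=lambda m: m.span.start)
        first = ms[0]
        kind = "TSS" if first.span.strand == "+" else "TTS"
        sides.append((contig, first.span.start, -1, first.span.start - L,
                      kind, first.gene_id, first.span.strand))
        for left, right in zip(ms[:-1], ms[1:]):
            room = (right.span.start - left.span.end - L) / 2.0 - 1
            lk = "TTS" if left.span.strand == "+" else "TSS"
            rk = "TSS" if right.span.strand == "+" else "TTS"
            sides.append((contig, left.span.end, +1, room, lk, left.gene_id,
                          left.span.strand))
            sides.append((contig, right.span.start, -1, room, rk, right.gene_id,
                          right.span.strand))
        last = ms[-1]
        kind = "TTS" if last.span.strand == "+" else "TSS"
        sides.append((contig, last.span.end, +1, 25_000.0, kind, last.gene_id,
                      last.span.strand))
    return sides


def _generate_reads(cfg: SynthConfig, models: list[GeneModel], p: pd.DataFrame,
                    rng: np.random.Generator):
    L = cfg.read_length
    by_gene = {m.gene_id: m for m in models}
    weights = p.iloc[:, 0].reindex([m.gene_id for m in models]).to_numpy()
    exon_ok = np.array([any(e.length >= L for e in m.exons) for m in models])
    introns = {}
    for m in models:
        gaps = [(a.end, b.start) for a, b in zip(m.exons[:-1], m.exons[1:])
                if b.start - a.end >= L]
        if gaps:
            introns[m.gene_id] = gaps
    intron_ok = np.array([m.gene_id in introns for m in models])

    def normalized(mask):
        w = np.where(mask, weights, 0.0)
        total = w.sum()
        if total <= 0:
            w = mask.astype(float)
            total = w.sum()
        return w / total

    w_exon = normalized(exon_ok)
    w_intron = normalized(intron_ok)
    gene_arr = np.array([m.gene_id for m in models], dtype=object)

    cats = rng.choice(["exon", "intron", "intergenic"], size=cfg.n_reads,
                      p=[cfg.read_fractions[c] for c in ("exon", "intron", "intergenic")])
    sides = _intergenic_sides(cfg, models)
    prox_sides = [s for s in sides if s[3] >= L + 10]
    distal_sides = [s for s in sides if s[3] >= cfg.proximal_max_distance + L + 10]

    reads, labels = [], []
    for i, cat in enumerate(cats):
        rid = f"r{i:06d}"
        if cat == "exon":
            g = gene_arr[rng.choice(len(gene_arr), p=w_exon)]
            m = by_gene[g]
            eligible = [e for e in m.exons if e.length >= L]
            lens = np.array([e.length - L + 1 for e in eligible], dtype=float)
            e = eligible[rng.choice(len(eligible), p=lens / lens.sum())]
            start = int(rng.integers(e.start, e.end - L + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            reads.append(MappedRead(rid, GenomicInterval(m.span.contig, start,
                                                         start + L, strand)))
            labels.append((rid, "exon", g, None, None))
        elif cat == "intron":
            g = gene_arr[rng.choice(len(gene_arr), p=w_intron)]
            m = by_gene[g]
            gaps = introns[g]
            lens = np.array([b - a - L + 1 for a, b in gaps], dtype=float)
            a, b = gaps[rng.choice(len(gaps), p=lens / lens.sum())]
            start = int(rng.integers(a, b - L + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            reads.append(MappedRead(rid, GenomicInterval(m.span.contig, start,
                                                         start + L, strand)))
            labels.append((rid, "intron", g, None, None))
        else:
            proximal = rng.random() < cfg.intergenic_proximal_fraction
            pool = prox_sides if proximal else distal_sides
            contig, b, sign, room, kind, gene, gstrand = pool[rng.choice(len(pool))]
            if proximal:
                d_hi = int(min(cfg.proximal_max_distance - 1, room))
                d = int(rng.integers(L, d_hi + 1))
            else:
                d_hi = int(min(room, cfg.proximal_max_distance + 15_000))
                d = int(rng.integers(cfg.proximal_max_distance + L, d_hi + 1))
            mid = b + sign * d
            start = int(mid - L // 2)
            sense = rng.random() < cfg.intergenic_sense_fraction
            strand = gstrand if sense else ("-" if gstrand == "+" else "+")
            reads.append(MappedRead(rid, GenomicInterval(contig, start, start + L,
                                                         strand)))
            labels.append((rid, "intergenic", None, d,
                           "sense" if sense else "antisense"))
    label_frame = pd.DataFrame(labels, columns=["read_id", "category", "gene_id",
                                                "distance_bp", "orientation"])
    return reads, label_frame


def _generate_qpcr(cfg: SynthConfig, genes: pd.DataFrame, p: pd.DataFrame,
                   rng: np.random.Generator):
    expressed = list(genes.index[genes["class_label"] != "silent"])
    n_panel = min(cfg.n_qpcr_genes, len(expressed))
    panel = sorted(rng.choice(expressed, size=n_panel, replace=False))
    ref_depth = cfg.depths[0]
    stages = list(cfg.stage_ids)
    records = []
    true_folds = {}
    for g in panel:
        m = ref_depth * p.loc[g, stages].to_numpy()  # expected normalized count
        dct_true = cfg.ct_intercept - np.log2(m + 1.0)
        true_folds[g] = (m + 1.0) / (m[0] + 1.0)
        for j, s in enumerate(stages):
            for rep in range(1, cfg.n_qpcr_replicates + 1):
                ct_ref = cfg.ct_reference_level + float(rng.normal(0, 0.05))
                ct_t = ct_ref + float(dct_true[j]) + float(rng.normal(0, cfg.ct_noise_sd))
                records.append(QpcrRecord(g, s, rep, ct_t, ct_ref))
    folds = pd.DataFrame.from_dict(true_folds, orient="index", columns=stages)
    folds.index.name = "gene_id"
    return records, folds


def generate_technical_replicates(cfg: SynthConfig, expression,
                                  rng: np.random.Generator | None = None,
                                  depth: float | None = None):
    """Two independent library draws from the same expression vector.

    ``expression`` is a vector of non-negative relative abundances; each
    replicate is a Poisson (or NB) draw at mean depth * p. Defaults to the
    lowest configured stage depth — the setting where the detection threshold
    is calibrated.
    """
    expression = np.asarray(expression, dtype=float)
    if (expression < 0).any():
        raise ValueError("expression must be >= 0")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    depth = depth if depth is not None else min(cfg.depths)
    total = expression.sum()
    mu = depth * (expression / total if total > 0 else expression)
    if cfg.dispersion > 0:
        r = 1.0 / cfg.dispersion
        rep1 = rng.poisson(rng.gamma(r, mu / r))
        rep2 = rng.poisson(rng.gamma(r, mu / r))
    else:
        rep1 = rng.poisson(mu)
        rep2 = rng.poisson(mu)
    return rep1, rep2


def planted_stage_specific_table(n_genes: int, baseline: float, fold: float,
                                 focal: str, seed: int,
                                 stage_ids=STAGES,
                                 planted_fraction: float = 0.5,
                                 direction: str = "up") -> tuple[CountTable, pd.DataFrame]:
    """Small controlled table for recovery experiments.

    Half the genes (by default) carry an exact ``fold`` shift at ``focal``
    on a flat baseline; counts are Poisson draws around those means and the
    table is returned as already depth-normalized (all stages at a common
    depth). The truth frame marks planted genes and their direction.
    """
    rng = np.random.default_rng(seed)
    stages = list(stage_ids)
    gene_ids = [f"p{i:04d}" for i in range(n_genes)]
    planted = np.zeros(n_genes, dtype=bool)
    planted[: int(round(planted_fraction * n_genes))] = True
    rng.shuffle(planted)
    mu = np.full((n_genes, len(stages)), float(baseline))
    j = stages.index(focal)
    shift = fold if direction == "up" else 1.0 / fold
    mu[planted, j] *= shift
    counts = rng.poisson(mu).astype(float)
    frame = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                         columns=stages)
    table = CountTable(frame, {s: float(n_genes * baseline) for s in stages},
                       normalized=True)
    truth = pd.DataFrame({"planted": planted,
                          "direction": np.where(planted, direction, "")},
                         index=frame.index)
    return table, truth


def generate_dataset(cfg: SynthConfig) -> SynthDataset:
    """Generate a complete in-memory dataset plus its truth record."""
    streams = np.random.SeedSequence(cfg.seed).spawn(6)
    rng_class, rng_layout, rng_expr, rng_counts, rng_reads, rng_rest = (
        np.random.default_rng(s) for s in streams)
    labels = _partition_classes(cfg, rng_class)
    models = _layout_genome(cfg, rng_layout)
    genes, p = _plant_expression(cfg, labels, rng_expr)
    counts = _draw_counts(cfg, p, rng_counts)
    reads, read_labels = _generate_reads(cfg, models, p, rng_reads)
    annotations, subject_terms, planted = _plant_annotation(cfg, genes, rng_rest)
    qpcr, true_folds = _generate_qpcr(cfg, genes, p, rng_rest)
    truth = SynthTruth(genes=genes, expression=p, read_labels=read_labels,
                       planted_terms=planted, qpcr_true_folds=true_folds,
                       config=cfg)
    return SynthDataset(models=models, reads=reads, counts=counts,
                        annotations=annotations, subject_terms=subject_terms,
                        qpcr=qpcr, truth=truth)


def write_dataset(ds: SynthDataset, out_dir) -> dict[str, Path]:
    """Write every component in the pipeline's input formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "models": out / "models.gff3",
        "reads": out / "reads.bed",
        "counts": out / "counts.tsv",
        "annotations": out / "annotations.tsv",
        "terms": out / "terms.tsv",
        "qpcr": out / "qpcr.tsv",
        "truth": out / "truth.json",
    }
    write_gene_models(ds.models, paths["models"])
    write_alignments(ds.reads, paths["reads"])
    write_count_table(ds.counts, paths["counts"])
    with open(paths["annotations"], "w") as fh:
        fh.write("gene_id\tsubject_id\tevalue\n")
        for rec in ds.annotations:
            fh.write(f"{rec.gene_id}\t{rec.subject_id}\t{rec.evalue:.6e}\n")
    write_terms(ds.subject_terms, paths["terms"])
    with open(paths["qpcr"], "w") as fh:
        fh.write("gene_id\tstage\treplicate\tct_target\tct_reference\n")
        for r in ds.qpcr:
            fh.write(f"{r.gene_id}\t{r.stage_id}\t{r.replicate_index}\t"
                     f"{r.ct_target!r}\t{r.ct_reference!r}\n")
    ds.truth.to_json(paths["truth"])
    return paths


def evaluate_calls(truth: SynthTruth, calls: pd.DataFrame,
                   enrichment_results: dict | None = None) -> dict:
    """Score pipeline calls against the planted truth.

    ``calls`` is a tidy frame (gene_id, contrast, direction) from the
    stage-specific or transition analysis. Stage-specific metrics treat a
    gene as called when any focal-stage contrast is non-unchanged; transition
    metrics are scored per planted transition. ``enrichment_results`` maps a
    differential-class label to its ordered EnrichmentResult list; the rank of
    each planted term (1-based position in the ordering) is reported.
    """
    calls = calls.reset_index(drop=True)
    known = set(truth.genes.index)
    extra = set(calls["gene_id"]) - known
    if extra:
        raise ValueError(f"gene id mismatch between truth and calls: {sorted(extra)[:3]}")

    metrics: dict = {}
    null_genes = set(truth.genes.index[
        truth.genes["class_label"].isin(["constant", "silent"])])
    stage_contrasts = set(truth.config.stage_ids)
    stage_calls = calls[calls["contrast"].isin(stage_contrasts)]
    if len(stage_calls):
        called = stage_calls[stage_calls["direction"] != "unchanged"]
        called_genes = set(called["gene_id"])
        truth_ss = truth.genes[truth.genes["class_label"] == "stage_specific"]
        tp = called_genes & set(truth_ss.index)
        metrics["stage_specific"] = {
            "n_true": int(len(truth_ss)),
            "n_called": int(len(called_genes)),
            "sensitivity": len(tp) / len(truth_ss) if len(truth_ss) else float("nan"),
            # calls on genes with no planted change at all
            "false_discovery_proportion":
                len(called_genes & null_genes) / len(called_genes) if called_genes else 0.0,
        }
        # direction accuracy among correct-locus calls at the planted focal stage
        merged = called.merge(truth_ss, left_on="gene_id", right_index=True)
        at_focal = merged[merged["contrast"] == merged["focal_stage"]]
        if len(at_focal):
            metrics["stage_specific"]["direction_accuracy"] = float(
                (at_focal["direction_x"] == at_focal["direction_y"]).mean())

    transition_calls_df = calls[calls["contrast"].str.contains("->", regex=False)]
    if len(transition_calls_df):
        called = transition_calls_df[transition_calls_df["direction"] != "unchanged"]
        truth_tr = truth.genes[truth.genes["class_label"] == "transition"]
        key_called = set(zip(called["gene_id"], called["contrast"]))
        key_true = set(zip(truth_tr.index, truth_tr["transition"]))
        tp_keys = key_called & key_true
        null_calls = {k for k in key_called if k[0] in null_genes}
        metrics["transition"] = {
            "n_true": int(len(key_true)),
            "n_called": int(len(key_called)),
            "sensitivity": len(tp_keys) / len(key_true) if key_true else float("nan"),
            "false_discovery_proportion":
                len(null_calls) / len(key_called) if key_called else 0.0,
        }
        merged = called.merge(truth_tr, left_on="gene_id", right_index=True)
        hit = merged[merged["contrast"] == merged["transition"]]
        if len(hit):
            metrics["transition"]["direction_accuracy"] = float(
                (hit["direction_x"] == hit["direction_y"]).mean())

    if enrichment_results:
        ranks: dict[str, dict[str, int | None]] = {}
        for label, results in enrichment_results.items():
            order = [r.term for r in results]
            ranks[label] = {term: (order.index(term) + 1 if term in order else None)
                            for term in truth.planted_terms.get(label, [])}
        metrics["planted_term_ranks"] = ranks
    return metrics
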