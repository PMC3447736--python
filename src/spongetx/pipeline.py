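"""End-to-end orchestration: simulate/ingest -> attribute -> detect -> DE ->
enrich -> qPCR -> report.

A run is driven by one JSON config holding either a synthetic-data block or
explicit input paths, plus analysis parameters. A single top-level seed is
fanned out to per-stage seeds through ``numpy.random.SeedSequence(seed).spawn``
(fixed order: synthetic data, calibration replicates, enrichment resampling),
so any stage can be re-run in isolation reproducibly and two runs with the
same config and seed produce byte-identical output bundles. Each stage writes
plain TSV/JSON and consumes only files or objects produced by earlier stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .differential_expression import (AnalysisParams, extreme_table,
                                      relative_expression_matrix,
                                      settlement_calls, stage_specific_calls,
                                      transition_calls)
from .enrichment import (at_peak, resampling_enrichment, stage_family_enrichment,
                         transfer_annotations)
from .io_models import (load_alignments, load_annotations, load_count_table,
                        load_qpcr, load_terms, parse_gene_models, write_count_table)
from .noise_detection import (NoiseModel, calibrate_detection_threshold,
                              detect_genes, normalize_depth)
from .qpcr_validation import anova_bonferroni, concordance, delta_delta_ct, qpcr_long_frame
from .read_attribution import (GeneIndex, classify_reads, count_exonic_reads,
                               export_track, intergenic_profile)
from .synthetic_data import (SynthConfig, evaluate_calls, generate_dataset,
                             generate_technical_replicates, write_dataset)

__all__ = ["ConfigError", "StageError", "PipelineConfig", "validate_config", "run_all"]

log = logging.getLogger("spongetx")


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


_PARAM_KEYS = {"fold_cutoff", "alpha", "pseudocount", "k", "detection_threshold",
               "peak_fraction", "extreme_log2"}
_ENRICH_KEYS = {"R", "q", "evalue_cutoff", "min_family_size", "max_families"}
_TOP_KEYS = {"seed", "synth", "inputs", "params", "noise", "enrichment", "log_level"}
_INPUT_KEYS = {"models", "reads", "counts", "annotations", "terms", "qpcr"}

_ENRICH_DEFAULTS = {"R": 10_000, "q": 0.75, "evalue_cutoff": 1e-4,
                    "min_family_size": 10, "max_families": 20}


@dataclass
class PipelineConfig:
    seed: int
    synth: SynthConfig | None
    inputs: dict | None
    params: AnalysisParams
    params_permissive: AnalysisParams
    noise: NoiseModel
    enrichment: dict
    log_level: str = "info"
    auto_threshold: bool = False

    def resolved(self) -> dict:
        out = {
            "seed": self.seed,
            "params": dataclasses.asdict(self.params),
            "noise": dataclasses.asdict(self.noise),
            "enrichment": dict(self.enrichment),
            "log_level": self.log_level,
        }
        if self.auto_threshold:
            out["params"]["detection_threshold"] = None
        if self.synth is not None:
            out["synth"] = dataclasses.asdict(self.synth)
        if self.inputs is not None:
            out["inputs"] = dict(self.inputs)
        return out


def _derived_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(3)
    names = ("synth", "calibration", "enrichment")
    return {n: int(c.generate_state(1)[0] % (2 ** 31)) for n, c in zip(names, children)}


def validate_config(config) -> PipelineConfig:
    """Validate a config dict (or JSON file path) and fill defaults.

    Unknown keys are rejected with a message listing them — no silent ignore.
    Re-validating a resolved config yields an identical structure.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = json.load(fh)
    unknown = set(config) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "seed" not in config:
        raise ConfigError("a top-level 'seed' is required")
    seed = int(config["seed"])
    has_synth = "synth" in config and config["synth"] is not None
    has_inputs = "inputs" in config and config["inputs"] is not None
    if has_synth == has_inputs:
        raise ConfigError("exactly one of 'synth' or 'inputs' must be present")

    synth = None
    inputs = None
    if has_synth:
        block = dict(config["synth"])
        block.setdefault("seed", _derived_seeds(seed)["synth"])
        try:
            synth = SynthConfig.from_dict(block)
        except (ValueError, TypeError) as exc:
            raise ConfigError(f"synth: {exc}") from exc
    else:
        inputs = dict(config["inputs"])
        unknown = set(inputs) - _INPUT_KEYS
        if unknown:
            raise ConfigError(f"unknown input keys: {sorted(unknown)}")
        for need in ("models", "counts"):
            if need not in inputs:
                raise ConfigError(f"inputs must include {need!r}")
        for key, path in inputs.items():
            if not Path(path).exists():
                raise ConfigError(f"input file for {key!r} does not exist: {path}")

    params_block = dict(config.get("params") or {})
    unknown = set(params_block) - _PARAM_KEYS
    if unknown:
        raise ConfigError(f"unknown params keys: {sorted(unknown)}")
    auto_threshold = params_block.get("detection_threshold", 64.0) is None
    if auto_threshold:
        params_block["detection_threshold"] = 64.0  # placeholder until calibrated
    try:
        params = AnalysisParams(**params_block)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"params: {exc}") from exc

    noise_block = dict(config.get("noise") or {})
    unknown = set(noise_block) - {"k", "dispersion"}
    if unknown:
        raise ConfigError(f"unknown noise keys: {sorted(unknown)}")
    try:
        noise = NoiseModel(**noise_block)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"noise: {exc}") from exc

    enrich = dict(_ENRICH_DEFAULTS)
    block = dict(config.get("enrichment") or {})
    unknown = set(block) - _ENRICH_KEYS
    if unknown:
        raise ConfigError(f"unknown enrichment keys: {sorted(unknown)}")
    enrich.update(block)
    if not 0 < enrich["q"] < 1:
        raise ConfigError("enrichment: q must be in (0, 1)")

    level = str(config.get("log_level", "info")).lower()
    if level not in ("debug", "info", "warning", "error"):
        raise ConfigError(f"log_level: unknown level {level!r}")

    permissive = dataclasses.replace(params, fold_cutoff=2.0)
    return PipelineConfig(seed=seed, synth=synth, inputs=inputs, params=params,
                          params_permissive=permissive, noise=noise,
                          enrichment=enrich, log_level=level,
                          auto_threshold=auto_threshold)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_enrichment(rows, path):
    frame = pd.DataFrame([{
        "gene_set": label, "term": r.term, "universe_size": r.universe_size,
        "set_size": r.set_size, "term_size": r.term_size, "overlap": r.overlap,
        "p_raw": r.p_raw, "p_adj": r.p_adj, "direction": r.direction,
    } for label, results in rows for r in results])
    frame.to_csv(path, sep="\t", index=False)
    return frame


def run_all(config: PipelineConfig, out_dir) -> dict:
    """Run every stage and write the report bundle under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr,
                        level=getattr(logging, config.log_level.upper()))
    seeds = _derived_seeds(config.seed)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "derived_seeds": seeds, "config": config.resolved(),
                      "inputs": {}, "outputs": []}

    stage = "ingest"
    try:
        truth = None
        if config.synth is not None:
            log.info("generating synthetic dataset (n_genes=%d)", config.synth.n_genes)
            ds = generate_dataset(config.synth)
            data_dir = out / "data"
            paths = write_dataset(ds, data_dir)
            models, reads, counts = ds.models, ds.reads, ds.counts
            annotations, subject_terms, qpcr = (ds.annotations, ds.subject_terms,
                                                ds.qpcr)
            truth = ds.truth
            manifest["inputs"] = {k: _sha256(p) for k, p in sorted(paths.items())}
        else:
            paths = {k: Path(v) for k, v in config.inputs.items()}
            models = parse_gene_models(paths["models"])
            counts = load_count_table(paths["counts"])
            reads = load_alignments(paths["reads"]) if "reads" in paths else None
            annotations = (load_annotations(paths["annotations"])
                           if "annotations" in paths else [])
            subject_terms = load_terms(paths["terms"]) if "terms" in paths else {}
            qpcr = (load_qpcr(paths["qpcr"], known_stages=counts.sample_ids)
                    if "qpcr" in paths else [])
            manifest["inputs"] = {k: _sha256(p) for k, p in sorted(paths.items())}

        stage = "attribution"
        if reads:
            index = GeneIndex(models)
            classes = classify_reads(reads, index)
            cls_frame = pd.DataFrame([{
                "read_id": c.read_id, "category": c.category,
                "gene_id": c.gene_id or "", "nearest_boundary": c.nearest_boundary or "",
                "distance_bp": "" if c.distance_bp is None else c.distance_bp,
                "orientation": c.orientation or "",
            } for c in classes])
            cls_frame.to_csv(out / "read_classes.tsv", sep="\t", index=False)
            profile = intergenic_profile(classes)
            profile.as_frame().to_csv(out / "intergenic_profile.tsv", sep="\t",
                                      index=False)
            with open(out / "attribution_summary.json", "w") as fh:
                cats = cls_frame["category"].value_counts()
                json.dump({
                    "n_reads": len(classes),
                    "fractions": {c: float(cats.get(c, 0)) / len(classes)
                                  for c in ("exon", "intron", "intergenic")},
                    "proximal_fraction": profile.proximal_fraction,
                    "sense_fraction": profile.sense_fraction,
                }, fh, sort_keys=True, indent=1)
            export_track(reads, total_mapped=len(reads), out=out / "coverage.bedGraph")
        else:
            log.info("no reads provided; attribution stage skipped")

        stage = "normalization"
        reference = counts.sample_ids[0]
        norm = normalize_depth(counts, reference)
        write_count_table(norm, out / "normalized_counts.tsv")

        stage = "detection"
        params = config.params
        raw_threshold = None
        if config.auto_threshold:
            if truth is None:
                raise ValueError("automatic threshold calibration requires "
                                 "synthetic input (technical replicates)")
            lowest = int(np.argmin(np.asarray(config.synth.depths)))
            rng = np.random.default_rng(seeds["calibration"])
            rep1, rep2 = generate_technical_replicates(
                config.synth, truth.expression.iloc[:, lowest].to_numpy(), rng=rng,
                depth=config.synth.depths[lowest])
            raw_threshold = calibrate_detection_threshold(rep1, rep2)
            factor = counts.total_mapped[reference] / counts.total_mapped.min()
            params = dataclasses.replace(params,
                                         detection_threshold=raw_threshold * factor)
            log.info("calibrated raw threshold %s -> normalized %.1f",
                     raw_threshold, params.detection_threshold)
        detection = detect_genes(norm, params.detection_threshold,
                                 raw_threshold_lowest_depth=raw_threshold)
        detection.detected.to_csv(out / "detection.tsv", sep="\t")
        with open(out / "detection_summary.json", "w") as fh:
            json.dump(detection.summary(), fh, sort_keys=True, indent=1)
        detected_any = list(detection.detected.index[detection.detected.any(axis=1)])

        stage = "differential_expression"
        stage_df = stage_specific_calls(norm, params, genes=detected_any)
        stage_df.to_csv(out / "calls_stage.tsv", sep="\t", index=False)
        settle_df = settlement_calls(norm, params, genes=detected_any)
        settle_df.to_csv(out / "calls_settlement.tsv", sep="\t", index=False)
        trans4 = transition_calls(norm, params)
        trans4.to_csv(out / "calls_transition_fold4.tsv", sep="\t", index=False)
        trans2 = transition_calls(norm, config.params_permissive)
        trans2.to_csv(out / "calls_transition_fold2.tsv", sep="\t", index=False)
        extremes = extreme_table(norm, params, genes=detected_any)
        extremes.to_csv(out / "extreme_genes.tsv", sep="\t")
        relative_expression_matrix(norm, genes=detected_any, params=params) \
            .to_csv(out / "relative_expression.tsv", sep="\t")

        stage = "enrichment"
        gene_terms, _best = transfer_annotations(
            annotations, subject_terms,
            evalue_cutoff=config.enrichment["evalue_cutoff"])
        universe = sorted(set(detected_any) & set(gene_terms))
        gene_sets: dict[str, set] = {}
        for (contrast, direction), sub in trans4[trans4["direction"] != "unchanged"] \
                .groupby(["contrast", "direction"]):
            gene_sets[f"transition:{contrast}:{direction}"] = set(sub["gene_id"])
        for (contrast, direction), sub in stage_df[stage_df["direction"] != "unchanged"] \
                .groupby(["contrast", "direction"]):
            gene_sets[f"stage_specific:{contrast}:{direction}"] = set(sub["gene_id"])
        rng = np.random.default_rng(seeds["enrichment"])
        enrichment_rows = []
        enrichment_by_label = {}
        for label in sorted(gene_sets):
            members = sorted(gene_sets[label] & set(universe))
            if not members:
                continue
            results = resampling_enrichment(members, gene_terms, universe,
                                            R=config.enrichment["R"], seed=rng)
            enrichment_rows.append((label, results))
            enrichment_by_label[label] = results
        _write_enrichment(enrichment_rows, out / "enrichment.tsv")

        peaks = at_peak(norm, detected_any, q=config.enrichment["q"])
        term_members: dict[str, set] = {}
        for g in universe:
            for t in gene_terms.get(g, ()):
                term_members.setdefault(t, set()).add(g)
        families = sorted(
            (t for t, m in term_members.items()
             if len(m) >= config.enrichment["min_family_size"]),
            key=lambda t: (-len(term_members[t]), t),
        )[: config.enrichment["max_families"]]
        fam_rows = []
        for fam in families:
            members = sorted(term_members[fam] & set(peaks.universe))
            if not members:
                continue
            for s in norm.sample_ids:
                enr, dep = stage_family_enrichment(members, peaks, s)
                fam_rows.append({"family": fam, "stage": s, "family_size": len(members),
                                 "at_peak": enr.overlap, "p_enriched": enr.p_raw,
                                 "p_depleted": dep.p_raw})
        pd.DataFrame(fam_rows).to_csv(out / "stage_family.tsv", sep="\t", index=False)

        stage = "qpcr"
        qpcr_summary = {}
        if qpcr:
            df = qpcr_long_frame(qpcr)
            rows = []
            for gene, sub in df.groupby("gene_id", sort=True):
                recs = [r for r in qpcr if r.gene_id == gene]
                rel = delta_delta_ct(recs, reference)
                groups = [g["delta_ct"].to_numpy()
                          for _, g in sub.groupby("stage_id", sort=False)]
                anova = anova_bonferroni(groups) if all(len(g) >= 2 for g in groups) \
                    and len(groups) >= 2 else None
                for r in rel:
                    rows.append({"gene_id": r.gene_id, "stage": r.stage_id,
                                 "delta_ct_mean": r.delta_ct_mean,
                                 "delta_ct_sd": r.delta_ct_sd, "ddct": r.ddct,
                                 "fold": r.fold,
                                 "anova_p": anova.p_value if anova else ""})
            pd.DataFrame(rows).to_csv(out / "qpcr_report.tsv", sep="\t", index=False)
            panel = sorted(df["gene_id"].unique())
            pearson, spearman = concordance(norm.counts.loc[panel], qpcr, reference)
            qpcr_summary = {
                "n_genes": len(panel),
                "spearman_ct_vs_log2count": spearman,
                "fraction_pearson_ge_0.70":
                    float((pearson.dropna() >= 0.70).mean()) if len(pearson) else None,
            }
            with open(out / "qpcr_summary.json", "w") as fh:
                json.dump(qpcr_summary, fh, sort_keys=True, indent=1)

        stage = "evaluation"
        if truth is not None:
            calls = pd.concat([stage_df[["gene_id", "contrast", "direction"]],
                               trans4[["gene_id", "contrast", "direction"]]],
                              ignore_index=True)
            metrics = evaluate_calls(truth, calls, enrichment_by_label)
            with open(out / "metrics.json", "w") as fh:
                json.dump(metrics, fh, sort_keys=True, indent=1)

        stage = "manifest"
        manifest["outputs"] = sorted(p.name for p in out.iterdir() if p.is_file())
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, sort_keys=True, indent=1)
    except Exception as exc:  # noqa: BLE001 - deliberate stage wrapping
        raise StageError(stage, exc) from exc
    return manifest
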