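"""Differential expression without biological replicates.

With one library per stage, the four stages themselves are the only
replication available. Three complementary views are implemented, all on
depth-normalized counts:

* stage-vs-rest: for each focal stage, a two-tailed one-sample t-test (df = 2)
  of the three other stages' log2(count + 1) values against the focal value,
  gated by a fold cutoff (default 4);
* settlement: pooled-variance two-sample t-test of the two pelagic stages
  against the two benthic stages (df = 2);
* stage transitions: successive-stage fold change gated by the k*sqrt(N)
  sampling-error envelope instead of a t-test (counts floored at 1 when
  forming ratios, so e.g. 64 -> 256 is exactly four-fold).

A gene is called up/down only when every filter passes; otherwise it is
"unchanged". The extreme-upregulation statistic (max over stages of the focal
log2 level minus the mean of the others, >= log2(100) flags an extreme gene)
and the per-gene min-max relative-expression matrix support the summary
exports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_models import CountTable

__all__ = [
    "AnalysisParams",
    "CallRecord",
    "UP", "DOWN", "UNCHANGED",
    "stage_specific_test",
    "stage_specific_calls",
    "settlement_test",
    "settlement_calls",
    "classify_transition",
    "transition_calls",
    "extreme_upregulation",
    "extreme_table",
    "relative_expression_matrix",
]

UP, DOWN, UNCHANGED = "up", "down", "unchanged"


@dataclass(frozen=True)
class AnalysisParams:
    """Shared thresholds for the expression analyses.

    fold_cutoff        minimum fold change for a call (inclusive; 4 default,
                       2 for the permissive variant)
    alpha              t-test significance level
    pseudocount        added inside log2 so zero counts stay defined
    k                  sampling-error envelope coefficient
    detection_threshold  normalized-count detection floor used to exclude
                       never-expressed genes from transition calls
    peak_fraction      at-peak quantile of the per-gene expression range
    extreme_log2       log2 differential that flags an extreme gene (100-fold)
    """

    fold_cutoff: float = 4.0
    alpha: float = 0.05
    pseudocount: float = 1.0
    k: float = 5.0
    detection_threshold: float = 64.0
    peak_fraction: float = 0.75
    extreme_log2: float = math.log2(100.0)

    def __post_init__(self):
        if self.fold_cutoff <= 1:
            raise ValueError("fold_cutoff must be > 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.peak_fraction < 1:
            raise ValueError("peak_fraction must be in (0, 1)")


@dataclass(frozen=True)
class CallRecord:
    """Outcome of one differential-expression comparison for one gene."""

    gene_id: str
    contrast: str  # stage id, "settlement", or "s1->s2"
    log2_ratio: float
    direction: str
    p_value: float | None = None
    passed_error_gate: bool | None = None
    flagged: bool = False


def _y(table: CountTable, params: AnalysisParams) -> pd.DataFrame:
    return np.log2(table.counts + params.pseudocount)


def _t_sf_df2(t: np.ndarray) -> np.ndarray:
    # two-tailed p for Student t with 2 df: 1 - |t| / sqrt(t^2 + 2)
    t = np.abs(t)
    return 1.0 - t / np.sqrt(t * t + 2.0)


def stage_specific_test(table: CountTable, gene: str, focal: str,
                        params: AnalysisParams = AnalysisParams()) -> CallRecord:
    """Focal stage versus the mean of the other three (one gene).

    The three non-focal log2 levels are treated as a sample and tested against
    the focal level with a one-sample two-tailed t-test (df = 2). Degenerate
    zero-variance cases collapse to p = 1 (focal equals the common value) or
    p = 0 (focal differs), flagged.
    """
    y = _y(table, params).loc[gene]
    others = y.drop(focal).to_numpy()
    yf = float(y[focal])
    mean_o = float(others.mean())
    sd_o = float(others.std(ddof=1))
    log2_ratio = yf - mean_o
    flagged = False
    if sd_o == 0.0:
        p = 1.0 if yf == mean_o else 0.0
        flagged = yf != mean_o
    else:
        t = (mean_o - yf) / (sd_o / math.sqrt(len(others)))
        p = float(_t_sf_df2(np.asarray(t)))
    passed = abs(log2_ratio) >= math.log2(params.fold_cutoff) and p < params.alpha
    direction = (UP if log2_ratio > 0 else DOWN) if passed else UNCHANGED
    return CallRecord(gene, focal, log2_ratio, direction, p_value=p, flagged=flagged)


def stage_specific_calls(table: CountTable,
                         params: AnalysisParams = AnalysisParams(),
                         genes=None) -> pd.DataFrame:
    """Vectorized stage-vs-rest calls for every (gene, focal stage) pair."""
    y = _y(table, params)
    if genes is not None:
        y = y.loc[list(genes)]
    frames = []
    samples = list(y.columns)
    log2_cut = math.log2(params.fold_cutoff)
    for focal in samples:
        others = y.drop(columns=focal).to_numpy()
        yf = y[focal].to_numpy()
        mean_o = others.mean(axis=1)
        sd_o = others.std(axis=1, ddof=1)
        ratio = yf - mean_o
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (mean_o - yf) / (sd_o / math.sqrt(others.shape[1]))
        p = _t_sf_df2(np.where(sd_o > 0, t, 0.0))
        degenerate = sd_o == 0
        p = np.where(degenerate, np.where(ratio == 0, 1.0, 0.0), p)
        passed = (np.abs(ratio) >= log2_cut) & (p < params.alpha)
        direction = np.where(passed, np.where(ratio > 0, UP, DOWN), UNCHANGED)
        frames.append(pd.DataFrame({
            "gene_id": y.index, "contrast": focal, "log2_ratio": ratio,
            "p_value": p, "direction": direction,
            "flagged": degenerate & (ratio != 0),
        }))
    return pd.concat(frames, ignore_index=True)


def _settlement_groups(samples: list[str]) -> tuple[list[str], list[str]]:
    if len(samples) != 4:
        raise ValueError("settlement contrast requires exactly 4 stages")
    return samples[:2], samples[2:]


def settlement_test(table: CountTable, gene: str,
                    params: AnalysisParams = AnalysisParams()) -> CallRecord:
    """Pelagic (first two stages) versus benthic (last two) for one gene."""
    y = _y(table, params).loc[gene]
    pelagic, benthic = _settlement_groups(list(y.index))
    a = y[pelagic].to_numpy()
    b = y[benthic].to_numpy()
    log2_ratio = float(b.mean() - a.mean())
    va, vb = a.var(ddof=1), b.var(ddof=1)
    sp2 = (va + vb) / 2.0  # pooled, n1 = n2 = 2
    flagged = False
    if sp2 == 0.0:
        p = 1.0 if log2_ratio == 0 else 0.0
        flagged = log2_ratio != 0
    else:
        t = log2_ratio / math.sqrt(sp2)  # sp * sqrt(1/2 + 1/2) = sp
        p = float(_t_sf_df2(np.asarray(t)))
    passed = abs(log2_ratio) >= math.log2(params.fold_cutoff) and p < params.alpha
    direction = (UP if log2_ratio > 0 else DOWN) if passed else UNCHANGED
    return CallRecord(gene, "settlement", log2_ratio, direction, p_value=p,
                      flagged=flagged)


def settlement_calls(table: CountTable,
                     params: AnalysisParams = AnalysisParams(),
                     genes=None) -> pd.DataFrame:
    y = _y(table, params)
    if genes is not None:
        y = y.loc[list(genes)]
    pelagic, benthic = _settlement_groups(list(y.columns))
    a = y[pelagic].to_numpy()
    b = y[benthic].to_numpy()
    ratio = b.mean(axis=1) - a.mean(axis=1)
    sp2 = (a.var(axis=1, ddof=1) + b.var(axis=1, ddof=1)) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = ratio / np.sqrt(sp2)
    p = _t_sf_df2(np.where(sp2 > 0, t, 0.0))
    degenerate = sp2 == 0
    p = np.where(degenerate, np.where(ratio == 0, 1.0, 0.0), p)
    passed = (np.abs(ratio) >= math.log2(params.fold_cutoff)) & (p < params.alpha)
    direction = np.where(passed, np.where(ratio > 0, UP, DOWN), UNCHANGED)
    return pd.DataFrame({
        "gene_id": y.index, "contrast": "settlement", "log2_ratio": ratio,
        "p_value": p, "direction": direction, "flagged": degenerate & (ratio != 0),
    })


def classify_transition(table: CountTable, gene: str, stage_pair: tuple[str, str],
                        params: AnalysisParams = AnalysisParams()) -> CallRecord | None:
    """Up/down/unchanged call for one gene across one successive-stage pair.

    Requires detection (>= threshold) in at least one of the two stages; a
    gene below detection in both is excluded (returns None). The call needs
    both an inclusive fold cutoff on count ratios (counts floored at 1) and
    the sampling-error gate |n2 - n1| > k * sqrt(max(n1, n2)).
    """
    s1, s2 = stage_pair
    n1 = float(table.counts.at[gene, s1])
    n2 = float(table.counts.at[gene, s2])
    if n1 < params.detection_threshold and n2 < params.detection_threshold:
        return None
    a, b = max(n1, 1.0), max(n2, 1.0)
    fold = max(a, b) / min(a, b)
    gate = abs(n2 - n1) > params.k * math.sqrt(max(n1, n2))
    log2_ratio = math.log2(b / a)
    if fold >= params.fold_cutoff and gate:
        direction = UP if n2 > n1 else DOWN
    else:
        direction = UNCHANGED
    return CallRecord(gene, f"{s1}->{s2}", log2_ratio, direction,
                      passed_error_gate=gate)


def transition_calls(table: CountTable,
                     params: AnalysisParams = AnalysisParams()) -> pd.DataFrame:
    """Vectorized successive-stage calls for all genes detected in >= 1 of
    the two stages of each transition."""
    samples = list(table.counts.columns)
    frames = []
    for s1, s2 in zip(samples[:-1], samples[1:]):
        n1 = table.counts[s1].to_numpy(dtype=float)
        n2 = table.counts[s2].to_numpy(dtype=float)
        keep = (n1 >= params.detection_threshold) | (n2 >= params.detection_threshold)
        a = np.maximum(n1, 1.0)
        b = np.maximum(n2, 1.0)
        fold = np.maximum(a, b) / np.minimum(a, b)
        gate = np.abs(n2 - n1) > params.k * np.sqrt(np.maximum(n1, n2))
        called = (fold >= params.fold_cutoff) & gate
        direction = np.where(called, np.where(n2 > n1, UP, DOWN), UNCHANGED)
        frames.append(pd.DataFrame({
            "gene_id": table.counts.index[keep],
            "contrast": f"{s1}->{s2}",
            "log2_ratio": np.log2(b / a)[keep],
            "direction": direction[keep],
            "passed_error_gate": gate[keep],
        }))
    return pd.concat(frames, ignore_index=True)


def extreme_upregulation(table: CountTable, gene: str,
                         params: AnalysisParams = AnalysisParams()):
    """(max stage-vs-rest log2 differential, is_extreme, focal stage)."""
    y = _y(table, params).loc[gene]
    best_stat, best_stage = -math.inf, None
    for focal in y.index:
        stat = float(y[focal] - y.drop(focal).mean())
        if stat > best_stat:
            best_stat, best_stage = stat, focal
    return best_stat, best_stat >= params.extreme_log2, best_stage


def extreme_table(table: CountTable,
                  params: AnalysisParams = AnalysisParams(),
                  genes=None) -> pd.DataFrame:
    """Max-upregulation statistic for every gene, flagged at 100-fold."""
    y = _y(table, params)
    if genes is not None:
        y = y.loc[list(genes)]
    mat = y.to_numpy()
    total = mat.sum(axis=1, keepdims=True)
    k = mat.shape[1]
    stat_all = mat - (total - mat) / (k - 1)  # focal minus mean of others
    idx = stat_all.argmax(axis=1)
    stat = stat_all[np.arange(len(y)), idx]
    return pd.DataFrame({
        "gene_id": y.index,
        "max_upregulation_log2": stat,
        "focal_stage": np.asarray(y.columns)[idx],
        "is_extreme": stat >= params.extreme_log2,
    }).set_index("gene_id")


def relative_expression_matrix(table: CountTable, genes=None,
                               params: AnalysisParams = AnalysisParams()) -> pd.DataFrame:
    """Per-gene min-max scaled log2 expression in [0, 1] (0.5 for constants)."""
    y = _y(table, params)
    if genes is not None:
        y = y.loc[list(genes)]
    lo = y.min(axis=1)
    span = y.max(axis=1) - lo
    rel = y.sub(lo, axis=0).div(span.replace(0.0, np.nan), axis=0)
    return rel.fillna(0.5)
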