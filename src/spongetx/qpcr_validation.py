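"""qPCR relative quantification and sequencing concordance.

Relative expression from Ct values uses the delta-delta-Ct method: each
replicate's target Ct is normalized to the reference gene (beta-actin in the
study design), per-stage means are differenced against a reference stage, and
fold = 2^(-ddCt). Replicate variance across stages is assessed with one-way
ANOVA plus Bonferroni-adjusted pairwise t-tests. Concordance with sequencing
is summarized two ways: per-gene Pearson r between log2 fold profiles, and a
pooled Spearman rank correlation between raw Ct and log2(normalized count + 1)
over all gene x stage x replicate points (expected strongly negative — more
template means fewer cycles).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_models import CountTable, QpcrRecord

__all__ = [
    "RelativeExpression",
    "AnovaResult",
    "delta_delta_ct",
    "anova_bonferroni",
    "concordance",
    "qpcr_long_frame",
]


@dataclass(frozen=True)
class RelativeExpression:
    gene_id: str
    stage_id: str
    delta_ct_mean: float
    delta_ct_sd: float
    ddct: float
    fold: float


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    pairwise_adjusted: dict
    flagged: bool = False


def qpcr_long_frame(records: Iterable[QpcrRecord]) -> pd.DataFrame:
    rows = [(r.gene_id, r.stage_id, r.replicate_index, r.ct_target, r.ct_reference)
            for r in records]
    df = pd.DataFrame(rows, columns=["gene_id", "stage_id", "replicate",
                                     "ct_target", "ct_reference"])
    df["delta_ct"] = df["ct_target"] - df["ct_reference"]
    return df


def delta_delta_ct(records: Iterable[QpcrRecord],
                   reference_stage: str) -> list[RelativeExpression]:
    """ddCt relative quantification for one gene's records.

    Fold is 2^(-ddCt) relative to the reference stage, which gets fold 1 by
    construction. The fold is invariant under any constant shift applied to
    all Ct values, and changing the reference stage rescales every fold by a
    single constant.
    """
    df = qpcr_long_frame(records)
    genes = df["gene_id"].unique()
    if len(genes) != 1:
        raise ValueError(f"records must belong to one gene, got {list(genes)}")
    gene = genes[0]
    per_stage = df.groupby("stage_id", sort=False)["delta_ct"].agg(["mean", "std", "count"])
    if reference_stage not in per_stage.index:
        raise ValueError(f"reference stage {reference_stage!r} has no records")
    ref_mean = per_stage.at[reference_stage, "mean"]
    out = []
    for stage, row in per_stage.iterrows():
        ddct = row["mean"] - ref_mean
        sd = row["std"] if row["count"] > 1 else 0.0
        out.append(RelativeExpression(gene, stage, float(row["mean"]), float(sd),
                                      float(ddct), float(2.0 ** (-ddct))))
    return out


def anova_bonferroni(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA with Bonferroni-adjusted pairwise t-tests.

    Degenerate all-constant input is defined explicitly: equal group means
    give F = 0, p = 1; unequal means with zero within-group variance give
    p -> 0, flagged.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 replicates each")
    within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    means = np.array([a.mean() for a in arrays])
    flagged = False
    if within == 0.0:
        if np.allclose(means, means[0]):
            f, p = 0.0, 1.0
        else:
            f, p = math.inf, 0.0
            flagged = True
    else:
        f, p = stats.f_oneway(*arrays)
        f, p = float(f), float(p)
    m = len(arrays) * (len(arrays) - 1) // 2
    pairwise = {}
    for i, j in itertools.combinations(range(len(arrays)), 2):
        if arrays[i].var(ddof=1) == 0 and arrays[j].var(ddof=1) == 0:
            raw = 1.0 if arrays[i].mean() == arrays[j].mean() else 0.0
        else:
            raw = float(stats.ttest_ind(arrays[i], arrays[j], equal_var=True).pvalue)
        pairwise[(i, j)] = min(1.0, raw * m)
    return AnovaResult(f, p, pairwise, flagged=flagged)


def concordance(seq_counts: pd.DataFrame, records: Iterable[QpcrRecord],
                reference_stage: str, pseudocount: float = 1.0):
    """Per-gene Pearson trend agreement and pooled Spearman Ct correlation.

    seq_counts: normalized counts, genes x stages (must cover the qPCR panel).
    Per gene, Pearson r is computed between the log2 sequencing fold profile
    (log2((count + 1)/(count_ref + 1))) and the log2 qPCR fold profile, both
    relative to ``reference_stage``. Genes with a constant profile on either
    side have undefined r and are reported as NaN. The pooled statistic is the
    Spearman rank correlation between target Ct and log2(count + 1) across all
    gene x stage x replicate points.

    Returns (per-gene Pearson Series, pooled Spearman rho).
    """
    df = qpcr_long_frame(records)
    stages = list(seq_counts.columns)
    if reference_stage not in stages:
        raise ValueError(f"reference stage {reference_stage!r} not in seq profile")
    y = np.log2(seq_counts + pseudocount)

    pearson = {}
    for gene, sub in df.groupby("gene_id", sort=True):
        if gene not in seq_counts.index:
            raise ValueError(f"qPCR gene {gene!r} absent from sequencing profile")
        rel = delta_delta_ct(
            [QpcrRecord(gene, r.stage_id, int(r.replicate), r.ct_target, r.ct_reference)
             for r in sub.itertuples()], reference_stage)
        qpcr_log2 = pd.Series({r.stage_id: math.log2(r.fold) for r in rel})
        qpcr_log2 = qpcr_log2.reindex(stages).dropna()
        seq_log2 = y.loc[gene, qpcr_log2.index] - y.at[gene, reference_stage]
        if seq_log2.nunique() <= 1 or qpcr_log2.nunique() <= 1:
            pearson[gene] = float("nan")
        else:
            pearson[gene] = float(stats.pearsonr(seq_log2, qpcr_log2)[0])

    pooled_ct = df["ct_target"].to_numpy()
    pooled_y = np.array([y.at[g, s] for g, s in zip(df["gene_id"], df["stage_id"])])
    rho = float(stats.spearmanr(pooled_ct, pooled_y)[0])
    return pd.Series(pearson, name="pearson_r"), rho
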