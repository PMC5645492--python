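"""Simplified two-group differential expression on RNA-seq counts.

Genes pass the expression filter when they reach one count per million in
every replicate of at least one group.  Counts are TMM-scaled, transformed
to voom-style log2-CPM, and tested per gene with a pooled-variance two-sample
t statistic.  P-values are Benjamini-Hochberg adjusted; a gene is called
significant when its adjusted p falls below ``alpha`` and its absolute log2
fold-change reaches ``lfc_threshold``.

This is deliberately an approximate stand-in for a moderated-variance
limma-voom fit: there is no mean-variance precision weighting and no
empirical-Bayes shrinkage, so per-gene variances at three replicates are
noisier than limma's.  Output tables are labelled "approximate limma-voom".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import RunConfig
from .io import QueryCounts
from .normalize import compute_cpm, tmm_factors, voom_log2_cpm

logger = logging.getLogger(__name__)


def filter_expressed(query: QueryCounts) -> pd.Index:
    """Genes with CPM >= 1 in all replicates of at least one group."""
    cpm = compute_cpm(query).values
    keep = np.zeros(len(query.gene_ids), dtype=bool)
    for group in query.groups:
        reps = query.replicates_of(group)
        if not reps:
            raise ValueError(f"group {group!r} has no replicates")
        keep |= (cpm[reps] >= 1.0).all(axis=1).to_numpy()
    return query.gene_ids[keep]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_test(
    query: QueryCounts,
    group1: str,
    group2: str,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Per-gene differential expression between two replicate groups.

    Returns one row per filtered gene with columns ``gene_id, log_fc,
    t_statistic, p_value, adj_p, significant, low_variance``; ``log_fc`` is
    group2 minus group1 mean log2-CPM.  Genes with (near-)zero variance in
    both groups get their pooled variance floored at ``config.var_floor``
    and are flagged ``low_variance``.
    """
    config = config or RunConfig()
    reps1 = query.replicates_of(group1)
    reps2 = query.replicates_of(group2)
    if len(reps1) < 2 or len(reps2) < 2:
        raise ValueError("each group needs at least two replicates")
    kept = filter_expressed(query)
    sub = QueryCounts(
        counts=query.counts.loc[kept],
        group_map=query.group_map,
        gene_lengths=None,
    )
    factors = tmm_factors(sub)
    logcpm = voom_log2_cpm(sub, factors=factors).values
    x1 = logcpm[reps1].to_numpy()
    x2 = logcpm[reps2].to_numpy()
    n1, n2 = x1.shape[1], x2.shape[1]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    ss1 = ((x1 - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((x2 - m2[:, None]) ** 2).sum(axis=1)
    df = n1 + n2 - 2
    pooled_var = (ss1 + ss2) / df
    low_variance = pooled_var < config.var_floor
    if low_variance.any():
        logger.warning(
            "%d gene(s) with near-zero within-group variance; variance "
            "floored at %g", int(low_variance.sum()), config.var_floor,
        )
    pooled_var = np.maximum(pooled_var, config.var_floor)
    se = np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    log_fc = m2 - m1
    t_stat = log_fc / se
    p = 2.0 * stats.t.sf(np.abs(t_stat), df)
    adj_p = bh_adjust(p)
    significant = (adj_p < config.alpha) & (
        np.abs(log_fc) >= config.lfc_threshold
    )
    out = pd.DataFrame({
        "gene_id": kept,
        "log_fc": log_fc,
        "t_statistic": t_stat,
        "p_value": p,
        "adj_p": adj_p,
        "significant": significant,
        "low_variance": low_variance,
    })
    return out.reset_index(drop=True)


class DifferentialExpression:
    """Model: approximate limma-voom differential expression.

    Thin statsmodels-style wrapper over :func:`de_test`; ``fit()`` returns a
    :class:`DEResults` carrying the gene table and a ``summary()``.
    """

    def __init__(
        self,
        query: QueryCounts,
        group1: str,
        group2: str,
        config: RunConfig | None = None,
    ) -> None:
        groups = query.groups
        for g in (group1, group2):
            if g not in groups:
                raise ValueError(f"group {g!r} not in query groups {groups}")
        self.query = query
        self.group1 = group1
        self.group2 = group2
        self.config = config or RunConfig()

    def fit(self) -> "DEResults":
        table = de_test(self.query, self.group1, self.group2, self.config)
        return DEResults(model=self, table=table)


@dataclass
class DEResults:
    model: DifferentialExpression
    table: pd.DataFrame

    @property
    def n_tested(self) -> int:
        return len(self.table)

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    def significant_genes(self) -> list[str]:
        return list(self.table.loc[self.table["significant"], "gene_id"])

    def volcano_data(self) -> pd.DataFrame:
        """(log_fc, -log10 adjusted p) pairs for volcano plotting."""
        return pd.DataFrame({
            "gene_id": self.table["gene_id"],
            "log_fc": self.table["log_fc"],
            "neglog10_adj_p": -np.log10(
                np.maximum(self.table["adj_p"].to_numpy(), 5e-324)
            ),
            "significant": self.table["significant"],
        })

    def summary(self) -> str:
        cfg = self.model.config
        top = (
            self.table.sort_values("adj_p")
            .head(10)[["gene_id", "log_fc", "t_statistic", "p_value", "adj_p"]]
            .round(4)
        )
        return "\n".join([
            "Differential expression (approximate limma-voom)",
            "================================================",
            f"{self.model.group2} vs {self.model.group1}: "
            f"{self.n_tested} genes tested, {self.n_significant} significant "
            f"(BH adj p < {cfg.alpha}, |log2 FC| >= {cfg.lfc_threshold})",
            "",
            top.to_string(index=False),
        ])
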