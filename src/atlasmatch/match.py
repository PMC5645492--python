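"""Rank-difference matching of a query transcriptome to atlas regions.

The procedure: average the atlas expression per micro-dissected region at a
developmental stage, rank-transform each region profile and the query over a
shared gene index, take per-gene (absolute) rank differences, and score each
region with a one-sided Wilcoxon rank-sum test of its rank differences
against a pooled background of all other regions' differences at the same
stage.  Small differences relative to background mean the query's expression
ranking matches that region ("matched-rank strength"), reported as
-log10 p.  Structure-level scores aggregate the per-region scores with a
second rank-sum test of member versus non-member regions.

Everything downstream of the rank transform depends on the query values only
through their ordering, so the procedure is invariant to any monotone
transform of the query — which is what lets RNA-seq counts be compared with
microarray intensities.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .config import RunConfig
from .io import Atlas, QueryCounts, collapse_probes, filter_atlas, harmonize_genes
from .normalize import (
    NormalizedMatrix,
    average_replicates,
    compute_cpm,
    log2_transform,
)

logger = logging.getLogger(__name__)

_LN10 = math.log(10.0)


# ---------------------------------------------------------------------------
# rank primitives

def rank_transform(values: np.ndarray | pd.Series) -> np.ndarray:
    """Ascending ranks in [1, G]; ties get the average of their positions."""
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("rank_transform expects a 1-D vector of length >= 2")
    if not np.isfinite(arr).all():
        raise ValueError("non-finite values cannot be ranked")
    return rankdata(arr)


def rank_difference(
    query_ranks: np.ndarray,
    region_ranks: np.ndarray,
    signed: bool = False,
) -> np.ndarray:
    """Per-gene rank difference between query and region profiles.

    Absolute by default; ``signed=True`` returns query minus region.
    """
    q = np.asarray(query_ranks, dtype=float)
    r = np.asarray(region_ranks, dtype=float)
    if q.shape != r.shape:
        raise ValueError("rank profiles have mismatched gene indices")
    d = q - r
    return d if signed else np.abs(d)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum

def _exact_logp(pooled_ranks: np.ndarray, n1: int, w_obs: float,
                alternative: str) -> float:
    """Exact log p by counting all C(N, n1) label assignments.

    Ranks (average-tie convention) are multiples of 1/2, so a dynamic
    programme over doubled integer ranks counts, for every achievable
    rank-sum, the number of size-``n1`` subsets attaining it.  Identical to
    literal enumeration of assignments, in polynomial time.
    """
    r2 = np.rint(2.0 * pooled_ranks).astype(np.int64)
    total_sum = int(r2.sum())
    # dp[k, s] = number of size-k subsets with doubled-rank sum s
    dp = np.zeros((n1 + 1, total_sum + 1), dtype=np.float64)
    dp[0, 0] = 1.0
    for r in r2:
        # descending k so each rank is used at most once per subset
        for k in range(n1, 0, -1):
            dp[k, r:] += dp[k - 1, : total_sum + 1 - r]
    counts = dp[n1]
    total = counts.sum()
    w2 = int(np.rint(2.0 * w_obs))
    p_less = counts[: w2 + 1].sum() / total
    p_greater = counts[w2:].sum() / total
    if alternative == "less":
        p = p_less
    elif alternative == "greater":
        p = p_greater
    elif alternative == "two_sided":
        p = min(1.0, 2.0 * min(p_less, p_greater))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return math.log(p)


def _normal_logp(pooled_ranks: np.ndarray, n1: int, w_obs: float,
                 alternative: str) -> float:
    """Normal approximation with tie-corrected variance and a 0.5
    continuity correction, on the log scale for deep tails."""
    n = pooled_ranks.size
    n2 = n - n1
    mu = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled_ranks, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        return 0.0  # all observations tied: p = 1
    sigma = math.sqrt(sigma2)
    logp_less = norm.logcdf((w_obs - mu + 0.5) / sigma)
    logp_greater = norm.logcdf(-(w_obs - mu - 0.5) / sigma)
    if alternative == "less":
        return logp_less
    if alternative == "greater":
        return logp_greater
    if alternative == "two_sided":
        return min(0.0, math.log(2.0) + min(logp_less, logp_greater))
    raise ValueError(f"unknown alternative {alternative!r}")


def _rank_sum_logp(x: np.ndarray, y: np.ndarray, alternative: str,
                   exact_limit: int) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w = float(ranks[: x.size].sum())
    if pooled.size <= exact_limit:
        logp = _exact_logp(ranks, x.size, w, alternative)
    else:
        logp = _normal_logp(ranks, x.size, w, alternative)
    return w, logp


def wilcoxon_rank_sum(
    x, y, alternative: str = "two_sided", exact_limit: int = 20
) -> tuple[float, float]:
    """Wilcoxon rank-sum test.

    Returns ``(w, p)`` where ``w`` is the rank-sum of ``x`` within the
    pooled sample.  Exact enumeration over label assignments of the observed
    (possibly tied) multiset when the pooled size is at most ``exact_limit``;
    otherwise a tie- and continuity-corrected normal approximation.
    """
    w, logp = _rank_sum_logp(x, y, alternative, exact_limit)
    return w, min(1.0, math.exp(logp))


def neglog10_from_logp(logp: float, cap: float = 320.0) -> float:
    return float(min(-logp / _LN10, cap))


# ---------------------------------------------------------------------------
# region scoring

def score_region(
    region_diffs: np.ndarray,
    background: np.ndarray,
    exact_limit: int = 20,
    neglog10_cap: float = 320.0,
) -> tuple[float, float, float]:
    """Score one region's rank differences against the pooled background.

    One-sided: small differences (better match than background) win.
    Returns ``(w, p, neglog10_p)``.
    """
    if np.asarray(background).size == 0:
        raise ValueError("empty background")
    w, logp = _rank_sum_logp(region_diffs, background, "less", exact_limit)
    p = max(math.exp(logp), 5e-324)
    return w, p, neglog10_from_logp(logp, neglog10_cap)


def _region_profiles(
    atlas: Atlas, stage: str, gene_index: pd.Index, collapse: str
) -> pd.DataFrame:
    """Per-region arithmetic-mean gene-level profiles at one stage."""
    in_stage = atlas.meta["stage"] == stage
    if not in_stage.any():
        raise ValueError(f"stage {stage!r} absent from atlas")
    gexpr = collapse_probes(atlas, collapse=collapse)
    gexpr = gexpr.loc[gene_index, atlas.meta.index[in_stage]]
    regions = atlas.meta.loc[in_stage, "region_id"]
    return gexpr.T.groupby(regions.to_numpy()).mean().T


def score_all_regions(
    query_values: pd.Series,
    atlas: Atlas,
    stage: str,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Score every atlas region at one stage against a query profile.

    ``query_values`` is a single expression column indexed by the shared
    gene index (any monotone scale).  Returns one row per region sorted by
    descending -log10 p, with columns ``region_id, structure, stage,
    n_genes, median_abs_rank_diff, w_statistic, p_value, neglog10_p``.
    """
    config = config or RunConfig()
    gene_index = query_values.index
    if len(gene_index) < config.min_genes:
        raise ValueError(
            f"shared gene index has {len(gene_index)} genes, "
            f"fewer than min_genes={config.min_genes}"
        )
    profiles = _region_profiles(atlas, stage, gene_index, config.collapse)
    region_ids = sorted(profiles.columns)
    structure_of = (
        atlas.meta.drop_duplicates("region_id")
        .set_index("region_id")["structure"]
    )
    g = len(gene_index)
    q_ranks = rank_transform(query_values.to_numpy())
    diffs = {
        rid: rank_difference(
            q_ranks,
            rank_transform(profiles[rid].to_numpy()),
            signed=config.signed_rank_diff,
        )
        for rid in region_ids
    }
    rng = np.random.default_rng(config.seed)
    cap = config.background_cap * g
    rows = []
    for rid in region_ids:
        background = np.concatenate(
            [diffs[other] for other in region_ids if other != rid]
        )
        if background.size > cap:
            background = rng.choice(background, size=cap, replace=False)
        w, p, nlp = score_region(
            diffs[rid], background,
            exact_limit=config.exact_limit,
            neglog10_cap=config.neglog10_cap,
        )
        rows.append({
            "region_id": rid,
            "structure": structure_of[rid],
            "stage": stage,
            "n_genes": g,
            "median_abs_rank_diff": float(np.median(np.abs(diffs[rid]))),
            "w_statistic": w,
            "p_value": p,
            "neglog10_p": nlp,
        })
    out = pd.DataFrame(rows)
    out = out.sort_values(
        ["neglog10_p", "region_id"], ascending=[False, True]
    ).reset_index(drop=True)
    return out


def score_structures(
    results: pd.DataFrame,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Aggregate per-region scores to anatomical structures.

    Per structure: one-sided Wilcoxon rank-sum of member regions'
    -log10 p values against non-member regions' (members greater).
    """
    config = config or RunConfig()
    if results.empty:
        raise ValueError("no region results to aggregate")
    structures = sorted(results["structure"].unique())
    if len(structures) < 2:
        raise ValueError(
            "structure scoring needs at least two structures "
            f"(got {structures})"
        )
    scores = results["neglog10_p"].to_numpy()
    member = {s: (results["structure"] == s).to_numpy() for s in structures}
    rows = []
    for s in structures:
        x = scores[member[s]]
        y = scores[~member[s]]
        _, logp = _rank_sum_logp(x, y, "greater", config.exact_limit)
        rows.append({
            "structure": s,
            "stage": results["stage"].iloc[0],
            "neglog10_p": neglog10_from_logp(logp, config.neglog10_cap),
            "n_regions": int(x.size),
        })
    return pd.DataFrame(rows)


def stage_comparison(
    query_values: pd.Series,
    atlas: Atlas,
    stages: list[str],
    config: RunConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run region and structure scoring at each stage.

    Returns ``(region_table, structure_table)``; the structure table has one
    row per (structure, stage).
    """
    config = config or RunConfig()
    region_tables, structure_tables = [], []
    for stage in stages:
        rt = score_all_regions(query_values, atlas, stage, config)
        region_tables.append(rt)
        structure_tables.append(score_structures(rt, config))
    empty_regions = pd.DataFrame(
        columns=["region_id", "structure", "stage", "n_genes",
                 "median_abs_rank_diff", "w_statistic", "p_value",
                 "neglog10_p"]
    )
    empty_structures = pd.DataFrame(
        columns=["structure", "stage", "neglog10_p", "n_regions"]
    )
    region_table = (
        pd.concat(region_tables, ignore_index=True)
        if region_tables else empty_regions
    )
    structure_table = (
        pd.concat(structure_tables, ignore_index=True)
        if structure_tables else empty_structures
    )
    return region_table, structure_table


# ---------------------------------------------------------------------------
# model / results objects

class RegionMatcher:
    """Model: match a query count table against a region-annotated atlas.

    Construction filters the atlas (regions assayed and probes expressed in
    at least ``config.min_samples`` samples) and intersects the gene
    universes.  :meth:`fit` normalizes the query (CPM, log2, replicate
    averaging — the scoring itself is rank-based, so the scale is a
    convenience, not an assumption) and scores every region and structure at
    each requested stage for each query group.
    """

    def __init__(
        self,
        atlas: Atlas,
        query: QueryCounts,
        config: RunConfig | None = None,
    ) -> None:
        self.config = config or RunConfig()
        self.atlas = filter_atlas(
            atlas,
            min_samples=self.config.min_samples,
            detection_threshold=self.config.detection_threshold,
        )
        self.query = query
        self.shared_genes = harmonize_genes(
            self.atlas, query, collapse=self.config.collapse
        )

    @classmethod
    def from_files(
        cls,
        atlas_expr,
        atlas_meta,
        query_counts,
        query_groups,
        gene_map=None,
        config: RunConfig | None = None,
    ) -> "RegionMatcher":
        from .io import load_atlas, load_query_counts

        atlas = load_atlas(atlas_expr, atlas_meta, gene_map_path=gene_map)
        query = load_query_counts(query_counts, query_groups)
        return cls(atlas, query, config=config)

    def fit(
        self,
        stages: list[str] | None = None,
        groups: list[str] | None = None,
    ) -> "RegionMatchResults":
        cfg = self.config
        if stages is None:
            stages = cfg.stages or self.atlas.stages
        if groups is None:
            groups = self.query.groups
        cpm = compute_cpm(self.query)
        logged = log2_transform(cpm, pseudocount=cfg.pseudocount)
        averaged = average_replicates(logged, self.query.group_map)
        region_tables, structure_tables = [], []
        for group in groups:
            qvals = averaged.values[group].loc[self.shared_genes]
            rt, st = stage_comparison(qvals, self.atlas, stages, cfg)
            rt.insert(0, "query", group)
            st.insert(0, "query", group)
            region_tables.append(rt)
            structure_tables.append(st)
        return RegionMatchResults(
            model=self,
            region_scores=pd.concat(region_tables, ignore_index=True),
            structure_scores=pd.concat(structure_tables, ignore_index=True),
        )


@dataclass
class RegionMatchResults:
    """Results of :meth:`RegionMatcher.fit`.

    ``region_scores``: one row per (query group, stage, region), sorted by
    descending -log10 p within each (query, stage).  ``structure_scores``:
    one row per (query group, stage, structure).
    """

    model: RegionMatcher
    region_scores: pd.DataFrame
    structure_scores: pd.DataFrame

    @property
    def n_shared_genes(self) -> int:
        return len(self.model.shared_genes)

    def top_regions(self, n: int = 5) -> pd.DataFrame:
        return (
            self.region_scores
            .groupby(["query", "stage"], sort=False)
            .head(n)
            .reset_index(drop=True)
        )

    def best_region(self, query: str, stage: str) -> str:
        sub = self.region_scores
        sub = sub[(sub["query"] == query) & (sub["stage"] == stage)]
        return str(sub.iloc[0]["region_id"])

    def best_stage(self, query: str, structure: str) -> str:
        sub = self.structure_scores
        sub = sub[(sub["query"] == query) & (sub["structure"] == structure)]
        return str(sub.loc[sub["neglog10_p"].idxmax(), "stage"])

    def summary(self) -> str:
        lines = [
            "Region match results",
            "====================",
            f"shared genes: {self.n_shared_genes}",
            f"regions scored: {self.region_scores['region_id'].nunique()}",
            "",
            "Structure scores (-log10 p, member vs non-member regions)",
            self.structure_scores.pivot_table(
                index=["query", "structure"], columns="stage",
                values="neglog10_p",
            ).round(3).to_string(),
            "",
            "Top regions per query and stage",
            self.top_regions(3)[
                ["query", "stage", "region_id", "structure",
                 "median_abs_rank_diff", "neglog10_p"]
            ].round(3).to_string(index=False),
        ]
        return "\n".join(lines)

    def export_voxel_scores(self, out, query: str | None = None,
                            stage: str | None = None):
        from .report import export_voxel_scores

        sub = self.region_scores
        if query is not None:
            sub = sub[sub["query"] == query]
        if stage is not None:
            sub = sub[sub["stage"] == stage]
        return export_voxel_scores(sub, self.model.atlas, out)

    def heatmap_table(self, query: str | None = None) -> pd.DataFrame:
        from .report import heatmap_table

        sub = self.region_scores
        if query is not None:
            sub = sub[sub["query"] == query]
        return heatmap_table(sub)
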