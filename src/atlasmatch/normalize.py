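"""Count normalization: CPM, RPKM, TMM scale factors, log2, median-centering.

TMM (trimmed mean of M-values) follows the published procedure: per-gene
log-ratios M and average log-intensities A against a reference library are
doubly trimmed (30% on M, 5% on A, symmetric tails, rank-based with average
ranks at ties) and the surviving M-values are combined with delta-method
precision weights.  Factors are rescaled to geometric mean 1 so they are
pure composition corrections on top of library size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import QueryCounts


@dataclass
class NormalizedMatrix:
    """A genes x samples matrix of normalized expression values."""

    values: pd.DataFrame
    unit: str
    tmm_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("normalized matrix contains non-finite values")
        if self.tmm_factors is not None:
            gm = np.exp(np.mean(np.log(self.tmm_factors.to_numpy())))
            if abs(gm - 1.0) > 1e-9:
                raise ValueError("TMM factors must have geometric mean 1")


def _library_sizes(query: QueryCounts) -> pd.Series:
    lib = query.counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        bad = lib.index[lib <= 0][0]
        raise ValueError(f"zero library size in sample {bad!r}")
    return lib


def compute_cpm(
    query: QueryCounts, factors: pd.Series | None = None
) -> NormalizedMatrix:
    """Counts per million: count / (library size x scale factor) x 1e6."""
    lib = _library_sizes(query)
    if factors is not None:
        lib = lib * factors.reindex(lib.index).astype(float)
        if (lib <= 0).any():
            raise ValueError("non-positive effective library size")
    values = query.counts.div(lib, axis=1) * 1e6
    return NormalizedMatrix(values=values, unit="cpm")


def compute_rpkm(query: QueryCounts) -> NormalizedMatrix:
    """Reads per kilobase of transcript per million mapped reads."""
    if query.gene_lengths is None:
        raise ValueError("RPKM requires gene lengths")
    lengths = query.gene_lengths.reindex(query.gene_ids)
    if lengths.isna().any() or (lengths <= 0).any():
        bad = lengths.index[lengths.isna() | (lengths <= 0)][0]
        raise ValueError(f"missing or non-positive length for gene {bad!r}")
    lib = _library_sizes(query)
    values = query.counts.div(lib / 1e6, axis=1).div(lengths / 1e3, axis=0)
    return NormalizedMatrix(values=values, unit="rpkm")


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    logratio_trim: float,
    sum_trim: float,
    do_weighting: bool,
) -> float:
    """TMM factor of one library against the reference (log2 scale -> 2**)."""
    n_obs, n_ref = obs.sum(), ref.sum()
    both = (obs > 0) & (ref > 0)
    if not both.any():
        raise ValueError("no gene expressed in both library and reference")
    o, r = obs[both].astype(float), ref[both].astype(float)
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    # delta-method variance of M; inverse is the precision weight
    v = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    # trim the stated fraction from EACH tail, rank-based (published rule)
    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rm, ra = rankdata(m), rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 1.0
    if do_weighting:
        f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    else:
        f = np.mean(m[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def choose_reference(query: QueryCounts) -> str:
    """Reference library: upper quartile (of scaled counts) closest to the
    mean upper quartile over libraries."""
    lib = _library_sizes(query)
    scaled = query.counts.div(lib, axis=1)
    q75 = scaled.quantile(0.75, axis=0)
    return str((q75 - q75.mean()).abs().idxmin())


def tmm_factors(
    query: QueryCounts,
    ref_sample: str | None = None,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
    do_weighting: bool = True,
) -> pd.Series:
    """Per-sample TMM scale factors, rescaled to geometric mean 1."""
    if query.counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    if ref_sample is None:
        ref_sample = choose_reference(query)
    ref = query.counts[ref_sample].to_numpy()
    raw = {}
    for col in query.counts.columns:
        if col == ref_sample:
            raw[col] = 1.0
        else:
            raw[col] = _tmm_pair(
                query.counts[col].to_numpy(), ref,
                logratio_trim, sum_trim, do_weighting,
            )
    f = pd.Series(raw, dtype=float).reindex(query.counts.columns)
    f /= np.exp(np.mean(np.log(f)))
    return f


def log2_transform(
    mat: NormalizedMatrix, pseudocount: float = 1.0
) -> NormalizedMatrix:
    """Element-wise log2(value + pseudocount)."""
    arr = mat.values.to_numpy()
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if pseudocount == 0 and (arr <= 0).any():
        raise ValueError("zero values need a positive pseudocount")
    values = np.log2(mat.values + pseudocount)
    return NormalizedMatrix(values=values, unit=f"log2{mat.unit}",
                            tmm_factors=mat.tmm_factors)


def voom_log2_cpm(
    query: QueryCounts, factors: pd.Series | None = None
) -> NormalizedMatrix:
    """log2-CPM with the 0.5/1.0 offset convention of the voom transform:
    log2((count + 0.5) / (effective library size + 1) * 1e6)."""
    lib = _library_sizes(query)
    if factors is not None:
        lib = lib * factors.reindex(lib.index).astype(float)
    values = np.log2((query.counts + 0.5).div(lib + 1.0, axis=1) * 1e6)
    return NormalizedMatrix(values=values, unit="log2cpm",
                            tmm_factors=factors)


def median_center(mat: NormalizedMatrix, axis: str = "gene") -> NormalizedMatrix:
    """Subtract the median along genes (rows) or samples (columns)."""
    if mat.values.size == 0:
        raise ValueError("empty matrix")
    if axis == "gene":
        values = mat.values.sub(mat.values.median(axis=1), axis=0)
    elif axis == "sample":
        values = mat.values.sub(mat.values.median(axis=0), axis=1)
    else:
        raise ValueError(f"unknown axis {axis!r}")
    return NormalizedMatrix(values=values, unit=f"centered_{mat.unit}",
                            tmm_factors=mat.tmm_factors)


def average_replicates(
    mat: NormalizedMatrix, group_map: dict[str, str]
) -> NormalizedMatrix:
    """Arithmetic mean within replicate groups, one output column per group.

    Output group order follows first appearance in ``group_map`` restricted
    to the matrix columns.
    """
    unmapped = [c for c in mat.values.columns if c not in group_map]
    if unmapped:
        raise ValueError(f"replicates without group: {unmapped}")
    order = list(dict.fromkeys(group_map[c] for c in mat.values.columns))
    cols = {}
    for g in order:
        members = [c for c in mat.values.columns if group_map[c] == g]
        if not members:
            raise ValueError(f"empty group {g!r}")
        cols[g] = mat.values[members].mean(axis=1)
    values = pd.DataFrame(cols)[order]
    return NormalizedMatrix(values=values, unit=mat.unit,
                            tmm_factors=None)
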