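"""Reading, validation and filtering of the reference atlas and query counts.

The atlas is a probe-level expression matrix (already-normalized continuous
intensities, e.g. microarray) with one metadata row per sample carrying the
donor, developmental stage, micro-dissected region label, coarse anatomical
structure and an optional 3-D voxel coordinate.  The query is a gene-level
RNA-seq count table with a replicate-to-group map.

Both are plain tab-separated files (gzip transparently accepted): expression
matrices have the probe/gene id in the first column and sample ids in the
header; metadata has columns ``sample_id, donor_id, stage, region_id,
structure`` and optionally ``x, y, z``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Developmental stages of the reference atlas: adult donors plus two fetal
#: windows (post-conception weeks 15-16 and 21-22).  Extensible per load call.
DEFAULT_STAGES: tuple[str, ...] = ("adult", "pcw15_16", "pcw21_22")

#: Coarse anatomical structures: brain stem, cortex, cerebellum.
DEFAULT_STRUCTURES: tuple[str, ...] = ("BS", "CX", "CB")

META_COLUMNS = ("sample_id", "donor_id", "stage", "region_id", "structure")
COORD_COLUMNS = ("x", "y", "z")


class AtlasValidationError(ValueError):
    """Raised when an atlas or query file violates its contract."""


@dataclass(frozen=True)
class AtlasSample:
    """One micro-dissected atlas sample."""

    sample_id: str
    donor_id: str
    stage: str
    region_id: str
    structure: str
    coordinate: tuple[float, float, float] | None = None


@dataclass
class Atlas:
    """Reference expression atlas: probes x samples plus per-sample metadata.

    Parameters
    ----------
    expr
        Probes x samples matrix of continuous expression intensities.  The
        index holds unique probe ids; columns are sample ids.
    meta
        One row per sample, indexed by sample id, aligned to ``expr``
        columns, with columns ``donor_id, stage, region_id, structure`` and
        optionally ``x, y, z``.
    gene_map
        Optional probe id -> gene symbol mapping for probe-level atlases.
    """

    expr: pd.DataFrame
    meta: pd.DataFrame
    gene_map: pd.Series | None = None

    def __post_init__(self) -> None:
        if list(self.expr.columns) != list(self.meta.index):
            raise AtlasValidationError(
                "expression columns and metadata rows are not aligned"
            )
        if self.expr.index.has_duplicates:
            dup = self.expr.index[self.expr.index.duplicated()][0]
            raise AtlasValidationError(f"duplicate probe id {dup!r}")
        if (self.meta["region_id"].astype(str).str.len() == 0).any():
            raise AtlasValidationError("empty region label in metadata")

    @property
    def probe_ids(self) -> pd.Index:
        return self.expr.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.expr.columns

    @property
    def regions(self) -> list[str]:
        return list(dict.fromkeys(self.meta["region_id"]))

    @property
    def stages(self) -> list[str]:
        return list(dict.fromkeys(self.meta["stage"]))

    @property
    def samples(self) -> list[AtlasSample]:
        out = []
        for sid, row in self.meta.iterrows():
            coord = None
            if all(c in self.meta.columns for c in COORD_COLUMNS):
                vals = [row[c] for c in COORD_COLUMNS]
                if all(np.isfinite(v) for v in vals):
                    coord = (float(vals[0]), float(vals[1]), float(vals[2]))
            out.append(
                AtlasSample(
                    sample_id=str(sid),
                    donor_id=str(row["donor_id"]),
                    stage=str(row["stage"]),
                    region_id=str(row["region_id"]),
                    structure=str(row["structure"]),
                    coordinate=coord,
                )
            )
        return out

    def region_coordinates(self) -> pd.DataFrame:
        """First finite (x, y, z) per region, with its structure label.

        Regions without coordinate columns or with non-finite coordinates
        are omitted.
        """
        if not all(c in self.meta.columns for c in COORD_COLUMNS):
            return pd.DataFrame(
                columns=["region_id", "structure", *COORD_COLUMNS]
            ).set_index("region_id")
        rows = {}
        for sid, row in self.meta.iterrows():
            rid = row["region_id"]
            if rid in rows:
                continue
            vals = np.asarray([row[c] for c in COORD_COLUMNS], dtype=float)
            if np.all(np.isfinite(vals)):
                rows[rid] = {
                    "structure": row["structure"],
                    "x": vals[0],
                    "y": vals[1],
                    "z": vals[2],
                }
        return pd.DataFrame.from_dict(rows, orient="index").rename_axis("region_id")


@dataclass
class QueryCounts:
    """Gene-level RNA-seq counts: genes x replicate samples.

    ``group_map`` assigns every replicate column to exactly one phenotypic
    group (e.g. cell line or differentiation day).  ``gene_lengths`` (bp)
    is only needed for RPKM.
    """

    counts: pd.DataFrame
    group_map: dict[str, str]
    gene_lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise AtlasValidationError(f"duplicate gene id {dup!r}")
        missing = [c for c in self.counts.columns if c not in self.group_map]
        if missing:
            raise AtlasValidationError(
                f"replicates without group assignment: {missing}"
            )
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise AtlasValidationError("negative counts")
        if not np.allclose(arr, np.round(arr)):
            raise AtlasValidationError("non-integer counts")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def groups(self) -> list[str]:
        seen = dict.fromkeys(self.group_map[c] for c in self.counts.columns)
        return list(seen)

    def replicates_of(self, group: str) -> list[str]:
        return [c for c in self.counts.columns if self.group_map[c] == group]


def _read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated expression matrix, first column = row ids."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str).str.strip()
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise AtlasValidationError(f"{path}: duplicate row id {dup!r}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = pd.to_numeric(df[col], errors="coerce")
            i = int(np.flatnonzero(bad.isna())[0])
            raise AtlasValidationError(
                f"{path}: non-numeric value {df[col].iloc[i]!r} at "
                f"row {df.index[i]!r}, column {col!r}"
            ) from None
    out = pd.DataFrame(values, index=df.index, columns=df.columns)
    if not np.isfinite(out.to_numpy()).all():
        i, j = np.argwhere(~np.isfinite(out.to_numpy()))[0]
        raise AtlasValidationError(
            f"{path}: non-finite value at row {out.index[i]!r}, "
            f"column {out.columns[j]!r}"
        )
    return out


def load_atlas(
    expr_path: str | Path,
    meta_path: str | Path,
    gene_map_path: str | Path | None = None,
    stages: Sequence[str] = DEFAULT_STAGES,
) -> Atlas:
    """Load an atlas expression matrix plus its sample metadata.

    Samples are ordered as in the expression header; a metadata row missing
    for any expression sample id is an error, as is a stage label outside
    ``stages``.
    """
    expr = _read_matrix(expr_path)
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    missing_cols = [c for c in META_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise AtlasValidationError(f"{meta_path}: missing columns {missing_cols}")
    meta["sample_id"] = meta["sample_id"].str.strip()
    if meta["sample_id"].duplicated().any():
        dup = meta["sample_id"][meta["sample_id"].duplicated()].iloc[0]
        raise AtlasValidationError(f"{meta_path}: duplicate sample id {dup!r}")
    meta = meta.set_index("sample_id")
    for col in ("donor_id", "stage", "region_id", "structure"):
        meta[col] = meta[col].astype(str).str.strip()
    for col in COORD_COLUMNS:
        if col in meta.columns:
            meta[col] = pd.to_numeric(meta[col], errors="coerce")
    absent = [s for s in expr.columns if s not in meta.index]
    if absent:
        raise AtlasValidationError(
            f"{meta_path}: no metadata row for sample(s) {absent}"
        )
    meta = meta.loc[list(expr.columns)]
    bad_stage = sorted(set(meta["stage"]) - set(stages))
    if bad_stage:
        raise AtlasValidationError(
            f"{meta_path}: stage label(s) {bad_stage} outside declared set {list(stages)}"
        )
    gene_map = None
    if gene_map_path is not None:
        gm = pd.read_csv(gene_map_path, sep="\t", dtype=str)
        gene_map = pd.Series(
            gm.iloc[:, 1].str.strip().to_numpy(),
            index=gm.iloc[:, 0].str.strip(),
            name="gene",
        )
    atlas = Atlas(expr=expr, meta=meta, gene_map=gene_map)
    logger.info(
        "loaded atlas: %d probes, %d samples, %d regions, %d stages",
        expr.shape[0], expr.shape[1], len(atlas.regions), len(atlas.stages),
    )
    return atlas


def load_query_counts(
    counts_path: str | Path,
    groups: str | Path | Mapping[str, str],
    gene_lengths_path: str | Path | None = None,
) -> QueryCounts:
    """Load a gene-level count table and its replicate-to-group map.

    ``groups`` is either a mapping or the path of a two-column TSV
    (``sample_id<TAB>group``).
    """
    counts = _read_matrix(counts_path)
    if isinstance(groups, (str, Path)):
        gdf = pd.read_csv(groups, sep="\t", dtype=str)
        group_map = dict(
            zip(gdf.iloc[:, 0].str.strip(), gdf.iloc[:, 1].str.strip())
        )
    else:
        group_map = dict(groups)
    lengths = None
    if gene_lengths_path is not None:
        ldf = pd.read_csv(gene_lengths_path, sep="\t", dtype=str)
        lengths = pd.Series(
            pd.to_numeric(ldf.iloc[:, 1], errors="raise").to_numpy(),
            index=ldf.iloc[:, 0].str.strip(),
            name="length",
        )
    counts = counts.round().astype(np.int64)
    return QueryCounts(counts=counts, group_map=group_map, gene_lengths=lengths)


def filter_atlas(
    atlas: Atlas, min_samples: int = 2, detection_threshold: float = 0.0
) -> Atlas:
    """Keep regions assayed in >= ``min_samples`` samples and probes
    expressed (value > ``detection_threshold``) in >= ``min_samples`` samples.

    Regions are filtered first and probe expression calls are made on the
    surviving samples, which makes the operation idempotent.
    """
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    counts = atlas.meta["region_id"].value_counts()
    keep_regions = set(counts[counts >= min_samples].index)
    keep_samples = atlas.meta.index[atlas.meta["region_id"].isin(keep_regions)]
    meta = atlas.meta.loc[keep_samples]
    expr = atlas.expr[keep_samples]
    expressed = (expr.to_numpy() > detection_threshold).sum(axis=1)
    keep_probes = expr.index[expressed >= min_samples]
    expr = expr.loc[keep_probes]
    if expr.shape[0] == 0 or expr.shape[1] == 0:
        raise AtlasValidationError("atlas empty after filtering")
    logger.info(
        "filter_atlas: probes %d -> %d, regions %d -> %d, samples %d -> %d",
        atlas.expr.shape[0], expr.shape[0],
        len(counts), len(keep_regions),
        atlas.expr.shape[1], expr.shape[1],
    )
    gene_map = None
    if atlas.gene_map is not None:
        gene_map = atlas.gene_map[atlas.gene_map.index.isin(keep_probes)]
    return Atlas(expr=expr, meta=meta, gene_map=gene_map)


def collapse_probes(atlas: Atlas, collapse: str = "mean") -> pd.DataFrame:
    """Collapse the probe-level matrix to gene level (genes x samples).

    Multi-probe genes are combined by ``collapse`` ("mean" or "median").
    Without a gene map, probe ids are taken to be gene symbols already.
    """
    if atlas.gene_map is None:
        return atlas.expr
    mapped = atlas.expr.loc[atlas.expr.index.isin(atlas.gene_map.index)]
    genes = atlas.gene_map.loc[mapped.index]
    grouped = mapped.groupby(genes.to_numpy())
    if collapse == "mean":
        out = grouped.mean()
    elif collapse == "median":
        out = grouped.median()
    else:
        raise ValueError(f"unknown collapse rule {collapse!r}")
    return out.rename_axis(atlas.expr.index.name)


def harmonize_genes(
    atlas: Atlas, query: QueryCounts, collapse: str = "mean"
) -> pd.Index:
    """Ordered intersection of query gene ids with (mapped) atlas genes.

    Order follows the query's gene list.  Raises on an empty intersection.
    """
    atlas_genes = collapse_probes(atlas, collapse=collapse).index
    shared = pd.Index([g for g in query.gene_ids if g in set(atlas_genes)])
    if len(shared) == 0:
        raise AtlasValidationError(
            "no genes shared between atlas and query"
        )
    logger.info(
        "harmonize_genes: %d shared genes (atlas %d, query %d)",
        len(shared), len(atlas_genes), len(query.gene_ids),
    )
    return shared


def write_atlas(atlas: Atlas, expr_path: str | Path, meta_path: str | Path) -> None:
    """Write the atlas back to its TSV dialect at full printed precision."""
    atlas.expr.rename_axis("probe_id").to_csv(
        expr_path, sep="\t", float_format="%.12g"
    )
    meta = atlas.meta.rename_axis("sample_id")
    meta.to_csv(meta_path, sep="\t", float_format="%.12g")
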