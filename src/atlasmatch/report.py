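"""Score-table exports: voxel-coordinate projections and flattened heatmaps.

Voxel scores attach each region's -log10 p to its 3-D atlas coordinate so
the match can be rendered as colored dots in anatomical space; the CSV is
the contract, plotting is an optional cosmetic helper.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .io import Atlas

logger = logging.getLogger(__name__)

VOXEL_COLUMNS = ["region_id", "structure", "x", "y", "z", "neglog10_p"]


def voxel_scores(results: pd.DataFrame, atlas: Atlas) -> pd.DataFrame:
    """Join per-region scores with region coordinates.

    Regions without finite coordinates are skipped (count logged); an error
    is raised when no region has coordinates at all.
    """
    coords = atlas.region_coordinates()
    scored = results.drop_duplicates("region_id")
    have = scored["region_id"].isin(coords.index)
    n_missing = int((~have).sum())
    if have.sum() == 0:
        raise ValueError("no scored region has voxel coordinates")
    if n_missing:
        logger.info("%d region(s) without coordinates skipped", n_missing)
    sub = scored.loc[have, ["region_id", "neglog10_p"]]
    out = sub.merge(
        coords[["structure", "x", "y", "z"]],
        left_on="region_id", right_index=True,
    )
    return out[VOXEL_COLUMNS].reset_index(drop=True)


def export_voxel_scores(
    results: pd.DataFrame, atlas: Atlas, out: str | Path
) -> pd.DataFrame:
    """Write the voxel-score CSV (12 significant digits) and return it."""
    table = voxel_scores(results, atlas)
    table.to_csv(out, index=False, float_format="%.12g")
    return table


def heatmap_table(results: pd.DataFrame) -> pd.DataFrame:
    """Wide region x stage table of -log10 p values.

    Rows ordered by descending maximum score across stages; (region, stage)
    pairs never scored stay missing.
    """
    if results.empty:
        raise ValueError("no results to tabulate")
    wide = results.pivot_table(
        index="region_id", columns="stage", values="neglog10_p",
        aggfunc="first",
    )
    order = wide.max(axis=1).sort_values(ascending=False).index
    return wide.loc[order]


def export_heatmap_table(results: pd.DataFrame, out: str | Path) -> pd.DataFrame:
    table = heatmap_table(results)
    table.to_csv(out, sep="\t", float_format="%.12g")
    return table


def plot_voxel_scores(table: pd.DataFrame, out: str | Path) -> None:
    """Optional 3-D scatter of voxel scores (PNG), colored by score."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(7, 6))
    ax = fig.add_subplot(projection="3d")
    sc = ax.scatter(
        table["x"], table["y"], table["z"],
        c=table["neglog10_p"], cmap="viridis", s=25,
    )
    fig.colorbar(sc, ax=ax, label="-log10 p")
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    ax.set_zlabel("z")
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
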