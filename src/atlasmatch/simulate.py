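"""Synthetic region-annotated atlas and query generators.

The generator emulates the structure of a multi-donor, multi-stage brain
expression atlas: micro-dissected regions grouped into three anatomical
structures (brain stem / cortex / cerebellum, sizes echoing the real 59 /
362 / 80 imbalance at desk scale), assayed at three developmental stages
(adult and two fetal windows) in two donors each.  Atlas values live
directly on the log2 scale (microarray-like intensities); queries are
negative-binomial integer counts (RNA-seq-like), so the pipeline has to
bridge the two platforms exactly as the rank-based method intends.

Per-sample model (log2 units):

    baseline(probe)                       lognormal-like probe abundance
  + structure_effect * [probe in structure's shared marker set]
  + region_effect    * [probe in region's signature]
  + stage_effect     * [probe in the structure's marker set FOR THAT STAGE]
  + Normal(0, noise_sd)

Region signatures are disjoint across regions and stage-invariant; they
carry regional identity.  Each structure additionally expresses a different
developmental marker subset at each stage (drawn from a dedicated stage-
variable pool), which is what makes developmental stages distinguishable:
a globally shared stage shift would enter every region's rank-difference
vector identically and cancel out of the region-versus-background test.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import Atlas, QueryCounts

#: default stage labels with donors per stage
DEFAULT_STAGE_DONORS: dict[str, int] = {"adult": 2, "pcw15_16": 2, "pcw21_22": 2}


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic atlas.

    Effects are log2-unit elevations.  ``signature_size`` probes per region
    are region signatures (disjoint across regions); each structure has a
    stage-invariant shared marker set of ``structure_set_size`` probes and,
    per stage, a developmental marker set of ``stage_set_size`` probes drawn
    from the stage-variable pool (the probes left over after signature and
    shared-set allocation).
    """

    n_probes: int = 2000
    n_regions: int = 30
    structure_names: tuple[str, ...] = ("BS", "CX", "CB")
    structure_sizes: tuple[int, ...] = (5, 20, 5)
    stage_donors: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_DONORS)
    )
    signature_size: int = 50
    region_effect: float = 2.0
    structure_effect: float = 0.5
    structure_set_size: int = 60
    stage_effect: float = 1.0
    stage_set_size: int = 100
    noise_sd: float = 0.5
    baseline_mean: float = 6.0
    baseline_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.structure_sizes) != self.n_regions:
            raise ValueError(
                f"structure_sizes {self.structure_sizes} do not sum to "
                f"n_regions={self.n_regions}"
            )
        if len(self.structure_sizes) != len(self.structure_names):
            raise ValueError("one size per structure name required")
        for name in ("signature_size", "structure_set_size", "stage_set_size",
                     "n_probes", "n_regions"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("region_effect", "structure_effect", "stage_effect",
                     "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        used = (self.n_regions * self.signature_size
                + len(self.structure_names) * self.structure_set_size)
        if used + self.stage_set_size > self.n_probes:
            raise ValueError(
                "probe budget exceeded: signatures + structure sets + stage "
                f"pool need more than n_probes={self.n_probes}"
            )

    @property
    def stages(self) -> list[str]:
        return list(self.stage_donors)


@dataclass
class SyntheticTruth:
    """Ground truth of a generated dataset.

    ``true_region``/``true_stage`` identify the origin of the simulated
    query (None until a query has been generated).
    """

    config: GeneratorConfig
    region_structure: dict[str, str]
    region_signatures: dict[str, list[str]]
    structure_sets: dict[str, list[str]]
    stage_sets: dict[str, list[str]]  # keyed "structure|stage"
    true_region: str | None = None
    true_stage: str | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "true_region": self.true_region,
            "true_stage": self.true_stage,
            "config": dataclasses.asdict(self.config),
            "region_structure": self.region_structure,
            "region_signatures": self.region_signatures,
            "structure_sets": self.structure_sets,
            "stage_sets": self.stage_sets,
        }
        payload["config"]["structure_names"] = list(
            self.config.structure_names)
        payload["config"]["structure_sizes"] = list(
            self.config.structure_sizes)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        cfg = payload["config"]
        cfg["structure_names"] = tuple(cfg["structure_names"])
        cfg["structure_sizes"] = tuple(cfg["structure_sizes"])
        return cls(
            config=GeneratorConfig(**cfg),
            region_structure=payload["region_structure"],
            region_signatures=payload["region_signatures"],
            structure_sets=payload["structure_sets"],
            stage_sets=payload["stage_sets"],
            true_region=payload["true_region"],
            true_stage=payload["true_stage"],
        )


def _probe_ids(n: int) -> list[str]:
    return [f"P{i:05d}" for i in range(1, n + 1)]


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


def generate_atlas(config: GeneratorConfig) -> tuple[Atlas, SyntheticTruth]:
    """Simulate a region-annotated atlas; deterministic per config seed."""
    rng = np.random.default_rng(config.seed)
    probes = np.asarray(_probe_ids(config.n_probes))
    genes = _gene_ids(config.n_probes)
    gene_map = pd.Series(genes, index=probes, name="gene")

    regions = [f"R{i:02d}" for i in range(1, config.n_regions + 1)]
    region_structure: dict[str, str] = {}
    i = 0
    for name, size in zip(config.structure_names, config.structure_sizes):
        for _ in range(size):
            region_structure[regions[i]] = name
            i += 1

    perm = rng.permutation(config.n_probes)
    pos = 0
    region_signatures = {}
    for r in regions:
        idx = perm[pos: pos + config.signature_size]
        region_signatures[r] = list(probes[idx])
        pos += config.signature_size
    structure_sets = {}
    for s in config.structure_names:
        idx = perm[pos: pos + config.structure_set_size]
        structure_sets[s] = list(probes[idx])
        pos += config.structure_set_size
    stage_pool = perm[pos:]
    stage_sets = {}
    for s in config.structure_names:
        for stage in config.stages:
            idx = rng.choice(stage_pool, size=config.stage_set_size,
                             replace=False)
            stage_sets[f"{s}|{stage}"] = list(probes[idx])

    baseline = rng.normal(config.baseline_mean, config.baseline_sd,
                          config.n_probes)
    probe_pos = {p: k for k, p in enumerate(probes)}

    def mask(probe_list: list[str]) -> np.ndarray:
        m = np.zeros(config.n_probes, dtype=bool)
        m[[probe_pos[p] for p in probe_list]] = True
        return m

    sig_mask = {r: mask(region_signatures[r]) for r in regions}
    struct_mask = {s: mask(structure_sets[s]) for s in config.structure_names}
    stage_mask = {k: mask(v) for k, v in stage_sets.items()}

    # clustered 3-D coordinates: structures far apart, member regions nearby
    centers = {
        s: np.array([60.0 * k, 30.0 * (k % 2), 15.0 * k])
        for k, s in enumerate(config.structure_names)
    }
    region_coord = {
        r: centers[region_structure[r]] + rng.normal(0.0, 5.0, 3)
        for r in regions
    }

    columns, meta_rows = {}, []
    for stage, n_donors in config.stage_donors.items():
        for d in range(1, n_donors + 1):
            donor = f"{stage}_d{d}"
            for r in regions:
                s = region_structure[r]
                values = baseline.copy()
                values[struct_mask[s]] += config.structure_effect
                values[sig_mask[r]] += config.region_effect
                values[stage_mask[f"{s}|{stage}"]] += config.stage_effect
                if config.noise_sd > 0:
                    values = values + rng.normal(
                        0.0, config.noise_sd, config.n_probes)
                sid = f"{donor}_{r}"
                columns[sid] = values
                meta_rows.append({
                    "sample_id": sid,
                    "donor_id": donor,
                    "stage": stage,
                    "region_id": r,
                    "structure": s,
                    "x": region_coord[r][0],
                    "y": region_coord[r][1],
                    "z": region_coord[r][2],
                })
    expr = pd.DataFrame(columns, index=probes)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    atlas = Atlas(expr=expr, meta=meta, gene_map=gene_map)
    truth = SyntheticTruth(
        config=config,
        region_structure=region_structure,
        region_signatures=region_signatures,
        structure_sets=structure_sets,
        stage_sets=stage_sets,
    )
    return atlas, truth


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    """Negative binomial with variance mean + dispersion * mean**2."""
    if dispersion <= 1e-12:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def generate_query(
    atlas: Atlas,
    truth: SyntheticTruth,
    region: str,
    stage: str,
    n_reps: int = 3,
    mean_libsize: int = 5_000_000,
    dispersion: float = 0.1,
    seed: int = 0,
    group: str = "query",
) -> tuple[QueryCounts, SyntheticTruth]:
    """Simulate RNA-seq replicate counts for a cell population from one
    atlas region at one stage.

    Expected expression is proportional to 2**(the region's mean log2
    profile at that stage); replicate counts are negative-binomial.
    """
    sel = (atlas.meta["region_id"] == region) & (atlas.meta["stage"] == stage)
    if not sel.any():
        raise ValueError(f"region {region!r} at stage {stage!r} not in atlas")
    mean_log2 = atlas.expr[atlas.meta.index[sel]].mean(axis=1)
    if atlas.gene_map is not None:
        mean_log2 = mean_log2.groupby(
            atlas.gene_map.loc[mean_log2.index].to_numpy()).mean()
    rel = np.power(2.0, mean_log2.to_numpy())
    mu = rel / rel.sum() * float(mean_libsize)
    rng = np.random.default_rng(seed)
    cols = {}
    for k in range(1, n_reps + 1):
        cols[f"{group}_rep{k}"] = _nb_draw(rng, mu, dispersion)
    counts = pd.DataFrame(cols, index=mean_log2.index, dtype=np.int64)
    counts.index.name = "gene_id"
    query = QueryCounts(
        counts=counts,
        group_map={c: group for c in counts.columns},
    )
    completed = dataclasses.replace(truth, true_region=region,
                                    true_stage=stage)
    return query, completed


def generate_de_counts(
    n_genes: int = 2000,
    n_de: int = 0,
    lfc: float = 0.0,
    n_per_group: int = 3,
    mean_libsize: int = 1_000_000,
    dispersion: float = 0.1,
    seed: int = 0,
) -> tuple[QueryCounts, set[str]]:
    """Two-group negative-binomial count matrix with a known DE truth set.

    ``n_de`` genes are shifted by ``lfc`` log2 units in group 2; per-group
    expected proportions are renormalized, so large shifts induce the
    composition effect TMM exists to correct.
    """
    if n_de > n_genes:
        raise ValueError("n_de cannot exceed n_genes")
    if n_genes < 1 or n_per_group < 1:
        raise ValueError("invalid sizes")
    rng = np.random.default_rng(seed)
    genes = np.asarray(_gene_ids(n_genes))
    base = np.power(2.0, rng.normal(0.0, 1.0, n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    shifted = base.copy()
    shifted[de_idx] *= 2.0 ** lfc
    mu1 = base / base.sum() * float(mean_libsize)
    mu2 = shifted / shifted.sum() * float(mean_libsize)
    cols = {}
    for k in range(1, n_per_group + 1):
        cols[f"g1_rep{k}"] = _nb_draw(rng, mu1, dispersion)
    for k in range(1, n_per_group + 1):
        cols[f"g2_rep{k}"] = _nb_draw(rng, mu2, dispersion)
    counts = pd.DataFrame(cols, index=genes, dtype=np.int64)
    counts.index.name = "gene_id"
    group_map = {c: ("g1" if c.startswith("g1") else "g2") for c in cols}
    truth = set(genes[de_idx])
    return QueryCounts(counts=counts, group_map=group_map), truth


def write_fixture_bundle(
    out_dir: str | Path,
    config: GeneratorConfig | None = None,
    region: str | None = None,
    stage: str | None = None,
    n_reps: int = 3,
    mean_libsize: int = 5_000_000,
    dispersion: float = 0.1,
) -> dict[str, Path]:
    """Write a complete synthetic dataset in the pipeline's file dialects.

    Defaults pick the first region of the last structure (the cerebellum
    surrogate) at the last stage.  Byte-stable for a fixed config seed.
    """
    config = config or GeneratorConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    atlas, truth = generate_atlas(config)
    if region is None:
        last = config.structure_names[-1]
        region = next(r for r, s in truth.region_structure.items()
                      if s == last)
    if stage is None:
        stage = config.stages[-1]
    query, truth = generate_query(
        atlas, truth, region, stage,
        n_reps=n_reps, mean_libsize=mean_libsize,
        dispersion=dispersion, seed=config.seed,
    )
    paths = {
        "atlas_expr": out / "atlas_expr.tsv",
        "atlas_meta": out / "atlas_meta.tsv",
        "gene_map": out / "gene_map.tsv",
        "query_counts": out / "query_counts.tsv",
        "query_groups": out / "query_groups.tsv",
        "truth": out / "truth.json",
    }
    atlas.expr.rename_axis("probe_id").to_csv(
        paths["atlas_expr"], sep="\t", float_format="%.12g")
    atlas.meta.rename_axis("sample_id").to_csv(
        paths["atlas_meta"], sep="\t", float_format="%.12g")
    atlas.gene_map.rename_axis("probe_id").to_csv(
        paths["gene_map"], sep="\t")
    query.counts.to_csv(paths["query_counts"], sep="\t")
    pd.Series(query.group_map, name="group").rename_axis("sample_id").to_csv(
        paths["query_groups"], sep="\t")
    truth.to_json(paths["truth"])
    return paths
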