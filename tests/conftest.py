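"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings
from scipy.stats import rankdata

import atlasmatch as am

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# oracles (kept deliberately naive and independent of the implementation)

def brute_force_rank_sum_p(x, y, alternative: str) -> float:
    """Exact rank-sum p by literal enumeration of all label assignments."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n1 = x.size
    w_obs = ranks[:n1].sum()
    sums = [ranks[list(c)].sum() for c in combinations(range(pooled.size), n1)]
    sums = np.asarray(sums)
    eps = 1e-9
    p_less = np.mean(sums <= w_obs + eps)
    p_greater = np.mean(sums >= w_obs - eps)
    if alternative == "less":
        return float(p_less)
    if alternative == "greater":
        return float(p_greater)
    return float(min(1.0, 2.0 * min(p_less, p_greater)))


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Direct min-over-tails Benjamini-Hochberg, O(m^2)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    adj_sorted = np.empty(m)
    for i in range(m):
        adj_sorted[i] = min(
            min(m * sorted_p[j] / (j + 1) for j in range(i, m)), 1.0
        )
    out = np.empty(m)
    out[order] = adj_sorted
    return out


# ---------------------------------------------------------------------------
# fixtures

@pytest.fixture
def toy_atlas(tmp_path):
    """Hand-written 4-probe x 6-sample atlas on disk; returns the paths."""
    expr = "\n".join([
        "probe_id\ts1\ts2\ts3\ts4\ts5\ts6",
        "p1\t1.0\t2.0\t3.0\t4.0\t5.0\t6.0",
        "p2\t0.0\t0.0\t0.0\t0.0\t0.0\t7.0",   # expressed in 1 sample only
        "p3\t2.5\t2.5\t2.5\t2.5\t2.5\t2.5",
        "p4\t9.0\t8.0\t7.0\t6.0\t5.0\t4.0",
    ])
    meta = "\n".join([
        "sample_id\tdonor_id\tstage\tregion_id\tstructure\tx\ty\tz",
        "s1\td1\tadult\trA\tCX\t0\t0\t0",
        "s2\td2\tadult\trA\tCX\t0\t0\t0",
        "s3\td1\tadult\trB\tCB\t10\t0\t0",
        "s4\td2\tadult\trB\tCB\t10\t0\t0",
        "s5\td1\tadult\trB\tCB\t10\t0\t0",
        "s6\td1\tadult\trC\tBS\t20\t0\t0",    # region with a single sample
    ])
    expr_path = tmp_path / "expr.tsv"
    meta_path = tmp_path / "meta.tsv"
    expr_path.write_text(expr + "\n")
    meta_path.write_text(meta + "\n")
    return expr_path, meta_path


@pytest.fixture(scope="session")
def small_generator_config():
    """Desk-scale generator configuration for fast pipeline tests."""
    return am.GeneratorConfig(
        n_probes=600, n_regions=6, structure_sizes=(2, 2, 2),
        signature_size=30, structure_set_size=30, stage_set_size=50,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_generator_config):
    """(atlas, truth, query) from a fixed-seed small simulation."""
    atlas, truth = am.generate_atlas(small_generator_config)
    query, truth = am.generate_query(
        atlas, truth, region="R05", stage="pcw21_22", seed=11
    )
    return atlas, truth, query


def query_from_counts(counts: dict[str, list[int]], index=None,
                      groups: dict[str, str] | None = None) -> am.QueryCounts:
    df = pd.DataFrame(counts, index=index, dtype=np.int64)
    if index is None:
        df.index = [f"g{i}" for i in range(1, len(df) + 1)]
    gm = groups or {c: "g" for c in df.columns}
    return am.QueryCounts(counts=df, group_map=gm)
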