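"""Diagonal-window filter and the three-class / six-cluster trajectory
partition.

Midlife expression changes in wildtype animals that are environment-invariant
are isolated with a relative window around the SE-vs-EE diagonal; DEG sets
from the temporal (WT and TG 12-vs-6) and genotype (TG vs WT at 12 months)
axes are combined into the age-x-genotype-regulated union; each union gene is
then assigned a disturbance class:

* class 1 — temporal change present in both WT and TG with the same sign
  (trajectory preserved),
* class 2 — no (window-consistent) WT temporal change, but a TG temporal
  change or a genotype offset at 12 months (disturbance mode I),
* class 3 — WT temporal change that fails to occur in TG (mode II).

Genes with opposing WT/TG temporal signs are flagged unclassified. Clusters
split each class by direction, and each cluster is summarised by its medoid
trajectory over the four standard-environment cells.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .synthetic_data import Cell, cell_key

__all__ = [
    "diagonal_window_filter",
    "combine_temporal_degs",
    "assign_classes",
    "zscore_matrix",
    "cell_mean_profiles",
    "cluster_medoids",
    "hierarchical_order",
    "SE_PROFILE_CELLS",
]

logger = logging.getLogger(__name__)

#: trajectory profile cells, in plotting order
SE_PROFILE_CELLS: list[Cell] = [("WT", 6, "SE"), ("WT", 12, "SE"), ("TG", 6, "SE"), ("TG", 12, "SE")]

_DIR_NUM = {"up": 1, "down": -1}


def diagonal_window_filter(
    fc_table: pd.DataFrame,
    window: float = 0.5,
    rule: str = "relative",
) -> pd.DataFrame:
    """Mark genes whose EE fold-change stays within a window of the SE one.

    ``rule='relative'`` (default): |fc_ee - fc_se| <= window * |fc_se|;
    ``rule='symmetric'``: the bound is window * max(|fc_se|, |fc_ee|).
    Genes with fc_se == 0 are inside only when fc_ee == 0 as well.
    Expects columns ``fc_se`` and ``fc_ee``; returns a copy with an
    ``inside_window`` column appended.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    fc_se = fc_table["fc_se"].to_numpy(dtype=float)
    fc_ee = fc_table["fc_ee"].to_numpy(dtype=float)
    delta = np.abs(fc_ee - fc_se)
    if rule == "relative":
        bound = window * np.abs(fc_se)
    elif rule == "symmetric":
        bound = window * np.maximum(np.abs(fc_se), np.abs(fc_ee))
    else:
        raise ValueError(f"unknown window rule {rule!r}")
    inside = np.where(fc_se == 0, fc_ee == 0, delta <= bound)
    out = fc_table.copy()
    out["inside_window"] = inside
    return out


def combine_temporal_degs(deg_sets: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Union of DEG sets with per-source direction columns.

    ``deg_sets`` maps a source label to a DEG table (indexed by gene_id, with
    a ``direction`` column). Conflicting directions across sources are kept
    per source, never merged. Returns a table indexed by the union of genes
    with one ``dir_<label>`` column per source plus ``n_sources``.
    """
    union = pd.Index([], name="gene_id")
    for df in deg_sets.values():
        union = union.union(df.index)
    out = pd.DataFrame(index=union.sort_values())
    for label, df in deg_sets.items():
        if df.index.has_duplicates:
            raise ValueError(f"duplicate genes in DEG set {label!r}")
        out[f"dir_{label}"] = df["direction"].reindex(out.index)
    out["n_sources"] = out.notna().sum(axis=1)
    return out


def _directions(deg_set: pd.DataFrame) -> pd.Series:
    return deg_set["direction"].map(_DIR_NUM)


def assign_classes(
    wt_temporal: pd.DataFrame,
    tg_temporal: pd.DataFrame,
    genotype_12: pd.DataFrame,
) -> pd.DataFrame:
    """Partition the union of the three DEG sets into disturbance classes.

    Inputs are DEG tables (gene-indexed, ``direction`` column): the
    window-restricted WT temporal set, the TG temporal set, and the TG-vs-WT
    set at 12 months. Every union gene receives class 1, 2 or 3, or
    class 0 = unclassified (WT/TG temporal changes with opposing signs).
    Cluster direction is the WT temporal sign for classes 1 and 3, and the TG
    temporal sign (falling back to the genotype sign) for class 2.
    """
    a_dir = _directions(wt_temporal)
    b_dir = _directions(tg_temporal)
    c_dir = _directions(genotype_12)

    universe = a_dir.index.union(b_dir.index).union(c_dir.index).sort_values()
    A = universe.isin(a_dir.index)
    B = universe.isin(b_dir.index)
    C = universe.isin(c_dir.index)
    av = a_dir.reindex(universe).fillna(0).to_numpy(dtype=int)
    bv = b_dir.reindex(universe).fillna(0).to_numpy(dtype=int)
    cv = c_dir.reindex(universe).fillna(0).to_numpy(dtype=int)

    cls = np.zeros(len(universe), dtype=int)
    sign = np.zeros(len(universe), dtype=int)

    same = A & B & (av == bv)
    cls[same] = 1
    sign[same] = av[same]

    two = ~A & (B | C)
    cls[two] = 2
    sign[two] = np.where(bv[two] != 0, bv[two], cv[two])

    three = A & ~B
    cls[three] = 3
    sign[three] = av[three]

    cluster = np.where(
        cls == 0,
        "unclassified",
        np.char.add(
            np.char.add(cls.astype(str), "-"),
            np.where(sign > 0, "up", "down"),
        ),
    )
    out = pd.DataFrame(
        {
            "class_label": cls,
            "cluster": cluster,
            "in_wt_temporal": A,
            "wt_temporal_sign": av,
            "in_tg_temporal": B,
            "tg_temporal_sign": bv,
            "in_genotype_12": C,
            "genotype_12_sign": cv,
        },
        index=universe,
    )
    out.index.name = "gene_id"
    return out


def zscore_matrix(norm_expr: pd.DataFrame) -> pd.DataFrame:
    """Row-wise standardization (sample SD, ddof=1); constant rows map to 0."""
    x = norm_expr.to_numpy(dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mean) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = 0.0
    return pd.DataFrame(z, index=norm_expr.index, columns=norm_expr.columns)


def cell_mean_profiles(
    expr: pd.DataFrame,
    design: pd.DataFrame,
    cells: list[Cell] = None,
) -> pd.DataFrame:
    """Aggregate a genes x samples matrix to per-design-cell means, ordered
    as the requested trajectory cells (default WT-6, WT-12, TG-6, TG-12 in
    SE)."""
    if cells is None:
        cells = SE_PROFILE_CELLS
    out = {}
    for cell in cells:
        g, a, e = cell
        ids = design.loc[
            (design["genotype"] == g)
            & (design["age_months"] == a)
            & (design["environment"] == e),
            "sample_id",
        ]
        ids = [s for s in ids if s in expr.columns]
        if not ids:
            raise ValueError(f"no samples for profile cell {cell_key(cell)}")
        out[cell_key(cell)] = expr[ids].mean(axis=1)
    return pd.DataFrame(out)


def cluster_medoids(profiles: pd.DataFrame, assignment: pd.DataFrame) -> pd.DataFrame:
    """Medoid trajectory and per-point SD for each directional cluster.

    The medoid is the member minimizing the summed Euclidean distance to all
    other members' profiles (lexicographically first gene on ties). Empty
    clusters are omitted with a log note. Returns one row per cluster with
    the medoid gene, member count, medoid profile and per-point SD.
    """
    rows = []
    classified = assignment.loc[assignment["class_label"] > 0]
    for cluster_id in sorted(classified["cluster"].unique()):
        members = classified.index[classified["cluster"] == cluster_id]
        members = members.intersection(profiles.index).sort_values()
        if len(members) == 0:
            logger.info("cluster %s has no profiled members; omitted", cluster_id)
            continue
        block = profiles.loc[members].to_numpy()
        diff = block[:, None, :] - block[None, :, :]
        dist = np.sqrt(np.square(diff).sum(axis=2))
        medoid_pos = int(np.argmin(dist.sum(axis=1)))
        row = {
            "cluster": cluster_id,
            "medoid_gene": members[medoid_pos],
            "n_members": len(members),
        }
        for j, col in enumerate(profiles.columns):
            row[f"medoid_{col}"] = block[medoid_pos, j]
            row[f"sd_{col}"] = block[:, j].std(ddof=0) if len(members) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def correlation_distance_matrix(z: pd.DataFrame) -> np.ndarray:
    """Pearson-correlation distance (1 - r); constant rows get the maximal
    distance 2 to every other row."""
    x = z.to_numpy(dtype=float)
    sd = x.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    d = 1.0 - r
    const = sd == 0
    d[const, :] = 2.0
    d[:, const] = 2.0
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def hierarchical_order(z: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    """Average-linkage agglomeration on correlation distance.

    Rows are sorted lexicographically first so that ties resolve
    deterministically by gene id. Returns the leaf order (gene ids, for
    heatmap export) and the scipy linkage matrix.
    """
    if len(z) < 2:
        raise ValueError("need at least 2 genes to cluster")
    z = z.sort_index()
    d = correlation_distance_matrix(z)
    lk = linkage(squareform(d, checks=False), method="average")
    order = [z.index[i] for i in leaves_list(lk)]
    return order, lk
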