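"""Synthetic count-data generator for the age x genotype x environment design.

Generates negative-binomial count matrices over the factorial design cells
(wildtype/transgenic x 6/12 months x standard/enriched/stress housing),
together with the ground-truth gene labels needed to score every downstream
stage: planted class-1/2/3 trajectory genes, enrichment-compensated genes, a
sequencing-day batch shift, interaction networks wired around designated hub
genes, and marker-structured mixtures for cell-type deconvolution.

The generative model matches the assumptions of the differential-expression
engine: counts are NB-distributed with a log-link mean
``library_size * base_mean * 2**(lfc + batch_shift)`` and gene-wise
dispersion ``alpha`` (variance ``mu + alpha * mu**2``).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_CELLS",
    "Cell",
    "SyntheticTruth",
    "InvalidDesignError",
    "cell_key",
    "make_design",
    "make_truth",
    "simulate_counts",
    "simulate_network",
    "make_celltype_signature",
    "simulate_mixture",
    "make_signature_sets",
    "make_ortholog_map",
    "write_counts_tsv",
    "write_design_tsv",
    "write_truth_tsv",
    "write_edges_tsv",
]

Cell = tuple[str, int, str]

GENOTYPES = ("WT", "TG")
AGES = (6, 12)
ENVIRONMENTS = ("SE", "EE", "ST")

#: The ten tested design cells: at 6 months only standard and enriched
#: housing exist; at 12 months all three environments were sampled.
DEFAULT_CELLS: list[Cell] = [
    (g, 6, e) for g in GENOTYPES for e in ("SE", "EE")
] + [(g, 12, e) for g in GENOTYPES for e in ENVIRONMENTS]

REFERENCE_CELL: Cell = ("WT", 6, "SE")


class InvalidDesignError(ValueError):
    """Raised for unusable sample designs (no cells, n per cell < 2, ...)."""


def cell_key(cell: Cell) -> str:
    """Canonical string form of a design cell, e.g. ``WT_12_SE``."""
    g, a, e = cell
    return f"{g}_{a}_{e}"


def parse_cell(text: str) -> Cell:
    """Parse ``WT,12,SE`` or ``WT_12_SE`` into a cell tuple."""
    parts = text.replace(",", "_").split("_")
    if len(parts) != 3:
        raise ValueError(f"cannot parse design cell from {text!r}")
    g, a, e = parts[0].upper(), int(parts[1]), parts[2].upper()
    if g not in GENOTYPES or a not in AGES or e not in ENVIRONMENTS:
        raise ValueError(f"unknown design cell {text!r}")
    return (g, a, e)


def make_design(
    n_per_cell: int,
    cells: list[Cell] | None = None,
    n_batches: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Build a sample sheet with ``n_per_cell`` replicates per design cell.

    Batches (sequencing-day labels) are assigned round-robin across the full
    sample list, so every cell is spread over sequencing days — with
    ``n_batches == n_per_cell`` each cell contributes exactly one sample per
    day. The result is deterministic for a given argument set.

    Returns a DataFrame with columns sample_id, genotype, age_months,
    environment, batch.
    """
    if cells is None:
        cells = list(DEFAULT_CELLS)
    if not cells:
        raise InvalidDesignError("at least one design cell is required")
    if len(set(cells)) != len(cells):
        raise InvalidDesignError("duplicate design cells")
    if n_per_cell < 2:
        raise InvalidDesignError("need at least 2 samples per design cell")
    if n_batches < 1:
        raise InvalidDesignError("n_batches must be positive")

    rows = []
    counter = itertools.count()
    for g, a, e in cells:
        for r in range(1, n_per_cell + 1):
            rows.append(
                {
                    "sample_id": f"{g}{a}_{e}_r{r}",
                    "genotype": g,
                    "age_months": a,
                    "environment": e,
                    "batch": next(counter) % n_batches,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class SyntheticTruth:
    """Planted per-gene ground truth.

    ``genes`` is indexed by gene_id with columns base_mean, dispersion,
    class_label (0 = non-DE), direction ('up'/'down'/'none'), ee_compensated
    and bias_shift (log2 offset applied to samples of ``bias_batch``).
    ``lfc`` holds the planted log2 offsets versus the WT-6-SE reference,
    one column per design cell (keyed by :func:`cell_key`).
    """

    genes: pd.DataFrame
    lfc: pd.DataFrame
    cells: list[Cell]
    bias_batch: int = 0
    extras: dict = field(default_factory=dict)

    @property
    def gene_ids(self) -> pd.Index:
        return self.genes.index

    def class_genes(self, label: int) -> pd.Index:
        return self.genes.index[self.genes["class_label"] == label]


def make_truth(
    n_genes: int,
    class_fractions: dict[int, float],
    lfc_magnitude: float,
    frac_compensated: float = 0.0,
    seed: int = 0,
    cells: list[Cell] | None = None,
    base_mean_range: tuple[float, float] = (5.0, 5000.0),
    dispersion_coef: tuple[float, float] = (3.0, 0.05),
    dispersion_lognoise_sd: float = 0.2,
    n_bias_genes: int = 0,
    bias_shift: float = 0.0,
    bias_batch: int = 0,
) -> SyntheticTruth:
    """Plant the three trajectory archetypes into a gene population.

    Class 1 genes change between 6 and 12 months identically in WT and TG
    (midlife trajectory preserved); class 2 genes are flat in WT but acquire
    a TG-12 offset (disturbance mode I, "too early"); class 3 genes change in
    WT but stay flat in TG (mode II, "failed adaptation"). Offsets are planted
    in SE and EE alike (midlife changes are environment-invariant); stress
    cells carry no archetype offsets. A fraction ``frac_compensated`` of
    class-2 genes has its TG-12-EE offset returned to zero, emulating the
    compensatory effect of enriched housing.

    The planted offset magnitude is exactly ``lfc_magnitude`` for every
    affected gene; randomness enters through the up/down direction,
    base means (log-uniform over ``base_mean_range``) and dispersions
    (``a / mu + b`` trend times log-normal noise).
    """
    if n_genes < 1:
        raise ValueError("n_genes must be positive")
    fracs = {int(k): float(v) for k, v in class_fractions.items()}
    if any(v < 0 for v in fracs.values()) or sum(fracs.values()) > 1 + 1e-9:
        raise ValueError("class fractions must be non-negative and sum to <= 1")
    if not 0 <= frac_compensated <= 1:
        raise ValueError("frac_compensated must be in [0, 1]")
    if cells is None:
        cells = list(DEFAULT_CELLS)
    if REFERENCE_CELL not in cells:
        raise ValueError(f"design cells must include the reference {REFERENCE_CELL}")

    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    gene_ids = pd.Index([f"g{i:0{width}d}" for i in range(1, n_genes + 1)], name="gene_id")

    lo, hi = base_mean_range
    base_mean = np.exp(rng.uniform(np.log(lo), np.log(hi), n_genes))
    a, b = dispersion_coef
    dispersion = (a / base_mean + b) * np.exp(
        rng.normal(0.0, dispersion_lognoise_sd, n_genes)
    )

    n_per_class = {k: int(round(fracs.get(k, 0.0) * n_genes)) for k in (1, 2, 3)}
    if sum(n_per_class.values()) > n_genes:
        raise ValueError("class fractions leave no room for null genes")
    class_label = np.zeros(n_genes, dtype=int)
    pos = 0
    for k in (1, 2, 3):
        class_label[pos : pos + n_per_class[k]] = k
        pos += n_per_class[k]

    sign = np.where(rng.random(n_genes) < 0.5, 1.0, -1.0)
    direction = np.where(class_label == 0, "none", np.where(sign > 0, "up", "down"))
    d = sign * lfc_magnitude

    compensated = np.zeros(n_genes, dtype=bool)
    class2_idx = np.flatnonzero(class_label == 2)
    if frac_compensated > 0 and class2_idx.size:
        n_comp = int(round(frac_compensated * class2_idx.size))
        compensated[rng.choice(class2_idx, size=n_comp, replace=False)] = True

    lfc = pd.DataFrame(0.0, index=gene_ids, columns=[cell_key(c) for c in cells])
    for cell in cells:
        g, age, env = cell
        if env == "ST":  # archetypes are defined on SE/EE only
            continue
        col = cell_key(cell)
        offsets = np.zeros(n_genes)
        if age == 12:
            if g == "WT":
                offsets = np.where(np.isin(class_label, (1, 3)), d, 0.0)
            else:  # TG at 12 months
                offsets = np.where(class_label == 1, d, 0.0)
                tg12 = np.where(class_label == 2, d, 0.0)
                if env == "EE":
                    tg12 = np.where(compensated, 0.0, tg12)
                offsets = offsets + tg12
        lfc[col] = offsets

    bias = np.zeros(n_genes)
    if n_bias_genes > 0:
        if n_bias_genes > n_genes:
            raise ValueError("more bias genes than genes")
        biased = rng.choice(n_genes, size=n_bias_genes, replace=False)
        bias[biased] = bias_shift

    genes = pd.DataFrame(
        {
            "base_mean": base_mean,
            "dispersion": dispersion,
            "class_label": class_label,
            "direction": direction,
            "ee_compensated": compensated,
            "bias_shift": bias,
        },
        index=gene_ids,
    )
    return SyntheticTruth(genes=genes, lfc=lfc, cells=list(cells), bias_batch=bias_batch)


def simulate_counts(
    truth: SyntheticTruth,
    design: pd.DataFrame,
    library_sizes: np.ndarray | pd.Series | None = None,
    seed: int = 0,
    library_size_lognoise_sd: float = 0.2,
) -> pd.DataFrame:
    """Draw an NB count matrix (genes x samples) under the planted truth.

    The mean for gene *i* in sample *j* is
    ``library_size_j * base_mean_i * 2**(lfc_i[cell(j)] + bias_ij)`` where the
    bias term applies only to samples sequenced in ``truth.bias_batch``.
    Counts are drawn as a gamma-Poisson mixture, which is numerically robust
    down to the Poisson limit (alpha -> 0). Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    n_samples = len(design)
    if library_sizes is None:
        library_sizes = np.exp(rng.normal(0.0, library_size_lognoise_sd, n_samples))
    library_sizes = np.asarray(library_sizes, dtype=float)
    if library_sizes.shape != (n_samples,):
        raise ValueError("library_sizes length must match the number of samples")
    if np.any(library_sizes <= 0):
        raise ValueError("library sizes must be strictly positive")

    sample_cells = [
        cell_key((r.genotype, int(r.age_months), r.environment))
        for r in design.itertuples()
    ]
    missing = sorted(set(sample_cells) - set(truth.lfc.columns))
    if missing:
        raise ValueError(f"design cells absent from the planted lfc profile: {missing}")

    lfc = truth.lfc[sample_cells].to_numpy()  # genes x samples
    in_bias_batch = (design["batch"].to_numpy() == truth.bias_batch).astype(float)
    log2_offset = lfc + np.outer(truth.genes["bias_shift"].to_numpy(), in_bias_batch)
    mu = (
        library_sizes[None, :]
        * truth.genes["base_mean"].to_numpy()[:, None]
        * np.exp2(log2_offset)
    )
    alpha = truth.genes["dispersion"].to_numpy()[:, None]
    lam = rng.gamma(shape=1.0 / alpha, scale=mu * alpha)
    counts = rng.poisson(lam)
    return pd.DataFrame(counts, index=truth.gene_ids, columns=design["sample_id"].to_numpy())


def simulate_network(
    truth: SyntheticTruth,
    hub_genes: list[str],
    edge_density: float,
    seed: int = 0,
    hub_degree: int = 20,
    class2_bias: float = 1.0,
    target_classes: tuple[int, ...] = (2, 3),
    self_loop_genes: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Wire hub genes preferentially into class-2/3 neighbourhoods.

    Each hub receives ``hub_degree`` neighbours sampled from the class-2/3
    pool, class-2 candidates weighted by ``class2_bias`` against
    ``1 - class2_bias`` for class 3. On top, background edges are drawn as an
    Erdos-Renyi layer with probability ``edge_density`` per unordered gene
    pair. Undirected edges are deduplicated; deliberate self-loops can be
    requested to exercise their exclusion from topological metrics downstream.
    """
    if not 0 < edge_density <= 1:
        raise ValueError("edge_density must be in (0, 1]")
    genes = list(truth.gene_ids)
    unknown = set(hub_genes) - set(genes)
    if unknown:
        raise ValueError(f"hub genes not in truth: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    idx = {g: i for i, g in enumerate(genes)}
    labels = truth.genes["class_label"].to_numpy()

    edges: set[tuple[str, str]] = set()

    def add(u: str, v: str) -> None:
        if u == v:
            edges.add((u, v))
        else:
            edges.add((min(u, v), max(u, v)))

    # hub wiring
    weights_by_class = {2: class2_bias, 3: 1.0 - class2_bias}
    for hub in hub_genes:
        pool = [g for g in genes if labels[idx[g]] in target_classes and g != hub]
        if not pool:
            continue
        w = np.array([weights_by_class.get(labels[idx[g]], 0.0) for g in pool])
        if w.sum() <= 0:
            w = np.ones(len(pool))
        w = w / w.sum()
        k = min(hub_degree, np.count_nonzero(w))
        chosen = rng.choice(len(pool), size=k, replace=False, p=w)
        for c in chosen:
            add(hub, pool[c])

    # background Erdos-Renyi layer over unordered pairs
    n = len(genes)
    n_pairs = n * (n - 1) // 2
    if n_pairs:
        m = rng.binomial(n_pairs, edge_density)
        seen: set[int] = set()
        while len(seen) < m:
            draw = rng.integers(0, n_pairs, size=m - len(seen))
            seen.update(int(x) for x in draw)
        for flat in sorted(seen):
            # invert the row-major upper-triangle index
            i = int(n - 2 - np.floor(np.sqrt(-8 * flat + 4 * n * (n - 1) - 7) / 2 - 0.5))
            j = int(flat + i + 1 - n * (n - 1) // 2 + (n - i) * ((n - i) - 1) // 2)
            add(genes[i], genes[j])

    for g in self_loop_genes:
        add(g, g)

    rows = sorted(edges)
    return pd.DataFrame(rows, columns=["source", "target"]).assign(interaction="pp")


# ---------------------------------------------------------------------------
# cell-type deconvolution fixtures
# ---------------------------------------------------------------------------

DEFAULT_CELL_TYPES = ("neuron", "astrocyte", "microglia", "oligodendrocyte")


def make_celltype_signature(
    n_markers: int = 50,
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES,
    seed: int = 0,
    high: tuple[float, float] = (50.0, 150.0),
    low: tuple[float, float] = (0.0, 5.0),
) -> pd.DataFrame:
    """Synthetic marker signature matrix (markers in rows, cell types in
    columns): each marker is highly expressed in its own type and near-silent
    elsewhere. A stand-in for a real single-cell-derived hippocampal
    reference."""
    rng = np.random.default_rng(seed)
    k = len(cell_types)
    sig = rng.uniform(*low, size=(n_markers, k))
    owner = np.arange(n_markers) % k
    sig[np.arange(n_markers), owner] = rng.uniform(*high, size=n_markers)
    markers = pd.Index([f"mk{i:03d}" for i in range(1, n_markers + 1)], name="marker")
    return pd.DataFrame(sig, index=markers, columns=list(cell_types))


def simulate_mixture(
    signature: pd.DataFrame,
    proportions: pd.DataFrame,
    seed: int = 0,
    alpha: float = 0.05,
    library_size: float = 1.0,
) -> pd.DataFrame:
    """NB-noised bulk marker expression for given per-sample mixing
    proportions (samples x cell types, rows summing to 1)."""
    props = proportions[signature.columns].to_numpy()
    mu = library_size * signature.to_numpy() @ props.T  # markers x samples
    rng = np.random.default_rng(seed)
    if alpha <= 0:
        counts = rng.poisson(mu)
    else:
        counts = rng.poisson(rng.gamma(shape=1.0 / alpha, scale=mu * alpha + 1e-12))
    return pd.DataFrame(counts, index=signature.index, columns=proportions.index)


# ---------------------------------------------------------------------------
# reference-signature and ortholog fixtures
# ---------------------------------------------------------------------------

def make_ortholog_map(
    gene_ids: pd.Index | list[str],
    seed: int = 0,
    n_ambiguous: int = 0,
    prefix: str = "HS_",
) -> pd.DataFrame:
    """One-to-one mouse -> human-style id map, with optional planted
    one-to-many ambiguities for exercising the quarantine path."""
    rng = np.random.default_rng(seed)
    gene_ids = list(gene_ids)
    rows = [(g, prefix + g.upper()) for g in gene_ids]
    if n_ambiguous > len(gene_ids):
        raise ValueError("more ambiguous genes than genes")
    if n_ambiguous:
        for i in rng.choice(len(gene_ids), size=n_ambiguous, replace=False):
            rows.append((gene_ids[i], prefix + gene_ids[i].upper() + "B"))
    return pd.DataFrame(rows, columns=["source", "target"])


def make_signature_sets(
    truth: SyntheticTruth,
    n_from_class2: int = 20,
    n_from_class3: int = 10,
    n_background: int = 30,
    seed: int = 0,
    prefix: str = "HS_",
) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Planted reference signature sets in the mapped (human-style) id space.

    Returns a GMT-style dict of gene sets plus a direction sidecar table
    (set, gene, direction). The aging signature deliberately overlaps the
    planted class-2 genes (accelerated processes) and, more weakly, class 3.
    """
    rng = np.random.default_rng(seed)

    def sample(pool: pd.Index, k: int) -> list[str]:
        k = min(k, len(pool))
        return [pool[i] for i in rng.choice(len(pool), size=k, replace=False)]

    c2 = sample(truth.class_genes(2), n_from_class2)
    c3 = sample(truth.class_genes(3), n_from_class3)
    nulls = sample(truth.class_genes(0), n_background)
    mapped = lambda gs: [prefix + g.upper() for g in gs]  # noqa: E731

    sets = {
        "age_signature": mapped(c2) + mapped(nulls[: n_background // 2]),
        "age_pd_signature": mapped(c3) + mapped(nulls[n_background // 2 :]),
    }
    rows = []
    for name, members in sets.items():
        for g in members:
            mouse_id = g[len(prefix):].lower()
            dir_ = (
                truth.genes.loc[mouse_id, "direction"]
                if mouse_id in truth.genes.index and truth.genes.loc[mouse_id, "direction"] != "none"
                else ("up" if rng.random() < 0.5 else "down")
            )
            rows.append({"set": name, "gene": g, "direction": dir_})
    return sets, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# writers (tab-separated, UTF-8, '#' comments allowed on read)
# ---------------------------------------------------------------------------

def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def write_design_tsv(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False)


def write_truth_tsv(truth: SyntheticTruth, path) -> None:
    table = truth.genes.join(truth.lfc.add_prefix("lfc_"))
    table.to_csv(path, sep="\t", index_label="gene_id")


def write_edges_tsv(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False)
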