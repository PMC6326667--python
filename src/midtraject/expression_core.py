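"""Normalization, filtering and factorial NB differential expression.

The engine follows the classic count-based RNA-seq workflow: median-of-ratios
size factors, a total-read-count gene filter, gene-wise NB dispersions
(method-of-moments, shrunk toward a log-log mean-dispersion trend), and a
negative-binomial GLM with log link fitted per gene under a cell-means
parameterization of the factorial design (genotype x age x environment, with
the known sequencing batch as an optional additive covariate). Group
contrasts are tested with a Wald statistic against the standard normal, and
p-values are Benjamini-Hochberg adjusted per contrast.

Differential expression uses the joint rule |log2FC| >= 0.3 and adjusted
p <= 0.1 (both inclusive); genes covered by fewer than 50 reads in total are
excluded up front; candidate genes whose expression shows a recurrent
sequencing-day deviation (> 4 SD against the leave-one-out mean of their
design cell) are excluded as technically biased.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import Cell, cell_key

__all__ = [
    "DEConfig",
    "NBFit",
    "NoReferenceGeneError",
    "SingularDesignError",
    "size_factors",
    "low_count_filter",
    "nrpkm",
    "estimate_dispersions",
    "fit_nb_glm",
    "contrast",
    "fit_contrast",
    "bh_adjust",
    "call_degs",
    "leave_one_out_stats",
    "technical_bias_filter",
    "isoform_shares",
]

LN2 = float(np.log(2.0))

_ALPHA_FLOOR = 1e-8
_ALPHA_CEIL = 50.0


class NoReferenceGeneError(ValueError):
    """No gene has positive counts in every sample."""


class SingularDesignError(ValueError):
    """The model matrix is rank deficient."""


@dataclass(frozen=True)
class DEConfig:
    """Thresholds of the differential-expression workflow.

    min_total_reads: genes with a smaller raw total across all samples are
        dropped before analysis (applied to raw, not normalized, counts).
    lfc_threshold / padj_threshold: the joint DEG rule, both inclusive.
    bias_sd_threshold: leave-one-out SD multiple for the technical-bias
        filter.
    """

    min_total_reads: int = 50
    lfc_threshold: float = 0.3
    padj_threshold: float = 0.1
    bias_sd_threshold: float = 4.0

    def __post_init__(self) -> None:
        for name in ("min_total_reads", "lfc_threshold", "padj_threshold", "bias_sd_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


# ---------------------------------------------------------------------------
# normalization and filtering
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    Reference genes are those with positive counts in every sample; each
    sample's factor is the median ratio of its counts to the gene-wise
    geometric mean over that reference set. Factors are not rescaled
    afterwards.
    """
    x = counts.to_numpy(dtype=float)
    all_positive = (x > 0).all(axis=1)
    if not all_positive.any():
        raise NoReferenceGeneError(
            "no gene with positive counts in all samples; cannot anchor size factors"
        )
    ref = x[all_positive]
    gm = np.exp(np.log(ref).mean(axis=1, keepdims=True))
    factors = np.median(ref / gm, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def low_count_filter(counts: pd.DataFrame, min_total_reads: int = 50) -> pd.DataFrame:
    """Keep genes whose raw total across all samples is >= the threshold."""
    return counts.loc[counts.sum(axis=1) >= min_total_reads]


def nrpkm(
    counts: pd.DataFrame,
    factors: pd.Series,
    gene_lengths_kb: pd.Series,
) -> pd.DataFrame:
    """Normalized reads per kilobase per million total (normalized) reads.

    nRPKM_ij = (count_ij / factor_j) / (length_kb_i * total_norm_j / 1e6).
    """
    lengths = gene_lengths_kb.reindex(counts.index)
    if lengths.isna().any():
        missing = list(counts.index[lengths.isna()][:5])
        raise ValueError(f"missing gene lengths, e.g. {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be strictly positive")
    norm = counts.div(factors, axis=1)
    total_norm = norm.sum(axis=0)
    return norm.div(lengths, axis=0).div(total_norm / 1e6, axis=1)


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------

def estimate_dispersions(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    factors: pd.Series,
    residual_df: int | None = None,
    prior_weight: float = 10.0,
) -> pd.Series:
    """Gene-wise NB dispersions: method-of-moments, shrunk toward a trend.

    Within-cell variances of size-factor-normalized counts are pooled per
    gene; the moment estimator alpha = (var - mu * E[1/s]) / mu^2 is then
    shrunk in log space toward a log-log linear mean-dispersion trend fitted
    across genes, weighting the gene-wise estimate by its residual degrees of
    freedom against a constant prior weight.
    """
    q = counts.div(factors, axis=1).to_numpy()
    groups = design.groupby(["genotype", "age_months", "environment"]).indices
    cols = {s: i for i, s in enumerate(counts.columns)}
    pooled_var = np.zeros(q.shape[0])
    total_df = 0
    for rows in groups.values():
        ii = [cols[design["sample_id"].iloc[r]] for r in rows]
        if len(ii) < 2:
            continue
        sub = q[:, ii]
        pooled_var += sub.var(axis=1, ddof=1) * (len(ii) - 1)
        total_df += len(ii) - 1
    if total_df == 0:
        raise ValueError("need at least one design cell with >= 2 samples")
    pooled_var /= total_df
    mu = q.mean(axis=1)
    mean_inv_sf = float((1.0 / factors).mean())
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_mom = (pooled_var - mu * mean_inv_sf) / np.square(mu)
    alpha_mom = np.clip(np.nan_to_num(alpha_mom, nan=_ALPHA_FLOOR), _ALPHA_FLOOR, _ALPHA_CEIL)

    # log-log trend over informatively estimated genes
    ok = (mu > 0) & (alpha_mom > 1e-6)
    if ok.sum() >= 10:
        lx, ly = np.log(mu[ok]), np.log(alpha_mom[ok])
        slope, intercept = np.polyfit(lx, ly, 1)
        with np.errstate(divide="ignore"):
            alpha_trend = np.exp(intercept + slope * np.log(np.maximum(mu, 1e-8)))
        alpha_trend = np.clip(alpha_trend, _ALPHA_FLOOR, _ALPHA_CEIL)
    else:
        alpha_trend = np.full_like(alpha_mom, np.median(alpha_mom))

    d = float(residual_df if residual_df is not None else total_df)
    w = d / (d + prior_weight)
    alpha = np.exp(w * np.log(alpha_mom) + (1 - w) * np.log(alpha_trend))
    return pd.Series(alpha, index=counts.index, name="dispersion")


# ---------------------------------------------------------------------------
# NB GLM fit and Wald contrasts
# ---------------------------------------------------------------------------

@dataclass
class NBFit:
    """Fitted cell-means NB model for all genes.

    coef: genes x parameters (log scale); cov: per-gene parameter covariance;
    params: parameter names (cell keys first, then batch dummies).
    """

    coef: pd.DataFrame
    cov: np.ndarray
    alpha: pd.Series
    params: list[str]
    cells: list[Cell]
    size_factors: pd.Series
    mean_norm: pd.Series
    design: pd.DataFrame
    zero_in_cell: pd.DataFrame = field(repr=False, default=None)


def _model_matrix(design: pd.DataFrame, batch_covariate: bool):
    cells = sorted(
        {(r.genotype, int(r.age_months), r.environment) for r in design.itertuples()},
        key=cell_key,
    )
    keys = [cell_key(c) for c in cells]
    sample_keys = [
        cell_key((r.genotype, int(r.age_months), r.environment)) for r in design.itertuples()
    ]
    X = np.array([[1.0 if sk == k else 0.0 for k in keys] for sk in sample_keys])
    params = list(keys)
    if batch_covariate:
        batches = sorted(design["batch"].unique())
        for b in batches[1:]:
            X = np.column_stack([X, (design["batch"].to_numpy() == b).astype(float)])
            params.append(f"batch_{b}")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularDesignError("model matrix is rank deficient")
    return X, params, cells, sample_keys


def fit_nb_glm(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    factors: pd.Series | None = None,
    alpha: pd.Series | None = None,
    batch_covariate: bool = False,
    prior_weight: float = 10.0,
    max_iter: int = 60,
    tol: float = 1e-8,
) -> NBFit:
    """Fit the NB GLM (log link, log size-factor offsets) to every gene.

    The IRLS updates are vectorized across genes: all genes share the model
    matrix, each keeps its own dispersion. Linear predictors are clipped to
    avoid overflow for cells with all-zero counts.
    """
    counts = counts[design["sample_id"].to_numpy()]
    if factors is None:
        factors = size_factors(counts)
    factors = factors.reindex(counts.columns)
    X, params, cells, sample_keys = _model_matrix(design, batch_covariate)
    if alpha is None:
        alpha = estimate_dispersions(
            counts, design, factors,
            residual_df=len(design) - len(params), prior_weight=prior_weight,
        )
    alpha_v = alpha.reindex(counts.index).to_numpy()[:, None]

    y = counts.to_numpy(dtype=float)
    offset = np.log(factors.to_numpy(dtype=float))[None, :]
    G, N = y.shape
    P = X.shape[1]

    # initialize cell coefs at log cell means of normalized counts
    q = y / np.exp(offset)
    beta = np.zeros((G, P))
    key_arr = np.array(sample_keys)
    for j, p in enumerate(params):
        if p.startswith("batch_"):
            continue
        mask = key_arr == p
        beta[:, j] = np.log(np.maximum(q[:, mask].mean(axis=1), 1e-8))

    eye = np.eye(P)[None, :, :]
    for _ in range(max_iter):
        eta = np.clip(beta @ X.T + offset, -30.0, 30.0)
        mu = np.exp(eta)
        W = mu / (1.0 + alpha_v * mu)  # IRLS working weights
        z = (eta - offset) + (y - mu) / mu
        XtWX = np.einsum("np,gn,nq->gpq", X, W, X, optimize=True) + 1e-10 * eye
        XtWz = np.einsum("np,gn,gn->gp", X, W, z, optimize=True)
        beta_new = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        delta = np.abs(beta_new - beta).max()
        beta = beta_new
        if delta < tol:
            break

    eta = np.clip(beta @ X.T + offset, -30.0, 30.0)
    mu = np.exp(eta)
    W = mu / (1.0 + alpha_v * mu)
    XtWX = np.einsum("np,gn,nq->gpq", X, W, X, optimize=True) + 1e-10 * eye
    cov = np.linalg.inv(XtWX)

    zero_in_cell = pd.DataFrame(
        {p: (y[:, key_arr == p].sum(axis=1) == 0) for p in params if not p.startswith("batch_")},
        index=counts.index,
    )
    return NBFit(
        coef=pd.DataFrame(beta, index=counts.index, columns=params),
        cov=cov,
        alpha=pd.Series(alpha_v.ravel(), index=counts.index, name="dispersion"),
        params=params,
        cells=cells,
        size_factors=factors,
        mean_norm=pd.Series(q.mean(axis=1), index=counts.index, name="mean_norm"),
        design=design.reset_index(drop=True),
        zero_in_cell=zero_in_cell,
    )


def contrast(fit: NBFit, cell_a: Cell, cell_b: Cell) -> pd.DataFrame:
    """Wald contrast of cell_b versus cell_a (log2FC = (coef_b - coef_a)/ln 2).

    Genes with zero counts in both contrasted cells are reported with
    log2FC = 0 and p = 1. Returns a table with columns log2fc, se, stat,
    pvalue, padj, mean_norm (BH adjustment across all tested genes).
    """
    ka, kb = cell_key(cell_a), cell_key(cell_b)
    for k in (ka, kb):
        if k not in fit.params:
            raise ValueError(f"cell {k} not in fitted model")
    c = np.zeros(len(fit.params))
    c[fit.params.index(kb)] = 1.0
    c[fit.params.index(ka)] = -1.0
    diff = fit.coef.to_numpy() @ c
    var = np.einsum("p,gpq,q->g", c, fit.cov, c)
    se = np.sqrt(np.maximum(var, 0.0))
    lfc = diff / LN2
    se2 = se / LN2
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(se2 > 0, lfc / se2, 0.0)
    pvalue = 2.0 * stats.norm.sf(np.abs(stat))

    both_zero = (fit.zero_in_cell[ka] & fit.zero_in_cell[kb]).to_numpy()
    lfc = np.where(both_zero, 0.0, lfc)
    stat = np.where(both_zero, 0.0, stat)
    pvalue = np.where(both_zero, 1.0, pvalue)

    out = pd.DataFrame(
        {
            "log2fc": lfc,
            "se": se2,
            "stat": stat,
            "pvalue": pvalue,
            "padj": bh_adjust(pvalue),
            "mean_norm": fit.mean_norm.to_numpy(),
        },
        index=fit.coef.index,
    )
    out.index.name = "gene_id"
    return out


def fit_contrast(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    cell_a: Cell,
    cell_b: Cell,
    config: DEConfig = DEConfig(),
    batch_covariate: bool = False,
    fit: NBFit | None = None,
) -> pd.DataFrame:
    """Convenience wrapper: fit the factorial model and test one contrast."""
    for cell in (cell_a, cell_b):
        n = (
            (design["genotype"] == cell[0])
            & (design["age_months"] == cell[1])
            & (design["environment"] == cell[2])
        ).sum()
        if n < 2:
            raise ValueError(f"cell {cell_key(cell)} has fewer than 2 samples")
    if fit is None:
        fit = fit_nb_glm(counts, design, batch_covariate=batch_covariate)
    return contrast(fit, cell_a, cell_b)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d vector of p-values")
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1] with no missing values")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def call_degs(result: pd.DataFrame, config: DEConfig = DEConfig()) -> pd.DataFrame:
    """Apply the joint DEG rule |log2FC| >= threshold and padj <= threshold
    (both inclusive); direction is the fold-change sign."""
    hit = (result["log2fc"].abs() >= config.lfc_threshold) & (
        result["padj"] <= config.padj_threshold
    )
    sub = result.loc[hit]
    return pd.DataFrame(
        {"direction": np.where(sub["log2fc"] > 0, "up", "down")}, index=sub.index
    )


# ---------------------------------------------------------------------------
# technical-bias filter
# ---------------------------------------------------------------------------

def leave_one_out_stats(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column leave-one-out mean and SD (ddof=1) across a genes x samples
    block belonging to one design cell."""
    x = np.asarray(matrix, dtype=float)
    k = x.shape[1]
    if k < 3:
        raise ValueError("need at least 3 samples for leave-one-out statistics")
    s = x.sum(axis=1, keepdims=True)
    ss = np.square(x).sum(axis=1, keepdims=True)
    loo_mean = (s - x) / (k - 1)
    loo_var = (ss - np.square(x) - (k - 1) * np.square(loo_mean)) / (k - 2)
    return loo_mean, np.sqrt(np.clip(loo_var, 0.0, None))


def technical_bias_filter(
    norm_expr: pd.DataFrame,
    design: pd.DataFrame,
    candidate_genes,
    sd_threshold: float = 4.0,
    min_flagged: int = 3,
) -> tuple[set, pd.DataFrame]:
    """Exclude candidate genes with a recurrent sequencing-day deviation.

    A sample is flagged for a gene when its expression deviates from the mean
    of the remaining samples of its design cell by more than ``sd_threshold``
    times their SD. A gene is excluded when some batch accumulates at least
    ``min_flagged`` flagged samples — a deviation pattern attributable to a
    sequencing day rather than to an isolated outlier. Cells with fewer than
    3 samples are skipped with a warning.

    Returns the excluded gene set and the boolean flag matrix.
    """
    candidates = [g for g in candidate_genes if g in norm_expr.index]
    sub = norm_expr.loc[candidates]
    flags = pd.DataFrame(False, index=sub.index, columns=sub.columns)
    cell_of = design.set_index("sample_id")[["genotype", "age_months", "environment"]]
    for _, members in design.groupby(["genotype", "age_months", "environment"]):
        ids = [s for s in members["sample_id"] if s in sub.columns]
        if len(ids) < 3:
            warnings.warn(
                f"design cell with {len(ids)} samples skipped by the bias filter",
                stacklevel=2,
            )
            continue
        block = sub[ids].to_numpy()
        loo_mean, loo_sd = leave_one_out_stats(block)
        dev = np.abs(block - loo_mean)
        flags.loc[:, ids] = (dev > sd_threshold * loo_sd) | ((loo_sd == 0) & (dev > 0))

    batch_of = design.set_index("sample_id")["batch"]
    excluded: set = set()
    flags_arr = flags.to_numpy()
    batches = batch_of.reindex(flags.columns).to_numpy()
    for b in np.unique(batches):
        per_gene = flags_arr[:, batches == b].sum(axis=1)
        excluded.update(flags.index[per_gene >= min_flagged])
    _ = cell_of  # retained for clarity of intent
    return excluded, flags


# ---------------------------------------------------------------------------
# transcript-level composition
# ---------------------------------------------------------------------------

def isoform_shares(
    transcript_abundance: pd.DataFrame,
    transcript_to_gene: pd.Series | dict,
    factors: pd.Series,
) -> pd.DataFrame:
    """Per-sample share of each transcript within its gene.

    Abundances are scaled by the sample size factors; a transcript's share is
    its scaled abundance divided by the scaled total over its gene's
    transcripts. Samples where a gene's total is zero get NaN shares.
    """
    t2g = pd.Series(transcript_to_gene)
    orphans = transcript_abundance.index.difference(t2g.index)
    if len(orphans):
        raise ValueError(f"transcripts without a gene mapping: {list(orphans[:5])}")
    scaled = transcript_abundance.div(factors, axis=1)
    genes = t2g.reindex(transcript_abundance.index)
    totals = scaled.groupby(genes.to_numpy()).transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        shares = scaled / totals
    shares[totals == 0] = np.nan
    shares.insert(0, "gene_id", genes.to_numpy())
    return shares
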