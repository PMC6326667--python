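"""Bulk deconvolution against marker signatures and composition-shift tests.

Per-sample cell-type proportions are estimated by non-negative least squares
of the bulk marker-gene vector on a cell-types x markers signature matrix
(a minimal, assumption-light deconvolution); proportions are normalized to
sum to one. Group differences in composition are assessed with a label
permutation test on per-type mean proportions, BH-adjusted across types.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .expression_core import bh_adjust

__all__ = [
    "CollinearSignatureError",
    "estimate_proportions",
    "composition_shift_test",
]


class CollinearSignatureError(ValueError):
    """The signature matrix is rank deficient; names the collinear types."""


def estimate_proportions(
    bulk_expr: pd.DataFrame,
    signature: pd.DataFrame,
) -> pd.DataFrame:
    """NNLS cell-type proportions per sample.

    ``bulk_expr``: markers x samples; ``signature``: markers x cell types.
    Markers missing from the bulk matrix are dropped with a warning; at least
    as many shared markers as cell types are required. Weights are normalized
    to sum to 1 per sample (all-zero samples fall back to a uniform vector
    with a warning). The estimate is invariant to global rescaling of the
    bulk vector.
    """
    shared = signature.index.intersection(bulk_expr.index)
    dropped = signature.index.difference(bulk_expr.index)
    if len(dropped):
        warnings.warn(f"{len(dropped)} signature markers absent from bulk matrix; dropped",
                      stacklevel=2)
    k = signature.shape[1]
    if len(shared) < k:
        raise ValueError("need at least as many shared markers as cell types")
    S = signature.loc[shared].to_numpy(dtype=float)
    if np.linalg.matrix_rank(S) < k:
        corr = np.corrcoef(S.T)
        pairs = [
            f"{signature.columns[i]}~{signature.columns[j]}"
            for i in range(k)
            for j in range(i + 1, k)
            if abs(corr[i, j]) > 0.999
        ]
        raise CollinearSignatureError(
            "rank-deficient signature matrix; collinear cell types: " + (", ".join(pairs) or "unknown")
        )
    B = bulk_expr.loc[shared].to_numpy(dtype=float)
    props = np.zeros((bulk_expr.shape[1], k))
    for j in range(B.shape[1]):
        w, _ = nnls(S, B[:, j])
        total = w.sum()
        if total <= 0:
            warnings.warn(f"sample {bulk_expr.columns[j]!r} has an all-zero fit; "
                          "reporting uniform proportions", stacklevel=2)
            props[j] = 1.0 / k
        else:
            props[j] = w / total
    return pd.DataFrame(props, index=bulk_expr.columns, columns=signature.columns)


def composition_shift_test(
    estimates_a: pd.DataFrame,
    estimates_b: pd.DataFrame,
    n_permutations: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation test for per-cell-type proportion shifts between groups.

    Statistic: difference of group mean proportions. Two-sided p from
    ``n_permutations`` random label reassignments (with the +1 correction);
    BH adjustment across cell types.
    """
    if len(estimates_a) < 3 or len(estimates_b) < 3:
        raise ValueError("need at least 3 samples per group")
    if n_permutations < 100:
        warnings.warn("fewer than 100 permutations gives a coarse p-value", stacklevel=2)
    cols = estimates_a.columns
    a = estimates_a[cols].to_numpy(dtype=float)
    b = estimates_b[cols].to_numpy(dtype=float)
    na = a.shape[0]
    pooled = np.vstack([a, b])
    obs = a.mean(axis=0) - b.mean(axis=0)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(cols))
    n_total = pooled.shape[0]
    for _ in range(n_permutations):
        perm = rng.permutation(n_total)
        pa = pooled[perm[:na]]
        pb = pooled[perm[na:]]
        exceed += np.abs(pa.mean(axis=0) - pb.mean(axis=0)) >= np.abs(obs) - 1e-12
    pvals = (1.0 + exceed) / (n_permutations + 1.0)
    return pd.DataFrame(
        {
            "cell_type": cols,
            "mean_a": a.mean(axis=0),
            "mean_b": b.mean(axis=0),
            "difference": obs,
            "pvalue": pvals,
            "padj": bh_adjust(pvals),
        }
    )
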