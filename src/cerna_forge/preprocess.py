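"""Background filtering and quantile normalization of intensity matrices.

Arrays from different samples are forced onto one empirical distribution by
quantile normalization: the value assigned to rank k in every sample is the
mean over samples of each sample's k-th order statistic. Ties within a
sample receive the mean of the reference values at their tied ranks, so the
transform is idempotent and preserves within-sample rank order.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .model import ExpressionMatrix


def filter_background(
    matrix: ExpressionMatrix, background_level: float, min_samples: int = 1
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop genes that never rise above the background intensity.

    A gene is kept when its value strictly exceeds ``background_level`` in at
    least ``min_samples`` samples. Returns the filtered matrix and the list
    of removed gene ids (callers log these to ``filtered_genes.txt``).
    """
    n_samples = len(matrix.sample_ids)
    if min_samples > n_samples:
        raise ConfigError(
            f"min_samples={min_samples} exceeds sample count {n_samples}"
        )
    above = (matrix.values.to_numpy() > background_level).sum(axis=1)
    keep_mask = above >= min_samples
    removed = [g for g, keep in zip(matrix.gene_ids, keep_mask) if not keep]
    kept = [g for g, keep in zip(matrix.gene_ids, keep_mask) if keep]
    return matrix.subset_genes(kept), removed


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize so every sample shares one sorted value vector."""
    values = matrix.values
    if values.shape[1] < 2:
        raise DataError("quantile normalization needs at least 2 samples")
    if values.isna().to_numpy().any():
        raise DataError(
            "matrix contains missing values; impute or filter upstream before "
            "quantile normalization"
        )
    arr = values.to_numpy(dtype=float)
    order = np.argsort(arr, axis=0, kind="stable")
    reference = np.sort(arr, axis=0).mean(axis=1)

    out = np.empty_like(arr)
    n = arr.shape[0]
    for j in range(arr.shape[1]):
        col = arr[:, j]
        idx = order[:, j]
        assigned = np.empty(n)
        i = 0
        while i < n:
            # run of tied values in this sample -> mean of their rank-values
            k = i
            while k + 1 < n and col[idx[k + 1]] == col[idx[i]]:
                k += 1
            assigned[idx[i : k + 1]] = reference[i : k + 1].mean()
            i = k + 1
        out[:, j] = assigned

    return ExpressionMatrix(
        values=pd.DataFrame(out, index=values.index, columns=values.columns),
        biotype_of=dict(matrix.biotype_of),
        group_of=dict(matrix.group_of),
        pair_of=dict(matrix.pair_of),
    )
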