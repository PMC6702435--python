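"""Pearson correlation and the mutual rank (MR) coexpression statistic.

For each gene, its partners are ranked by descending correlation (best
partner = rank 1, self excluded).  The mutual rank of a pair is the
geometric mean of the two directed ranks,

    MR(A, B) = sqrt(rank_A(B) * rank_B(A)),

so MR = 1 exactly for reciprocal best partners and low MR means strong,
reciprocal coexpression.  Correlation ties are broken deterministically by
ascending partner gene id so outputs are bit-stable.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

MR_COLUMNS = ["gene_a", "gene_b", "r", "rank_ab", "rank_ba", "mr"]


def correlation_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Gene x gene Pearson correlation over samples.

    Genes with zero variance are excluded with a warning (their
    correlation is undefined).  Requires >= 3 samples and no missing
    values; values are used as given (the compendium is assumed to be
    log-scale and pre-normalised).
    """
    if expr.shape[1] < 3:
        raise ValidationError("correlation_matrix: need >= 3 samples")
    if expr.isna().any().any():
        raise ValidationError("correlation_matrix: missing values are not supported")
    sd = expr.values.std(axis=1)
    constant = sd == 0
    if constant.any():
        dropped = list(expr.index[constant])
        logger.warning("excluding %d constant gene(s): %s", len(dropped), dropped[:10])
        expr = expr.loc[~constant]
    corr = np.corrcoef(expr.values)
    return pd.DataFrame(corr, index=expr.index, columns=expr.index)


def mutual_rank(corr: pd.DataFrame, mr_max: float | None = None) -> pd.DataFrame:
    """Mutual rank table from a correlation matrix.

    Returns one row per unordered gene pair with columns
    ``gene_a, gene_b, r, rank_ab, rank_ba, mr`` (gene_a < gene_b), sorted
    by (mr, gene_a, gene_b).  With ``mr_max`` set, rows with MR above the
    ceiling are dropped.
    """
    n = corr.shape[0]
    if n < 3:
        raise ValidationError("mutual_rank: need >= 3 genes")
    if not corr.index.equals(corr.columns):
        raise ValidationError("mutual_rank: correlation matrix must be square and labeled")

    values = corr.values.copy()
    np.fill_diagonal(values, -np.inf)  # self ranks last, then excluded
    # ranks[i, j] = rank of j among i's partners; ties by ascending gene index
    idx = np.arange(n)
    ranks = np.empty((n, n), dtype=np.int64)
    for i in range(n):
        order = np.lexsort((idx, -values[i]))
        ranks[i, order] = np.arange(1, n + 1)

    mr = np.sqrt(ranks * ranks.T.astype(np.float64))
    iu, ju = np.triu_indices(n, k=1)
    table = pd.DataFrame({
        "gene_a": corr.index[iu],
        "gene_b": corr.index[ju],
        "r": corr.values[iu, ju],
        "rank_ab": ranks[iu, ju],
        "rank_ba": ranks[ju, iu],
        "mr": mr[iu, ju],
    })
    if mr_max is not None:
        table = table[table["mr"] <= mr_max]
    return table.sort_values(["mr", "gene_a", "gene_b"], ignore_index=True)
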