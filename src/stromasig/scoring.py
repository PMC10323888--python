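"""Per-sample gene-set scores and over-representation testing.

Two scoring conventions coexist deliberately:

* ``signature_score`` — mean of row-z-scored expression over the signature
  genes.  Z-scoring absorbs gene-wise location/scale, so the score is
  comparable across signatures within one matrix.
* ``marker_population_score`` — mean of *raw* log expression over a
  population's marker genes (the MCP-counter aggregation rule).  Scores are
  comparable between samples for one population, not across populations.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import ExpressionMatrix, GeneSet
from .sigscreen import bh_adjust

logger = logging.getLogger("stromasig")

__all__ = [
    "zscore_rows",
    "signature_score",
    "marker_population_score",
    "ora_hypergeometric",
]


def zscore_rows(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Center each gene row to mean 0 and scale to unit sample sd (ddof=1).

    Zero-variance rows carry no information on a z scale and are dropped
    with a logged warning; a matrix with no variable row is an error.
    """
    if matrix.n_samples < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    values = matrix.values
    sd = values.std(axis=1, ddof=1)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("zscore_rows: dropping %d zero-variance rows", n_dropped)
    if not keep.any():
        raise ValueError("all rows have zero variance")
    z = (values[keep] - values[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    return ExpressionMatrix(
        pd.DataFrame(z, index=matrix.data.index[keep], columns=matrix.data.columns),
        harmonize=False,
    )


def signature_score(
    matrix: ExpressionMatrix, signature: GeneSet, method: str = "mean_z"
) -> pd.Series:
    """Per-sample signature score: mean of z-scored expression over the
    signature genes present in the matrix (absent genes are logged)."""
    if method != "mean_z":
        raise ValueError(f"unknown method {method!r}")
    present = [g for g in signature.genes_sorted if g in matrix.data.index]
    missing = len(signature) - len(present)
    if not present:
        raise ValueError(
            f"no gene of signature {signature.name!r} present in the matrix"
        )
    if missing:
        logger.info(
            "signature_score(%s): %d of %d genes absent from matrix",
            signature.name,
            missing,
            len(signature),
        )
    z = zscore_rows(matrix.subset_genes(present))
    score = z.data.mean(axis=0)
    score.name = signature.name
    return score


def marker_population_score(
    matrix: ExpressionMatrix, marker_sets: Sequence[GeneSet]
) -> pd.DataFrame:
    """MCP-counter-style abundance scores: per population, the arithmetic
    mean of raw log expression over its marker genes, per sample.

    Returns samples × populations.  A population whose markers are all
    absent is skipped with a warning.
    """
    columns = {}
    for ms in marker_sets:
        present = [g for g in ms.genes_sorted if g in matrix.data.index]
        if not present:
            logger.warning(
                "marker_population_score: all markers of %r absent; skipped", ms.name
            )
            continue
        columns[ms.name] = matrix.data.loc[present].mean(axis=0)
    if not columns:
        raise ValueError("no marker set had any gene present in the matrix")
    return pd.DataFrame(columns)


def ora_hypergeometric(
    query: GeneSet,
    annotations: Iterable[GeneSet],
    universe: GeneSet,
    q_max: float = 0.01,
) -> pd.DataFrame:
    """Over-representation analysis with the upper-tail hypergeometric test.

    For each annotation set, ``p = P(X >= overlap)`` drawing ``query_size``
    genes without replacement from a universe containing ``set_size``
    annotated genes.  Query genes outside the universe are dropped with a
    warning; annotation sets are intersected with the universe.  q is BH
    over annotation sets; rows are flagged ``significant`` at ``q < q_max``.
    """
    if len(universe) == 0:
        raise ValueError("empty universe")
    uni = universe.genes
    query_in = query.genes & uni
    n_out = len(query.genes) - len(query_in)
    if n_out:
        logger.warning(
            "ora_hypergeometric: %d query genes outside the universe dropped", n_out
        )
    M, N = len(uni), len(query_in)
    rows = []
    for ann in annotations:
        ann_in = ann.genes & uni
        k = len(ann_in & query_in)
        K = len(ann_in)
        p = float(stats.hypergeom.sf(k - 1, M, K, N)) if K else 1.0
        rows.append(
            {
                "set_name": ann.name,
                "overlap": k,
                "set_size": K,
                "query_size": N,
                "universe_size": M,
                "p": min(max(p, np.finfo(float).tiny), 1.0),
            }
        )
    out = pd.DataFrame(rows).set_index("set_name")
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    out["significant"] = out["q"] < q_max
    return out
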