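"""Anchor-gene correlation screen and cross-cohort signature intersection.

The derivation is: in each cohort, Pearson-correlate the anchor gene's
expression with every other gene, convert r to a two-sided p-value via the
exact t transform, control the FDR with Benjamini–Hochberg within the cohort,
keep genes passing the per-cohort (r, q) cut-offs, and intersect the
surviving gene lists across cohorts.  The intersection is the signature.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import ExpressionMatrix, GeneSet, SignatureGeneSet, harmonize_gene_id

logger = logging.getLogger("stromasig")

__all__ = [
    "correlate_to_anchor",
    "bh_adjust",
    "select_correlated",
    "intersect_signatures",
]


def correlate_to_anchor(matrix: ExpressionMatrix, anchor: str) -> pd.DataFrame:
    """Pearson-correlate every gene with the anchor gene.

    Returns a DataFrame indexed by gene id with columns

    ``r``       Pearson correlation with the anchor row,
    ``p``       two-sided p-value from ``t = r*sqrt((n-2)/(1-r^2))`` on
                ``n-2`` degrees of freedom,
    ``q``       Benjamini–Hochberg adjusted p over all screened genes,
    ``n_used``  number of samples entering each correlation.

    The anchor itself is excluded.  Genes with zero variance cannot be
    screened and are dropped with a logged count.
    """
    anchor = harmonize_gene_id(anchor)
    if anchor not in matrix.data.index:
        raise ValueError(f"anchor gene {anchor!r} not present in matrix")
    n = matrix.n_samples
    if n < 3:
        raise ValueError("correlation screen needs at least 3 samples")

    a = matrix.data.loc[anchor].to_numpy()
    a_c = a - a.mean()
    a_ss = float(a_c @ a_c)
    if a_ss == 0.0:
        raise ValueError(f"anchor gene {anchor!r} has zero variance")

    others = matrix.data.drop(index=anchor)
    X = others.to_numpy()
    Xc = X - X.mean(axis=1, keepdims=True)
    row_ss = np.einsum("ij,ij->i", Xc, Xc)
    nonconstant = row_ss > 0
    n_dropped = int((~nonconstant).sum())
    if n_dropped:
        logger.info("correlate_to_anchor: dropping %d zero-variance genes", n_dropped)

    Xc = Xc[nonconstant]
    row_ss = row_ss[nonconstant]
    r = (Xc @ a_c) / np.sqrt(row_ss * a_ss)
    r = np.clip(r, -1.0, 1.0)

    df = n - 2
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r * r, np.finfo(float).tiny))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)  # keep p in (0, 1] for BH

    result = pd.DataFrame(
        {"r": r, "p": p, "q": bh_adjust(p), "n_used": n},
        index=others.index[nonconstant],
    )
    result.index.name = "gene_id"
    return result


def bh_adjust(p: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    With sorted p-values ``p(1) <= ... <= p(m)``, ``q(i) = min_{j>=i}
    m*p(j)/j`` capped at 1, mapped back to the input order.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a non-empty 1-d vector")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def select_correlated(
    result: pd.DataFrame,
    r_min: float,
    q_max: float,
    sided: str = "positive",
    name: str = "correlated",
) -> GeneSet:
    """Filter a screen result to the correlated gene set.

    Keeps genes with ``q < q_max`` and ``r > r_min`` (``sided="positive"``,
    the default reading of a one-sided positive cut-off) or ``|r| > r_min``
    (``sided="absolute"``).  Both inequalities are strict.  An empty
    selection is a valid empty set.
    """
    if not (0 <= r_min < 1):
        raise ValueError("r_min must lie in [0, 1)")
    if not (0 < q_max <= 1):
        raise ValueError("q_max must lie in (0, 1]")
    if sided == "positive":
        keep = (result["r"] > r_min) & (result["q"] < q_max)
    elif sided == "absolute":
        keep = (result["r"].abs() > r_min) & (result["q"] < q_max)
    else:
        raise ValueError(f"unknown sided mode {sided!r}")
    genes = frozenset(result.index[keep])
    return GeneSet(name=name, description=f"r>{r_min}, q<{q_max}, {sided}", genes=genes)


def intersect_signatures(sets: Iterable[GeneSet], name: str) -> SignatureGeneSet:
    """Exact intersection of per-cohort selections (identifiers already
    harmonized by :class:`GeneSet`); gene order is deterministic (sorted)."""
    sets = list(sets)
    if len(sets) < 2:
        raise ValueError("need at least two gene sets to intersect")
    genes = frozenset.intersection(*(gs.genes for gs in sets))
    return SignatureGeneSet(
        name=name,
        description=f"intersection of {len(sets)} sets",
        genes=genes,
    )
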