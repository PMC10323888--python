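"""Two-group differential expression and the invasiveness intersection.

``dge`` computes per-gene log2 fold-changes (difference of group means on a
log2-scale matrix) with either an unequal-variance Welch t-test or a
moderated t-test in which gene-wise variances are shrunk toward a common
prior estimated by moment matching on the log sample variances — the
empirical-Bayes behaviour of the standard linear-model moderation used for
microarray DGE.  p-values are BH-adjusted over all tested genes.

The invasiveness signature is the three-way intersection of (i) genes up in
carcinoma vs the pre-invasive lesion, (ii) genes up in carcinoma vs normal
tissue, and (iii) the anchor-correlated signature.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

from .dataio import ExpressionMatrix, GeneSet, SignatureGeneSet
from .sigscreen import bh_adjust

logger = logging.getLogger("stromasig")

__all__ = ["dge", "filter_dge", "derive_invasive_signature"]

_VAR_FLOOR = 1e-8


def dge(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    groups: tuple[str, str] | None = None,
    method: str = "moderated",
) -> pd.DataFrame:
    """Two-group differential expression on a log2-scale matrix.

    Parameters
    ----------
    labels
        Per-sample group labels indexed by sample id (samples with labels
        outside ``groups`` are ignored).
    groups
        ``(A, B)`` contrast; ``log2fc = mean(A) - mean(B)``.  Defaults to the
        two sorted unique labels.
    method
        ``"welch"`` (unequal-variance t) or ``"moderated"`` (empirical-Bayes
        shrinkage of the pooled variance; the default).

    Returns a DataFrame indexed by gene with columns ``log2fc``, ``t``,
    ``p``, ``q``.
    """
    labels = labels.reindex(matrix.sample_ids).dropna()
    if groups is None:
        uniq = sorted(labels.unique())
        if len(uniq) != 2:
            raise ValueError(f"labels must define exactly two groups, got {uniq}")
        groups = (uniq[0], uniq[1])
    group_a, group_b = groups

    a_ids = labels.index[labels == group_a]
    b_ids = labels.index[labels == group_b]
    n_a, n_b = len(a_ids), len(b_ids)
    if n_a < 2 or n_b < 2:
        raise ValueError(
            f"each group needs >=2 samples (got {group_a}:{n_a}, {group_b}:{n_b})"
        )

    A = matrix.data.loc[:, a_ids].to_numpy()
    B = matrix.data.loc[:, b_ids].to_numpy()
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    log2fc = mean_a - mean_b
    var_a = A.var(axis=1, ddof=1)
    var_b = B.var(axis=1, ddof=1)

    if method == "welch":
        se2 = var_a / n_a + var_b / n_b
        zero = se2 < _VAR_FLOOR
        if zero.any():
            logger.info("dge(welch): variance floor applied to %d genes", int(zero.sum()))
            se2 = np.maximum(se2, _VAR_FLOOR)
        t = log2fc / np.sqrt(se2)
        with np.errstate(invalid="ignore", divide="ignore"):
            df = se2**2 / (
                (var_a / n_a) ** 2 / (n_a - 1) + (var_b / n_b) ** 2 / (n_b - 1)
            )
        df = np.where(np.isfinite(df) & (df > 0), df, n_a + n_b - 2)
    elif method == "moderated":
        d = n_a + n_b - 2
        s2 = ((n_a - 1) * var_a + (n_b - 1) * var_b) / d
        zero = s2 < _VAR_FLOOR
        if zero.any():
            logger.info(
                "dge(moderated): variance floor applied to %d genes", int(zero.sum())
            )
            s2 = np.maximum(s2, _VAR_FLOOR)
        d0, s0_sq = _fit_variance_prior(s2, d)
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_sq)
            df = np.full(s2.shape, np.inf)
        else:
            s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
            df = np.full(s2.shape, d0 + d)
        t = log2fc / np.sqrt(s2_post * (1.0 / n_a + 1.0 / n_b))
    else:
        raise ValueError(f"unknown method {method!r}")

    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    out = pd.DataFrame(
        {"log2fc": log2fc, "t": t, "p": p, "q": bh_adjust(p)}, index=matrix.data.index
    )
    out.index.name = "gene_id"
    return out


def _fit_variance_prior(s2: np.ndarray, d: int) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior (d0, s0^2) to the
    observed gene variances via the log-variance mean and spread.

    If sample variances follow ``s0^2 * chi2_d / d`` scaled by gene effects,
    ``e = log(s2) - digamma(d/2) + log(d/2)`` has mean ``log(s0^2) +
    digamma(d0/2) - log(d0/2)`` and excess variance ``trigamma(d0/2)`` above
    ``trigamma(d/2)``; inverting the trigamma recovers d0.  Excess <= 0 means
    no detectable gene-to-gene variance heterogeneity: d0 = inf and all genes
    share s0^2.
    """
    e = np.log(s2) - digamma(d / 2.0) + np.log(d / 2.0)
    e_mean = float(np.mean(e))
    n = e.size
    if n < 2:
        return np.inf, float(np.exp(e_mean))
    excess = float(np.var(e, ddof=1) - polygamma(1, d / 2.0))
    if excess <= 0:
        return np.inf, float(np.exp(e_mean))
    half_d0 = _trigamma_inverse(excess)
    d0 = 2.0 * half_d0
    s0_sq = float(np.exp(e_mean + digamma(half_d0) - np.log(half_d0)))
    return d0, s0_sq


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration on 1/y scale)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(75):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def filter_dge(
    result: pd.DataFrame,
    lfc_min: float = 1.0,
    q_max: float = 0.05,
    direction: str = "up",
    name: str = "dge",
) -> GeneSet:
    """Apply the DGE cut-offs (strict inequalities): ``q < q_max`` and
    ``log2fc > lfc_min`` (up), ``log2fc < -lfc_min`` (down) or
    ``|log2fc| > lfc_min`` (both)."""
    sig = result["q"] < q_max
    if direction == "up":
        keep = sig & (result["log2fc"] > lfc_min)
    elif direction == "down":
        keep = sig & (result["log2fc"] < -lfc_min)
    elif direction == "both":
        keep = sig & (result["log2fc"].abs() > lfc_min)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return GeneSet(
        name=name,
        description=f"|log2FC|>{lfc_min}, q<{q_max}, {direction}",
        genes=frozenset(result.index[keep]),
    )


def derive_invasive_signature(
    up_vs_premalignant: GeneSet,
    up_vs_normal: GeneSet,
    anchor_signature: SignatureGeneSet,
    name: str = "invasive_signature",
) -> SignatureGeneSet:
    """Three-way intersection: genes up in carcinoma versus the pre-invasive
    lesion AND up versus normal tissue AND in the anchor-correlated
    signature.  Deterministic (sorted) gene order."""
    if len(anchor_signature) == 0:
        raise ValueError("anchor signature is empty")
    genes = up_vs_premalignant.genes & up_vs_normal.genes & anchor_signature.genes
    return SignatureGeneSet(
        name=name,
        description="up vs premalignant ∩ up vs normal ∩ anchor signature",
        genes=genes,
    )
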