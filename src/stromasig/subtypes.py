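"""Cross-cohort molecular subtype machinery.

Centroid transfer: per subtype, a one-versus-all differential analysis ranks
genes (ascending p, then descending |t|); the top ``n_top`` genes form the
subtype's signature and its centroid is the mean expression of the subtype's
training samples over those genes.  A new sample is assigned to the subtype
whose centroid its profile correlates with best (Pearson), each centroid
being evaluated on its *own* signature gene space.

Consensus-style clustering: samples are clustered hierarchically (average
linkage) on correlation distance over a supplied gene set, the dendrogram is
cut into k branches, and branches are labeled deterministically by ordering
them on the mean of a supplied per-sample score — a reproducible stand-in
for manual branch annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .dataio import ExpressionMatrix, GeneSet
from .differential import dge

logger = logging.getLogger("stromasig")

__all__ = ["CentroidModel", "build_centroids", "assign_by_centroid", "consensus_cluster"]


@dataclass
class CentroidModel:
    """Per-subtype signature genes (ordered by DE rank) and mean profiles."""

    signatures: dict[str, list[str]]
    centroids: dict[str, pd.Series]
    n_top: int

    @property
    def subtype_names(self) -> list[str]:
        return sorted(self.signatures)


def build_centroids(
    matrix: ExpressionMatrix, labels: pd.Series, n_top: int = 1000
) -> CentroidModel:
    """Build per-subtype centroids from one-versus-all differential analysis.

    For each subtype s, a moderated two-group DGE of s versus all remaining
    samples ranks genes by ascending p (ties: descending |t|, then gene id);
    the top ``n_top`` genes are s's signature and the centroid is the mean
    expression of s's samples over them.
    """
    labels = labels.reindex(matrix.sample_ids)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    subtype_names = sorted(labels.astype(str).unique())
    if len(subtype_names) < 2:
        raise ValueError("need at least two subtypes")
    counts = labels.value_counts()
    small = counts[counts < 3]
    if len(small):
        raise ValueError(f"subtypes with <3 samples: {', '.join(small.index.astype(str))}")
    if n_top > matrix.n_genes:
        logger.warning(
            "build_centroids: n_top=%d exceeds %d genes; capped", n_top, matrix.n_genes
        )
        n_top = matrix.n_genes

    signatures: dict[str, list[str]] = {}
    centroids: dict[str, pd.Series] = {}
    for s in subtype_names:
        ova = pd.Series(
            np.where(labels.astype(str) == s, s, "_rest"), index=labels.index
        )
        res = dge(matrix, ova, groups=(s, "_rest"), method="moderated")
        # ascending p, then descending |t|; sorting the index first makes the
        # stable sort break residual ties by gene id
        ranked = (
            res.assign(abs_t=res["t"].abs())
            .sort_index()
            .sort_values(by=["p", "abs_t"], ascending=[True, False], kind="mergesort")
        )
        top = list(ranked.index[:n_top])
        signatures[s] = top
        centroids[s] = matrix.data.loc[top, labels.astype(str) == s].mean(axis=1)
    return CentroidModel(signatures=signatures, centroids=centroids, n_top=n_top)


def assign_by_centroid(
    matrix: ExpressionMatrix, model: CentroidModel
) -> pd.DataFrame:
    """Assign each sample to the subtype with the highest Pearson correlation
    between the sample's profile (restricted to that subtype's signature
    genes present in the matrix) and the centroid.

    Returns a DataFrame indexed by sample with one correlation column per
    subtype and a ``label`` column; ties go to the lexicographically first
    subtype (flagged in the log), samples with no defined correlation are
    labeled ``"unassigned"``.
    """
    corr_cols: dict[str, pd.Series] = {}
    for s in model.subtype_names:
        genes = [g for g in model.signatures[s] if g in matrix.data.index]
        if len(genes) < 3:
            raise ValueError(
                f"subtype {s!r}: fewer than 3 signature genes present in matrix"
            )
        centroid = model.centroids[s].loc[genes].to_numpy()
        X = matrix.data.loc[genes].to_numpy()  # genes x samples
        c = centroid - centroid.mean()
        c_ss = float(c @ c)
        Xc = X - X.mean(axis=0, keepdims=True)
        ss = np.einsum("ij,ij->j", Xc, Xc)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (c @ Xc) / np.sqrt(ss * c_ss)
        if c_ss == 0:
            r = np.full(matrix.n_samples, np.nan)
        corr_cols[s] = pd.Series(r, index=matrix.data.columns)
    corr = pd.DataFrame(corr_cols)

    def _label(row: pd.Series) -> str:
        if row.isna().all():
            return "unassigned"
        best = row.max()
        winners = sorted(row.index[row == best])
        if len(winners) > 1:
            logger.warning(
                "assign_by_centroid: tie between %s; taking %s",
                winners,
                winners[0],
            )
        return winners[0]

    corr["label"] = corr.apply(_label, axis=1)
    corr.index.name = "sample_id"
    return corr


def consensus_cluster(
    matrix: ExpressionMatrix,
    genes: GeneSet,
    k: int,
    score_for_labeling: pd.Series,
) -> pd.Series:
    """Average-linkage hierarchical clustering on 1 - Pearson(sample, sample)
    over a gene set, cut into k branches.

    Branches are relabeled ``C1..Ck`` in ascending order of the mean of
    ``score_for_labeling`` within the branch, making the labeling
    deterministic.
    """
    if k > matrix.n_samples:
        raise ValueError(f"k={k} exceeds {matrix.n_samples} samples")
    present = [g for g in genes.genes_sorted if g in matrix.data.index]
    if len(present) < 2:
        raise ValueError("need at least 2 of the clustering genes in the matrix")
    X = matrix.data.loc[present].to_numpy().T  # samples x genes
    r = np.corrcoef(X)
    dist = 1.0 - np.clip(r, -1.0, 1.0)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0  # exact symmetry for squareform
    Z = linkage(squareform(dist, checks=False), method="average")
    raw = fcluster(Z, t=k, criterion="maxclust")
    raw = pd.Series(raw, index=matrix.data.columns, name="cluster")

    scores = score_for_labeling.reindex(matrix.sample_ids)
    means = scores.groupby(raw).mean().sort_values(kind="mergesort")
    remap = {old: f"C{i + 1}" for i, old in enumerate(means.index)}
    labels = raw.map(remap)
    labels.name = "cluster"
    return labels
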