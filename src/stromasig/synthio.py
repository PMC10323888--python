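"""Synthetic multi-cohort data with known ground truth.

The generators build datasets carrying exactly the statistical structure the
downstream analysis assumes, so that every derivation step can be tested as a
recovery problem:

* :func:`generate_cohort` — a single-latent-factor model in which one
  unobserved "stromal program" per sample drives both the anchor gene and a
  planted module of correlated genes, and (through a log-linear hazard)
  survival.  Remaining genes are independent noise.
* :func:`generate_multicohort` — several such cohorts sharing the planted
  module, mimicking a discovery + validation cohort design.
* :func:`generate_panin_study` — a three-group (normal / pre-invasive /
  carcinoma) design with planted up-regulated genes for each contrast.
* :func:`generate_cutpoint_study` — a continuous score with a planted hazard
  step at a known quantile, for cutpoint-recovery tests.
* :func:`generate_subtype_cohorts` — cohorts with block-structured subtype
  mean shifts, for centroid-transfer tests.

All generators are deterministic given their seed.  Expression and survival
draw from independent child streams of the root seed, so changing survival
parameters (e.g. the censoring horizon) never perturbs the expression draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dataio import ExpressionMatrix, GeneSet, SurvivalTable

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "generate_cohort",
    "generate_multicohort",
    "generate_panin_study",
    "generate_cutpoint_study",
    "generate_subtype_cohorts",
]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one simulated cohort.

    Defaults emulate a resected-PDAC microarray cohort: n=250 samples,
    5000 genes, a 24-gene correlated module with loadings 0.8 against unit
    noise, a moderate survival effect (log-hazard 0.5 per latent-factor unit),
    baseline hazard ln(2)/20 per month (median OS 20 months at factor 0) and
    uniform censoring over a 5-year follow-up window.
    """

    n_samples: int = 250
    n_genes: int = 5000
    anchor_gene: str = "SALL4"
    module_genes: int = 24
    anchor_loading: float = 0.8
    module_loading: float = 0.8
    noise_sd: float = 1.0
    beta: float = 0.5
    baseline_hazard: float = np.log(2) / 20.0
    censor_max: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 10:
            raise ValueError("n_samples must be >= 10")
        if self.anchor_loading < 0 or self.module_loading < 0:
            raise ValueError("loadings must be non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.censor_max <= 0:
            raise ValueError("censor_max must be positive")
        if self.module_genes + 1 > self.n_genes:
            raise ValueError("module_genes + anchor exceed n_genes")


@dataclass
class GroundTruth:
    """What the generator planted, for recovery scoring."""

    module_genes: GeneSet | None = None
    latent_factor: pd.Series | None = None
    true_beta: float | None = None
    planted_de_genes: GeneSet | None = None
    planted_up_vs_premalignant: GeneSet | None = None
    planted_up_vs_normal: GeneSet | None = None
    planted_cutpoint_quantile: float | None = None
    subtype_labels: pd.Series | None = None


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(s)) for s in np.random.SeedSequence(seed).spawn(n)]


def _module_gene_names(m: int) -> list[str]:
    return [f"MOD{i:04d}" for i in range(1, m + 1)]


def generate_cohort(
    spec: CohortSpec,
    module_gene_ids: Sequence[str] | None = None,
    sample_prefix: str = "S",
) -> tuple[ExpressionMatrix, SurvivalTable, GroundTruth]:
    """Simulate one cohort under the shared-latent-factor model.

    Per sample j a latent factor :math:`f_j \\sim N(0,1)` drives

    * anchor row: ``anchor_loading * f + eps``,
    * each module gene: ``module_loading * f + eps``,
    * background genes: pure noise ``eps``,

    with ``eps ~ N(0, noise_sd^2)`` i.i.d.  Survival time is exponential with
    hazard ``baseline_hazard * exp(beta * f)``, censored at an independent
    Uniform(0, censor_max) time.
    """
    rng_expr, rng_surv, rng_f = _streams(spec.seed, 3)
    n, g, m = spec.n_samples, spec.n_genes, spec.module_genes

    if module_gene_ids is None:
        module_gene_ids = _module_gene_names(m)
    module_gene_ids = [str(x) for x in module_gene_ids]
    if len(module_gene_ids) != m:
        raise ValueError("module_gene_ids length must equal spec.module_genes")

    f = rng_f.standard_normal(n)
    samples = [f"{sample_prefix}{j + 1:04d}" for j in range(n)]

    n_background = g - m - 1
    background_ids = [f"G{i:05d}" for i in range(1, n_background + 1)]
    gene_ids = [spec.anchor_gene, *module_gene_ids, *background_ids]

    values = rng_expr.normal(0.0, spec.noise_sd, size=(g, n))
    values[0] += spec.anchor_loading * f
    if m:
        values[1 : m + 1] += spec.module_loading * f

    expr = ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=samples))

    hazard = spec.baseline_hazard * np.exp(spec.beta * f)
    event_time = rng_surv.exponential(1.0 / hazard)
    censor_time = rng_surv.uniform(0.0, spec.censor_max, size=n)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    surv = SurvivalTable(
        pd.DataFrame({"sample_id": samples, "time": time, "event": event})
    )

    truth = GroundTruth(
        module_genes=GeneSet(name="planted_module", genes=frozenset(module_gene_ids)),
        latent_factor=pd.Series(f, index=samples, name="latent_factor"),
        true_beta=spec.beta,
    )
    return expr, surv, truth


def generate_multicohort(
    specs: Sequence[CohortSpec], shared_module: bool = True
) -> tuple[list[tuple[ExpressionMatrix, SurvivalTable, GroundTruth]], GroundTruth]:
    """Simulate several cohorts, optionally sharing one planted module.

    With ``shared_module`` the same module gene ids are injected into every
    cohort (their intersection is the recovery target); otherwise each cohort
    gets its own disjoint planted set.
    """
    if len(specs) < 2:
        raise ValueError("need at least two cohort specs")
    anchors = {s.anchor_gene for s in specs}
    if len(anchors) != 1:
        raise ValueError(f"inconsistent anchor genes across cohorts: {sorted(anchors)}")

    cohorts = []
    if shared_module:
        m = specs[0].module_genes
        if any(s.module_genes != m for s in specs):
            raise ValueError("shared_module requires equal module_genes in all specs")
        shared_ids = _module_gene_names(m)
        for i, spec in enumerate(specs):
            cohorts.append(
                generate_cohort(spec, module_gene_ids=shared_ids, sample_prefix=f"C{i + 1}_")
            )
        shared_truth = GroundTruth(
            module_genes=GeneSet(name="planted_module", genes=frozenset(shared_ids))
        )
    else:
        offset = 0
        for i, spec in enumerate(specs):
            ids = [f"MOD{offset + j:04d}" for j in range(1, spec.module_genes + 1)]
            offset += spec.module_genes
            cohorts.append(
                generate_cohort(spec, module_gene_ids=ids, sample_prefix=f"C{i + 1}_")
            )
        shared_truth = GroundTruth()  # no shared module to recover
    return cohorts, shared_truth


def generate_panin_study(
    n_per_group: int = 10,
    n_genes: int = 2000,
    n_up_pdac_vs_panin: int = 40,
    n_up_pdac_vs_normal: int = 40,
    n_shared_up: int = 10,
    effect_log2fc: float = 2.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.Series, GroundTruth]:
    """Three-group carcinogenesis design: normal, PanIN (pre-invasive), PDAC.

    ``n_shared_up`` genes are shifted up by ``effect_log2fc`` in PDAC relative
    to *both* other groups, so they appear in both contrast lists and the
    intersection is non-empty by construction.  Genes up only versus PanIN are
    also elevated in normal tissue (so the PDAC-vs-normal contrast is null for
    them), and vice versa.

    Returns the expression matrix, a per-sample group label Series and the
    ground truth (per-contrast planted sets; ``planted_de_genes`` holds the
    shared overlap).
    """
    if n_shared_up > min(n_up_pdac_vs_panin, n_up_pdac_vs_normal):
        raise ValueError("n_shared_up exceeds a contrast's planted count")
    n_planted = n_up_pdac_vs_panin + n_up_pdac_vs_normal - n_shared_up
    if n_planted > n_genes:
        raise ValueError("planted counts exceed n_genes")

    rng, = _streams(seed, 1)
    groups = ["normal"] * n_per_group + ["PanIN"] * n_per_group + ["PDAC"] * n_per_group
    samples = [f"{g}_{i + 1:03d}" for g, i in zip(groups, list(range(n_per_group)) * 3)]
    labels = pd.Series(groups, index=samples, name="group")

    gene_ids = [f"G{i:05d}" for i in range(1, n_genes + 1)]
    shared = gene_ids[:n_shared_up]
    only_vs_panin = gene_ids[n_shared_up:n_up_pdac_vs_panin]
    only_vs_normal = gene_ids[
        n_up_pdac_vs_panin : n_up_pdac_vs_panin + n_up_pdac_vs_normal - n_shared_up
    ]

    values = rng.normal(0.0, noise_sd, size=(n_genes, 3 * n_per_group))
    df = pd.DataFrame(values, index=gene_ids, columns=samples)
    is_pdac = (labels == "PDAC").to_numpy()
    is_normal = (labels == "normal").to_numpy()
    is_panin = (labels == "PanIN").to_numpy()

    for g in shared:
        df.loc[g, is_pdac] += effect_log2fc
    for g in only_vs_panin:  # up in PDAC and normal, low only in PanIN
        df.loc[g, is_pdac | is_normal] += effect_log2fc
    for g in only_vs_normal:  # up in PDAC and PanIN, low only in normal
        df.loc[g, is_pdac | is_panin] += effect_log2fc

    truth = GroundTruth(
        planted_de_genes=GeneSet(name="planted_shared_up", genes=frozenset(shared)),
        planted_up_vs_premalignant=GeneSet(
            name="planted_up_vs_panin", genes=frozenset(shared + only_vs_panin)
        ),
        planted_up_vs_normal=GeneSet(
            name="planted_up_vs_normal", genes=frozenset(shared + only_vs_normal)
        ),
    )
    return ExpressionMatrix(df), labels, truth


def generate_cutpoint_study(
    n: int = 250,
    hazard_ratio: float = 2.5,
    cut_quantile: float = 0.5,
    baseline_hazard: float = np.log(2) / 20.0,
    censor_max: float = 60.0,
    seed: int = 0,
) -> tuple[pd.Series, SurvivalTable, GroundTruth]:
    """Continuous score with a planted hazard step.

    Scores are standard normal; samples whose score exceeds the empirical
    ``cut_quantile`` carry ``hazard_ratio`` times the baseline hazard.  With
    ``hazard_ratio == 1`` the score is independent of survival (a null
    dataset for calibration checks).
    """
    rng_score, rng_surv = _streams(seed, 2)
    samples = [f"S{j + 1:04d}" for j in range(n)]
    score = pd.Series(rng_score.standard_normal(n), index=samples, name="score")
    threshold = float(np.quantile(score, cut_quantile))
    high = (score > threshold).to_numpy()
    hazard = baseline_hazard * np.where(high, hazard_ratio, 1.0)
    event_time = rng_surv.exponential(1.0 / hazard)
    censor_time = rng_surv.uniform(0.0, censor_max, size=n)
    surv = SurvivalTable(
        pd.DataFrame(
            {
                "sample_id": samples,
                "time": np.minimum(event_time, censor_time),
                "event": (event_time <= censor_time).astype(int),
            }
        )
    )
    truth = GroundTruth(planted_cutpoint_quantile=cut_quantile)
    return score, surv, truth


def generate_subtype_cohorts(
    n_cohorts: int = 2,
    n_per_subtype: int = 40,
    n_genes: int = 1000,
    n_subtypes: int = 3,
    block_size: int = 30,
    effect: float = 1.5,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> list[tuple[ExpressionMatrix, pd.Series]]:
    """Cohorts sharing a block-structured subtype signal.

    Each subtype imprints a *signed pattern* (random ±``effect``, in units of
    the noise sd) on its own disjoint block of ``block_size`` genes, so the
    subtype mean profiles differ in shape, not merely in level — the
    structure a correlation-based centroid classifier actually uses.  All
    cohorts share the same patterns but draw independent noise, so a
    centroid model built on one cohort should transfer to the others.
    """
    if n_subtypes * block_size > n_genes:
        raise ValueError("subtype blocks exceed n_genes")
    pattern_rng, *streams = _streams(seed, n_cohorts + 1)
    # pattern shared across cohorts; independent of every cohort's noise
    signs = pattern_rng.choice([-1.0, 1.0], size=(n_subtypes, block_size))
    gene_ids = [f"G{i:05d}" for i in range(1, n_genes + 1)]
    subtype_names = [f"ST{k + 1}" for k in range(n_subtypes)]
    out = []
    for c, rng in enumerate(streams):
        n = n_per_subtype * n_subtypes
        labels = np.repeat(subtype_names, n_per_subtype)
        samples = [f"C{c + 1}_{j + 1:04d}" for j in range(n)]
        values = rng.normal(0.0, noise_sd, size=(n_genes, n))
        for k in range(n_subtypes):
            rows = slice(k * block_size, (k + 1) * block_size)
            cols = labels == subtype_names[k]
            values[rows][:, cols] += effect * noise_sd * signs[k][:, None]
        df = pd.DataFrame(values, index=gene_ids, columns=samples)
        out.append((ExpressionMatrix(df), pd.Series(labels, index=samples, name="subtype")))
    return out
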