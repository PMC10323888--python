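"""End-to-end orchestration: simulate (or load) cohorts, screen, intersect,
score, stratify, and model survival — from a single validated config.

Every stage writes its artifact to the output directory and registers it in
``manifest.json`` with a SHA-256 checksum; rerunning the same config and
seed reproduces the deterministic artifacts bit for bit.  Stage seeds are
fanned out from the root seed and recorded in the manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .dataio import (
    ExpressionMatrix,
    SurvivalTable,
    read_expression,
    read_survival,
    write_expression,
    write_gmt,
    write_survival,
)
from .scoring import signature_score
from .sigscreen import correlate_to_anchor, intersect_signatures, select_correlated
from .survcut import categorize_by_quantile, cox_fit, km_estimate, logrank_test, maxstat_cutpoint
from .synthio import CohortSpec, generate_multicohort

logger = logging.getLogger("stromasig")

__all__ = ["PipelineConfig", "run_pipeline"]

_COHORT_SIM_KEYS = {
    "n_samples",
    "n_genes",
    "module_genes",
    "anchor_loading",
    "module_loading",
    "noise_sd",
    "beta",
    "baseline_hazard",
    "censor_max",
}
_COHORT_PATH_KEYS = {"expression", "survival", "name"}


@dataclasses.dataclass
class PipelineConfig:
    """Validated pipeline configuration (unknown keys are rejected)."""

    cohorts: list[dict]
    anchor_gene: str = "SALL4"
    r_min: list[float] | float = 0.4
    q_max: float = 0.05
    signature_name: str = "anchor_signature"
    quantile: float = 2.0 / 3.0
    minprop: float = 0.1
    n_perm: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.cohorts) < 2:
            raise ValueError("pipeline needs at least two cohorts")
        if isinstance(self.r_min, (int, float)):
            self.r_min = [float(self.r_min)] * len(self.cohorts)
        if len(self.r_min) != len(self.cohorts):
            raise ValueError("r_min must be scalar or one value per cohort")
        for i, entry in enumerate(self.cohorts):
            keys = set(entry)
            if "expression" in keys:
                unknown = keys - _COHORT_PATH_KEYS
            else:
                unknown = keys - _COHORT_SIM_KEYS
            if unknown:
                raise ValueError(f"cohort {i}: unknown keys {sorted(unknown)}")

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw or {})


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seed(root: int, stage: int) -> int:
    return int(np.random.SeedSequence([root, stage]).generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the full pipeline and return the output manifest.

    Stages: obtain cohorts (simulate or load) → per-cohort anchor
    correlation screen → per-cohort selection → cross-cohort intersection →
    per-sample signature scoring → maxstat and upper-quantile
    stratification of the first cohort → Kaplan–Meier/log-rank comparison →
    Cox modelling of the dichotomized signature.  An empty intersection is a
    clean terminal state ("empty_signature"), not an error.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config": dataclasses.asdict(config),
        "seeds": {},
        "outputs": {},
        "status": "ok",
    }

    def register(name: str, path: Path) -> None:
        manifest["outputs"][name] = {
            "path": str(path.relative_to(outdir)),
            "sha256": _sha256(path),
        }

    # -- stage 1: cohorts ---------------------------------------------------
    sim_entries = [c for c in config.cohorts if "expression" not in c]
    cohorts: list[tuple[str, ExpressionMatrix, SurvivalTable]] = []
    if sim_entries and len(sim_entries) != len(config.cohorts):
        raise ValueError("mixing simulated and file-based cohorts is not supported")
    if sim_entries:
        sim_seed = _stage_seed(config.seed, 1)
        manifest["seeds"]["simulate"] = sim_seed
        specs = [
            CohortSpec(
                anchor_gene=config.anchor_gene,
                seed=_stage_seed(sim_seed, i),
                **entry,
            )
            for i, entry in enumerate(config.cohorts)
        ]
        generated, _truth = generate_multicohort(specs, shared_module=True)
        for i, (expr, surv, _t) in enumerate(generated):
            name = f"cohort{i + 1}"
            cohorts.append((name, expr, surv))
            expr_path = outdir / f"{name}_expression.tsv"
            surv_path = outdir / f"{name}_survival.csv"
            write_expression(expr, expr_path)
            write_survival(surv, surv_path)
            register(f"{name}_expression", expr_path)
            register(f"{name}_survival", surv_path)
    else:
        for i, entry in enumerate(config.cohorts):
            name = entry.get("name", f"cohort{i + 1}")
            expr = read_expression(entry["expression"])
            surv = read_survival(entry["survival"])
            cohorts.append((name, expr, surv))

    # -- stage 2-3: screen and select per cohort ----------------------------
    selections = []
    for (name, expr, _surv), r_min in zip(cohorts, config.r_min):
        screen = correlate_to_anchor(expr, config.anchor_gene)
        screen_path = outdir / f"{name}_screen.tsv"
        screen.to_csv(screen_path, sep="\t", float_format="%.10g")
        register(f"{name}_screen", screen_path)
        selections.append(
            select_correlated(screen, r_min=r_min, q_max=config.q_max, name=f"{name}_selected")
        )

    # -- stage 4: intersection ----------------------------------------------
    signature = intersect_signatures(selections, name=config.signature_name)
    sig_path = outdir / "signature.gmt"
    if len(signature) == 0:
        sig_path.write_text("")  # empty GMT: zero sets
        register("signature", sig_path)
        manifest["status"] = "empty_signature"
        _write_manifest(manifest, outdir)
        logger.warning("run_pipeline: empty signature; stopping after intersection")
        return manifest
    write_gmt([signature], sig_path)
    register("signature", sig_path)

    # -- stage 5: scoring ----------------------------------------------------
    scores_by_cohort = {}
    for name, expr, _surv in cohorts:
        score = signature_score(expr, signature)
        scores_by_cohort[name] = score
        score_path = outdir / f"{name}_scores.tsv"
        score.rename("score").to_csv(score_path, sep="\t", float_format="%.10g")
        register(f"{name}_scores", score_path)

    # -- stage 6: stratification of the first cohort -------------------------
    name0, _expr0, surv0 = cohorts[0]
    score0 = scores_by_cohort[name0]
    maxstat_seed = _stage_seed(config.seed, 6)
    manifest["seeds"]["maxstat"] = maxstat_seed
    cut = maxstat_cutpoint(
        score0, surv0, minprop=config.minprop, n_perm=config.n_perm, seed=maxstat_seed
    )
    tert_labels, tert_threshold = categorize_by_quantile(score0, q=config.quantile)
    cut_json = {
        "cohort": name0,
        "maxstat_cutpoint": cut.cutpoint,
        "max_stat": cut.max_stat,
        "p_perm": cut.p_perm,
        "n_candidates": cut.n_candidates,
        "quantile_threshold": tert_threshold,
        "quantile": config.quantile,
    }
    cut_path = outdir / "cutpoint.json"
    cut_path.write_text(json.dumps(cut_json, indent=2))
    register("cutpoint", cut_path)
    labels_path = outdir / "group_labels.csv"
    pd.DataFrame(
        {"maxstat_group": cut.groups, "quantile_group": tert_labels}
    ).rename_axis("sample_id").to_csv(labels_path)
    register("group_labels", labels_path)

    # -- stage 7: KM + log-rank ----------------------------------------------
    km_rows = []
    for group in ("low", "high"):
        ids = cut.groups.index[cut.groups == group]
        curve = km_estimate(surv0.subset(list(ids)))
        km_rows.append(
            {
                "group": group,
                "n": len(ids),
                "events": int(surv0.subset(list(ids)).event.sum()),
                "median_os_months": curve.median,
                "median_ci_lower": curve.median_ci[0],
                "median_ci_upper": curve.median_ci[1],
            }
        )
    lr = logrank_test(surv0, cut.groups)
    km_path = outdir / "km_summary.tsv"
    pd.DataFrame(km_rows).to_csv(km_path, sep="\t", index=False, float_format="%.6g")
    register("km_summary", km_path)
    lr_path = outdir / "logrank.json"
    lr_path.write_text(
        json.dumps({"chi2": lr.chi2, "p": lr.p, "U": lr.U, "V": lr.V}, indent=2)
    )
    register("logrank", lr_path)

    # -- stage 8: Cox ---------------------------------------------------------
    covars = pd.DataFrame(
        {"signature_high": (cut.groups == "high").astype(float)}
    )
    extra = surv0.covariates
    if extra.shape[1]:
        covars = pd.concat([covars, extra], axis=1)
    cox = cox_fit(surv0, covariates=covars, mode="multivariable")
    cox_path = outdir / "cox_summary.csv"
    cox.summary.to_csv(cox_path, float_format="%.6g")
    register("cox_summary", cox_path)

    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
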