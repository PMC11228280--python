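"""Deterministic orchestration of the full subtyping + biomarker pipeline.

Each stochastic stage (training, GMM initialisation, train/valid split,
forest fitting) consumes its own child seed fanned out from the run seed via
``numpy.random.SeedSequence``, so stages are individually reproducible and
changing one stage's behaviour cannot silently reseed another.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .biomarker import (
    biomarker_report,
    finalize,
    fit_rf,
    gini_importance,
    omics_contribution,
    region_contribution,
    select_candidates,
    split_train_valid,
    summarize_significant,
    validate_candidates,
)
from .io import (
    MultiOmicsDataset,
    build_combined,
    combined_feature_ids,
    preprocess_dataset,
)
from .model import ModelConfig, NetworkWeights, TrainReport, encode_dataset, train
from .subtype import SubtypeAssignment, assign_subtypes, gmm_fit, pca_project
from .survival import logrank_test, neg_log10_p

log = logging.getLogger("omicsmix")

STAGES = ("train", "gmm", "split", "forest")


def stage_seeds(run_seed: int) -> dict[str, int]:
    """Deterministic per-stage child seeds (each below 2**31)."""
    children = np.random.SeedSequence(run_seed).spawn(len(STAGES))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(STAGES, children)
    }


@dataclass
class PipelineResult:
    latent: np.ndarray
    assignment: SubtypeAssignment
    logrank_chi2: float
    logrank_p: float
    report: TrainReport
    weights: NetworkWeights
    candidates: list = field(default_factory=list)
    significant: list = field(default_factory=list)
    contributions_omics: dict[str, float] = field(default_factory=dict)
    contributions_regions: dict[str, dict[str, float]] = field(default_factory=dict)
    projection: np.ndarray | None = None


def run_pipeline(
    dataset: MultiOmicsDataset,
    K: int,
    model_config: ModelConfig | None = None,
    seed: int = 0,
    n_candidates: int = 50,
    alpha: float = 0.05,
    split_ratio: float = 0.6,
    preprocess: bool = True,
    variance_threshold: float = 0.2,
    n_restarts: int = 3,
) -> PipelineResult:
    """Preprocess -> train -> encode -> cluster -> log-rank -> biomarkers.

    Training is restarted ``n_restarts`` times from different seeds and the
    restart whose latent attains the highest Gaussian-mixture log-likelihood
    is kept: adversarial training is run-to-run variable, and the mixture
    likelihood is an unsupervised measure of how well the latent space is
    organised into K Gaussian clusters.
    """
    seeds = stage_seeds(seed)
    if preprocess:
        dataset = preprocess_dataset(dataset, variance_threshold)

    cfg = model_config if model_config is not None else ModelConfig()
    best = None
    for r in range(max(n_restarts, 1)):
        cfg.seed = (seeds["train"] + r) % (2**31)
        weights_r, report_r = train(dataset, cfg)
        latent_r = encode_dataset(weights_r, dataset)
        params_r = gmm_fit(latent_r, K, seed=seeds["gmm"])
        ll = params_r.log_likelihood_trace[-1]
        log.info("restart %d: GMM log-likelihood %.1f", r, ll)
        if best is None or ll > best[0]:
            best = (ll, weights_r, report_r, latent_r, params_r)
    _, weights, report, latent, params = best
    assignment = assign_subtypes(params, latent)

    clin = dataset.clinical
    lr = logrank_test(clin.survival_time, clin.event, assignment.labels)
    log.info(
        "subtype log-rank: chi2=%.4f df=%d p=%.3g (-log10 p=%.3f)",
        lr.chi2, lr.df, lr.p_value, neg_log10_p(max(lr.p_value, 1e-300)),
    )

    # biomarker discovery on the preprocessed combined matrix
    combined, _ = build_combined(dataset)
    feature_ids = combined_feature_ids(dataset)
    ann = dataset.annotation_map()
    train_idx, valid_idx = split_train_valid(
        dataset.n_samples, assignment.labels, ratio=split_ratio, seed=seeds["split"]
    )
    forest = fit_rf(
        combined[train_idx],
        assignment.labels[train_idx],
        feature_ids,
        seed=seeds["forest"],
    )
    ranking = gini_importance(forest)
    candidates = select_candidates(ranking, ann, k=n_candidates)
    validate_candidates(
        candidates,
        combined[valid_idx],
        feature_ids,
        clin.survival_time[valid_idx],
        clin.event[valid_idx],
    )
    significant = finalize(candidates, alpha=alpha)

    contributions_regions = {
        name: region_contribution(ranking, ann, name)
        for name in ("Mut", "CNA")
        if any(a.omics_name == name for a in ann.values())
    }
    return PipelineResult(
        latent=latent,
        assignment=assignment,
        logrank_chi2=lr.chi2,
        logrank_p=lr.p_value,
        report=report,
        weights=weights,
        candidates=candidates,
        significant=significant,
        contributions_omics=omics_contribution(ranking, ann),
        contributions_regions=contributions_regions,
        projection=pca_project(latent, d=min(2, latent.shape[1])),
    )


# ---------------------------------------------------------------------------
# on-disk outputs


def write_outputs(result: PipelineResult, dataset: MultiOmicsDataset, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    samples = dataset.sample_ids

    pd.DataFrame({"sample_id": samples, "subtype": result.assignment.labels}).to_csv(
        outdir / "subtypes.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        result.latent, index=pd.Index(samples, name="sample_id")
    ).to_csv(outdir / "latent.tsv", sep="\t", float_format="%.10g")
    biomarker_report(result.candidates).to_csv(
        outdir / "biomarkers.tsv", sep="\t", index=False, float_format="%.10g"
    )
    pd.DataFrame(
        sorted(result.contributions_omics.items()), columns=["omics", "fraction"]
    ).to_csv(outdir / "contributions_omics.tsv", sep="\t", index=False, float_format="%.10g")
    rows = [
        {"omics": omics, "region": region, "fraction": frac}
        for omics, regions in result.contributions_regions.items()
        for region, frac in regions.items()
    ]
    pd.DataFrame(rows).to_csv(
        outdir / "contributions_regions.tsv", sep="\t", index=False, float_format="%.10g"
    )
    pd.DataFrame(
        {
            "chi2": [result.logrank_chi2],
            "p_value": [result.logrank_p],
            "neg_log10_p": [neg_log10_p(max(result.logrank_p, 1e-300))],
        }
    ).to_csv(outdir / "logrank.tsv", sep="\t", index=False, float_format="%.10g")
    result.report.to_frame().to_csv(
        outdir / "train_report.tsv", sep="\t", index=False, float_format="%.10g"
    )


def write_manifest(outdir, seed: int, config: dict, inputs: dict[str, str]) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    manifest = {
        "package": "omicsmix",
        "version": __version__,
        "seed": seed,
        "stage_seeds": stage_seeds(seed),
        "config_hash": hashlib.sha256(payload).hexdigest(),
        "config": config,
        "inputs": inputs,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
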