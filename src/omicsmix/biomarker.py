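"""Genome-wide biomarker discovery from subtype labels.

Pipeline: stratified 6:4 train/validation split, random-forest fit of omics
features against subtype labels (100 trees, depth 10, sqrt(n_features)
candidates per split), Gini-importance ranking, top-50 candidate selection,
and median-split log-rank validation of each candidate on the held-out
samples (p < 0.05 keeps a candidate). Importance mass is also aggregated into
per-omics and per-region contribution fractions; splice-site (SS) mass is
folded into CDS for region reporting, and Enhancer features — which cannot be
mapped to genes — are excluded from gene-level reporting but retained in
region contributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .io import FeatureAnnotation
from .survival import logrank_test

REGION_REPORT_ORDER = ("CDS", "PromCore", "UTR5", "UTR3", "Enhancer", "ncRNA")


@dataclass
class ForestModel:
    estimator: RandomForestClassifier
    feature_ids: list[str]
    n_trees: int
    max_depth: int
    seed: int


@dataclass
class GiniRanking:
    feature_ids: list[str]
    scores: np.ndarray  # normalised to sum 1
    order: np.ndarray   # indices by descending score, ties by feature id

    def top(self, k: int) -> list[tuple[str, float]]:
        return [(self.feature_ids[i], float(self.scores[i])) for i in self.order[:k]]


@dataclass
class CandidateBiomarker:
    feature_id: str
    omics_name: str
    region: str
    gini_score: float
    gene_symbol: str | None = None
    p_value: float | None = None
    status: str = "candidate"  # candidate | significant | rejected


def split_train_valid(
    n_samples: int, labels: np.ndarray, ratio: float = 0.6, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified split: each subtype contributes ~ratio of its members to train."""
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie strictly between 0 and 1")
    labels = np.asarray(labels)
    if labels.shape[0] != n_samples:
        raise ValueError("labels must align with samples")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    valid_idx: list[int] = []
    for k in np.unique(labels):
        members = np.flatnonzero(labels == k)
        if members.size < 2:
            warnings.warn(
                f"subtype {k} has {members.size} member(s); assigned wholly to train",
                stacklevel=2,
            )
            train_idx.extend(members)
            continue
        perm = rng.permutation(members)
        n_train = int(round(ratio * members.size))
        n_train = min(max(n_train, 1), members.size - 1)
        train_idx.extend(perm[:n_train])
        valid_idx.extend(perm[n_train:])
    if not valid_idx:
        raise ValueError("validation set is empty; lower the ratio or add samples")
    return np.sort(np.array(train_idx)), np.sort(np.array(valid_idx))


def gini_impurity(class_counts) -> float:
    """1 - sum_k (count_k / total)^2 over the node's class proportions."""
    counts = np.asarray(class_counts, float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    total = counts.sum()
    if total == 0:
        raise ValueError("all-zero class counts")
    p = counts / total
    return float(1.0 - np.sum(p**2))


def fit_rf(
    features: np.ndarray,
    labels: np.ndarray,
    feature_ids: list[str],
    n_trees: int = 100,
    max_depth: int = 10,
    seed: int = 0,
    max_features: str | int | float | None = "sqrt",
) -> ForestModel:
    """Random forest of Gini-split trees on bootstrap resamples.

    sqrt(n_features) candidate features per split, the standard
    classification default (configurable via ``max_features``).
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("need at least two classes to fit the forest")
    est = RandomForestClassifier(
        n_estimators=n_trees,
        max_depth=max_depth,
        max_features=max_features,
        criterion="gini",
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    est.fit(features, labels)
    return ForestModel(est, list(feature_ids), n_trees, max_depth, seed)


def gini_importance(forest: ForestModel) -> GiniRanking:
    """Mean decrease in Gini impurity per feature, normalised to sum 1.

    Per tree: for every internal node splitting on feature f, accumulate
    (weighted parent impurity - weighted child impurities), weights being the
    node's sample fraction; tree totals are normalised then averaged.
    """
    scores = forest.estimator.feature_importances_.astype(float)
    total = scores.sum()
    if total > 0:
        scores = scores / total
    order = np.lexsort((forest.feature_ids, -scores))
    return GiniRanking(list(forest.feature_ids), scores, order)


def tree_impurity_importances(tree) -> np.ndarray:
    """Exhaustive per-node impurity-decrease accounting for one fitted tree.

    Independent of the estimator's own importance computation; used as the
    accounting oracle for :func:`gini_importance`.
    """
    t = tree.tree_
    imp = np.zeros(t.n_features)
    total_weight = t.weighted_n_node_samples[0]
    for node in range(t.node_count):
        left, right = t.children_left[node], t.children_right[node]
        if left == -1:  # leaf
            continue
        w = t.weighted_n_node_samples
        decrease = (
            w[node] * t.impurity[node]
            - w[left] * t.impurity[left]
            - w[right] * t.impurity[right]
        ) / total_weight
        imp[t.feature[node]] += decrease
    s = imp.sum()
    return imp / s if s > 0 else imp


def select_candidates(
    ranking: GiniRanking,
    annotations: dict[str, FeatureAnnotation],
    k: int = 50,
) -> list[CandidateBiomarker]:
    """Top-k features by Gini importance, annotated with omics and region."""
    if len(ranking.feature_ids) < k:
        warnings.warn(
            f"only {len(ranking.feature_ids)} features available; selecting all",
            stacklevel=2,
        )
    out = []
    for fid, score in ranking.top(k):
        try:
            ann = annotations[fid]
        except KeyError:
            raise KeyError(f"feature {fid!r} has no annotation") from None
        out.append(
            CandidateBiomarker(
                feature_id=fid,
                omics_name=ann.omics_name,
                region=ann.region,
                gini_score=score,
                gene_symbol=ann.gene_symbol,
            )
        )
    return out


def median_split_validate(
    values: np.ndarray, times: np.ndarray, events: np.ndarray
) -> tuple[float, bool]:
    """Two-group log-rank p for {value > median} vs {value <= median}.

    Computed on validation samples only. Returns (p, degenerate); a split
    leaving one side empty (e.g. a constant or heavily zero-inflated feature)
    yields p = 1 and degenerate = True.
    """
    values = np.asarray(values, float)
    median = np.median(values)
    high = values > median  # ties at the median go to the low group
    if high.all() or not high.any():
        return 1.0, True
    res = logrank_test(times, events, high.astype(int))
    return res.p_value, False


def validate_candidates(
    candidates: list[CandidateBiomarker],
    valid_features: np.ndarray,
    feature_ids: list[str],
    valid_times: np.ndarray,
    valid_events: np.ndarray,
) -> list[CandidateBiomarker]:
    col = {f: j for j, f in enumerate(feature_ids)}
    for cand in candidates:
        p, degenerate = median_split_validate(
            valid_features[:, col[cand.feature_id]], valid_times, valid_events
        )
        cand.p_value = p
        cand.status = "rejected" if degenerate else "candidate"
    return candidates


def finalize(
    candidates: list[CandidateBiomarker], alpha: float = 0.05, bh_correct: bool = False
) -> list[CandidateBiomarker]:
    """Keep candidates with validation p < alpha (strict).

    ``bh_correct`` optionally applies a Benjamini-Hochberg step-up across the
    candidate set before thresholding; off by default.
    """
    ps = np.array([c.p_value if c.p_value is not None else 1.0 for c in candidates])
    if bh_correct and len(ps):
        m = len(ps)
        order = np.argsort(ps)
        adj = np.empty(m)
        running = 1.0
        for rank_pos in range(m - 1, -1, -1):
            i = order[rank_pos]
            running = min(running, ps[i] * m / (rank_pos + 1))
            adj[i] = running
        ps = adj
    significant = []
    for cand, p in zip(candidates, ps):
        if cand.status != "rejected" and p < alpha:
            cand.status = "significant"
            significant.append(cand)
        elif cand.status != "rejected":
            cand.status = "rejected"
    return significant


def summarize_significant(significant: list[CandidateBiomarker]) -> dict[str, dict[str, int]]:
    by_omics: dict[str, int] = {}
    coding = 0
    for c in significant:
        by_omics[c.omics_name] = by_omics.get(c.omics_name, 0) + 1
        if c.region in ("CDS", "SS"):
            coding += 1
    return {
        "by_omics": by_omics,
        "by_coding": {"coding": coding, "non_coding": len(significant) - coding},
    }


def omics_contribution(
    ranking: GiniRanking, annotations: dict[str, FeatureAnnotation]
) -> dict[str, float]:
    """Fraction of total Gini importance carried by each omics layer."""
    frac: dict[str, float] = {}
    for fid, score in zip(ranking.feature_ids, ranking.scores):
        if fid not in annotations:
            raise KeyError(f"feature {fid!r} has no omics annotation")
        name = annotations[fid].omics_name
        frac[name] = frac.get(name, 0.0) + float(score)
    return frac


def region_contribution(
    ranking: GiniRanking,
    annotations: dict[str, FeatureAnnotation],
    omics_filter: str,
) -> dict[str, float]:
    """Per-region importance fractions within one of the Mut/CNA layers.

    SS mass is folded into CDS; fractions are normalised to sum 1 within the
    selected omics layer.
    """
    if omics_filter not in ("Mut", "CNA"):
        raise ValueError("region contributions are defined for Mut and CNA layers")
    mass: dict[str, float] = {r: 0.0 for r in REGION_REPORT_ORDER}
    for fid, score in zip(ranking.feature_ids, ranking.scores):
        ann = annotations.get(fid)
        if ann is None or ann.omics_name != omics_filter:
            continue
        region = "CDS" if ann.region == "SS" else ann.region
        mass[region] = mass.get(region, 0.0) + float(score)
    total = sum(mass.values())
    if total > 0:
        mass = {r: v / total for r, v in mass.items()}
    return mass


def biomarker_report(candidates: list[CandidateBiomarker]) -> pd.DataFrame:
    # Enhancer features cannot be mapped to a gene, so their gene column stays blank
    return pd.DataFrame(
        {
            "feature_id": [c.feature_id for c in candidates],
            "gene": ["" if c.region == "Enhancer" else (c.gene_symbol or "") for c in candidates],
            "omics": [c.omics_name for c in candidates],
            "region": [c.region for c in candidates],
            "gini_score": [c.gini_score for c in candidates],
            "p_value": [c.p_value for c in candidates],
            "status": [c.status for c in candidates],
        }
    )
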