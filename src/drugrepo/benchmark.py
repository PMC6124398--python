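"""ROC/AUC benchmark evaluation of screen scores under k-fold CV.

A benchmark is a set of known (positive) drug-disease indications plus a
negative set; the screen's -log10(P) score for each pair is evaluated by
the area under the ROC curve. Because the screen has no trainable
parameters, the k-fold protocol quantifies score stability across
benchmark subsets (each fold is scored with the same fixed screen) rather
than generalization of a fitted model; the full-set AUC is reported
alongside the per-fold values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .enrichment import ScreenReport

__all__ = [
    "Pair",
    "BenchmarkSet",
    "RocResult",
    "RocReport",
    "load_benchmark",
    "sample_negatives",
    "score_pairs",
    "roc_auc",
    "cross_validate",
]

Pair = tuple[str, str]  # (drug_id, mesh_id)

#: floor applied to P before -log10, so underflowed P still yields a
#: finite (very large) score
_P_FLOOR = 1e-300


@dataclass
class BenchmarkSet:
    """Labelled drug-disease pairs for evaluation."""

    positives: set[Pair]
    negatives: set[Pair] = field(default_factory=set)
    provenance: str = ""

    def __post_init__(self) -> None:
        overlap = self.positives & self.negatives
        if overlap:
            raise ValueError(
                f"{len(overlap)} pairs labelled both positive and negative"
            )


@dataclass
class RocResult:
    """One ROC curve from a threshold sweep over distinct scores."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


@dataclass
class RocReport:
    """Cross-validated benchmark evaluation."""

    scored_pairs: list[tuple[Pair, float, int, int]]  # (pair, score, label, fold)
    roc: RocResult                                    # full-set curve
    auc: float                                        # full-set AUC
    fold_aucs: list[float]
    mean_auc: float
    n_folds: int
    seed: int
    excluded_folds: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "fold_aucs": self.fold_aucs,
            "mean_auc": self.mean_auc,
            "n_folds": self.n_folds,
            "seed": self.seed,
            "n_positives": sum(1 for _, _, y, _ in self.scored_pairs if y == 1),
            "n_negatives": sum(1 for _, _, y, _ in self.scored_pairs if y == 0),
            "excluded_folds": self.excluded_folds,
        }


def load_benchmark(path, dialect: dict | None = None) -> BenchmarkSet:
    """Read a benchmark TSV with columns drug_id, mesh_id and an optional
    0/1 label column (missing label means every pair is positive).
    Duplicate pairs are collapsed; a pair labelled both ways is an error.
    """
    cols = {"drug_id": "drug_id", "mesh_id": "mesh_id", "label": "label",
            **(dialect or {})}
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for key in ("drug_id", "mesh_id"):
        if cols[key] not in df.columns:
            raise ValueError(f"missing required column '{cols[key]}' in {path}")
    has_label = cols["label"] in df.columns
    positives: set[Pair] = set()
    negatives: set[Pair] = set()
    for _, row in df.iterrows():
        pair = (row[cols["drug_id"]].strip(), row[cols["mesh_id"]].strip())
        if not pair[0] or not pair[1]:
            continue
        label = int(row[cols["label"]]) if has_label else 1
        (positives if label else negatives).add(pair)
    return BenchmarkSet(positives=positives, negatives=negatives,
                        provenance=str(path))


def sample_negatives(positives: set[Pair], candidate_pairs, ratio: float = 1.0,
                     strategy: str = "uniform", seed: int = 0) -> set[Pair]:
    """Sample a negative set from candidate pairs not in ``positives``.

    ``uniform``: simple random sample of size round(ratio * |positives|).
    ``drug_matched``: for each positive drug, sample (ratio x its positive
    count) of that drug's non-positive diseases where the drug's pool
    allows, topping up uniformly from the remaining pool. Deterministic
    for a fixed seed.
    """
    if strategy not in ("uniform", "drug_matched"):
        raise ValueError(f"unknown strategy {strategy!r}")
    pool = sorted(set(candidate_pairs) - set(positives))
    n_needed = int(round(ratio * len(positives)))
    if len(pool) < n_needed:
        raise ValueError(
            f"candidate pool has {len(pool)} pairs but {n_needed} negatives "
            f"requested (shortfall {n_needed - len(pool)})"
        )
    rng = np.random.default_rng(seed)
    if strategy == "uniform":
        idx = rng.choice(len(pool), size=n_needed, replace=False)
        return {pool[i] for i in sorted(idx)}
    # drug_matched
    per_drug_needed: dict[str, int] = {}
    for drug_id, _ in sorted(positives):
        per_drug_needed[drug_id] = per_drug_needed.get(drug_id, 0) + 1
    by_drug: dict[str, list[Pair]] = {}
    for pair in pool:
        by_drug.setdefault(pair[0], []).append(pair)
    chosen: set[Pair] = set()
    for drug_id in sorted(per_drug_needed):
        want = int(round(ratio * per_drug_needed[drug_id]))
        avail = by_drug.get(drug_id, [])
        take = min(want, len(avail))
        if take:
            idx = rng.choice(len(avail), size=take, replace=False)
            chosen.update(avail[i] for i in sorted(idx))
    remaining = [p for p in pool if p not in chosen]
    shortfall = n_needed - len(chosen)
    if shortfall > 0:
        idx = rng.choice(len(remaining), size=shortfall, replace=False)
        chosen.update(remaining[i] for i in sorted(idx))
    return chosen


def score_pairs(report: ScreenReport, pairs) -> np.ndarray:
    """-log10(P) for each pair tested by the screen; pairs the screen never
    tested (no gene overlap) score 0, the natural floor since an untested
    pair's Fisher P is 1 by construction."""
    pmap = {(r.drug_id, r.mesh_id): r.p_value for r in report.results}
    pairs = list(pairs)
    out = np.zeros(len(pairs))
    for i, pair in enumerate(pairs):
        p = pmap.get(tuple(pair))
        if p is not None:
            out[i] = -np.log10(max(p, _P_FLOOR))
    return out


def roc_auc(scores, labels) -> RocResult:
    """ROC from a threshold sweep over distinct scores, AUC by trapezoid
    (equivalent to the tie-corrected Mann-Whitney probability that a
    random positive outscores a random negative, with half credit for
    ties)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-d arrays")
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC undefined: labels contain a single class")
    fpr, tpr, thresholds = roc_curve(labels, scores, drop_intermediate=False)
    return RocResult(fpr=fpr, tpr=tpr, thresholds=thresholds,
                     auc=float(_trapezoid_auc(fpr, tpr)))


def cross_validate(score_fn, benchmark: BenchmarkSet, k: int = 5,
                   seed: int = 0) -> RocReport:
    """k-fold stratified evaluation of ``score_fn`` on the benchmark.

    Positives and negatives are partitioned into k stratified folds with
    a seeded shuffler; each held-out fold's AUC is computed from the fixed
    screen scores. A fold that ends up single-class (tiny benchmarks) is
    excluded with a warning. ``mean_auc`` is the mean of the retained
    fold AUCs.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(benchmark.positives) < k or len(benchmark.negatives) < k:
        raise ValueError(
            f"benchmark needs >= {k} positives and negatives for {k} folds"
        )
    pairs = sorted(benchmark.positives) + sorted(benchmark.negatives)
    labels = np.array([1] * len(benchmark.positives)
                      + [0] * len(benchmark.negatives))
    scores = np.asarray(score_fn(pairs), dtype=float)

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_of = np.full(len(pairs), -1, dtype=int)
    fold_aucs: list[float] = []
    excluded: list[int] = []
    for fold_idx, (_, test_idx) in enumerate(skf.split(scores.reshape(-1, 1),
                                                       labels)):
        fold_of[test_idx] = fold_idx
        y_test = labels[test_idx]
        if len(np.unique(y_test)) < 2:
            warnings.warn(f"fold {fold_idx} is single-class; excluded",
                          stacklevel=2)
            excluded.append(fold_idx)
            continue
        fold_aucs.append(roc_auc(scores[test_idx], y_test).auc)

    full = roc_auc(scores, labels)
    scored = [(pairs[i], float(scores[i]), int(labels[i]), int(fold_of[i]))
              for i in range(len(pairs))]
    return RocReport(
        scored_pairs=scored,
        roc=full,
        auc=full.auc,
        fold_aucs=fold_aucs,
        mean_auc=float(np.mean(fold_aucs)) if fold_aucs else float("nan"),
        n_folds=k,
        seed=seed,
        excluded_folds=excluded,
    )
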