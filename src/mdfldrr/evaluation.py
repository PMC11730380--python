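"""Cross-validation protocols and link-prediction metrics.

Two five-fold protocols mirror the two prediction goals:

* goal 1 — the known unordered interacting pairs are partitioned into folds;
  each fold's pairs are removed (both triangles) from the training network
  and scored together with every never-interacting pair;
* goal 2 — the drugs themselves are partitioned; each fold's drugs are
  removed from the network entirely and scored cold-start against the
  training drugs.

Negatives are all non-interacting candidate pairs — no negative sampling —
so the class imbalance of the real task is preserved and the area under the
precision-recall curve (AUPR) is the primary metric. Recall, precision, F1
and accuracy additionally need a decision threshold, which the published
protocol leaves open; the default here predicts as many positives as the
training prevalence implies, and can be overridden.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .datamodel import DrugCatalog, FeatureMatrix, InteractionMatrix
from .projection import Hyperparameters, fit, predict_new_drug

logger = logging.getLogger(__name__)

__all__ = [
    "FoldSplit",
    "MetricReport",
    "split_goal1",
    "split_goal2",
    "confusion",
    "recall",
    "precision",
    "f1",
    "accuracy",
    "auc",
    "aupr",
    "cross_validate",
    "grid_search",
    "PARAMETER_GRID",
    "CASE_STUDY_FRACTIONS",
]

#: The sensitivity-analysis grid each tunable weight is swept over.
PARAMETER_GRID = (1e-5, 1e-4, 1e-3, 1e-2, 1e-1)

#: Named preset: 66.67/16.67/16.67 train/validation/test drug split.
CASE_STUDY_FRACTIONS = (2 / 3, 1 / 6, 1 / 6)

METRIC_NAMES = ("recall", "precision", "f1", "accuracy", "auc", "aupr")


@dataclass(frozen=True)
class FoldSplit:
    """Fold assignment for one protocol: per pair (goal1) or per drug (goal2)."""

    mode: str  # "goal1" | "goal2"
    units: tuple  # unordered pairs (goal1) or drug ids (goal2)
    assignments: np.ndarray  # fold index per unit
    n_folds: int
    seed: int

    def fold_units(self, fold: int) -> list:
        return [u for u, a in zip(self.units, self.assignments) if a == fold]


def split_goal1(
    J: InteractionMatrix, k: int = 5, seed: int = 0
) -> FoldSplit:
    """Partition the known unordered interacting pairs into k balanced folds."""
    pairs = J.pairs()
    if len(pairs) < k:
        raise ValueError(f"need >= {k} interacting pairs, have {len(pairs)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    assignments = np.empty(len(pairs), dtype=int)
    assignments[order] = np.arange(len(pairs)) % k
    return FoldSplit("goal1", tuple(pairs), assignments, k, seed)


def split_goal2(catalog: DrugCatalog, k: int = 5, seed: int = 0) -> FoldSplit:
    """Partition the drugs into k balanced folds."""
    n = len(catalog)
    if n < k:
        raise ValueError(f"need >= {k} drugs, have {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assignments = np.empty(n, dtype=int)
    assignments[order] = np.arange(n) % k
    return FoldSplit("goal2", tuple(catalog.ids), assignments, k, seed)


def confusion(
    scores: Sequence[float], labels: Sequence[int], threshold: float
) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) counts at ``score >= threshold``."""
    s = np.asarray(scores, float)
    y = np.asarray(labels)
    if s.size == 0:
        raise ValueError("empty input")
    if s.shape != y.shape:
        raise ValueError("scores and labels differ in length")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary")
    pred = s >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    return tp, fp, tn, fn


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); returning 0", stacklevel=3)
        return 0.0
    return num / den


def recall(counts: tuple[int, int, int, int]) -> float:
    tp, fp, tn, fn = counts
    return _safe_ratio(tp, tp + fn, "recall")


def precision(counts: tuple[int, int, int, int]) -> float:
    tp, fp, tn, fn = counts
    return _safe_ratio(tp, tp + fp, "precision")


def f1(counts: tuple[int, int, int, int]) -> float:
    p, r = precision(counts), recall(counts)
    return _safe_ratio(2 * p * r, p + r, "f1")


def accuracy(counts: tuple[int, int, int, int]) -> float:
    tp, fp, tn, fn = counts
    return _safe_ratio(tp + tn, tp + fp + tn + fn, "accuracy")


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve; equals P(score+ > score-) + 0.5 P(tie)."""
    y = np.asarray(labels)
    if len(set(y.tolist())) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(y, np.asarray(scores, float)))


def aupr(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the precision-recall curve by step-wise summation.

    Computed as average precision over descending unique score thresholds
    (no linear interpolation between PR points, which is known to be biased).
    """
    y = np.asarray(labels)
    if np.sum(y) == 0:
        raise ValueError("AUPR needs at least one positive")
    return float(average_precision_score(y, np.asarray(scores, float)))


@dataclass
class MetricReport:
    """Per-fold and aggregate metric values for one cross-validation run."""

    mode: str
    per_fold: pd.DataFrame  # rows = folds, columns = METRIC_NAMES
    threshold_rule: str
    seed: int

    @property
    def mean(self) -> pd.Series:
        return self.per_fold.mean()

    @property
    def std(self) -> pd.Series:
        return self.per_fold.std(ddof=0)

    def summary(self) -> pd.DataFrame:
        out = self.per_fold.copy()
        out.loc["mean"] = self.mean
        out.loc["std"] = self.std
        return out

    def to_csv(self, path) -> None:
        self.summary().to_csv(path, index_label="fold")

    def to_json(self, path) -> None:
        import json

        payload = {
            "mode": self.mode,
            "seed": self.seed,
            "threshold_rule": self.threshold_rule,
            "folds": self.per_fold.to_dict(orient="index"),
            "mean": self.mean.to_dict(),
            "std": self.std.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _prevalence_threshold(scores: np.ndarray, prevalence: float) -> float:
    """Score cutting off as many predicted positives as ``prevalence`` implies."""
    k = int(round(prevalence * scores.size))
    k = min(max(k, 1), scores.size)
    return float(np.sort(scores)[::-1][k - 1])


def _fold_metrics(
    scores: np.ndarray,
    labels: np.ndarray,
    threshold: float | None,
    train_prevalence: float,
) -> dict[str, float]:
    if threshold is None:
        threshold = _prevalence_threshold(scores, train_prevalence)
    counts = confusion(scores, labels, threshold)
    return {
        "recall": recall(counts),
        "precision": precision(counts),
        "f1": f1(counts),
        "accuracy": accuracy(counts),
        "auc": auc(scores, labels),
        "aupr": aupr(scores, labels),
    }


def _subset_features(
    Hs: Sequence[FeatureMatrix], catalog: DrugCatalog, keep: np.ndarray
) -> list[FeatureMatrix]:
    sub_cat = DrugCatalog(tuple(np.asarray(catalog.ids)[keep]))
    return [
        FeatureMatrix(H.feature_name, H.descriptors, H.values[keep], sub_cat)
        for H in Hs
    ]


def cross_validate(
    Hs: Sequence[FeatureMatrix],
    J: InteractionMatrix,
    hp: Hyperparameters | None = None,
    mode: str = "goal1",
    k: int = 5,
    seed: int = 0,
    theta_drr: float = 1e-2,
    threshold: float | None = None,
) -> MetricReport:
    """Run one k-fold cross-validation and report the six metrics per fold.

    Hyperparameters are fixed across folds (tuning is a separate concern,
    see :func:`grid_search`). ``threshold`` overrides the prevalence-matched
    default cut for the four count-based metrics.
    """
    if mode not in ("goal1", "goal2"):
        raise ValueError("mode must be 'goal1' or 'goal2'")
    hp = hp or (Hyperparameters.goal1() if mode == "goal1" else Hyperparameters.goal2())
    catalog = J.catalog
    n = len(catalog)
    rows = []

    if mode == "goal1":
        split = split_goal1(J, k, seed)
        all_pairs_known = {tuple(sorted(p)) for p in split.units}
        for fold in range(k):
            held = split.fold_units(fold)
            J_train = J.values.copy()
            for a, b in held:
                i, j = catalog.position(a), catalog.position(b)
                J_train[i, j] = J_train[j, i] = 0.0
            Jm = InteractionMatrix(J_train, catalog)
            model = fit(Hs, Jm, hp, theta_drr)
            Ssym = 0.5 * (model.S + model.S.T)
            held_idx = {
                (catalog.position(a), catalog.position(b)) for a, b in held
            }
            scores, labels = [], []
            iu, ju = np.triu_indices(n, k=1)
            for i, j in zip(iu, ju):
                a, b = catalog.ids[i], catalog.ids[j]
                if (i, j) in held_idx or tuple(sorted((a, b))) not in all_pairs_known:
                    scores.append(Ssym[i, j])
                    labels.append(1 if (i, j) in held_idx else 0)
            scores, labels = np.asarray(scores), np.asarray(labels)
            train_prev = Jm.n_interactions / (n * (n - 1) / 2)
            rows.append(_fold_metrics(scores, labels, threshold, train_prev))
    else:
        split = split_goal2(catalog, k, seed)
        for fold in range(k):
            test_drugs = set(split.fold_units(fold))
            keep = np.array([d not in test_drugs for d in catalog.ids])
            train_cat_ids = [d for d in catalog.ids if d not in test_drugs]
            sub_Hs = _subset_features(Hs, catalog, keep)
            sub_J = InteractionMatrix(
                J.values[np.ix_(keep, keep)], sub_Hs[0].catalog
            )
            model = fit(sub_Hs, sub_J, hp, theta_drr)
            scores, labels = [], []
            for d in sorted(test_drugs):
                di = catalog.position(d)
                feats = {
                    H.feature_name: H.values[di] for H in Hs
                }
                s = predict_new_drug(model, feats)
                truth = J.values[di, keep]
                scores.extend(s.tolist())
                labels.extend(truth.astype(int).tolist())
            scores, labels = np.asarray(scores), np.asarray(labels)
            n_tr = len(train_cat_ids)
            train_prev = sub_J.n_interactions / (n_tr * (n_tr - 1) / 2)
            rows.append(_fold_metrics(scores, labels, threshold, train_prev))

    per_fold = pd.DataFrame(rows, columns=list(METRIC_NAMES))
    rule = "override" if threshold is not None else "training-prevalence-matched"
    return MetricReport(mode, per_fold, rule, seed)


def grid_search(
    Hs: Sequence[FeatureMatrix],
    J: InteractionMatrix,
    mode: str = "goal1",
    grid: Sequence[float] = PARAMETER_GRID,
    k: int = 5,
    seed: int = 0,
    theta_drr: float = 1e-2,
    max_iter: int = 100,
    tol: float = 1e-4,
) -> pd.DataFrame:
    """Sweep (lambda, theta[, sigma]) over the grid, ranking by mean AUPR.

    For goal 2 sigma is pinned at 0 (a cold-start drug has no neighbourhood
    for the relation penalty), so the sweep is two-dimensional.
    """
    sigmas = list(grid) if mode == "goal1" else [0.0]
    records = []
    for lam, theta, sigma in product(grid, grid, sigmas):
        hp = Hyperparameters(
            lambda_sparsity=lam, theta=theta, sigma=sigma,
            max_iter=max_iter, tol=tol, seed=seed,
        )
        report = cross_validate(Hs, J, hp, mode=mode, k=k, seed=seed, theta_drr=theta_drr)
        rec = {"lambda": lam, "theta": theta, "sigma": sigma}
        rec.update({f"mean_{m}": report.mean[m] for m in METRIC_NAMES})
        records.append(rec)
        logger.info("grid point %s -> AUPR %.4f", (lam, theta, sigma), rec["mean_aupr"])
    out = pd.DataFrame(records).sort_values("mean_aupr", ascending=False)
    return out.reset_index(drop=True)
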