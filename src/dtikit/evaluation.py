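"""Repeated cross-validation over drugs and AUC computation.

The protocol: drugs are randomly split into k balanced folds; per-protein
models are trained on the k-1 training folds and score every (held-out drug,
protein) pair; pairs are pooled across proteins into one ROC AUC per fold
("global accuracy").  The random split is repeated, giving k x repeats AUC
values whose arithmetic mean is the headline number (25 at the 5 x 5
default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .blm import BLMConfig, _side_predict
from .core_io import InteractionTable
from .models import build_features, fit_kl1lr, predict_kl1lr

__all__ = [
    "CVPlan",
    "CVResult",
    "make_cv_plan",
    "roc_auc",
    "run_cv",
    "lambda_grid",
    "cost_grid",
]


@dataclass(frozen=True)
class CVPlan:
    """Per-repeat assignment of each drug to one of k balanced folds."""

    k: int
    repeats: int
    seed: int
    assignments: np.ndarray  # repeats x n_drugs fold labels

    def fold_indices(self, repeat: int, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments[repeat] == fold)


@dataclass
class CVResult:
    """All per-run AUCs, their mean, and the per-run skip log."""

    per_run_auc: np.ndarray  # repeats x k
    skip_log: list[str] = field(default_factory=list)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.per_run_auc))


def make_cv_plan(n_drugs: int, k: int = 5, repeats: int = 5, seed: int = 0) -> CVPlan:
    """Balanced random k-fold partitions, one per repeat, reproducible from seed."""
    if n_drugs < k:
        raise ValueError(f"cannot split {n_drugs} drugs into {k} folds")
    rng = np.random.default_rng(seed)
    assignments = np.empty((repeats, n_drugs), dtype=np.intp)
    base = np.arange(n_drugs) % k  # fold sizes differ by at most one
    for r in range(repeats):
        assignments[r] = base[rng.permutation(n_drugs)]
    return CVPlan(k, repeats, seed, assignments)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve with midrank tie handling.

    Equals P(score_pos > score_neg) + 0.5 * P(tie), computed from the
    Mann-Whitney rank-sum identity.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc needs both classes present")
    ranks = rankdata(s, method="average")
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def run_cv(config: BLMConfig, dti: InteractionTable, plan: CVPlan) -> CVResult:
    """Repeated k-fold CV of per-protein drug-side models; one pooled AUC per run.

    Proteins whose training labels in a given run are degenerate (fewer than
    two positives or two negatives among training drugs) are excluded from
    that run's pooled pairs and logged.  Raises if a run retains no usable
    protein.
    """
    if not config.drug_kernels:
        raise ValueError("run_cv requires drug kernels in the config")
    drugs = config.drug_kernels[0].entities
    if drugs.ids != dti.drugs.ids:
        raise ValueError("drug kernels and interaction table have mismatched drug registries")
    y = dti.label_matrix().astype(np.int8)
    n = len(drugs)
    aucs = np.empty((plan.repeats, plan.k))
    skip_log: list[str] = []

    for r in range(plan.repeats):
        for fold in range(plan.k):
            held = plan.fold_indices(r, fold)
            train = np.setdiff1d(np.arange(n), held)
            pooled_scores: list[np.ndarray] = []
            pooled_labels: list[np.ndarray] = []
            for j, protein in enumerate(dti.proteins.ids):
                yj = y[:, j]
                n_pos = int(yj[train].sum())
                n_neg = train.size - n_pos
                if n_pos < 2 or n_neg < 2:
                    skip_log.append(
                        f"repeat {r} fold {fold} protein {protein}: "
                        f"{n_pos} positives / {n_neg} negatives in training, skipped"
                    )
                    continue
                probs = _side_predict(
                    config,
                    config.drug_kernels,
                    config.svm_drug_kernel,
                    yj,
                    held,
                    train,
                )
                pooled_scores.append(probs)
                pooled_labels.append(yj[held])
            if not pooled_scores:
                raise ValueError(f"repeat {r} fold {fold}: every protein degenerate; AUC undefined")
            scores = np.concatenate(pooled_scores)
            labels = np.concatenate(pooled_labels)
            if labels.min() == labels.max():
                raise ValueError(
                    f"repeat {r} fold {fold}: pooled held-out pairs are single-class"
                )
            aucs[r, fold] = roc_auc(scores, labels)
    return CVResult(aucs, skip_log)


def lambda_grid(n: int = 13, low: float = 0.01, high: float = 0.3) -> np.ndarray:
    """Default KL1LR regularization sweep: 13 log-spaced values in [0.01, 0.3]."""
    return np.geomspace(low, high, n)


def cost_grid(n: int = 18, low: float = 0.1, high: float = 100.0) -> np.ndarray:
    """Default SVM cost sweep: 18 log-spaced values in [0.1, 100]."""
    return np.geomspace(low, high, n)
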