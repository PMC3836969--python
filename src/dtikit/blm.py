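"""Bipartite local model (BLM) pipeline.

A pair (drug d, protein p) is scored twice: a drug-side classifier trained
over drugs labelled by "interacts with p" (using drug kernels), and a
protein-side classifier trained over proteins labelled by "targeted by d"
(using the protein kernel).  The two probabilities are aggregated — by
default their geometric mean — into one interaction probability.  Entities
whose training labels are degenerate (all positive or all negative) are
skipped and logged, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core_io import InteractionTable, PredictionTable, SimilarityMatrix, aligned
from .kernel_ops import FusionCoefficients, fuse_kernels, make_psd
from .models import SVMSpec, build_features, fit_kl1lr, fit_svm, predict_kl1lr

__all__ = [
    "BLMConfig",
    "predict_drug_side",
    "predict_protein_side",
    "aggregate_pair",
    "predict_all",
    "rank_unknown",
    "cross_dataset_ratio",
]

AGGREGATIONS = ("geometric_mean", "arithmetic_mean", "max")


@dataclass
class BLMConfig:
    """Method, kernels and hyperparameters for the bipartite local model.

    ``drug_kernels`` must share the interaction table's drug registry and
    ``protein_kernel`` its protein registry.  ``lam`` is the KL1LR
    regularization strength, ``cost`` the SVM C; ``fusion_weights`` (SVM only)
    default to 1 per drug kernel.
    """

    method: str = "kl1lr"
    drug_kernels: Sequence[SimilarityMatrix] = ()
    protein_kernel: Optional[SimilarityMatrix] = None
    aggregation: str = "geometric_mean"
    lam: float = 0.04
    cost: float = 1.0
    fusion_weights: Optional[Sequence[float]] = None
    _svm_drug_kernel: Optional[SimilarityMatrix] = field(default=None, repr=False)
    _svm_protein_kernel: Optional[SimilarityMatrix] = field(default=None, repr=False)

    def __post_init__(self):
        if self.method not in ("kl1lr", "svm"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.aggregation not in AGGREGATIONS:
            raise ValueError(f"unknown aggregation {self.aggregation!r}")
        self.drug_kernels = list(self.drug_kernels)
        if not self.drug_kernels and self.protein_kernel is None:
            raise ValueError("need at least one drug kernel or a protein kernel")
        if self.drug_kernels:
            aligned(self.drug_kernels)

    def svm_drug_kernel(self) -> SimilarityMatrix:
        """Fused + PSD-corrected drug kernel for the SVM route (cached)."""
        if self._svm_drug_kernel is None:
            w = self.fusion_weights or [1.0] * len(self.drug_kernels)
            fused = fuse_kernels(self.drug_kernels, FusionCoefficients(tuple(w)))
            self._svm_drug_kernel = make_psd(fused)
        return self._svm_drug_kernel

    def svm_protein_kernel(self) -> SimilarityMatrix:
        if self._svm_protein_kernel is None:
            self._svm_protein_kernel = make_psd(self.protein_kernel)
        return self._svm_protein_kernel


def _side_predict(
    config: BLMConfig,
    kernels: Sequence[SimilarityMatrix],
    svm_kernel_fn,
    labels: np.ndarray,
    heldout_idx: np.ndarray,
    train_idx: np.ndarray,
) -> np.ndarray:
    if config.method == "kl1lr":
        f_train = build_features(kernels, labels, train_idx)
        model = fit_kl1lr(f_train, config.lam)
        f_held = build_features(kernels, labels, train_idx, heldout_idx)
        return predict_kl1lr(model, f_held)
    spec = SVMSpec(cost=config.cost, kernel=svm_kernel_fn())
    return fit_svm(spec, labels, train_idx, heldout_idx)


def predict_drug_side(
    config: BLMConfig,
    dti: InteractionTable,
    protein: str,
    heldout_drugs: Sequence[str],
    train_drugs: Optional[Sequence[str]] = None,
) -> np.ndarray:
    """Probability that each held-out drug targets ``protein``.

    Trains the configured model on training drugs (all non-held-out drugs by
    default) labelled by their known interaction with the protein.
    """
    if not config.drug_kernels:
        raise ValueError("config has no drug kernels")
    drugs = config.drug_kernels[0].entities
    held_idx = drugs.positions(heldout_drugs)
    if train_drugs is None:
        train_idx = np.setdiff1d(np.arange(len(drugs)), held_idx)
    else:
        train_idx = drugs.positions(train_drugs)
    labels = np.array([1 if (d, protein) in dti.pairs else 0 for d in drugs.ids], dtype=np.int8)
    return _side_predict(
        config, config.drug_kernels, config.svm_drug_kernel, labels, held_idx, train_idx
    )


def predict_protein_side(
    config: BLMConfig,
    dti: InteractionTable,
    drug: str,
    heldout_proteins: Sequence[str],
    train_proteins: Optional[Sequence[str]] = None,
) -> np.ndarray:
    """Probability that ``drug`` targets each held-out protein (protein kernel side)."""
    if config.protein_kernel is None:
        raise ValueError("config has no protein kernel")
    proteins = config.protein_kernel.entities
    held_idx = proteins.positions(heldout_proteins)
    if train_proteins is None:
        train_idx = np.setdiff1d(np.arange(len(proteins)), held_idx)
    else:
        train_idx = proteins.positions(train_proteins)
    labels = np.array([1 if (drug, p) in dti.pairs else 0 for p in proteins.ids], dtype=np.int8)
    return _side_predict(
        config, [config.protein_kernel], config.svm_protein_kernel, labels, held_idx, train_idx
    )


def aggregate_pair(p1: float, p2: float, mode: str = "geometric_mean") -> float:
    """Combine drug-side and protein-side probabilities into one.

    All modes are symmetric and return a value within [min(p1,p2), max(p1,p2)];
    the geometric mean additionally absorbs zeros.
    """
    if not (0.0 <= p1 <= 1.0 and 0.0 <= p2 <= 1.0):
        raise ValueError(f"probabilities must lie in [0, 1], got ({p1}, {p2})")
    if mode == "geometric_mean":
        return float(np.sqrt(p1 * p2))
    if mode == "arithmetic_mean":
        return (p1 + p2) / 2.0
    if mode == "max":
        return max(p1, p2)
    raise ValueError(f"unknown aggregation {mode!r}")


def predict_all(
    config: BLMConfig, dti: InteractionTable
) -> tuple[PredictionTable, list[str]]:
    """Score every (drug, protein) pair; returns the table and a skip log.

    Drug-side models are trained per protein on all drugs (in-sample scoring
    with self-excluded features); protein-side models per drug on all
    proteins; available sides are aggregated.  Proteins or drugs whose labels
    are degenerate contribute no score from that side and are logged.
    """
    drugs, proteins = dti.drugs, dti.proteins
    y = dti.label_matrix().astype(np.int8)
    skip_log: list[str] = []
    drug_scores = np.full((len(drugs), len(proteins)), np.nan)
    prot_scores = np.full((len(drugs), len(proteins)), np.nan)

    if config.drug_kernels:
        all_drugs = np.arange(len(drugs))
        for j, protein in enumerate(proteins.ids):
            yj = y[:, j]
            if yj.sum() < 2 or (1 - yj).sum() < 2:
                skip_log.append(f"protein {protein}: degenerate drug labels, drug-side skipped")
                continue
            f = build_features(config.drug_kernels, yj, all_drugs)
            if config.method == "kl1lr":
                model = fit_kl1lr(f, config.lam)
                drug_scores[:, j] = predict_kl1lr(model, f)
            else:
                spec = SVMSpec(cost=config.cost, kernel=config.svm_drug_kernel())
                drug_scores[:, j] = fit_svm(spec, yj, all_drugs, all_drugs)
    if config.protein_kernel is not None:
        all_prots = np.arange(len(proteins))
        for i, drug in enumerate(drugs.ids):
            yi = y[i, :]
            if yi.sum() < 2 or (1 - yi).sum() < 2:
                skip_log.append(f"drug {drug}: degenerate protein labels, protein-side skipped")
                continue
            f = build_features([config.protein_kernel], yi, all_prots)
            if config.method == "kl1lr":
                model = fit_kl1lr(f, config.lam)
                prot_scores[i, :] = predict_kl1lr(model, f)
            else:
                spec = SVMSpec(cost=config.cost, kernel=config.svm_protein_kernel())
                prot_scores[i, :] = fit_svm(spec, yi, all_prots, all_prots)

    scores: dict[tuple[str, str], float] = {}
    for i, d in enumerate(drugs.ids):
        for j, p in enumerate(proteins.ids):
            a, b = drug_scores[i, j], prot_scores[i, j]
            if np.isnan(a) and np.isnan(b):
                continue
            if np.isnan(a):
                scores[(d, p)] = float(b)
            elif np.isnan(b):
                scores[(d, p)] = float(a)
            else:
                scores[(d, p)] = aggregate_pair(float(a), float(b), config.aggregation)
    return PredictionTable(drugs, proteins, scores), skip_log


def rank_unknown(
    preds: PredictionTable, known: InteractionTable, top_k: Optional[int] = None
) -> list[tuple[tuple[str, str], float]]:
    """Unknown pairs ranked by descending probability; ties broken by pair id."""
    items = [
        (pair, prob) for pair, prob in preds.scores.items() if pair not in known.pairs
    ]
    items.sort(key=lambda kv: (-kv[1], kv[0]))
    return items if top_k is None else items[:top_k]


def cross_dataset_ratio(
    ranked_unknowns: Sequence[tuple[tuple[str, str], float]],
    other: InteractionTable,
    bins: Optional[Sequence[tuple[int, int]]] = None,
    threshold: Optional[float] = None,
):
    """Fraction of ranked unknown pairs confirmed by another interaction table.

    With ``bins`` (1-based inclusive rank ranges, non-overlapping, ordered):
    one ratio per bin, ``None`` for empty bins.  With ``threshold``: the two
    ratios for pairs scored >= t and < t.
    """
    if (bins is None) == (threshold is None):
        raise ValueError("provide exactly one of bins or threshold")

    def _known(pair: tuple[str, str]) -> bool:
        return pair in other.pairs

    if threshold is not None:
        hi = [p for p, s in ranked_unknowns if s >= threshold]
        lo = [p for p, s in ranked_unknowns if s < threshold]
        return {
            "above": sum(map(_known, hi)) / len(hi) if hi else None,
            "below": sum(map(_known, lo)) / len(lo) if lo else None,
        }

    prev_end = 0
    out = []
    for start, end in bins:
        if start <= prev_end or end < start:
            raise ValueError("bins must be ordered, non-overlapping, with start <= end")
        prev_end = end
        chunk = [p for p, _ in ranked_unknowns[start - 1 : end]]
        out.append(sum(map(_known, chunk)) / len(chunk) if chunk else None)
    return out
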