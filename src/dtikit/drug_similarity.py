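"""Drug similarity kernels.

Three families, mirroring the three data sources a drug brings to target
prediction:

* chemical structure — Tanimoto similarity over binary fingerprints and the
  signature (dot-product) kernel over count vectors;
* side effects — weighted Dice similarity with down-weighting of frequent
  and mutually correlated side effects;
* drug–drug interactions (DDI) — direct-edge, inverse shortest-path, and
  graph diffusion kernels over the DDI network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.linalg import expm
from scipy.sparse.csgraph import shortest_path
from scipy.spatial.distance import squareform

from .core_io import EntityRegistry, DDINetwork, FingerprintSet, SideEffectProfiles, SimilarityMatrix

__all__ = [
    "DiffusionParams",
    "SideEffectWeights",
    "tanimoto_matrix",
    "signature_kernel_matrix",
    "side_effect_weights",
    "side_effect_similarity",
    "ddi_direct_similarity",
    "ddi_shortest_path_similarity",
    "ddi_diffusion_kernel",
]


@dataclass(frozen=True)
class DiffusionParams:
    """Diffusion constant beta > 0; larger beta weights longer indirect paths more."""

    beta: float = 0.5

    def __post_init__(self):
        if not self.beta > 0:
            raise ValueError("diffusion constant beta must be > 0")


@dataclass
class SideEffectWeights:
    """Per-side-effect down-weights.

    ``freq_weight`` penalises frequently reported side effects
    (1/ln(e + frequency)); ``corr_weight`` penalises side effects that cluster
    with many correlated ones (1/cluster size).  ``combined`` is their product
    and is what the similarity uses.
    """

    side_effects: EntityRegistry
    freq_weight: np.ndarray
    corr_weight: np.ndarray

    @property
    def combined(self) -> np.ndarray:
        return self.freq_weight * self.corr_weight


def tanimoto_matrix(fp: FingerprintSet) -> SimilarityMatrix:
    """Tanimoto (Jaccard) similarity |A∩B| / |A∪B| over binary fingerprints.

    The 0/0 case (two all-zero fingerprints, including a zero fingerprint with
    itself) is defined as 0 with a warning.
    """
    if fp.mode != "binary":
        raise ValueError("tanimoto_matrix requires binary fingerprints")
    b = fp.vectors.astype(float)
    inter = b @ b.T
    pop = b.sum(axis=1)
    union = pop[:, None] + pop[None, :] - inter
    n_empty = int(np.sum(pop == 0))
    if n_empty:
        warnings.warn(f"{n_empty} all-zero fingerprint(s); their pairwise similarity is set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    return SimilarityMatrix(fp.drugs, sim)


def signature_kernel_matrix(fp: FingerprintSet, normalize: bool = True) -> SimilarityMatrix:
    """Dot-product (Gram) kernel of molecular signature count vectors.

    With ``normalize`` the cosine form K_ij / sqrt(K_ii K_jj) is returned;
    zero vectors get 0 off-diagonal and 1 on the diagonal, with a warning.
    """
    if fp.mode != "count":
        raise ValueError("signature_kernel_matrix requires count fingerprints")
    v = fp.vectors.astype(float)
    gram = v @ v.T
    if not normalize:
        return SimilarityMatrix(fp.drugs, gram)
    diag = np.diag(gram).copy()
    zero = diag == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero signature vector(s); normalized rows set to 0 (diag 1)")
    scale = np.sqrt(np.where(zero, 1.0, diag))
    k = gram / scale[:, None] / scale[None, :]
    k[zero, :] = 0.0
    k[:, zero] = 0.0
    np.fill_diagonal(k, 1.0)
    return SimilarityMatrix(fp.drugs, k)


def side_effect_weights(p: SideEffectProfiles, corr_threshold: float = 0.7) -> SideEffectWeights:
    """Frequency and correlation down-weights for side effects.

    Frequency: f_s = number of drugs reporting s, weight 1/ln(e + f_s).
    Correlation: side effects are clustered by average-linkage agglomerative
    clustering on the Jaccard similarity of their drug sets; the dendrogram is
    cut where between-cluster similarity drops below ``corr_threshold``, and
    each side effect is weighted 1/|its cluster|.  Side effects carried by no
    drug are excluded with a warning.
    """
    if not 0 < corr_threshold < 1:
        raise ValueError("corr_threshold must lie in (0, 1)")
    if not p.assignments:
        raise ValueError("side-effect profiles are empty")
    ind = p.indicator().astype(float)  # drugs x side effects
    freq = ind.sum(axis=0)
    keep = freq > 0
    if not keep.all():
        dropped = [s for s, k in zip(p.side_effects.ids, keep) if not k]
        warnings.warn(f"excluded {len(dropped)} side effect(s) with no carrier drugs")
    ids = tuple(s for s, k in zip(p.side_effects.ids, keep) if k)
    reg = EntityRegistry(ids)
    m = ind[:, keep]
    f = freq[keep]
    freq_weight = 1.0 / np.log(np.e + f)

    n_se = len(ids)
    if n_se == 1:
        corr_weight = np.ones(1)
    else:
        inter = m.T @ m
        sizes = f
        union = sizes[:, None] + sizes[None, :] - inter
        jac = inter / union  # union > 0 since every kept side effect has carriers
        dist = 1.0 - jac
        np.fill_diagonal(dist, 0.0)
        z = linkage(squareform(dist, checks=False), method="average")
        labels = fcluster(z, t=1.0 - corr_threshold, criterion="distance")
        _, counts = np.unique(labels, return_counts=True)
        cluster_size = counts[labels - 1] if labels.min() == 1 else np.array(
            [np.sum(labels == l) for l in labels]
        )
        corr_weight = 1.0 / cluster_size
    return SideEffectWeights(reg, freq_weight, corr_weight.astype(float))


def side_effect_similarity(p: SideEffectProfiles, w: SideEffectWeights) -> SimilarityMatrix:
    """Weighted Dice similarity of side-effect profiles.

    sim(i, j) = 2 * sum_{s in S_i ∩ S_j} w(s) / (sum_{S_i} w(s) + sum_{S_j} w(s)),
    with w the combined frequency x correlation weight.  Drugs with empty
    profiles get 0 off-diagonal and 1 on the diagonal.
    """
    present = {s for _, s in p.assignments}
    missing = present - set(w.side_effects.ids)
    if missing:
        raise ValueError(f"weights missing for side effects: {sorted(missing)[:5]}")
    cols = p.side_effects.positions(w.side_effects.ids)
    ind = p.indicator().astype(float)[:, cols]  # drugs x weighted side effects
    wv = w.combined
    weighted = ind * wv[None, :]
    shared = weighted @ ind.T  # sum of w(s) over S_i ∩ S_j
    totals = weighted.sum(axis=1)
    denom = totals[:, None] + totals[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(denom > 0, 2.0 * shared / np.where(denom > 0, denom, 1.0), 0.0)
    empty = totals == 0
    sim[empty, :] = 0.0
    sim[:, empty] = 0.0
    np.fill_diagonal(sim, 1.0)
    return SimilarityMatrix(p.drugs, sim)


def ddi_direct_similarity(g: DDINetwork) -> SimilarityMatrix:
    """Adjacency similarity: 1 if two drugs interact directly, else 0; diagonal 1."""
    a = g.adjacency()
    np.fill_diagonal(a, 1.0)
    return SimilarityMatrix(g.drugs, a)


def ddi_shortest_path_similarity(g: DDINetwork) -> SimilarityMatrix:
    """Inverse shortest-path similarity 1/d(i, j); unreachable pairs get 0."""
    a = g.adjacency()
    d = shortest_path(a, method="D", unweighted=True, directed=False)
    with np.errstate(divide="ignore"):
        sim = np.where(np.isinf(d), 0.0, np.where(d > 0, 1.0 / np.where(d > 0, d, 1.0), 1.0))
    np.fill_diagonal(sim, 1.0)
    return SimilarityMatrix(g.drugs, sim)


def ddi_diffusion_kernel(g: DDINetwork, params: DiffusionParams = DiffusionParams()) -> SimilarityMatrix:
    """Graph diffusion kernel K = exp(beta * H), H = A - D.

    H is the negative graph Laplacian (adjacency minus degree matrix); K
    accumulates walks of all lengths, discounted by the diffusion constant.
    Rows sum to 1 because H annihilates the constant vector, and K is PSD.
    """
    a = g.adjacency()
    h = a - np.diag(a.sum(axis=1))
    k = expm(params.beta * h)
    k = (k + k.T) / 2.0  # expm symmetry to machine noise
    return SimilarityMatrix(g.drugs, k)
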