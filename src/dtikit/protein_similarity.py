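"""Protein kernels from sequence alignment and EC-number hierarchy.

The sequence kernel is the Smith-Waterman local-alignment score, normalized
as SW(i,j)/sqrt(SW(i,i)*SW(j,j)) so the diagonal is exactly 1.  The Enzyme
Commission (EC) kernel counts shared leading EC fields plus one — a value in
1..5 — optionally scaled to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
from Bio import Align

from .core_io import EntityRegistry, SimilarityMatrix

__all__ = [
    "AlignmentParams",
    "ECNumber",
    "smith_waterman_score",
    "normalized_sw_matrix",
    "ec_hierarchy_score",
    "ec_matrix",
]

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class AlignmentParams:
    """Smith-Waterman scoring: linear gaps by default, optional substitution matrix.

    With ``substitution_matrix`` set (e.g. ``"BLOSUM62"``), match/mismatch are
    ignored and ``gap_open``/``gap_extend`` give an affine gap model.
    """

    match: float = 2.0
    mismatch: float = -1.0
    gap: float = -1.0
    substitution_matrix: Optional[str] = None
    gap_open: Optional[float] = None
    gap_extend: Optional[float] = None

    def __post_init__(self):
        if self.gap > 0:
            raise ValueError("gap cost must be <= 0")
        if self.substitution_matrix is None and not self.match > self.mismatch:
            raise ValueError("match score must exceed mismatch score")

    def aligner(self) -> Align.PairwiseAligner:
        al = Align.PairwiseAligner()
        al.mode = "local"
        if self.substitution_matrix is not None:
            al.substitution_matrix = Align.substitution_matrices.load(self.substitution_matrix)
            al.open_gap_score = self.gap_open if self.gap_open is not None else -11.0
            al.extend_gap_score = self.gap_extend if self.gap_extend is not None else -1.0
        else:
            al.match_score = self.match
            al.mismatch_score = self.mismatch
            al.open_gap_score = self.gap
            al.extend_gap_score = self.gap
        return al


def _check_sequence(seq: str, name: str = "sequence") -> str:
    if not seq:
        raise ValueError(f"{name} is empty")
    seq = seq.upper()
    for pos, ch in enumerate(seq):
        if ch not in AMINO_ACIDS:
            raise ValueError(f"illegal residue {ch!r} at position {pos} of {name}")
    return seq


def smith_waterman_score(a: str, b: str, p: AlignmentParams = AlignmentParams()) -> float:
    """Optimal local-alignment score of two amino-acid sequences (>= 0)."""
    a = _check_sequence(a, "first sequence")
    b = _check_sequence(b, "second sequence")
    return float(p.aligner().score(a, b))


def normalized_sw_matrix(
    seqs: Mapping[str, str], p: AlignmentParams = AlignmentParams()
) -> SimilarityMatrix:
    """Normalized Smith-Waterman kernel SW(i,j)/sqrt(SW(i,i)*SW(j,j)).

    The diagonal is exactly 1 and entries lie in [0, 1] under linear-gap
    positive-match scoring.  The result is symmetric but not guaranteed PSD;
    apply :func:`dtikit.kernel_ops.make_psd` before SVM use.
    """
    ids = list(seqs)
    cleaned = {i: _check_sequence(seqs[i], i) for i in ids}
    aligner = p.aligner()
    n = len(ids)
    self_scores = np.array([aligner.score(cleaned[i], cleaned[i]) for i in ids])
    if np.any(self_scores <= 0):
        bad = ids[int(np.argmin(self_scores))]
        raise ValueError(f"non-positive self-alignment score for {bad!r}")
    k = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = aligner.score(cleaned[ids[i]], cleaned[ids[j]])
            k[i, j] = k[j, i] = s / np.sqrt(self_scores[i] * self_scores[j])
    return SimilarityMatrix(EntityRegistry.from_iterable(ids), k)


@dataclass(frozen=True)
class ECNumber:
    """Enzyme Commission number with up to 4 known fields; '-' marks unknown.

    Known fields must form a prefix: "1.2.-.4" is invalid.
    """

    fields: tuple[Optional[int], ...]

    def __post_init__(self):
        if len(self.fields) != 4:
            raise ValueError("EC number must have exactly 4 slots")
        seen_unknown = False
        for f in self.fields:
            if f is None:
                seen_unknown = True
            else:
                if seen_unknown:
                    raise ValueError(f"known EC field after unknown one in {self.fields}")
                if f <= 0:
                    raise ValueError("EC fields must be positive integers")

    @classmethod
    def parse(cls, text: str) -> "ECNumber":
        parts = text.strip().split(".")
        if len(parts) > 4 or not parts or parts == [""]:
            raise ValueError(f"cannot parse EC number {text!r}")
        parts = parts + ["-"] * (4 - len(parts))
        fields = tuple(None if p in ("-", "") else int(p) for p in parts)
        return cls(fields)

    def known_prefix(self) -> tuple[int, ...]:
        out = []
        for f in self.fields:
            if f is None:
                break
            out.append(f)
        return tuple(out)

    def __str__(self) -> str:
        return ".".join("-" if f is None else str(f) for f in self.fields)


def ec_hierarchy_score(x: ECNumber, y: ECNumber) -> int:
    """Shared leading EC fields plus one: an integer in 1..5."""
    px, py = x.known_prefix(), y.known_prefix()
    common = 0
    for a, b in zip(px, py):
        if a != b:
            break
        common += 1
    return common + 1


def ec_matrix(ecs: Mapping[str, "ECNumber | str"], normalize: bool = False) -> SimilarityMatrix:
    """EC hierarchy-score kernel over proteins (raw 1..5, or /5 if normalized).

    Every protein must carry an EC number; filter proteins lacking one before
    calling.  PSD by construction (sum of prefix-indicator kernels plus a
    constant).
    """
    ids = list(ecs)
    if not ids:
        raise ValueError("no EC numbers given")
    parsed = {}
    for pid in ids:
        v = ecs[pid]
        if v is None or (isinstance(v, str) and not v.strip()):
            raise ValueError(f"protein {pid!r} has no EC number; filter such proteins upstream")
        parsed[pid] = v if isinstance(v, ECNumber) else ECNumber.parse(v)
    n = len(ids)
    k = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            s = ec_hierarchy_score(parsed[ids[i]], parsed[ids[j]])
            k[i, j] = k[j, i] = s
    if normalize:
        k = k / 5.0
    return SimilarityMatrix(EntityRegistry.from_iterable(ids), k)
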