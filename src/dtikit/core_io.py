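"""Shared domain types and plain-text I/O.

All entity collections (drugs, proteins, side effects) are tracked through an
:class:`EntityRegistry`, which fixes a stable 0-based order so that similarity
matrices, interaction tables and kernel algebra all agree on positions.

File formats are deliberately minimal: 2-column TSV edge lists with optional
``#`` comment lines, labelled dense TSV matrices, standard FASTA, and a
2-column EC-number TSV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "EntityRegistry",
    "SimilarityMatrix",
    "InteractionTable",
    "DDINetwork",
    "SideEffectProfiles",
    "FingerprintSet",
    "PredictionTable",
    "ParseError",
    "read_edge_list",
    "write_edge_list",
    "read_fasta",
    "write_fasta",
    "read_matrix",
    "write_matrix",
    "read_ec_table",
    "write_ec_table",
]

SYMMETRY_TOL = 1e-9


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class EntityRegistry:
    """Ordered set of unique identifier strings with O(1) positional lookup."""

    ids: tuple[str, ...]
    index: Mapping[str, int] = field(repr=False, compare=False, default=None)

    def __post_init__(self):
        if self.index is None:
            object.__setattr__(self, "index", {e: i for i, e in enumerate(self.ids)})
        if len(self.index) != len(self.ids):
            dupes = [e for e in self.ids if sum(1 for x in self.ids if x == e) > 1]
            raise ValueError(f"duplicate identifiers in registry: {sorted(set(dupes))[:5]}")

    @classmethod
    def from_iterable(cls, ids: Iterable[str]) -> "EntityRegistry":
        """Build a registry preserving first-appearance order, dropping repeats."""
        seen: dict[str, None] = {}
        for e in ids:
            seen.setdefault(str(e), None)
        return cls(tuple(seen))

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self) -> Iterator[str]:
        return iter(self.ids)

    def __contains__(self, item: str) -> bool:
        return item in self.index

    def positions(self, ids: Iterable[str]) -> np.ndarray:
        return np.array([self.index[e] for e in ids], dtype=np.intp)


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity (kernel) matrix over a registry of entities."""

    entities: EntityRegistry
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.entities)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("similarity matrix contains non-finite entries")
        asym = np.abs(self.values - self.values.T).max() if n else 0.0
        if asym > SYMMETRY_TOL:
            raise ValueError(f"matrix not symmetric (max |K - K.T| = {asym:.3g})")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = pair
        return float(self.values[self.entities.index[i], self.entities.index[j]])

    def min_eigenvalue(self) -> float:
        from scipy.linalg import eigvalsh

        return float(eigvalsh(self.values, subset_by_index=[0, 0])[0])


@dataclass
class InteractionTable:
    """Binary drug x protein incidence; absent pairs mean *unknown*, not absent."""

    drugs: EntityRegistry
    proteins: EntityRegistry
    pairs: frozenset[tuple[str, str]]

    def __post_init__(self):
        self.pairs = frozenset(self.pairs)
        for d, p in self.pairs:
            if d not in self.drugs or p not in self.proteins:
                raise ValueError(f"pair ({d}, {p}) references unregistered id")

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.pairs

    def label_matrix(self) -> np.ndarray:
        """Dense 0/1 incidence in registry order (drugs x proteins)."""
        y = np.zeros((len(self.drugs), len(self.proteins)), dtype=np.int8)
        for d, p in self.pairs:
            y[self.drugs.index[d], self.proteins.index[p]] = 1
        return y

    def targets_of(self, drug: str) -> set[str]:
        return {p for d, p in self.pairs if d == drug}

    def drugs_of(self, protein: str) -> set[str]:
        return {d for d, p in self.pairs if p == protein}


@dataclass
class DDINetwork:
    """Undirected drug-drug interaction graph (no self-loops)."""

    drugs: EntityRegistry
    edges: frozenset[frozenset[str]]

    def __post_init__(self):
        canon = set()
        for e in self.edges:
            a, b = tuple(e) if len(e) == 2 else (next(iter(e)),) * 2
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            if a not in self.drugs or b not in self.drugs:
                raise ValueError(f"edge ({a}, {b}) references unregistered drug")
            canon.add(frozenset((a, b)))
        self.edges = frozenset(canon)

    @classmethod
    def from_pairs(cls, drugs: EntityRegistry, pairs: Iterable[tuple[str, str]]) -> "DDINetwork":
        return cls(drugs, frozenset(frozenset(p) for p in pairs))

    def has_edge(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.edges

    def adjacency(self) -> np.ndarray:
        n = len(self.drugs)
        a = np.zeros((n, n))
        for e in self.edges:
            u, v = tuple(e)
            i, j = self.drugs.index[u], self.drugs.index[v]
            a[i, j] = a[j, i] = 1.0
        return a


@dataclass
class SideEffectProfiles:
    """Drug -> side-effect assignments (binary profiles)."""

    drugs: EntityRegistry
    side_effects: EntityRegistry
    assignments: frozenset[tuple[str, str]]

    def __post_init__(self):
        self.assignments = frozenset(self.assignments)
        for d, s in self.assignments:
            if d not in self.drugs or s not in self.side_effects:
                raise ValueError(f"assignment ({d}, {s}) references unregistered id")

    def profile(self, drug: str) -> set[str]:
        return {s for d, s in self.assignments if d == drug}

    def carriers(self, side_effect: str) -> set[str]:
        return {d for d, s in self.assignments if s == side_effect}

    def indicator(self) -> np.ndarray:
        """Dense drugs x side-effects 0/1 matrix in registry order."""
        m = np.zeros((len(self.drugs), len(self.side_effects)), dtype=np.int8)
        for d, s in self.assignments:
            m[self.drugs.index[d], self.side_effects.index[s]] = 1
        return m


@dataclass
class FingerprintSet:
    """Per-drug fingerprint vectors: binary bit-sets or signature counts."""

    drugs: EntityRegistry
    width: int
    vectors: np.ndarray
    mode: str = "binary"

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors)
        if self.mode not in ("binary", "count"):
            raise ValueError(f"mode must be 'binary' or 'count', got {self.mode!r}")
        if self.width <= 0:
            raise ValueError("width must be positive")
        if self.vectors.shape != (len(self.drugs), self.width):
            raise ValueError(
                f"vectors shape {self.vectors.shape} != ({len(self.drugs)}, {self.width})"
            )
        if np.any(self.vectors < 0):
            raise ValueError("fingerprint entries must be non-negative")
        if self.mode == "binary" and not np.all(np.isin(self.vectors, (0, 1))):
            raise ValueError("binary fingerprints must contain only 0/1")


@dataclass
class PredictionTable:
    """Interaction probability per (drug, protein) pair."""

    drugs: EntityRegistry
    proteins: EntityRegistry
    scores: dict[tuple[str, str], float]

    def __post_init__(self):
        for (d, p), s in self.scores.items():
            if d not in self.drugs or p not in self.proteins:
                raise ValueError(f"score key ({d}, {p}) references unregistered id")
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"score {s} for ({d}, {p}) outside [0, 1]")


# ---------------------------------------------------------------------------
# readers / writers


def _iter_tsv_rows(path) -> Iterator[tuple[int, list[str]]]:
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_edge_list(path, kind: str):
    """Read a 2-column TSV edge list.

    ``kind`` selects the returned type: ``ddi`` -> :class:`DDINetwork`,
    ``dti`` -> :class:`InteractionTable`, ``side_effect`` ->
    :class:`SideEffectProfiles`.  Registries follow column-wise first
    appearance; duplicate rows collapse; DDI self-loops are dropped with a
    warning.
    """
    if kind not in ("ddi", "dti", "side_effect"):
        raise ValueError(f"unknown edge-list kind {kind!r}")
    left: dict[str, None] = {}
    right: dict[str, None] = {}
    rows: list[tuple[str, str]] = []
    n_self = 0
    for lineno, fields in _iter_tsv_rows(path):
        if len(fields) != 2:
            raise ParseError(f"{path}: line {lineno}: expected 2 tab-separated columns, got {len(fields)}")
        a, b = fields[0].strip(), fields[1].strip()
        if not a or not b:
            raise ParseError(f"{path}: line {lineno}: empty identifier")
        if kind == "ddi" and a == b:
            n_self += 1
            continue
        left.setdefault(a)
        right.setdefault(b)
        rows.append((a, b))
    if n_self:
        warnings.warn(f"{path}: dropped {n_self} self-loop(s) from DDI edge list")
    if kind == "ddi":
        drugs = EntityRegistry.from_iterable(list(left) + [b for b in right if b not in left])
        return DDINetwork.from_pairs(drugs, rows)
    if kind == "dti":
        return InteractionTable(
            EntityRegistry.from_iterable(left),
            EntityRegistry.from_iterable(right),
            frozenset(rows),
        )
    return SideEffectProfiles(
        EntityRegistry.from_iterable(left),
        EntityRegistry.from_iterable(right),
        frozenset(rows),
    )


def write_edge_list(obj, path) -> None:
    """Write a DDI network, interaction table, or side-effect profile as TSV."""
    if isinstance(obj, DDINetwork):
        rows = sorted(tuple(sorted(e)) for e in obj.edges)
    elif isinstance(obj, InteractionTable):
        rows = sorted(obj.pairs)
    elif isinstance(obj, SideEffectProfiles):
        rows = sorted(obj.assignments)
    else:
        raise TypeError(f"cannot write {type(obj).__name__} as edge list")
    with open(path, "wt", encoding="utf-8") as fh:
        for a, b in rows:
            fh.write(f"{a}\t{b}\n")


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into ``{id: SEQUENCE}`` (upper-cased, first header token)."""
    out: dict[str, str] = {}
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # pragma: no cover - biopython raises rarely here
        raise ParseError(f"{path}: not parseable as FASTA: {exc}") from exc
    if not records:
        # SeqIO silently yields nothing for garbage input; detect that.
        with open(path, "rt", encoding="utf-8") as fh:
            content = fh.read()
        if content.strip() and not content.lstrip().startswith(">"):
            raise ParseError(f"{path}: not FASTA (no '>' header)")
    for rec in records:
        pid = rec.id
        seq = str(rec.seq).upper()
        if pid in out:
            raise ParseError(f"{path}: duplicate sequence id {pid!r}")
        if not seq:
            raise ParseError(f"{path}: empty sequence for {pid!r}")
        out[pid] = seq
    return out


def write_fasta(seqs: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for pid, seq in seqs.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_matrix(m: SimilarityMatrix, path) -> None:
    """Write a labelled similarity matrix as TSV (ids as header row/column)."""
    df = pd.DataFrame(m.values, index=list(m.entities.ids), columns=list(m.entities.ids))
    df.to_csv(path, sep="\t", float_format="%.17g", index_label="")


def read_matrix(path) -> SimilarityMatrix:
    """Read a labelled matrix TSV; validates squareness and symmetry."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids_r = [str(x) for x in df.index]
    ids_c = [str(x) for x in df.columns]
    if ids_r != ids_c:
        raise ParseError(f"{path}: row and column labels differ")
    values = df.to_numpy(dtype=float)
    asym = np.abs(values - values.T).max() if len(values) else 0.0
    if asym > SYMMETRY_TOL:
        raise ParseError(f"{path}: matrix asymmetric (max |K - K.T| = {asym:.3g})")
    values = (values + values.T) / 2.0
    return SimilarityMatrix(EntityRegistry.from_iterable(ids_r), values)


def read_ec_table(path) -> dict[str, str]:
    """Read protein-id -> EC string TSV ('-' marks unknown trailing fields)."""
    out: dict[str, str] = {}
    for lineno, fields in _iter_tsv_rows(path):
        if len(fields) != 2:
            raise ParseError(f"{path}: line {lineno}: expected 2 columns")
        pid, ec = fields[0].strip(), fields[1].strip()
        if pid in out:
            raise ParseError(f"{path}: line {lineno}: duplicate protein id {pid!r}")
        out[pid] = ec
    return out


def write_ec_table(ecs: Mapping[str, str], path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for pid, ec in ecs.items():
            fh.write(f"{pid}\t{ec}\n")


def aligned(matrices: Iterable[SimilarityMatrix]) -> list[SimilarityMatrix]:
    """Validate that all matrices share one registry order; return them as a list."""
    ms = list(matrices)
    if not ms:
        raise ValueError("no matrices given")
    ref = ms[0].entities.ids
    for m in ms[1:]:
        if m.entities.ids != ref:
            raise ValueError("similarity matrices have mismatched entity registries")
    return ms
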