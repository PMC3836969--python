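"""Joint synthetic data with latent module structure.

All modalities hang off one latent assignment of drugs and proteins to
modules (think pharmacological classes): drug-target edges are dense within
a module and sparse across, the DDI network is enriched among drugs of the
same module, side-effect profiles and fingerprints are drawn from per-module
pools/templates with configurable noise, protein sequences mutate from a
per-module ancestor, and EC numbers share a module-determined 3-field
prefix.  Coupling strengths are independent knobs, so each kernel's
informativeness can be dialed separately; a single seeded generator stream
makes every dataset bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core_io import (
    DDINetwork,
    EntityRegistry,
    FingerprintSet,
    InteractionTable,
    SideEffectProfiles,
    write_ec_table,
    write_edge_list,
    write_fasta,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "generate",
    "write_dataset",
    "read_fingerprints",
    "PRESETS",
]

AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator knobs.

    ``p_in``/``p_out``: drug-target edge probability when drug and protein
    share a module / do not.  ``q_in``/``q_out``: same for drug-drug edges.
    ``se_noise`` is the per-assignment probability that a drawn side effect
    is swapped for a random pool-wide one; ``fp_flip_prob`` the per-bit flip
    probability away from the module fingerprint template; ``seq_mut_prob``
    the per-site substitution rate from the module ancestor sequence.
    """

    n_drugs: int = 150
    n_proteins: int = 60
    n_modules: int = 5
    p_in: float = 0.9
    p_out: float = 0.02
    q_in: float = 0.6
    q_out: float = 0.02
    se_pool_size: int = 100
    se_per_drug: int = 8
    se_noise: float = 0.2
    fp_width: int = 128
    fp_module_bits: int = 24
    fp_flip_prob: float = 0.45
    seq_length: int = 120
    seq_mut_prob: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for name in ("p_in", "p_out", "q_in", "q_out", "se_noise", "fp_flip_prob", "seq_mut_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_modules > min(self.n_drugs, self.n_proteins):
            raise ValueError("n_modules cannot exceed min(n_drugs, n_proteins)")
        if self.n_modules < 1 or self.n_drugs < 1 or self.n_proteins < 1:
            raise ValueError("counts must be positive")
        if self.fp_module_bits > self.fp_width:
            raise ValueError("fp_module_bits cannot exceed fp_width")
        if self.se_per_drug > self.se_pool_size:
            raise ValueError("se_per_drug cannot exceed se_pool_size")


#: Named presets: ``signal`` couples DDI strongly and fingerprints weakly
#: (DDI kernel should win); ``chem-strong`` reverses that; ``null`` removes
#: all module structure from the drug-target edges.
PRESETS: dict[str, dict] = {
    "signal": {},
    "null": {"p_in": 0.1, "p_out": 0.1},
    "chem-strong": {"q_in": 0.05, "q_out": 0.02, "fp_flip_prob": 0.05},
}


@dataclass
class SyntheticDataset:
    """All generated inputs plus the ground-truth module assignments."""

    dti: InteractionTable
    ddi: DDINetwork
    side_effects: SideEffectProfiles
    fingerprints: FingerprintSet
    sequences: dict[str, str]
    ecs: dict[str, str]
    drug_modules: dict[str, int]
    protein_modules: dict[str, int]
    config: SyntheticConfig


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Draw one dataset; identical config (incl. seed) gives identical output."""
    rng = np.random.default_rng(config.seed)
    nd, np_, nm = config.n_drugs, config.n_proteins, config.n_modules

    drug_ids = tuple(f"d{i:04d}" for i in range(nd))
    prot_ids = tuple(f"p{i:04d}" for i in range(np_))
    drugs = EntityRegistry(drug_ids)
    proteins = EntityRegistry(prot_ids)

    # module assignments: one guaranteed member per module, rest uniform
    d_mod = np.concatenate([np.arange(nm), rng.integers(0, nm, nd - nm)])
    p_mod = np.concatenate([np.arange(nm), rng.integers(0, nm, np_ - nm)])

    # drug-target edges
    same = d_mod[:, None] == p_mod[None, :]
    prob = np.where(same, config.p_in, config.p_out)
    dti_mask = rng.random((nd, np_)) < prob
    dti_pairs = frozenset(
        (drug_ids[i], prot_ids[j]) for i, j in zip(*np.nonzero(dti_mask))
    )

    # drug-drug edges (upper triangle only)
    same_d = d_mod[:, None] == d_mod[None, :]
    qprob = np.where(same_d, config.q_in, config.q_out)
    upper = rng.random((nd, nd)) < qprob
    iu, ju = np.triu_indices(nd, k=1)
    edge_pairs = [(drug_ids[i], drug_ids[j]) for i, j in zip(iu, ju) if upper[i, j]]
    ddi = DDINetwork.from_pairs(drugs, edge_pairs)

    # side effects: module pools partition the global pool
    se_ids = tuple(f"se{i:04d}" for i in range(config.se_pool_size))
    pool_of = np.arange(config.se_pool_size) % nm
    assignments = set()
    for i in range(nd):
        pool = np.flatnonzero(pool_of == d_mod[i])
        n_draw = min(config.se_per_drug, pool.size)
        chosen = rng.choice(pool, size=n_draw, replace=False)
        swap = rng.random(n_draw) < config.se_noise
        chosen[swap] = rng.integers(0, config.se_pool_size, int(swap.sum()))
        for s in chosen:
            assignments.add((drug_ids[i], se_ids[s]))
    side_effects = SideEffectProfiles(drugs, EntityRegistry(se_ids), frozenset(assignments))

    # fingerprints: module templates with per-bit flips
    templates = np.zeros((nm, config.fp_width), dtype=np.int8)
    for m in range(nm):
        on = rng.choice(config.fp_width, size=config.fp_module_bits, replace=False)
        templates[m, on] = 1
    flips = rng.random((nd, config.fp_width)) < config.fp_flip_prob
    vectors = np.where(flips, 1 - templates[d_mod], templates[d_mod]).astype(np.int8)
    fingerprints = FingerprintSet(drugs, config.fp_width, vectors, mode="binary")

    # protein sequences from per-module ancestors
    aa = np.array(list(AA))
    ancestors = rng.integers(0, len(AA), (nm, config.seq_length))
    sequences = {}
    for j in range(np_):
        seq = ancestors[p_mod[j]].copy()
        mut = rng.random(config.seq_length) < config.seq_mut_prob
        seq[mut] = rng.integers(0, len(AA), int(mut.sum()))
        sequences[prot_ids[j]] = "".join(aa[seq])

    # EC numbers: 3-field module prefix, random 4th field
    ecs = {
        prot_ids[j]: f"{p_mod[j] + 1}.{p_mod[j] + 1}.{p_mod[j] + 1}.{rng.integers(1, 100)}"
        for j in range(np_)
    }

    return SyntheticDataset(
        dti=InteractionTable(drugs, proteins, dti_pairs),
        ddi=ddi,
        side_effects=side_effects,
        fingerprints=fingerprints,
        sequences=sequences,
        ecs=ecs,
        drug_modules={drug_ids[i]: int(d_mod[i]) for i in range(nd)},
        protein_modules={prot_ids[j]: int(p_mod[j]) for j in range(np_)},
        config=config,
    )


def write_dataset(ds: SyntheticDataset, directory, force: bool = False) -> None:
    """Write every component in core_io formats plus a manifest JSON."""
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    if any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty (use force=True to overwrite)")
    write_edge_list(ds.dti, out / "dti.tsv")
    write_edge_list(ds.ddi, out / "ddi.tsv")
    write_edge_list(ds.side_effects, out / "side_effects.tsv")
    write_fasta(ds.sequences, out / "proteins.fasta")
    write_ec_table(ds.ecs, out / "ec.tsv")
    with open(out / "fingerprints.tsv", "wt", encoding="utf-8") as fh:
        fh.write("# drug\t" + "\t".join(f"b{i}" for i in range(ds.fingerprints.width)) + "\n")
        for i, d in enumerate(ds.fingerprints.drugs.ids):
            fh.write(d + "\t" + "\t".join(map(str, ds.fingerprints.vectors[i])) + "\n")
    manifest = {
        "config": dataclasses.asdict(ds.config),
        "drug_modules": ds.drug_modules,
        "protein_modules": ds.protein_modules,
    }
    with open(out / "manifest.json", "wt", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_fingerprints(path) -> FingerprintSet:
    """Read the fingerprint TSV written by :func:`write_dataset`."""
    ids = []
    rows = []
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            ids.append(parts[0])
            rows.append([int(x) for x in parts[1:]])
    vectors = np.array(rows, dtype=np.int8)
    mode = "binary" if np.all(np.isin(vectors, (0, 1))) else "count"
    return FingerprintSet(EntityRegistry.from_iterable(ids), vectors.shape[1], vectors, mode=mode)
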