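"""Ligand chemistry: bond perception, path fingerprints, Tanimoto similarity,
maximum-common-substructure atom equivalence, and leader clustering.

Ligands come from HETATM records, where bond orders and protonation are
unreliable, so everything here works on element-labelled heavy-atom graphs:
bonds are perceived from interatomic distances against covalent radii, the
fingerprint hashes linear element paths (lengths 1-7 atoms) into 1024 bits,
and the common substructure is a connected induced common subgraph matched
on element labels only.
"""

from __future__ import annotations

import logging
import time
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .structures import LigandInstance

logger = logging.getLogger("pocketbench.chem")

FINGERPRINT_BITS = 1024
MAX_PATH_ATOMS = 7
#: scale factor applied to the sum of covalent radii when perceiving bonds
BOND_TOLERANCE = 1.15
#: atoms closer than this are treated as a corrupt structure (A)
OVERLAP_THRESHOLD = 0.5

#: single-bond covalent radii (A), Cordero et al. consensus values
COVALENT_RADII = {
    "H": 0.31, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "SI": 1.11, "P": 1.07, "S": 1.05, "CL": 1.02, "BR": 1.20, "I": 1.39,
    "SE": 1.20, "AS": 1.19, "FE": 1.32, "ZN": 1.22, "MG": 1.41, "MN": 1.39,
}
_DEFAULT_RADIUS = 1.0


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class MoleculeGraph:
    """Simple undirected heavy-atom graph labelled by element."""

    elements: list[str]
    bonds: list[tuple[int, int]]
    name: str = ""

    def __post_init__(self) -> None:
        n = len(self.elements)
        norm = []
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(f"invalid bond ({i},{j}) for {n} atoms")
            norm.append((min(i, j), max(i, j)))
        self.bonds = sorted(set(norm))

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def adjacency(self) -> list[set[int]]:
        adj: list[set[int]] = [set() for _ in range(self.n_atoms)]
        for i, j in self.bonds:
            adj[i].add(j)
            adj[j].add(i)
        return adj

    def bond_set(self) -> set[tuple[int, int]]:
        return set(self.bonds)


@dataclass
class Fingerprint:
    bits: frozenset[int]
    n_bits: int = FINGERPRINT_BITS

    def __post_init__(self) -> None:
        if any(not 0 <= b < self.n_bits for b in self.bits):
            raise ValueError("fingerprint bit out of range")

    def to_hex(self) -> str:
        v = 0
        for b in self.bits:
            v |= 1 << b
        return f"{v:0{self.n_bits // 4}x}"

    @classmethod
    def from_hex(cls, hexstr: str, n_bits: int = FINGERPRINT_BITS) -> "Fingerprint":
        v = int(hexstr, 16)
        return cls(frozenset(b for b in range(n_bits) if v >> b & 1), n_bits)


@dataclass
class AtomEquivalence:
    """One-to-one element-preserving atom mapping between two molecules."""

    pairs: list[tuple[int, int]]
    truncated: bool = False

    def __post_init__(self) -> None:
        a_side = [a for a, _ in self.pairs]
        b_side = [b for _, b in self.pairs]
        if len(set(a_side)) != len(a_side) or len(set(b_side)) != len(b_side):
            raise ValueError("atom equivalence must be one-to-one")

    @property
    def size(self) -> int:
        return len(self.pairs)

    def mapping(self) -> dict[int, int]:
        return dict(self.pairs)

    def inverted(self) -> "AtomEquivalence":
        return AtomEquivalence([(b, a) for a, b in self.pairs], self.truncated)

    @classmethod
    def identity(cls, n: int) -> "AtomEquivalence":
        return cls([(i, i) for i in range(n)])


# ---------------------------------------------------------------------------
# Bond perception
# ---------------------------------------------------------------------------

def perceive_molecule(ligand: LigandInstance) -> MoleculeGraph:
    """Infer the heavy-atom bond graph of a ligand from coordinates.

    A bond is placed between atoms closer than
    ``BOND_TOLERANCE * (r_cov(a) + r_cov(b))``. Disconnected graphs are
    returned (and logged); atoms closer than 0.5 A raise an error.
    """
    coords = ligand.coords()
    elements = [a.element.upper() for a in ligand.atoms]
    n = len(elements)
    bonds: list[tuple[int, int]] = []
    if n > 1:
        dmat = squareform(pdist(coords))
        for i in range(n):
            for j in range(i + 1, n):
                if dmat[i, j] < OVERLAP_THRESHOLD:
                    raise ValueError(
                        f"overlapping atoms {i},{j} at {dmat[i, j]:.2f} A")
                rsum = (COVALENT_RADII.get(elements[i], _DEFAULT_RADIUS)
                        + COVALENT_RADII.get(elements[j], _DEFAULT_RADIUS))
                if dmat[i, j] <= BOND_TOLERANCE * rsum:
                    bonds.append((i, j))
    mol = MoleculeGraph([a.element for a in ligand.atoms], bonds,
                        name=ligand.res_name)
    if _n_components(mol) > 1:
        logger.info("molecule %s perceived as disconnected", ligand.res_name)
    return mol


def _n_components(mol: MoleculeGraph) -> int:
    adj = mol.adjacency()
    seen: set[int] = set()
    n_comp = 0
    for start in range(mol.n_atoms):
        if start in seen:
            continue
        n_comp += 1
        stack = [start]
        while stack:
            v = stack.pop()
            if v in seen:
                continue
            seen.add(v)
            stack.extend(adj[v] - seen)
    return n_comp


# ---------------------------------------------------------------------------
# Fingerprints and Tanimoto
# ---------------------------------------------------------------------------

def path_fingerprint(mol: MoleculeGraph) -> Fingerprint:
    """1024-bit fingerprint of hashed linear element paths (1-7 atoms).

    Every simple path is canonicalized to the lexicographically smaller of
    its two read directions and hashed with CRC-32, so the fingerprint is
    deterministic across runs, platforms and atom orderings.
    """
    adj = mol.adjacency()
    elems = [e.upper() for e in mol.elements]
    paths: set[str] = set()

    def extend(path: list[int]) -> None:
        seq = "-".join(elems[i] for i in path)
        rev = "-".join(elems[i] for i in reversed(path))
        paths.add(min(seq, rev))
        if len(path) == MAX_PATH_ATOMS:
            return
        for nxt in adj[path[-1]]:
            if nxt not in path:
                extend(path + [nxt])

    for start in range(mol.n_atoms):
        extend([start])

    bits = frozenset(zlib.crc32(p.encode()) % FINGERPRINT_BITS for p in paths)
    return Fingerprint(bits)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |a&b| / |a|b| of two bit sets; 0 if both empty."""
    if a.n_bits != b.n_bits:
        raise ValueError("fingerprint length mismatch")
    union = len(a.bits | b.bits)
    if union == 0:
        return 0.0
    return len(a.bits & b.bits) / union


# ---------------------------------------------------------------------------
# Maximum common substructure
# ---------------------------------------------------------------------------

def mcs_atom_equivalence(
    mol_a: MoleculeGraph,
    mol_b: MoleculeGraph,
    time_budget: float = 30.0,
) -> AtomEquivalence:
    """Maximum connected common substructure under element-label matching.

    Backtracking search for the largest connected *induced* common subgraph:
    matched atoms share an element and every atom pair in the mapping is
    bonded in one molecule iff bonded in the other. On time-budget expiry
    the best mapping found so far is returned with ``truncated=True``.
    An empty mapping is legal when the element sets are disjoint.
    """
    if mol_a.n_atoms == 0 or mol_b.n_atoms == 0:
        raise ValueError("MCS requires two non-empty molecules")

    elems_a = [e.upper() for e in mol_a.elements]
    elems_b = [e.upper() for e in mol_b.elements]
    adj_a = mol_a.adjacency()
    adj_b = mol_b.adjacency()
    deadline = time.monotonic() + time_budget

    best: list[tuple[int, int]] = []
    truncated = False
    upper = min(
        sum(min(elems_a.count(e), elems_b.count(e)) for e in set(elems_a)),
        mol_a.n_atoms, mol_b.n_atoms,
    )

    def compatible(i: int, j: int, mapping: dict[int, int]) -> bool:
        # induced-subgraph condition against every already-mapped pair
        for i2, j2 in mapping.items():
            if (i2 in adj_a[i]) != (j2 in adj_b[j]):
                return False
        return True

    def grow(mapping: dict[int, int],
             excluded: frozenset[tuple[int, int]]) -> None:
        nonlocal best, truncated
        if truncated or time.monotonic() > deadline:
            truncated = True
            return
        if len(mapping) > len(best):
            best = list(mapping.items())
        mapped_b = set(mapping.values())
        candidates = [
            (a, b)
            for i in mapping
            for a in adj_a[i] if a not in mapping
            for b in adj_b[mapping[i]] if b not in mapped_b
            if elems_a[a] == elems_b[b] and (a, b) not in excluded
            and compatible(a, b, mapping)
        ]
        # bound: per-element count of unmapped atoms still matchable
        if not candidates:
            return
        unmapped_a = [elems_a[a] for a in range(len(elems_a))
                      if a not in mapping]
        unmapped_b = [elems_b[b] for b in range(len(elems_b))
                      if b not in mapped_b]
        slack = sum(min(unmapped_a.count(e), unmapped_b.count(e))
                    for e in set(unmapped_a))
        if len(mapping) + slack <= len(best):
            return
        seen_here: set[tuple[int, int]] = set()
        for a, b in sorted(set(candidates)):
            mapping[a] = b
            grow(mapping, excluded | frozenset(seen_here))
            del mapping[a]
            seen_here.add((a, b))
            if len(best) >= upper or truncated:
                return

    # seed every element-compatible atom pair, excluding seeds already tried
    tried_seeds: set[tuple[int, int]] = set()
    for i in range(mol_a.n_atoms):
        if len(best) >= upper or truncated:
            break
        for j in range(mol_b.n_atoms):
            if elems_a[i] != elems_b[j]:
                continue
            grow({i: j}, frozenset(tried_seeds))
            tried_seeds.add((i, j))
            if len(best) >= upper or truncated:
                break

    if truncated:
        logger.warning("MCS search truncated by time budget (best=%d)", len(best))
    return AtomEquivalence(sorted(best), truncated=truncated)


# ---------------------------------------------------------------------------
# Leader clustering
# ---------------------------------------------------------------------------

def leader_cluster(
    mols: list[MoleculeGraph],
    threshold: float = 0.7,
    fingerprints: list[Fingerprint] | None = None,
) -> list[int]:
    """Deterministic leader clustering on fingerprint Tanimoto similarity.

    Molecules are processed in descending heavy-atom count (ties keep input
    order); each joins the first existing cluster representative with
    TC >= ``threshold``, otherwise it founds a new cluster. Returns the
    cluster index of each input molecule (input order).
    """
    if not mols:
        return []
    fps = fingerprints or [path_fingerprint(m) for m in mols]
    order = sorted(range(len(mols)), key=lambda i: (-mols[i].n_atoms, i))
    reps: list[int] = []  # representative molecule index per cluster
    assignment = [-1] * len(mols)
    for idx in order:
        for cluster_id, rep in enumerate(reps):
            if tanimoto(fps[idx], fps[rep]) >= threshold:
                assignment[idx] = cluster_id
                break
        else:
            assignment[idx] = len(reps)
            reps.append(idx)
    return assignment
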