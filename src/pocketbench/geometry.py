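"""Rigid-body superposition and alignment-quality geometry.

Two geometric primitives drive the benchmark:

* the *reference alignment* between two pockets — superpose the bound
  ligands on their chemically equivalent atoms, then pair binding residues
  one-to-one by minimum-cost assignment on Calpha distances; and
* the *ligand RMSD of an alignment* — superpose the two proteins on the
  Calpha atoms of aligned binding residues and measure the RMSD over
  equivalent ligand heavy atoms. A low value means the alignment places
  the two ligands on top of each other, i.e. it is geometrically correct.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .chem import AtomEquivalence
from .structures import ComplexRecord, ResidueId

#: Calpha-Calpha distance admitting a residue pair into a reference alignment (A)
PAIR_CUTOFF = 5.0


@dataclass
class RigidTransform:
    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det = +1)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


@dataclass
class SuperpositionResult:
    transform: RigidTransform
    rmsd: float
    n_fitted: int


@dataclass
class PocketAlignment:
    """Ordered one-to-one residue correspondences between two pockets."""

    pairs: list[tuple[ResidueId, ResidueId]]
    method: str = "other"
    score: float | None = None
    ligand_rmsd: float | None = None

    def __post_init__(self) -> None:
        a_side = [a for a, _ in self.pairs]
        b_side = [b for _, b in self.pairs]
        if len(set(a_side)) != len(a_side) or len(set(b_side)) != len(b_side):
            raise ValueError("pocket alignment must be one-to-one")

    def __len__(self) -> int:
        return len(self.pairs)

    def pair_set(self) -> set[tuple[ResidueId, ResidueId]]:
        return set(self.pairs)

    def to_tsv(self) -> str:
        score = "" if self.score is None else f"{self.score:g}"
        rows = [f"# method={self.method}\tscore={score}",
                "chainA\tresA\ticodeA\tchainB\tresB\ticodeB"]
        for a, b in self.pairs:
            rows.append(f"{a.chain_id}\t{a.seq_num}\t{a.icode}\t"
                        f"{b.chain_id}\t{b.seq_num}\t{b.icode}")
        return "\n".join(rows) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "PocketAlignment":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        method, score = "other", None
        if lines and lines[0].startswith("#"):
            for tok in lines.pop(0).lstrip("# ").split("\t"):
                key, _, val = tok.partition("=")
                if key == "method":
                    method = val
                elif key == "score" and val:
                    score = float(val)
        pairs = []
        for ln in lines[1:]:  # skip header
            ca, ra, ia, cb, rb, ib = (ln.split("\t") + [""] * 6)[:6]
            pairs.append((ResidueId(ca, int(ra), ia), ResidueId(cb, int(rb), ib)))
        return cls(pairs, method=method, score=score)


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

def kabsch_fit(coords_a: np.ndarray, coords_b: np.ndarray) -> SuperpositionResult:
    """Least-squares optimal proper rotation + translation of B onto A.

    SVD of the cross-covariance with the usual determinant sign correction
    so reflections are never returned. Degenerate (collinear) point sets
    and sets of fewer than 3 points are rejected.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("coordinate arrays must both be (n, 3)")
    n = A.shape[0]
    if n < 3:
        raise ValueError("kabsch_fit requires at least 3 points")
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(B))):
        raise ValueError("non-finite coordinates")

    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    for M in (A0, B0):
        s = np.linalg.svd(M, compute_uv=False)
        if s[1] < 1e-9:
            raise ValueError("degenerate (collinear) point set")

    H = B0.T @ A0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ca - R @ cb
    transform = RigidTransform(R, t)
    rmsd = float(np.sqrt(np.mean(np.sum((transform.apply(B) - A) ** 2, axis=1))))
    return SuperpositionResult(transform, rmsd, n)


# ---------------------------------------------------------------------------
# Reference alignments and ligand RMSD
# ---------------------------------------------------------------------------

def _eq_ligand_coords(rec_a: ComplexRecord, rec_b: ComplexRecord,
                      eq: AtomEquivalence) -> tuple[np.ndarray, np.ndarray]:
    ca = rec_a.ligand.coords()
    cb = rec_b.ligand.coords()
    ia = [i for i, _ in eq.pairs]
    ib = [j for _, j in eq.pairs]
    return ca[ia], cb[ib]


def reference_alignment(
    rec_a: ComplexRecord,
    rec_b: ComplexRecord,
    eq: AtomEquivalence,
    pair_cutoff: float = PAIR_CUTOFF,
) -> PocketAlignment:
    """Ground-truth residue correspondence induced by ligand superposition.

    Complex B is superposed onto A over the equivalent ligand atoms, then
    binding residues are paired one-to-one by minimum-total-distance
    assignment on Calpha-Calpha distances, admitting only pairs within
    ``pair_cutoff``. The ligand RMSD over equivalent atoms after the
    superposition is recorded on the returned alignment.
    """
    if eq.size < 3:
        raise ValueError("ligand atom equivalence must have >= 3 pairs")
    lig_a, lig_b = _eq_ligand_coords(rec_a, rec_b, eq)
    sup = kabsch_fit(lig_a, lig_b)

    rids_a = [r for r in rec_a.binding_residues if rec_a.ca_coord(r) is not None]
    rids_b = [r for r in rec_b.binding_residues if rec_b.ca_coord(r) is not None]
    if not rids_a or not rids_b:
        return PocketAlignment([], method="reference", ligand_rmsd=sup.rmsd)

    ca_a = np.array([rec_a.ca_coord(r) for r in rids_a])
    ca_b = sup.transform.apply(np.array([rec_b.ca_coord(r) for r in rids_b]))
    dists = np.linalg.norm(ca_a[:, None, :] - ca_b[None, :, :], axis=2)

    # Hungarian assignment; inadmissible pairs get a large finite cost and
    # are filtered from the solution afterwards
    big = pair_cutoff * 1e6
    cost = np.where(dists <= pair_cutoff, dists, big)
    rows, cols = linear_sum_assignment(cost)
    pairs = [(rids_a[i], rids_b[j]) for i, j in zip(rows, cols)
             if dists[i, j] <= pair_cutoff]
    # present pairs in A's sequence order, the convention for alignments
    pairs.sort(key=lambda p: rec_a.sequence_position(p[0]))
    return PocketAlignment(pairs, method="reference", ligand_rmsd=sup.rmsd)


def ligand_rmsd_of_alignment(
    aln: PocketAlignment,
    rec_a: ComplexRecord,
    rec_b: ComplexRecord,
    eq: AtomEquivalence,
) -> float:
    """RMSD over equivalent ligand heavy atoms after superposing the proteins
    on the Calpha atoms of the aligned binding residues."""
    ca_pairs = [
        (rec_a.ca_coord(a), rec_b.ca_coord(b))
        for a, b in aln.pairs
        if rec_a.ca_coord(a) is not None and rec_b.ca_coord(b) is not None
    ]
    if len(ca_pairs) < 3:
        raise ValueError(
            f"need >= 3 aligned residue pairs with Calpha atoms, "
            f"have {len(ca_pairs)}")
    A = np.array([p[0] for p in ca_pairs])
    B = np.array([p[1] for p in ca_pairs])
    sup = kabsch_fit(A, B)
    lig_a, lig_b = _eq_ligand_coords(rec_a, rec_b, eq)
    moved = sup.transform.apply(lig_b)
    return float(np.sqrt(np.mean(np.sum((moved - lig_a) ** 2, axis=1))))
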