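"""Scalar statistics of pocket similarity and alignment quality.

* SSC — Szymkiewicz-Simpson overlap of two typed contact lists,
  ``|A n B| / min(|A|, |B|)``; two contacts match when their ligand atoms
  are chemically equivalent and their residues fall in the same group
  (I-VIII), and the intersection is a maximum one-to-one matching.
* Kendall tau (tau-a) — ordinal association of a pocket alignment:
  ``tau = (n_C - n_D) / (n(n-1)/2)`` over all alignment-position pairs;
  1 for fully sequential alignments, -1 for reversed, ~0 for sequence
  order-independent ones.
* Spearman rho — rank correlation of two virtual-screening rankings:
  ``rho = 1 - 6 sum(d_i^2) / (n(n^2-1))`` without ties, Pearson of
  midranks with ties.
* MCC, Pearson r, and the meta-predictor score (direct alignment score
  times screening rho).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import sqrt

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching
from scipy.stats import rankdata

from .chem import AtomEquivalence
from .geometry import PocketAlignment
from .structures import ComplexRecord, Contact


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class OrderStatistics:
    n_concordant: int
    n_discordant: int
    n: int

    @property
    def tau(self) -> float:
        return (self.n_concordant - self.n_discordant) / (self.n * (self.n - 1) / 2)


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn)


@dataclass
class RankVector:
    """Per-compound screening scores for one target; rank 1 = best affinity
    (most negative predicted score), ties resolved to midranks."""

    target_id: str
    compounds: list[str]
    values: np.ndarray
    ranks: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.compounds) != len(self.values):
            raise ValueError("compounds and values length mismatch")
        self.ranks = rankdata(self.values, method="average")

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass
class MethodScore:
    method: str
    value: float
    significance: float | None = None

    def __post_init__(self) -> None:
        if self.method in ("ps-score", "ga-score") and not 0 <= self.value <= 1:
            raise ValueError(f"{self.method} must lie in [0, 1]")


@dataclass
class PairMetrics:
    pair_id: str
    ssc: float | None = None
    tau: OrderStatistics | None = None
    ligand_rmsd: float | None = None
    alignment_mcc: float | None = None
    tm_score: float | None = None
    seq_identity: float | None = None


# ---------------------------------------------------------------------------
# SSC
# ---------------------------------------------------------------------------

def ssc(profile_a: list[Contact], profile_b: list[Contact],
        eq: AtomEquivalence) -> float:
    """Szymkiewicz-Simpson overlap coefficient of two contact profiles.

    A contact in A matches one in B iff the ligand atoms correspond under
    ``eq`` and the residue groups are identical; the intersection size is a
    maximum one-to-one matching of contacts (greedy matching would
    undercount atoms making several contacts).
    """
    if not profile_a and not profile_b:
        raise ValueError("both contact profiles are empty")
    if not profile_a or not profile_b:
        return 0.0
    amap = eq.mapping()
    rows, cols = [], []
    for i, ca in enumerate(profile_a):
        target = amap.get(ca.ligand_atom)
        if target is None:
            continue
        for j, cb in enumerate(profile_b):
            if cb.ligand_atom == target and cb.residue_group == ca.residue_group:
                rows.append(i)
                cols.append(j)
    if not rows:
        return 0.0
    graph = csr_matrix((np.ones(len(rows)), (rows, cols)),
                       shape=(len(profile_a), len(profile_b)))
    matching = maximum_bipartite_matching(graph, perm_type="column")
    n_matched = int((matching >= 0).sum())
    return n_matched / min(len(profile_a), len(profile_b))


# ---------------------------------------------------------------------------
# Kendall tau
# ---------------------------------------------------------------------------

def kendall_tau_from_positions(pos_a: list[int],
                               pos_b: list[int]) -> OrderStatistics:
    """tau-a over all C(n,2) alignment-position pairs.

    A pair is concordant when the two residues keep the same relative
    sequence order on both sides, discordant when the order flips.
    """
    n = len(pos_a)
    if n != len(pos_b):
        raise ValueError("position lists differ in length")
    if n < 2:
        raise ValueError("Kendall tau needs an alignment of length >= 2")
    order = np.argsort(pos_a, kind="stable")
    a = np.asarray(pos_a)[order]
    b = np.asarray(pos_b)[order]
    n_c = n_d = 0
    for i in range(n):
        for j in range(i + 1, n):
            s = (a[j] - a[i]) * (b[j] - b[i])
            if s > 0:
                n_c += 1
            elif s < 0:
                n_d += 1
    return OrderStatistics(n_c, n_d, n)


def kendall_tau(aln: PocketAlignment, rec_a: ComplexRecord,
                rec_b: ComplexRecord) -> OrderStatistics:
    """Ordinal association of a pocket alignment via chain sequence positions."""
    pos_a = [rec_a.sequence_position(a) for a, _ in aln.pairs]
    pos_b = [rec_b.sequence_position(b) for _, b in aln.pairs]
    return kendall_tau_from_positions(pos_a, pos_b)


# ---------------------------------------------------------------------------
# Spearman rho
# ---------------------------------------------------------------------------

def spearman_rho(a: RankVector, b: RankVector) -> float:
    """Rank correlation between two targets' compound rankings.

    Without ties this is exactly ``1 - 6 sum(d_i^2) / (n(n^2-1))``; with
    ties it is the Pearson correlation of midranks, of which the formula
    is the no-ties special case.
    """
    if a.n != b.n:
        raise ValueError("rank vectors differ in length")
    if a.n < 3:
        raise ValueError("Spearman rho needs n >= 3")
    if a.compounds != b.compounds:
        raise ValueError("rank vectors must cover the same compounds in order")
    for rv in (a, b):
        if np.unique(rv.values).size == 1:
            raise ValueError(f"constant score vector for {rv.target_id}: "
                             "correlation undefined")
    ties = (np.unique(a.ranks).size < a.n) or (np.unique(b.ranks).size < b.n)
    if ties:
        return pearson_cc(a.ranks, b.ranks)
    d = a.ranks - b.ranks
    n = a.n
    return float(1 - 6 * np.sum(d * d) / (n * (n ** 2 - 1)))


# ---------------------------------------------------------------------------
# MCC
# ---------------------------------------------------------------------------

def binary_mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty."""
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    if tp + fp + tn + fn == 0:
        raise ValueError("all confusion counts are zero")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / sqrt(denom)


def alignment_mcc(test: PocketAlignment, reference: PocketAlignment,
                  n_a: int, n_b: int) -> float:
    """MCC of a pocket alignment against the reference alignment, treating
    every possible residue pair as a classification unit (TN over the
    ``n_a * n_b`` pair universe)."""
    ref = reference.pair_set()
    if not ref:
        raise ValueError("reference alignment is empty")
    tst = test.pair_set()
    tp = len(tst & ref)
    fp = len(tst - ref)
    fn = len(ref - tst)
    tn = n_a * n_b - tp - fp - fn
    return binary_mcc(ConfusionCounts(tp, fp, tn, fn))


# ---------------------------------------------------------------------------
# Pearson and the meta-predictor
# ---------------------------------------------------------------------------

def pearson_cc(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; errors on constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be 1-D and equal length")
    if x.size < 3:
        raise ValueError("Pearson correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant series: correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def meta_score(direct: MethodScore, rho: float) -> MethodScore:
    """Meta-predictor: the direct pocket-alignment score multiplied by the
    virtual-screening rank correlation of the two targets."""
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [-1, 1]")
    return MethodScore(method="meta", value=direct.value * rho)


def characterize_pair(
    rec_a: ComplexRecord,
    rec_b: ComplexRecord,
    eq: AtomEquivalence | None = None,
    aln: PocketAlignment | None = None,
    tm_score: float | None = None,
) -> PairMetrics:
    """Full metric panel for one pocket pair.

    When no chemical atom equivalence is supplied it is computed by the
    maximum-common-substructure search; when no alignment is supplied the
    ligand-superposition reference alignment is characterized.
    """
    from .chem import mcs_atom_equivalence, perceive_molecule
    from .geometry import ligand_rmsd_of_alignment, reference_alignment

    if eq is None:
        eq = mcs_atom_equivalence(perceive_molecule(rec_a.ligand),
                                  perceive_molecule(rec_b.ligand))
    reference = reference_alignment(rec_a, rec_b, eq)
    target = aln if aln is not None else reference
    return PairMetrics(
        pair_id=f"{rec_a.record_id}|{rec_b.record_id}",
        ssc=ssc(rec_a.contacts, rec_b.contacts, eq),
        tau=kendall_tau(target, rec_a, rec_b),
        ligand_rmsd=ligand_rmsd_of_alignment(target, rec_a, rec_b, eq),
        alignment_mcc=alignment_mcc(target, reference,
                                    len(rec_a.binding_residues),
                                    len(rec_b.binding_residues))
        if aln is not None else 1.0,
        tm_score=tm_score,
    )
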