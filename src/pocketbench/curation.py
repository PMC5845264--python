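"""Benchmark dataset curation: from ligand-bound complexes to labelled
Positive/Negative pocket pairs.

The pipeline mirrors the published compilation procedure: keep drug-like
single-ligand complexes on chains of 50-999 residues, cluster sequences at
40% identity and keep one representative per redundant binding situation,
keep only records whose predicted pocket matches the ligand-derived pocket
at MCC >= 0.4, cluster the ligands chemically (leader clustering at
TC 0.7), then enumerate globally dissimilar protein pairs (TM-score < 0.4)
within ligand clusters (Positives) or between cluster representatives
(Negatives). Every filter decision is logged with the rule that fired, and
``verify_manifest`` re-audits the final manifest against every constraint.

TM-scores are consumed, never computed: the lookup is fed by an external
structural-alignment tool or by the fixture generators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from Bio import Align
from Bio.Align import substitution_matrices

from . import chem
from .chem import Fingerprint, tanimoto
from .metrics import ConfusionCounts, binary_mcc
from .structures import ComplexRecord, ResidueId

logger = logging.getLogger("pocketbench.curation")

PairList = list[tuple[str, str, float]]
TmLookup = dict[frozenset, float]


@dataclass
class CurationConfig:
    min_len: int = 50
    max_len: int = 999
    drug_tc: float = 0.5
    seq_cluster: float = 0.40
    multi_ligand_tc: float = 0.5
    site_separation: float = 8.0
    pocket_mcc: float = 0.4
    ligand_cluster_tc: float = 0.7
    tm_max: float = 0.4
    #: "or": dissimilar ligands OR separated sites keep both representatives;
    #: "and": both conditions must hold
    representative_rule: str = "or"
    gap_open: float = -11.0
    gap_extend: float = -1.0

    def __post_init__(self) -> None:
        for name, lo, hi in [
            ("drug_tc", 0, 1), ("seq_cluster", 0, 1), ("multi_ligand_tc", 0, 1),
            ("pocket_mcc", -1, 1), ("ligand_cluster_tc", 0, 1), ("tm_max", 0, 1),
        ]:
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo},{hi}]")
        if self.representative_rule not in ("or", "and"):
            raise ValueError("representative_rule must be 'or' or 'and'")

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "CurationConfig":
        return cls(**(yaml.safe_load(text) or {}))


@dataclass
class DatasetManifest:
    complexes: list[str]
    ligand_clusters: dict[str, int]
    positive_pairs: PairList
    negative_pairs: PairList
    filter_log: list[tuple[str, str, str]] = field(default_factory=list)

    def pairs_tsv(self) -> str:
        rows = ["idA\tidB\tlabel\ttm_score"]
        for a, b, tm in self.positive_pairs:
            rows.append(f"{a}\t{b}\tpositive\t{tm:.4f}")
        for a, b, tm in self.negative_pairs:
            rows.append(f"{a}\t{b}\tnegative\t{tm:.4f}")
        return "\n".join(rows) + "\n"

    def log_tsv(self) -> str:
        rows = ["record_id\tstage\tdecision"]
        rows += [f"{r}\t{s}\t{d}" for r, s, d in self.filter_log]
        return "\n".join(rows) + "\n"


# ---------------------------------------------------------------------------
# Stage 1: complex-level filters
# ---------------------------------------------------------------------------

def filter_complexes(
    records: list[ComplexRecord],
    drugs: list[Fingerprint],
    cfg: CurationConfig,
) -> tuple[list[ComplexRecord], list[tuple[str, str, str]]]:
    """Keep drug-like, single-ligand records on chains of permitted length.

    Rejection rules (logged per record): ``length`` (chain outside
    [min_len, max_len]), ``multi_ligand`` (the chain carries more than one
    qualifying ligand), ``drug_tc`` (best Tanimoto to the drug library
    below the threshold).
    """
    if not drugs:
        raise ValueError("drug fingerprint library is empty")
    if not records:
        logger.warning("filter_complexes called with no records")
        return [], []

    chain_count: dict[tuple[str, str], int] = {}
    for rec in records:
        key = (rec.pdb_id, rec.chain_id)
        chain_count[key] = chain_count.get(key, 0) + 1

    kept, log = [], []
    for rec in records:
        if not cfg.min_len <= len(rec.sequence) <= cfg.max_len:
            log.append((rec.record_id, "filter_complexes", "length"))
            continue
        if chain_count[(rec.pdb_id, rec.chain_id)] > 1:
            log.append((rec.record_id, "filter_complexes", "multi_ligand"))
            continue
        fp = chem.path_fingerprint(chem.perceive_molecule(rec.ligand))
        best = max(tanimoto(fp, d) for d in drugs)
        if best < cfg.drug_tc:
            log.append((rec.record_id, "filter_complexes", "drug_tc"))
            continue
        kept.append(rec)
        log.append((rec.record_id, "filter_complexes", "kept"))
    return kept, log


# ---------------------------------------------------------------------------
# Stage 2: sequence clustering
# ---------------------------------------------------------------------------

def _make_aligner(cfg: CurationConfig) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = cfg.gap_open
    aligner.extend_gap_score = cfg.gap_extend
    return aligner


def sequence_identity(seq_a: str, seq_b: str,
                      cfg: CurationConfig | None = None) -> float:
    """Global-alignment identity: exact matches / alignment columns."""
    cfg = cfg or CurationConfig()
    aligner = _make_aligner(cfg)
    aln = aligner.align(seq_a, seq_b)[0]
    counts = aln.counts()
    return counts.identities / aln.length


def cluster_sequences(records: list[ComplexRecord],
                      cfg: CurationConfig | None = None) -> dict[str, int]:
    """Greedy longest-first sequence clustering at ``cfg.seq_cluster``
    identity; each record joins the first representative it matches."""
    cfg = cfg or CurationConfig()
    order = sorted(range(len(records)),
                   key=lambda i: (-len(records[i].sequence), i))
    reps: list[int] = []
    assignment: dict[str, int] = {}
    for idx in order:
        rec = records[idx]
        for cluster_id, rep in enumerate(reps):
            ident = sequence_identity(records[rep].sequence, rec.sequence, cfg)
            if ident >= cfg.seq_cluster:
                assignment[rec.record_id] = cluster_id
                break
        else:
            assignment[rec.record_id] = len(reps)
            reps.append(idx)
    return assignment


# ---------------------------------------------------------------------------
# Stage 3: representatives within sequence clusters
# ---------------------------------------------------------------------------

def select_representatives(
    cluster: list[ComplexRecord],
    cfg: CurationConfig,
) -> tuple[list[ComplexRecord], list[tuple[str, str, str]]]:
    """Within one sequence cluster, keep a maximal greedy subset of records
    representing distinct binding situations: chemically dissimilar ligands
    (TC < multi_ligand_tc) or well-separated sites (ligand centroids
    >= site_separation apart); the rule combination follows
    ``cfg.representative_rule``.
    """
    order = sorted(range(len(cluster)),
                   key=lambda i: (-len(cluster[i].sequence), i))
    fps = {i: chem.path_fingerprint(chem.perceive_molecule(cluster[i].ligand))
           for i in order}
    centroids = {i: cluster[i].ligand.centroid() for i in order}

    kept_idx: list[int] = []
    log = []
    for idx in order:
        distinct = True
        for k in kept_idx:
            tc_ok = tanimoto(fps[idx], fps[k]) < cfg.multi_ligand_tc
            sep_ok = (np.linalg.norm(centroids[idx] - centroids[k])
                      >= cfg.site_separation)
            same = not (tc_ok or sep_ok) if cfg.representative_rule == "or" \
                else not (tc_ok and sep_ok)
            if same:
                distinct = False
                break
        if distinct:
            kept_idx.append(idx)
            log.append((cluster[idx].record_id, "select_representatives", "kept"))
        else:
            log.append((cluster[idx].record_id, "select_representatives",
                        "redundant_site"))
    kept_idx.sort()
    return [cluster[i] for i in kept_idx], log


# ---------------------------------------------------------------------------
# Stage 4: predicted-pocket quality
# ---------------------------------------------------------------------------

def pocket_quality_filter(
    records: list[ComplexRecord],
    predicted_pockets: dict[str, set[ResidueId]],
    cfg: CurationConfig,
) -> tuple[list[ComplexRecord], list[tuple[str, str, str]]]:
    """Keep records whose predicted pocket matches the contact-derived
    binding residues at MCC >= ``cfg.pocket_mcc`` over all chain residues."""
    kept, log = [], []
    for rec in records:
        pred = predicted_pockets.get(rec.record_id)
        if pred is None:
            log.append((rec.record_id, "pocket_quality", "no_prediction"))
            continue
        truth = set(rec.binding_residues)
        universe = {r.rid for r in rec.residues}
        pred = pred & universe
        tp = len(pred & truth)
        fp = len(pred - truth)
        fn = len(truth - pred)
        tn = len(universe) - tp - fp - fn
        mcc = binary_mcc(ConfusionCounts(tp, fp, tn, fn))
        if mcc >= cfg.pocket_mcc:
            kept.append(rec)
            log.append((rec.record_id, "pocket_quality", "kept"))
        else:
            log.append((rec.record_id, "pocket_quality", f"mcc_below:{mcc:.2f}"))
    return kept, log


# ---------------------------------------------------------------------------
# Stage 5: pair enumeration
# ---------------------------------------------------------------------------

def _tm(tm_lookup: TmLookup, id_a: str, id_b: str) -> float | None:
    return tm_lookup.get(frozenset((id_a, id_b)))


def cluster_representative(records: list[ComplexRecord]) -> ComplexRecord:
    """Representative of a ligand cluster: most binding residues, ties by id."""
    return min(records, key=lambda r: (-len(r.binding_residues), r.record_id))


def enumerate_pairs(
    records: list[ComplexRecord],
    ligand_clusters: dict[str, int],
    tm_lookup: TmLookup,
    cfg: CurationConfig,
) -> tuple[PairList, PairList, int]:
    """Positive pairs (within a ligand cluster) and Negative pairs (between
    per-cluster representatives), both restricted to globally dissimilar
    proteins (TM-score < tm_max). Returns (positives, negatives,
    n_missing_tm); candidate pairs without a TM-score are skipped."""
    by_cluster: dict[int, list[ComplexRecord]] = {}
    for rec in records:
        by_cluster.setdefault(ligand_clusters[rec.record_id], []).append(rec)

    n_missing = 0
    positives: PairList = []
    for members in by_cluster.values():
        members = sorted(members, key=lambda r: r.record_id)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i].record_id, members[j].record_id
                tm = _tm(tm_lookup, a, b)
                if tm is None:
                    n_missing += 1
                    continue
                if tm < cfg.tm_max:
                    positives.append((a, b, tm))

    reps = sorted((cluster_representative(m) for m in by_cluster.values()),
                  key=lambda r: r.record_id)
    negatives: PairList = []
    for i in range(len(reps)):
        for j in range(i + 1, len(reps)):
            a, b = reps[i].record_id, reps[j].record_id
            tm = _tm(tm_lookup, a, b)
            if tm is None:
                n_missing += 1
                continue
            if tm < cfg.tm_max:
                negatives.append(tuple(sorted((a, b))) + (tm,))  # type: ignore

    positives = sorted({(min(a, b), max(a, b), tm) for a, b, tm in positives})
    negatives = sorted(set(negatives))
    return positives, negatives, n_missing


# ---------------------------------------------------------------------------
# Audit
# ---------------------------------------------------------------------------

def verify_manifest(manifest: DatasetManifest,
                    cfg: CurationConfig) -> list[str]:
    """Re-check every manifest invariant; an empty report means compliant."""
    violations: list[str] = []
    known = set(manifest.complexes)

    def check_pairs(pairs: PairList, label: str) -> None:
        seen: set[tuple[str, str]] = set()
        for a, b, tm in pairs:
            key = (min(a, b), max(a, b))
            if a == b:
                violations.append(f"{label}: self-pair {a}")
            if key in seen:
                violations.append(f"{label}: duplicate pair {key}")
            seen.add(key)
            if tm >= cfg.tm_max:
                violations.append(
                    f"{label}: pair {key} TM-score {tm:.3f} >= {cfg.tm_max}")
            for rid in (a, b):
                if rid not in known:
                    violations.append(f"{label}: unknown record {rid}")
                elif rid not in manifest.ligand_clusters:
                    violations.append(f"{label}: unclustered record {rid}")

    check_pairs(manifest.positive_pairs, "positive")
    check_pairs(manifest.negative_pairs, "negative")

    lc = manifest.ligand_clusters
    for a, b, _ in manifest.positive_pairs:
        if a in lc and b in lc and lc[a] != lc[b]:
            violations.append(f"positive pair ({a},{b}) spans ligand clusters")
    for a, b, _ in manifest.negative_pairs:
        if a in lc and b in lc and lc[a] == lc[b]:
            violations.append(f"negative pair ({a},{b}) shares a ligand cluster")

    pos_keys = {(min(a, b), max(a, b)) for a, b, _ in manifest.positive_pairs}
    neg_keys = {(min(a, b), max(a, b)) for a, b, _ in manifest.negative_pairs}
    for key in pos_keys & neg_keys:
        violations.append(f"pair {key} labelled both positive and negative")
    return violations


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def run_pipeline(
    records: list[ComplexRecord],
    drugs: list[Fingerprint],
    tm_lookup: TmLookup,
    cfg: CurationConfig | None = None,
    predicted_pockets: dict[str, set[ResidueId]] | None = None,
) -> DatasetManifest:
    """Run every curation stage in order and assemble the manifest.

    When ``predicted_pockets`` is None the pocket-quality stage is a no-op
    (records keep their ligand-derived pockets).
    """
    cfg = cfg or CurationConfig()
    log: list[tuple[str, str, str]] = []

    kept, stage_log = filter_complexes(records, drugs, cfg)
    log += stage_log

    seq_clusters = cluster_sequences(kept, cfg)
    by_seq: dict[int, list[ComplexRecord]] = {}
    for rec in kept:
        by_seq.setdefault(seq_clusters[rec.record_id], []).append(rec)
    survivors: list[ComplexRecord] = []
    for members in by_seq.values():
        reps, stage_log = select_representatives(members, cfg)
        survivors += reps
        log += stage_log
    survivors.sort(key=lambda r: r.record_id)

    if predicted_pockets is not None:
        survivors, stage_log = pocket_quality_filter(
            survivors, predicted_pockets, cfg)
        log += stage_log

    mols = [chem.perceive_molecule(r.ligand) for r in survivors]
    assignment = chem.leader_cluster(mols, threshold=cfg.ligand_cluster_tc)
    ligand_clusters = {r.record_id: c for r, c in zip(survivors, assignment)}

    positives, negatives, n_missing = enumerate_pairs(
        survivors, ligand_clusters, tm_lookup, cfg)
    if n_missing:
        logger.warning("%d candidate pairs lacked a TM-score", n_missing)

    return DatasetManifest(
        complexes=[r.record_id for r in survivors],
        ligand_clusters=ligand_clusters,
        positive_pairs=positives,
        negative_pairs=negatives,
        filter_log=log,
    )
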