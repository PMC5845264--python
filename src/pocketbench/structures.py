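"""Protein-ligand complex structures: PDB parsing, ligand extraction, contacts.

A *complex record* couples one protein chain with one bound small molecule,
the residues lining its binding site, and the typed ligand-protein contacts
used by the binding-environment overlap coefficient. Contacts are typed by
the physicochemical group of the protein residue:

    I (LVIMC), II (AG), III (ST), IV (P), V (FYW), VI (EDNQ), VII (KR), VIII (H)

Parsing is backed by gemmi; a pre-validation pass reports malformed
coordinate fields with their line number, and alternate locations are
resolved to the highest-occupancy conformer (ties broken by the lowest
altloc character). Only the first MODEL is read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import gemmi
import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger("pocketbench.structures")

# ---------------------------------------------------------------------------
# Configuration constants
# ---------------------------------------------------------------------------

#: ligand-heavy-atom / residue-heavy-atom distance defining a contact (A)
CONTACT_CUTOFF = 4.5
#: any ligand-protein heavy-atom distance below this marks a covalent link (A)
COVALENT_THRESHOLD = 1.9
#: chain-length window for curation-grade records (polymer residues)
MIN_CHAIN_LEN = 50
MAX_CHAIN_LEN = 999

#: residue groups used to type protein-ligand contacts
RESIDUE_GROUPS: dict[str, str] = {}
for _group, _aas in [
    ("I", "LVIMC"), ("II", "AG"), ("III", "ST"), ("IV", "P"),
    ("V", "FYW"), ("VI", "EDNQ"), ("VII", "KR"), ("VIII", "H"),
]:
    for _aa in _aas:
        RESIDUE_GROUPS[_aa] = _group

AMINO3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

#: modified residues mapped to the parent amino acid for grouping
RESIDUE_ALIASES = {
    "MSE": "MET", "SEC": "CYS", "PYL": "LYS", "SEP": "SER",
    "TPO": "THR", "PTR": "TYR", "CSO": "CYS", "HYP": "PRO",
    "MLY": "LYS", "KCX": "LYS",
}

#: solvent / ion / cryoprotectant HET codes never treated as ligands
DEFAULT_EXCLUSION = frozenset({
    "HOH", "DOD", "WAT", "NA", "K", "CL", "MG", "CA", "ZN", "MN", "FE",
    "FE2", "CU", "CO", "NI", "CD", "HG", "BR", "IOD", "SO4", "PO4",
    "GOL", "EDO", "PEG", "PG4", "MPD", "DMS", "ACT", "ACE", "FMT",
    "TRS", "EPE", "MES", "BME", "DTT", "NO3", "AZI", "CIT", "TLA",
    "IMD", "NH4", "CO3", "BCT", "CSD",
}) | frozenset(RESIDUE_ALIASES)


class PDBParseError(ValueError):
    """Raised for malformed PDB input, carrying the offending line number."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

class ResidueId(NamedTuple):
    chain_id: str
    seq_num: int
    icode: str


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")


@dataclass
class Residue:
    chain_id: str
    seq_num: int
    icode: str
    res_name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def rid(self) -> ResidueId:
        return ResidueId(self.chain_id, self.seq_num, self.icode)

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms if a.element != "H"],
                        dtype=float)

    def ca(self) -> np.ndarray | None:
        for a in self.atoms:
            if a.name == "CA":
                return a.coords
        return None

    def one_letter(self) -> str:
        name = RESIDUE_ALIASES.get(self.res_name, self.res_name)
        return AMINO3TO1.get(name, "X")

    def group(self) -> str | None:
        """Contact group I-VIII, or None for ungroupable residues."""
        return RESIDUE_GROUPS.get(self.one_letter())


@dataclass
class LigandInstance:
    res_name: str
    atoms: list[Atom]
    parent_chain: str

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("ligand must have at least one heavy atom")
        if any(a.element == "H" for a in self.atoms):
            raise ValueError("ligand atoms must be heavy atoms")

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def centroid(self) -> np.ndarray:
        return self.coords().mean(axis=0)


@dataclass
class Contact:
    ligand_atom: int
    residue: ResidueId
    residue_group: str
    distance: float


@dataclass
class ComplexRecord:
    """One protein chain + one bound ligand + its typed binding environment."""

    pdb_id: str
    chain_id: str
    sequence: str
    ligand: LigandInstance
    binding_residues: list[ResidueId]
    contacts: list[Contact]
    residues: list[Residue]
    pocket_source: str = "ligand-derived"

    @property
    def record_id(self) -> str:
        return f"{self.pdb_id}_{self.chain_id}_{self.ligand.res_name}"

    def residue_map(self) -> dict[ResidueId, Residue]:
        return {r.rid: r for r in self.residues}

    def sequence_position(self, rid: ResidueId) -> int:
        """1-based position of a residue along the chain."""
        for i, r in enumerate(self.residues, start=1):
            if r.rid == rid:
                return i
        raise KeyError(f"residue {rid} not in chain {self.chain_id}")

    def ca_coord(self, rid: ResidueId) -> np.ndarray | None:
        res = self.residue_map().get(rid)
        return None if res is None else res.ca()


@dataclass
class ParsedStructure:
    pdb_id: str
    chains: dict[str, list[Residue]]
    hetero: list[Residue]


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def _validate_coordinate_lines(pdb_text: str) -> None:
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line) < 54:
            raise PDBParseError(
                f"line {lineno}: coordinate record too short")
        for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            try:
                float(line[lo:hi])
            except ValueError:
                raise PDBParseError(
                    f"line {lineno}: malformed {what} coordinate field "
                    f"{line[lo:hi]!r}") from None


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one conformer per atom name: highest occupancy, ties by altloc."""
    by_name: dict[str, list[Atom]] = {}
    for a in atoms:
        by_name.setdefault(a.name, []).append(a)
    kept = []
    for group in by_name.values():
        kept.append(min(group, key=lambda a: (-a.occupancy, a.altloc or "~")))
    kept.sort(key=lambda a: a.serial)
    return kept


def _is_polymer(res_name: str) -> bool:
    return res_name in AMINO3TO1 or res_name in RESIDUE_ALIASES


def parse_pdb(pdb_text: str, pdb_id: str = "xxxx") -> ParsedStructure:
    """Parse PDB-format text into chains of residues plus hetero groups.

    Only the first MODEL is read; alternate locations are resolved to the
    highest-occupancy conformer. Residues are keyed by
    (chain_id, seq_num, icode), insertion codes preserved.

    Raises
    ------
    PDBParseError
        on empty input or a malformed coordinate field (names the line).
    """
    if not pdb_text.strip():
        raise PDBParseError("empty PDB input")
    _validate_coordinate_lines(pdb_text)

    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise PDBParseError("no MODEL found in PDB input")
    model = st[0]  # first MODEL only

    chains: dict[str, list[Residue]] = {}
    hetero: list[Residue] = []
    for chain in model:
        for res in chain:
            atoms = [
                Atom(
                    serial=a.serial,
                    name=a.name,
                    element=a.element.name,
                    coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    occupancy=a.occ,
                    altloc=a.altloc if a.altloc != "\0" else "",
                    is_hetero=res.het_flag == "H",
                )
                for a in res
            ]
            atoms = _resolve_altlocs(atoms)
            icode = res.seqid.icode.strip()
            r = Residue(chain.name, res.seqid.num, icode, res.name, atoms)
            if _is_polymer(res.name):
                chains.setdefault(chain.name, []).append(r)
            else:
                hetero.append(r)
    return ParsedStructure(pdb_id=pdb_id, chains=chains, hetero=hetero)


# ---------------------------------------------------------------------------
# Complex extraction
# ---------------------------------------------------------------------------

def _chain_heavy_coords(residues: list[Residue]) -> np.ndarray:
    coords = [a.coords for r in residues for a in r.atoms if a.element != "H"]
    return np.array(coords, dtype=float)


def extract_complexes(
    parsed: ParsedStructure,
    exclusion_list: frozenset[str] | set[str] = DEFAULT_EXCLUSION,
    min_len: int = MIN_CHAIN_LEN,
    max_len: int = MAX_CHAIN_LEN,
    contact_cutoff: float = CONTACT_CUTOFF,
    covalent_threshold: float = COVALENT_THRESHOLD,
) -> list[ComplexRecord]:
    """Build one ComplexRecord per (chain, ligand) pair passing the filters.

    A hetero group qualifies as a ligand when its code is not on the
    exclusion list, it has at least one heavy atom, and no heavy atom sits
    within ``covalent_threshold`` of any protein heavy atom (covalently
    linked groups are discarded). The record's chain must have
    ``min_len``-``max_len`` polymer residues and at least one contact with
    the ligand at ``contact_cutoff``.
    """
    records: list[ComplexRecord] = []

    eligible_chains = {
        cid: residues
        for cid, residues in parsed.chains.items()
        if min_len <= sum(1 for r in residues if r.atoms) <= max_len
    }
    all_protein = [r for residues in parsed.chains.values() for r in residues]
    protein_coords = _chain_heavy_coords(all_protein)

    for het in parsed.hetero:
        if het.res_name in exclusion_list:
            continue
        heavy = [a for a in het.atoms if a.element != "H"]
        if not heavy:
            continue
        lig_coords = np.array([a.coords for a in heavy])
        if protein_coords.size:
            dmin = cdist(lig_coords, protein_coords).min()
            if dmin < covalent_threshold:
                logger.info("discarding covalently linked group %s", het.res_name)
                continue

        for cid, residues in eligible_chains.items():
            ligand = LigandInstance(het.res_name, list(heavy), parent_chain=cid)
            contacts = _contacts(ligand, residues, contact_cutoff)
            if not contacts:
                continue
            seen: list[ResidueId] = []
            for c in contacts:
                if c.residue not in seen:
                    seen.append(c.residue)
            sequence = "".join(r.one_letter() for r in residues)
            records.append(ComplexRecord(
                pdb_id=parsed.pdb_id,
                chain_id=cid,
                sequence=sequence,
                ligand=ligand,
                binding_residues=seen,
                contacts=contacts,
                residues=list(residues),
            ))
    return records


def _contacts(ligand: LigandInstance, residues: Iterable[Residue],
              cutoff: float) -> list[Contact]:
    lig_coords = ligand.coords()
    contacts: list[Contact] = []
    for res in residues:
        group = res.group()
        if group is None:
            logger.debug("skipping ungroupable residue %s", res.res_name)
            continue
        rc = res.heavy_coords()
        if rc.size == 0:
            continue
        dists = cdist(lig_coords, rc).min(axis=1)
        for atom_idx in np.nonzero(dists <= cutoff)[0]:
            contacts.append(Contact(
                ligand_atom=int(atom_idx),
                residue=res.rid,
                residue_group=group,
                distance=float(dists[atom_idx]),
            ))
    return contacts


def contact_profile(record: ComplexRecord,
                    cutoff: float = CONTACT_CUTOFF) -> list[Contact]:
    """Typed ligand-protein contacts: one per (ligand heavy atom, residue)
    pair whose minimum heavy-atom distance is within ``cutoff``.

    Residues with no group assignment (non-standard, not aliased) are
    skipped and logged. Raises ValueError for an empty ligand.
    """
    if not record.ligand.atoms:
        raise ValueError("contact_profile: ligand has no atoms")
    return _contacts(record.ligand, record.residues, cutoff)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _pdb_atom_line(atom: Atom, res: Residue, record: str) -> str:
    return (
        f"{record:<6}{atom.serial:>5} {atom.name:<4}{'':1}{res.res_name:>3} "
        f"{res.chain_id:1}{res.seq_num:>4}{res.icode or ' ':1}   "
        f"{atom.coords[0]:8.3f}{atom.coords[1]:8.3f}{atom.coords[2]:8.3f}"
        f"{atom.occupancy:6.2f}{0.0:6.2f}          {atom.element:>2}"
    )


def write_pocket_pdb(record: ComplexRecord) -> str:
    """Pocket-only PDB: binding residues as ATOM, the ligand as HETATM."""
    lines = []
    rmap = record.residue_map()
    for rid in record.binding_residues:
        res = rmap[rid]
        for atom in res.atoms:
            lines.append(_pdb_atom_line(atom, res, "ATOM"))
    lig_res = Residue("L", 1, "", record.ligand.res_name, record.ligand.atoms)
    for atom in record.ligand.atoms:
        lines.append(_pdb_atom_line(atom, lig_res, "HETATM"))
    lines.append("END")
    return "\n".join(lines) + "\n"


def contacts_tsv(record: ComplexRecord) -> str:
    """Contacts as TSV: ligand_atom_name, chain, seq_num, icode, res_name,
    group, distance."""
    rmap = record.residue_map()
    rows = ["ligand_atom_name\tchain\tseq_num\ticode\tres_name\tgroup\tdistance"]
    for c in record.contacts:
        res = rmap[c.residue]
        rows.append(
            f"{record.ligand.atoms[c.ligand_atom].name}\t{c.residue.chain_id}\t"
            f"{c.residue.seq_num}\t{c.residue.icode}\t{res.res_name}\t"
            f"{c.residue_group}\t{c.distance:.3f}"
        )
    return "\n".join(rows) + "\n"
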