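#!/usr/bin/env python
"""Worked pocket-pair examples on deposited structures.

Compares the ATP pocket of mouse inositol trisphosphate 3-kinase B
(PDB 2aqx, chain A) against two ADP pockets: yeast inositol polyphosphate
multikinase (2if8:A, a structurally similar kinase) and E. coli glutathione
synthetase (1gsa:A, an unrelated fold). For each pair it reports the ligand
RMSD of the ligand-superposition reference alignment, the alignment's
Kendall tau, and the contact-overlap SSC.

The PDB files must be available locally (they are not shipped):

    python scripts/worked_examples.py --pdb-dir data/pdb

With network access, ``--fetch`` downloads them from RCSB first.
"""

from __future__ import annotations

import argparse
import sys
import urllib.request
from pathlib import Path

from pocketbench import extract_complexes, parse_pdb
from pocketbench.metrics import characterize_pair

CASES = {"2aqx": ("A", "ATP"), "2if8": ("A", "ADP"), "1gsa": ("A", "ADP")}
PAIRS = [("2aqx", "2if8"), ("2aqx", "1gsa")]


def fetch(pdb_dir: Path) -> None:
    pdb_dir.mkdir(parents=True, exist_ok=True)
    for code in CASES:
        dest = pdb_dir / f"{code}.pdb"
        if dest.exists():
            continue
        url = f"https://files.rcsb.org/download/{code.upper()}.pdb"
        print(f"fetching {url}")
        urllib.request.urlretrieve(url, dest)


def load(pdb_dir: Path, code: str):
    chain, het = CASES[code]
    path = pdb_dir / f"{code}.pdb"
    parsed = parse_pdb(path.read_text(), pdb_id=code)
    for rec in extract_complexes(parsed):
        if rec.chain_id == chain and rec.ligand.res_name == het:
            return rec
    raise SystemExit(f"{path}: no {het} complex on chain {chain}")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--pdb-dir", type=Path, default=Path("data/pdb"))
    parser.add_argument("--fetch", action="store_true",
                        help="download the entries from RCSB first")
    args = parser.parse_args()

    if args.fetch:
        fetch(args.pdb_dir)
    missing = [c for c in CASES if not (args.pdb_dir / f"{c}.pdb").exists()]
    if missing:
        sys.exit(f"missing PDB files under {args.pdb_dir}: {missing} "
                 "(rerun with --fetch when online)")

    records = {code: load(args.pdb_dir, code) for code in CASES}
    print(f"{'pair':<14}{'ligand_rmsd_A':>14}{'kendall_tau':>13}{'ssc':>8}")
    for a, b in PAIRS:
        pm = characterize_pair(records[a], records[b])
        print(f"{a}:{CASES[a][0]}-{b}:{CASES[b][0]}"
              f"{pm.ligand_rmsd:>14.2f}{pm.tau.tau:>13.2f}{pm.ssc:>8.2f}")


if __name__ == "__main__":
    main()
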