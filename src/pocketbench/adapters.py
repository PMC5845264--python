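"""Parsers for external-tool outputs.

The benchmark consumes, never runs, the external tools: pocket-matching
aligners (residue correspondences + a similarity score), docking score
tables from virtual screening, and pocket-predictor residue sets. Exact
output dialects are version-dependent, so each parser documents the
grammar it accepts and is exercised against a synthetic fixture corpus.

Accepted grammars
-----------------
Alignment reports (``parse_alignment_report``): free-text preamble
containing the tool's score line, then a table of residue pairs.

* apoc:        ``PS-score = <x>[, P-value = <p>]`` and rows
               ``<idx> <chain1> <res1> <aa1> <chain2> <res2> <aa2>``
               after a header line containing ``Index``.
* siteengine:  ``Match score : <x>`` and rows ``<chainA> <resA> <-> <chainB> <resB>``.
* glosa:       ``GA-score : <x>`` and the same row layout as apoc.

Screening tables (``parse_screening_scores``): whitespace/TSV rows of
``<compound_id> <score>``; ``#`` comments ignored; lower score = better
predicted affinity, rank 1 = best, ties get midranks.

Pocket predictions (``parse_pocket_prediction``): blocks opened by
``POCKET <rank>`` followed by ``RES <chain> <seq_num> [icode]`` lines.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

from .geometry import PocketAlignment
from .metrics import ConfusionCounts, MethodScore, RankVector, binary_mcc
from .structures import ResidueId

logger = logging.getLogger("pocketbench.adapters")


class AdapterParseError(ValueError):
    """Raised for unparseable tool output, naming the offending line."""


@dataclass
class ToolReport:
    tool: str
    payload: object
    raw_text: str


_SCORE_PATTERNS = {
    "apoc": (re.compile(r"PS-score\s*[:=]\s*([-\d.eE+]+)"
                        r"(?:\s*,\s*P-value\s*[:=]\s*([-\d.eE+]+))?"),
             "ps-score"),
    "siteengine": (re.compile(r"Match\s+score\s*[:=]\s*([-\d.eE+]+)"),
                   "match"),
    "glosa": (re.compile(r"GA-score\s*[:=]\s*([-\d.eE+]+)"), "ga-score"),
}

_ARROW_ROW = re.compile(
    r"^\s*(\S+)\s+(\S+)\s*<->\s*(\S+)\s+(\S+)\s*$")
_TABLE_ROW = re.compile(
    r"^\s*\d+\s+(\S+)\s+(\S+)\s+\S+\s+(\S+)\s+(\S+)(?:\s+\S+)?\s*$")


def _parse_residue(token: str, lineno: int) -> int:
    if not re.fullmatch(r"-?\d+", token):
        raise AdapterParseError(
            f"line {lineno}: malformed residue field {token!r}")
    return int(token)


def parse_alignment_report(
    tool: str, text: str,
) -> tuple[PocketAlignment, MethodScore | None]:
    """Extract the residue correspondences and the tool's score.

    Pair order is preserved exactly as printed (it is the input to the
    Kendall tau analysis). A missing score yields ``None`` with a warning;
    an empty alignment block yields an empty PocketAlignment (flagged in
    the log). Unrecognized rows inside the alignment table raise
    AdapterParseError at the first offending line.
    """
    if tool not in _SCORE_PATTERNS:
        raise AdapterParseError(f"unknown tool dialect {tool!r}")
    score_re, score_tag = _SCORE_PATTERNS[tool]

    score: MethodScore | None = None
    m = score_re.search(text)
    if m:
        pvalue = float(m.group(2)) if score_re.groups > 1 and m.group(2) \
            else None
        score = MethodScore(score_tag, float(m.group(1)), pvalue)
    else:
        logger.warning("%s report carries no score line", tool)

    pairs: list[tuple[ResidueId, ResidueId]] = []
    in_table = tool == "siteengine"  # arrow rows are self-delimiting
    for lineno, line in enumerate(text.splitlines(), start=1):
        if tool == "siteengine":
            m = _ARROW_ROW.match(line)
            if m:
                ra = _parse_residue(m.group(2), lineno)
                rb = _parse_residue(m.group(4), lineno)
                pairs.append((ResidueId(m.group(1), ra, ""),
                              ResidueId(m.group(3), rb, "")))
            continue
        if not in_table:
            if re.search(r"\bIndex\b", line):
                in_table = True
            continue
        if not line.strip():
            break
        m = _TABLE_ROW.match(line)
        if not m:
            raise AdapterParseError(
                f"line {lineno}: unrecognized alignment row {line!r}")
        ra = _parse_residue(m.group(2), lineno)
        rb = _parse_residue(m.group(4), lineno)
        pairs.append((ResidueId(m.group(1), ra, ""),
                      ResidueId(m.group(3), rb, "")))

    if not pairs:
        logger.warning("%s report contains an empty alignment block", tool)
    aln = PocketAlignment(pairs, method=tool,
                          score=None if score is None else score.value)
    return aln, score


def parse_screening_scores(tool: str, text: str,
                           target_id: str = "target") -> RankVector:
    """One best score per compound; rank 1 = best predicted affinity."""
    compounds: list[str] = []
    values: list[float] = []
    seen: set[str] = set()
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise AdapterParseError(
                f"line {lineno}: expected '<compound> <score>', got {line!r}")
        cid, raw = parts[0], parts[1]
        if cid in seen:
            raise AdapterParseError(
                f"line {lineno}: duplicate compound id {cid!r}")
        try:
            val = float(raw)
        except ValueError:
            raise AdapterParseError(
                f"line {lineno}: non-numeric score {raw!r}") from None
        seen.add(cid)
        compounds.append(cid)
        values.append(val)
    return RankVector(target_id, compounds, values)


def parse_pocket_prediction(
    tool: str, text: str,
    structure_residues: set[ResidueId] | None = None,
) -> list[tuple[set[ResidueId], int]]:
    """Per-pocket residue sets with the predictor's ranking preserved
    (rank 1 = top pocket). Residues absent from ``structure_residues``
    (when given) are dropped with a warning. No pockets -> empty list."""
    pockets: list[tuple[set[ResidueId], int]] = []
    current: set[ResidueId] | None = None
    rank = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.upper().startswith("POCKET"):
            parts = line.split()
            rank = int(parts[1]) if len(parts) > 1 else len(pockets) + 1
            current = set()
            pockets.append((current, rank))
        elif line.upper().startswith("RES"):
            if current is None:
                raise AdapterParseError(
                    f"line {lineno}: RES before any POCKET header")
            parts = line.split()
            if len(parts) < 3:
                raise AdapterParseError(
                    f"line {lineno}: expected 'RES <chain> <seq> [icode]'")
            rid = ResidueId(parts[1], _parse_residue(parts[2], lineno),
                            parts[3] if len(parts) > 3 else "")
            if structure_residues is not None and rid not in structure_residues:
                logger.warning("dropping residue %s absent from structure", rid)
                continue
            current.add(rid)
        else:
            raise AdapterParseError(
                f"line {lineno}: unrecognized line {line!r}")
    return pockets


def best_pocket_by_mcc(
    pockets: list[tuple[set[ResidueId], int]],
    truth: set[ResidueId],
    universe: set[ResidueId],
) -> tuple[int, float]:
    """Rank of the predicted pocket best matching the true binding residues,
    judged by MCC over the residue universe."""
    if not pockets:
        raise ValueError("no pockets to evaluate")
    best_rank, best_mcc = pockets[0][1], -2.0
    for residues, rank in pockets:
        pred = residues & universe
        tp = len(pred & truth)
        fp = len(pred - truth)
        fn = len(truth - pred)
        tn = len(universe) - tp - fp - fn
        mcc = binary_mcc(ConfusionCounts(tp, fp, tn, fn))
        if mcc > best_mcc:
            best_rank, best_mcc = rank, mcc
    return best_rank, best_mcc
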