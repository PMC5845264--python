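"""ROC analysis of pocket-pair scores over a labelled benchmark dataset.

Positive pairs are pockets binding chemically similar ligands in globally
dissimilar proteins; Negative pairs bind dissimilar ligands. Any scalar
score claiming to separate them is evaluated with the ROC curve, the area
under it (computed through the Mann-Whitney rank identity, ties credited
0.5), and the sensitivity at fixed false-positive rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass
class LabeledPair:
    pair_id: str
    id_a: str
    id_b: str
    label: str  # "positive" | "negative"
    scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in ("positive", "negative"):
            raise ValueError(f"label must be positive/negative, got {self.label!r}")


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_pos: int
    n_neg: int
    n_excluded: int = 0


def roc_auc(pairs: list[LabeledPair], method: str,
            higher_is_similar: bool = True) -> ROCCurve:
    """ROC curve and AUC of one method's score over labelled pocket pairs.

    The curve sweeps every distinct score threshold; the AUC comes from the
    Mann-Whitney identity (probability a positive outscores a negative,
    ties counted 0.5), which equals the trapezoidal integral of the curve.
    Pairs missing the score are excluded and counted in the result.
    """
    scored = [p for p in pairs if method in p.scores
              and np.isfinite(p.scores[method])]
    n_excluded = len(pairs) - len(scored)
    y = np.array([1 if p.label == "positive" else 0 for p in scored])
    s = np.array([p.scores[method] for p in scored], dtype=float)
    if not higher_is_similar:
        s = -s
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError(f"method {method!r}: need both classes "
                         f"(P={n_pos}, N={n_neg})")

    # Mann-Whitney AUC with midrank tie handling
    ranks = rankdata(s, method="average")
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    # step curve over distinct thresholds, descending
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    distinct = np.nonzero(np.diff(s_sorted))[0]
    idx = np.r_[distinct, len(s_sorted) - 1]
    tp = np.cumsum(y_sorted)[idx]
    fp = np.cumsum(1 - y_sorted)[idx]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    thresholds = np.r_[np.inf, s_sorted[idx]]
    return ROCCurve(thresholds, fpr, tpr, float(auc), n_pos, n_neg, n_excluded)


def sensitivity_at_fpr(curve: ROCCurve, fpr_level: float) -> float:
    """TPR at the largest achieved FPR <= ``fpr_level`` (step convention)."""
    if not 0 < fpr_level < 1:
        raise ValueError("fpr_level must lie in (0, 1)")
    ok = np.nonzero(curve.fpr <= fpr_level)[0]
    return float(curve.tpr[ok].max()) if ok.size else 0.0


def evaluate_methods(pairs: list[LabeledPair], methods: list[str],
                     higher_is_similar: bool = True,
                     fpr_levels: tuple[float, ...] = (0.01, 0.05)
                     ) -> tuple[pd.DataFrame, dict[str, ROCCurve]]:
    """Per-method AUC and sensitivity at fixed FPR levels.

    A method whose ROC cannot be computed (e.g. single-class after
    exclusions) is reported with an error string; the report is still
    produced for the others.
    """
    rows = []
    curves: dict[str, ROCCurve] = {}
    for method in methods:
        row: dict[str, object] = {"method": method}
        try:
            curve = roc_auc(pairs, method, higher_is_similar)
        except ValueError as exc:
            row.update(auc=np.nan, error=str(exc))
        else:
            curves[method] = curve
            row.update(
                auc=curve.auc,
                n_pos=curve.n_pos, n_neg=curve.n_neg,
                n_excluded=curve.n_excluded, error="",
            )
            for lvl in fpr_levels:
                row[f"tpr_at_fpr{int(round(lvl * 100))}"] = \
                    sensitivity_at_fpr(curve, lvl)
        rows.append(row)
    report = pd.DataFrame(rows)
    return report, curves


def pairs_from_manifest_df(df: pd.DataFrame,
                           method_columns: list[str]) -> list[LabeledPair]:
    """Build LabeledPairs from a manifest table with columns
    pair_id, idA, idB, label plus one column per method score."""
    pairs = []
    for _, row in df.iterrows():
        scores = {m: float(row[m]) for m in method_columns
                  if m in row and pd.notna(row[m])}
        pairs.append(LabeledPair(str(row["pair_id"]), str(row["idA"]),
                                 str(row["idB"]), str(row["label"]), scores))
    return pairs
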