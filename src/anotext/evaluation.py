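"""Evaluation of sentiment labels against expert opinion.

Three artifacts mirror how the classifier and the dictionary method were
scored in the source study:

* **one-vs-rest quality metrics** per sentiment label (TPR, TNR, PPV,
  NPV, F1), plus a mean row;
* a **stratified error table**: per clinical group, the percentage of
  misclassified documents broken down by the expert (true) label, with
  per-group and overall totals;
* the **Wilcoxon matched-pairs signed-ranks test** for agreement between
  paired label vectors (H0: equal medians).

Conventions (documented in docs/methods.md): the neutral-label metric row
reports only TNR and NPV (the binary network never predicts neutral, and
the published tables dash the remaining cells for both methods); column
means average the *rounded* displayed cells, half-up, because that is the
arithmetic the published means follow; percentages and metrics round
half-up to 2 decimals at display time only.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "LabelRecord",
    "ConfusionCounts",
    "MetricRow",
    "ErrorTable",
    "WilcoxonResult",
    "read_labels",
    "one_vs_rest_counts",
    "metrics",
    "metric_table",
    "stratified_errors",
    "wilcoxon_matched_pairs",
    "agreement_tests",
    "round2",
]

LABELS = (1, 0, -1)
LABEL_NAMES = {1: "positive", 0: "neutral", -1: "negative"}
METHODS = ("rnn", "dict")


def round2(x: float | None) -> float | None:
    """Half-up rounding to 2 decimals, exact in decimal arithmetic."""
    if x is None:
        return None
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class LabelRecord:
    """One scored document: expert and method labels."""

    doc_id: str
    group: str            # pathological | control
    expert: int           # -1, 0, +1
    rnn: int              # -1, +1 (the network has no neutral output)
    dict: int             # -1, 0, +1

    def __post_init__(self) -> None:
        if self.group not in ("pathological", "control"):
            raise ValueError(f"group must be pathological/control, got {self.group!r}")
        if self.expert not in (-1, 0, 1) or self.dict not in (-1, 0, 1):
            raise ValueError("expert/dict labels must be in {-1, 0, +1}")
        if self.rnn not in (-1, 1):
            raise ValueError("rnn label must be in {-1, +1}")

    def label(self, method: str) -> int:
        if method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        return self.rnn if method == "rnn" else self.dict


def read_labels(path: str | Path) -> list[LabelRecord]:
    """Read a label TSV with columns ``doc_id, group, expert, rnn, dict``."""
    import pandas as pd

    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = ["doc_id", "group", "expert", "rnn", "dict"]
    missing = set(required) - set(frame.columns)
    if missing:
        raise ValueError(f"label table missing columns: {sorted(missing)}")
    return [
        LabelRecord(row.doc_id, row.group, int(row.expert), int(row.rnn),
                    int(row.dict))
        for row in frame.itertuples(index=False)
    ]


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest confusion counts for a designated target label."""

    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricRow:
    """TPR/TNR/PPV/NPV/F1; None marks an undefined (dashed) cell."""

    TPR: float | None
    TNR: float | None
    PPV: float | None
    NPV: float | None
    F1: float | None

    def as_tuple(self) -> tuple:
        return (self.TPR, self.TNR, self.PPV, self.NPV, self.F1)

    def rounded(self) -> "MetricRow":
        return MetricRow(*(round2(v) for v in self.as_tuple()))


def one_vs_rest_counts(
    records: Sequence[LabelRecord], method: str, label: int
) -> ConfusionCounts:
    """Confusion counts treating ``label`` as the positive class."""
    if not records:
        raise ValueError("no records to score")
    TP = TN = FP = FN = 0
    for rec in records:
        pred = rec.label(method)
        if rec.expert == label:
            if pred == label:
                TP += 1
            else:
                FN += 1
        elif pred == label:
            FP += 1
        else:
            TN += 1
    return ConfusionCounts(TP, TN, FP, FN)


def metrics(counts: ConfusionCounts) -> MetricRow:
    """The five quality measures; a zero denominator leaves a cell undefined.

    TPR = TP/(TP+FN), TNR = TN/(TN+FP), PPV = TP/(TP+FP),
    NPV = TN/(TN+FN), F1 = 2*TP/(2*TP+FP+FN).
    """
    def ratio(num: int, den: int) -> float | None:
        return num / den if den else None

    return MetricRow(
        TPR=ratio(counts.TP, counts.TP + counts.FN),
        TNR=ratio(counts.TN, counts.TN + counts.FP),
        PPV=ratio(counts.TP, counts.TP + counts.FP),
        NPV=ratio(counts.TN, counts.TN + counts.FN),
        F1=ratio(2 * counts.TP, 2 * counts.TP + counts.FP + counts.FN),
    )


def metric_table(
    records: Sequence[LabelRecord], method: str
) -> dict[str, MetricRow]:
    """Per-label metric rows plus the mean row, rounded for display.

    The neutral row keeps only TNR and NPV; the mean of each column
    averages its defined (already rounded) cells.
    """
    rows: dict[str, MetricRow] = {}
    for label in LABELS:
        row = metrics(one_vs_rest_counts(records, method, label)).rounded()
        if label == 0:
            row = MetricRow(None, row.TNR, None, row.NPV, None)
        rows[LABEL_NAMES[label]] = row
    mean_cells = []
    for i in range(5):
        defined = [row.as_tuple()[i] for row in rows.values()
                   if row.as_tuple()[i] is not None]
        mean_cells.append(round2(sum(defined) / len(defined)) if defined else None)
    rows["mean"] = MetricRow(*mean_cells)
    return rows


@dataclass(frozen=True)
class ErrorTable:
    """Misclassification percentages stratified by group and expert label.

    ``by_group[group][label]`` is 100 * (errors among documents whose
    expert label is ``label``) / (group's scored size); ``group_total``
    sums a group's entries; ``overall`` is the total error percentage over
    all scored records.  Values are unrounded; round at display time.
    """

    by_group: Mapping[str, Mapping[int, float]]
    group_total: Mapping[str, float]
    overall: float


def stratified_errors(records: Sequence[LabelRecord], method: str) -> ErrorTable:
    if not records:
        raise ValueError("no records to score")
    groups = sorted({rec.group for rec in records})
    by_group: dict[str, dict[int, float]] = {}
    group_total: dict[str, float] = {}
    total_errors = 0
    for group in groups:
        members = [rec for rec in records if rec.group == group]
        n = len(members)
        errs = {
            label: sum(
                1 for rec in members
                if rec.expert == label and rec.label(method) != label
            )
            for label in LABELS
        }
        by_group[group] = {label: 100.0 * errs[label] / n for label in LABELS}
        group_errors = sum(errs.values())
        group_total[group] = 100.0 * group_errors / n
        total_errors += group_errors
    return ErrorTable(by_group, group_total, 100.0 * total_errors / len(records))


# ---------------------------------------------------------------------------
# Wilcoxon matched-pairs signed-ranks test


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float      # W+ = sum of ranks of positive differences
    n_effective: int      # pairs with nonzero difference
    p_value: float
    degenerate: bool = False  # all differences were zero
    exact: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def _exact_two_sided_p(doubled_ranks: np.ndarray, w_plus_doubled: int) -> float:
    """Exact two-sided p from the null distribution of W+.

    Works on ranks doubled to integers so midranks (ties) stay exact.  The
    distribution is built by dynamic-programming convolution over the 2^n
    equiprobable sign assignments; the two-sided p doubles the smaller
    tail (counting the observed point in both), capped at 1.
    """
    total = int(doubled_ranks.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in doubled_ranks.astype(int):
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = 0.5 * (dist + shifted)
    lower = dist[: w_plus_doubled + 1].sum()
    upper = dist[w_plus_doubled:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def wilcoxon_matched_pairs(
    a: Sequence[float], b: Sequence[float], exact_limit: int = 25
) -> WilcoxonResult:
    """Two-sided Wilcoxon matched-pairs signed-ranks test.

    Classic zero handling: pairs with zero difference are dropped before
    ranking; absolute differences receive midranks on ties.  The exact
    null distribution is used for up to ``exact_limit`` effective pairs,
    a normal approximation with tie correction and a 0.5 continuity
    correction beyond.  All differences zero is a degenerate result
    reported with p = 1.
    """
    from scipy.stats import rankdata

    a_arr = np.asarray(a, dtype=float)
    b_arr = np.asarray(b, dtype=float)
    if a_arr.shape != b_arr.shape or a_arr.ndim != 1 or a_arr.size < 1:
        raise ValueError("inputs must be equal-length 1-d vectors, length >= 1")
    diff = a_arr - b_arr
    diff = diff[diff != 0.0]
    n = diff.size
    if n == 0:
        return WilcoxonResult(0.0, 0, 1.0, degenerate=True)
    ranks = rankdata(np.abs(diff))
    w_plus = float(ranks[diff > 0].sum())
    if n <= exact_limit:
        doubled = np.rint(2.0 * ranks).astype(int)
        w2 = int(round(2.0 * w_plus))
        p = _exact_two_sided_p(doubled, w2)
        return WilcoxonResult(w_plus, n, p, exact=True)
    mean = n * (n + 1) / 4.0
    # tie correction on the variance
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return WilcoxonResult(w_plus, n, 1.0, exact=False)
    d = w_plus - mean
    z = (d - 0.5 * np.sign(d)) / np.sqrt(var)
    from scipy.stats import norm

    p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return WilcoxonResult(w_plus, n, p, exact=False)


def agreement_tests(records: Sequence[LabelRecord]) -> dict[str, WilcoxonResult]:
    """Pairwise agreement tests between expert, dictionary and network labels."""
    expert = [rec.expert for rec in records]
    dic = [rec.dict for rec in records]
    rnn = [rec.rnn for rec in records]
    return {
        "expert_vs_dict": wilcoxon_matched_pairs(expert, dic),
        "expert_vs_rnn": wilcoxon_matched_pairs(expert, rnn),
        "dict_vs_rnn": wilcoxon_matched_pairs(dic, rnn),
    }
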