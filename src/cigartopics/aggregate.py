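"""Prevalence / overlap aggregation.

Builds the topic-by-topic lower-triangular matrix a surveillance report
prints: diagonal cells are per-topic prevalences, off-diagonal cells are
pairwise overlaps (a tweet carrying three topics contributes to all three
diagonal cells and all three pairwise cells), plus the coverage
statistic — the fraction of the analytic sample assigned at least one
topic. Percentages are round-half-up to two decimals, which reproduces a
printed percentage exactly from its count and sample size.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .classify import TopicAssignment

__all__ = [
    "OverlapMatrix",
    "CoverageStats",
    "format_percent",
    "build_matrix",
    "coverage",
    "write_matrix",
    "read_matrix",
]

EMPTY_CELL = "—"


def format_percent(count: int, total: int) -> str:
    """``100*count/total`` rounded half-up to 2 decimals, with trailing
    zeros ("32.77", "0.00")."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= count <= total:
        raise ValueError(f"count {count} outside [0, {total}]")
    pct = (Decimal(count) * 100 / Decimal(total)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP
    )
    return f"{pct:.2f}"


def _pct(count: int, total: int) -> str:
    # degenerate empty sample renders as 0.00 instead of erroring
    return "0.00" if total == 0 else format_percent(count, total)


@dataclass(frozen=True)
class OverlapMatrix:
    """Lower-triangular topic count/percentage matrix over an analytic
    sample of ``n_total`` tweets. ``counts[i, i]`` is the number of tweets
    assigned topic ``labels[i]``; ``counts[i, j]`` for i > j the number
    assigned both topics."""

    labels: tuple[str, ...]
    counts: np.ndarray
    n_total: int

    @property
    def percents(self) -> np.ndarray:
        k = len(self.labels)
        out = np.zeros((k, k))
        for i in range(k):
            for j in range(i + 1):
                out[i, j] = float(_pct(int(self.counts[i, j]), self.n_total))
        return out

    def cell(self, row_label: str, col_label: str) -> int:
        i = self.labels.index(row_label)
        j = self.labels.index(col_label)
        if i < j:
            i, j = j, i
        return int(self.counts[i, j])


@dataclass(frozen=True)
class CoverageStats:
    """How much of the analytic sample the topic set accounts for."""

    n_total: int
    n_classified: int
    n_unclassified: int
    pct_classified: float
    pct_unclassified: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n", "utf-8")


def build_matrix(
    assignments: Sequence[TopicAssignment],
    labels: Sequence[str],
    n_total: int,
) -> OverlapMatrix:
    """Count diagonal prevalences and pairwise overlaps.

    Every assignment's topics must be within ``labels``; an unknown label
    is a fatal error naming it. ``n_total`` may exceed the number of
    assignments (tweets absent from the sequence count as unclassified).
    """
    if n_total < len(assignments):
        raise ValueError("n_total smaller than the number of assignments")
    labels = tuple(labels)
    index = {label: i for i, label in enumerate(labels)}
    if len(index) != len(labels):
        raise ValueError("duplicate labels")
    k = len(labels)
    counts = np.zeros((k, k), dtype=np.int64)
    for a in assignments:
        idx = []
        for topic in a.topics:
            if topic not in index:
                raise ValueError(f"assignment {a.tweet_id!r} has unknown label {topic!r}")
            idx.append(index[topic])
        for i in idx:
            counts[i, i] += 1
        idx.sort()
        for x in range(len(idx)):
            for y in range(x + 1, len(idx)):
                counts[idx[y], idx[x]] += 1
    return OverlapMatrix(labels=labels, counts=counts, n_total=n_total)


def coverage(assignments: Sequence[TopicAssignment], n_total: int) -> CoverageStats:
    """Classified / unclassified split of the analytic sample."""
    if n_total < len(assignments):
        raise ValueError("n_total smaller than the number of assignments")
    n_classified = sum(1 for a in assignments if a.topics)
    n_un = n_total - n_classified
    return CoverageStats(
        n_total=n_total,
        n_classified=n_classified,
        n_unclassified=n_un,
        pct_classified=float(format_percent(n_classified, n_total)) if n_total else 0.0,
        pct_unclassified=float(format_percent(n_un, n_total)) if n_total else 0.0,
    )


def write_matrix(matrix: OverlapMatrix, path: str | Path) -> None:
    """Write the matrix as CSV mirroring the printed report layout:
    header row of labels, lower-triangle cells ``count (pct)``, em-dash
    above the diagonal, and a trailing ``n_total`` row."""
    path = Path(path)
    k = len(matrix.labels)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["topic", *matrix.labels])
        for i in range(k):
            row = [matrix.labels[i]]
            for j in range(k):
                if j > i:
                    row.append(EMPTY_CELL)
                else:
                    c = int(matrix.counts[i, j])
                    row.append(f"{c} ({_pct(c, matrix.n_total)})")
            writer.writerow(row)
        writer.writerow(["n_total", matrix.n_total])


_CELL_RE = re.compile(r"^(\d+) \(\d+\.\d{2}\)$")


def read_matrix(path: str | Path) -> OverlapMatrix:
    """Parse a CSV written by :func:`write_matrix` back into an
    :class:`OverlapMatrix` (exact count round-trip)."""
    rows = list(csv.reader(Path(path).open(encoding="utf-8")))
    labels = tuple(rows[0][1:])
    k = len(labels)
    counts = np.zeros((k, k), dtype=np.int64)
    for i in range(k):
        for j in range(i + 1):
            m = _CELL_RE.match(rows[1 + i][1 + j])
            if not m:
                raise ValueError(f"unparseable cell at row {i}, col {j}: {rows[1 + i][1 + j]!r}")
            counts[i, j] = int(m.group(1))
    n_total = int(rows[1 + k][1])
    return OverlapMatrix(labels=labels, counts=counts, n_total=n_total)
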