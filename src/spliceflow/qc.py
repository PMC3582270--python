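"""Pre-processing quality checks.

Purely reporting: per-cycle quality-score summaries (boxplot-style), per-cycle
ambiguous-base (N) fractions, read counts, read-length distribution, the
fraction of reads free of Ns, and the number of unique sequences as a
percentage of the total.  No trimming or filtering decision is taken here —
that is left to the user.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .core import ReadRecord


@dataclass
class CycleQuality:
    """Nearest-rank five-number summary plus mean of the quality scores at one
    read position, over the reads long enough to reach it."""

    n: int
    mean: float
    minimum: int
    q1: int
    median: int
    q3: int
    maximum: int


@dataclass
class QCReport:
    total_reads: int
    pct_no_ambiguous: Optional[float]
    pct_unique_sequences: Optional[float]
    per_cycle_quality: list  # of CycleQuality (empty without qualities)
    per_cycle_n_fraction: list  # fraction of N at each position
    read_length_distribution: dict  # length -> count

    def per_cycle_table(self) -> pd.DataFrame:
        rows = []
        ncyc = max(len(self.per_cycle_quality), len(self.per_cycle_n_fraction))
        for i in range(ncyc):
            row = {"cycle": i, "n_fraction": self.per_cycle_n_fraction[i]}
            if i < len(self.per_cycle_quality):
                cq = self.per_cycle_quality[i]
                row.update(
                    n=cq.n, mean_quality=cq.mean, min=cq.minimum, q1=cq.q1,
                    median=cq.median, q3=cq.q3, max=cq.maximum,
                )
            rows.append(row)
        return pd.DataFrame(rows)

    def summary_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                ("total_reads", self.total_reads),
                ("pct_no_ambiguous", self.pct_no_ambiguous),
                ("pct_unique_sequences", self.pct_unique_sequences),
            ],
            columns=["metric", "value"],
        )


def _nearest_rank(sorted_vals: np.ndarray, p: float) -> int:
    """Nearest-rank quantile: the ceil(p*n)-th smallest value."""
    n = len(sorted_vals)
    rank = max(1, int(np.ceil(p * n)))
    return int(sorted_vals[rank - 1])


def compute_qc(reads: Iterable[ReadRecord]) -> QCReport:
    """Single-pass QC over a read stream; order-invariant by construction.

    Position-``i`` statistics are computed over the reads of length > i.
    An empty stream yields total_reads 0 with the percentages absent.
    """
    total = 0
    no_n = 0
    seen: set = set()
    length_hist: dict = {}
    qual_by_cycle: list = []  # list of lists of scores
    n_by_cycle: list = []  # list of [n_count, total] pairs

    for read in reads:
        total += 1
        seq = read.sequence
        if "N" not in seq:
            no_n += 1
        seen.add(seq)
        length_hist[len(seq)] = length_hist.get(len(seq), 0) + 1
        while len(n_by_cycle) < len(seq):
            n_by_cycle.append([0, 0])
        for i, base in enumerate(seq):
            n_by_cycle[i][1] += 1
            if base == "N":
                n_by_cycle[i][0] += 1
        if read.qualities is not None:
            while len(qual_by_cycle) < len(seq):
                qual_by_cycle.append([])
            for i, q in enumerate(read.qualities):
                qual_by_cycle[i].append(q)

    if total == 0:
        return QCReport(0, None, None, [], [], {})

    per_cycle_quality = []
    for scores in qual_by_cycle:
        arr = np.sort(np.asarray(scores))
        per_cycle_quality.append(
            CycleQuality(
                n=len(arr),
                mean=float(arr.mean()),
                minimum=int(arr[0]),
                q1=_nearest_rank(arr, 0.25),
                median=_nearest_rank(arr, 0.5),
                q3=_nearest_rank(arr, 0.75),
                maximum=int(arr[-1]),
            )
        )

    return QCReport(
        total_reads=total,
        pct_no_ambiguous=100.0 * no_n / total,
        pct_unique_sequences=100.0 * len(seen) / total,
        per_cycle_quality=per_cycle_quality,
        per_cycle_n_fraction=[c[0] / c[1] for c in n_by_cycle],
        read_length_distribution=dict(sorted(length_hist.items())),
    )


def write_qc_report(report: QCReport, summary_path: str, per_cycle_path: Optional[str] = None) -> None:
    report.summary_table().to_csv(summary_path, sep="\t", index=False)
    if per_cycle_path is not None:
        report.per_cycle_table().to_csv(per_cycle_path, sep="\t", index=False)
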