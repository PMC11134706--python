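"""Per-read error summaries and length-stratified aggregates.

Read accuracy is the BLAST identity of the alignment,

    accuracy = N_match / (N_match + N_mis + N_del + N_ins),

with per-read mismatch/insertion/deletion rates over the same
denominator. Counts come from the per-position verdicts produced by
`alignio.alignment_columns`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .alignio import AlignedRead, AlignmentColumn
from .errors import EmptyInputError, InvalidParameterError


@dataclass
class ReadErrorSummary:
    read_id: str
    n_match: int
    n_mis: int
    n_del: int
    n_ins: int
    query_length: int = 0
    clip5: int = 0
    clip3: int = 0
    reported_q: float | None = None

    @property
    def denominator(self) -> int:
        return self.n_match + self.n_mis + self.n_del + self.n_ins

    @property
    def accuracy(self) -> float:
        return self.n_match / self.denominator

    @property
    def mis_rate(self) -> float:
        return self.n_mis / self.denominator

    @property
    def del_rate(self) -> float:
        return self.n_del / self.denominator

    @property
    def ins_rate(self) -> float:
        return self.n_ins / self.denominator

    @property
    def aligned_length(self) -> int:
        """Reference bases covered by the alignment (match+mis+del)."""
        return self.n_match + self.n_mis + self.n_del

    @property
    def aligned_fraction(self) -> float:
        """Aligned query bases over the full query length (clips and all)."""
        if self.query_length == 0:
            return float("nan")
        return (self.n_match + self.n_mis + self.n_ins) / self.query_length


def summarize_read(
    columns: Sequence[AlignmentColumn],
    read: AlignedRead | None = None,
    read_id: str = "",
) -> ReadErrorSummary:
    """Summarize one read's columns into counts and rates.

    All columns are counted regardless of the excluded-position mask:
    read-level accuracy is a pure CIGAR statistic, while the mask only
    gates base/motif analyses.
    """
    if not columns:
        raise EmptyInputError("cannot summarize an empty alignment")
    n_match = n_mis = n_del = n_ins = 0
    for c in columns:
        if c.verdict == "match":
            n_match += 1
        elif c.verdict == "mismatch":
            n_mis += 1
        else:
            n_del += 1
        n_ins += c.ins_count
    return ReadErrorSummary(
        read_id=read.read_id if read is not None else read_id,
        n_match=n_match,
        n_mis=n_mis,
        n_del=n_del,
        n_ins=n_ins,
        query_length=read.query_length if read is not None else 0,
        clip5=read.clip5 if read is not None else 0,
        clip3=read.clip3 if read is not None else 0,
        reported_q=read.reported_q if read is not None else None,
    )


def summaries_frame(summaries: Iterable[ReadErrorSummary]) -> pd.DataFrame:
    rows = [
        {
            "read_id": s.read_id,
            "n_match": s.n_match,
            "n_mis": s.n_mis,
            "n_del": s.n_del,
            "n_ins": s.n_ins,
            "accuracy": s.accuracy,
            "mis_rate": s.mis_rate,
            "del_rate": s.del_rate,
            "ins_rate": s.ins_rate,
            "aligned_length": s.aligned_length,
            "aligned_fraction": s.aligned_fraction,
            "clip5": s.clip5,
            "clip3": s.clip3,
            "reported_q": s.reported_q,
        }
        for s in summaries
    ]
    return pd.DataFrame(rows)


_QUANTILE_METHOD = "median_unbiased"


def aggregate_by_length(
    summaries: Iterable[ReadErrorSummary], bin_edges: Sequence[int]
) -> pd.DataFrame:
    """Accuracy/rate statistics per half-open aligned-length bin.

    Bin edges must be strictly increasing; each read falls in exactly
    one ``[lo, hi)`` bin (reads outside the edge range are dropped).
    Empty bins are reported with null statistics. Quantiles use
    median-unbiased interpolation.
    """
    edges = list(bin_edges)
    if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise InvalidParameterError("bin edges must be strictly increasing")
    summaries = list(summaries)
    rows = []
    lengths = np.array([s.aligned_length for s in summaries])
    for lo, hi in zip(edges, edges[1:]):
        sel = [s for s, l in zip(summaries, lengths) if lo <= l < hi] if summaries else []
        row: dict = {"lo": lo, "hi": hi, "n": len(sel)}
        for stat in ("accuracy", "mis_rate", "del_rate", "ins_rate"):
            vals = np.array([getattr(s, stat) for s in sel])
            if len(sel):
                row[f"median_{stat}"] = float(
                    np.quantile(vals, 0.5, method=_QUANTILE_METHOD)
                )
                row[f"q25_{stat}"] = float(
                    np.quantile(vals, 0.25, method=_QUANTILE_METHOD)
                )
                row[f"q75_{stat}"] = float(
                    np.quantile(vals, 0.75, method=_QUANTILE_METHOD)
                )
            else:
                row[f"median_{stat}"] = None
                row[f"q25_{stat}"] = None
                row[f"q75_{stat}"] = None
        rows.append(row)
    return pd.DataFrame(rows)
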