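"""Homopolymer/heteropolymer segmentation and error attribution.

A homopolymer is a maximal run (length >= 2) of one nucleotide on the
reference; it is counted once at its full length, never as multiple
shorter motifs (AAAA is one homopolymer of length 4, not two of length
2). Every position outside such runs is its own length-1 heteropolymer
segment, so the segments tile the reference. In AAGCC there are two
homopolymers of length 2 and one heteropolymer of length 1.

Mismatch and deletion errors are attributed to the category of the
segment covering their reference position; insertions are excluded
entirely (indel edge ambiguity: an insertion at a homopolymer boundary
cannot be assigned to either side). A homopolymer instance is called
accurately only when both the nucleotide identity and the run length
are correct (AAAA called AAA is wrong).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .alignio import AlignmentColumn
from .errors import AlphabetError, InternalConsistencyError

HOMOPOLYMER = "homopolymer"
HETEROPOLYMER = "heteropolymer"


@dataclass(frozen=True)
class PolymerSegment:
    start: int  # 0-based half-open reference interval
    end: int
    category: str  # HOMOPOLYMER | HETEROPOLYMER
    base: str | None  # homopolymers only
    length: int


def segment_polymers(sequence: str) -> list[PolymerSegment]:
    """Tile a reference into homopolymer and heteropolymer segments.

    Maximal single-base runs of length >= 2 become homopolymer
    segments; every other position (including N placeholders, which are
    excluded downstream anyway) is a length-1 heteropolymer segment.
    Raises `AlphabetError` on characters outside {A, C, G, U, N}.
    """
    bad = set(sequence) - set("ACGUNacgun")
    if bad:
        raise AlphabetError(f"unsupported characters in sequence: {sorted(bad)}")
    seq = sequence.upper()
    segments: list[PolymerSegment] = []
    i = 0
    n = len(seq)
    while i < n:
        j = i + 1
        while j < n and seq[j] == seq[i] and seq[i] != "N":
            j += 1
        run = j - i
        if run >= 2:
            segments.append(PolymerSegment(i, j, HOMOPOLYMER, seq[i], run))
            i = j
        else:
            segments.append(PolymerSegment(i, i + 1, HETEROPOLYMER, None, 1))
            i += 1
    return segments


def length_class(segment: PolymerSegment, group_longer_than: int | None = 3) -> str:
    """Class label: 'heteropolymer' or 'homopolymer_<len>' with lengths
    above ``group_longer_than`` grouped as e.g. 'homopolymer_4+'."""
    if segment.category == HETEROPOLYMER:
        return HETEROPOLYMER
    if group_longer_than is not None and segment.length > group_longer_than:
        return f"{HOMOPOLYMER}_{group_longer_than + 1}+"
    return f"{HOMOPOLYMER}_{segment.length}"


def _segment_index(segments: Sequence[PolymerSegment], seq_len: int) -> np.ndarray:
    idx = np.full(seq_len, -1, dtype=np.int64)
    for i, s in enumerate(segments):
        idx[s.start : s.end] = i
    return idx


@dataclass
class PolymerErrorTally:
    """Per-category error counts and relative shares (insertions ignored)."""

    table: pd.DataFrame  # class, n_sites, n_mismatch, n_deletion, shares

    @property
    def total_mismatch(self) -> int:
        return int(self.table["n_mismatch"].sum())

    @property
    def total_deletion(self) -> int:
        return int(self.table["n_deletion"].sum())


def attribute_polymer_errors(
    read_columns: Iterable[Sequence[AlignmentColumn]],
    segments: Sequence[PolymerSegment],
    group_longer_than: int | None = 3,
) -> PolymerErrorTally:
    """Attribute mismatch/deletion columns to polymer categories.

    Each non-excluded column is assigned to the segment covering its
    reference position; ``n_sites`` counts all covered positions per
    class (the abundance denominator), ``n_mismatch``/``n_deletion``
    the error columns, and the share columns give each class's fraction
    of all mismatch (resp. deletion) errors. Insertions never enter the
    tally.
    """
    if not segments:
        raise InternalConsistencyError("no segments supplied")
    seq_len = max(s.end for s in segments)
    idx = _segment_index(segments, seq_len)
    classes = sorted({length_class(s, group_longer_than) for s in segments})
    per_class = {c: {"n_sites": 0, "n_mismatch": 0, "n_deletion": 0} for c in classes}
    seg_class = [length_class(s, group_longer_than) for s in segments]
    for columns in read_columns:
        for c in columns:
            if c.excluded:
                continue
            if c.ref_pos >= seq_len or idx[c.ref_pos] < 0:
                raise InternalConsistencyError(
                    f"column at {c.ref_pos} outside any segment"
                )
            cls = seg_class[idx[c.ref_pos]]
            tally = per_class[cls]
            tally["n_sites"] += 1
            if c.verdict == "mismatch":
                tally["n_mismatch"] += 1
            elif c.verdict == "deletion":
                tally["n_deletion"] += 1
    rows = [{"class": c, **per_class[c]} for c in classes]
    df = pd.DataFrame(rows)
    for err in ("mismatch", "deletion"):
        total = df[f"n_{err}"].sum()
        df[f"{err}_share"] = df[f"n_{err}"] / total if total else math.nan
        df[f"{err}_rate"] = df[f"n_{err}"] / df["n_sites"].where(df["n_sites"] > 0)
    return PolymerErrorTally(df)


def homopolymer_accuracy_table(
    read_columns: Iterable[Sequence[AlignmentColumn]],
    segments: Sequence[PolymerSegment],
) -> pd.DataFrame:
    """Accuracy per (base, length) over fully covered homopolymer runs.

    An instance is correct iff every column in the run is a match, and
    no insertion sits at an internal junction of the run (which would
    change the called run length). Boundary insertions are ignored, as
    their attribution is ambiguous.
    """
    homos = [s for s in segments if s.category == HOMOPOLYMER]
    stats: dict[tuple[str, int], list[int]] = {}
    for columns in read_columns:
        by_pos = {c.ref_pos: c for c in columns}
        for s in homos:
            cols = [by_pos.get(p) for p in range(s.start, s.end)]
            if any(c is None or c.excluded for c in cols):
                continue
            correct = all(c.verdict == "match" for c in cols) and not any(
                c.ins_count for c in cols[:-1]
            )
            key = (s.base, s.length)
            agg = stats.setdefault(key, [0, 0])
            agg[0] += 1
            agg[1] += int(correct)
    rows = [
        {
            "base": b,
            "length": l,
            "n_instances": n,
            "n_correct": ok,
            "accuracy": ok / n,
        }
        for (b, l), (n, ok) in sorted(stats.items())
    ]
    return pd.DataFrame(rows)
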