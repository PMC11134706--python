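"""Base-level confusion and k-mer motif / context error statistics.

Counting rules for motifs (reference k-mers, transcript orientation,
enumerated by sliding window so occurrences overlap):

- mismatch event: at least one constituent base mismatched (partial and
  complete mismatches count as a single instance);
- deletion event: at least one constituent base deleted (again a single
  instance, so a fully deleted 2-mer is one event, not two);
- insertion event: any bases inserted strictly between the first and
  last motif base, independent of the insertion's length (GA -> GAA and
  GA -> GAAA are each one insertion event for GA; insertions at a
  motif's outer boundaries do not count for that motif).

An occurrence with both a mismatch and a deletion increments both
counters: the error types are defined independently. Occurrences
touching excluded (soft-masked / ambiguous) reference positions are
skipped.

Context analysis conditions on correct flanks: for an odd-k context the
center base's mismatch and deletion rates are computed over instances
whose non-center bases are all match-verdict, limiting error
propagation from neighbours.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._alphabet import RNA_BASES
from .alignio import AlignmentColumn, contiguous_blocks
from .errors import EmptyInputError, InvalidParameterError

#: Default minimum occurrences for a motif rate to be reported.
DEFAULT_MIN_INSTANCES = 100

_VERDICTS = ("A", "C", "G", "U", "deletion")


@dataclass
class ConfusionMatrix:
    """Reference base -> called base / deletion frequency table.

    Insertions are not represented: an inserted base has no reference
    base to attribute it to.
    """

    counts: pd.DataFrame  # index: reference base; columns: called A/C/G/U + deletion

    @property
    def frequencies(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        return self.counts.div(totals.where(totals > 0, 1), axis=0)

    @property
    def row_counts(self) -> pd.Series:
        return self.counts.sum(axis=1)


def base_confusion(columns: Iterable[AlignmentColumn]) -> ConfusionMatrix:
    """Tally per-base verdicts over a stream of (oriented) columns.

    Excluded columns and non-ACGU reference bases are skipped; raises
    `EmptyInputError` if nothing remains.
    """
    counts = np.zeros((4, 5), dtype=np.int64)
    base_idx = {b: i for i, b in enumerate(RNA_BASES)}
    n = 0
    for c in columns:
        if c.excluded or c.ref_base not in base_idx:
            continue
        i = base_idx[c.ref_base]
        if c.verdict == "deletion":
            counts[i, 4] += 1
        else:
            counts[i, base_idx[c.called_base]] += 1
        n += 1
    if n == 0:
        raise EmptyInputError("no usable columns for the confusion matrix")
    return ConfusionMatrix(
        pd.DataFrame(counts, index=list(RNA_BASES), columns=list(_VERDICTS))
    )


@dataclass
class MotifErrorRecord:
    """Error tallies for one reference k-mer under the counting rules."""

    motif: str
    n_instances: int = 0
    n_mismatch: int = 0
    n_deletion: int = 0
    n_insertion: int = 0
    insertion_spectrum: Counter = field(default_factory=Counter)

    @property
    def mismatch_rate(self) -> float:
        return self.n_mismatch / self.n_instances if self.n_instances else math.nan

    @property
    def deletion_rate(self) -> float:
        return self.n_deletion / self.n_instances if self.n_instances else math.nan

    @property
    def insertion_rate(self) -> float:
        if len(self.motif) < 2:
            return math.nan  # insertion semantics need an internal junction
        return self.n_insertion / self.n_instances if self.n_instances else math.nan


def motif_errors(
    read_columns: Iterable[Sequence[AlignmentColumn]],
    k: int = 2,
    motifs: Iterable[str] | None = None,
    min_instances: int = 1,
) -> dict[str, MotifErrorRecord]:
    """Per-motif error records over per-read column lists.

    ``read_columns`` yields one transcript-oriented column list per
    aligned read; every covered occurrence of every k-mer contributes
    once per read. Windows never span splice gaps. With ``motifs``
    given, only those k-mers are tallied (k taken from them).
    """
    if motifs is not None:
        motifs = {m.upper() for m in motifs}
        ks = {len(m) for m in motifs}
        if len(ks) != 1:
            raise InvalidParameterError("explicit motif set must share one length")
        k = ks.pop()
    if k < 1:
        raise InvalidParameterError("k must be >= 1")
    records: dict[str, MotifErrorRecord] = {}
    for columns in read_columns:
        for block in contiguous_blocks(list(columns)):
            for i in range(len(block) - k + 1):
                w = block[i : i + k]
                if any(c.excluded or c.ref_base not in "ACGU" for c in w):
                    continue
                motif = "".join(c.ref_base for c in w)
                if motifs is not None and motif not in motifs:
                    continue
                rec = records.get(motif)
                if rec is None:
                    rec = records[motif] = MotifErrorRecord(motif)
                rec.n_instances += 1
                if any(c.verdict == "mismatch" for c in w):
                    rec.n_mismatch += 1
                if any(c.verdict == "deletion" for c in w):
                    rec.n_deletion += 1
                if k >= 2:
                    inserted = "".join(c.ins_bases for c in w[:-1])
                    if inserted:
                        rec.n_insertion += 1
                        rec.insertion_spectrum[inserted] += 1
    return {
        m: r for m, r in sorted(records.items()) if r.n_instances >= min_instances
    }


def motif_table(records: dict[str, MotifErrorRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "motif": r.motif,
                "n_instances": r.n_instances,
                "mismatch_rate": r.mismatch_rate,
                "deletion_rate": r.deletion_rate,
                "insertion_rate": r.insertion_rate,
                "n_mismatch": r.n_mismatch,
                "n_deletion": r.n_deletion,
                "n_insertion": r.n_insertion,
            }
            for r in records.values()
        ]
    )


def insertion_spectrum_table(
    records: dict[str, MotifErrorRecord], min_fraction: float = 0.05
) -> pd.DataFrame:
    """Inserted-sequence spectrum per motif; sequences below
    ``min_fraction`` of a motif's insertions are grouped as "others"."""
    rows = []
    for r in records.values():
        total = sum(r.insertion_spectrum.values())
        if total == 0:
            continue
        others = 0
        for seq, n in r.insertion_spectrum.most_common():
            frac = n / total
            if frac < min_fraction:
                others += n
            else:
                rows.append(
                    {"motif": r.motif, "inserted_seq": seq, "n": n, "fraction": frac}
                )
        if others:
            rows.append(
                {
                    "motif": r.motif,
                    "inserted_seq": "others",
                    "n": others,
                    "fraction": others / total,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ContextErrorRecord:
    """Center-base errors within a k-mer context, flanks correct."""

    context: str
    n_conditioning_instances: int = 0
    n_center_mismatch: int = 0
    n_center_deletion: int = 0
    deletion_excluded: bool = False

    @property
    def mismatch_rate(self) -> float:
        n = self.n_conditioning_instances
        return self.n_center_mismatch / n if n else math.nan

    @property
    def deletion_rate(self) -> float:
        if self.deletion_excluded:
            return math.nan
        n = self.n_conditioning_instances
        return self.n_center_deletion / n if n else math.nan


def _center_adjacent_homopolymer(context: str) -> bool:
    c = len(context) // 2
    return context[c - 1] == context[c] or context[c] == context[c + 1]


def context_center_errors(
    read_columns: Iterable[Sequence[AlignmentColumn]],
    k: int = 3,
    exclude_internal_homopolymer: bool = False,
) -> dict[str, ContextErrorRecord]:
    """Center-base mismatch/deletion rates conditional on correct flanks.

    ``k`` must be odd (3 or 5 in practice). With
    ``exclude_internal_homopolymer``, contexts whose center base repeats
    an adjacent base are flagged and their deletion rate reported as NaN:
    a deletion there cannot be unambiguously assigned to the center (a C
    deletion in CCA could be the first or the center position).
    """
    if k < 3 or k % 2 == 0:
        raise InvalidParameterError("context k must be odd and >= 3")
    center = k // 2
    records: dict[str, ContextErrorRecord] = {}
    for columns in read_columns:
        for block in contiguous_blocks(list(columns)):
            for i in range(len(block) - k + 1):
                w = block[i : i + k]
                if any(c.excluded or c.ref_base not in "ACGU" for c in w):
                    continue
                if any(
                    c.verdict != "match" for j, c in enumerate(w) if j != center
                ):
                    continue
                context = "".join(c.ref_base for c in w)
                rec = records.get(context)
                if rec is None:
                    rec = records[context] = ContextErrorRecord(
                        context,
                        deletion_excluded=exclude_internal_homopolymer
                        and _center_adjacent_homopolymer(context),
                    )
                rec.n_conditioning_instances += 1
                if w[center].verdict == "mismatch":
                    rec.n_center_mismatch += 1
                elif w[center].verdict == "deletion":
                    rec.n_center_deletion += 1
    return dict(sorted(records.items()))


def context_table(records: dict[str, ContextErrorRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "context": r.context,
                "n": r.n_conditioning_instances,
                "mismatch_rate": r.mismatch_rate,
                "deletion_rate": r.deletion_rate,
                "deletion_excluded": r.deletion_excluded,
            }
            for r in records.values()
        ]
    )
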