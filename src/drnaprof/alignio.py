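"""Reference/alignment ingestion and per-position error decomposition.

Reads FASTA references and SAM/BAM alignments of direct RNA sequencing
reads (minimap2 ``-ax splice --eqx`` upstream), applies the standard
filters (drop unmapped/secondary/supplementary records, MapQ < 20, reads
shorter than 100 bases), and decomposes each surviving alignment into a
list of per-reference-position verdicts (match / mismatch / deletion,
with insertions anchored to the junction after a reference position) by
walking the CIGAR string.

Coordinates are 0-based half-open throughout; SAM's 1-based coordinates
are converted at the boundary by pysam.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pysam
from Bio import SeqIO

from ._alphabet import complement, revcomp, to_rna
from .errors import FormatError, InvalidParameterError, UnsupportedCigarError

#: Standard alignment filters for this assay.
DEFAULT_MIN_MAPQ = 20
DEFAULT_MIN_LENGTH = 100
#: Cap used when large runs are subsampled for tractability.
DEFAULT_SUBSAMPLE_CAP = 200_000

_QUERY_OPS = set("MIS=X")
_REF_OPS = set("MDN=X")


@dataclass
class ReferenceSequence:
    """A reference sequence with an excluded-position mask.

    Soft-masked (lowercase) and ambiguous (N/n) positions in the source
    FASTA are flagged as excluded; columns over them are dropped from
    base/motif statistics downstream.
    """

    name: str
    sequence: str  # uppercase RNA alphabet (N retained)
    excluded: np.ndarray  # bool mask, same length as sequence

    def __post_init__(self) -> None:
        self.excluded = np.asarray(self.excluded, dtype=bool)
        if len(self.excluded) != len(self.sequence):
            raise InvalidParameterError("mask length must equal sequence length")

    def __len__(self) -> int:
        return len(self.sequence)


def load_reference(fasta_path: str | Path) -> dict[str, ReferenceSequence]:
    """Load a FASTA file into `ReferenceSequence` objects, keyed by name.

    Lowercase and N/n positions are flagged excluded; the stored sequence
    is uppercased with T mapped to U.
    """
    path = Path(fasta_path)
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:
        raise FormatError(f"malformed FASTA {path}: {exc}") from exc
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    refs: dict[str, ReferenceSequence] = {}
    for rec in records:
        raw = str(rec.seq)
        if not rec.id:
            raise FormatError(f"FASTA record without a name in {path}")
        mask = np.fromiter(
            (c.islower() or c in "Nn" for c in raw), dtype=bool, count=len(raw)
        )
        refs[rec.id] = ReferenceSequence(rec.id, to_rna(raw), mask)
    return refs


@dataclass
class AlignedRead:
    """One filtered alignment record.

    ``query`` and ``qualities`` are in SAM (reference-forward)
    orientation; ``clip5``/``clip3`` are soft-clip lengths in *read*
    orientation (for a reverse-strand alignment the trailing S in the SAM
    CIGAR is the read's 5' clip).
    """

    read_id: str
    query: str
    qualities: np.ndarray | None
    reference_name: str
    reference_start: int
    strand: str  # '+' or '-'
    cigar: list[tuple[str, int]]
    mapq: int
    flag: int
    clip5: int
    clip3: int
    reported_q: float | None = None

    @property
    def query_length(self) -> int:
        return len(self.query)


@dataclass(slots=True)
class AlignmentColumn:
    """Verdict at one reference position.

    ``ins_count``/``ins_bases`` describe bases inserted between this and
    the next reference position (reference-forward orientation).
    ``query_pos`` indexes the SAM-orientation query (None for deletions).
    """

    ref_pos: int
    ref_base: str
    verdict: str  # 'match' | 'mismatch' | 'deletion'
    called_base: str | None
    query_pos: int | None
    ins_count: int = 0
    ins_bases: str = ""
    excluded: bool = False


def _cigar_clips(cigar: list[tuple[str, int]], strand: str) -> tuple[int, int]:
    left = cigar[0][1] if cigar and cigar[0][0] == "S" else 0
    right = cigar[-1][1] if cigar and cigar[-1][0] == "S" else 0
    return (left, right) if strand == "+" else (right, left)


def _to_aligned_read(
    rec: pysam.AlignedSegment, qscores: Mapping[str, float] | None
) -> AlignedRead | None:
    if rec.query_sequence is None or rec.cigartuples is None:
        return None
    cigar = [
        ("MIDNSHP=XB"[op], length) for op, length in rec.cigartuples
    ]
    strand = "-" if rec.is_reverse else "+"
    clip5, clip3 = _cigar_clips(cigar, strand)
    quals = (
        np.asarray(rec.query_qualities, dtype=float)
        if rec.query_qualities is not None
        else None
    )
    reported = None
    if qscores is not None:
        reported = qscores.get(rec.query_name)
    return AlignedRead(
        read_id=rec.query_name,
        query=to_rna(rec.query_sequence),
        qualities=quals,
        reference_name=rec.reference_name,
        reference_start=rec.reference_start,
        strand=strand,
        cigar=cigar,
        mapq=rec.mapping_quality,
        flag=rec.flag,
        clip5=clip5,
        clip3=clip3,
        reported_q=reported,
    )


def load_qscore_summary(path: str | Path) -> dict[str, float]:
    """Read a sequencing-summary-style TSV (read_id, mean_qscore)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    if "read_id" not in df.columns or "mean_qscore" not in df.columns:
        raise FormatError("summary TSV needs columns read_id, mean_qscore")
    return dict(zip(df["read_id"], df["mean_qscore"].astype(float)))


def stream_alignments(
    sam_path: str | Path,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    min_length: int = DEFAULT_MIN_LENGTH,
    *,
    qscores: Mapping[str, float] | str | Path | None = None,
    subsample: int | None = None,
    seed: int | None = None,
) -> Iterator[AlignedRead]:
    """Stream filtered alignments from a SAM/BAM file.

    Unmapped, secondary and supplementary records are dropped, as are
    records below ``min_mapq`` or whose full query (clips included) is
    shorter than ``min_length`` bases. With ``subsample`` set, a seeded
    reservoir sample of that many reads is returned (in file order), so
    repeated passes over the same file select the same reads.
    """
    if isinstance(qscores, (str, Path)):
        qscores = load_qscore_summary(qscores)
    if subsample is not None and seed is None:
        raise InvalidParameterError("subsampling requires a seed")

    def _iter() -> Iterator[AlignedRead]:
        try:
            handle = pysam.AlignmentFile(str(sam_path), "r")
        except ValueError as exc:  # e.g. missing @SQ header lines
            raise FormatError(f"cannot open {sam_path}: {exc}") from exc
        with handle:
            for rec in handle:
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                if rec.mapping_quality < min_mapq:
                    continue
                if rec.query_sequence is None or len(rec.query_sequence) < min_length:
                    continue
                read = _to_aligned_read(rec, qscores)
                if read is not None:
                    yield read

    if subsample is None:
        yield from _iter()
        return
    rng = random.Random(seed)
    reservoir: list[tuple[int, AlignedRead]] = []
    for i, read in enumerate(_iter()):
        if len(reservoir) < subsample:
            reservoir.append((i, read))
        else:
            j = rng.randrange(i + 1)
            if j < subsample:
                reservoir[j] = (i, read)
    for _, read in sorted(reservoir, key=lambda t: t[0]):
        yield read


def alignment_columns(
    read: AlignedRead, reference: ReferenceSequence | None = None
) -> list[AlignmentColumn]:
    """Decompose one alignment into per-reference-position verdicts.

    ``=``/``X``/``D`` map directly to verdicts; ``M`` is resolved by base
    comparison against the reference (required in that case); ``N``
    (splice) advances the reference without emitting columns; soft clips
    are recorded on the read, not as columns. An insertion before the
    first aligned column is folded into the 5' soft clip. Columns over
    excluded reference positions carry ``excluded=True``.
    """
    cols: list[AlignmentColumn] = []
    rpos = read.reference_start
    qpos = 0
    q = read.query

    def _refbase(p: int) -> str:
        if reference is None:
            return "N"
        return reference.sequence[p]

    def _excl(p: int) -> bool:
        return bool(reference.excluded[p]) if reference is not None else False

    for op, length in read.cigar:
        if op == "S":
            qpos += length
        elif op == "H":
            continue
        elif op == "=":
            for i in range(length):
                b = q[qpos + i]
                cols.append(
                    AlignmentColumn(rpos + i, b, "match", b, qpos + i, excluded=_excl(rpos + i))
                )
            rpos += length
            qpos += length
        elif op == "X":
            for i in range(length):
                cols.append(
                    AlignmentColumn(
                        rpos + i,
                        _refbase(rpos + i),
                        "mismatch",
                        q[qpos + i],
                        qpos + i,
                        excluded=_excl(rpos + i),
                    )
                )
            rpos += length
            qpos += length
        elif op == "M":
            if reference is None:
                raise UnsupportedCigarError(
                    "CIGAR op M requires the reference to resolve match/mismatch"
                )
            for i in range(length):
                rb = reference.sequence[rpos + i]
                cb = q[qpos + i]
                verdict = "match" if cb == rb else "mismatch"
                cols.append(
                    AlignmentColumn(
                        rpos + i, rb, verdict, cb, qpos + i, excluded=_excl(rpos + i)
                    )
                )
            rpos += length
            qpos += length
        elif op == "D":
            for i in range(length):
                cols.append(
                    AlignmentColumn(
                        rpos + i,
                        _refbase(rpos + i),
                        "deletion",
                        None,
                        None,
                        excluded=_excl(rpos + i),
                    )
                )
            rpos += length
        elif op == "N":
            rpos += length
        elif op == "I":
            bases = q[qpos : qpos + length]
            qpos += length
            if cols:
                cols[-1].ins_count += length
                cols[-1].ins_bases += bases
            # else: leading insertion, treated as part of the 5' clip
        else:
            raise UnsupportedCigarError(f"unsupported CIGAR op {op!r}")
    return cols


def orient_columns(
    columns: list[AlignmentColumn], strand: str
) -> list[AlignmentColumn]:
    """Return columns in transcript (read-sense) orientation.

    Direct RNA reads are sense-strand; motif and context analysis is done
    in the orientation the molecule passed the pore. For '+' alignments
    this is the identity. For '-' alignments the column list is reversed,
    bases complemented, and each insertion re-anchored to the junction it
    occupies in transcript orientation (with its bases reverse
    complemented). The insertion after the highest reference position, if
    any, falls before the first transcript-oriented column and is dropped
    (boundary junction).
    """
    if strand == "+":
        return columns
    out: list[AlignmentColumn] = []
    n = len(columns)
    for j in range(n - 1, -1, -1):
        c = columns[j]
        cc = AlignmentColumn(
            ref_pos=c.ref_pos,
            ref_base=complement(c.ref_base),
            verdict=c.verdict,
            called_base=complement(c.called_base) if c.called_base else None,
            query_pos=c.query_pos,
            excluded=c.excluded,
        )
        if j > 0 and columns[j - 1].ins_count:
            prev = columns[j - 1]
            cc.ins_count = prev.ins_count
            cc.ins_bases = revcomp(prev.ins_bases)
        out.append(cc)
    return out


def contiguous_blocks(
    columns: list[AlignmentColumn],
) -> Iterable[list[AlignmentColumn]]:
    """Split a column list into blocks of adjacent reference positions.

    Splice gaps (N ops) break adjacency; motif windows must not span
    them. Works on both orientations (checks |Δref_pos| == 1).
    """
    if not columns:
        return
    block = [columns[0]]
    for c in columns[1:]:
        if abs(c.ref_pos - block[-1].ref_pos) == 1:
            block.append(c)
        else:
            yield block
            block = [c]
    yield block
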