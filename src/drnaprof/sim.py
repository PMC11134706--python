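"""Truth-annotated simulator for direct RNA sequencing reads and signals.

The generator is the study-conditions stand-in for real basecalled data:
it produces references (random or de Bruijn, so that every k-mer context
is represented, as in curlcake-style synthetic RNA), reads corrupted by
configurable substitution / deletion / insertion processes (deletions
optionally homopolymer-run-length dependent), truthful or deliberately
mis-calibrated per-base qualities, spliced and reverse-strand
alignments, 3' adapter-failure soft clips, and per-base Gaussian signal
segments with dwell times in multiples of a fixed stride.

Defaults mirror the error structure typical of SQK-RNA001/002 data:
deletions ~5% per read, mismatches ~3%, insertions ~2%, ~30% of reads
carrying a 50-130 nt 3' adapter-failure clip, pore levels ranked
G > A > U > C, and longer dwells on C/U than on G/A.

Every stochastic choice flows through a single seeded numpy Generator,
so a given seed reproduces the dataset byte for byte. The emitted SAM is
in ``--eqx`` dialect (``=``/``X`` ops), so truth alignments can be
re-counted without a reference lookup.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from ._alphabet import BASE_INDEX, RNA_BASES, revcomp
from .errors import InvalidParameterError
from .signal import SignalRead

#: Quality assigned to adapter-junk (soft-clipped) bases: adapter
#: basecalls are characteristically low quality, but no distribution is
#: established, so a flat low Phred value is used.
CLIP_QUALITY = 3.0


# ---------------------------------------------------------------------------
# models


def _uniform_substitution(rate: float) -> np.ndarray:
    m = np.full((4, 4), rate / 3.0)
    np.fill_diagonal(m, 0.0)
    return m


@dataclass(frozen=True)
class ErrorModel:
    """Generative error model for read simulation.

    ``substitution_matrix[i, j]`` is the absolute probability that
    reference base i is called as base j (diagonal zero; the implied
    match probability completes each row to 1 together with the deletion
    probability). ``deletion_rate_by_context`` overrides the flat
    deletion rate for ``(base, homopolymer run length)`` keys; a lookup
    for run length L falls back to the largest key <= L for that base,
    then to ``deletion_rate``. ``quality_model`` is either "truthful"
    (per-base q encodes the model-marginal error probability of that
    base) or a fixed Phred offset added to the truthful value.
    """

    substitution_matrix: np.ndarray
    deletion_rate: float = 0.05
    deletion_rate_by_context: Mapping[tuple[str, int], float] = field(
        default_factory=dict
    )
    insertion_rate: float = 0.02
    insertion_base_probs: Sequence[float] = (0.25, 0.25, 0.25, 0.25)
    adapter_failure_fraction: float = 0.3
    adapter_clip_range: tuple[int, int] = (50, 130)
    baseline_clip_mean: float = 3.0
    quality_model: str | float = "truthful"
    seed: int = 0

    def __post_init__(self) -> None:
        m = np.asarray(self.substitution_matrix, dtype=float)
        object.__setattr__(self, "substitution_matrix", m)
        if m.shape != (4, 4) or (m < 0).any() or np.diag(m).any():
            raise InvalidParameterError(
                "substitution_matrix must be 4x4, non-negative, zero diagonal"
            )
        rates = [self.deletion_rate, self.insertion_rate, self.adapter_failure_fraction]
        rates += list(self.deletion_rate_by_context.values())
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise InvalidParameterError("all probabilities must be in [0, 1]")
        row = m.sum(axis=1)
        dmax = max([self.deletion_rate, *self.deletion_rate_by_context.values()], default=0.0)
        if (row + dmax > 1.0).any():
            raise InvalidParameterError(
                "substitution row plus deletion probability exceeds 1"
            )
        lo, hi = self.adapter_clip_range
        if not lo < hi:
            raise InvalidParameterError("adapter_clip_range min must be < max")
        if isinstance(self.quality_model, str) and self.quality_model != "truthful":
            raise InvalidParameterError(
                "quality_model must be 'truthful' or a Phred offset"
            )

    @classmethod
    def uniform(
        cls,
        substitution_rate: float = 0.03,
        deletion_rate: float = 0.05,
        insertion_rate: float = 0.02,
        **kwargs,
    ) -> "ErrorModel":
        """Model with uniform off-diagonal substitutions at a total rate."""
        return cls(
            substitution_matrix=_uniform_substitution(substitution_rate),
            deletion_rate=deletion_rate,
            insertion_rate=insertion_rate,
            **kwargs,
        )

    @classmethod
    def error_free(cls, **kwargs) -> "ErrorModel":
        kwargs.setdefault("adapter_failure_fraction", 0.0)
        kwargs.setdefault("baseline_clip_mean", 0.0)
        return cls.uniform(0.0, 0.0, 0.0, **kwargs)

    def deletion_prob(self, base: str, run_length: int) -> float:
        if self.deletion_rate_by_context:
            for length in range(run_length, 0, -1):
                if (base, length) in self.deletion_rate_by_context:
                    return self.deletion_rate_by_context[(base, length)]
        return self.deletion_rate


@dataclass(frozen=True)
class PoreModel:
    """Per-base signal model for squiggle simulation.

    Current levels (pA) default to the observed intensity ranking
    G > A > U > C; dwell defaults to a geometric number of stride steps
    per base with longer means on C/U than G/A. ``dwell_sampler`` can
    replace the geometric family (called as ``f(rng, base) -> strides``).
    """

    mean_pa: Mapping[str, float] = field(
        default_factory=lambda: {"G": 110.0, "A": 100.0, "U": 90.0, "C": 80.0}
    )
    sd_pa: Mapping[str, float] = field(
        default_factory=lambda: {b: 3.0 for b in RNA_BASES}
    )
    dwell_mean_strides: Mapping[str, float] = field(
        default_factory=lambda: {"G": 3.0, "A": 3.0, "U": 5.0, "C": 6.0}
    )
    stride: int = 10
    dwell_sampler: Callable | None = None

    def __post_init__(self) -> None:
        if self.stride < 1:
            raise InvalidParameterError("stride must be >= 1")
        if any(v < 0 for v in self.sd_pa.values()):
            raise InvalidParameterError("current SDs must be >= 0")
        if any(v < 1 for v in self.dwell_mean_strides.values()):
            raise InvalidParameterError("mean dwell must be >= 1 stride")


# ---------------------------------------------------------------------------
# reference generation


def _de_bruijn_sequence(k: int, alphabet: str) -> str:
    """Linear sequence of length ``4**k + k - 1`` containing every k-mer
    over ``alphabet`` exactly once (standard Lyndon-word construction,
    cyclic sequence linearized by appending its first k-1 symbols)."""
    n = len(alphabet)
    a = [0] * (n * k)
    seq: list[int] = []

    def db(t: int, p: int) -> None:
        if t > k:
            if k % p == 0:
                seq.extend(a[1 : p + 1])
        else:
            a[t] = a[t - p]
            db(t + 1, p)
            for j in range(a[t - p] + 1, n):
                a[t] = j
                db(t + 1, t)

    db(1, 1)
    cyc = "".join(alphabet[i] for i in seq)
    return cyc + cyc[: k - 1]


def make_reference(
    length: int | None = None,
    mode: str = "random",
    k: int = 5,
    seed: int = 0,
) -> str:
    """Generate a reference sequence over {A, C, G, U}.

    ``debruijn`` mode returns a linear sequence of length ``4**k + k - 1``
    containing every k-mer exactly once (the design principle of
    curlcake-style synthetic RNA, which covers all 5-mer contexts);
    ``length`` is ignored there. ``random`` mode draws uniform i.i.d.
    bases. The seed permutes the alphabet in de Bruijn mode and seeds the
    RNG in random mode, so the same seed always reproduces the sequence.
    """
    rng = np.random.default_rng(seed)
    if mode == "debruijn":
        if k < 1:
            raise InvalidParameterError("k must be >= 1")
        alphabet = "".join(rng.permutation(list(RNA_BASES)))
        return _de_bruijn_sequence(k, alphabet)
    if mode == "random":
        if length is None or length < 1:
            raise InvalidParameterError("length must be >= 1 in random mode")
        return "".join(rng.choice(list(RNA_BASES), size=length))
    raise InvalidParameterError(f"unknown reference mode {mode!r}")


def write_fasta(references: Mapping[str, str], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=n, description="") for n, s in references.items()]
    seqio_write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# read simulation


@dataclass
class GroundTruthRecord:
    """Per-read truth: the outcome at every covered reference position.

    ``outcomes`` is in transcript orientation, one of '=', 'X', 'D' per
    covered reference position (splice gaps excluded);
    ``insertion_positions`` are transcript-orientation junction indices
    (insertion after template position i). ``clip3`` is the 3' soft-clip
    length in read orientation; ``adapter_failed`` marks second-mode
    clips.
    """

    read_id: str
    reference_name: str
    start: int
    end: int
    strand: str
    outcomes: list[str]
    insertion_positions: list[int]
    clip5: int
    clip3: int
    adapter_failed: bool
    intron: tuple[int, int] | None = None  # (template junction, gap length)

    @property
    def n_match(self) -> int:
        return self.outcomes.count("=")

    @property
    def n_mis(self) -> int:
        return self.outcomes.count("X")

    @property
    def n_del(self) -> int:
        return self.outcomes.count("D")

    @property
    def n_ins(self) -> int:
        return len(self.insertion_positions)


@dataclass
class SimulatedRead:
    """One simulated read in basecall (transcript-sense) orientation."""

    read_id: str
    sequence: str  # full read, clips included
    qualities: np.ndarray  # float Phred per base, unrounded
    mean_qscore: float
    strand: str
    reference_name: str
    ref_start: int
    ref_end: int
    cigar: list[tuple[str, int]]  # transcript orientation, clips included
    clip5: int
    clip3: int


def _run_lengths(seq: str) -> np.ndarray:
    """Length of the maximal single-base run covering each position."""
    out = np.empty(len(seq), dtype=np.int64)
    i = 0
    for _, grp in itertools.groupby(seq):
        n = len(list(grp))
        out[i : i + n] = n
        i += n
    return out


def _rle(ops: Iterable[str]) -> list[tuple[str, int]]:
    return [(op, len(list(g))) for op, g in itertools.groupby(ops)]


def _draw_length(read_length, rng: np.random.Generator) -> int:
    if callable(read_length):
        return int(read_length(rng))
    if isinstance(read_length, (tuple, list)):
        lo, hi = read_length
        if hi < lo or hi < 1:
            raise InvalidParameterError("invalid read length range")
        return int(rng.integers(lo, hi + 1))
    if read_length < 1:
        raise InvalidParameterError("read length must be >= 1")
    return int(read_length)


@dataclass
class SimulatedReadSet:
    """Reads + ground truth + writers for the on-disk exchange formats."""

    reads: list[SimulatedRead]
    truth: list[GroundTruthRecord]
    references: Mapping[str, str]
    model: ErrorModel

    def write_fastq(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.reads:
                q = np.clip(np.rint(r.qualities), 0, 93).astype(int)
                qstr = "".join(chr(v + 33) for v in q)
                fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qstr}\n")

    def write_summary_tsv(self, path: str | Path) -> None:
        """Sequencing-summary-style table: read_id, mean_qscore."""
        with open(path, "w") as fh:
            fh.write("read_id\tmean_qscore\n")
            for r in self.reads:
                fh.write(f"{r.read_id}\t{r.mean_qscore:.4f}\n")

    def write_truth_tsv(self, path: str | Path) -> None:
        rows = [
            {
                "read_id": t.read_id,
                "reference": t.reference_name,
                "start": t.start,
                "end": t.end,
                "strand": t.strand,
                "n_match": t.n_match,
                "n_mis": t.n_mis,
                "n_del": t.n_del,
                "n_ins": t.n_ins,
                "clip5": t.clip5,
                "clip3": t.clip3,
                "adapter_failed": t.adapter_failed,
            }
            for t in self.truth
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    def write_sam(self, path: str | Path) -> None:
        """Truth alignments as text SAM in ``--eqx`` dialect."""
        header = pysam.AlignmentHeader.from_dict(
            {
                "HD": {"VN": "1.6", "SO": "unsorted"},
                "SQ": [
                    {"SN": name, "LN": len(seq)}
                    for name, seq in self.references.items()
                ],
            }
        )
        ref_ids = {name: i for i, name in enumerate(self.references)}
        opcodes = {"M": 0, "I": 1, "D": 2, "N": 3, "S": 4, "=": 7, "X": 8}
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            for r in self.reads:
                a = pysam.AlignedSegment(header)
                a.query_name = r.read_id
                a.flag = 16 if r.strand == "-" else 0
                a.reference_id = ref_ids[r.reference_name]
                a.reference_start = r.ref_start
                a.mapping_quality = 60
                cigar = r.cigar if r.strand == "+" else r.cigar[::-1]
                a.cigartuples = [(opcodes[op], n) for op, n in cigar]
                seq = r.sequence if r.strand == "+" else revcomp(r.sequence)
                quals = np.clip(np.rint(r.qualities), 0, 93).astype(int)
                if r.strand == "-":
                    quals = quals[::-1]
                a.query_sequence = seq
                a.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(v + 33) for v in quals)
                )
                out.write(a)

    def write_all(self, prefix: str | Path) -> dict[str, Path]:
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": prefix.with_suffix(".ref.fasta"),
            "fastq": prefix.with_suffix(".fastq"),
            "sam": prefix.with_suffix(".sam"),
            "truth": prefix.with_suffix(".truth.tsv"),
            "summary": prefix.with_suffix(".summary.tsv"),
        }
        write_fasta(self.references, paths["fasta"])
        self.write_fastq(paths["fastq"])
        self.write_sam(paths["sam"])
        self.write_truth_tsv(paths["truth"])
        self.write_summary_tsv(paths["summary"])
        return paths

    def pooled_rates(self) -> dict[str, float]:
        """Generator's own pooled error tallies (mis/del/ins/accuracy)."""
        n_match = sum(t.n_match for t in self.truth)
        n_mis = sum(t.n_mis for t in self.truth)
        n_del = sum(t.n_del for t in self.truth)
        n_ins = sum(t.n_ins for t in self.truth)
        denom = n_match + n_mis + n_del + n_ins
        return {
            "accuracy": n_match / denom,
            "mis_rate": n_mis / denom,
            "del_rate": n_del / denom,
            "ins_rate": n_ins / denom,
            "n_bases": denom,
        }


def simulate_reads(
    reference: str | Mapping[str, str],
    error_model: ErrorModel,
    n_reads: int,
    read_length: int | tuple[int, int] | Callable = (500, 1500),
    *,
    reverse_fraction: float = 0.0,
    splice: tuple[int, float] | None = None,
    seed: int | None = None,
    read_id_prefix: str = "read",
) -> SimulatedReadSet:
    """Simulate reads as corrupted reference substrings with full truth.

    Each read takes a substring of a reference (chosen in proportion to
    the number of possible start positions), optionally reverse-strand
    (``reverse_fraction``) or carrying one fixed-length splice gap
    (``splice=(gap_nt, probability)``). Errors are drawn per the
    `ErrorModel`; per-base qualities follow its quality model, with
    soft-clipped junk bases at Phred 3. The per-read ``mean_qscore``
    (Phred back-conversion of the mean per-base error probability) is
    computed from unrounded qualities, as a basecaller would from its
    internal floats.
    """
    if n_reads < 1:
        raise InvalidParameterError("n_reads must be >= 1")
    refs = {"ref": reference} if isinstance(reference, str) else dict(reference)
    if not refs or any(len(s) == 0 for s in refs.values()):
        raise InvalidParameterError("reference must be non-empty")
    rng = np.random.default_rng(error_model.seed if seed is None else seed)
    model = error_model
    m = model.substitution_matrix
    row_tot = m.sum(axis=1)
    # conditional substitution target distributions per reference base
    cond = np.where(row_tot[:, None] > 0, m / np.where(row_tot[:, None] == 0, 1, row_tot[:, None]), 0.25)
    ins_probs = np.asarray(model.insertion_base_probs, dtype=float)
    ins_probs = ins_probs / ins_probs.sum()
    offset = 0.0 if model.quality_model == "truthful" else float(model.quality_model)

    ref_names = list(refs)
    reads: list[SimulatedRead] = []
    truths: list[GroundTruthRecord] = []
    for idx in range(n_reads):
        L = _draw_length(read_length, rng)
        weights = np.array([max(len(refs[n]) - L + 1, 0) for n in ref_names], float)
        if weights.sum() == 0:  # read longer than every reference: clamp
            name = ref_names[int(np.argmax([len(refs[n]) for n in ref_names]))]
            L = len(refs[name])
            gap = 0
            start = 0
        else:
            name = ref_names[int(rng.choice(len(ref_names), p=weights / weights.sum()))]
        ref = refs[name]
        gap, junction = 0, None
        if splice is not None and L >= 100:
            gap_len, prob = splice
            if rng.random() < prob and len(ref) >= L + gap_len:
                gap = gap_len
                junction = int(rng.integers(20, L - 20))
        span = L + gap
        if span > len(ref):
            gap, junction, span = 0, None, L
        start = int(rng.integers(0, len(ref) - span + 1))
        strand = "-" if rng.random() < reverse_fraction else "+"
        covered = ref[start : start + L] if gap == 0 else (
            ref[start : start + junction] + ref[start + junction + gap : start + span]
        )
        template = covered if strand == "+" else revcomp(covered)
        # splice junction index in template orientation
        tjunction = None
        if junction is not None:
            tjunction = junction if strand == "+" else L - junction

        runs = _run_lengths(template)
        tidx = np.fromiter((BASE_INDEX[b] for b in template), dtype=np.int64, count=L)
        if model.deletion_rate_by_context:
            d = np.fromiter(
                (model.deletion_prob(b, int(r)) for b, r in zip(template, runs)),
                dtype=float,
                count=L,
            )
        else:
            d = np.full(L, model.deletion_rate)
        s = row_tot[tidx]
        u = rng.random(L)
        del_mask = u < d
        sub_mask = (~del_mask) & (u < d + s)
        ins_mask = np.zeros(L, dtype=bool)
        if L > 1 and model.insertion_rate > 0:
            ins_mask[: L - 1] = rng.random(L - 1) < model.insertion_rate
        alt = np.full(L, -1, dtype=np.int64)
        for bi in range(4):
            sel = sub_mask & (tidx == bi)
            nsel = int(sel.sum())
            if nsel:
                alt[sel] = rng.choice(4, size=nsel, p=cond[bi])
        n_ins_total = int(ins_mask.sum())
        ins_bases = rng.choice(4, size=n_ins_total, p=ins_probs) if n_ins_total else []

        ops: list[str] = []
        qbases: list[str] = []
        pvals: list[float] = []
        outcomes: list[str] = []
        ins_positions: list[int] = []
        ins_iter = iter(ins_bases)
        for i in range(L):
            if tjunction is not None and i == tjunction:
                ops.append("N")
            b = template[i]
            p_err = min((d[i] + s[i]) / max(1.0 - d[i], 1e-12), 1.0)
            if del_mask[i]:
                ops.append("D")
                outcomes.append("D")
            elif sub_mask[i]:
                cb = RNA_BASES[alt[i]]
                ops.append("X")
                qbases.append(cb)
                pvals.append(p_err)
                outcomes.append("X")
            else:
                ops.append("=")
                qbases.append(b)
                pvals.append(p_err)
                outcomes.append("=")
            if ins_mask[i]:
                ops.append("I")
                qbases.append(RNA_BASES[next(ins_iter)])
                pvals.append(1.0)
                ins_positions.append(i)

        # soft clips: ordinary short clips, plus adapter-failure junk at 3'
        def _geom_clip() -> int:
            if model.baseline_clip_mean <= 0:
                return 0
            p = 1.0 / (1.0 + model.baseline_clip_mean)
            return int(rng.geometric(p) - 1)

        clip5 = _geom_clip()
        adapter_failed = rng.random() < model.adapter_failure_fraction
        if adapter_failed:
            lo, hi = model.adapter_clip_range
            clip3 = int(rng.integers(lo, hi + 1))
        else:
            clip3 = _geom_clip()
        junk5 = "".join(rng.choice(list(RNA_BASES), size=clip5)) if clip5 else ""
        junk3 = "".join(rng.choice(list(RNA_BASES), size=clip3)) if clip3 else ""

        aligned_q = np.array(pvals, dtype=float)
        with np.errstate(divide="ignore"):
            q_aligned = -10.0 * np.log10(np.maximum(aligned_q, 1e-12))
        q_aligned = np.minimum(q_aligned, 60.0) + offset
        quals = np.concatenate(
            [np.full(clip5, CLIP_QUALITY), q_aligned, np.full(clip3, CLIP_QUALITY)]
        )
        p_all = 10 ** (-quals / 10.0)
        mean_q = float(-10.0 * np.log10(p_all.mean())) if quals.size else 0.0

        cigar = _rle(ops)
        if tjunction is not None and gap:  # expand the N placeholder
            cigar = [(op, n if op != "N" else gap) for op, n in cigar]
        if clip5:
            cigar = [("S", clip5)] + cigar
        if clip3:
            cigar = cigar + [("S", clip3)]
        read_id = f"{read_id_prefix}{idx:06d}"
        reads.append(
            SimulatedRead(
                read_id=read_id,
                sequence=junk5 + "".join(qbases) + junk3,
                qualities=quals,
                mean_qscore=mean_q,
                strand=strand,
                reference_name=name,
                ref_start=start,
                ref_end=start + span,
                cigar=cigar,
                clip5=clip5,
                clip3=clip3,
            )
        )
        truths.append(
            GroundTruthRecord(
                read_id=read_id,
                reference_name=name,
                start=start,
                end=start + span,
                strand=strand,
                outcomes=outcomes,
                insertion_positions=ins_positions,
                clip5=clip5,
                clip3=clip3,
                adapter_failed=adapter_failed,
                intron=(junction, gap) if gap else None,
            )
        )
    return SimulatedReadSet(reads, truths, refs, model)


# ---------------------------------------------------------------------------
# signal simulation


def simulate_signals(
    reads: Sequence[SimulatedRead],
    pore_model: PoreModel,
    seed: int = 0,
    *,
    offset_range: tuple[int, int] = (50, 150),
    adapter_level: tuple[float, float] = (75.0, 8.0),
) -> list[SignalRead]:
    """Simulate per-read squiggles matching the Move-table convention.

    Per base, the dwell is a draw from the pore model's dwell
    distribution (in multiples of the stride) and samples are i.i.d.
    Gaussian around that base's current level. The Move table has a 1 at
    each base start; total samples = start offset + stride x Move
    length. The ``start_offset`` region is filled with adapter-like
    noise.
    """
    pm = pore_model
    rng = np.random.default_rng(seed)
    lo, hi = offset_range
    if lo < 0 or hi < lo:
        raise InvalidParameterError("invalid offset range")
    out: list[SignalRead] = []
    for r in reads:
        move_parts: list[np.ndarray] = []
        sample_parts: list[np.ndarray] = []
        offset = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        if offset:
            sample_parts.append(
                rng.normal(adapter_level[0], adapter_level[1], size=offset)
            )
        for b in r.sequence:
            if pm.dwell_sampler is not None:
                nstr = int(pm.dwell_sampler(rng, b))
            else:
                nstr = int(rng.geometric(1.0 / pm.dwell_mean_strides[b]))
            nstr = max(nstr, 1)
            step = np.zeros(nstr, dtype=np.uint8)
            step[0] = 1
            move_parts.append(step)
            sd = pm.sd_pa[b]
            if sd == 0:
                sample_parts.append(np.full(nstr * pm.stride, pm.mean_pa[b]))
            else:
                sample_parts.append(
                    rng.normal(pm.mean_pa[b], sd, size=nstr * pm.stride)
                )
        out.append(
            SignalRead(
                read_id=r.read_id,
                samples=np.concatenate(sample_parts)
                if sample_parts
                else np.empty(0),
                start_offset=offset,
                stride=pm.stride,
                move=np.concatenate(move_parts)
                if move_parts
                else np.empty(0, dtype=np.uint8),
            )
        )
    return out
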