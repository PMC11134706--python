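"""Raw-signal (squiggle) feature extraction via Move-table segmentation.

The basecaller segments the raw current into fixed-stride chunks (10
samples per step for the RNA models considered here) and records base
transitions in a binary "Move" table; decoding starts at sample
``first_sample_template``. Base *i*'s signal segment therefore starts at
``offset + stride * (index of the i-th 1 in Move)`` and runs to the next
1 (or the end of the Move table), so dwell times are multiples of the
stride.

This module maps those segments to bases, computes dwell/intensity
features at correctly basecalled positions, builds resampled 3-mer
signal profiles (10 points per base), and quantifies the bimodality of
3' soft-clip lengths that marks adapter-detection failure.

Signal exchange uses a documented tabular format (one row per read:
read_id, start_offset, stride, move string, comma-separated samples);
native fast5/pod5 parsing is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from ._alphabet import RNA_BASES, complement
from .alignio import AlignedRead, AlignmentColumn, contiguous_blocks, orient_columns
from .errors import (
    EmptyInputError,
    InsufficientDataError,
    InvalidParameterError,
    SegmentationError,
)

DEFAULT_STRIDE = 10
#: Fallback 3'-clip boundary between the ordinary mode and the
#: adapter-failure mode when valley detection finds no second mode.
FALLBACK_CLIP_BOUNDARY = 30


@dataclass
class SignalRead:
    """Raw samples plus the basecaller's segmentation for one read."""

    read_id: str
    samples: np.ndarray  # raw current, pA
    start_offset: int  # first_sample_template
    stride: int
    move: np.ndarray  # binary, one entry per stride step

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.move = np.asarray(self.move, dtype=np.uint8)
        if self.stride < 1:
            raise InvalidParameterError("stride must be >= 1")
        if self.move.size and self.move[0] != 1:
            raise InvalidParameterError("Move table must begin with 1")
        needed = self.start_offset + self.stride * len(self.move) - self.stride + 1
        if self.samples.size < needed:
            raise InvalidParameterError("samples shorter than Move table implies")

    @property
    def n_bases(self) -> int:
        return int(self.move.sum())


def assign_base_segments(
    signal_read: SignalRead, n_bases: int
) -> list[tuple[int, int]]:
    """Per-base ``(start, dwell)`` in raw-sample coordinates.

    Raises `SegmentationError` when the number of 1s in Move disagrees
    with ``n_bases``.
    """
    ones = np.flatnonzero(signal_read.move)
    if len(ones) != n_bases:
        raise SegmentationError(
            f"Move table has {len(ones)} base starts, expected {n_bases}"
        )
    stride, off = signal_read.stride, signal_read.start_offset
    bounds = np.append(ones, len(signal_read.move))
    return [
        (off + stride * int(bounds[i]), stride * int(bounds[i + 1] - bounds[i]))
        for i in range(n_bases)
    ]


def _basecall_index(read: AlignedRead, query_pos: int) -> int:
    # SAM stores reverse-strand queries reverse-complemented; the signal
    # follows the basecall (read) orientation.
    if read.strand == "+":
        return query_pos
    return read.query_length - 1 - query_pos


def _match_segments(
    read: AlignedRead,
    columns: Sequence[AlignmentColumn],
    signal_read: SignalRead,
) -> Iterable[tuple[str, np.ndarray]]:
    """Yield (base identity, raw segment) at match-verdict positions."""
    segments = assign_base_segments(signal_read, read.query_length)
    raw = signal_read.samples
    for c in columns:
        if c.verdict != "match" or c.excluded or c.query_pos is None:
            continue
        base = c.called_base if read.strand == "+" else complement(c.called_base)
        start, dwell = segments[_basecall_index(read, c.query_pos)]
        yield base, raw[start : start + dwell]


def base_signal_features(
    signal_reads: Mapping[str, SignalRead],
    read_columns: Iterable[tuple[AlignedRead, Sequence[AlignmentColumn]]],
) -> pd.DataFrame:
    """Dwell/intensity features per base identity, matches only.

    Returns one row per base with the number of segments, mean of
    per-segment mean intensities, mean of per-segment intensity SDs, and
    mean/median dwell (in samples).
    """
    acc: dict[str, dict[str, list[float]]] = {
        b: {"mean": [], "sd": [], "dwell": []} for b in RNA_BASES
    }
    n_joined = 0
    for read, columns in read_columns:
        sig = signal_reads.get(read.read_id)
        if sig is None:
            continue
        n_joined += 1
        for base, seg in _match_segments(read, columns, sig):
            if base not in acc or seg.size == 0:
                continue
            acc[base]["mean"].append(float(seg.mean()))
            acc[base]["sd"].append(float(seg.std()))
            acc[base]["dwell"].append(float(seg.size))
    if n_joined == 0:
        raise EmptyInputError("no reads joined between signal and alignment inputs")
    rows = []
    for b in RNA_BASES:
        m = acc[b]
        n = len(m["mean"])
        rows.append(
            {
                "base": b,
                "n": n,
                "mean_intensity": float(np.mean(m["mean"])) if n else math.nan,
                "sd_intensity": float(np.mean(m["sd"])) if n else math.nan,
                "mean_dwell": float(np.mean(m["dwell"])) if n else math.nan,
                "median_dwell": float(np.median(m["dwell"])) if n else math.nan,
            }
        )
    return pd.DataFrame(rows)


def resample_segment(x: np.ndarray, n: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Running-window means/SDs of a segment, resampled to ``n`` points.

    Non-overlapping windows of size ``len(x) // n`` (the remainder is
    folded into the last window). A segment of exactly ``n`` samples is
    returned unchanged (windows of one sample).
    """
    if len(x) < n:
        raise InvalidParameterError(f"segment of {len(x)} samples cannot yield {n} points")
    w = len(x) // n
    means = np.empty(n)
    sds = np.empty(n)
    for i in range(n):
        lo = i * w
        hi = (i + 1) * w if i < n - 1 else len(x)
        means[i] = x[lo:hi].mean()
        sds[i] = x[lo:hi].std()
    return means, sds


@dataclass
class MotifSignalProfile:
    """Averaged resampled signal for one 3-mer (10 points per base)."""

    motif: str
    mean: np.ndarray  # (3 * points,)
    sd: np.ndarray  # mean within-window SD, same shape
    n_instances: int
    points_per_base: int = 10


def motif_signal_profile(
    signal_reads: Mapping[str, SignalRead],
    read_columns: Iterable[tuple[AlignedRead, Sequence[AlignmentColumn]]],
    motifs: Iterable[str],
    points_per_base: int = 10,
) -> dict[str, MotifSignalProfile]:
    """Resampled mean-intensity profiles for 3-mer motifs.

    Only instances correctly basecalled at all three positions (match
    verdict, no internal insertions, reference-contiguous) contribute;
    each instance contributes exactly ``3 * points_per_base`` points.
    Motifs with zero qualifying instances are omitted.
    """
    motifs = {m.upper() for m in motifs}
    k = 3
    sums: dict[str, np.ndarray] = {}
    sdsums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for read, columns in read_columns:
        sig = signal_reads.get(read.read_id)
        if sig is None:
            continue
        segments = assign_base_segments(sig, read.query_length)
        raw = sig.samples
        oriented = orient_columns(list(columns), read.strand)
        for block in contiguous_blocks(oriented):
            for i in range(len(block) - k + 1):
                w = block[i : i + k]
                if any(c.verdict != "match" or c.excluded for c in w):
                    continue
                if any(c.ins_count for c in w[:-1]):
                    continue
                motif = "".join(c.ref_base for c in w)
                if motif not in motifs:
                    continue
                pieces_m, pieces_s = [], []
                ok = True
                for c in w:
                    base_idx = _basecall_index(read, c.query_pos)
                    start, dwell = segments[base_idx]
                    if dwell < points_per_base:
                        ok = False
                        break
                    m, s = resample_segment(raw[start : start + dwell], points_per_base)
                    pieces_m.append(m)
                    pieces_s.append(s)
                if not ok:
                    continue
                vec_m = np.concatenate(pieces_m)
                vec_s = np.concatenate(pieces_s)
                if motif not in sums:
                    sums[motif] = np.zeros_like(vec_m)
                    sdsums[motif] = np.zeros_like(vec_s)
                    counts[motif] = 0
                sums[motif] += vec_m
                sdsums[motif] += vec_s
                counts[motif] += 1
    return {
        m: MotifSignalProfile(
            m, sums[m] / counts[m], sdsums[m] / counts[m], counts[m], points_per_base
        )
        for m in sums
    }


@dataclass
class SoftClipModeStats:
    """Histogram and second-mode statistics of soft-clip lengths."""

    end: str  # "5'" or "3'"
    bin_edges: np.ndarray
    counts: np.ndarray
    boundary: float
    boundary_method: str  # "valley" or "fixed"
    second_mode_fraction: float
    second_mode_interval: tuple[float, float] | None


def adapter_failure_stats(
    clip_lengths: Sequence[int],
    boundary_method: str = "valley",
    *,
    end: str = "3'",
    bin_width: int = 5,
    fixed_threshold: int = FALLBACK_CLIP_BOUNDARY,
    min_reads: int = 100,
) -> SoftClipModeStats:
    """Quantify the second (adapter-failure) mode of soft-clip lengths.

    3' soft clips of direct RNA reads are bimodal when the basecaller
    sometimes starts decoding inside the DNA adapter: an ordinary
    short-clip mode and a second mode of spurious adapter basecalls. The
    inter-mode boundary is located at the histogram valley between the
    two most prominent peaks (fallback: fixed threshold when no second
    mode is detectable); the second-mode fraction is the fraction of
    reads whose clip length reaches the boundary.
    """
    clips = np.asarray(clip_lengths, dtype=float)
    if clips.size < min_reads:
        raise InsufficientDataError(
            f"need >= {min_reads} reads for clip-mode statistics, got {clips.size}"
        )
    if boundary_method not in ("valley", "fixed"):
        raise InvalidParameterError(f"unknown boundary method {boundary_method!r}")
    hi = max(clips.max(), fixed_threshold) + 2 * bin_width
    edges = np.arange(0, hi + bin_width, bin_width)
    counts, edges = np.histogram(clips, bins=edges)

    boundary = float(fixed_threshold)
    method = "fixed"
    if boundary_method == "valley":
        smooth = np.convolve(counts, np.ones(3) / 3, mode="same")
        p_main = int(np.argmax(smooth))
        tail = smooth[p_main + 2 :]
        if tail.size:
            peaks, props = find_peaks(
                np.r_[tail, 0.0], prominence=max(2.0, 0.01 * smooth[p_main])
            )
            if peaks.size:
                p2 = p_main + 2 + int(peaks[np.argmax(props["prominences"])])
                valley = p_main + int(np.argmin(smooth[p_main : p2 + 1]))
                if smooth[valley] < 0.5 * smooth[p2]:
                    boundary = float(edges[valley])
                    method = "valley"
    frac = float(np.mean(clips >= boundary))
    interval = None
    second = clips[clips >= boundary]
    if second.size:
        interval = (
            float(np.percentile(second, 2.5)),
            float(np.percentile(second, 97.5)),
        )
    return SoftClipModeStats(end, edges, counts, boundary, method, frac, interval)


def qscore_by_adapter_failure(
    summaries: Iterable,
    boundary: float,
    length_bins: Sequence[int] = (0, 200, 400, 800, 10_000_000),
) -> pd.DataFrame:
    """Read Q-scores stratified by second-mode membership and length bin.

    Adapter-failure basecalls are low quality and drag the read Q-score
    of short reads below the conventional pass threshold of Q7; this
    table makes that effect visible. ``summaries`` are
    `readmetrics.ReadErrorSummary` objects with ``reported_q`` set.
    """
    rows = [
        {
            "read_id": s.read_id,
            "aligned_length": s.aligned_length,
            "adapter_failed": s.clip3 >= boundary,
            "reported_q": s.reported_q,
        }
        for s in summaries
        if s.reported_q is not None
    ]
    df = pd.DataFrame(rows)
    if df.empty:
        raise EmptyInputError("no reads with reported Q-scores")
    df["length_bin"] = pd.cut(df["aligned_length"], bins=list(length_bins), right=False)
    out = (
        df.groupby(["length_bin", "adapter_failed"], observed=False)["reported_q"]
        .agg(["count", "median", "mean"])
        .reset_index()
    )
    out["q7_pass_fraction"] = (
        df.assign(ok=df["reported_q"] >= 7.0)
        .groupby(["length_bin", "adapter_failed"], observed=False)["ok"]
        .mean()
        .values
    )
    return out


def write_signal_table(signal_reads: Iterable[SignalRead], path: str | Path) -> None:
    """Write signal reads to the tabular exchange format (TSV)."""
    with open(path, "w") as fh:
        fh.write("read_id\tstart_offset\tstride\tmove\tsamples\n")
        for s in signal_reads:
            move = "".join(map(str, s.move.tolist()))
            samples = ",".join(f"{v:.2f}" for v in s.samples)
            fh.write(f"{s.read_id}\t{s.start_offset}\t{s.stride}\t{move}\t{samples}\n")


def read_signal_table(path: str | Path) -> dict[str, SignalRead]:
    """Load a signal table written by `write_signal_table`."""
    out: dict[str, SignalRead] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:5] != ["read_id", "start_offset", "stride", "move", "samples"]:
            raise InvalidParameterError(f"unrecognized signal table header in {path}")
        for line in fh:
            rid, off, stride, move, samples = line.rstrip("\n").split("\t")
            out[rid] = SignalRead(
                read_id=rid,
                samples=np.fromiter((float(v) for v in samples.split(",")), dtype=float),
                start_offset=int(off),
                stride=int(stride),
                move=np.frombuffer(move.encode(), dtype=np.uint8) - ord("0"),
            )
    return out
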