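"""Pipeline orchestration: configuration, stages, and report bundling.

`run_pipeline` executes the full error profile over a filtered SAM:
per-read summaries -> Q-score calibration -> base confusion and motif /
context errors -> polymer attribution -> (signal features, when a
signal table is supplied), writing every table as TSV plus a manifest
with checksums, run parameters and seeds. Identical configuration and
seeds give byte-identical tables.

Each stage re-streams the SAM (the seeded reservoir subsample selects
the same reads on every pass), so memory stays proportional to the
tallies rather than to the dataset.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alignio import (
    AlignedRead,
    AlignmentColumn,
    alignment_columns,
    load_reference,
    load_qscore_summary,
    orient_columns,
    stream_alignments,
)
from .errors import ConfigurationError
from .motiferr import (
    base_confusion,
    context_center_errors,
    context_table,
    insertion_spectrum_table,
    motif_errors,
    motif_table,
)
from .polymer import (
    attribute_polymer_errors,
    homopolymer_accuracy_table,
    segment_polymers,
)
from .qscore import (
    calibration_curve,
    empirical_vs_reported_fit,
    read_qscore_from_bases,
)
from .readmetrics import aggregate_by_length, summaries_frame, summarize_read
from .signal import (
    adapter_failure_stats,
    base_signal_features,
    motif_signal_profile,
    read_signal_table,
)

logger = logging.getLogger("drnaprof")

DEFAULT_LENGTH_BINS = (100, 200, 500, 1000, 2000, 5000, 10_000, 100_000)


@dataclass
class PipelineConfig:
    """All pipeline inputs and parameters (defaults = standard filters)."""

    sam: str
    fasta: str
    report_dir: str
    summary: str | None = None  # sequencing-summary TSV (read_id, mean_qscore)
    signal_table: str | None = None
    fastq: str | None = None  # unused by stages; kept for provenance
    min_mapq: int = 20
    min_length: int = 100
    subsample: int | None = 200_000
    seed: int = 0
    motif_k: Sequence[int] = (1, 2)
    context_k: Sequence[int] = (3,)
    context_exclude_homopolymer: bool = True
    bin_width: float = 0.2
    length_bins: Sequence[int] = DEFAULT_LENGTH_BINS
    group_longer_than: int | None = 3
    min_motif_instances: int = 100
    profile_motifs: Sequence[str] = ("GCA", "GUA", "UCU", "UUU")

    def validate(self) -> None:
        for label in ("sam", "fasta"):
            p = getattr(self, label)
            if not p or not Path(p).exists():
                raise ConfigurationError(f"missing {label} input: {p!r}")
        for label in ("summary", "signal_table", "fastq"):
            p = getattr(self, label)
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"missing {label} input: {p!r}")
        if self.subsample is not None and self.seed is None:
            raise ConfigurationError("subsampling requires a seed")


def load_config(path: str | Path, **overrides) -> PipelineConfig:
    """Load a YAML/JSON config file, applying keyword overrides."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)


@dataclass
class ReportBundle:
    """Manifest of an emitted report directory."""

    report_dir: Path
    manifest: dict
    manifest_path: Path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class _Run:
    """One pipeline execution over a validated config."""

    def __init__(self, config: PipelineConfig):
        config.validate()
        self.cfg = config
        self.refs = load_reference(config.fasta)
        self.qscores = (
            load_qscore_summary(config.summary) if config.summary else None
        )
        self.outdir = Path(config.report_dir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.files: dict[str, Path] = {}
        self.meta: dict = {}

    def reads(self) -> Iterator[AlignedRead]:
        yield from stream_alignments(
            self.cfg.sam,
            min_mapq=self.cfg.min_mapq,
            min_length=self.cfg.min_length,
            qscores=self.qscores,
            subsample=self.cfg.subsample,
            seed=self.cfg.seed,
        )

    def read_columns(self) -> Iterator[tuple[AlignedRead, list[AlignmentColumn]]]:
        for read in self.reads():
            ref = self.refs.get(read.reference_name)
            if ref is None:
                continue
            yield read, alignment_columns(read, ref)

    def oriented(self) -> Iterator[list[AlignmentColumn]]:
        for read, cols in self.read_columns():
            yield orient_columns(cols, read.strand)

    def _emit(self, name: str, df: pd.DataFrame) -> Path:
        path = self.outdir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        self.files[name] = path
        return path

    def _emit_json(self, name: str, obj) -> Path:
        path = self.outdir / f"{name}.json"
        path.write_text(json.dumps(obj, indent=2, default=str) + "\n")
        self.files[name] = path
        return path

    # -- stages ------------------------------------------------------------

    def stage_reads(self) -> None:
        summaries = []
        empirical = {}
        n_in = 0
        for read, cols in self.read_columns():
            n_in += 1
            if not cols:
                continue
            s = summarize_read(cols, read)
            if read.qualities is not None and len(read.qualities):
                empirical[read.read_id] = read_qscore_from_bases(read.qualities)
            if s.reported_q is None:
                s.reported_q = empirical.get(read.read_id)
            summaries.append(s)
        logger.info("reads stage: %d analyzed", len(summaries))
        self.meta["n_reads_analyzed"] = len(summaries)
        self.meta["qscore_source"] = "summary" if self.qscores else "empirical"
        self._summaries = summaries
        self._empirical = empirical
        self._emit("read_summaries", summaries_frame(summaries))
        self._emit(
            "length_aggregates",
            aggregate_by_length(summaries, list(self.cfg.length_bins)),
        )

    def stage_qscore(self) -> None:
        withq = [s for s in self._summaries if s.reported_q is not None]
        if withq:
            bins = calibration_curve(withq, self.cfg.bin_width)
            self._emit(
                "calibration_bins",
                pd.DataFrame(
                    [
                        {
                            "lo": b.lo,
                            "hi": b.hi,
                            "n_reads": b.n_reads,
                            "observed_error": b.observed_error,
                            "expected_error": b.expected_error,
                        }
                        for b in bins
                    ]
                ),
            )
        if self.qscores:
            pairs = [
                (s.reported_q, self._empirical[s.read_id])
                for s in withq
                if s.read_id in self._empirical
            ]
            if len(pairs) >= 3 and len({p[0] for p in pairs}) > 1:
                fit = empirical_vs_reported_fit(*zip(*pairs))
                self._emit_json(
                    "calibration_fit",
                    {
                        "slope": fit.slope,
                        "intercept": fit.intercept,
                        "p_value": fit.p_value,
                        "n": fit.n,
                    },
                )

    def stage_motifs(self) -> None:
        conf = base_confusion(c for cols in self.oriented() for c in cols)
        freq = conf.frequencies.reset_index(names="ref_base").melt(
            id_vars="ref_base", var_name="called", value_name="frequency"
        )
        freq["n_ref_base"] = freq["ref_base"].map(conf.row_counts)
        self._emit("confusion", freq)
        for k in self.cfg.motif_k:
            recs = motif_errors(
                self.oriented(), k=k, min_instances=self.cfg.min_motif_instances
            )
            self._emit(f"motif_k{k}", motif_table(recs))
            if k >= 2:
                spec = insertion_spectrum_table(recs)
                if not spec.empty:
                    self._emit(f"insertion_spectrum_k{k}", spec)
        for k in self.cfg.context_k:
            recs = context_center_errors(
                self.oriented(),
                k=k,
                exclude_internal_homopolymer=self.cfg.context_exclude_homopolymer,
            )
            self._emit(f"context_k{k}", context_table(recs))

    def stage_polymers(self) -> None:
        seg_rows = []
        tallies = []
        acc_frames = []
        for name, ref in self.refs.items():
            segments = segment_polymers(ref.sequence)
            seg_rows += [
                {
                    "reference": name,
                    "start": s.start,
                    "end": s.end,
                    "category": s.category,
                    "base": s.base or ".",
                    "length": s.length,
                }
                for s in segments
            ]
            cols_for_ref = [
                cols
                for read, cols in self.read_columns()
                if read.reference_name == name
            ]
            if not cols_for_ref:
                continue
            tally = attribute_polymer_errors(
                cols_for_ref, segments, self.cfg.group_longer_than
            )
            t = tally.table.copy()
            t.insert(0, "reference", name)
            tallies.append(t)
            acc = homopolymer_accuracy_table(cols_for_ref, segments)
            if not acc.empty:
                acc.insert(0, "reference", name)
                acc_frames.append(acc)
        self._emit("polymer_segments", pd.DataFrame(seg_rows))
        if tallies:
            self._emit("polymer_tally", pd.concat(tallies, ignore_index=True))
        if acc_frames:
            self._emit(
                "homopolymer_accuracy", pd.concat(acc_frames, ignore_index=True)
            )

    def stage_clips(self) -> None:
        clips3 = [s.clip3 for s in self._summaries]
        if len(clips3) < 100:
            logger.info("clip stage skipped: fewer than 100 reads")
            return
        stats = adapter_failure_stats(clips3)
        self._emit(
            "clip3_histogram",
            pd.DataFrame(
                {
                    "bin_lo": stats.bin_edges[:-1],
                    "bin_hi": stats.bin_edges[1:],
                    "count": stats.counts,
                }
            ),
        )
        self._emit_json(
            "clip3_modes",
            {
                "boundary": stats.boundary,
                "boundary_method": stats.boundary_method,
                "second_mode_fraction": stats.second_mode_fraction,
                "second_mode_interval": stats.second_mode_interval,
            },
        )

    def stage_signal(self) -> None:
        signal_reads = read_signal_table(self.cfg.signal_table)
        feats = base_signal_features(signal_reads, self.read_columns())
        self._emit("signal_base_features", feats)
        profiles = motif_signal_profile(
            signal_reads, self.read_columns(), self.cfg.profile_motifs
        )
        rows = []
        for p in profiles.values():
            for i, (m, s) in enumerate(zip(p.mean, p.sd)):
                rows.append(
                    {
                        "motif": p.motif,
                        "position": i + 1,
                        "mean": m,
                        "sd": s,
                        "n_instances": p.n_instances,
                    }
                )
        self._emit("motif_signal_profiles", pd.DataFrame(rows))

    def finish(self) -> ReportBundle:
        manifest = {
            "tool": "drnaprof",
            "version": __version__,
            "parameters": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(self.cfg).items()
            },
            "seed": self.cfg.seed,
            "metadata": self.meta,
            "orientation": "transcript (reverse-strand alignments re-oriented)",
            "files": {
                name: {"path": p.name, "sha256": _sha256(p)}
                for name, p in sorted(self.files.items())
            },
        }
        manifest_path = self.outdir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
        return ReportBundle(self.outdir, manifest, manifest_path)


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run every stage over the configured inputs and bundle the report."""
    run = _Run(config)
    run.stage_reads()
    run.stage_qscore()
    run.stage_motifs()
    run.stage_polymers()
    run.stage_clips()
    if config.signal_table:
        run.stage_signal()
    return run.finish()
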