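# Methods

## Scope and model of the data

`drnaprof` profiles the errors of nanopore direct RNA sequencing
(dRNA-seq) reads. Native polyadenylated RNA is ligated to a 3' DNA
adapter and threaded 3'→5' through the pore; the basecaller segments the
raw current into fixed-stride chunks (stride 10 for the RNA models
targeted here), records base transitions in a binary Move table, and
starts decoding at sample `first_sample_template`. Basecalled reads are
aligned upstream (minimap2, splice-aware, ideally with `--eqx`), and the
package consumes the SAM, the reference FASTA, optionally a
sequencing-summary table of per-read Q-scores, and optionally a tabular
dump of raw signal plus Move tables.

All analyses run on the RNA alphabet {A, C, G, U}; T is mapped to U at
every ingestion point. Coordinates are 0-based half-open internally.

## Read-level metrics

Alignments are filtered as is standard for this assay: unmapped,
secondary and supplementary records are dropped, as are reads with MapQ
below 20 or shorter than 100 bases (full query length, soft clips
included). Each surviving CIGAR is decomposed into per-reference-position
verdicts — match, mismatch (with called base), deletion — with inserted
bases anchored to the junction after a reference position. `M` ops are
resolved by base comparison against the reference; `N` (splice) ops
advance the reference silently; soft clips stay on the read. A leading
insertion (before any aligned base) is folded into the 5' soft clip,
since nothing distinguishes it from clipped sequence.

Read accuracy is the BLAST identity

    accuracy = N_match / (N_match + N_mis + N_del + N_ins)

and the per-read mismatch/insertion/deletion rates use the same
denominator. Reads are aggregated into half-open aligned-length bins;
quantiles use median-unbiased interpolation.

Reverse-strand alignments are re-oriented to transcript (read-sense)
orientation before any motif or context analysis: dRNA reads are
sense-strand molecules, so the k-mer that physically transited the pore
is the reverse complement of a minus-strand reference window. Reports
carry an orientation note. Per-read error counts are orientation
invariant (tested).

## Base, motif, and context errors

The confusion matrix tallies, per reference base, the frequency of each
called base and of deletion; insertions are absent by construction (no
reference base). Motif errors follow instance-counting rules: every
sliding-window occurrence of a reference k-mer in an aligned read is one
instance; an instance is a mismatch event if at least one constituent
base mismatched, a deletion event if at least one base was deleted (a
fully deleted 2-mer is one event), and an insertion event if any bases
were inserted strictly between the first and last motif base, regardless
of insertion length (GA→GAA and GA→GAAA are each one event; boundary
insertions do not count). Mismatch and deletion events on the same
instance increment both counters — the error types are defined
independently. Occurrences touching soft-masked or ambiguous (N)
reference positions are skipped; motifs are reported above a configurable
minimum instance count (default 100) to suppress small-sample noise.
Inserted-sequence spectra group sequences below 5% of a motif's
insertions into "others".

Context analysis conditions on correct flanks: for a 3-mer (or 5-mer)
context, the center base's mismatch and deletion rates are computed over
instances whose non-center bases are all match-verdict. Optionally,
contexts whose center repeats an adjacent base (CCA-like) have their
deletion rate masked: the deleted position is not identifiable there.

## Homopolymer attribution

Maximal single-base runs of length ≥ 2 are homopolymer segments; every
other position is a length-1 heteropolymer segment, so segments tile the
reference (AAGCC = two length-2 homopolymers + one heteropolymer; AAAA
is one length-4 homopolymer, never two of length 2). Mismatch and
deletion columns are attributed to the covering segment's class
(heteropolymer, homopolymer_2, homopolymer_3, homopolymer_4+ by default;
full length resolution by flag); insertions are excluded entirely
because an indel at a run boundary cannot be assigned to either side. A
homopolymer instance is called accurately only if every column matches
and no insertion sits at an internal junction — identity and run length
must both be right.

## Quality scores

`q_to_error` and `read_qscore_from_bases` implement the Phred
conversion and its per-read pooling (back-conversion of the mean
per-base error probability). Calibration bins reads by reported Q-score
in 0.2-Q intervals and compares each bin's mean observed error (1 −
accuracy) with the Phred expectation at the bin midpoint. When no
sequencing-summary Q-score is available, the pipeline computes per-read
Q-scores from FASTQ qualities and flags the source as "empirical" in the
manifest; when both exist, an OLS fit of empirical on reported Q-scores
quantifies their systematic deviation.

## Signal features

Base *i*'s signal segment starts at `offset + stride × (index of the
i-th 1 in Move)` and runs to the next 1, so dwell is a multiple of the
stride and total samples = offset + stride × len(Move). Intensity and
dwell statistics use match-verdict positions only. 3-mer signal profiles
resample each base's segment to 10 running-window means (non-overlapping
windows of `dwell // 10` samples, remainder folded into the last
window — the resampling is the identity on a 10-sample segment), giving
exactly 30 points per instance, averaged over instances.

3' soft-clip lengths are summarized as a histogram (5-nt bins); the
boundary between the ordinary short-clip mode and the adapter-failure
mode is the histogram valley between the two most prominent smoothed
peaks, falling back to a fixed 30-nt threshold when no second mode is
detectable. The second-mode fraction is the fraction of reads at or
beyond the boundary; the reported interval is the central 95% of
second-mode clips. `qscore_by_adapter_failure` stratifies read Q-scores
by second-mode membership and length bin (the Q7 pass threshold is the
relevant annotation: spurious adapter basecalls mainly endanger short
reads).

## The simulator

The generator emits reads as corrupted reference substrings with exact
ground truth, so every downstream statistic can be checked against the
generator's own tally (integer equality per read for error counts).
Design choices:

- **Error draws.** Per reference base one categorical draw: deletion
  (flat rate, or per (base, homopolymer-run-length) with
  largest-key-below fallback), substitution (4×4 matrix of absolute
  call probabilities), else match. Insertions are per-junction Bernoulli
  with a configurable inserted-base distribution. Defaults 3% / 5% / 2%
  mirror the mismatch/deletion/insertion structure typical of
  RNA001/002-era data. Indels are emitted left-aligned; the truth SAM is
  written in `--eqx` dialect.
- **Qualities.** "Truthful" per-base q encodes the model-marginal error
  probability of the emitted base, p = (d + s)/(1 − d) for aligned bases
  (the deletion mass is folded onto emitted neighbours because deleted
  bases carry no FASTQ quality) and p = 1 for inserted bases.
  Soft-clipped junk is Phred 3 (adapter basecalls are low quality; no
  distribution is published, so a flat low value is used). The per-read
  `mean_qscore` is computed from unrounded qualities, as a basecaller
  does internally; FASTQ qualities are integer-rounded. A numeric
  `quality_model` adds a fixed Phred offset, for miscalibration
  experiments.
- **Clips.** Ordinary reads get short geometric soft clips (mean 3 nt)
  at both ends; with probability `adapter_failure_fraction` (default
  0.3) the 3' clip is instead uniform on 50–130 nt — the second mode
  observed in real data.
- **Strand and splice.** A configurable fraction of reads is emitted as
  minus-strand SAM records (sequence reverse-complemented, CIGAR
  reversed); splice support is a single fixed-length N gap per read,
  enough to exercise the splice-aware column walk, and deliberately no
  more.
- **Signals.** Per base, dwell is geometric on stride count (the dwell
  family is not established for this platform, so it is pluggable via
  `PoreModel.dwell_sampler`; geometric is the minimal memoryless
  choice) and samples are i.i.d. Gaussian around per-base levels.
  Default levels 110/100/90/80 pA for G/A/U/C encode the observed
  intensity ranking G > A > U > C; default mean dwells 3/3/5/6 strides
  for G/A/U/C encode the longer residence of pyrimidines. These are
  caricatures with the right orderings and magnitudes, not a per-5-mer
  pore model.
- **References.** Random i.i.d. sequences, or de Bruijn sequences of
  order k (length 4^k + k − 1, every k-mer exactly once) — the design
  principle of curlcake-style synthetic RNA used to cover all 5-mer
  contexts.

What the simulator does *not* emulate: sequence-context-dependent
substitution structure beyond the 4×4 matrix, per-k-mer signal levels,
RNA modifications, true splice-junction geometry, inter-read quality
heterogeneity, or basecaller-specific artefacts. Passing tests therefore
demonstrate that the *counting and estimation machinery* is correct and
unbiased under known generative conditions — not that real data meet
those conditions.

## Numerical and procedural choices

- Reservoir subsampling (mandatory seed) caps large runs at 200,000
  reads by default; repeated passes select identical reads, which is
  what lets the pipeline re-stream the SAM per stage with flat memory.
- Reported motif/context rates are plain event-count ratios; no
  smoothing or shrinkage.
- The calibration curve uses the bin midpoint for the expectation; the
  OLS fit uses statsmodels with an intercept; a constant predictor or
  n < 3 is a degenerate-fit error, not a NaN.
- Degenerate inputs raise typed exceptions (`errors.py`) rather than
  returning sentinel values: empty alignments, Move/basecall length
  disagreement, even context k, non-increasing bin edges, fewer than
  100 reads for clip-mode statistics.
- Problem sizes in the test-suite and acceptance script (2,000 reads of
  500–700 nt for round-trip rates, 5,000 reads for calibration, 10,000
  reads for clip modes, ~150 reads with signals) were chosen as the
  smallest sizes at which binomial sampling error is comfortably inside
  the assertion tolerances.

## Known limitations

- Signal ingestion is the documented TSV format only; fast5/pod5
  readers would be thin adapters behind the same `SignalRead` interface
  but are out of scope.
- The valley-detection boundary between clip modes is heuristic; its
  method ("valley" vs "fixed") is recorded in the output metadata.
- Whether real pipelines re-orient minus-strand genome alignments for
  motif analysis is tool-dependent; this package always analyses in
  transcript orientation and says so in the manifest.
- Motif instances are tallied per aligned read occurrence (a read
  covering a locus contributes that occurrence once); per-locus
  aggregation across reads is a different statistic and not provided.
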