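"""Reference loading, alignment filtering, and CIGAR decomposition."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from drnaprof.alignio import (
    alignment_columns,
    contiguous_blocks,
    load_reference,
    orient_columns,
    stream_alignments,
    ReferenceSequence,
)
from drnaprof.errors import FormatError, UnsupportedCigarError
from drnaprof.readmetrics import summarize_read

from ._oracle import naive_counts, naive_rows
from .conftest import mk_read


def _ref(seq, name="ref"):
    return ReferenceSequence(name, seq, np.zeros(len(seq), dtype=bool))


class TestLoadReference:
    def test_masking_rule(self, tmp_path):
        p = tmp_path / "r.fa"
        p.write_text(">r\nACGTacgtNN\n")
        refs = load_reference(p)
        r = refs["r"]
        assert len(r) == 10
        assert r.sequence == "ACGUACGUNN"  # uppercased, T->U
        assert list(np.flatnonzero(r.excluded)) == [4, 5, 6, 7, 8, 9]

    def test_two_records(self, tmp_path):
        p = tmp_path / "r.fa"
        p.write_text(">a\nACGU\n>b\nGGGG\n")
        refs = load_reference(p)
        assert set(refs) == {"a", "b"}

    def test_no_header_is_format_error(self, tmp_path):
        p = tmp_path / "r.fa"
        p.write_text("ACGTACGT\n")
        with pytest.raises(FormatError):
            load_reference(p)


def _write_sam(path, records, ref_len=1000):
    lines = ["@HD\tVN:1.6", f"@SQ\tSN:ref\tLN:{ref_len}"]
    lines += records
    path.write_text("\n".join(lines) + "\n")


def _rec(name, flag=0, mapq=60, seq="A" * 150, cigar=None, pos=1):
    cigar = cigar or f"{len(seq)}M"
    return f"{name}\t{flag}\t{ref_name(flag)}\t{pos}\t{mapq}\t{cigar}\t*\t0\t0\t{seq}\t*"


def ref_name(flag):
    return "*" if flag & 4 else "ref"


class TestStreamAlignments:
    def test_mapq_filter(self, tmp_path):
        p = tmp_path / "a.sam"
        _write_sam(p, [_rec("low", mapq=19), _rec("ok", mapq=20)])
        ids = [r.read_id for r in stream_alignments(p)]
        assert ids == ["ok"]

    def test_length_filter(self, tmp_path):
        p = tmp_path / "a.sam"
        _write_sam(p, [_rec("short", seq="A" * 99), _rec("ok", seq="A" * 100)])
        ids = [r.read_id for r in stream_alignments(p)]
        assert ids == ["ok"]

    def test_secondary_and_supplementary_excluded(self, tmp_path):
        p = tmp_path / "a.sam"
        _write_sam(p, [_rec("sec", flag=256), _rec("sup", flag=2048), _rec("ok")])
        ids = [r.read_id for r in stream_alignments(p)]
        assert ids == ["ok"]

    def test_unmapped_only_gives_empty_stream(self, tmp_path):
        p = tmp_path / "a.sam"
        _write_sam(p, [f"u\t4\t*\t0\t0\t*\t*\t0\t0\t{'A'*150}\t*"])
        assert list(stream_alignments(p)) == []

    def test_reservoir_subsample_is_seeded_and_stable(self, tmp_path):
        p = tmp_path / "a.sam"
        _write_sam(p, [_rec(f"r{i}") for i in range(50)])
        a = [r.read_id for r in stream_alignments(p, subsample=10, seed=3)]
        b = [r.read_id for r in stream_alignments(p, subsample=10, seed=3)]
        c = [r.read_id for r in stream_alignments(p, subsample=10, seed=4)]
        assert a == b and len(a) == 10
        assert a != c


class TestAlignmentColumns:
    def test_eqx_worked_example(self):
        # 5=1X3=1D2= consumes 12 reference bases: 10 match + 1 mismatch
        # + 1 deletion columns
        ref = _ref("AAAAACGGGUCC")
        read = mk_read("AAAAAUGGGCC", "5=1X3=1D2=")
        cols = alignment_columns(read, ref)
        verdicts = [c.verdict for c in cols]
        assert len(cols) == 12
        assert verdicts.count("match") == 10
        assert verdicts.count("mismatch") == 1
        assert verdicts.count("deletion") == 1
        assert cols[5].called_base == "U" and cols[5].ref_base == "C"

    def test_splice_emits_no_columns(self):
        ref = _ref("A" * 520)
        read = mk_read("A" * 20, "10=500N10=")
        cols = alignment_columns(read, ref)
        assert len(cols) == 20
        assert all(c.verdict == "match" for c in cols)
        assert [len(b) for b in contiguous_blocks(cols)] == [10, 10]

    def test_m_resolution_matches_naive(self):
        ref = _ref("ACGUACGU")
        read = mk_read("ACGUUCGU", "8M")
        cols = alignment_columns(read, ref)
        rows, ins = naive_rows(read.query, read.cigar, ref.sequence, 0)
        match, mis, dele, n_ins = naive_counts(rows, ins)
        assert (match, mis) == (7, 1)
        s = summarize_read(cols, read)
        assert (s.n_match, s.n_mis, s.n_del, s.n_ins) == (match, mis, dele, n_ins)

    def test_m_without_reference_raises(self):
        read = mk_read("ACGU", "4M")
        with pytest.raises(UnsupportedCigarError):
            alignment_columns(read, None)

    def test_padding_op_rejected(self):
        read = mk_read("ACGU", "2=1P2=")
        with pytest.raises(UnsupportedCigarError):
            alignment_columns(read, _ref("ACGU"))

    def test_insertion_anchored_after_previous_column(self):
        ref = _ref("GA")
        read = mk_read("GUA", "1=1I1=")
        cols = alignment_columns(read, ref)
        assert cols[0].ins_count == 1 and cols[0].ins_bases == "U"
        assert cols[1].ins_count == 0

    def test_leading_insertion_folds_into_clip(self):
        ref = _ref("GA")
        read = mk_read("UGA", "1I2=")
        cols = alignment_columns(read, ref)
        assert len(cols) == 2
        assert sum(c.ins_count for c in cols) == 0

    def test_excluded_positions_flagged(self):
        ref = ReferenceSequence(
            "ref", "ACGU", np.array([False, True, False, False])
        )
        cols = alignment_columns(mk_read("ACGU", "4="), ref)
        assert [c.excluded for c in cols] == [False, True, False, False]


class TestOrientColumns:
    def test_reverse_strand_complements_and_reanchors(self):
        # reference GAUC aligned on '-': transcript sense is GAUC's revcomp
        ref = _ref("GAUC")
        read = mk_read("GAGUC", "2=1I2=", strand="-")  # SAM orientation
        cols = alignment_columns(read, ref)
        oriented = orient_columns(cols, "-")
        assert "".join(c.ref_base for c in oriented) == "GAUC"
        # insertion was after SAM position 1 -> transcript junction after
        # oriented position 1 (between ref pos 2 and 1)
        anchors = [i for i, c in enumerate(oriented) if c.ins_count]
        assert anchors == [1]
        assert oriented[1].ins_bases == "C"  # complement of inserted G

    def test_forward_is_identity(self):
        ref = _ref("GAUC")
        cols = alignment_columns(mk_read("GAUC", "4="), ref)
        assert orient_columns(cols, "+") is cols


class TestConservation:
    """Column counts must conserve the CIGAR's consumed lengths."""

    def test_on_simulated_reads(self, medium_sim, medium_sim_paths):
        refs = load_reference(medium_sim_paths["fasta"])
        n = 0
        for read in stream_alignments(medium_sim_paths["sam"]):
            cols = alignment_columns(read, refs[read.reference_name])
            ref_len = sum(
                length for op, length in read.cigar if op in "MDX="
            )
            query_aligned = sum(
                length for op, length in read.cigar if op in "MIX="
            )
            n_cols = len(cols)
            n_ins = sum(c.ins_count for c in cols)
            n_del = sum(1 for c in cols if c.verdict == "deletion")
            assert n_cols == ref_len
            assert (n_cols - n_del) + n_ins == query_aligned
            n += 1
        assert n == len(medium_sim.reads)

    def test_strand_roundtrip_counts_match_truth(self):
        from drnaprof.sim import ErrorModel, make_reference, simulate_reads

        ref = make_reference(5000, "random", seed=21)
        model = ErrorModel.uniform(0.03, 0.05, 0.02, seed=21)
        rs = simulate_reads(
            ref, model, 100, (200, 400), reverse_fraction=0.5, seed=21
        )
        assert {r.strand for r in rs.reads} == {"+", "-"}
        import pathlib
        import tempfile

        d = pathlib.Path(tempfile.mkdtemp())
        paths = rs.write_all(d / "x")
        refs = load_reference(paths["fasta"])
        truth = {t.read_id: t for t in rs.truth}
        for read in stream_alignments(paths["sam"]):
            s = summarize_read(
                alignment_columns(read, refs[read.reference_name]), read
            )
            t = truth[read.read_id]
            assert (s.n_match, s.n_mis, s.n_del, s.n_ins) == (
                t.n_match, t.n_mis, t.n_del, t.n_ins,
            )


@given(st.integers(0, 10_000))
def test_m_resolution_equivalence_random_alignments(seed):
    """Resolving M ops must equal counting on the pre-resolved =/X CIGAR."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 40))
    ref_seq = "".join(rng.choice(list("ACGU"), size=n))
    query = "".join(
        b if rng.random() > 0.2 else rng.choice(list("ACGU")) for b in ref_seq
    )
    ref = _ref(ref_seq)
    eqx_ops = "".join("=" if q == r else "X" for q, r in zip(query, ref_seq))
    from .conftest import parse_cigar  # RLE via the parser's inverse

    import itertools

    eqx = "".join(
        f"{len(list(g))}{op}" for op, g in itertools.groupby(eqx_ops)
    )
    cols_m = alignment_columns(mk_read(query, f"{n}M"), ref)
    cols_eqx = alignment_columns(mk_read(query, eqx), ref)
    assert [(c.ref_pos, c.verdict, c.called_base) for c in cols_m] == [
        (c.ref_pos, c.verdict, c.called_base) for c in cols_eqx
    ]
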