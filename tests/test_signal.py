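"""Move-table segmentation, signal features, profiles, and clip modes."""

import numpy as np
import pytest

from drnaprof.alignio import ReferenceSequence, alignment_columns
from drnaprof.errors import (
    EmptyInputError,
    InsufficientDataError,
    InvalidParameterError,
)
from drnaprof.signal import (
    SignalRead,
    adapter_failure_stats,
    assign_base_segments,
    base_signal_features,
    motif_signal_profile,
    read_signal_table,
    resample_segment,
    write_signal_table,
)

from .conftest import mk_read


def _sig(read_id, samples, move, offset=0, stride=10):
    return SignalRead(read_id, np.asarray(samples, float), offset, stride,
                      np.asarray(move, np.uint8))


class TestSegments:
    def test_all_ones_move_gives_stride_dwells(self):
        sig = _sig("r", np.zeros(50), [1, 1, 1, 1, 1])
        segs = assign_base_segments(sig, 5)
        assert [d for _, d in segs] == [10] * 5
        starts = [s for s, _ in segs]
        assert starts == sorted(starts) and len(set(starts)) == 5

    def test_sample_conservation(self):
        sig = _sig("r", np.zeros(90), [1, 0, 0, 1, 1, 0], offset=30)
        segs = assign_base_segments(sig, 3)
        assert sum(d for _, d in segs) == 10 * len(sig.move)
        assert segs[0][0] == 30

    def test_move_must_start_with_one(self):
        with pytest.raises(InvalidParameterError):
            _sig("r", np.zeros(20), [0, 1])


class TestResampling:
    def test_dwell_ten_is_identity(self):
        x = np.arange(10.0)
        means, sds = resample_segment(x, 10)
        assert np.allclose(means, x)
        assert np.allclose(sds, 0.0)

    def test_constant_segment_any_dwell(self):
        means, _ = resample_segment(np.full(30, 5.0), 10)
        assert means.shape == (10,)
        assert np.allclose(means, 5.0)

    def test_remainder_folds_into_last_window(self):
        x = np.r_[np.zeros(25), np.ones(3)]  # dwell 28: windows of 2, last 10
        means, _ = resample_segment(x, 10)
        assert means[-1] == pytest.approx(0.3)

    def test_too_short_segment_rejected(self):
        with pytest.raises(InvalidParameterError):
            resample_segment(np.zeros(5), 10)


def _aligned_case():
    """A 4-base read, all matches, with a known constant signal."""
    ref = ReferenceSequence("ref", "GACU", np.zeros(4, dtype=bool))
    read = mk_read("GACU", "4=")
    cols = alignment_columns(read, ref)
    samples = np.concatenate([np.full(10, v) for v in (110.0, 100.0, 80.0, 90.0)])
    sig = _sig("r1", samples, [1, 1, 1, 1])
    return read, cols, sig


class TestBaseSignalFeatures:
    def test_constant_signal_exact_features(self):
        read, cols, sig = _aligned_case()
        df = base_signal_features({"r1": sig}, [(read, cols)]).set_index("base")
        assert df.loc["G", "mean_intensity"] == 110.0
        assert df.loc["C", "mean_intensity"] == 80.0
        assert df.loc["A", "sd_intensity"] == 0.0
        assert df.loc["U", "mean_dwell"] == 10.0

    def test_mismatch_positions_excluded(self):
        ref = ReferenceSequence("ref", "GACU", np.zeros(4, dtype=bool))
        read = mk_read("GGCU", "1=1X2=")
        cols = alignment_columns(read, ref)
        samples = np.full(40, 100.0)
        df = base_signal_features({"r1": _sig("r1", samples, [1, 1, 1, 1])},
                                  [(read, cols)])
        counts = df.set_index("base")["n"]
        assert counts["A"] == 0  # the mismatched reference A contributes nothing
        assert counts["G"] == 1 and counts["C"] == 1 and counts["U"] == 1

    def test_no_joined_reads_raises(self):
        read, cols, _ = _aligned_case()
        with pytest.raises(EmptyInputError):
            base_signal_features({}, [(read, cols)])

    def test_pore_model_orderings_recovered(self):
        """G>A>U>C intensity and C/U dwell > G/A dwell from simulation."""
        from drnaprof.alignio import load_reference, stream_alignments
        from drnaprof.sim import (
            ErrorModel, PoreModel, make_reference, simulate_reads,
            simulate_signals,
        )
        import pathlib, tempfile

        ref = make_reference(5000, "random", seed=51)
        rs = simulate_reads(
            ref, ErrorModel.error_free(seed=51), 40, 300, seed=51
        )
        sigs = {s.read_id: s for s in simulate_signals(rs.reads, PoreModel(), seed=52)}
        d = pathlib.Path(tempfile.mkdtemp())
        paths = rs.write_all(d / "x")
        refs = load_reference(paths["fasta"])
        pairs = [
            (r, alignment_columns(r, refs[r.reference_name]))
            for r in stream_alignments(paths["sam"])
        ]
        df = base_signal_features(sigs, pairs).set_index("base")
        m = df["mean_intensity"]
        assert m["G"] > m["A"] > m["U"] > m["C"]
        dw = df["mean_dwell"]
        assert min(dw["C"], dw["U"]) > max(dw["G"], dw["A"])


class TestMotifSignalProfile:
    def test_thirty_points_per_instance(self):
        read, cols, sig = _aligned_case()
        profiles = motif_signal_profile({"r1": sig}, [(read, cols)], ["GAC", "ACU"])
        assert set(profiles) == {"GAC", "ACU"}
        for p in profiles.values():
            assert p.mean.shape == (30,)
            assert p.n_instances == 1

    def test_constant_segments_give_flat_profile(self):
        read, cols, sig = _aligned_case()
        p = motif_signal_profile({"r1": sig}, [(read, cols)], ["GAC"])["GAC"]
        assert np.allclose(p.mean[:10], 110.0)
        assert np.allclose(p.mean[10:20], 100.0)
        assert np.allclose(p.mean[20:], 80.0)

    def test_unobserved_motif_omitted(self):
        read, cols, sig = _aligned_case()
        profiles = motif_signal_profile({"r1": sig}, [(read, cols)], ["UUU"])
        assert profiles == {}

    def test_center_base_separation_gca_vs_gua(self):
        """Distinct C/U pore levels keep GCA and GUA center profiles
        separated by more than 2 SD of the profile estimate."""
        from drnaprof.sim import (
            ErrorModel, PoreModel, make_reference, simulate_reads,
            simulate_signals,
        )
        from drnaprof.alignio import load_reference, stream_alignments
        import pathlib, tempfile

        ref = "".join(["GCAGUA"] * 200)
        rs = simulate_reads(ref, ErrorModel.error_free(seed=53), 30, 400, seed=53)
        sigs = {s.read_id: s for s in simulate_signals(rs.reads, PoreModel(), seed=54)}
        d = pathlib.Path(tempfile.mkdtemp())
        paths = rs.write_all(d / "x")
        refs = load_reference(paths["fasta"])
        pairs = [
            (r, alignment_columns(r, refs[r.reference_name]))
            for r in stream_alignments(paths["sam"])
        ]
        profiles = motif_signal_profile(sigs, pairs, ["GCA", "GUA"])
        gca, gua = profiles["GCA"], profiles["GUA"]
        center = slice(10, 20)
        gap = np.abs(gca.mean[center] - gua.mean[center])
        est_sd = np.maximum(gca.sd[center] / np.sqrt(gca.n_instances),
                            gua.sd[center] / np.sqrt(gua.n_instances))
        assert np.all(gap > 2 * est_sd)


class TestAdapterFailureStats:
    def test_unimodal_short_clips_have_zero_second_mode(self):
        rng = np.random.default_rng(5)
        clips = rng.geometric(0.3, size=500) - 1
        stats = adapter_failure_stats(clips)
        assert stats.second_mode_fraction == 0.0

    def test_mixture_fraction_recovered(self):
        rng = np.random.default_rng(6)
        n = 10_000
        failed = rng.random(n) < 0.30
        clips = np.where(
            failed,
            rng.integers(50, 131, size=n),
            rng.geometric(0.25, size=n) - 1,
        )
        stats = adapter_failure_stats(clips)
        assert stats.boundary_method == "valley"
        assert 15 <= stats.boundary <= 50
        assert stats.second_mode_fraction == pytest.approx(0.30, abs=0.02)
        lo, hi = stats.second_mode_interval
        assert 45 <= lo <= 60 and 120 <= hi <= 135

    def test_insufficient_reads(self):
        with pytest.raises(InsufficientDataError):
            adapter_failure_stats(list(range(50)))


class TestSignalTableRoundTrip:
    def test_write_then_read(self, tmp_path):
        sig = _sig("r1", np.linspace(80, 120, 40), [1, 0, 1, 1], offset=0)
        path = tmp_path / "signals.tsv"
        write_signal_table([sig], path)
        back = read_signal_table(path)["r1"]
        assert back.start_offset == 0 and back.stride == 10
        assert np.array_equal(back.move, sig.move)
        assert np.allclose(back.samples, sig.samples, atol=0.01)
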