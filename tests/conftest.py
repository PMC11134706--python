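import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from drnaprof.alignio import AlignedRead

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def parse_cigar(cigar_str: str) -> list[tuple[str, int]]:
    out = []
    num = ""
    for ch in cigar_str:
        if ch.isdigit():
            num += ch
        else:
            out.append((ch, int(num)))
            num = ""
    return out


def mk_read(
    query: str,
    cigar: str,
    ref_start: int = 0,
    strand: str = "+",
    read_id: str = "r1",
    reference_name: str = "ref",
    quals=None,
    reported_q=None,
) -> AlignedRead:
    """Hand-build an AlignedRead for unit tests."""
    cig = parse_cigar(cigar)
    clip_l = cig[0][1] if cig[0][0] == "S" else 0
    clip_r = cig[-1][1] if cig[-1][0] == "S" else 0
    clip5, clip3 = (clip_l, clip_r) if strand == "+" else (clip_r, clip_l)
    return AlignedRead(
        read_id=read_id,
        query=query,
        qualities=np.asarray(quals, dtype=float) if quals is not None else None,
        reference_name=reference_name,
        reference_start=ref_start,
        strand=strand,
        cigar=cig,
        mapq=60,
        flag=16 if strand == "-" else 0,
        clip5=clip5,
        clip3=clip3,
        reported_q=reported_q,
    )


@pytest.fixture(scope="session")
def medium_sim():
    """Shared mid-size simulation with the standard error structure."""
    from drnaprof.sim import ErrorModel, make_reference, simulate_reads

    ref = make_reference(10000, "random", seed=101)
    model = ErrorModel.uniform(0.03, 0.05, 0.02, seed=101)
    return simulate_reads(ref, model, 300, (300, 600), seed=101)


@pytest.fixture(scope="session")
def medium_sim_paths(medium_sim, tmp_path_factory):
    d = tmp_path_factory.mktemp("medium_sim")
    return medium_sim.write_all(d / "sim")
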