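"""RNA alphabet helpers shared across modules.

Everything downstream works on the RNA alphabet {A, C, G, U}; T in any
input (references written as DNA, basecalls emitted as DNA) is mapped to U
on ingestion.
"""

from __future__ import annotations

RNA_BASES = "ACGU"
BASE_INDEX = {b: i for i, b in enumerate(RNA_BASES)}

_COMPLEMENT = str.maketrans("ACGUNacgun", "UGCANugcan")


def to_rna(seq: str) -> str:
    """Uppercase a sequence and map T to U."""
    return seq.upper().replace("T", "U")


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    """Reverse complement on the RNA alphabet (N passes through)."""
    return seq.translate(_COMPLEMENT)[::-1]
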