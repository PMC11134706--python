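"""Independent naive re-implementations used as test oracles.

Deliberately written in a different style from the package (character
expansion and string scanning rather than op-wise walking) so that
agreement is meaningful.
"""

from __future__ import annotations


def naive_rows(query: str, cigar: list[tuple[str, int]], ref: str, ref_start: int):
    """Expand an alignment to per-position rows and insertion anchors.

    Returns (rows, ins) where rows are (ref_pos, ref_char, query_char
    or '-') and ins are (anchor_ref_pos, inserted_base) with the anchor
    being the last reference position consumed before the insertion.
    Leading insertions (before any aligned position) are dropped, like
    the 5'-clip convention of the implementation under test.
    """
    ops = "".join(op * n for op, n in cigar)
    rp, qp = ref_start, 0
    rows: list[tuple[int, str, str]] = []
    ins: list[tuple[int, str]] = []
    seen = False
    for op in ops:
        if op == "S":
            qp += 1
        elif op in "M=X":
            rows.append((rp, ref[rp], query[qp]))
            rp += 1
            qp += 1
            seen = True
        elif op == "D":
            rows.append((rp, ref[rp], "-"))
            rp += 1
            seen = True
        elif op == "I":
            if seen:
                ins.append((rp - 1, query[qp]))
            qp += 1
        elif op == "N":
            rp += 1
        elif op == "H":
            pass
        else:
            raise ValueError(f"oracle cannot handle op {op!r}")
    return rows, ins


def naive_counts(rows, ins) -> tuple[int, int, int, int]:
    """(match, mismatch, deletion, insertion) base counts."""
    match = sum(1 for _, r, q in rows if q != "-" and q == r)
    mis = sum(1 for _, r, q in rows if q != "-" and q != r)
    dele = sum(1 for _, _, q in rows if q == "-")
    return match, mis, dele, len(ins)


def naive_motif_events(rows, ins, ref: str, k: int) -> dict[str, list[int]]:
    """Per-motif [instances, mismatch, deletion, insertion] events.

    Slides every window of k covered, consecutive reference positions;
    an insertion is internal when its anchor lies strictly before the
    window's last position.
    """
    covered = {p: (r, q) for p, r, q in rows}
    anchors = {}
    for a, _ in ins:
        anchors[a] = anchors.get(a, 0) + 1
    out: dict[str, list[int]] = {}
    if not covered:
        return out
    for p in range(min(covered), max(covered) - k + 2):
        window = list(range(p, p + k))
        if not all(w in covered for w in window):
            continue
        motif = "".join(ref[w] for w in window)
        rec = out.setdefault(motif, [0, 0, 0, 0])
        rec[0] += 1
        if any(covered[w][1] != "-" and covered[w][1] != covered[w][0] for w in window):
            rec[1] += 1
        if any(covered[w][1] == "-" for w in window):
            rec[2] += 1
        if k >= 2 and any(anchors.get(w, 0) for w in window[:-1]):
            rec[3] += 1
    return out
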