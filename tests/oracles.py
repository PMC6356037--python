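"""Independent brute-force oracles used by the property tests.

These deliberately re-derive expected results by exhaustive enumeration,
without reusing the package's matching/scanning logic.
"""

from __future__ import annotations

RESIDUE_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY" "XBZUOJ")


def element_matches(elem, ch: str) -> bool:
    """Re-state the per-position matching rules independently."""
    if elem.kind == "wildcard":
        return ch in RESIDUE_ALPHABET
    if ch == "X":
        return False
    if elem.kind == "exclusion":
        return ch in RESIDUE_ALPHABET and ch not in elem.residues
    return ch in elem.residues


def brute_force_matches(pattern, seq: str) -> list[tuple[int, int]]:
    """All (start, end) 1-based hits by exhaustive expansion enumeration."""
    elems = pattern.elements

    def ends_from(i: int, ei: int) -> set[int]:
        if ei == len(elems):
            return {i}
        elem = elems[ei]
        out: set[int] = set()
        for cnt in range(elem.min_repeat, elem.max_repeat + 1):
            if i + cnt > len(seq):
                break
            if all(element_matches(elem, seq[i + k]) for k in range(cnt)):
                out |= ends_from(i + cnt, ei + 1)
        return out

    starts = [0] if pattern.anchored_start else range(len(seq))
    hits = []
    for s in starts:
        ends = {e for e in ends_from(s, 0) if e > s}
        if pattern.anchored_end:
            ends = {e for e in ends if e == len(seq)}
        if ends:
            hits.append((s + 1, min(ends)))
    return hits


def count_chy(seq: str) -> int:
    return sum(1 for ch in seq if ch in "CHY")
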