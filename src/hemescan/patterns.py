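"""Local PROSITE-syntax consensus-pattern matching.

Consensus sequences derived from heme-binding peptide screens (for example
``H-x(3)-C`` for the loop-forming HXXXC arrangement) can be screened against
protein sequences without a web service.  The dialect implemented is the
standard PROSITE pattern syntax:

* elements separated by ``-``; an optional terminal ``.`` is ignored;
* a fixed residue letter, an alternative set ``[HY]``, an exclusion set
  ``{P}``, or the wildcard ``x``;
* optional repeats ``(n)`` and ranges ``(n,m)``;
* ``<`` anchors the match to the N-terminus, ``>`` to the C-terminus.

Matching semantics: every start position with a match is reported
(overlapping matches at distinct starts allowed); for ranged repeats the
shortest match at each start is reported.  Matching is case-insensitive on
both sides; an ``X`` *in the sequence* (unknown residue) satisfies only
wildcard elements, never a fixed residue, set or exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import FormatError
from .seq_io import ACCEPTED_ALPHABET, ProteinRecord


@dataclass(frozen=True)
class PatternElement:
    """One pattern position class with a repeat range.

    ``kind`` is one of ``fixed``, ``set``, ``exclusion``, ``wildcard``;
    ``residues`` holds the literal residues for fixed/set/exclusion.
    """

    kind: str
    residues: frozenset[str]
    min_repeat: int = 1
    max_repeat: int = 1

    def matches(self, ch: str) -> bool:
        if self.kind == "wildcard":
            return ch in ACCEPTED_ALPHABET
        if ch == "X":  # unknown residue never satisfies a specific requirement
            return False
        if self.kind == "exclusion":
            return ch in ACCEPTED_ALPHABET and ch not in self.residues
        return ch in self.residues  # fixed or set


@dataclass(frozen=True)
class PrositePattern:
    source_text: str
    elements: tuple[PatternElement, ...]
    anchored_start: bool = False
    anchored_end: bool = False


def _parse_repeat(suffix: str, offset: int) -> tuple[int, int]:
    if not (suffix.startswith("(") and suffix.endswith(")")):
        raise FormatError(f"bad repeat syntax {suffix!r} at offset {offset}")
    body = suffix[1:-1]
    try:
        if "," in body:
            lo_s, hi_s = body.split(",", 1)
            lo, hi = int(lo_s), int(hi_s)
        else:
            lo = hi = int(body)
    except ValueError:
        raise FormatError(f"bad repeat count {body!r} at offset {offset}") from None
    if lo < 0 or hi < lo or hi < 1:
        raise FormatError(f"invalid repeat range ({lo},{hi}) at offset {offset}")
    return lo, hi


def parse_pattern(text: str) -> PrositePattern:
    """Parse a PROSITE pattern string; errors carry the character offset."""
    source = text
    work = text.strip()
    if work.endswith("."):
        work = work[:-1]
    anchored_start = work.startswith("<")
    if anchored_start:
        work = work[1:]
    anchored_end = work.endswith(">")
    if anchored_end:
        work = work[:-1]
    if not work:
        raise FormatError("empty pattern")

    elements: list[PatternElement] = []
    offset = 0
    for token in work.split("-"):
        token = token.strip()
        if not token:
            raise FormatError(f"empty pattern element at offset {offset}")
        body, repeat = token, ""
        if "(" in token:
            idx = token.index("(")
            body, repeat = token[:idx], token[idx:]
        lo, hi = _parse_repeat(repeat, offset) if repeat else (1, 1)

        body_u = body.upper()
        if body_u in ("X",):
            elem = PatternElement("wildcard", frozenset(), lo, hi)
        elif body_u.startswith("["):
            if not body_u.endswith("]") or len(body_u) < 3:
                raise FormatError(f"malformed alternative set {body!r} at offset {offset}")
            residues = frozenset(body_u[1:-1])
            if not residues <= ACCEPTED_ALPHABET:
                raise FormatError(f"illegal residue in set {body!r} at offset {offset}")
            elem = PatternElement("set", residues, lo, hi)
        elif body_u.startswith("{"):
            if not body_u.endswith("}") or len(body_u) < 3:
                raise FormatError(f"malformed exclusion set {body!r} at offset {offset}")
            residues = frozenset(body_u[1:-1])
            if not residues <= ACCEPTED_ALPHABET:
                raise FormatError(f"illegal residue in exclusion {body!r} at offset {offset}")
            elem = PatternElement("exclusion", residues, lo, hi)
        elif len(body_u) == 1 and body_u in ACCEPTED_ALPHABET:
            elem = PatternElement("fixed", frozenset(body_u), lo, hi)
        else:
            raise FormatError(f"unrecognized pattern element {body!r} at offset {offset}")
        elements.append(elem)
        offset += len(token) + 1  # account for the '-' separator

    return PrositePattern(source, tuple(elements), anchored_start, anchored_end)


def _match_ends(pattern: PrositePattern, seq: str, start: int) -> set[int]:
    """All end positions (exclusive) reachable by matching from ``start``."""
    reachable = {start}
    for elem in pattern.elements:
        nxt: set[int] = set()
        for p in sorted(reachable):
            # consume between min_repeat and max_repeat matching residues
            q = p
            count = 0
            while count < elem.max_repeat and q < len(seq) and elem.matches(seq[q]):
                q += 1
                count += 1
                if count >= elem.min_repeat:
                    nxt.add(q)
            if elem.min_repeat == 0:
                nxt.add(p)
        if not nxt:
            return set()
        reachable = nxt
    return reachable


def match_pattern(
    pattern: PrositePattern, record: ProteinRecord
) -> list[tuple[int, int]]:
    """All matches as 1-based inclusive (start, end) pairs.

    One (shortest) match per matching start position; anchors restrict the
    candidate starts/ends to the termini.
    """
    seq = record.residues.upper()
    starts = [0] if pattern.anchored_start else range(len(seq))
    hits = []
    for s in starts:
        ends = _match_ends(pattern, seq, s)
        ends = {e for e in ends if e > s}  # ignore zero-length matches
        if pattern.anchored_end:
            ends = {e for e in ends if e == len(seq)}
        if ends:
            hits.append((s + 1, min(ends)))
    return hits


def scan_database(
    patterns: list[PrositePattern], records: list[ProteinRecord]
) -> pd.DataFrame:
    """Match every pattern against every record.

    Returns a DataFrame with columns ``pattern, record_id, start, end,
    match`` ordered by record, then start position, then pattern order.
    """
    rows = []
    for record in records:
        per_record = []
        for p_idx, pattern in enumerate(patterns):
            for start, end in match_pattern(pattern, record):
                per_record.append((start, p_idx, pattern, record, end))
        per_record.sort(key=lambda t: (t[0], t[1]))
        for start, _p_idx, pattern, rec, end in per_record:
            rows.append(
                {
                    "pattern": pattern.source_text,
                    "record_id": rec.identifier,
                    "start": start,
                    "end": end,
                    "match": rec.residues[start - 1:end],
                }
            )
    return pd.DataFrame(rows, columns=["pattern", "record_id", "start", "end", "match"])
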