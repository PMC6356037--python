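"""FASTA input, scan-report output, and sequence validation.

Protein sequences come in as standard (possibly multi-record, line-wrapped)
FASTA; the scan results go out as a flat tab-separated table with one row per
candidate heme-coordination site.  Sequences are validated against the 20
standard one-letter amino-acid codes plus the ambiguity/special codes
``X B Z U O`` and ``J`` (used here for norleucine, Nle, which has no standard
one-letter code; the scanner never treats J as a coordination site).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: 20 standard residues plus ambiguity codes (X, B, Z), selenocysteine (U),
#: pyrrolysine (O) and norleucine (J).
ACCEPTED_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY" "XBZUOJ")

REPORT_COLUMNS = (
    "record_id",
    "position",
    "axial_ligand",
    "motif",
    "net_charge",
    "class",
    "exposure",
    "comment",
)


@dataclass(frozen=True)
class ProteinRecord:
    """One FASTA entry: identifier, free-text description, residue string."""

    identifier: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValidationError(f"record {self.identifier!r}: empty sequence")
        for i, ch in enumerate(self.residues, start=1):
            if ch not in ACCEPTED_ALPHABET:
                raise ValidationError(
                    f"record {self.identifier!r}: illegal residue {ch!r} "
                    f"at position {i}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class ScanReportRow:
    """One line of the tabulated scan output."""

    record_id: str
    site_position: int
    axial_ligand: str
    motif: str
    net_charge: int
    hbm_class: str
    exposure: str = "unknown"
    comments: list[str] = field(default_factory=list)


def read_fasta(source: TextIO | str) -> list[ProteinRecord]:
    """Parse FASTA text into validated :class:`ProteinRecord` objects.

    Lowercase residues are uppercased; ``*`` (stop) characters are stripped
    with a warning.  Raises :class:`FormatError` on empty input or sequence
    data before the first header, :class:`ValidationError` on illegal
    residue characters.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    text = source.read()
    stripped = text.strip()
    if not stripped:
        raise FormatError("no records: input is empty")
    if not stripped.startswith(">"):
        raise FormatError("sequence data before first FASTA header ('>')")

    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        seq = str(rec.seq).upper()
        if "*" in seq:
            logger.warning(
                "record %r: stripping %d stop character(s) '*'",
                rec.id, seq.count("*"),
            )
            seq = seq.replace("*", "")
        description = rec.description[len(rec.id):].strip()
        records.append(ProteinRecord(rec.id, seq, description))
    if not records:
        raise FormatError("no records found in FASTA input")
    return records


def write_fasta(records: Iterable[ProteinRecord], sink: TextIO, width: int = 60) -> None:
    """Write records as wrapped FASTA (inverse of :func:`read_fasta`)."""
    seqrecords = [
        SeqRecord(Seq(r.residues), id=r.identifier, description=r.description)
        for r in records
    ]
    writer = SeqIO.FastaIO.FastaWriter(sink, wrap=width)
    writer.write_file(seqrecords)


def write_report(rows: Iterable[ScanReportRow], sink: TextIO) -> None:
    """Write scan rows as a TSV table (one header line, input order kept).

    Comments are joined with ``"; "``; tabs/newlines inside fields are not
    permitted in any field value.
    """
    sink.write("\t".join(REPORT_COLUMNS) + "\n")
    for row in rows:
        comment = "; ".join(row.comments)
        fields = (
            row.record_id,
            str(row.site_position),
            row.axial_ligand,
            row.motif,
            str(row.net_charge),
            row.hbm_class,
            row.exposure,
            comment,
        )
        for f in fields:
            if "\t" in f or "\n" in f:
                raise ValidationError(f"field contains tab/newline: {f!r}")
        sink.write("\t".join(fields) + "\n")


def read_report(source: TextIO | str) -> list[ScanReportRow]:
    """Parse a TSV scan report back into rows (round-trip of write_report)."""
    if isinstance(source, str):
        source = io.StringIO(source)
    lines = source.read().splitlines()
    if not lines:
        raise FormatError("empty report")
    header = tuple(lines[0].split("\t"))
    if header != REPORT_COLUMNS:
        raise FormatError(f"unexpected report header: {header!r}")
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != len(REPORT_COLUMNS):
            raise FormatError(f"line {lineno}: expected {len(REPORT_COLUMNS)} fields")
        rid, pos, lig, motif, charge, cls, exposure, comment = parts
        rows.append(
            ScanReportRow(
                record_id=rid,
                site_position=int(pos),
                axial_ligand=lig,
                motif=motif,
                net_charge=int(charge),
                hbm_class=cls,
                exposure=exposure,
                comments=comment.split("; ") if comment else [],
            )
        )
    return rows
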