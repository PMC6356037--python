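"""Core motif scanner: coordination sites, 9-mer windows, charge, CP, ancillary sites.

Transient heme binding is coordinated through the side chain of a cysteine,
histidine or tyrosine (the axial ligand, position P0 of the motif
nomenclature).  The scanner locates every C/H/Y in a protein sequence and
extracts the surrounding nonapeptide window — up to four residues on either
side of P0, truncated at the sequence termini — then annotates each window
with its net charge, whether the axial ligand starts a cysteine–proline (CP)
dipeptide, and any additional potential coordination sites inside the window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ContractError
from .seq_io import ProteinRecord

#: Residues that can serve as the heme axial ligand.
COORDINATING_RESIDUES = "CHY"

#: Half-width of the motif window around P0 (9-mer = 4 + 1 + 4).
FLANK = 4

POSITIVE_RESIDUES = frozenset("KR")
NEGATIVE_RESIDUES = frozenset("DE")


@dataclass(frozen=True)
class CoordinationSite:
    """A candidate axial-ligand residue: 1-based position and ligand letter."""

    position: int
    ligand: str


@dataclass
class MotifWindow:
    """Up-to-9-residue window centered on a coordination site.

    ``center_offset`` is the 0-based index of the axial ligand inside
    ``sequence``; ``ancillary_sites`` lists further C/H/Y residues in the
    window as (ligand, signed offset relative to P0) pairs.
    """

    site: CoordinationSite
    sequence: str
    center_offset: int
    left_truncated: bool
    right_truncated: bool
    net_charge: int = 0
    is_cp: bool = False
    ancillary_sites: list[tuple[str, int]] = field(default_factory=list)


def find_coordination_sites(
    record: ProteinRecord, ligands: str = COORDINATING_RESIDUES
) -> list[CoordinationSite]:
    """All positions bearing a coordinating residue, ascending by position."""
    return [
        CoordinationSite(i, ch)
        for i, ch in enumerate(record.residues, start=1)
        if ch in ligands
    ]


def net_charge(window: "MotifWindow | str", histidine_positive: bool = False) -> int:
    """Integer net charge of the window sequence.

    Convention: K/R count +1, D/E count −1, histidine is neutral (implied
    physiological pH; set ``histidine_positive`` to count H as +1 for acidic
    conditions), and no terminal charges are added because the window is an
    internal protein fragment.
    """
    seq = window if isinstance(window, str) else window.sequence
    pos = sum(1 for ch in seq if ch in POSITIVE_RESIDUES)
    neg = sum(1 for ch in seq if ch in NEGATIVE_RESIDUES)
    if histidine_positive:
        pos += seq.count("H")
    return pos - neg


def detect_cp(window: MotifWindow) -> bool:
    """True iff the axial ligand is C immediately followed by P in the window."""
    nxt = window.center_offset + 1
    return (
        window.site.ligand == "C"
        and nxt < len(window.sequence)
        and window.sequence[nxt] == "P"
    )


def find_ancillary_sites(window: MotifWindow) -> list[tuple[str, int]]:
    """Additional C/H/Y residues in the window, as (ligand, offset != 0) pairs."""
    return [
        (ch, i - window.center_offset)
        for i, ch in enumerate(window.sequence)
        if ch in COORDINATING_RESIDUES and i != window.center_offset
    ]


def extract_window(record: ProteinRecord, site: CoordinationSite) -> MotifWindow:
    """Extract and fully annotate the motif window around ``site``.

    Raises :class:`ContractError` if the site does not match the record.
    """
    seq = record.residues
    pos = site.position
    if not (1 <= pos <= len(seq)) or seq[pos - 1] != site.ligand:
        raise ContractError(
            f"site {site.ligand}@{pos} does not match record {record.identifier!r}"
        )
    start = max(1, pos - FLANK)          # 1-based inclusive
    end = min(len(seq), pos + FLANK)
    window = MotifWindow(
        site=site,
        sequence=seq[start - 1:end],
        center_offset=pos - start,
        left_truncated=pos - FLANK < 1,
        right_truncated=pos + FLANK > len(seq),
    )
    window.net_charge = net_charge(window)
    window.is_cp = detect_cp(window)
    window.ancillary_sites = find_ancillary_sites(window)
    return window


def scan(
    record: ProteinRecord, ligands: str = COORDINATING_RESIDUES
) -> list[MotifWindow]:
    """One fully populated window per coordination site, in sequence order."""
    return [extract_window(record, s) for s in find_coordination_sites(record, ligands)]
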