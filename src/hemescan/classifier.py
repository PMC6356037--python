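"""Eight-class heme-binding-motif (HBM) taxonomy and report annotations.

The classes partition motifs by axial ligand (C, H, Y), with the cysteine
branch split further by the presence of a CP dipeptide, and every branch
split by the presence or absence of additional potential coordination sites
within the 9-mer window:

    I    C, no CP, no ancillary   — hexa-coordinated, sandwich-like complex
    II   C, no CP, ancillary      — hexa-coordinated, loop/clamp-like (e.g. HXXXC)
    III  CP, no ancillary         — penta-coordinated
    IV   CP, ancillary            — penta-coordinated (CP dominates the split)
    V    H, no ancillary          — penta-coordinated
    VI   H, ancillary             — hexa-coordinated, loop/clamp-like
    VII  Y, no ancillary          — penta-coordinated
    VIII Y, ancillary             — hexa-coordinated, sandwich-like

The coordination mode and complex topology attached to each class summarize
peptide-level spectroscopy/NMR evidence; they are metadata hints, not
structure predictions for arbitrary proteins.  The V–VIII numbering follows
the penta = {III, IV, V, VII} / hexa = {I, II, VI, VIII} grouping; users who
read the class diagram differently can re-map labels via the exported table.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ContractError
from .scanner import MotifWindow

CLASS_LABELS = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII")


@dataclass(frozen=True)
class MotifClass:
    label: str
    axial_ligand: str
    requires_cp: bool
    requires_ancillary: bool
    expected_coordination: str  # penta | hexa | mixed
    expected_topology: str      # sandwich | loop | single | unknown


_CLASS_TABLE: tuple[MotifClass, ...] = (
    MotifClass("I", "C", False, False, "hexa", "sandwich"),
    MotifClass("II", "C", False, True, "hexa", "loop"),
    MotifClass("III", "C", True, False, "penta", "single"),
    MotifClass("IV", "C", True, True, "penta", "single"),
    MotifClass("V", "H", False, False, "penta", "single"),
    MotifClass("VI", "H", False, True, "hexa", "loop"),
    MotifClass("VII", "Y", False, False, "penta", "single"),
    MotifClass("VIII", "Y", False, True, "hexa", "sandwich"),
)

_BY_KEY = {
    (c.axial_ligand, c.requires_cp, c.requires_ancillary): c for c in _CLASS_TABLE
}


def enumerate_classes() -> list[MotifClass]:
    """The eight classes, in label order."""
    return list(_CLASS_TABLE)


def assign_class(window: MotifWindow) -> MotifClass:
    """Deterministically map a window to its class.

    CP status dominates the cysteine split: a CP window with an ancillary
    site is class IV, not II.
    """
    ligand = window.site.ligand
    if ligand not in "CHY":
        raise ContractError(f"no class defined for axial ligand {ligand!r}")
    is_cp = window.is_cp if ligand == "C" else False
    return _BY_KEY[(ligand, is_cp, bool(window.ancillary_sites))]


_TOPOLOGY_PHRASE = {
    "sandwich": "sandwich-like complex (two peptides per heme)",
    "loop": "loop/clamp-like complex",
    "single": "single axial coordination",
    "unknown": "topology unknown",
}


def annotate(window: MotifWindow, cls: MotifClass) -> list[str]:
    """Comment strings for the report's 'comment' column.

    Raises :class:`ContractError` if ``cls`` is not the class of ``window``.
    """
    if cls.label != assign_class(window).label:
        raise ContractError(
            f"class {cls.label} does not match window at {window.site.position}"
        )
    comments: list[str] = []
    if window.is_cp:
        comments.append("CP motif")
    if window.ancillary_sites:
        sites = ", ".join(f"{lig} at {off:+d}" for lig, off in window.ancillary_sites)
        comments.append(f"additional coordination site(s): {sites}")
    if window.net_charge < 0:
        comments.append("negative net charge: heme binding disfavored")
    elif window.net_charge > 0:
        comments.append("positive net charge: heme binding favored")
    comments.append(
        f"class {cls.label}: expected {cls.expected_coordination}-coordination, "
        f"{_TOPOLOGY_PHRASE[cls.expected_topology]} (peptide-level evidence)"
    )
    return comments


def class_table_tsv() -> str:
    """The class table as TSV text, for documentation export."""
    lines = ["label\tligand\tcp\tancillary\tcoordination\ttopology"]
    for c in _CLASS_TABLE:
        lines.append(
            f"{c.label}\t{c.axial_ligand}\t{c.requires_cp}\t"
            f"{c.requires_ancillary}\t{c.expected_coordination}\t{c.expected_topology}"
        )
    return "\n".join(lines) + "\n"
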