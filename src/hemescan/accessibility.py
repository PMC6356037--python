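"""Solvent-exposure filtering of candidate coordination sites.

A buried C/H/Y cannot transiently coordinate heme, so the scanner's default
mode keeps only sites predicted to be surface-exposed.  Exposure labels come
from one of two pluggable sources behind the same profile type:

* :func:`builtin_predictor` — a deterministic sliding-window Kyte–Doolittle
  hydropathy heuristic (strongly hydrophobic neighborhoods are labeled
  buried).  This is a simple sequence-only heuristic; per-residue labels from
  a dedicated solvent-accessibility predictor or from structure (DSSP RSA)
  should be preferred when available.
* :func:`read_accessibility_file` — user-supplied per-residue labels or
  relative-solvent-accessibility (RSA) fractions, binarized at a cutoff.

Structure mode performs no filtering at all: every site is reported and the
user curates against the known structure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence, TextIO

from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .errors import ValidationError
from .scanner import CoordinationSite
from .seq_io import ProteinRecord

logger = logging.getLogger(__name__)

EXPOSED, BURIED, UNKNOWN = "exposed", "buried", "unknown"

#: RSA at or above this fraction counts as surface-exposed.
DEFAULT_RSA_CUTOFF = 0.25


@dataclass
class AccessibilityProfile:
    """Per-residue exposed/buried/unknown labels for one protein."""

    record_id: str
    labels: Sequence[str]
    source: str

    def validate_against(self, record: ProteinRecord) -> None:
        if len(self.labels) != len(record):
            raise ValidationError(
                f"accessibility profile for {self.record_id!r} has "
                f"{len(self.labels)} labels but record {record.identifier!r} "
                f"has {len(record)} residues"
            )


def filter_sites(
    sites: list[CoordinationSite],
    profile: AccessibilityProfile,
    mode: str = "default",
) -> list[CoordinationSite]:
    """Apply the operation mode to a site list.

    ``structure`` mode is the identity.  ``default`` mode keeps exposed
    sites; unknown labels pass with a warning (missing evidence should not
    suppress a candidate), buried sites are dropped.
    """
    if mode == "structure":
        return list(sites)
    if mode != "default":
        raise ValidationError(f"unknown mode {mode!r}; expected default|structure")
    kept = []
    for site in sites:
        if site.position > len(profile.labels):
            raise ValidationError(
                f"site position {site.position} beyond profile length "
                f"{len(profile.labels)} for {profile.record_id!r}"
            )
        label = profile.labels[site.position - 1]
        if label == BURIED:
            continue
        if label == UNKNOWN:
            logger.warning(
                "%s: exposure unknown at position %d; treating as exposed",
                profile.record_id, site.position,
            )
        kept.append(site)
    return kept


def builtin_predictor(
    record: ProteinRecord, window_size: int = 9, threshold: float = 0.0
) -> AccessibilityProfile:
    """Label residues by sliding-window mean Kyte–Doolittle hydropathy.

    Mean hydropathy above ``threshold`` (positive = hydrophobic) → buried,
    else exposed.  Windows are truncated at the termini; residue codes
    without a hydropathy value (X, B, Z, U, O, J) contribute 0 with a warning.
    """
    if window_size < 3 or window_size % 2 == 0:
        raise ValidationError("window_size must be an odd integer >= 3")
    values = []
    for ch in record.residues:
        if ch in KYTE_DOOLITTLE:
            values.append(KYTE_DOOLITTLE[ch])
        else:
            logger.warning(
                "%s: no hydropathy value for residue %r; using 0.0",
                record.identifier, ch,
            )
            values.append(0.0)
    half = window_size // 2
    n = len(values)
    labels = []
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        mean = math.fsum(values[lo:hi]) / (hi - lo)  # order-independent sum
        labels.append(BURIED if mean > threshold else EXPOSED)
    return AccessibilityProfile(record.identifier, labels, "builtin-heuristic")


def read_accessibility_file(
    source: TextIO,
    record: ProteinRecord,
    rsa_cutoff: float = DEFAULT_RSA_CUTOFF,
) -> AccessibilityProfile:
    """Read a two-column (position, label-or-RSA) file into a profile.

    Accepted values per position: ``exposed``/``buried`` (case-insensitive)
    or an RSA fraction in [0, 1], binarized at ``rsa_cutoff`` (>= cutoff →
    exposed).  Unlisted positions are labeled unknown.  Lines starting with
    ``#`` and blank lines are skipped.
    """
    labels = [UNKNOWN] * len(record)
    name = getattr(source, "name", "<stream>")
    for lineno, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValidationError(f"{name}:{lineno}: expected 2 columns, got {len(parts)}")
        try:
            pos = int(parts[0])
        except ValueError:
            raise ValidationError(f"{name}:{lineno}: bad position {parts[0]!r}") from None
        if not (1 <= pos <= len(record)):
            raise ValidationError(
                f"{name}:{lineno}: position {pos} out of range 1..{len(record)}"
            )
        value = parts[1].lower()
        if value in (EXPOSED, BURIED):
            labels[pos - 1] = value
        else:
            try:
                rsa = float(value)
            except ValueError:
                raise ValidationError(
                    f"{name}:{lineno}: expected exposed/buried or RSA fraction, "
                    f"got {parts[1]!r}"
                ) from None
            if not (0.0 <= rsa <= 1.0):
                raise ValidationError(f"{name}:{lineno}: RSA {rsa} outside [0, 1]")
            labels[pos - 1] = EXPOSED if rsa >= rsa_cutoff else BURIED
    return AccessibilityProfile(record.identifier, labels, f"file:{name}")
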