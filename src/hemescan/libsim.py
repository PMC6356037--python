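"""Synthetic combinatorial nonapeptide library generator.

Emulates the X₄(C/H/Y)⁰X₄ one-bead-one-compound library design: a fixed
central coordinating residue (Cys, His or Tyr) with four fully randomized
flanking residues on each side, where the flank alphabet is all standard
amino acids except Cys (to avoid intramolecular disulfides) and Met
(incompatible with the sequencing chemistry) plus norleucine (Nle, written
``J``) — 19 letters in total.

Two center-weight regimes matter:

* the *synthesized* library is uniform over {C, H, Y};
* the *hit* population recovered from heme-binding screens shows His and Tyr
  centers at roughly 40% each and Cys at roughly 20% — these hit frequencies
  are the default ``center_weights`` so that generated libraries resemble
  the binder population rather than the naive synthesis.

Only sequences are simulated; bead chemistry, heme incubation and binding
outcomes have no computable model here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError, ValidationError
from .seq_io import ProteinRecord

#: 20 standard residues minus {C, M}, plus norleucine 'J' → 19 letters.
DEFAULT_FLANK_ALPHABET = tuple(sorted(set("ACDEFGHIKLMNPQRSTVWY") - {"C", "M"} | {"J"}))

DEFAULT_CENTER_WEIGHTS = {"H": 0.40, "Y": 0.40, "C": 0.20}

#: Optional polar-enriched flank weighting (binder flanks skew polar); the
#: enrichment factor is a qualitative choice — no numeric enrichment is
#: established — so uniform sampling stays the default.
POLAR_ENRICHED_RESIDUES = frozenset("EDQNRKHY")


@dataclass
class LibrarySpec:
    """Parameters of the combinatorial library to simulate."""

    flank_length: int = 4
    center_alphabet: tuple[str, ...] = ("C", "H", "Y")
    flank_alphabet: tuple[str, ...] = DEFAULT_FLANK_ALPHABET
    center_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CENTER_WEIGHTS)
    )
    polar_enrichment: float = 1.0  # >1 up-weights polar flank residues
    seed: int = 0

    def validate(self) -> None:
        if self.flank_length < 0:
            raise ValidationError("flank_length must be >= 0")
        if set(self.center_weights) != set(self.center_alphabet):
            raise ValidationError(
                "center_weights keys must equal center_alphabet "
                f"({sorted(self.center_alphabet)})"
            )
        total = sum(self.center_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"center_weights must sum to 1, got {total}")
        if any(w < 0 for w in self.center_weights.values()):
            raise ValidationError("center_weights must be non-negative")
        if self.polar_enrichment <= 0:
            raise ValidationError("polar_enrichment must be positive")


def generate_library(spec: LibrarySpec, n: int) -> list[ProteinRecord]:
    """Draw ``n`` library peptides of length ``2 * flank_length + 1``.

    Centers follow ``center_weights``; flank positions are i.i.d. over the
    flank alphabet (uniform unless ``polar_enrichment != 1``).  Reproducible
    for a fixed ``spec.seed``.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    centers = np.array(spec.center_alphabet)
    center_p = np.array([spec.center_weights[c] for c in spec.center_alphabet])
    center_idx = rng.choice(len(centers), size=n, p=center_p)

    flanks = np.array(spec.flank_alphabet)
    k = 2 * spec.flank_length
    if spec.polar_enrichment == 1.0:
        flank_idx = rng.integers(0, len(flanks), size=(n, k))
    else:
        w = np.array([
            spec.polar_enrichment if a in POLAR_ENRICHED_RESIDUES else 1.0
            for a in spec.flank_alphabet
        ])
        flank_idx = rng.choice(len(flanks), size=(n, k), p=w / w.sum())

    records = []
    fl = spec.flank_length
    for i in range(n):
        row = flanks[flank_idx[i]]
        seq = "".join(row[:fl]) + str(centers[center_idx[i]]) + "".join(row[fl:])
        records.append(ProteinRecord(f"pep{i + 1}", seq))
    return records


def _center_index(records: list[ProteinRecord]) -> int:
    length = len(records[0])
    if length % 2 == 0 or any(len(r) != length for r in records):
        raise ContractError("records must share a common odd peptide length")
    return length // 2


def ligand_fractions(records: list[ProteinRecord]) -> dict[str, float]:
    """Empirical frequency of each center residue; fractions sum to 1."""
    if not records:
        raise ContractError("ligand_fractions requires at least one record")
    mid = _center_index(records)
    counts: dict[str, int] = {}
    for r in records:
        counts[r.residues[mid]] = counts.get(r.residues[mid], 0) + 1
    return {ligand: c / len(records) for ligand, c in sorted(counts.items())}


def ancillary_fraction(records: list[ProteinRecord]) -> float:
    """Fraction of peptides carrying >= 1 His or Tyr among the flank positions.

    For uniform flanks over an alphabet of size A containing H and Y this
    converges to ``1 - ((A - 2) / A) ** (2 * flank_length)`` (~0.589 for the
    default 19-letter alphabet and 8 flank positions).
    """
    if not records:
        raise ContractError("ancillary_fraction requires at least one record")
    mid = _center_index(records)
    hits = 0
    for r in records:
        flanks = r.residues[:mid] + r.residues[mid + 1:]
        if "H" in flanks or "Y" in flanks:
            hits += 1
    return hits / len(records)


def expected_ancillary_fraction(spec: LibrarySpec) -> float:
    """Closed-form ancillary fraction for uniform flank sampling."""
    a = len(spec.flank_alphabet)
    hy = sum(1 for x in spec.flank_alphabet if x in ("H", "Y"))
    return 1.0 - ((a - hy) / a) ** (2 * spec.flank_length)
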