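"""Rule engine mapping spectroscopic readouts to heme coordination states.

Three techniques report on the geometry of a heme–peptide/protein complex,
i.e. whether the ferric iron carries one (penta) or two (hexa) axial ligands
beyond the four porphyrin nitrogens:

* **UV/Vis** — the Soret band near 400 nm shifts on complex formation.  A
  lone maximum near 370 nm correlates primarily with penta-coordination; a
  shift into the 420–430 nm band cannot be uniquely assigned (ambiguous);
  maxima in both bands frequently indicate a penta/hexa mixture.
* **resonance Raman** — the ν₃ marker band sits near 1491 cm⁻¹ for free
  hemin and penta-coordinated complexes (so a lone 1491 band carries a
  free-hemin caveat) and near 1505 cm⁻¹ for hexa-coordination; a double band
  indicates a mixture.
* **cw-EPR** — high-spin penta-coordination shows signals at g⊥ ≈ 6 and
  g∥ ≈ 2; low-spin hexa-coordination shows three g-values (gx, gy, gz)
  between ≈1.5 and ≈3.

Each ``infer_from_*`` function produces a partial verdict with an evidence
trail; :func:`combine_evidence` merges partials, letting any decisive
technique resolve a UV-ambiguous call and flagging penta-vs-hexa conflicts
as mixed.  Band-center tolerances are configurable via :class:`Tolerances`
(the literature reports band positions as approximate values).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ContractError, ValidationError

PENTA, HEXA, MIXED, AMBIGUOUS, UNDETERMINED = (
    "penta", "hexa", "mixed", "ambiguous", "undetermined",
)


@dataclass(frozen=True)
class Tolerances:
    """Band-center tolerances for the rule base (all configurable)."""

    soret_penta_nm: float = 370.0
    soret_tol_nm: float = 8.0
    soret_hexa_min_nm: float = 415.0   # the ~420-430 nm band
    soret_hexa_max_nm: float = 435.0
    nu3_penta_cm1: float = 1491.0
    nu3_hexa_cm1: float = 1505.0
    nu3_tol_cm1: float = 5.0
    g_perp: float = 6.0
    g_par: float = 2.0
    g_tol: float = 0.4
    g_lowspin_min: float = 1.5
    g_lowspin_max: float = 3.0


DEFAULT_TOLERANCES = Tolerances()


@dataclass(frozen=True)
class Evidence:
    technique: str
    rule: str
    verdict: str


@dataclass
class SpectralReadout:
    """Already-extracted band positions from one sample.

    ν₇ band positions are accepted but uninterpreted (no quantitative rule).
    """

    soret_maxima_nm: list[float] = field(default_factory=list)
    nu3_wavenumbers_cm1: list[float] = field(default_factory=list)
    epr_g_values: list[float] = field(default_factory=list)
    nu7_wavenumbers_cm1: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("soret_maxima_nm", "nu3_wavenumbers_cm1",
                     "epr_g_values", "nu7_wavenumbers_cm1"):
            values = getattr(self, name)
            if any(v <= 0 for v in values):
                raise ValidationError(f"{name}: values must be strictly positive")
            setattr(self, name, sorted(values))


@dataclass
class PartialCall:
    """One technique's contribution: verdict plus matched-rule evidence."""

    technique: str
    verdict: str
    evidence: list[Evidence] = field(default_factory=list)
    uv_group: str | None = None  # set only by the UV rule


@dataclass
class CoordinationCall:
    verdict: str
    evidence: list[Evidence] = field(default_factory=list)
    uv_group: str = "none"


def infer_from_uv(
    soret_maxima_nm: list[float], tol: Tolerances = DEFAULT_TOLERANCES
) -> PartialCall:
    """Classify Soret maxima (single-maximum bands → penta/ambiguous; both → mixed)."""
    for wl in soret_maxima_nm:
        if not (300.0 <= wl <= 800.0):
            raise ValidationError(f"Soret maximum {wl} nm outside 300-800 nm")
    near370 = any(abs(wl - tol.soret_penta_nm) <= tol.soret_tol_nm
                  for wl in soret_maxima_nm)
    in420band = any(tol.soret_hexa_min_nm <= wl <= tol.soret_hexa_max_nm
                    for wl in soret_maxima_nm)
    ev: list[Evidence] = []
    if near370 and in420band:
        verdict, group = MIXED, "III"
        ev.append(Evidence("UV/Vis", "Soret maxima in both ~370 and ~420-430 nm bands",
                           MIXED))
    elif near370:
        verdict, group = PENTA, "I"
        ev.append(Evidence("UV/Vis", f"lone Soret maximum near {tol.soret_penta_nm} nm",
                           PENTA))
    elif in420band:
        verdict, group = AMBIGUOUS, "II"
        ev.append(Evidence("UV/Vis",
                           "Soret maximum in ~420-430 nm band: not uniquely assignable",
                           AMBIGUOUS))
    else:
        verdict, group = UNDETERMINED, "IV"
    return PartialCall("UV/Vis", verdict, ev, uv_group=group)


def infer_from_rraman(
    nu3_wavenumbers_cm1: list[float], tol: Tolerances = DEFAULT_TOLERANCES
) -> PartialCall:
    """Classify the ν₃ marker band (~1491 penta / ~1505 hexa / double band mixed)."""
    for wn in nu3_wavenumbers_cm1:
        if not (1400.0 <= wn <= 1600.0):
            raise ValidationError(f"nu3 wavenumber {wn} cm-1 outside 1400-1600 cm-1")
    at1491 = any(abs(wn - tol.nu3_penta_cm1) <= tol.nu3_tol_cm1
                 for wn in nu3_wavenumbers_cm1)
    at1505 = any(abs(wn - tol.nu3_hexa_cm1) <= tol.nu3_tol_cm1
                 for wn in nu3_wavenumbers_cm1)
    ev: list[Evidence] = []
    if at1491 and at1505:
        verdict = MIXED
        ev.append(Evidence("rRaman", "nu3 double band: penta/hexa mixture", MIXED))
    elif at1491:
        verdict = PENTA
        ev.append(Evidence("rRaman",
                           f"nu3 band near {tol.nu3_penta_cm1:g} cm-1 "
                           "(caveat: indistinguishable from free hemin)",
                           PENTA))
    elif at1505:
        verdict = HEXA
        ev.append(Evidence("rRaman", f"nu3 band near {tol.nu3_hexa_cm1:g} cm-1", HEXA))
    else:
        verdict = UNDETERMINED
    return PartialCall("rRaman", verdict, ev)


def infer_from_epr(
    epr_g_values: list[float], tol: Tolerances = DEFAULT_TOLERANCES
) -> PartialCall:
    """Classify the cw-EPR g-value pattern (high-spin penta / low-spin hexa)."""
    for g in epr_g_values:
        if not (0.5 <= g <= 10.0):
            raise ValidationError(f"g-value {g} outside 0.5-10")
    high_spin = (
        any(abs(g - tol.g_perp) <= tol.g_tol for g in epr_g_values)
        and any(abs(g - tol.g_par) <= tol.g_tol for g in epr_g_values)
    )
    low_spin = (
        len(epr_g_values) == 3
        and all(tol.g_lowspin_min <= g <= tol.g_lowspin_max for g in epr_g_values)
    )
    ev: list[Evidence] = []
    if high_spin and low_spin:
        verdict = MIXED
        ev.append(Evidence("cwEPR", "both high-spin and low-spin signatures", MIXED))
    elif high_spin:
        verdict = PENTA
        ev.append(Evidence("cwEPR",
                           f"high-spin pattern g ~ {tol.g_perp:g} and g ~ {tol.g_par:g}",
                           PENTA))
    elif low_spin:
        verdict = HEXA
        ev.append(Evidence("cwEPR",
                           f"three g-values within {tol.g_lowspin_min:g}-"
                           f"{tol.g_lowspin_max:g} (low spin)",
                           HEXA))
    else:
        verdict = UNDETERMINED
    return PartialCall("cwEPR", verdict, ev)


def combine_evidence(partials: list[PartialCall]) -> CoordinationCall:
    """Merge per-technique partial verdicts into one coordination call.

    Unanimous verdicts pass through; any mixed partial → mixed; a direct
    penta-vs-hexa conflict → mixed with a conflict flag in the evidence; an
    ambiguous UV call is resolved by any decisive technique.  The UV group
    label (I: ~370 only, II: ~420-430 only, III: both, IV: neither — an
    interpretation, the groups are not formally defined) is carried over
    from the UV partial when present.
    """
    if not partials:
        raise ContractError("combine_evidence requires at least one partial call")
    evidence = [e for p in partials for e in p.evidence]
    uv_group = next((p.uv_group for p in partials if p.uv_group is not None), "none")
    verdicts = {p.verdict for p in partials}

    decisive = verdicts & {PENTA, HEXA, MIXED}
    if MIXED in verdicts:
        verdict = MIXED
    elif PENTA in verdicts and HEXA in verdicts:
        verdict = MIXED
        evidence.append(Evidence("combined",
                                 "conflict: penta and hexa evidence from "
                                 "different techniques", MIXED))
    elif decisive:
        verdict = decisive.pop()
    elif AMBIGUOUS in verdicts:
        verdict = AMBIGUOUS
    else:
        verdict = UNDETERMINED
    return CoordinationCall(verdict, evidence, uv_group)


def interpret(
    readout: SpectralReadout, tol: Tolerances = DEFAULT_TOLERANCES
) -> CoordinationCall:
    """Run every technique with data in ``readout`` and combine the partials."""
    partials: list[PartialCall] = []
    if readout.soret_maxima_nm:
        partials.append(infer_from_uv(readout.soret_maxima_nm, tol))
    if readout.nu3_wavenumbers_cm1:
        partials.append(infer_from_rraman(readout.nu3_wavenumbers_cm1, tol))
    if readout.epr_g_values:
        partials.append(infer_from_epr(readout.epr_g_values, tol))
    if not partials:
        return CoordinationCall(UNDETERMINED, [], "none")
    call = combine_evidence(partials)
    if readout.nu7_wavenumbers_cm1:
        call.evidence.append(
            Evidence("rRaman", "nu7 band recorded: uninterpreted (no rule)",
                     UNDETERMINED)
        )
    return call
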