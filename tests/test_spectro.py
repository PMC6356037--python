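import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from hemescan.errors import ContractError, ValidationError
from hemescan.spectro import (
    SpectralReadout,
    Tolerances,
    combine_evidence,
    infer_from_epr,
    infer_from_rraman,
    infer_from_uv,
    interpret,
)


class TestUvRule:
    @pytest.mark.parametrize(
        "maxima,verdict",
        [
            ([370], "penta"),
            ([365], "penta"),
            ([425], "ambiguous"),
            ([417], "ambiguous"),
            ([370, 425], "mixed"),
            ([400], "undetermined"),
            ([], "undetermined"),
        ],
    )
    def test_band_assignment(self, maxima, verdict):
        assert infer_from_uv(maxima).verdict == verdict

    @pytest.mark.parametrize(
        "maxima,group",
        [([370], "I"), ([425], "II"), ([370, 425], "III"), ([500], "IV")],
    )
    def test_uv_group_labels(self, maxima, group):
        assert infer_from_uv(maxima).uv_group == group

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            infer_from_uv([250.0])


class TestRamanRule:
    def test_penta_band_with_free_hemin_caveat(self):
        call = infer_from_rraman([1491])
        assert call.verdict == "penta"
        assert any("hemin" in e.rule for e in call.evidence)

    def test_hexa_band(self):
        assert infer_from_rraman([1505]).verdict == "hexa"

    def test_double_band_is_mixture(self):
        assert infer_from_rraman([1491, 1505]).verdict == "mixed"

    def test_band_far_from_markers_undetermined(self):
        assert infer_from_rraman([1450]).verdict == "undetermined"

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            infer_from_rraman([1700])


class TestEprRule:
    def test_high_spin_pattern_is_penta(self):
        assert infer_from_epr([2.0, 6.0]).verdict == "penta"

    def test_three_low_spin_values_is_hexa(self):
        assert infer_from_epr([1.8, 2.2, 2.9]).verdict == "hexa"

    def test_empty_undetermined(self):
        assert infer_from_epr([]).verdict == "undetermined"

    def test_lone_g6_insufficient(self):
        assert infer_from_epr([6.0]).verdict == "undetermined"

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            infer_from_epr([12.0])


class TestCombine:
    def test_unanimous_passes_through(self):
        call = combine_evidence([infer_from_uv([370]), infer_from_rraman([1491])])
        assert call.verdict == "penta"

    def test_decisive_technique_resolves_ambiguous_uv(self):
        call = combine_evidence([infer_from_uv([425]), infer_from_epr([1.8, 2.2, 2.9])])
        assert call.verdict == "hexa"
        assert call.uv_group == "II"

    def test_penta_hexa_conflict_flagged_as_mixed(self):
        call = combine_evidence([infer_from_rraman([1491]), infer_from_epr([1.8, 2.2, 2.9])])
        assert call.verdict == "mixed"
        assert any("conflict" in e.rule for e in call.evidence)

    def test_empty_input_rejected(self):
        with pytest.raises(ContractError):
            combine_evidence([])

    def test_undetermined_iff_no_rule_matched(self):
        call = combine_evidence([infer_from_uv([400]), infer_from_epr([6.0])])
        assert call.verdict == "undetermined"
        assert call.evidence == []

    def test_order_invariance(self):
        partials = [
            infer_from_uv([425]),
            infer_from_rraman([1505]),
            infer_from_epr([2.0, 6.0]),
        ]
        verdicts = {
            combine_evidence(list(p)).verdict
            for p in itertools.permutations(partials)
        }
        assert len(verdicts) == 1


class TestInterpret:
    def test_full_readout(self):
        call = interpret(SpectralReadout([370], [1491], [2.0, 6.0]))
        assert call.verdict == "penta"
        assert call.uv_group == "I"

    def test_empty_readout_undetermined(self):
        assert interpret(SpectralReadout()).verdict == "undetermined"

    def test_nu7_recorded_but_uninterpreted(self):
        call = interpret(SpectralReadout([370], nu7_wavenumbers_cm1=[670]))
        assert call.verdict == "penta"
        assert any("nu7" in e.rule for e in call.evidence)

    def test_readout_sorts_and_validates(self):
        r = SpectralReadout([425, 370])
        assert r.soret_maxima_nm == [370, 425]
        with pytest.raises(ValidationError):
            SpectralReadout([-1.0])


@given(
    st.lists(st.floats(min_value=300, max_value=800), max_size=2),
    st.floats(min_value=0, max_value=20),
)
def test_widening_uv_tolerance_never_flips_a_decisive_verdict(maxima, extra):
    """Tolerance monotonicity: wider bands only convert undetermined→matched."""
    narrow = infer_from_uv(sorted(maxima)).verdict
    wide_tol = Tolerances(
        soret_tol_nm=8.0 + extra,
        soret_hexa_min_nm=415.0 - extra,
        soret_hexa_max_nm=435.0 + extra,
    )
    wide = infer_from_uv(sorted(maxima), wide_tol).verdict
    if narrow == "penta":
        assert wide in ("penta", "mixed")
    elif narrow == "ambiguous":
        assert wide in ("ambiguous", "mixed")
    elif narrow == "mixed":
        assert wide == "mixed"
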