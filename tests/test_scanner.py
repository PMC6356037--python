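import pytest
from hypothesis import given

from hemescan.errors import ContractError
from hemescan.scanner import (
    CoordinationSite,
    detect_cp,
    extract_window,
    find_ancillary_sites,
    find_coordination_sites,
    net_charge,
    scan,
)
from hemescan.seq_io import ProteinRecord

from conftest import protein_sequences
from oracles import count_chy


def rec(seq: str) -> ProteinRecord:
    return ProteinRecord("r", seq)


class TestFindSites:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("ACA", [(2, "C")]),
            ("AHAYACA", [(2, "H"), (4, "Y"), (6, "C")]),
            ("AGLVFW", []),
        ],
    )
    def test_examples(self, seq, expected):
        sites = find_coordination_sites(rec(seq))
        assert [(s.position, s.ligand) for s in sites] == expected

    def test_selenocysteine_not_a_site(self):
        assert find_coordination_sites(rec("AUA")) == []

    def test_optional_extra_ligands(self):
        sites = find_coordination_sites(rec("AMAKA"), ligands="CHYMK")
        assert [(s.position, s.ligand) for s in sites] == [(2, "M"), (4, "K")]


class TestExtractWindow:
    def test_full_nonamer(self):
        w = extract_window(rec("AAAACAAAA"), CoordinationSite(5, "C"))
        assert w.sequence == "AAAACAAAA"
        assert w.center_offset == 4
        assert not w.left_truncated and not w.right_truncated

    def test_left_truncation(self):
        w = extract_window(rec("ACAAAAAAA"), CoordinationSite(2, "C"))
        assert w.sequence == "ACAAAA"  # 1 left, 4 right
        assert w.center_offset == 1
        assert w.left_truncated and not w.right_truncated

    def test_right_truncation(self):
        w = extract_window(rec("AAAAAAACA"), CoordinationSite(8, "C"))
        assert w.sequence == "AAAACA"  # 4 left, 1 right
        assert not w.left_truncated and w.right_truncated

    def test_ancillary_his_with_three_residue_spacer(self):
        # HXXXC arrangement: His at offset -4, three-residue spacer to P0
        w = extract_window(rec("AAHAAACAA"), CoordinationSite(7, "C"))
        assert ("H", -4) in w.ancillary_sites
        spacer = w.sequence[w.center_offset - 3 : w.center_offset]
        assert len(spacer) == 3 and "H" not in spacer

    def test_mismatched_site_rejected(self):
        with pytest.raises(ContractError):
            extract_window(rec("AAAACAAAA"), CoordinationSite(5, "H"))

    @given(protein_sequences)
    def test_window_stays_inside_sequence(self, seq):
        record = rec(seq)
        for site in find_coordination_sites(record):
            w = extract_window(record, site)
            assert len(w.sequence) <= 9
            assert (len(w.sequence) == 9) == (
                not w.left_truncated and not w.right_truncated
            )
            assert w.sequence[w.center_offset] == site.ligand
            assert seq[site.position - 1] == site.ligand
            # window is a substring at the expected coordinates
            start = site.position - 1 - w.center_offset
            assert seq[start : start + len(w.sequence)] == w.sequence


class TestNetCharge:
    @pytest.mark.parametrize(
        "seq,expected",
        [("AAAACAAAA", 0), ("RKAACAAAA", 2), ("DEAACAAKR", 0), ("DDDDCAAAA", -4)],
    )
    def test_counting(self, seq, expected):
        assert net_charge(seq) == expected

    def test_histidine_neutral_by_default_positive_on_toggle(self):
        assert net_charge("HHHACAAAA") == 0
        assert net_charge("HHHACAAAA", histidine_positive=True) == 3

    @given(protein_sequences, protein_sequences)
    def test_additivity_over_concatenation(self, a, b):
        assert net_charge(a + b) == net_charge(a) + net_charge(b)


class TestCpAndAncillary:
    def test_cp_detected_at_center(self):
        w = extract_window(rec("AAAACPAAA"), CoordinationSite(5, "C"))
        assert w.is_cp and detect_cp(w)
        assert w.sequence[w.center_offset : w.center_offset + 2] == "CP"

    def test_non_cysteine_center_never_cp(self):
        w = extract_window(rec("AAAAHPAAA"), CoordinationSite(5, "H"))
        assert not w.is_cp

    def test_terminal_cysteine_without_following_residue(self):
        w = extract_window(rec("AAAAC"), CoordinationSite(5, "C"))
        assert not w.is_cp

    @pytest.mark.parametrize(
        "seq,center,expected",
        [
            ("AAAACAAAA", 5, []),
            ("HAAACAAAA", 5, [("H", -4)]),
            ("YAAAHAAAY", 5, [("Y", -4), ("Y", 4)]),
        ],
    )
    def test_ancillary_sites(self, seq, center, expected):
        w = extract_window(rec(seq), CoordinationSite(center, seq[center - 1]))
        assert w.ancillary_sites == expected
        assert find_ancillary_sites(w) == expected


class TestScan:
    def test_no_sites_no_windows(self):
        assert scan(rec("AGLVFW")) == []

    def test_two_windows_in_order(self):
        windows = scan(rec("AAHAAACAA"))
        assert [(w.site.position, w.site.ligand) for w in windows] == [
            (3, "H"),
            (7, "C"),
        ]

    @given(protein_sequences)
    def test_window_count_matches_character_count_oracle(self, seq):
        assert len(scan(rec(seq))) == count_chy(seq)
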