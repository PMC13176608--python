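"""PROSITE pattern parsing, matching, derivation and ERM arithmetic."""

import re

import numpy as np
import pytest

import tfrmotifs as tm
from tfrmotifs.alphabet import AMINO_ACIDS
from tfrmotifs.conservation import OccurrenceStack, column_profile
from tfrmotifs.prosite import (
    Element,
    PrositePattern,
    ResidueFrequencyTable,
    derive_pattern,
    expected_random_matches,
    match_pattern,
    parse_pattern,
    signature_report,
    window_probability,
)


class TestParsing:
    def test_published_ramr2_pattern_structure(self):
        pat = parse_pattern("K-x(3)-[RH]-x-[IV]-W-N-S-Y-[IV]-x-W")
        assert len(pat.elements) == 12
        assert pat.min_length == 14
        kinds = [e.kind for e in pat.elements]
        assert kinds == [
            "fixed", "wildcard", "set", "wildcard", "set", "fixed", "fixed",
            "fixed", "fixed", "set", "wildcard", "fixed",
        ]

    def test_single_wildcard(self):
        pat = parse_pattern("x")
        assert pat.min_length == 1
        assert pat.elements == (Element("wildcard"),)

    def test_letter_runs_parse_as_consecutive_fixed_positions(self):
        pat = parse_pattern("IN-x-[VI]-LK-[GPE]-YL")
        expected = [
            Element("fixed", ("I",)), Element("fixed", ("N",)), Element("wildcard"),
            Element("set", ("V", "I")), Element("fixed", ("L",)), Element("fixed", ("K",)),
            Element("set", ("G", "P", "E")), Element("fixed", ("Y",)), Element("fixed", ("L",)),
        ]
        assert list(pat.elements) == expected

    def test_round_trip_is_identity(self):
        for text in [
            "K-x(3)-[RH]-x-[IV]-W-N-S-Y-[IV]-x-W",
            "x",
            "W-[AG]-x(4)-C",
            "{P}-A-x",
        ]:
            pat = parse_pattern(text)
            assert parse_pattern(pat.text) == PrositePattern(pat.elements)

    @pytest.mark.parametrize(
        "bad", ["[AB", "A-[]-C", "x(0)", "A--B", "", "A-?-C"]
    )
    def test_malformed_patterns_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_pattern(bad)


class TestMatching:
    def test_ramr2_matches_published_sequence_at_2(self):
        pat = parse_pattern("K-x(3)-[RH]-x-[IV]-W-N-S-Y-[IV]-x-W")
        assert match_pattern(pat, "AKMMTRFIWNSYISW") == [2]

    def test_dest3_matches_published_sequence_at_1(self):
        pat = parse_pattern("[LAG]-[KR]-H-W-[QRH]-G-L-[GSP]")
        assert match_pattern(pat, "GKHWHGLP") == [1]

    def test_pure_wildcards_match_everything(self):
        assert match_pattern(parse_pattern("x(3)"), "AAA") == [1]
        assert match_pattern(parse_pattern("x(3)"), "AAAA") == [1, 2]

    def test_x_in_sequence_matches_only_wildcards(self):
        assert match_pattern(parse_pattern("A-x-C"), "AXC") == [1]
        assert match_pattern(parse_pattern("A-C"), "AX") == []
        assert match_pattern(parse_pattern("W"), "X") == []

    def test_every_published_pattern_hits_its_matched_sequence_once(
        self, curated_table
    ):
        """Each proposed pattern matches the motif occurrence it was derived
        from at exactly one position (the flagged tFadR-2 row within its first
        14 residues)."""
        patterns = tm.load_prosite_patterns()
        by_motif = curated_table.set_index("motif_id")
        for _, row in patterns.iterrows():
            pat = parse_pattern(row["pattern"])
            target = by_motif.loc[row["motif_id"], "matched"]
            starts = match_pattern(pat, target)
            assert len(starts) == 1, row["motif_id"]
            if row["motif_id"] == "tFadR-2":
                assert starts[0] + pat.min_length - 1 <= 14

    def test_matcher_agrees_with_regex_oracle_on_random_patterns(self):
        """Sliding-set matcher vs an independent regex-with-lookahead oracle."""
        rng = np.random.default_rng(12)
        letters = list(AMINO_ACIDS)
        for trial in range(150):
            elements = []
            regex_parts = []
            n_el = rng.integers(1, 7)
            for _ in range(n_el):
                kind = rng.choice(["fixed", "set", "wildcard"])
                if kind == "fixed":
                    a = str(rng.choice(letters))
                    elements.append(Element("fixed", (a,)))
                    regex_parts.append(a)
                elif kind == "set":
                    members = tuple(
                        dict.fromkeys(rng.choice(letters, size=rng.integers(2, 5)))
                    )
                    elements.append(Element("set", members))
                    regex_parts.append("[" + "".join(members) + "]")
                else:
                    n = int(rng.integers(1, 4))
                    elements.append(Element("wildcard", count=n))
                    regex_parts.append("[" + "".join(letters) + "X]{" + str(n) + "}")
            pat = PrositePattern(tuple(elements))
            if pat.min_length > 12:
                continue
            seq = "".join(rng.choice(letters + ["X"], size=rng.integers(5, 30)))
            oracle = [
                m.start() + 1
                for m in re.finditer("(?=(" + "".join(regex_parts) + "))", seq)
            ]
            assert match_pattern(pat, seq) == oracle, pat.text


class TestDerivation:
    def _profiles(self, freq_dicts):
        from tfrmotifs.alphabet import AA_INDEX
        from tfrmotifs.conservation import MAX_IC, ColumnProfile

        out = []
        for pos, d in enumerate(freq_dicts, start=1):
            freqs = np.zeros(20)
            for k, v in d.items():
                freqs[AA_INDEX[k]] = v
            out.append(ColumnProfile(pos, freqs, 0.0, MAX_IC, freqs, 9))
        return out

    def test_fixed_set_wildcard_rules(self):
        uniform = {a: 0.05 for a in AMINO_ACIDS}
        pat = derive_pattern(
            self._profiles([{"W": 1.0}, {"A": 0.6, "G": 0.4}, uniform])
        )
        assert pat.text == "W-[AG]-x"

    def test_all_uniform_columns_merge_into_one_wildcard(self):
        uniform = {a: 0.05 for a in AMINO_ACIDS}
        pat = derive_pattern(self._profiles([uniform] * 4))
        assert pat.text == "x(4)"

    def test_empty_profile_list_rejected(self):
        with pytest.raises(ValueError):
            derive_pattern([])

    def test_derive_match_closure_on_sampled_stack(self):
        """With t_set = 1 and max_set = 20 the derived pattern accepts every
        row it was derived from."""
        rng = np.random.default_rng(13)
        rows = ["".join(rng.choice(list("ACDEFGH"), size=8)) for _ in range(25)]
        stack = OccurrenceStack("m", "ref", 1, rows)
        profiles = column_profile(stack)
        pat = derive_pattern(profiles, t_fixed=1.0, t_set=1.0, max_set=20)
        for row in rows:
            assert 1 in match_pattern(pat, row)

    def test_ramr2_stack_recovers_pattern_matching_published_occurrence(self):
        """A pattern derived from occurrences of the RamR-2 motif matrix accepts
        the occurrence reported in RamR itself."""
        mats = {m.motif_id: m for m in tm.curated_motif_matrices()}
        rng = np.random.default_rng(3)
        motif = mats["RamR-2"]
        letters = np.array(list(AMINO_ACIDS))
        rows = [
            "".join(letters[rng.choice(20, p=motif.probs[i])] for i in range(motif.width))
            for _ in range(500)
        ]
        profiles = column_profile(
            OccurrenceStack("RamR-2", "Sen_RamR", 81, rows), pseudocount=0.5
        )
        pat = derive_pattern(profiles, source_motif_id="RamR-2")
        assert match_pattern(pat, "AKMMTRFIWNSYISW")


class TestExpectedRandomMatches:
    def test_wildcard_alone_expects_every_position(self):
        assert expected_random_matches(parse_pattern("x")) == 50_000_000

    def test_two_letter_toy_composition(self):
        freqs = np.full(20, 1e-9)
        freqs[0] = 0.5  # A
        freqs[1] = 0.5  # C
        table = ResidueFrequencyTable(freqs, "toy")
        erm = expected_random_matches(parse_pattern("[AC]-A"), table, n_residues=1000)
        assert erm == pytest.approx(500.0, rel=1e-6)

    def test_published_dest3_value_within_factor_two(self):
        pat = parse_pattern("[LAG]-[KR]-H-W-[QRH]-G-L-[GSP]")
        erm = expected_random_matches(pat)
        assert 4.77e-2 / 2 <= erm <= 4.77e-2 * 2

    def test_published_eilr2_value_within_factor_two(self):
        pat = parse_pattern("[DE]-x(3)-[ED]-P-[YH]-[IV]-x-L-W-R-[EQ]-[AG]-[QL]")
        erm = expected_random_matches(pat)
        assert 2.51e-5 / 2 <= erm <= 2.51e-5 * 2

    def test_erm_monotone_under_tightening(self):
        freqs = ResidueFrequencyTable.swissprot()
        base = parse_pattern("A-x-C")
        tightened = parse_pattern("A-[ILV]-C")
        subset = parse_pattern("A-[IL]-C")
        fixed = parse_pattern("A-I-C")
        values = [
            window_probability(p, freqs) for p in (base, tightened, subset, fixed)
        ]
        assert values == sorted(values, reverse=True)


class TestSignatureReport:
    def _pat(self):
        return parse_pattern("A-C-D")

    def test_low_erm_is_yes(self):
        rep = signature_report(self._pat(), 1e-5)
        assert rep.recommendation == "YES"
        assert "threshold" in rep.rationale

    def test_high_erm_with_off_target_hits_is_no(self):
        rep = signature_report(
            self._pat(), 1.1, hit_ids=["other"], homolog_ids={"src"}
        )
        assert rep.recommendation == "NO"
        assert "off-target" in rep.rationale

    def test_moderate_erm_with_only_homolog_hits_is_yes(self):
        rep = signature_report(
            self._pat(), 8.28e-2, hit_ids=["src"], homolog_ids={"src"}
        )
        assert rep.recommendation == "YES"
        assert "homolog" in rep.rationale
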