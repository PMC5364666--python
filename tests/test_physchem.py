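import random

import pytest
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from hypothesis import given, settings, strategies as st

from orthobridge import (MotifPattern, SequenceRecord, charged_fraction,
                         find_pest_regions, isoelectric_point,
                         molecular_mass, motif_conservation, motif_scan,
                         net_charge, pest_score)

from .oracles import grid_pi, regex_motif_anchors

AA20 = "ACDEFGHIKLMNPQRSTVWY"
seqs = st.text(alphabet=AA20, min_size=1, max_size=120)


def rec(seq):
    return SequenceRecord(id="p", species="s", residues=seq)


class TestChargedFraction:
    def test_trivial_extremes(self):
        assert charged_fraction(rec("DEKR")) == 100.0
        assert charged_fraction(rec("AAAA")) == 0.0

    def test_x_excluded_from_denominator(self):
        assert charged_fraction(rec("DXAX")) == 50.0

    def test_histidine_in_default_set(self):
        assert charged_fraction(rec("HAAA")) == 25.0
        assert charged_fraction(rec("HAAA"), charged_set=set("DEKR")) == 0.0

    @settings(max_examples=50, deadline=None)
    @given(seqs)
    def test_permutation_invariant(self, s):
        shuffled = "".join(sorted(s))
        assert charged_fraction(rec(s)) == pytest.approx(
            charged_fraction(rec(shuffled)))


class TestIsoelectricPoint:
    def test_glycylglycine_is_terminal_midpoint(self):
        # only termini ionize: pI = (pKa_N + pKa_C)/2 under the table
        assert isoelectric_point(rec("GG")) == pytest.approx(
            (7.5 + 3.55) / 2, abs=1e-3)

    def test_net_charge_zero_at_reported_pi(self):
        rng = random.Random(19)
        for _ in range(25):
            s = "".join(rng.choice(AA20) for _ in range(rng.randint(5, 80)))
            ph = isoelectric_point(rec(s))
            assert abs(net_charge(s, ph)) < 1e-3

    def test_matches_fine_grid_root_oracle(self):
        rng = random.Random(29)
        for _ in range(10):
            s = "".join(rng.choice(AA20) for _ in range(40))
            assert isoelectric_point(rec(s)) == pytest.approx(
                grid_pi(net_charge, s, "bjellqvist"), abs=2e-3)

    def test_agrees_with_biopython_bjellqvist(self):
        """Independent oracle: Bio.SeqUtils.IsoelectricPoint implements the
        same Bjellqvist model."""
        from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint
        rng = random.Random(37)
        compared = 0
        for _ in range(15):
            s = "".join(rng.choice(AA20) for _ in range(rng.randint(10, 120)))
            ours = isoelectric_point(rec(s))
            if not 4.1 < ours < 11.9:
                continue  # biopython's bisection is clamped to [4.05, 12]
            theirs = IsoelectricPoint(s).pi()
            assert ours == pytest.approx(theirs, abs=0.02)
            compared += 1
        assert compared >= 10

    def test_acidic_vs_basic_ordering(self):
        assert isoelectric_point(rec("DDDDDDGG")) < 4.5
        assert isoelectric_point(rec("KKKKKKGG")) > 9.0

    def test_alternative_tables_selectable(self):
        s = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        vals = {t: isoelectric_point(rec(s), pka_table=t)
                for t in ("bjellqvist", "emboss", "lehninger")}
        assert len({round(v, 2) for v in vals.values()}) > 1  # tables differ


class TestMolecularMass:
    def test_single_glycine(self):
        # free glycine: residue 57.0519 + water 18.0153 = 75.07 Da
        assert molecular_mass(rec("G")) == pytest.approx(0.0751, abs=1e-4)

    @settings(max_examples=30, deadline=None)
    @given(seqs, seqs)
    def test_additive_up_to_one_water(self, a, b):
        got = molecular_mass(rec(a + b))
        want = molecular_mass(rec(a)) + molecular_mass(rec(b)) - 0.0180153
        assert got == pytest.approx(want, abs=1e-9)

    def test_agrees_with_biopython_average_mass(self):
        from Bio.SeqUtils import molecular_weight
        s = "MTEYKLVVVGAGGVGKSALTIQLIQNHFVDEYDPTIE"
        assert molecular_mass(rec(s)) * 1000 == pytest.approx(
            molecular_weight(s, seq_type="protein", monoisotopic=False),
            abs=0.5)


class TestPestRegions:
    def test_stretch_without_required_residues_ignored(self):
        assert find_pest_regions(rec("K" + "A" * 14 + "K")) == []

    def test_crafted_region_matches_hand_computed_score(self):
        """Spreadsheet-style recomputation of the stated formula with
        independent table literals."""
        inner = "PEDSTPEDSTPEDSTPED"
        regions = find_pest_regions(rec("K" + inner + "K"))
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end) == (2, 19)
        assert r.flanks == ("K", "K")
        mass = {"P": 97.1167, "E": 129.1155, "D": 115.0886,
                "S": 87.0782, "T": 101.1051}
        hv = {"P": 10 * -1.6 + 45, "E": 10 * -3.5 + 45, "D": 10 * -3.5 + 45,
              "S": 10 * -0.8 + 45, "T": 10 * -0.7 + 45}
        total = sum(mass[c] for c in inner)
        depst_pct = 100.0  # every residue is D/E/P/S/T
        hyd = sum(mass[c] * hv[c] for c in inner) / total
        assert r.score == pytest.approx(0.55 * depst_pct - 0.5 * hyd, abs=0.01)

    def test_short_stretch_below_minimum_length(self):
        # 11 inner residues < 12 → no region
        assert find_pest_regions(rec("K" + "PEDSTPEDSTP" + "K")) == []

    def test_termini_act_as_boundaries(self):
        regions = find_pest_regions(rec("PEDSTPEDSTPEDST"))
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (1, 15)
        assert regions[0].flanks == ("^", "$")

    def test_reported_regions_satisfy_invariants(self):
        rng = random.Random(43)
        for _ in range(40):
            s = "".join(rng.choice(AA20) for _ in range(rng.randint(20, 300)))
            for r in find_pest_regions(rec(s)):
                inner = s[r.start - 1:r.end]
                assert len(inner) >= 12
                assert not set(inner) & set("KRH")
                assert set(inner) & {"P"} and set(inner) & set("DE") \
                       and set(inner) & set("ST")
                assert -45.0 <= r.score <= 50.0

    def test_score_bounds_attained_in_limits(self):
        assert pest_score("D" * 20) == pytest.approx(50.0)
        assert pest_score("I" * 20) == pytest.approx(-45.0)


class TestMotifScan:
    PAT = MotifPattern.from_string("RxxxRxx[RK]")

    def test_prp38_binding_style_motif_positions(self):
        """A motif anchored at 282 constrains residues 282, 286 and 289."""
        rng = random.Random(47)
        backbone = "".join(rng.choice("ACDEFGHILMNPQSTVWY")  # no R/K
                           for _ in range(300))
        s = list(backbone)
        s[281], s[285], s[288] = "R", "R", "R"  # 0-based
        anchors = motif_scan(rec("".join(s)), self.PAT)
        assert 282 in anchors
        offsets = self.PAT.constrained_offsets()
        assert [282 + o for o in offsets] == [282, 286, 289]

    def test_arginine_free_sequence_empty(self):
        assert motif_scan(rec("ACDEFGHILMNPQSTVWY" * 3), self.PAT) == []

    def test_terminal_lysine_variant_matches(self):
        # anchor 4 needs R at positions 4 and 8 and R/K at 11
        s = "AAA" + "R" + "AAA" + "R" + "AA" + "K" + "AAAA"
        anchors = motif_scan(rec(s), self.PAT)
        assert 4 in anchors

    @settings(max_examples=60, deadline=None)
    @given(st.text(alphabet="ARKG", min_size=8, max_size=60))
    def test_matches_equal_regex_oracle(self, s):
        got = motif_scan(rec(s), self.PAT)
        want = regex_motif_anchors(s, "RxxxRxx[RK]")
        assert got == want
        assert len(got) <= len(s) - self.PAT.length + 1


def build_msa(rows):
    return MultipleSeqAlignment(
        [SeqRecord(Seq(s), id=name) for name, s in rows])


class TestMotifConservation:
    def test_identical_alignment_fully_conserved(self):
        msa = build_msa([("a", "MKRDE"), ("b", "MKRDE"), ("c", "MKRDE")])
        cons = motif_conservation(msa, "a", [1, 3, 5])
        assert cons == {1: 100.0, 3: 100.0, 5: 100.0}

    def test_single_substitution_gives_75_percent(self):
        msa = build_msa([("a", "MKRD"), ("b", "MKRD"),
                         ("c", "MKRD"), ("d", "MQRD")])
        assert motif_conservation(msa, "a", [2])[2] == 75.0

    def test_gap_columns_excluded_from_denominator(self):
        msa = build_msa([("a", "MKR"), ("b", "M-R"), ("c", "MKR")])
        assert motif_conservation(msa, "a", [2])[2] == 100.0

    def test_reference_coordinates_skip_reference_gaps(self):
        msa = build_msa([("a", "M-KR"), ("b", "MQKR")])
        # reference ungapped position 2 is the K in column 3
        assert motif_conservation(msa, "a", [2])[2] == 100.0

    def test_allowed_class_widens_match(self):
        msa = build_msa([("a", "R"), ("b", "K"), ("c", "R"), ("d", "A")])
        assert motif_conservation(msa, "a", [1])[1] == 50.0
        assert motif_conservation(msa, "a", [1], [set("RK")])[1] == 75.0

    def test_hand_tally_on_ten_by_twenty_fixture(self):
        """Column percentages equal an independent per-column tally."""
        rng = random.Random(53)
        ref = "".join(rng.choice(AA20) for _ in range(20))
        rows = [("ref", ref)]
        for i in range(9):
            s = list(ref)
            for pos in rng.sample(range(20), rng.randint(0, 8)):
                s[pos] = rng.choice(AA20)
            rows.append((f"s{i}", "".join(s)))
        msa = build_msa(rows)
        positions = list(range(1, 21))
        cons = motif_conservation(msa, "ref", positions)
        for p in positions:
            col = [s[p - 1] for _, s in rows]
            expected = sum(1 for c in col if c == ref[p - 1]) / len(col) * 100
            assert cons[p] == pytest.approx(expected, abs=0.05)

    def test_position_out_of_range_errors(self):
        msa = build_msa([("a", "MK"), ("b", "MK")])
        with pytest.raises(ValueError):
            motif_conservation(msa, "a", [5])
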