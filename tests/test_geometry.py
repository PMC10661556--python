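"""Protospacer scanning and paired-nick geometry against brute-force oracles."""

import numpy as np
import pytest

from nickpair import (
    GeometryError,
    InputError,
    ProtospacerSite,
    enumerate_pairs,
    find_protospacers,
    nick_position,
    overlap_series,
    pair_geometry,
    released_ssdna_length,
)
from nickpair.geometry import TARGET_LEN

from _oracles import (
    brute_force_protospacers,
    enumerate_nick,
    strand_separation_polarity,
)
from conftest import random_seq


class TestFindProtospacers:
    def test_single_forced_plus_strand_match(self):
        seq = "A" * 20 + "AGG"
        sites = find_protospacers(seq)
        assert len(sites) == 1
        (s,) = sites
        assert (s.start, s.strand, s.pam_seq) == (0, "+", "AGG")
        assert s.spacer_seq == "A" * 20

    def test_no_pam_means_no_sites(self):
        assert find_protospacers("A" * 100) == []

    def test_rejects_empty_and_non_nucleotide_input(self):
        with pytest.raises(InputError):
            find_protospacers("")
        with pytest.raises(InputError):
            find_protospacers("ACGTQ" * 10)

    def test_short_reference_yields_nothing(self):
        assert find_protospacers("ACGGAGG") == []

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_exhaustive_scan_on_random_sequences(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_seq(rng, 200)
        got = [(s.start, s.strand, s.spacer_seq, s.pam_seq)
               for s in find_protospacers(seq)]
        assert got == brute_force_protospacers(seq)

    def test_sites_satisfy_invariants_against_reference(self, rng):
        seq = random_seq(rng, 300)
        for site in find_protospacers(seq):
            site.validate_against(seq)  # raises on any violation


class TestNickPosition:
    @pytest.mark.parametrize("start,strand,variant,exp_strand,exp_junction", [
        (5, "+", "D10A", "-", 22),
        (5, "+", "H840A", "+", 22),
        (30, "-", "D10A", "+", 36),
        (30, "-", "H840A", "-", 36),
    ])
    def test_worked_coordinate_examples(self, start, strand, variant,
                                        exp_strand, exp_junction):
        site = ProtospacerSite.abstract("r", start, strand)
        nick = nick_position(site, variant)
        assert (nick.strand_nicked, nick.junction) == (exp_strand, exp_junction)

    @pytest.mark.parametrize("variant", ["D10A", "H840A"])
    def test_matches_per_base_enumeration_oracle(self, rng, variant):
        for _ in range(60):
            start = int(rng.integers(0, 400))
            strand = "+" if rng.random() < 0.5 else "-"
            site = ProtospacerSite.abstract("r", start, strand)
            nick = nick_position(site, variant)
            assert (nick.strand_nicked, nick.junction) == \
                enumerate_nick(start, strand, variant)

    def test_released_ssdna_is_17_for_h840a_and_0_for_d10a(self):
        site = ProtospacerSite.abstract("r", 10, "+")
        assert released_ssdna_length(site, "H840A") == 17
        assert released_ssdna_length(site, "D10A") == 0


def _abstract_pair(plus_start, minus_start, variant):
    p = ProtospacerSite.abstract("r", plus_start, "+")
    m = ProtospacerSite.abstract("r", minus_start, "-")
    return pair_geometry(p, m, variant)


class TestPairGeometry:
    def test_d10a_blunt_at_12bp_overlap(self):
        geoms = {g.overlap_length: g for g in overlap_series("D10A", "pam_in")}
        assert geoms[12].overhang_polarity == "blunt"
        assert geoms[12].overhang_length == 0

    def test_d10a_overlap_1_gives_11nt_three_prime(self):
        geoms = {g.overlap_length: g for g in overlap_series("D10A", "pam_in")}
        assert geoms[1].overhang_polarity == "three_prime"
        assert geoms[1].overhang_length == 11

    def test_h840a_pam_out_overlap_1_gives_33nt_three_prime(self):
        geoms = {g.overlap_length: g for g in overlap_series("H840A", "pam_out")}
        assert geoms[1].overhang_polarity == "three_prime"
        assert geoms[1].overhang_length == 33

    def test_d10a_pam_in_closed_form(self):
        """3' overhang = 12 - overlap across the whole PAM-in sliding series."""
        for g in overlap_series("D10A", "pam_in"):
            if 1 <= g.overlap_length <= 12:
                assert g.overhang_length == 12 - g.overlap_length
                assert g.overhang_polarity == (
                    "blunt" if g.overlap_length == 12 else "three_prime")

    def test_h840a_closed_forms_both_branches(self):
        for g in overlap_series("H840A", "pam_out"):
            assert g.overhang_length == 34 - g.overlap_length \
                or g.overlap_length == TARGET_LEN
            if g.overlap_length < TARGET_LEN:
                assert g.overhang_polarity == "three_prime"
        for g in overlap_series("H840A", "pam_in"):
            if g.overlap_length >= 12:
                assert g.overhang_length == g.overlap_length - 12

    def test_maximum_overlap_is_23_at_full_coincidence(self):
        series = overlap_series("H840A", "pam_out")
        best = max(series, key=lambda g: g.overlap_length)
        assert best.overlap_length == TARGET_LEN
        assert best.site_a.start == best.site_b.start

    def test_variant_swap_preserves_length_and_flips_polarity(self, rng):
        flip = {"five_prime": "three_prime", "three_prime": "five_prime",
                "blunt": "blunt"}
        for _ in range(80):
            ps, ms = int(rng.integers(0, 150)), int(rng.integers(0, 150))
            d = _abstract_pair(ps, ms, "D10A")
            h = _abstract_pair(ps, ms, "H840A")
            assert h.overhang_length == d.overhang_length
            assert h.overhang_polarity == flip[d.overhang_polarity]

    def test_polarity_matches_strand_separation_oracle(self, rng):
        for _ in range(50):
            ps, ms = int(rng.integers(0, 200)), int(rng.integers(0, 200))
            for variant in ("D10A", "H840A"):
                g = _abstract_pair(ps, ms, variant)
                plus_j = g.nick_a.junction if g.nick_a.strand_nicked == "+" \
                    else g.nick_b.junction
                minus_j = g.nick_b.junction if g.nick_a.strand_nicked == "+" \
                    else g.nick_a.junction
                polarity, length = strand_separation_polarity(
                    plus_j, minus_j, 400)
                assert (g.overhang_polarity, g.overhang_length) == \
                    (polarity, length)

    def test_same_strand_pairs_have_no_overhang(self):
        a = ProtospacerSite.abstract("r", 0, "+")
        b = ProtospacerSite.abstract("r", 60, "+")
        g = pair_geometry(a, b, "D10A")
        assert g.overhang_polarity == "same_strand"
        assert g.overhang_length == 0

    def test_cross_reference_pairs_rejected(self):
        a = ProtospacerSite.abstract("r1", 0, "+")
        b = ProtospacerSite.abstract("r2", 60, "-")
        with pytest.raises(InputError):
            pair_geometry(a, b, "D10A")


class TestEnumeratePairs:
    def test_single_site_yields_nothing(self):
        sites = [ProtospacerSite.abstract("r", 10, "+")]
        assert enumerate_pairs(sites, "D10A") == []

    def test_same_strand_sites_excluded(self):
        sites = [ProtospacerSite.abstract("r", 10, "+"),
                 ProtospacerSite.abstract("r", 80, "+")]
        assert enumerate_pairs(sites, "D10A") == []

    def test_matches_exhaustive_double_loop(self, rng):
        import itertools
        starts = sorted(int(x) for x in rng.choice(250, size=6, replace=False))
        strands = ["+", "-", "+", "-", "-", "+"]
        sites = [ProtospacerSite.abstract("r", s, st)
                 for s, st in zip(starts, strands)]
        max_d = 100
        got = enumerate_pairs(sites, "H840A", max_d)
        expected = []
        for s1, s2 in itertools.combinations(sites, 2):
            g = pair_geometry(s1, s2, "H840A")
            if g.overhang_polarity != "same_strand" \
                    and g.inter_nick_distance <= max_d:
                expected.append((min(g.nick_a.junction, g.nick_b.junction),
                                 g.inter_nick_distance))
        assert sorted((min(g.nick_a.junction, g.nick_b.junction),
                       g.inter_nick_distance) for g in got) == sorted(expected)
        # normalisation: nick_a is always the left junction
        for g in got:
            assert g.nick_a.junction <= g.nick_b.junction

    def test_pairs_and_sites_agree_with_oracles_on_random_references(self):
        """Randomised 500-bp references: scan and pairing match brute force."""
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            seq = random_seq(rng, 500)
            sites = find_protospacers(seq)
            assert [(s.start, s.strand) for s in sites] == \
                [(h[0], h[1]) for h in brute_force_protospacers(seq)]
            pairs = enumerate_pairs(sites, "D10A", 60)
            for g in pairs:
                assert g.overhang_polarity != "same_strand"
                assert g.inter_nick_distance <= 60
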