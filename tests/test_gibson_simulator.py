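"""One-pot assembly simulator tests: homology search, cycle finding,
ambiguity detection, order invariance."""

import random

import pytest

from unskit.gibson_simulator import (
    GibsonParams,
    canonical_circular,
    simulate_one_pot,
    terminal_homology,
    verify_junctions,
)
from unskit.seqcore import DnaSequence, Fragment, FragmentEnd, reverse_complement

from oracles import assemble_brute, canon_circ, terminal_match_brute


def frag(name: str, seq: str) -> Fragment:
    end = FragmentEnd(None, "", "native")
    return Fragment(DnaSequence(seq, "linear", name), end, end, (name, 0, len(seq)))


def rand_dna(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestTerminalHomology:
    def test_uns_shared_fixture_ends(self, lib5, plan5):
        a = plan5.roster[3].fragment  # ends with UNS5 (+ 9 nt remnant)
        b = plan5.roster[4].fragment  # starts with remnant + UNS5
        jn = terminal_homology(a, b)
        assert jn is not None
        assert jn.overlap_length >= 40
        assert lib5.uns_set["UNS5"] in jn.overlap_sequence

    def test_unrelated_ends_none(self):
        rng = random.Random(0)
        a = frag("a", rand_dna(rng, 150))
        b = frag("b", rand_dna(rng, 150))
        assert terminal_homology(a, b) is None

    def test_revcomp_orientation_found(self):
        rng = random.Random(1)
        word = rand_dna(rng, 30)
        a = frag("a", rand_dna(rng, 100) + word)
        # b's reverse complement begins with the shared word
        b = frag("b", reverse_complement(word + rand_dna(rng, 100)))
        jn = terminal_homology(a, b)
        assert jn is not None and jn.right_orientation == "-"
        assert jn.overlap_length == 30

    def test_flap_tolerance_enforced(self):
        rng = random.Random(2)
        word = rand_dna(rng, 25)
        tail = rand_dna(rng, 20)  # 20 nt of junk beyond the overlap
        a = frag("a", rand_dna(rng, 80) + word + tail)
        b = frag("b", word + rand_dna(rng, 80))
        assert terminal_homology(a, b, GibsonParams(flap_tolerance=15)) is None
        jn = terminal_homology(a, b, GibsonParams(flap_tolerance=20))
        assert jn is not None and jn.flap_left == 20

    def test_agrees_with_bruteforce_window_match(self):
        rng = random.Random(3)
        params = GibsonParams(min_overlap=12, chew_window=40, flap_tolerance=8)
        for _ in range(150):
            word = rand_dna(rng, rng.randint(8, 30))
            a = rand_dna(rng, rng.randint(40, 90)) + word + rand_dna(rng, rng.randint(0, 10))
            b = rand_dna(rng, rng.randint(0, 10)) + word + rand_dna(rng, rng.randint(40, 90))
            got = terminal_homology(frag("a", a), frag("b", b), params, try_revcomp=False)
            want = terminal_match_brute(
                a, b, params.chew_window, params.flap_tolerance, params.min_overlap
            )
            assert (got.overlap_length if got else None) == want


def ring_fragments(rng, n, word_len=40, body=(60, 200)):
    """n fragments sharing consecutive junction words around a ring."""
    words = [rand_dna(rng, word_len) for _ in range(n)]
    frags = []
    for i in range(n):
        mid = rand_dna(rng, rng.randint(*body))
        frags.append(frag(f"f{i}", words[i] + mid + words[(i + 1) % n]))
    return frags, words


class TestSimulateOnePot:
    def test_five_tu_fixture_unique_circular(self, lib5, plan5):
        products = simulate_one_pot(plan5.fragments)
        assert len(products) == 1
        p = products[0]
        assert p.status == "unique_circular"
        assert len(p.composition) == 7
        assert len(p.junctions) == 7

    def test_input_order_invariance(self, plan5):
        base = simulate_one_pot(plan5.fragments)[0]
        rng = random.Random(9)
        for _ in range(3):
            shuffled = list(plan5.fragments)
            rng.shuffle(shuffled)
            p = simulate_one_pot(shuffled)[0]
            assert p.sequence.residues == base.sequence.residues
            assert p.status == base.status

    def test_length_conservation_at_junctions(self, plan5):
        p = simulate_one_pot(plan5.fragments)[0]
        oriented_total = sum(len(f) for f in plan5.fragments)
        spliced = oriented_total - sum(
            j.overlap_length + j.flap_left + j.flap_right for j in p.junctions
        )
        assert len(p.sequence) == spliced

    def test_duplicate_address_pair_is_ambiguous(self):
        rng = random.Random(11)
        frags, words = ring_fragments(rng, 4)
        clone = frag("f1b", words[1] + rand_dna(rng, 120) + words[2])
        products = simulate_one_pot(frags + [clone])
        assert products[0].status == "ambiguous"
        # both closures (with f1 or with its address clone) are reported
        assert len(products) >= 2

    def test_repeated_internal_sequence_is_harmless(self):
        rng = random.Random(13)
        frags, _ = ring_fragments(rng, 5, body=(150, 150))
        # plant one identical internal block in every fragment
        block = rand_dna(rng, 120)
        frags = [
            frag(f.sequence.name, f.sequence.residues[:60] + block + f.sequence.residues[60:])
            for f in frags
        ]
        p = simulate_one_pot(frags)[0]
        assert p.status == "unique_circular"

    def test_no_closure_reports_incomplete_path(self):
        rng = random.Random(17)
        frags, _ = ring_fragments(rng, 4)
        products = simulate_one_pot(frags[:-1])  # break the ring
        assert products[0].status == "incomplete"
        assert products[0].sequence.topology == "linear"

    @pytest.mark.parametrize("n", [3, 4, 5, 6])
    def test_matches_exhaustive_enumeration(self, n):
        rng = random.Random(100 + n)
        frags, _ = ring_fragments(rng, n, word_len=30, body=(50, 120))
        if n >= 5:  # spice with an address collision for a second cycle
            w = frags[0].sequence.residues[:30]
            frags.append(
                frag("dup", w + rand_dna(rng, 80) + frags[1].sequence.residues[:30])
            )
        params = GibsonParams()
        products = simulate_one_pot(frags, params)
        got = {
            p.sequence.residues for p in products if p.sequence.is_circular
        }
        want = assemble_brute(
            {f.sequence.name: f.sequence.residues for f in frags},
            params.chew_window,
            params.flap_tolerance,
            params.min_overlap,
        )
        assert got == want


class TestCanonicalization:
    def test_least_rotation_matches_naive(self):
        rng = random.Random(23)
        for _ in range(50):
            s = rand_dna(rng, rng.randint(5, 60))
            assert canonical_circular(s) == canon_circ(s)

    def test_rotation_and_strand_invariance(self):
        rng = random.Random(29)
        s = rand_dna(rng, 200)
        for k in (0, 13, 77):
            assert canonical_circular(s[k:] + s[:k]) == canonical_circular(s)
        assert canonical_circular(reverse_complement(s)) == canonical_circular(s)


class TestVerifyJunctions:
    def test_fixture_product_passes(self, lib5, plan5):
        p = simulate_one_pot(plan5.fragments)[0]
        rep = verify_junctions(p, lib5.uns_set)
        assert rep.passed

    def test_junction_census_is_n_plus_2(self, plan5):
        p = simulate_one_pot(plan5.fragments)[0]
        assert len(p.junctions) == plan5.n_entries + 2

    def test_missing_adaptor_fails_x_junction(self, lib5, plan5):
        frags = [f for f in plan5.fragments if "adaptor" not in f.sequence.name]
        products = simulate_one_pot(frags)
        rep = verify_junctions(products[0], lib5.uns_set)
        assert not rep.passed
        assert any(c.detail == "X junction absent" for c in rep.failures())
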