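"""Restriction-map, panel-selection and screening-statistics tests."""

import random

import numpy as np
import pytest

from unskit.diagnostics import (
    GelModel,
    colonies_for_risk,
    maps_distinguishable,
    misassembly_alternatives,
    panel_score,
    restriction_map,
    screening_stats,
    select_diagnostic_panel,
)
from unskit.seqcore import DnaSequence, get_enzyme

from oracles import scan_sites


def rand_dna(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestRestrictionMap:
    def test_single_cutter_on_circle_one_full_length_band(self):
        rng = random.Random(1)
        s = rand_dna(rng, 3000).replace("GAATTC", "GAATTG") + "GAATTC"
        seq = DnaSequence(s, "circular")
        m = restriction_map(seq, ["EcoRI"])
        assert m.sizes == [len(seq)]

    def test_sizes_sum_to_length(self, plan5):
        construct = plan5.predicted_sequence
        for panel in (["EcoRI"], ["EcoRI", "HindIII"], ["XbaI", "XhoI", "NdeI"]):
            m = restriction_map(construct, panel)
            assert sum(m.sizes) == len(construct)
            assert m.sizes == sorted(m.sizes, reverse=True)

    def test_matches_bruteforce_site_scan(self):
        rng = random.Random(5)
        enz = get_enzyme("HindIII")
        for _ in range(30):
            s = rand_dna(rng, rng.randint(500, 2000))
            seq = DnaSequence(s, "circular")
            hits = scan_sites(s, enz.site, circular=True)
            m = restriction_map(seq, [enz])
            if not hits:
                assert m.sizes == [len(s)]
            else:
                cuts = sorted((p + enz.cut_top) % len(s) for p, _ in hits)
                expected = sorted(
                    ((b - a) % len(s) or len(s)
                     for a, b in zip(cuts, cuts[1:] + cuts[:1])),
                    reverse=True,
                )
                assert m.sizes == expected

    def test_empty_panel_rejected(self, plan5):
        with pytest.raises(ValueError, match="empty"):
            restriction_map(plan5.predicted_sequence, [])

    def test_comigration_grouping(self):
        gel = GelModel(resolution_fraction=0.08)
        # two sites ~half way round: bands 1500/1520 co-migrate
        rng = random.Random(7)
        body = rand_dna(rng, 3020).replace("GAATTC", "GAATTG")
        s = "GAATTC" + body[:1494] + "GAATTC" + body[1494:3008]
        m = restriction_map(DnaSequence(s, "circular"), ["EcoRI"], gel)
        assert len(m.comigrating_groups) == 1
        assert not any(b.distinguishable for b in m.bands)


class TestPanelScore:
    def test_identical_alternative_scores_zero(self, plan5):
        gel = GelModel()
        mc = restriction_map(plan5.predicted_sequence, ["EcoRI"], gel)
        assert panel_score(mc, [mc], gel)[0] == 0.0

    def test_missing_two_kb_block_distinguishable(self):
        rng = random.Random(9)
        body = rand_dna(rng, 8000).replace("GAATTC", "GAATTG")
        correct = DnaSequence("GAATTC" + body, "circular", "correct")
        dropout = DnaSequence("GAATTC" + body[:-2000], "circular", "dropout")
        gel = GelModel()
        mc = restriction_map(correct, ["EcoRI"], gel)
        ma = restriction_map(dropout, ["EcoRI"], gel)
        assert maps_distinguishable(mc, ma, gel)
        assert panel_score(mc, [ma], gel)[0] == 1.0

    def test_adding_distinguishable_alternative_never_lowers_score(self, plan5):
        gel = GelModel()
        mc = restriction_map(plan5.predicted_sequence, ["EcoRI"], gel)
        rng = random.Random(10)
        alt = restriction_map(
            DnaSequence(rand_dna(rng, 4000), "circular", "alt"), ["EcoRI"], gel
        )
        base = panel_score(mc, [mc], gel)[0]
        grown = panel_score(mc, [mc, alt], gel)[0]
        assert grown >= base


class TestSelectPanel:
    def test_discriminates_carrier_selfclosure(self, lib5, plan5):
        alts = [
            DnaSequence(
                plan5.carrier.fragment.sequence.residues, "circular", "carrier_only"
            )
        ]
        result = select_diagnostic_panel(
            plan5.predicted_sequence, alts,
            ["EcoRI", "HindIII", "BamHI", "NdeI"], max_enzymes=2,
        )
        assert result["score"]["discrimination"] == 1.0
        assert result["warning"] is None

    def test_single_candidate_returned(self, plan5):
        alts = [DnaSequence("ACGT" * 1000, "circular", "junk")]
        result = select_diagnostic_panel(
            plan5.predicted_sequence, alts, ["EcoRI"], max_enzymes=1
        )
        assert result["panel"] == ["EcoRI"]

    def test_duplicate_candidates_collapse(self, plan5):
        alts = [DnaSequence("ACGT" * 1000, "circular", "junk")]
        result = select_diagnostic_panel(
            plan5.predicted_sequence, alts, ["EcoRI", "EcoRI", "HindIII"],
            max_enzymes=2,
        )
        assert len(result["panel"]) == len(set(result["panel"]))

    def test_refuses_oversized_search(self, plan5):
        with pytest.raises(ValueError, match="max_enzymes"):
            select_diagnostic_panel(
                plan5.predicted_sequence,
                [plan5.predicted_sequence],
                ["EcoRI"],
                max_enzymes=4,
            )

    def test_misassembly_alternatives_include_carrier_selfclosure(self, plan5):
        alts = misassembly_alternatives(plan5)
        assert any("carrier_selfclose" in a.name for a in alts)
        target = plan5.predicted_sequence.residues
        assert all(a.residues != target for a in alts)


class TestScreeningStats:
    def test_two_colony_worked_example(self):
        assert screening_stats(0.7, 2) == pytest.approx(0.09)

    def test_certain_success(self):
        for k in (1, 2, 10):
            assert screening_stats(1.0, k) == 0.0

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            screening_stats(1.2, 2)

    def test_monte_carlo_agreement(self):
        rng = np.random.Generator(np.random.PCG64(42))
        n = 200_000
        for p, k in ((0.7, 2), (0.4, 3), (0.9, 1)):
            draws = rng.random((n, k)) >= p  # True = colony incorrect
            mc = float(np.mean(draws.all(axis=1)))
            exact = screening_stats(p, k)
            se = (exact * (1 - exact) / n) ** 0.5
            assert abs(mc - exact) < 3 * se + 1e-9

    def test_colonies_for_risk_examples(self):
        assert colonies_for_risk(0.5, 0.1) == 4
        assert colonies_for_risk(0.9, 0.1) == 1
        assert colonies_for_risk(1.0, 0.001) == 1

    def test_colonies_for_risk_consistency(self):
        for p in (0.3, 0.5, 0.68, 0.95):
            for r in (0.1, 0.01):
                k = colonies_for_risk(p, r)
                assert screening_stats(p, k) <= r
                if k > 1:
                    assert screening_stats(p, k - 1) > r

    def test_p_zero_unachievable(self):
        with pytest.raises(ValueError, match="unachievable"):
            colonies_for_risk(0.0, 0.1)
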