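"""Planner tests: addressing, adaptor alternation, rosters, arithmetic."""

import pytest

from unskit.assembly_planner import (
    CircuitDesign,
    PlanError,
    TUEntry,
    as_module,
    assign_positions,
    design_from_library,
    mass_ng,
    plan_assembly,
    plan_hierarchical,
    protocol_sheet,
    select_adaptor,
)
from unskit.gibson_simulator import simulate_one_pot
from unskit.parts_model import make_hierarchical_fixture
from unskit.seqcore import get_enzyme


def _tail_entries(lib):
    return [
        TUEntry(pv.tu_name, pv.tu_name.split("-")[0], pv.tu_name.split("-")[-1])
        for pv in sorted(lib.position_vectors, key=lambda p: p.position)
    ]


class TestAssignPositions:
    def test_five_tu_worked_example(self, lib5, uns6):
        design = design_from_library(lib5)
        addr = assign_positions(design, lib5.uns_set)
        assert [addr[i] for i in range(1, 6)] == [
            ("UNS1", "UNS2"),
            ("UNS2", "UNS3"),
            ("UNS3", "UNS4"),
            ("UNS4", "UNS5"),
            ("UNS5", "UNS6"),
        ]
        assert addr["adaptor"] == ("UNS6", "UNSX")

    def test_minimal_circuit(self, lib5):
        design = CircuitDesign([_tail_entries(lib5)[0]])
        addr = assign_positions(design, lib5.uns_set)
        assert addr[1] == ("UNS1", "UNS2")
        assert addr["adaptor"] == ("UNS2", "UNSX")

    def test_design_larger_than_set_errors(self, lib5):
        entries = _tail_entries(lib5) * 3  # 15 entries, set has UNS1..6
        design = CircuitDesign(entries)
        with pytest.raises(PlanError, match="UNS1-16"):
            assign_positions(design, lib5.uns_set)


class TestSelectAdaptor:
    def test_alternation(self, lib5):
        assert select_adaptor(5, "Kan", lib5.adaptors).marker == "Tet"
        assert select_adaptor(5, "Tet", lib5.adaptors).marker == "Kan"

    def test_first_round_defaults_to_kan(self, lib5):
        assert select_adaptor(5, "none", lib5.adaptors).marker == "Kan"

    def test_missing_address_errors(self, lib5):
        with pytest.raises(PlanError, match=r"\(9, X\)"):
            select_adaptor(8, "Tet", lib5.adaptors)


class TestPlanAssembly:
    def test_five_tu_roster_of_seven_inputs(self, plan5):
        assert plan5.n_entries == 5
        assert len(plan5.fragments) == 7  # 5 positions + adaptor + carrier

    def test_pooling_and_digestion_defaults(self, plan5):
        assert all(v == 7.0 for v in plan5.pooling.values())
        assert {r.digest_fmol for r in plan5.roster} == {70.0}
        assert plan5.adaptor.digest_fmol == 280.0
        assert plan5.carrier.digest_fmol == 140.0

    def test_digestion_enzymes(self, plan5, lib5):
        assert all(r.enzymes == ("I-SceI",) for r in plan5.roster)
        assert plan5.adaptor.enzymes == ("XbaI", "XhoI")
        assert plan5.carrier.enzymes == (lib5.carrier.linearization_enzyme,)

    def test_duplicate_position_is_positional_conflict(self, lib5):
        entries = _tail_entries(lib5)
        entries[1] = entries[2]  # slot 2 points at the position-3 vector
        with pytest.raises(PlanError, match="positional conflict"):
            plan_assembly(CircuitDesign(entries), lib5.uns_set, lib5)

    def test_junction_table_tiles_circle(self, plan5):
        assert plan5.junction_table == [
            "UNS1", "UNS2", "UNS3", "UNS4", "UNS5", "UNS6", "UNSX"
        ]

    def test_predicted_length_arithmetic(self, plan5):
        # independent arithmetic: sum of fragment lengths minus one
        # 40-bp overlap per junction minus the trimmed I-SceI remnants
        iscei = get_enzyme("I-SceI")
        flap_insert = (len(iscei.site) - iscei.cut_top) + iscei.cut_top  # 18/vector
        total = sum(len(f) for f in plan5.fragments)
        n_junctions = plan5.n_entries + 2
        # flaps: each position insert carries 9 nt at each end (18);
        # adaptor cassette: 5' XbaI remnant 5 nt + 3' XhoI remnant 1 nt;
        # carrier: FseI remnants 2 nt + 6 nt
        flaps = plan5.n_entries * flap_insert + (5 + 1) + (2 + 6)
        expected = total - n_junctions * 40 - flaps
        assert len(plan5.predicted_sequence) == expected

    def test_uns_census_of_prediction(self, lib5, plan5):
        wrapped = (
            plan5.predicted_sequence.residues + plan5.predicted_sequence.residues[:39]
        )
        from unskit.seqcore import reverse_complement

        for name, seq in lib5.uns_set.members.items():
            count = wrapped.count(seq) + wrapped.count(reverse_complement(seq))
            assert count == 1, name


class TestProtocolSheet:
    def test_mass_rule_worked_example(self):
        assert mass_ng(7, 10000) == pytest.approx(45.5)
        assert mass_ng(0, 10000) == 0.0

    def test_sheet_totals_additive(self, plan5):
        sheet = protocol_sheet(plan5)
        assert sheet.total_one_pot_ng == pytest.approx(
            sum(r.mass_ng for r in sheet.one_pot)
        )
        assert all(r.mass_ng >= 0 for r in sheet.one_pot + sheet.digestions)

    def test_volumes_from_concentrations(self, plan5):
        conc = {plan5.roster[0].name: 50.0}
        sheet = protocol_sheet(plan5, conc)
        row = next(r for r in sheet.one_pot if r.name == plan5.roster[0].name)
        assert row.volume_ul == pytest.approx(row.mass_ng / 50.0)

    def test_nonpositive_concentration_rejected(self, plan5):
        with pytest.raises(ValueError, match="positive"):
            protocol_sheet(plan5, {plan5.roster[0].name: 0.0})


@pytest.fixture(scope="module")
def hier():
    mlib, tlib, master = make_hierarchical_fixture(7, n_module=3, n_tail=2)
    mplan = plan_assembly(design_from_library(mlib), mlib.uns_set, mlib)
    product = simulate_one_pot(mplan.fragments)[0]
    module = as_module(mplan, product.sequence, "module3")
    return mlib, tlib, module


class TestHierarchical:
    def test_module_marker_recorded(self, hier):
        _, _, module = hier
        assert module.marker == "Kan"

    def test_tail_round_alternates_marker(self, hier):
        _, tlib, module = hier
        plan = plan_hierarchical(module, _tail_entries(tlib), tlib.uns_set, tlib)
        assert plan.adaptor.name == "adaptor:Tet"
        assert plan.n_entries == 3  # module + 2 tail TUs

    def test_internal_collision_rejected(self, hier):
        _, tlib, module = hier
        import copy

        colliding = copy.deepcopy(module)
        # pretend the module internally used the tail round's UNS3
        colliding.internal_uns["collision"] = tlib.uns_set["UNS3"]
        with pytest.raises(PlanError, match="collide"):
            plan_hierarchical(colliding, _tail_entries(tlib), tlib.uns_set, tlib)

    def test_degenerate_module_only_plan(self, hier):
        _, tlib, module = hier
        plan = plan_hierarchical(module, [], tlib.uns_set, tlib)
        assert plan.n_entries == 1
        assert plan.junction_table == ["UNS1", "UNS2", "UNSX"]
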