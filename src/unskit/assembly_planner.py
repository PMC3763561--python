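"""Turn an ordered circuit design into an executable assembly plan.

A circuit of n transcription units is addressed by consecutive UNS
pairs: entry i is flanked by (UNS_i, UNS_{i+1}), the adaptor bridges
(UNS_{n+1}, UNSX) and the carrier closes the circle UNSX -> UNS1. The
planner digests each source vector in silico, rosters the released
fragments with their expected flanks, selects the adaptor (alternating
Kan/Tet between rounds), computes the bench pooling table (fmol/ng)
and predicts the final circular sequence independently of the Gibson
simulator — by locating the expected address at each fragment end and
splicing, rather than by homology search. Agreement of the two routes
is the framework's central self-check.

Hierarchical rounds reuse an assembled circuit as the position 1-2
part: its I-SceI digest (one site upstream of UNS1, one downstream of
the adaptor's hand-off UNS2) yields a module fragment that is planned
exactly like a position vector. The planner refuses plans in which a
module's internal junction addresses reappear among the new round's
addresses, since colliding addresses make the one-pot outcome
ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqcore import DnaSequence, Fragment, digest, get_enzyme
from .parts_model import AdaptorVector, CarrierVector, FixtureLibrary, PositionVector
from .uns_designer import UnsSet

__all__ = [
    "TUEntry",
    "ModuleEntry",
    "CircuitDesign",
    "AssembledModule",
    "RosterEntry",
    "AssemblyPlan",
    "ProtocolSheet",
    "PlanError",
    "assign_positions",
    "select_adaptor",
    "plan_assembly",
    "predict_final_sequence",
    "plan_hierarchical",
    "protocol_sheet",
    "design_from_library",
    "as_module",
]

# bench defaults: fmol of each vector going into its digestion, and of
# each digested part going into the one-pot reaction
DIGEST_FMOL_POSITION = 70.0
DIGEST_FMOL_ADAPTOR = 280.0
DIGEST_FMOL_CARRIER = 140.0
ONE_POT_FMOL = 7.0

MEAN_BP_MASS_G_PER_MOL = 650.0  # average mass of one base pair


class PlanError(ValueError):
    pass


@dataclass(frozen=True)
class TUEntry:
    tu_name: str
    promoter: str
    gene: str


@dataclass
class AssembledModule:
    """An assembled circuit vector reusable as a position 1-2 part."""

    name: str
    sequence: DnaSequence          # circular assembled vector
    marker: str                    # Kan | Tet selection of its round
    internal_uns: dict[str, str]   # junction addresses inside the module piece
    terminal_uns: tuple[str, str]  # sequences expected at the piece's ends


@dataclass(frozen=True)
class ModuleEntry:
    module: AssembledModule


@dataclass
class CircuitDesign:
    entries: list[TUEntry | ModuleEntry]
    carrier: str = "carrier"
    previous_round_marker: str = "none"  # none | Kan | Tet

    def __post_init__(self) -> None:
        if not self.entries:
            raise PlanError("a circuit design needs at least one entry")
        if self.previous_round_marker not in ("none", "Kan", "Tet"):
            raise PlanError("previous_round_marker must be none|Kan|Tet")


@dataclass
class RosterEntry:
    name: str
    source: str                 # source vector name
    enzymes: tuple[str, ...]    # digestion instruction
    flanks: tuple[str, str]     # expected UNS names (left, right)
    fragment: Fragment
    digest_fmol: float


@dataclass
class AssemblyPlan:
    design: CircuitDesign
    uns_set: UnsSet
    roster: list[RosterEntry]          # entries in position order
    adaptor: RosterEntry
    carrier: RosterEntry
    junction_table: list[str]          # UNS names around the circle
    pooling: dict[str, float]          # input name -> one-pot fmol
    predicted_sequence: DnaSequence | None = None

    @property
    def fragments(self) -> list[Fragment]:
        return [r.fragment for r in self.roster] + [
            self.adaptor.fragment,
            self.carrier.fragment,
        ]

    @property
    def n_entries(self) -> int:
        return len(self.roster)


@dataclass
class SheetRow:
    name: str
    length_bp: int
    fmol: float
    mass_ng: float
    volume_ul: float | None


@dataclass
class ProtocolSheet:
    one_pot: list[SheetRow]
    digestions: list[SheetRow]

    @property
    def total_one_pot_ng(self) -> float:
        return sum(r.mass_ng for r in self.one_pot)


def mass_ng(fmol: float, length_bp: int) -> float:
    """fmol x bp x 650 g/mol/bp, expressed in nanograms."""
    return fmol * length_bp * MEAN_BP_MASS_G_PER_MOL * 1e-6


def assign_positions(design: CircuitDesign, uns_set: UnsSet) -> dict:
    """Map entry index (1-based) to its (UNS_i, UNS_{i+1}) flank pair.

    The adaptor gets (UNS_{n+1}, UNSX); n+2 distinct addresses in all.
    """
    n = len(design.entries)
    needed = [f"UNS{i}" for i in range(1, n + 2)] + ["UNSX"]
    missing = [m for m in needed if m not in uns_set.members]
    if missing:
        raise PlanError(
            f"design of {n} entries needs UNS1-{n + 1} + X; set lacks {missing}"
        )
    addresses = {
        i + 1: (f"UNS{i + 1}", f"UNS{i + 2}") for i in range(n)
    }
    addresses["adaptor"] = (f"UNS{n + 1}", "UNSX")
    return addresses


def select_adaptor(
    n: int,
    previous_round_marker: str,
    library: dict[tuple[int, str], AdaptorVector],
) -> AdaptorVector:
    """Adaptor at address (n+1, X) whose marker alternates with the
    previous round's; the first round defaults to Kan."""
    marker = {"Kan": "Tet", "Tet": "Kan", "none": "Kan"}.get(previous_round_marker)
    if marker is None:
        raise PlanError(f"unknown previous marker {previous_round_marker!r}")
    key = (n + 1, marker)
    if key not in library:
        raise PlanError(
            f"adaptor library lacks marker {marker} at address ({n + 1}, X)"
        )
    return library[key]


def _insert_fragment(
    vector: PositionVector, uns_set: UnsSet
) -> Fragment:
    iscei = get_enzyme("I-SceI")
    frags = digest(vector.sequence, iscei)
    if len(frags) != 2:
        raise PlanError(
            f"{vector.sequence.name}: expected 2 I-SceI fragments, got {len(frags)}"
        )
    (ln, ls), (rn, rs) = vector.uns_pair
    insert = next((f for f in frags if ls in f.sequence.residues), None)
    if insert is None or rs not in insert.sequence.residues:
        raise PlanError(f"{vector.sequence.name}: released insert lacks its UNS pair")
    return insert


def _module_fragment(module: AssembledModule) -> Fragment:
    iscei = get_enzyme("I-SceI")
    frags = digest(module.sequence, iscei)
    if len(frags) != 2:
        raise PlanError(
            f"module {module.name}: expected 2 I-SceI sites in assembled "
            f"vector, found {len(frags) if len(frags) != 1 else 'fewer'}"
        )
    l_seq, r_seq = module.terminal_uns
    # the assembled vector is stored in canonical strand; the released
    # piece may therefore carry its addresses on either strand
    from .seqcore import reverse_complement

    for f in frags:
        body = f.sequence.residues
        if l_seq in body and r_seq in body:
            return f
        rc = reverse_complement(body)
        if l_seq in rc and r_seq in rc:
            return Fragment(
                DnaSequence(rc, "linear", f.sequence.name),
                f.right_end,
                f.left_end,
                f.source,
            )
    raise PlanError(f"module {module.name}: digest yields no UNS1..UNS2 piece")


def plan_assembly(
    design: CircuitDesign,
    uns_set: UnsSet,
    registry: FixtureLibrary | "Registry",
) -> AssemblyPlan:
    """Build the full assembly plan for a circuit design.

    Digestions: I-SceI for every position vector or module, XbaI+XhoI
    for the adaptor, the carrier's own linearization enzyme for the
    carrier. Fragments are verified to carry their assigned addresses;
    two roster entries sharing an address pair is a positional
    conflict (the one-pot reaction could close more than one way).
    """
    addresses = assign_positions(design, uns_set)
    n = len(design.entries)
    roster: list[RosterEntry] = []
    seen_pairs: dict[tuple[str, str], str] = {}
    internal_by_entry: dict[str, dict[str, str]] = {}

    for i, entry in enumerate(design.entries, 1):
        want = addresses[i]
        if isinstance(entry, ModuleEntry):
            frag = _module_fragment(entry.module)
            source = entry.module.name
            name = f"module:{entry.module.name}"
            internal_by_entry[name] = dict(entry.module.internal_uns)
        else:
            vector = _lookup_position_vector(registry, entry, i)
            frag = _insert_fragment(vector, uns_set)
            source = vector.sequence.name
            name = f"TU{i}:{entry.tu_name}"
        flanks = _scan_flanks_expected(frag, uns_set, want)
        if flanks != want:
            raise PlanError(
                f"positional conflict: entry {i} ({name}) carries flanks "
                f"{flanks}, assigned {want}"
            )
        if want in seen_pairs:
            raise PlanError(
                f"positional conflict: {name} and {seen_pairs[want]} share "
                f"address pair {want}"
            )
        seen_pairs[want] = name
        frag.sequence.name = f"frag_{i}_{source}"
        roster.append(
            RosterEntry(name, source, ("I-SceI",), want, frag, DIGEST_FMOL_POSITION)
        )

    adaptor_vec = select_adaptor(
        n, design.previous_round_marker, _adaptor_library(registry)
    )
    adaptor_frag = _adaptor_fragment(adaptor_vec)
    adaptor_frag.sequence.name = f"frag_adaptor_{adaptor_vec.sequence.name}"
    adaptor_entry = RosterEntry(
        f"adaptor:{adaptor_vec.marker}",
        adaptor_vec.sequence.name,
        ("XbaI", "XhoI"),
        addresses["adaptor"],
        adaptor_frag,
        DIGEST_FMOL_ADAPTOR,
    )

    carrier_vec = _lookup_carrier(registry, design.carrier)
    carrier_frags = digest(carrier_vec.sequence, get_enzyme(carrier_vec.linearization_enzyme))
    if len(carrier_frags) != 1:
        raise PlanError("carrier must linearize with a single cut")
    carrier_frag = carrier_frags[0]
    carrier_frag.sequence.name = f"frag_carrier_{carrier_vec.sequence.name}"
    carrier_entry = RosterEntry(
        "carrier",
        carrier_vec.sequence.name,
        (carrier_vec.linearization_enzyme,),
        ("UNSX", "UNS1"),
        carrier_frag,
        DIGEST_FMOL_CARRIER,
    )

    # module internal addresses must not collide with this round's
    for name, internal in internal_by_entry.items():
        used = {u for pair in list(seen_pairs) + [addresses["adaptor"]] for u in pair}
        used_seqs = {uns_set[u] for u in used} | {uns_set["UNSX"]}
        colliding = sorted(
            iname for iname, iseq in internal.items() if iseq in used_seqs
        )
        if colliding:
            raise PlanError(
                f"module {name}: internal addresses {colliding} collide with "
                f"addresses used by this round"
            )

    junction_table = [f"UNS{i}" for i in range(1, n + 2)] + ["UNSX"]
    pooling = {r.name: ONE_POT_FMOL for r in roster}
    pooling[adaptor_entry.name] = ONE_POT_FMOL
    pooling["carrier"] = ONE_POT_FMOL

    plan = AssemblyPlan(
        design, uns_set, roster, adaptor_entry, carrier_entry, junction_table, pooling
    )
    plan.predicted_sequence = predict_final_sequence(plan)
    return plan


def _scan_flanks_expected(
    frag: Fragment, uns_set: UnsSet, want: tuple[str, str]
) -> tuple[str, str]:
    """Terminal addresses of a fragment: the outermost UNS occurrences."""
    body = frag.sequence.residues
    first = None
    last = None
    for name, seq in uns_set.members.items():
        i = body.find(seq)
        if i < 0:
            continue
        j = body.rfind(seq)
        if first is None or i < first[0]:
            first = (i, name)
        if last is None or j > last[0]:
            last = (j, name)
    if first is None or last is None or first == last:
        raise PlanError(f"{frag.sequence.name}: fragment lacks two terminal addresses")
    return first[1], last[1]


def _adaptor_fragment(adaptor: AdaptorVector) -> Fragment:
    frags = digest(
        adaptor.sequence, [get_enzyme("XbaI"), get_enzyme("XhoI")]
    )
    cassette = next(
        (f for f in frags if adaptor.uns_left[1] in f.sequence.residues), None
    )
    if cassette is None or adaptor.unsx not in cassette.sequence.residues:
        raise PlanError(f"{adaptor.sequence.name}: cassette lacks its UNS pair")
    return cassette


def predict_final_sequence(plan: AssemblyPlan) -> DnaSequence:
    """Planner-side prediction of the assembled circle.

    Splices roster fragments in address order, locating each shared
    UNS by exact search from the fragment ends (so each address is
    counted once) and trimming the restriction remnants outside the
    terminal UNSs. Reported in the same canonical rotation the
    simulator uses, to make the two routes directly comparable.
    """
    from .gibson_simulator import canonical_circular  # local: avoid cycle

    order = list(plan.roster) + [plan.adaptor, plan.carrier]
    names = plan.junction_table
    m = len(order)
    pieces = []
    feats: list[tuple[str, int]] = []
    offset = 0
    for idx, entry in enumerate(order):
        body = entry.fragment.sequence.residues
        start_uns = plan.uns_set[names[idx]]
        end_uns = plan.uns_set[names[(idx + 1) % m]]
        i = body.find(start_uns)
        j = body.rfind(end_uns)
        if i < 0 or j < 0 or j <= i:
            raise PlanError(
                f"{entry.name}: cannot locate addresses {names[idx]}, "
                f"{names[(idx + 1) % m]} on fragment"
            )
        piece = body[i:j]  # keep leading UNS; trailing UNS belongs to next piece
        pieces.append(piece)
        feats.append((names[idx], offset))
        feats.append((entry.name, offset + 40))
        offset += len(piece)
    raw = "".join(pieces)
    canon = canonical_circular(raw)
    seq = DnaSequence(canon, "circular", "pCircuit_predicted")
    # annotate each address on the canonical rotation (either strand)
    from .seqcore import reverse_complement

    wrapped = canon + canon[:39]
    for name in names:
        u = plan.uns_set[name]
        strand = 1
        i = wrapped.find(u)
        if i < 0:
            i = wrapped.find(reverse_complement(u))
            strand = -1
        if 0 <= i < len(canon):
            seq.annotate(name, i, i + 40, strand)
    return seq


def plan_hierarchical(
    module_vector: AssembledModule,
    design_tail: list[TUEntry],
    uns_set: UnsSet,
    registry: FixtureLibrary | "Registry",
) -> AssemblyPlan:
    """Plan a round that reuses an assembled module as position 1.

    The module's I-SceI digest supplies the UNS1..UNS2 piece; tail
    entries occupy positions 2..; the adaptor's marker alternates
    against the module's. Collisions between the module's internal
    junction addresses and any address used by this round are errors.
    """
    entries: list[TUEntry | ModuleEntry] = [ModuleEntry(module_vector)]
    entries.extend(design_tail)
    design = CircuitDesign(
        entries, previous_round_marker=module_vector.marker
    )
    return plan_assembly(design, uns_set, registry)


def protocol_sheet(
    plan: AssemblyPlan, concentrations: dict[str, float] | None = None
) -> ProtocolSheet:
    """Bench arithmetic: mass and volume per input.

    ``concentrations`` maps input names to ng/ul; volume is omitted
    for inputs without a stated concentration. Digestion rows use the
    bench default fmol inputs (70 position / 280 adaptor / 140
    carrier); one-pot rows use 7 fmol of each digested part.
    """
    concentrations = concentrations or {}
    one_pot: list[SheetRow] = []
    digestions: list[SheetRow] = []
    for entry in list(plan.roster) + [plan.adaptor, plan.carrier]:
        L = len(entry.fragment)
        fm = plan.pooling[entry.name]
        m = mass_ng(fm, L)
        conc = concentrations.get(entry.name)
        if conc is not None and conc <= 0:
            raise ValueError(f"{entry.name}: concentration must be positive")
        one_pot.append(
            SheetRow(entry.name, L, fm, m, (m / conc) if conc else None)
        )
        # digestion mass is quoted on the released fragment length; the
        # undigested parent adds its backbone, which the sheet does not track
        dig_mass = mass_ng(entry.digest_fmol, L)
        digestions.append(
            SheetRow(
                f"digest {entry.source} ({'+'.join(entry.enzymes)})",
                L,
                entry.digest_fmol,
                dig_mass,
                None,
            )
        )
    return ProtocolSheet(one_pot, digestions)


# --- registry helpers -------------------------------------------------

def _lookup_position_vector(registry, entry: TUEntry, position: int) -> PositionVector:
    if isinstance(registry, FixtureLibrary):
        wanted = {entry.tu_name, f"{entry.promoter}-{entry.gene}"}
        # prefer a vector built for this slot (repeated TU names are
        # legal when parts recur across positions), else fall back to
        # name match alone and let the flank check catch conflicts
        for pv in registry.position_vectors:
            if pv.position == position and pv.tu_name in wanted:
                return pv
        for pv in registry.position_vectors:
            if pv.tu_name in wanted:
                return pv
        raise PlanError(f"no position vector for TU {entry.tu_name!r}")
    return registry.position_vector(entry, position)


def _adaptor_library(registry) -> dict[tuple[int, str], AdaptorVector]:
    if isinstance(registry, FixtureLibrary):
        return registry.adaptors
    return registry.adaptors


def _lookup_carrier(registry, name: str) -> CarrierVector:
    if isinstance(registry, FixtureLibrary):
        return registry.carrier
    return registry.carrier_by_name(name)


def design_from_library(library: FixtureLibrary, marker_previous: str = "none") -> CircuitDesign:
    """Convenience: the full-circuit design implied by a fixture library."""
    entries = [
        TUEntry(pv.tu_name, pv.tu_name.split("-")[0], pv.tu_name.split("-")[-1])
        for pv in sorted(library.position_vectors, key=lambda p: p.position)
    ]
    return CircuitDesign(entries, previous_round_marker=marker_previous)


def as_module(
    plan: AssemblyPlan, product_sequence: DnaSequence, name: str = "module"
) -> AssembledModule:
    """Package an assembly outcome for reuse in a hierarchical round.

    The assembled vector must have been closed with a hierarchical
    adaptor (hand-off UNS + I-SceI site), so that its digest releases
    a piece whose 5' end is this round's UNS1 and whose 3' end is the
    hand-off address. Internal addresses (everything between) are
    recorded for collision checking.
    """
    handoff = _find_handoff(plan)
    if handoff is None:
        raise PlanError(
            "assembled vector has no hierarchical hand-off; it cannot seed "
            "a further round"
        )
    # the released piece spans UNS1 .. hand-off: the numbered junction
    # addresses between them are internal; UNSX stays on the backbone side
    internal = {
        n: plan.uns_set[n]
        for n in plan.junction_table
        if n not in ("UNS1", "UNSX")
    }
    marker = plan.adaptor.name.split(":")[-1]
    return AssembledModule(
        name,
        product_sequence,
        marker,
        internal,
        (plan.uns_set["UNS1"], handoff[1]),
    )


def _find_handoff(plan: AssemblyPlan) -> tuple[str, str] | None:
    body = plan.adaptor.fragment.sequence.residues
    iscei = get_enzyme("I-SceI")
    if iscei.site not in body:
        return None
    i = body.find(iscei.site)
    return ("handoff", body[i - 40 : i])
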