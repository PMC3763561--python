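"""Sequence-level model of the addressed vector system, plus fixtures.

The framework builds circuits from three vector classes:

* **Position vector** — circular, one transcription unit (TU) flanked
  by a numbered UNS pair and two I-SceI sites. Its anatomy, 5'->3'
  through the insert: I-SceI site, UNS_n, tandem insulator, promoter,
  gene, polyA, UNS_{n+1}, I-SceI site. I-SceI digestion releases the
  TU with its two 40-bp addresses (plus short site remnants that the
  isothermal reaction trims as flaps).
* **Carrier vector** — circular backbone with propagation and
  selection elements, contributing the UNSX -> UNS1 closure of the
  circle. It carries one site for its linearization enzyme (FseI or
  PacI) between UNS1 and UNSX, and an I-SceI site just upstream of
  UNS1 so that assembled circuits can be excised and reused.
* **Adaptor vector** — supplies the UNS_{n+1} -> UNSX bridge and a
  selection marker (Kan or Tet) as an XbaI/XhoI-excisable cassette.
  The *hierarchical* flavor additionally carries a hand-off UNS and an
  I-SceI site before UNSX, so that the assembled circuit digests into
  a position 1-2 piece for the next assembly round.

Gateway recombination, which the wet protocol uses to load a
promoter/gene pair into a destination vector, is modeled as
deterministic cassette substitution with configurable att-scar spacer
strings: the addressing logic, not the recombination chemistry, is
what this package is about.

``make_fixture_library`` generates complete synthetic part libraries
(realistic size ranges, optional deliberate part repetition) for tests
and demonstrations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .report import ValidationReport
from .seqcore import (
    DnaSequence,
    digest,
    find_sites,
    get_enzyme,
    reverse_complement,
)
from .uns_designer import (
    DesignConfig,
    UnsSet,
    generate_candidates,
    select_orthogonal_set,
)

__all__ = [
    "Part",
    "DestinationLayout",
    "PositionVector",
    "CarrierVector",
    "AdaptorVector",
    "FixtureLibrary",
    "gateway_lr_compose",
    "validate_layout",
    "make_fixture_library",
    "make_hierarchical_fixture",
    "random_dna",
]

PART_ROLES = (
    "promoter",
    "gene",
    "polyA",
    "insulator",
    "selection_marker",
    "replication_element",
    "backbone",
)

# advisory length bounds per role (bp); violations warn, never fail
ROLE_LENGTH_HINTS = {
    "promoter": (100, 3000),
    "gene": (300, 10000),
    "polyA": (50, 1000),
    "insulator": (100, 2500),
    "selection_marker": (400, 3000),
    "backbone": (1000, 20000),
}

# Gateway att-scar placeholders left between recombined elements
DEFAULT_ATTB1_SCAR = "ACAAGTTTGTACAAAAAAGCAGGCT"
DEFAULT_ATTB2_SCAR = "ACCCAGCTTTCTTGTACAAAGTGGT"


@dataclass
class Part:
    """A basic part: named linear sequence with a functional role."""

    name: str
    role: str
    sequence: DnaSequence

    def __post_init__(self) -> None:
        if self.role not in PART_ROLES:
            raise ValueError(f"unknown part role {self.role!r}")
        if self.sequence.is_circular:
            raise ValueError(f"part {self.name}: parts are linear sequences")
        if self.role == "gene":
            hits = find_sites(self.sequence, get_enzyme("I-SceI"))
            if hits:
                raise ValueError(
                    f"gene part {self.name!r} contains the I-SceI site at "
                    f"position {hits[0][0]}; it cannot be released intact"
                )
        lo_hi = ROLE_LENGTH_HINTS.get(self.role)
        if lo_hi and not (lo_hi[0] <= len(self.sequence) <= lo_hi[1]):
            warnings.warn(
                f"part {self.name} ({self.role}): length {len(self.sequence)} bp "
                f"outside typical range {lo_hi}",
                stacklevel=2,
            )


@dataclass
class DestinationLayout:
    """Fixed elements a destination vector contributes to every TU."""

    backbone: DnaSequence
    insulator: Part
    polya: Part
    scar_left: str = DEFAULT_ATTB1_SCAR   # promoter/gene boundary
    scar_right: str = DEFAULT_ATTB2_SCAR  # gene/polyA boundary


@dataclass
class PositionVector:
    sequence: DnaSequence  # circular, annotated
    position: int
    tu_name: str
    uns_pair: tuple[tuple[str, str], tuple[str, str]]  # ((name, seq), (name, seq))


@dataclass
class CarrierVector:
    sequence: DnaSequence  # circular
    linearization_enzyme: str  # FseI or PacI
    uns1: str
    unsx: str
    flavor: str = "standard"  # standard | linear_pJazz_like | BAC_like


@dataclass
class AdaptorVector:
    sequence: DnaSequence  # circular
    address: int           # numbered index k of the cassette's 5' UNS
    marker: str            # Kan | Tet
    uns_left: tuple[str, str]   # (name, sequence) of UNS_k
    unsx: str
    handoff: tuple[str, str] | None = None  # hierarchical hand-off UNS


def random_dna(rng: np.random.Generator, length: int, forbidden: list[str] = ()) -> str:
    """Uniform random DNA free of the given motifs on either strand.

    Occurrences are repaired in place by re-drawing one base inside
    each hit, so the result stays deterministic for a given generator
    state and the length is exact.
    """
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = bytearray(bases[rng.integers(0, 4, length)].tobytes())
    if forbidden:
        motifs = set()
        for m in forbidden:
            motifs.add(m.upper())
            motifs.add(reverse_complement(m))
        for _ in range(10 * length):
            s = seq.decode()
            hit = None
            for m in motifs:
                i = s.find(m)
                if i >= 0:
                    hit = (i, len(m))
                    break
            if hit is None:
                break
            i, mlen = hit
            j = i + mlen // 2
            old = seq[j]
            choices = [b for b in b"ACGT" if b != old]
            seq[j] = choices[int(rng.integers(0, 3))]
        else:
            raise RuntimeError("could not scrub forbidden motifs")
    return seq.decode()


def _core_sites() -> list[str]:
    return [get_enzyme(n).site for n in ("I-SceI", "XbaI", "XhoI", "FseI", "PacI")]


def gateway_lr_compose(
    promoter: Part,
    gene: Part,
    destination_layout: DestinationLayout,
    uns_set: UnsSet,
    position: int,
    tu_name: str | None = None,
) -> PositionVector:
    """Compose a position vector from a promoter/gene pair.

    Sequence-level stand-in for the Gateway LR reaction: the promoter
    and gene replace the destination vector's recombination cassette,
    leaving att-scar spacers. The vector's UNS pair (UNS_position,
    UNS_{position+1}) encodes the TU's slot in the final circuit.
    """
    if position < 1:
        raise ValueError("position is 1-based")
    left_name = f"UNS{position}"
    right_name = f"UNS{position + 1}"
    for needed in (left_name, right_name):
        if needed not in uns_set.members:
            raise ValueError(f"UNS set lacks {needed} (have {uns_set.names})")
    iscei = get_enzyme("I-SceI")
    for part in (promoter, gene):
        hits = find_sites(part.sequence, iscei)
        if hits:
            raise ValueError(
                f"part {part.name!r} contains the I-SceI site at position "
                f"{hits[0][0]}; the TU must not contain the 18-bp I-SceI site"
            )
    tu_name = tu_name or f"{promoter.name}-{gene.name}"
    uns_l = uns_set[left_name]
    uns_r = uns_set[right_name]
    lay = destination_layout

    pieces = [
        ("backbone", lay.backbone.residues),
        ("I-SceI_site", iscei.site),
        (left_name, uns_l),
        ("insulator_1", lay.insulator.sequence.residues),
        ("insulator_2", lay.insulator.sequence.residues),
        (f"promoter:{promoter.name}", promoter.sequence.residues),
        ("attB1_scar", lay.scar_left),
        (f"gene:{gene.name}", gene.sequence.residues),
        ("attB2_scar", lay.scar_right),
        (f"polyA:{lay.polya.name}", lay.polya.sequence.residues),
        (right_name, uns_r),
        ("I-SceI_site", iscei.site),
    ]
    seq = DnaSequence(
        "".join(p[1] for p in pieces), "circular", f"pPos{position}_{tu_name}"
    )
    off = 0
    for label, s in pieces:
        seq.annotate(label, off, off + len(s))
        off += len(s)
    return PositionVector(seq, position, tu_name, ((left_name, uns_l), (right_name, uns_r)))


def _build_carrier(
    rng: np.random.Generator,
    uns_set: UnsSet,
    backbone_len: int,
    enzyme_name: str = "FseI",
    flavor: str = "standard",
) -> CarrierVector:
    lin = get_enzyme(enzyme_name)
    iscei = get_enzyme("I-SceI")
    backbone = random_dna(rng, backbone_len, _core_sites())
    pieces = [
        ("UNSX", uns_set["UNSX"]),
        ("backbone", backbone),
        ("I-SceI_site", iscei.site),
        ("UNS1", uns_set["UNS1"]),
        (f"{enzyme_name}_site", lin.site),
    ]
    seq = DnaSequence("".join(p[1] for p in pieces), "circular", f"pCarrier_{flavor}")
    off = 0
    for label, s in pieces:
        seq.annotate(label, off, off + len(s))
        off += len(s)
    return CarrierVector(seq, enzyme_name, uns_set["UNS1"], uns_set["UNSX"], flavor)


def _build_adaptor(
    rng: np.random.Generator,
    uns_set: UnsSet,
    address: int,
    marker: str,
    marker_seq: str,
    backbone_len: int = 1500,
    handoff: tuple[str, str] | None = None,
) -> AdaptorVector:
    xba = get_enzyme("XbaI")
    xho = get_enzyme("XhoI")
    iscei = get_enzyme("I-SceI")
    uns_name = f"UNS{address}"
    backbone = random_dna(rng, backbone_len, _core_sites())
    pieces = [
        ("backbone", backbone),
        ("XbaI_site", xba.site),
        (uns_name, uns_set[uns_name]),
        (f"marker:{marker}", marker_seq),
    ]
    if handoff is not None:
        pieces.append((f"handoff:{handoff[0]}", handoff[1]))
        pieces.append(("I-SceI_site", iscei.site))
    pieces.append(("UNSX", uns_set["UNSX"]))
    pieces.append(("XhoI_site", xho.site))
    name = f"pAdaptor{address}X_{marker}" + ("_hier" if handoff else "")
    seq = DnaSequence("".join(p[1] for p in pieces), "circular", name)
    off = 0
    for label, s in pieces:
        seq.annotate(label, off, off + len(s))
        off += len(s)
    return AdaptorVector(
        seq, address, marker, (uns_name, uns_set[uns_name]), uns_set["UNSX"], handoff
    )


def _count_occurrences(hay: str, needle: str) -> int:
    n = i = 0
    while True:
        i = hay.find(needle, i)
        if i < 0:
            return n
        n += 1
        i += 1


def validate_layout(v: PositionVector | CarrierVector | AdaptorVector) -> ValidationReport:
    """Check a vector's structural invariants by direct sequence scans."""
    rep = ValidationReport([])
    if isinstance(v, PositionVector):
        iscei = get_enzyme("I-SceI")
        hits = find_sites(v.sequence, iscei)
        rep.add("I-SceI site count", len(hits) == 2, f"found {len(hits)}, expect 2")
        (ln, ls), (rn, rs) = v.uns_pair
        wrapped = v.sequence.residues + v.sequence.residues[:39]
        rep.add(
            "UNS census",
            _count_occurrences(wrapped, ls) == 1 and _count_occurrences(wrapped, rs) == 1,
            f"{ln} and {rn} each exactly once",
        )
        if len(hits) == 2:
            frags = digest(v.sequence, iscei)
            insert = next((f for f in frags if ls in f.sequence.residues), None)
            if insert is None:
                rep.add("insert anatomy", False, f"no fragment contains {ln}")
            else:
                body = insert.sequence.residues
                flap_l = len(iscei.site) - iscei.cut_top
                flap_r = iscei.cut_top
                ok_l = body[flap_l : flap_l + 40] == ls
                ok_r = body[len(body) - flap_r - 40 : len(body) - flap_r] == rs
                rep.add(
                    "insert anatomy",
                    ok_l and ok_r,
                    f"insert first internal 40 bp == {ln}: {ok_l}; last == {rn}: {ok_r}",
                )
                starts = []
                missing = []
                for prefix in ("insulator_1", "insulator_2", "promoter:", "gene:", "polyA:"):
                    feat = next(
                        (f for f in v.sequence.features if f.label.startswith(prefix)),
                        None,
                    )
                    if feat is None:
                        missing.append(prefix)
                    else:
                        starts.append(feat.start)
                rep.add(
                    "element order",
                    not missing and starts == sorted(starts),
                    f"missing {missing}" if missing else "insulator x2, promoter, gene, polyA in order",
                )
                rep.add(
                    "UNS order",
                    body.find(ls) < body.find(rs),
                    f"{ln} precedes {rn} in insert",
                )
    elif isinstance(v, CarrierVector):
        lin = get_enzyme(v.linearization_enzyme)
        hits = find_sites(v.sequence, lin)
        rep.add(
            f"{v.linearization_enzyme} site count",
            len(hits) == 1,
            f"found {len(hits)}, expect 1",
        )
        wrapped = v.sequence.residues + v.sequence.residues[:39]
        rep.add(
            "carrier UNS census",
            _count_occurrences(wrapped, v.uns1) == 1
            and _count_occurrences(wrapped, v.unsx) == 1,
            "UNS1 and UNSX each exactly once",
        )
        if len(hits) == 1:
            frag = digest(v.sequence, lin)[0]
            body = frag.sequence.residues
            rep.add(
                "linearized end order",
                body.find(v.unsx) >= 0
                and body.find(v.uns1) > body.find(v.unsx),
                "UNSX near 5' end, UNS1 near 3' end after linearization",
            )
    elif isinstance(v, AdaptorVector):
        for enz_name in ("XbaI", "XhoI"):
            hits = find_sites(v.sequence, get_enzyme(enz_name))
            rep.add(
                f"{enz_name} site count", len(hits) == 1, f"found {len(hits)}, expect 1"
            )
        frags = digest(v.sequence, [get_enzyme("XbaI"), get_enzyme("XhoI")])
        cassette = next(
            (f for f in frags if v.uns_left[1] in f.sequence.residues), None
        )
        ok = cassette is not None and v.unsx in cassette.sequence.residues
        rep.add(
            "cassette UNS census",
            bool(ok),
            f"cassette carries {v.uns_left[0]} and UNSX"
            if ok
            else "cassette missing a stated UNS",
        )
    else:
        raise TypeError(f"cannot validate {type(v).__name__}")
    return rep


@dataclass
class FixtureLibrary:
    """A complete synthetic test universe for one assembly round."""

    parts: list[Part]
    uns_set: UnsSet
    carrier: CarrierVector
    adaptors: dict[tuple[int, str], AdaptorVector]
    position_vectors: list[PositionVector]
    layout: DestinationLayout
    n_tus: int


DEFAULT_PART_SIZE_RANGES = {
    "promoter": (200, 1500),
    "gene": (700, 3000),
    "polyA": (200, 350),
    "insulator": (250, 251),
    "marker": (800, 1300),
    "carrier_backbone": (2000, 8000),
    "position_backbone": (2200, 2800),
    "adaptor_backbone": (1200, 1800),
}


def _design_set(n_numbered: int, rng_seed: int, config: DesignConfig | None) -> UnsSet:
    cfg = config or DesignConfig()
    # pool sized to the request; rejection sampling reports infeasibility
    pool_size = max(6 * (n_numbered + 1), 48)
    cfg = DesignConfig(
        gc_min=cfg.gc_min,
        gc_max=cfg.gc_max,
        tm_min=cfg.tm_min,
        tm_max=cfg.tm_max,
        threshold_hairpin=cfg.threshold_hairpin,
        threshold_cross=cfg.threshold_cross,
        homopolymer_max=cfg.homopolymer_max,
        forbidden_motifs=list(cfg.forbidden_motifs),
        rng_seed=rng_seed,
        n_candidates=pool_size,
        max_attempt_factor=cfg.max_attempt_factor,
    )
    return select_orthogonal_set(generate_candidates(cfg), n_numbered, cfg)


def make_fixture_library(
    rng_seed: int,
    n_tus: int,
    part_size_ranges: dict | None = None,
    repeat_fraction: float = 0.0,
    uns_set: UnsSet | None = None,
    design_config: DesignConfig | None = None,
    carrier_enzyme: str = "FseI",
    hierarchical_handoff: tuple[str, str] | None = None,
) -> FixtureLibrary:
    """Deterministic synthetic library: parts, UNS set, all vectors.

    ``repeat_fraction`` of TUs beyond the first reuse the promoter and
    gene of an earlier TU, emulating deliberately repetitive circuits.
    A pre-designed ``uns_set`` (e.g. a sub-range view of a master set)
    skips the built-in design step. ``hierarchical_handoff`` threads a
    (name, sequence) hand-off UNS plus an I-SceI site into every
    adaptor so the assembled circuit can seed a next round.
    """
    if n_tus < 1:
        raise ValueError("n_tus >= 1")
    sizes = dict(DEFAULT_PART_SIZE_RANGES)
    if part_size_ranges:
        sizes.update(part_size_ranges)
    # parts draw from a child stream distinct from the UNS designer's,
    # so part sequences can never replay the address sampler's output
    rng = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence([rng_seed, 1]))
    )
    if uns_set is None:
        uns_set = _design_set(n_tus + 1, rng_seed, design_config)
    needed = [f"UNS{i}" for i in range(1, n_tus + 2)] + ["UNSX"]
    missing = [m for m in needed if m not in uns_set.members]
    if missing:
        raise ValueError(f"UNS set lacks {missing} for {n_tus} TUs")

    scrub = _core_sites()

    def draw(lo_hi: tuple[int, int]) -> int:
        lo, hi = lo_hi
        return int(rng.integers(lo, hi))

    insulator = Part("cHS4_core_synth", "insulator", DnaSequence(
        random_dna(rng, draw(sizes["insulator"])), name="cHS4_core_synth"))
    polya = Part("polyA_synth", "polyA", DnaSequence(
        random_dna(rng, draw(sizes["polyA"]), scrub), name="polyA_synth"))
    dest_backbone = DnaSequence(
        random_dna(rng, draw(sizes["position_backbone"]), scrub), name="pos_backbone"
    )
    layout = DestinationLayout(dest_backbone, insulator, polya)

    promoters: list[Part] = []
    genes: list[Part] = []
    for i in range(n_tus):
        if i > 0 and repeat_fraction > 0 and rng.random() < repeat_fraction:
            src = int(rng.integers(0, i))
            promoters.append(promoters[src])
            genes.append(genes[src])
            continue
        promoters.append(
            Part(f"P{i + 1}", "promoter", DnaSequence(
                random_dna(rng, draw(sizes["promoter"]), scrub), name=f"P{i + 1}"))
        )
        genes.append(
            Part(f"G{i + 1}", "gene", DnaSequence(
                random_dna(rng, draw(sizes["gene"]), scrub), name=f"G{i + 1}"))
        )

    carrier = _build_carrier(
        rng, uns_set, draw(sizes["carrier_backbone"]), carrier_enzyme
    )

    marker_seqs = {
        "Kan": random_dna(rng, draw(sizes["marker"]), scrub),
        "Tet": random_dna(rng, draw(sizes["marker"]), scrub),
    }
    adaptors: dict[tuple[int, str], AdaptorVector] = {}
    backbone_len = draw(sizes["adaptor_backbone"])
    for address in range(2, n_tus + 2):
        for marker in ("Kan", "Tet"):
            adaptors[(address, marker)] = _build_adaptor(
                rng,
                uns_set,
                address,
                marker,
                marker_seqs[marker],
                backbone_len,
                handoff=hierarchical_handoff,
            )

    position_vectors = [
        gateway_lr_compose(promoters[i], genes[i], layout, uns_set, i + 1)
        for i in range(n_tus)
    ]
    parts = promoters + genes + [polya, insulator]
    return FixtureLibrary(
        parts, uns_set, carrier, adaptors, position_vectors, layout, n_tus
    )


def make_hierarchical_fixture(
    rng_seed: int,
    n_module: int = 7,
    n_tail: int = 5,
    part_size_ranges: dict | None = None,
    repeat_fraction: float = 0.0,
    design_config: DesignConfig | None = None,
) -> tuple[FixtureLibrary, FixtureLibrary, UnsSet]:
    """Two-round fixture for hierarchical assembly.

    One master UNS set is designed and split into disjoint address
    sub-ranges: the module round addresses its internal junctions from
    the high slice, the tail round from the low slice, and both share
    UNS1 and UNSX. The module round's adaptors carry a hand-off copy
    of the tail round's UNS2 followed by an I-SceI site, so the
    assembled module digests into a position 1-2 piece whose internal
    addresses cannot collide with the tail's.

    Returns (module_library, tail_library, master_set). The tail
    library's position vectors occupy positions 2..n_tail+1.
    """
    n_master = n_module + n_tail + 2
    master = _design_set(n_master, rng_seed, design_config)
    low = [f"UNS{i}" for i in range(1, n_tail + 3)]
    high = ["UNS1"] + [f"UNS{i}" for i in range(n_tail + 3, n_master + 1)]
    view_tail = master.subset_view(low)
    view_module = master.subset_view(high)

    module_lib = make_fixture_library(
        rng_seed,
        n_module,
        part_size_ranges,
        repeat_fraction,
        uns_set=view_module,
        hierarchical_handoff=("UNS2", view_tail["UNS2"]),
    )

    tail_lib = make_fixture_library(
        rng_seed + 1,
        n_tail + 1,  # sized so addresses up to UNS{n_tail+2} exist
        part_size_ranges,
        repeat_fraction,
        uns_set=view_tail,
    )
    # tail entries occupy positions 2..n_tail+1: rebuild position
    # vectors for those slots from the tail library's parts
    proms = [p for p in tail_lib.parts if p.role == "promoter"]
    genes = [p for p in tail_lib.parts if p.role == "gene"]
    tail_lib.position_vectors = [
        gateway_lr_compose(proms[i], genes[i], tail_lib.layout, view_tail, i + 2)
        for i in range(n_tail)
    ]
    tail_lib.n_tus = n_tail
    return module_lib, tail_lib, master
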