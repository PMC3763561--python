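"""One-pot isothermal ("Gibson") assembly simulation.

The wet reaction combines a 5'->3' exonuclease (exposes fragment ends
as single strands), a polymerase (fills gaps, removes non-homologous
flaps) and a ligase. In this model:

* annealing is exact-match only — junctions are the longest exact
  terminal homology between two fragment ends, searched within a
  ``chew_window`` of each end (finite exonuclease processivity). A
  repeated sequence *inside* a fragment can therefore never form a
  junction; only terminal addresses matter, which is precisely the
  property the UNS addressing system exploits;
* residues outside the homology (restriction-site remnants) are
  trimmed as flaps, up to ``flap_tolerance`` per end;
* every way of closing a circle (or extending a maximal linear path)
  is enumerated; the simulator reports structure, not kinetics or
  yields. Status ``unique_circular`` certifies that exactly one
  product exists, uses every fragment once, and no fragment end has
  two or more annealing partners.

Product sequences are reported in a canonical form (lexicographically
least rotation of the lesser of the two strands), so results are
independent of fragment input order.
"""

from __future__ import annotations

from dataclasses import dataclass

from .report import ValidationReport
from .seqcore import DnaSequence, Fragment, reverse_complement
from .uns_designer import UnsSet

__all__ = [
    "GibsonParams",
    "Junction",
    "AssemblyProduct",
    "terminal_homology",
    "simulate_one_pot",
    "verify_junctions",
    "canonical_circular",
]


@dataclass
class GibsonParams:
    min_overlap: int = 20     # nt of exact homology required to join
    chew_window: int = 80     # nt of each end exposed by chew-back
    flap_tolerance: int = 15  # nt of non-homologous terminus removable
    require_all_fragments: bool = True

    def __post_init__(self) -> None:
        if min(self.min_overlap, self.chew_window, self.flap_tolerance) < 0:
            raise ValueError("all parameters must be >= 0")
        if self.min_overlap > self.chew_window:
            raise ValueError("min_overlap must be <= chew_window")


@dataclass(frozen=True)
class Junction:
    """An annealing joint between the 3' end of `left` and 5' end of `right`."""

    left: str                # fragment id
    right: str
    overlap_length: int
    overlap_sequence: str
    flap_left: int           # nt trimmed from the 3' terminus of `left`
    flap_right: int          # nt trimmed from the 5' terminus of `right`
    right_orientation: str = "+"


@dataclass
class AssemblyProduct:
    sequence: DnaSequence
    composition: list[tuple[str, str]]  # (fragment id, orientation)
    junctions: list[Junction]
    status: str  # unique_circular | multiple_products | ambiguous | incomplete


def _as_string(x) -> str:
    if isinstance(x, Fragment):
        return x.sequence.residues
    if isinstance(x, DnaSequence):
        return x.residues
    return str(x).upper()


def _best_terminal_match(
    a: str, b: str, params: GibsonParams
) -> tuple[int, int, int] | None:
    """Longest terminal-window exact match between end of a and start of b.

    Returns (k, i, j): overlap length k with a[i:i+k] == b[j:j+k],
    i inside a's terminal window, j inside b's leading window, and the
    residues beyond the match (len(a)-i-k on a, j on b) each within
    flap_tolerance. Ties break to the smaller flap total, then the
    smaller j — a fixed, documented order.
    """
    w = params.chew_window
    awin = a[-w:] if len(a) > w else a
    aoff = len(a) - len(awin)
    bwin = b[:w]
    best: tuple[int, int, int] | None = None
    best_key = None
    la, lb = len(awin), len(bwin)
    prev = [0] * (lb + 1)
    for ia in range(1, la + 1):
        cur = [0] * (lb + 1)
        ca = awin[ia - 1]
        for jb in range(1, lb + 1):
            if ca == bwin[jb - 1]:
                cur[jb] = prev[jb - 1] + 1
                k = cur[jb]
                i = aoff + ia - k
                j = jb - k
                flap_a = len(a) - (i + k)
                flap_b = j
                if flap_a <= params.flap_tolerance and flap_b <= params.flap_tolerance:
                    key = (-k, flap_a + flap_b, j)
                    if best_key is None or key < best_key:
                        best_key = key
                        best = (k, i, j)
        prev = cur
    if best is None or best[0] < params.min_overlap:
        return None
    return best


def terminal_homology(
    a, b, params: GibsonParams | None = None, try_revcomp: bool = True
) -> Junction | None:
    """Best junction between the end of fragment a and the start of b.

    Both orientations of ``b`` are considered unless ``try_revcomp``
    is false; '+' wins exact ties. Returns None when the best exact
    terminal match is shorter than ``min_overlap``.
    """
    params = params or GibsonParams()
    sa, sb = _as_string(a), _as_string(b)
    name_a = a.sequence.name if isinstance(a, Fragment) else getattr(a, "name", "a")
    name_b = b.sequence.name if isinstance(b, Fragment) else getattr(b, "name", "b")
    options = [("+", sb)]
    if try_revcomp:
        options.append(("-", reverse_complement(sb)))
    best: Junction | None = None
    for orient, sbo in options:
        m = _best_terminal_match(sa, sbo, params)
        if m is None:
            continue
        k, i, j = m
        jn = Junction(
            name_a, name_b, k, sa[i : i + k], len(sa) - (i + k), j, orient
        )
        if best is None or jn.overlap_length > best.overlap_length:
            best = jn
    return best


def canonical_circular(s: str) -> str:
    """Canonical representative of a circular double-stranded sequence:
    the lexicographically least rotation of the lesser strand."""
    return min(_least_rotation(s), _least_rotation(reverse_complement(s)))


def _least_rotation(s: str) -> str:
    """Booth's algorithm, O(n)."""
    ss = s + s
    n = len(ss)
    f = [-1] * n
    k = 0
    for j in range(1, n):
        sj = ss[j]
        i = f[j - k - 1]
        while i != -1 and sj != ss[k + i + 1]:
            if sj < ss[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != ss[k + i + 1]:
            if sj < ss[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return ss[k : k + len(s)]


@dataclass
class _Pool:
    ids: list[str]
    seqs: dict[str, str]  # oriented: (id, '+') -> top strand


def _edge_map(
    ids: list[str], oriented: dict[tuple[str, str], str], params: GibsonParams
) -> dict[tuple[str, str], dict[tuple[str, str], Junction]]:
    edges: dict[tuple[str, str], dict[tuple[str, str], Junction]] = {
        (i, o): {} for i in ids for o in "+-"
    }
    for i in ids:
        for oi in "+-":
            sa = oriented[(i, oi)]
            for j in ids:
                if i == j:
                    continue
                for oj in "+-":
                    m = _best_terminal_match(sa, oriented[(j, oj)], params)
                    if m is None:
                        continue
                    k, pi, pj = m
                    edges[(i, oi)][(j, oj)] = Junction(
                        i, j, k, sa[pi : pi + k], len(sa) - (pi + k), pj, oj
                    )
    return edges


def _splice_cycle(
    cycle: list[tuple[str, str]],
    oriented: dict[tuple[str, str], str],
    edges,
) -> tuple[str, list[Junction]]:
    """Concatenate fragment bodies around a cycle, counting each
    junction overlap once and dropping flaps."""
    m = len(cycle)
    juncs = [edges[cycle[i]][cycle[(i + 1) % m]] for i in range(m)]
    pieces = []
    for i, node in enumerate(cycle):
        s = oriented[node]
        jn_in = juncs[i - 1]   # junction (prev -> this): match starts at flap_right
        jn_out = juncs[i]      # junction (this -> next)
        start = jn_in.flap_right
        stop = len(s) - jn_out.flap_left - jn_out.overlap_length
        pieces.append(s[start:stop])
    return "".join(pieces), juncs


def _find_cycles(ids, edges):
    """All simple cycles, each counted once: rooted at its smallest
    member id in '+' orientation (the reverse-complement traversal of
    a product carries the root in '-', so each dsDNA circle appears
    exactly once)."""
    order = {x: n for n, x in enumerate(sorted(ids))}
    cycles = []

    def dfs(root, node, path, used):
        for nxt in sorted(edges[node], key=lambda t: (order[t[0]], t[1])):
            fid, _ = nxt
            if fid == root[0]:
                if nxt == root and len(path) > 1:
                    cycles.append(list(path))
                continue
            if fid in used or order[fid] < order[root[0]]:
                continue
            used.add(fid)
            path.append(nxt)
            dfs(root, nxt, path, used)
            path.pop()
            used.remove(fid)

    for rid in sorted(ids, key=lambda x: order[x]):
        root = (rid, "+")
        dfs(root, root, [root], {rid})
    return cycles


def simulate_one_pot(
    fragments: list[Fragment], params: GibsonParams | None = None
) -> list[AssemblyProduct]:
    """Enumerate the products of a one-pot isothermal assembly.

    Deterministic and invariant to fragment input order. The first
    product in the returned list is the principal one; its ``status``
    summarizes the whole reaction:

    * ``unique_circular`` — one circle, all fragments, unambiguous ends;
    * ``ambiguous`` — some fragment end has two or more partners
      meeting ``min_overlap`` (address collision);
    * ``multiple_products`` — several distinct closures;
    * ``incomplete`` — no circle (maximal linear paths are reported).
    """
    params = params or GibsonParams()
    if not fragments:
        raise ValueError("no fragments supplied")
    if len(fragments) < 2:
        raise ValueError("one-pot assembly needs at least 2 fragments")
    ids = []
    oriented: dict[tuple[str, str], str] = {}
    for f in fragments:
        fid = f.sequence.name
        if fid in oriented or (fid, "+") in oriented:
            raise ValueError(f"duplicate fragment id {fid!r}")
        ids.append(fid)
        oriented[(fid, "+")] = f.sequence.residues
        oriented[(fid, "-")] = reverse_complement(f.sequence.residues)
    ids.sort()
    edges = _edge_map(ids, oriented, params)

    ambiguous = any(len(partners) >= 2 for partners in edges.values())
    cycles = _find_cycles(ids, edges)

    products: list[AssemblyProduct] = []
    seen: set[str] = set()
    for cyc in cycles:
        raw, juncs = _splice_cycle(cyc, oriented, edges)
        canon = canonical_circular(raw)
        if canon in seen:
            continue
        seen.add(canon)
        comp = _canonical_composition(cyc)
        products.append(
            AssemblyProduct(
                DnaSequence(canon, "circular", "assembly_product"),
                comp,
                juncs,
                "",
            )
        )
    products.sort(key=lambda p: (-len(p.sequence), p.sequence.residues))

    if ambiguous:
        status = "ambiguous"
    elif len(products) == 1 and (
        not params.require_all_fragments
        or len(products[0].composition) == len(ids)
    ):
        status = "unique_circular"
    elif len(products) >= 2:
        status = "multiple_products"
    elif len(products) == 1:
        status = "incomplete"  # single circle but fragments left over
    else:
        status = "incomplete"

    if not products:
        products = [_best_linear_path(ids, oriented, edges)]
    for p in products:
        p.status = status
    return products


def _canonical_composition(cycle: list[tuple[str, str]]) -> list[tuple[str, str]]:
    """Rotate the cycle so the smallest fragment id leads."""
    k = min(range(len(cycle)), key=lambda i: cycle[i][0])
    return cycle[k:] + cycle[:k]


def _best_linear_path(ids, oriented, edges) -> AssemblyProduct:
    """Longest maximal path, for reporting failed closures."""
    best_path: list[tuple[str, str]] = []

    def dfs(node, path, used):
        nonlocal best_path
        if len(path) > len(best_path):
            best_path = list(path)
        for nxt in sorted(edges[node]):
            if nxt[0] in used:
                continue
            used.add(nxt[0])
            path.append(nxt)
            dfs(nxt, path, used)
            path.pop()
            used.remove(nxt[0])

    for i in ids:
        dfs((i, "+"), [(i, "+")], {i})
    juncs = [
        edges[best_path[i]][best_path[i + 1]] for i in range(len(best_path) - 1)
    ]
    pieces = []
    for i, node in enumerate(best_path):
        s = oriented[node]
        start = juncs[i - 1].flap_right if i > 0 else 0
        stop = (
            len(s) - juncs[i].flap_left - juncs[i].overlap_length
            if i < len(best_path) - 1
            else len(s)
        )
        pieces.append(s[start:stop])
    return AssemblyProduct(
        DnaSequence("".join(pieces), "linear", "assembly_partial"),
        best_path,
        juncs,
        "incomplete",
    )


def verify_junctions(product: AssemblyProduct, uns_set: UnsSet) -> ValidationReport:
    """Check that every junction is a clean UNS joint in address order.

    Each junction overlap must contain exactly one full UNS member,
    and walking the circle must visit UNS1, UNS2, ..., UNS{m-1}, UNSX
    consecutively (any rotation).
    """
    rep = ValidationReport([])
    hit_names: list[str] = []
    for jn in product.junctions:
        found = [
            name
            for name, seq in uns_set.members.items()
            if seq in jn.overlap_sequence or reverse_complement(seq) in jn.overlap_sequence
        ]
        rep.add(
            f"junction {jn.left}->{jn.right}",
            len(found) == 1,
            f"contains UNS members {found} (expect exactly one)",
        )
        hit_names.append(found[0] if len(found) == 1 else "?")
    m = len(product.junctions)
    expected = [f"UNS{i}" for i in range(1, m)] + ["UNSX"]
    ok_order = False
    if "?" not in hit_names and m > 0:
        # the walk may traverse the circle in either direction and
        # start anywhere: compare as an undirected cyclic sequence
        doubled = hit_names + hit_names
        for seq in (expected, expected[::-1]):
            if any(doubled[r : r + m] == seq for r in range(m)):
                ok_order = True
                break
    rep.add(
        "address order",
        ok_order,
        f"junction UNS walk {hit_names} vs expected circle {expected}",
    )
    if "UNSX" not in hit_names:
        rep.add("X junction", False, "X junction absent")
    else:
        rep.add("X junction", True, "carrier-linking X junction present")
    return rep
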