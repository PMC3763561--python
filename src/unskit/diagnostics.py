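"""Construct verification: restriction maps, diagnostic panels, colony
screening statistics.

Large assembled circuits are verified on an agarose gel: a small panel
of restriction enzymes is chosen so that the correct construct's band
pattern is distinguishable from the patterns of plausible misassembly
products (parental re-circularization, fragment dropout, products of
address collisions). The gel is modeled as a resolvable size window
plus a ratio rule: two bands are separable when the larger exceeds the
smaller by a configurable fraction (default 8%). This is deliberately
a size-arithmetic model, not migration physics — it is deterministic
and directly testable.

Colony screening follows a Bernoulli model: if a fraction ``p`` of
colonies carry the correct construct, the chance that all ``k`` picked
colonies are wrong is ``(1-p)^k``; picking two colonies keeps that
risk under 10% whenever p > 1 - sqrt(0.1) ~= 0.68.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

from .gibson_simulator import AssemblyProduct
from .seqcore import DnaSequence, RestrictionEnzyme, digest, get_enzyme

__all__ = [
    "GelModel",
    "RestrictionMap",
    "Band",
    "restriction_map",
    "maps_distinguishable",
    "panel_score",
    "select_diagnostic_panel",
    "misassembly_alternatives",
    "screening_stats",
    "colonies_for_risk",
]


@dataclass
class GelModel:
    min_size: int = 250        # bp, smallest resolvable band
    max_size: int = 20000      # bp, largest resolvable band
    resolution_fraction: float = 0.08  # larger/smaller >= 1+this to separate

    def __post_init__(self) -> None:
        if self.min_size >= self.max_size:
            raise ValueError("min_size < max_size required")
        if self.resolution_fraction <= 0:
            raise ValueError("resolution_fraction must be positive")

    def in_range(self, size: int) -> bool:
        return self.min_size <= size <= self.max_size

    def separable(self, a: int, b: int) -> bool:
        lo, hi = sorted((a, b))
        if lo == 0:
            return hi > 0
        return hi / lo >= 1 + self.resolution_fraction


@dataclass
class Band:
    size: int
    in_range: bool
    distinguishable: bool  # separable from every other in-range band


@dataclass
class RestrictionMap:
    construct: str
    panel: tuple[str, ...]
    bands: list[Band]                 # sorted descending by size
    comigrating_groups: list[list[int]]

    @property
    def sizes(self) -> list[int]:
        return [b.size for b in self.bands]


def restriction_map(
    construct: DnaSequence,
    panel: list[RestrictionEnzyme | str],
    gel: GelModel | None = None,
) -> RestrictionMap:
    """Predicted band pattern of a digest under the gel model.

    Band sizes always sum to the construct length (complete digest).
    Consecutive sizes whose ratio is below the gel's resolution are
    grouped as co-migrating.
    """
    if not panel:
        raise ValueError("empty enzyme panel")
    gel = gel or GelModel()
    enzymes = [get_enzyme(e) if isinstance(e, str) else e for e in panel]
    frags = digest(construct, enzymes)
    sizes = sorted((len(f) for f in frags), reverse=True)

    groups: list[list[int]] = []
    for s in sizes:
        if groups and not gel.separable(groups[-1][-1], s):
            groups[-1].append(s)
        else:
            groups.append([s])
    bands = []
    for g in groups:
        for s in g:
            bands.append(Band(s, gel.in_range(s), len(g) == 1 and gel.in_range(s)))
    return RestrictionMap(
        construct.name, tuple(e.name for e in enzymes), bands, groups
    )


def _visible_pattern(m: RestrictionMap, gel: GelModel) -> list[int]:
    """Band sizes the gel can see, merged within resolution: each
    co-migrating group collapses to one apparent band."""
    out = []
    for g in m.comigrating_groups:
        rep = g[0]
        if gel.in_range(rep):
            out.append(rep)
    return out


def maps_distinguishable(a: RestrictionMap, b: RestrictionMap, gel: GelModel) -> bool:
    """True when the two visible band patterns differ under the ratio
    rule: different apparent band counts, or some aligned pair of
    bands separable."""
    va, vb = _visible_pattern(a, gel), _visible_pattern(b, gel)
    if len(va) != len(vb):
        return True
    return any(gel.separable(x, y) for x, y in zip(va, vb))


def panel_score(
    map_correct: RestrictionMap,
    maps_alternatives: list[RestrictionMap],
    gel: GelModel | None = None,
) -> tuple[float, float]:
    """(discrimination, clarity), each in [0, 1], compared lexicographically.

    discrimination: fraction of alternative products whose pattern is
    distinguishable from the correct construct's. clarity: fraction of
    the correct map's bands that are in-range and separable from every
    other band — a tie-break favoring panels that are easy to read.
    """
    if not maps_alternatives:
        raise ValueError("need at least one alternative product")
    gel = gel or GelModel()
    disc = sum(
        maps_distinguishable(map_correct, alt, gel) for alt in maps_alternatives
    ) / len(maps_alternatives)
    n = len(map_correct.bands)
    clarity = sum(b.distinguishable for b in map_correct.bands) / n if n else 0.0
    return (disc, clarity)


def select_diagnostic_panel(
    construct: DnaSequence,
    alternatives: list[DnaSequence],
    candidate_enzymes: list[RestrictionEnzyme | str],
    gel: GelModel | None = None,
    max_enzymes: int = 2,
) -> dict:
    """Exhaustive search for the best small diagnostic panel.

    Scores every enzyme combination of size 1..max_enzymes by
    :func:`panel_score`; ties resolve to fewer enzymes, then
    alphabetical order. Refuses ``max_enzymes`` beyond 3 (the search
    is exhaustive by design; larger panels are not gel practice).
    Returns a dict with the chosen panel, its score, and a warning
    when no panel discriminates anything.
    """
    if not candidate_enzymes:
        raise ValueError("no candidate enzymes")
    if max_enzymes > 3:
        raise ValueError("exhaustive panel search supports max_enzymes <= 3")
    if not alternatives:
        raise ValueError("no alternative products to discriminate")
    gel = gel or GelModel()
    enzymes = sorted(
        {(get_enzyme(e) if isinstance(e, str) else e).name for e in candidate_enzymes}
    )
    best = None
    for k in range(1, min(max_enzymes, len(enzymes)) + 1):
        for combo in combinations(enzymes, k):
            mc = restriction_map(construct, list(combo), gel)
            malts = [restriction_map(alt, list(combo), gel) for alt in alternatives]
            score = panel_score(mc, malts, gel)
            key = (score[0], score[1], -k, tuple(reversed(combo)))
            if best is None or _panel_better(key, best[0]):
                best = (key, combo, score, mc)
    _, combo, score, mc = best
    result = {
        "panel": list(combo),
        "score": {"discrimination": score[0], "clarity": score[1]},
        "map": mc,
        "warning": None,
    }
    if score[0] == 0:
        result["warning"] = (
            "no candidate panel distinguishes any alternative; verify by "
            "sequencing instead"
        )
    return result


def _panel_better(key, best_key) -> bool:
    # maximize discrimination, then clarity; then fewer enzymes
    # (-k larger); then alphabetical (reversed tuple compares so that
    # lexicographically smaller combo wins)
    if key[:3] != best_key[:3]:
        return key[:3] > best_key[:3]
    return key[3] > best_key[3]


def misassembly_alternatives(
    plan,
    products: list[AssemblyProduct] | None = None,
) -> list[DnaSequence]:
    """Plausible wrong-colony sequences for a given assembly plan.

    Combines the simulator's enumerated non-target products (if
    supplied) with two canned failure modes: the carrier closing on
    itself, and each single-fragment dropout that can still close a
    circle at a shared address (possible only under address
    collisions, but cheap to check).
    """
    from .gibson_simulator import GibsonParams, simulate_one_pot

    target = plan.predicted_sequence.residues if plan.predicted_sequence else None
    alts: list[DnaSequence] = []
    # parental carrier re-circularization
    carrier_body = plan.carrier.fragment.sequence.residues
    alts.append(DnaSequence(carrier_body, "circular", "alt_carrier_selfclose"))
    # single-fragment dropouts that still close
    frags = plan.fragments
    if len(frags) >= 3:
        for skip in range(len(frags)):
            subset = [f for i, f in enumerate(frags) if i != skip]
            try:
                prods = simulate_one_pot(subset, GibsonParams(require_all_fragments=True))
            except ValueError:
                continue
            for p in prods:
                if p.sequence.is_circular and p.sequence.residues != target:
                    alts.append(
                        DnaSequence(
                            p.sequence.residues,
                            "circular",
                            f"alt_dropout_{frags[skip].sequence.name}",
                        )
                    )
    if products:
        for p in products:
            if p.sequence.is_circular and p.sequence.residues != target:
                alts.append(p.sequence)
    # dedupe by sequence
    seen = set()
    out = []
    for a in alts:
        if a.residues not in seen:
            seen.add(a.residues)
            out.append(a)
    return out


def screening_stats(p_correct: float, k: int) -> float:
    """Probability that all k screened colonies are incorrect: (1-p)^k."""
    if not 0 <= p_correct <= 1:
        raise ValueError("p_correct must lie in [0, 1]")
    if k < 1:
        raise ValueError("k >= 1")
    return (1.0 - p_correct) ** k


def colonies_for_risk(p_correct: float, risk: float) -> int:
    """Smallest k with (1-p)^k <= risk."""
    if not 0 < risk < 1:
        raise ValueError("risk must lie in (0, 1)")
    if p_correct <= 0 or p_correct > 1:
        raise ValueError(
            "unachievable risk: p_correct must lie in (0, 1]"
        )
    if p_correct == 1:
        return 1
    k = math.ceil(math.log(risk) / math.log(1.0 - p_correct))
    return max(k, 1)
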