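"""DNA sequence primitives, restriction enzymes and digestion.

This is the string engine used by every other module: a small
:class:`DnaSequence` container (linear or circular, 0-based half-open
coordinates on the top strand), IUPAC-aware restriction-site search and a
digestion simulator that splits the top strand at the enzymes' cut
positions.

Conventions
-----------
* Coordinates are 0-based, half-open, always on the top strand.
* Circular sequences have a defined origin (index 0) but site searches
  and digestion are rotation-invariant: searches run on the doubled
  sequence and keep hits with start < L.
* Fragment sequences are the top-strand segments between successive
  top-strand cuts, so fragment lengths always sum to the parent length;
  the duplex overhang implied by an enzyme's cut offsets is recorded on
  the fragment end descriptors.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

__all__ = [
    "DnaSequence",
    "RestrictionEnzyme",
    "Fragment",
    "FragmentEnd",
    "Feature",
    "reverse_complement",
    "find_sites",
    "digest",
    "load_enzymes",
    "get_enzyme",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# IUPAC degenerate codes -> set of concrete bases (enzyme sites only).
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class Feature:
    """Annotation on the top strand: 0-based half-open [start, end)."""

    label: str
    start: int
    end: int
    strand: int = 1


@dataclass
class DnaSequence:
    """A named DNA sequence, linear or circular, with simple annotations."""

    residues: str
    topology: str = "linear"
    name: str = "seq"
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        seq = self.residues.upper()
        for i, ch in enumerate(seq):
            if ch not in "ACGT":
                raise ValueError(
                    f"{self.name}: non-ACGT character {ch!r} at position {i}"
                )
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"topology must be linear|circular, got {self.topology!r}")
        self.residues = seq

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def rotated(self, offset: int) -> "DnaSequence":
        """Return the circular sequence re-originated at ``offset``."""
        if not self.is_circular:
            raise ValueError("only circular sequences can be rotated")
        L = len(self)
        offset %= L
        # feature spans are remapped modulo L; a span that comes to
        # straddle the new origin keeps wrapped coordinates
        feats = [
            Feature(f.label, (f.start - offset) % L, (f.end - offset) % L, f.strand)
            for f in self.features
        ]
        return DnaSequence(
            self.residues[offset:] + self.residues[:offset],
            "circular",
            self.name,
            feats,
        )

    def annotate(self, label: str, start: int, end: int, strand: int = 1) -> None:
        self.features.append(Feature(label, start, end, strand))


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction enzyme: IUPAC recognition site and cut offsets.

    ``cut_top`` / ``cut_bottom`` are the positions (relative to site
    start, on top-strand coordinates) of the top- and bottom-strand
    phosphodiester cuts. ``cut_bottom - cut_top`` > 0 means a 5'
    overhang, < 0 a 3' overhang, 0 blunt.
    """

    name: str
    site: str
    cut_top: int
    cut_bottom: int

    def __post_init__(self) -> None:
        site = self.site.upper()
        if len(site) < 4:
            raise ValueError(f"{self.name}: recognition site shorter than 4 bp")
        for ch in site:
            if ch not in IUPAC:
                raise ValueError(f"{self.name}: invalid IUPAC code {ch!r} in site")
        object.__setattr__(self, "site", site)

    @property
    def overhang_length(self) -> int:
        return self.cut_bottom - self.cut_top

    @property
    def is_palindromic(self) -> bool:
        return self.site == self.site.translate(_IUPAC_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class FragmentEnd:
    """Descriptor of one end of a digestion fragment."""

    enzyme: str | None  # None for native (uncut) ends of linear parents
    overhang: str       # duplex overhang sequence on top-strand coordinates
    kind: str           # "5prime" | "3prime" | "blunt" | "native"


@dataclass
class Fragment:
    """A linear digestion product with provenance and end chemistry."""

    sequence: DnaSequence
    left_end: FragmentEnd
    right_end: FragmentEnd
    source: tuple[str, int, int]  # (parent name, start, end) on parent top strand

    def __len__(self) -> int:
        return len(self.sequence)


def reverse_complement(seq: str | DnaSequence) -> str | DnaSequence:
    """Watson-Crick reverse complement (involution).

    Accepts a plain string or a :class:`DnaSequence` (returned as the
    same type; features are dropped for DnaSequence input).
    """
    if isinstance(seq, DnaSequence):
        return DnaSequence(
            seq.residues.translate(_COMPLEMENT)[::-1], seq.topology, seq.name + "_rc"
        )
    s = seq.upper()
    for i, ch in enumerate(s):
        if ch not in "ACGT":
            raise ValueError(f"non-ACGT character {ch!r} at position {i}")
    return s.translate(_COMPLEMENT)[::-1]


def _site_regex(site: str) -> re.Pattern:
    pat = "".join(f"[{IUPAC[c]}]" if len(IUPAC[c]) > 1 else IUPAC[c] for c in site)
    return re.compile(f"(?=({pat}))")  # lookahead: overlapping matches


def iupac_revcomp(site: str) -> str:
    return site.upper().translate(_IUPAC_COMPLEMENT)[::-1]


def find_sites(seq: DnaSequence, enzyme: RestrictionEnzyme) -> list[tuple[int, str]]:
    """All recognition-site occurrences, both strands.

    Returns (position, strand) with position = 0-based start of the
    site footprint on the top strand. Palindromic sites are reported
    once, on '+'. Circular topology wraps across the origin.
    """
    L = len(seq)
    m = len(enzyme.site)
    if L == 0 or m > (2 * L if seq.is_circular else L):
        return []
    text = seq.residues + (seq.residues[: m - 1] if seq.is_circular else "")
    hits: list[tuple[int, str]] = []
    for match in _site_regex(enzyme.site).finditer(text):
        if match.start() < L:
            hits.append((match.start(), "+"))
    if not enzyme.is_palindromic:
        rc = iupac_revcomp(enzyme.site)
        for match in _site_regex(rc).finditer(text):
            if match.start() < L:
                hits.append((match.start(), "-"))
    hits.sort()
    return hits


def _cut_coords(
    seq: DnaSequence, enzymes: Sequence[RestrictionEnzyme]
) -> list[tuple[int, int, str]]:
    """Absolute (top_cut, bottom_cut, enzyme name) for every site.

    For a site on the minus strand the enzyme's offsets apply to the
    bottom strand, so top/bottom swap and count from the site's far end.
    """
    L = len(seq)
    cuts = []
    for enz in enzymes:
        m = len(enz.site)
        for pos, strand in find_sites(seq, enz):
            if strand == "+":
                top, bottom = pos + enz.cut_top, pos + enz.cut_bottom
            else:
                top = pos + m - enz.cut_bottom
                bottom = pos + m - enz.cut_top
            if seq.is_circular:
                cuts.append((top % L, bottom % L, enz.name))
            else:
                if 0 <= top <= L and 0 <= bottom <= L:
                    cuts.append((top, bottom, enz.name))
        # dedupe palindromic double-count is handled by find_sites
    cuts.sort()
    out = []
    for c in cuts:  # identical cut coordinates (isoschizomer panels) collapse
        if not out or (c[0], c[1]) != (out[-1][0], out[-1][1]):
            out.append(c)
    return out


def _end_pair(
    top: int, bottom: int, seq: DnaSequence, enzyme: str
) -> tuple[FragmentEnd, FragmentEnd]:
    """(right end of upstream fragment, left end of downstream fragment)."""
    L = len(seq)
    lo, hi = min(top, bottom), max(top, bottom)
    if seq.is_circular and hi > L:
        ov = (seq.residues * 2)[lo:hi]
    else:
        ov = seq.residues[lo:hi]
    if bottom > top:
        kind = "5prime"
    elif bottom < top:
        kind = "3prime"
    else:
        kind = "blunt"
    return FragmentEnd(enzyme, ov, kind), FragmentEnd(enzyme, ov, kind)


def digest(
    seq: DnaSequence, enzymes: Sequence[RestrictionEnzyme] | RestrictionEnzyme
) -> list[Fragment]:
    """Simulate a complete digest; fragments ordered by position.

    Circular input with k cut positions yields k fragments; linear
    input yields k+1. Fragment top strands partition the parent, so
    lengths are conserved exactly. A circular sequence with no site is
    returned intact with ``left_end.kind == right_end.kind == "uncut"``.
    """
    if isinstance(enzymes, RestrictionEnzyme):
        enzymes = [enzymes]
    L = len(seq)
    if L == 0:
        raise ValueError("cannot digest an empty sequence")
    cuts = _cut_coords(seq, enzymes)

    # Overlapping-cut guard: successive duplex cut footprints must not
    # intersect, or the fragment end chemistry is undefined.
    spans = sorted((min(t, b), max(t, b)) for t, b, _ in cuts)
    for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
        if a2 < b1:
            raise ValueError("overlapping cuts")
    if seq.is_circular and len(spans) >= 2:
        if spans[0][0] + L < spans[-1][1]:
            raise ValueError("overlapping cuts")

    if not cuts:
        if seq.is_circular:
            uncut = FragmentEnd(None, "", "uncut")
            return [
                Fragment(
                    DnaSequence(seq.residues, "linear", seq.name, list(seq.features)),
                    uncut,
                    uncut,
                    (seq.name, 0, L),
                )
            ]
        native = FragmentEnd(None, "", "native")
        return [
            Fragment(
                DnaSequence(seq.residues, "linear", seq.name, list(seq.features)),
                native,
                native,
                (seq.name, 0, L),
            )
        ]

    frags: list[Fragment] = []
    if seq.is_circular:
        doubled = seq.residues * 2
        for i, (top, bottom, enz) in enumerate(cuts):
            ntop, nbottom, nenz = cuts[(i + 1) % len(cuts)]
            start = top
            stop = ntop if ntop > top else ntop + L
            body = doubled[start:stop]
            _, left = _end_pair(top, bottom, seq, enz)
            right, _ = _end_pair(ntop, nbottom, seq, nenz)
            frags.append(
                Fragment(
                    DnaSequence(body, "linear", f"{seq.name}_frag{i}"),
                    left,
                    right,
                    (seq.name, start, stop % L or L),
                )
            )
    else:
        bounds = [0] + [t for t, _, _ in cuts] + [L]
        native = FragmentEnd(None, "", "native")
        for i, (start, stop) in enumerate(zip(bounds, bounds[1:])):
            if stop == start:
                continue
            if i == 0:
                left = native
            else:
                t, b, e = cuts[i - 1]
                _, left = _end_pair(t, b, seq, e)
            if i == len(bounds) - 2:
                right = native
            else:
                t, b, e = cuts[i]
                right, _ = _end_pair(t, b, seq, e)
            frags.append(
                Fragment(
                    DnaSequence(seq.residues[start:stop], "linear", f"{seq.name}_frag{i}"),
                    left,
                    right,
                    (seq.name, start, stop),
                )
            )
    return frags


def load_enzymes() -> dict[str, RestrictionEnzyme]:
    """Bundled enzyme table (REBASE-style site + cut offsets)."""
    table: dict[str, RestrictionEnzyme] = {}
    path = resources.files("unskit.data").joinpath("enzymes.csv")
    with path.open("r", newline="") as fh:
        for row in csv.DictReader(fh):
            table[row["name"]] = RestrictionEnzyme(
                row["name"], row["site"], int(row["cut_top"]), int(row["cut_bottom"])
            )
    return table


_ENZYMES: dict[str, RestrictionEnzyme] | None = None


def get_enzyme(name: str) -> RestrictionEnzyme:
    global _ENZYMES
    if _ENZYMES is None:
        _ENZYMES = load_enzymes()
    try:
        return _ENZYMES[name]
    except KeyError:
        raise KeyError(
            f"unknown enzyme {name!r}; bundled: {sorted(_ENZYMES)}"
        ) from None
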