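# Methods

This note records the models behind each module, the defaults and why
they were chosen, and what the synthetic fixtures do and do not
emulate.

## Sequence engine

Sequences are plain A/C/G/T strings (IUPAC degeneracy is allowed in
enzyme recognition sites only — parts are concrete synthesized DNA)
with 0-based half-open coordinates on the top strand. Circular
sequences keep an arbitrary origin; all site searches run on the
doubled sequence and keep hits starting before L, which makes them
rotation-invariant.

Restriction enzymes are rows of a bundled CSV (name, IUPAC site,
top/bottom cut offsets) seeded with canonical REBASE-style values for
I-SceI (18-bp site, 4-nt 3′ overhang), XbaI, XhoI, FseI, PacI and a
handful of common diagnostic six-cutters; users can construct
additional `RestrictionEnzyme` objects freely. Digestion splits the
top strand at the top-strand cut of every site, so fragment lengths
sum exactly to the parent length; the duplex overhang implied by the
cut offsets is recorded on each fragment end. Exact I-SceI cut offsets
matter only to the length of the flap remnants (9 nt on each side of
a released insert), which the assembly model trims anyway. Cuts whose
duplex footprints intersect raise an error rather than guessing end
chemistry. Methylation sensitivity and partial digestion are out of
scope.

## UNS design

An address set is judged by three numbers, all *contiguous
exact-complementarity lengths* in nucleotides rather than free
energies: the hairpin stem (longest intramolecular stem with a loop of
at least 3 nt), the self-dimer score (longest complementary stretch
between a sequence and its own copy), and the pairwise cross-annealing
score (longest common substring between one member and the reverse
complement of another, maximized over both strands). Exact-match
lengths are deterministic, cheap, directly checkable against
brute-force enumeration, and are the standard first-order proxy for
annealing specificity in overlap design; a thermodynamic scorer could
replace them behind the same interface.

Defaults (all exposed in `DesignConfig`): GC 0.40–0.60, duplex Tm
62–72 °C, hairpin stem ≤5 nt, cross/self score ≤12 nt, homopolymer
≤4 nt, forbidden motifs = the five platform enzyme sites and their
reverse complements. Tm is the nearest-neighbor model with the unified
parameter set as distributed with Biopython, evaluated at 25 nM per
strand and 50 mM Na⁺ with an entropy salt correction; the window was
chosen so that typical random 40-mers in the GC band fall inside it,
making rejection sampling efficient while excluding extremes.

Candidate generation is rejection sampling of uniform random 40-mers —
the simplest unbiased generator. Infeasible configurations fail loudly
with the measured acceptance rate and the filter responsible for most
rejections. Set selection is greedy max-min: seed with the candidate
of lowest self-dimer score, then repeatedly add the candidate whose
worst cross-annealing against the chosen members is smallest, breaking
ties toward the lexicographically smallest sequence. Greedy selection
is not optimal but is reproducible and linear in pool size; exhaustive
max-min selection is exponential and was rejected for that reason. The
last selected member is named UNSX, the distinguished linking address.

## Vector anatomy

Position vectors follow the fixed insert layout I-SceI site / UNS_n /
insulator ×2 / promoter / attB1 scar / gene / attB2 scar / polyA /
UNS_{n+1} / I-SceI site on a backbone. Gateway LR recombination is
modeled as deterministic cassette substitution leaving 25-bp att-scar
spacers: the recombination chemistry contributes nothing to the
addressing logic, only its sequence outcome matters. The polyA is
contributed by the destination layout, not the gene part. The
insulator is any user-supplied part placed in tandem; fixtures use a
250-bp random stand-in since only its presence as sequence affects
assembly.

The carrier circle reads UNSX / backbone / I-SceI site / UNS1 /
linearization site (FseI or PacI). Linearizing it yields a fragment
running UNSX → UNS1, closing the assembly circle, and leaves an
I-SceI site immediately upstream of UNS1 in every assembled circuit.
Adaptor cassettes (XbaI/XhoI-excisable) read UNS_{n+1} / marker /
UNSX; the hierarchical flavor inserts a hand-off UNS and an I-SceI
site before UNSX.

## Hierarchical addressing

A reused module must digest into a piece flanked by UNS1 and UNS2 of
the *next* round while its internal junction addresses stay inert.
Whether the original platform reuses numbered addresses inside modules
or draws from disjoint ranges is an open design choice; this package
makes sub-ranges explicit: one master set is designed, the tail round
addresses from the low slice, the module round renames the high slice
as its UNS2..UNS_{m+1} (both rounds share UNS1 and UNSX), and the
module round's adaptor carries the tail round's UNS2 as its hand-off.
The planner enforces this with a strict sequence-level collision check
— any module-internal address reappearing among a round's addresses is
an error, not a warning, because colliding addresses make the one-pot
outcome ambiguous. Modules occupy position 1–2 only; re-addressing a
module to another slot is not supported.

## One-pot assembly model

The simulator reduces the isothermal reaction to exact terminal
homology: the last `chew_window` (80 nt) of one fragment against the
first `chew_window` of another, in both orientations, keeping the
longest exact match of at least `min_overlap` (20 nt) whose unmatched
terminal residues are each at most `flap_tolerance` (15 nt). The
window models finite exonuclease processivity and is the reason
internal repeats are harmless; the flap tolerance accommodates the
restriction remnants outside the UNSs (≤9 nt for I-SceI) and models
their removal by the polymerase/exonuclease; 40-bp addresses exceed
the minimum overlap by design. No mismatches or gaps are allowed —
UNSs are designed for exact complementarity, and mismatch tolerance
would add parameters with nothing to constrain them.

Products are every distinct cycle in the directed junction graph (each
fragment used at most once, both orientations considered), reported
exhaustively with no kinetic or yield model — this is design
verification, not chemistry. A reaction is `unique_circular` only if
exactly one cycle exists, it uses every fragment, and no fragment end
has two or more partners; an end with multiple partners marks the
reaction `ambiguous`. Product sequences are canonicalized to the
lexicographically least rotation of the lesser strand (Booth's
algorithm), which makes the simulator invariant to fragment input
order and directly comparable with the planner's prediction.

The planner predicts the final sequence by a deliberately different
route — locating each expected address on each fragment by exact
search and splicing in address order. Byte-level agreement of the two
routes on every conflict-free fixture is the framework's central
self-check, exercised up to 12-TU/~50-kb circuits with 50% repeated
parts.

## Bench arithmetic

The protocol sheet uses the defaults of the wet protocol: 70 fmol of
each position vector into its I-SceI digestion, 280 fmol of adaptor
(XbaI+XhoI), 140 fmol of carrier (FseI or PacI), and 7 fmol of every
digested part into the one-pot reaction. Masses follow m[ng] =
fmol × bp × 650 × 10⁻⁶ (650 g/mol per base pair); digestion masses are
quoted on the released fragment length, which understates the parent
vector by its backbone share. The first assembly round defaults to the
Kan adaptor; alternation is relative to whatever the previous round
used.

## Diagnostics

The gel is a resolvable window (250–20,000 bp) plus a ratio rule: two
bands separate when larger/smaller ≥ 1.08. Two digests are
distinguishable when their visible band patterns differ in apparent
band count or any aligned pair separates. A panel's score is the pair
(fraction of alternative products distinguished, fraction of correct
bands cleanly readable), compared lexicographically. Panel search is
exhaustive up to 3 enzymes and refuses to go further rather than
approximate; candidate lists are small and determinism is preferred.
Alternative products come from the simulator's own enumerated
non-target closures plus two canned modes (carrier self-closure and
single-fragment dropouts that still close). Band migration physics,
densitometry and gel rendering are out of scope.

Colony screening is Bernoulli: with per-colony success probability p,
all k picks are wrong with probability (1−p)^k; two colonies keep that
risk under 10% whenever p > 1 − √0.1 ≈ 0.684.

## Synthetic fixtures

`make_fixture_library` emulates a realistic part universe: promoters
0.2–1.5 kb, genes 0.7–3 kb, polyA ~0.2–0.35 kb, insulator 250 bp,
markers 0.8–1.3 kb, carrier backbones 2–8 kb, with an optional
fraction of TUs re-using earlier promoter/gene pairs to exercise
repetitive circuits. Part sequences are uniform random DNA scrubbed of
the platform's five enzyme sites on both strands; parts draw from a
random stream separate from the address sampler's so they can never
reproduce an address by construction. Everything is deterministic
given the seed.

What passing fixtures show: the addressing, planning and junction
logic are exact on sequences with realistic lengths, repeats and site
content. What they do not show: real parts have biased composition,
long internal homopolymers and genuine secondary structure, so
wet-lab annealing efficiency, assembly yield and colony-correctness
rates are outside what these simulations can certify.

## Numerical and degenerate-input choices

Tie-breaks are fixed everywhere (documented in docstrings): greedy
selection prefers the lexicographically smallest sequence; terminal
homology prefers longest match, then smallest flap total; panel search
prefers higher score, fewer enzymes, alphabetical order. A circular
sequence with no site is returned intact and flagged uncut. An
assembly with no closure reports its longest linear path as
`incomplete`. Designs that exhaust their candidate budget or pool
raise errors carrying the measured acceptance rate or achieved set
size. Problem sizes in the test-suite and acceptance runs (candidate
pools of 24–120, circuits to 12 TUs) were chosen as the smallest
scales that still exercise every code path at the framework's stated
operating range.
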