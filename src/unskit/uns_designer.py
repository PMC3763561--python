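"""Design of orthogonal 40-bp unique nucleotide sequences (UNSs).

UNSs are the address blocks placed at transcription-unit boundaries:
during an isothermal (Gibson) one-pot reaction the exonuclease exposes
them as single strands and complementary UNSs on adjacent fragments
anneal, directing fragment order. A good UNS set therefore needs

* strong intended pairing: each UNS anneals to its own complement
  (40 bp of perfect duplex, well above the reaction's minimum overlap);
* weak unintended pairing: low cross-annealing between distinct
  members (and their reverse complements);
* little secondary structure: no long hairpin stems when
  single-stranded, no forbidden restriction sites, no homopolymer runs.

Scores are contiguous exact-complementarity lengths in nucleotides, not
free energies: they are deterministic, easy to audit and the standard
first-order proxy for annealing specificity. A thermodynamic scorer can
be slotted in behind the same interface.

Candidate generation is rejection sampling of uniform random 40-mers;
set selection is greedy max-min with documented tie-breaks, so a given
seed and config always reproduce the same set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.SeqUtils import MeltingTemp as _mt

from .report import ValidationCheck, ValidationReport
from .seqcore import reverse_complement, get_enzyme, iupac_revcomp

__all__ = [
    "DesignConfig",
    "UnsCandidate",
    "UnsSet",
    "DesignError",
    "melting_temperature",
    "hairpin_stem",
    "cross_anneal_score",
    "self_dimer_score",
    "generate_candidates",
    "select_orthogonal_set",
    "validate_set",
]

UNS_LENGTH = 40

# Duplex Tm model constants (nearest-neighbor, SantaLucia unified
# parameters as bundled with Biopython): 25 nM each strand, 50 mM Na+,
# entropy-based salt correction.
TM_DNAC1_NM = 25.0
TM_DNAC2_NM = 25.0
TM_NA_MM = 50.0
_TM_SALTCORR = 5


class DesignError(RuntimeError):
    """Raised when the sampler or selector cannot satisfy the config."""


def _default_forbidden() -> list[str]:
    sites = []
    for name in ("I-SceI", "XbaI", "XhoI", "FseI", "PacI"):
        s = get_enzyme(name).site
        sites.append(s)
        rc = iupac_revcomp(s)
        if rc != s:
            sites.append(rc)
    return sites


@dataclass
class DesignConfig:
    """Free parameters of UNS design, all exposed because the address
    system itself fixes only the 40-bp length."""

    gc_min: float = 0.40
    gc_max: float = 0.60
    tm_min: float = 62.0
    tm_max: float = 72.0
    threshold_hairpin: int = 5   # nt, max intramolecular stem
    threshold_cross: int = 12    # nt, max cross-annealing stretch
    homopolymer_max: int = 4     # nt, longest single-base run
    forbidden_motifs: list[str] = field(default_factory=_default_forbidden)
    rng_seed: int = 0
    n_candidates: int = 5000
    max_attempt_factor: int = 200  # attempt budget = factor * n_candidates

    def __post_init__(self) -> None:
        if not (0 <= self.gc_min < self.gc_max <= 1):
            raise ValueError("need 0 <= gc_min < gc_max <= 1")
        if self.threshold_hairpin >= UNS_LENGTH or self.threshold_cross >= UNS_LENGTH:
            raise ValueError("thresholds must be < 40")


@dataclass(frozen=True)
class UnsCandidate:
    sequence: str
    gc_fraction: float
    tm_celsius: float
    hairpin_stem: int
    self_dimer: int


@dataclass
class UnsSet:
    """Ordered, named set UNS1..UNSn plus the linking member UNSX.

    ``cross_matrix[i][j]`` is the worst cross-annealing score between
    members i and j considering both strands of each.
    """

    members: dict[str, str]
    cross_matrix: np.ndarray
    thresholds: DesignConfig

    @property
    def names(self) -> list[str]:
        return list(self.members)

    def numbered(self) -> list[str]:
        return [n for n in self.members if n != "UNSX"]

    def __getitem__(self, name: str) -> str:
        return self.members[name]

    def __len__(self) -> int:
        return len(self.members)

    def subset_view(self, numbered_sources: list[str]) -> "UnsSet":
        """Re-address a slice of this set as UNS1..UNSk (+ shared UNSX).

        Hierarchical rounds draw their numbered addresses from disjoint
        slices of one master set so that a module's internal junction
        sequences can never collide with the addresses of a later
        round. The view renames ``numbered_sources[i]`` to ``UNS{i+1}``
        and keeps UNSX.
        """
        members = {
            f"UNS{i + 1}": self.members[src]
            for i, src in enumerate(numbered_sources)
        }
        members["UNSX"] = self.members["UNSX"]
        view = UnsSet(members, np.zeros((0, 0), dtype=int), self.thresholds)
        view.cross_matrix = _cross_matrix(list(members.values()))
        return view


def melting_temperature(seq: str) -> float:
    """Nearest-neighbor duplex melting temperature in Celsius.

    Perfect-match duplex of ``seq`` with its complement at the module
    constants (25 nM strands, 50 mM Na+). Monotone non-decreasing in GC
    content at fixed length; symmetric under reverse complement.
    """
    if len(seq) < 8:
        raise ValueError("melting_temperature needs length >= 8")
    return float(
        _mt.Tm_NN(
            seq,
            dnac1=TM_DNAC1_NM,
            dnac2=TM_DNAC2_NM,
            Na=TM_NA_MM,
            saltcorr=_TM_SALTCORR,
        )
    )


_PAIR = {"A": "T", "T": "A", "C": "G", "G": "C"}


def hairpin_stem(seq: str) -> int:
    """Longest contiguous intramolecular stem with loop >= 3 nt.

    A stem of length k pairs positions a..a+k-1 with j-t for the t-th
    stem base, i.e. base i pairs base j on the antidiagonal i+j = const.
    Runs along antidiagonals are found by dynamic programming in
    O(L^2); the innermost pair must leave a loop of >= 3 unpaired
    bases. Returns 0 when no stem of length >= 2 exists.
    """
    s = seq.upper()
    L = len(s)
    if L < 7:  # 2-bp stem + 3-nt loop needs 7 bases
        return 0
    # ext[i][j] = length of complementary run pairing (i,j),(i+1,j-1),...
    best = 0
    # iterate i descending so ext(i+1, j-1) is available
    ext = [[0] * L for _ in range(L)]
    for i in range(L - 1, -1, -1):
        for j in range(L - 1, i, -1):
            if _PAIR[s[i]] == s[j]:
                inner = ext[i + 1][j - 1] if i + 1 <= j - 1 else 0
                ext[i][j] = 1 + inner
    for i in range(L):
        for j in range(i + 5, L):  # need at least k=1 + loop 3
            run = ext[i][j]
            if run == 0:
                continue
            # stem limited so innermost pair leaves loop >= 3:
            # loop = j - i - 2k + 1 >= 3  =>  k <= (j - i - 2) // 2
            k = min(run, (j - i - 2) // 2)
            if k > best:
                best = k
    return best if best >= 2 else 0


def _longest_common_substring(a: str, b: str) -> int:
    """Classic O(|a||b|) DP, lengths only."""
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    best = 0
    for ca in a:
        cur = [0] * (len(b) + 1)
        for j, cb in enumerate(b, 1):
            if ca == cb:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


def cross_anneal_score(a: str, b: str) -> int:
    """Longest contiguous duplex formable between a and b (nt).

    Equals the longest common substring between ``a`` and the reverse
    complement of ``b``; symmetric in its arguments. The intended
    pairing of a UNS with its own complement scores the full length.
    """
    if not a or not b:
        raise ValueError("cross_anneal_score needs non-empty sequences")
    return _longest_common_substring(a.upper(), reverse_complement(b))


def self_dimer_score(seq: str) -> int:
    """Longest complementary stretch between a sequence and its own copy."""
    return cross_anneal_score(seq, seq)


def _homopolymer_run(seq: str) -> int:
    best = run = 1
    for x, y in zip(seq, seq[1:]):
        run = run + 1 if x == y else 1
        best = max(best, run)
    return best


_FILTER_ORDER = (
    "gc", "homopolymer", "forbidden_motif", "hairpin", "self_dimer", "tm"
)


def _passes(seq: str, config: DesignConfig) -> tuple[UnsCandidate | None, str | None]:
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    if not (config.gc_min <= gc <= config.gc_max):
        return None, "gc"
    if _homopolymer_run(seq) > config.homopolymer_max:
        return None, "homopolymer"
    rc = reverse_complement(seq)
    for motif in config.forbidden_motifs:
        if motif in seq or motif in rc:
            return None, "forbidden_motif"
    hp = hairpin_stem(seq)
    if hp > config.threshold_hairpin:
        return None, "hairpin"
    sd = self_dimer_score(seq)
    if sd > config.threshold_cross:
        return None, "self_dimer"
    tm = melting_temperature(seq)
    if not (config.tm_min <= tm <= config.tm_max):
        return None, "tm"
    return UnsCandidate(seq, gc, tm, hp, sd), None


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def generate_candidates(config: DesignConfig) -> list[UnsCandidate]:
    """Rejection-sample 40-mers until ``n_candidates`` pass all filters.

    Deterministic for a given ``rng_seed``. If the attempt budget
    (``max_attempt_factor * n_candidates`` draws) is exhausted first, a
    :class:`DesignError` reports the acceptance rate and the filter
    that rejected most draws, so infeasible configs fail loudly.
    """
    rng = np.random.Generator(np.random.PCG64(config.rng_seed))
    budget = config.max_attempt_factor * config.n_candidates
    out: list[UnsCandidate] = []
    seen: set[str] = set()
    rejections = {name: 0 for name in _FILTER_ORDER}
    attempts = 0
    while len(out) < config.n_candidates and attempts < budget:
        attempts += 1
        seq = _BASES[rng.integers(0, 4, UNS_LENGTH)].tobytes().decode()
        if seq in seen:
            continue
        cand, failed = _passes(seq, config)
        if cand is None:
            rejections[failed] += 1
            continue
        seen.add(seq)
        out.append(cand)
    if len(out) < config.n_candidates:
        worst = max(rejections, key=lambda k: rejections[k])
        raise DesignError(
            f"candidate generation exhausted {attempts} attempts with "
            f"{len(out)}/{config.n_candidates} accepted "
            f"(acceptance rate {len(out)/max(attempts,1):.3f}); "
            f"tightest filter: {worst} ({rejections[worst]} rejections)"
        )
    return out


def _pair_cross(a: str, b: str) -> int:
    """Worst cross-annealing between two members, either strand of each.

    cross(a, rc(b)) reduces to the longest common substring of a and b,
    so both duplex geometries are covered by two DP calls.
    """
    return max(cross_anneal_score(a, b), _longest_common_substring(a, b.upper()))


def _cross_matrix(seqs: list[str]) -> np.ndarray:
    n = len(seqs)
    m = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i, n):
            v = self_dimer_score(seqs[i]) if i == j else _pair_cross(seqs[i], seqs[j])
            m[i, j] = m[j, i] = v
    return m


def select_orthogonal_set(
    candidates: list[UnsCandidate], n: int, config: DesignConfig
) -> UnsSet:
    """Greedy max-min selection of n numbered members plus UNSX.

    Seeds with the candidate of lowest self-dimer score, then
    repeatedly adds the candidate whose worst cross-annealing score
    against every chosen member (both strands) is smallest, skipping
    candidates that would exceed ``threshold_cross``. Ties break to the
    lexicographically smallest sequence, so the result is a pure
    function of the candidate list order and content.
    """
    if n < 2:
        raise ValueError("need n >= 2 numbered members")
    want = n + 1  # numbered 1..n plus X
    pool = list(candidates)
    if not pool:
        raise DesignError("empty candidate pool")
    chosen: list[str] = []
    seed = min(pool, key=lambda c: (c.self_dimer, c.sequence))
    chosen.append(seed.sequence)
    pool = [c for c in pool if c.sequence != seed.sequence]
    # worst cross score of each pool candidate against the chosen set,
    # updated incrementally as members are added
    worst_vs_chosen = {c.sequence: _pair_cross(c.sequence, seed.sequence) for c in pool}
    while len(chosen) < want:
        best_seq = None
        best_key = None
        for c in pool:
            worst = worst_vs_chosen[c.sequence]
            if worst > config.threshold_cross:
                continue
            key = (worst, c.sequence)
            if best_key is None or key < best_key:
                best_key = key
                best_seq = c.sequence
        if best_seq is None:
            raise DesignError(
                f"candidate pool exhausted at {len(chosen)}/{want} members "
                f"under threshold_cross={config.threshold_cross}"
            )
        chosen.append(best_seq)
        pool = [c for c in pool if c.sequence != best_seq]
        for c in pool:
            v = _pair_cross(c.sequence, best_seq)
            if v > worst_vs_chosen[c.sequence]:
                worst_vs_chosen[c.sequence] = v
    names = [f"UNS{i + 1}" for i in range(n)] + ["UNSX"]
    members = dict(zip(names, chosen))
    return UnsSet(members, _cross_matrix(chosen), config)


def validate_set(s: UnsSet, config: DesignConfig) -> ValidationReport:
    """Recompute every per-sequence and pairwise criterion from scratch."""
    checks: list[ValidationCheck] = []
    names = s.names
    seqs = [s[m] for m in names]

    bad_len = [n for n, q in zip(names, seqs) if len(q) != UNS_LENGTH]
    checks.append(
        ValidationCheck("length", not bad_len, f"offenders: {bad_len}" if bad_len else "all 40 bp")
    )
    checks.append(
        ValidationCheck(
            "has_UNSX", "UNSX" in names, "UNSX present" if "UNSX" in names else "UNSX missing"
        )
    )
    dup = len(set(seqs)) != len(seqs)
    checks.append(ValidationCheck("distinct", not dup, "duplicate member" if dup else "all distinct"))

    per_seq_fail = []
    for name, q in zip(names, seqs):
        cand, failed = _passes(q, config)
        if failed is not None:
            per_seq_fail.append((name, failed))
    checks.append(
        ValidationCheck(
            "per_sequence_filters",
            not per_seq_fail,
            f"offenders: {per_seq_fail}" if per_seq_fail else "gc/homopolymer/motif/hairpin/self-dimer/tm all pass",
        )
    )

    worst_pair = None
    worst = -1
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            v = _pair_cross(seqs[i], seqs[j])
            if v > worst:
                worst, worst_pair = v, (names[i], names[j])
    ok = worst <= config.threshold_cross
    checks.append(
        ValidationCheck(
            "orthogonality",
            ok,
            f"worst pair {worst_pair} scores {worst} (threshold {config.threshold_cross})",
        )
    )
    return ValidationReport(checks)
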