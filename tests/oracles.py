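"""Independent brute-force oracles the tests compare the package against.

Everything here is deliberately naive — O(L*m) scans, O(L^3)
enumerations, permutation searches — and shares no code with the
implementation it checks.
"""

from __future__ import annotations

import math

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}


def revcomp(s: str) -> str:
    return "".join(COMPLEMENT[c] for c in reversed(s))


def iupac_match(text: str, site: str, at: int) -> bool:
    if at + len(site) > len(text):
        return False
    return all(text[at + i] in IUPAC[c] for i, c in enumerate(site))


def scan_sites(seq: str, site: str, circular: bool) -> list[tuple[int, str]]:
    """O(L*m) brute-force site scan, both strands, palindromes once."""
    L = len(seq)
    text = seq + seq[: len(site) - 1] if circular else seq
    hits = []
    for i in range(min(L, len(text))):
        if iupac_match(text, site, i):
            hits.append((i, "+"))
    rc = "".join(
        {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "S": "S",
         "W": "W", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D",
         "N": "N"}[c]
        for c in reversed(site)
    )
    if rc != site:
        for i in range(min(L, len(text))):
            if iupac_match(text, rc, i):
                hits.append((i, "-"))
    return sorted(hits)


def hairpin_brute(seq: str) -> int:
    """O(L^3): try every (stem start a, stem start b, length k).

    A stem of length k pairs seq[a..a+k) with seq[b..b+k) read 3'->5':
    seq[a+t] must complement seq[b+k-1-t]; the loop between the arms,
    seq[a+k..b), must hold >= 3 unpaired bases.
    """
    L = len(seq)
    best = 0
    for a in range(L):
        for b in range(a + 1, L):
            for k in range(2, min(b - a, L - b) + 1):
                if b - (a + k) < 3:
                    break
                ok = all(
                    COMPLEMENT[seq[a + t]] == seq[b + k - 1 - t] for t in range(k)
                )
                if ok and k > best:
                    best = k
    return best


def lcs_substring_brute(a: str, b: str) -> int:
    """Longest common substring by substring-set enumeration."""
    best = 0
    subs = set()
    for i in range(len(a)):
        for j in range(i + 1, len(a) + 1):
            subs.add(a[i:j])
    for i in range(len(b)):
        for j in range(i + 1, len(b) + 1):
            if b[i:j] in subs and j - i > best:
                best = j - i
    return best


def cross_anneal_brute(a: str, b: str) -> int:
    return lcs_substring_brute(a, revcomp(b))


def terminal_match_brute(a: str, b: str, window: int, flap: int, min_k: int):
    """Best terminal overlap by trying every (i, j, k) explicitly."""
    best = None
    for i in range(max(0, len(a) - window), len(a)):
        for j in range(0, min(window, len(b))):
            k = 0
            while i + k < len(a) and j + k < len(b) and a[i + k] == b[j + k]:
                k += 1
            # trim k so the match stays inside both windows
            k = min(k, len(a) - i, window - j)
            if k < min_k:
                continue
            if len(a) - (i + k) <= flap and j <= flap:
                if best is None or k > best:
                    best = k
    return best


# --- nearest-neighbor Tm oracle --------------------------------------

NN_UNIFIED = {
    "AA": (-7.6, -21.3), "TT": (-7.6, -21.3),
    "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}


def tm_nn_brute(seq: str, dnac1=25e-9, dnac2=25e-9, na=0.05) -> float:
    """Hand-summed unified NN duplex Tm with entropy salt correction."""
    dh, ds = 0.2, -5.7
    for term in (seq[0], seq[-1]):
        if term in "AT":
            dh += 2.2
            ds += 6.9
    for i in range(len(seq) - 1):
        h, s = NN_UNIFIED[seq[i : i + 2]]
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * math.log(na)
    return dh * 1000.0 / (ds + 1.987 * math.log(dnac1 - dnac2 / 2.0)) - 273.15


# --- exhaustive one-pot assembly oracle --------------------------------

def assemble_brute(frag_seqs: dict[str, str], window: int, flap: int, min_k: int):
    """All circular closures by trying fragment orders and orientations.

    Returns the set of canonical product strings. Prunes prefixes whose
    last junction already fails, so 7-8 fragments stay tractable.
    """
    ids = sorted(frag_seqs)
    oriented = {}
    for fid, s in frag_seqs.items():
        oriented[(fid, "+")] = s
        oriented[(fid, "-")] = revcomp(s)

    def junction(x, y):
        return terminal_match_brute(oriented[x], oriented[y], window, flap, min_k)

    products = set()

    def extend(path, used):
        last = path[-1]
        for fid in ids:
            if fid in used:
                continue
            for o in "+-":
                node = (fid, o)
                if junction(last, node) is None:
                    continue
                path.append(node)
                used.add(fid)
                close = junction(node, path[0])
                if close is not None:
                    products.add(splice(path))
                extend(path, used)
                used.remove(fid)
                path.pop()

    def splice(path):
        seq = []
        m = len(path)
        for idx, node in enumerate(path):
            s = oriented[node]
            nxt = path[(idx + 1) % m]
            prv = path[idx - 1]
            # recompute junction coordinates explicitly
            kin = _match_coords(oriented[prv], s, window, flap, min_k)
            kout = _match_coords(s, oriented[nxt], window, flap, min_k)
            seq.append(s[kin[2] : kout[1]])
        return canon_circ("".join(seq))

    # enumerate cycles rooted at each fragment that is minimal in its cycle
    for ridx, root in enumerate(ids):
        path = [(root, "+")]
        used = {root}

        def extend_min(path, used):
            last = path[-1]
            for fid in ids[ridx + 1 :]:
                if fid in used:
                    continue
                for o in "+-":
                    node = (fid, o)
                    if junction(last, node) is None:
                        continue
                    path.append(node)
                    used.add(fid)
                    if junction(node, path[0]) is not None and len(path) > 1:
                        products.add(splice(path))
                    extend_min(path, used)
                    used.remove(fid)
                    path.pop()

        extend_min(path, used)
    return products


def _match_coords(a: str, b: str, window: int, flap: int, min_k: int):
    """(k, match start in a, match start in b) of the best terminal
    match, with the same tie-break as the implementation: longest k,
    then smallest flap total, then smallest j."""
    best = None
    best_key = None
    for i in range(max(0, len(a) - window), len(a)):
        for j in range(0, min(window, len(b))):
            k = 0
            while i + k < len(a) and j + k < len(b) and a[i + k] == b[j + k]:
                k += 1
            k = min(k, len(a) - i, window - j)
            if k < min_k:
                continue
            flap_a = len(a) - (i + k)
            if flap_a <= flap and j <= flap:
                key = (-k, flap_a + j, j)
                if best_key is None or key < best_key:
                    best_key = key
                    best = (k, i, j)
    return best


def canon_circ(s: str) -> str:
    rots = [s[i:] + s[:i] for i in range(len(s))]
    r = revcomp(s)
    rots += [r[i:] + r[:i] for i in range(len(r))]
    return min(rots)
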