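"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives a quantity with the most naive correct
algorithm available (full dynamic programming with explicit loops,
exhaustive enumeration) and is kept free of any package internals
beyond shared constants of the problem statement (scoring scheme,
IUPAC code sets).
"""

from __future__ import annotations

import itertools
from collections import Counter

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

MATCH, MISMATCH, GAP = 1, -1, -2


def _compat(a: str, b: str) -> bool:
    return bool(set(IUPAC[a]) & set(IUPAC[b]))


def dp_identity(a: str, b: str) -> float:
    """Query-in-target semi-global identity by explicit-loop DP.

    The shorter sequence (query, canonical pair order) is aligned in
    full; the target's terminal overhangs are free and excluded.  Start
    cell maximises (score, j) over the last row; traceback prefers
    diagonal, then up, then left, and a query prefix hanging off the
    target start counts as penalised gap columns.
    """
    a, b = a.upper(), b.upper()
    if (len(a), a) > (len(b), b):  # canonical pair order (symmetry)
        a, b = b, a
    n, m = len(a), len(b)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        H[i][0] = GAP * i
        for j in range(1, m + 1):
            s = MATCH if _compat(a[i - 1], b[j - 1]) else MISMATCH
            H[i][j] = max(H[i - 1][j - 1] + s,
                          H[i - 1][j] + GAP,
                          H[i][j - 1] + GAP)
    best = (H[n][0], 0)
    for j in range(m + 1):
        if (H[n][j], j) >= best:
            best = (H[n][j], j)
    _, j = best
    i = n
    matches = columns = 0
    while i > 0:
        if j == 0:
            columns += i
            break
        compat = _compat(a[i - 1], b[j - 1])
        s = MATCH if compat else MISMATCH
        if H[i][j] == H[i - 1][j - 1] + s:
            matches += compat
            columns += 1
            i -= 1
            j -= 1
        elif H[i][j] == H[i - 1][j] + GAP:
            columns += 1
            i -= 1
        else:
            columns += 1
            j -= 1
    return 100.0 * matches / columns if columns else 0.0


def exhaustive_best_accession(query: str, db: dict[str, str]) -> tuple[str, float, int]:
    """All-pairs scan: best accession, identity, tie count."""
    idents = {acc: dp_identity(query, seq) for acc, seq in db.items()}
    best = max(idents.values())
    ties = sorted(acc for acc, v in idents.items() if abs(v - best) <= 1e-9)
    return ties[0], best, len(ties)


def _rc(seq: str) -> str:
    comp = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
    return seq.translate(comp)[::-1]


def exhaustive_min_ows(primer: str, template: str,
                       non3_mm: float = 0.4, three_mm: float = 1.0,
                       non3_gap: float = 1.0, three_gap: float = 3.0,
                       three_len: int = 5,
                       both_strands: bool = True) -> float:
    """Minimum OWS over all offsets, single-gap variants and strands."""
    p = primer.upper()
    L = len(p)

    def mm_weight(idx: int) -> float:
        return three_mm if idx >= L - three_len else non3_mm

    def gap_weight(pos: int) -> float:
        return three_gap if pos >= L - three_len else non3_gap

    def scan(t: str) -> float:
        best = float("inf")
        # ungapped
        for o in range(len(t) - L + 1):
            s = sum(mm_weight(i) for i in range(L)
                    if not _compat(p[i], t[o + i]))
            best = min(best, s)
        # primer base k unpaired (template span L-1)
        for o in range(len(t) - (L - 1) + 1):
            for k in range(L):
                s = gap_weight(k)
                for i in range(L):
                    if i == k:
                        continue
                    ti = o + i if i < k else o + i - 1
                    if not _compat(p[i], t[ti]):
                        s += mm_weight(i)
                best = min(best, s)
        # skipped template base between primer k-1 and k (span L+1)
        for o in range(len(t) - (L + 1) + 1):
            for k in range(1, L):
                s = gap_weight(k)
                for i in range(L):
                    ti = o + i if i < k else o + i + 1
                    if not _compat(p[i], t[ti]):
                        s += mm_weight(i)
                best = min(best, s)
        return best

    strands = [template.upper()]
    if both_strands:
        strands.append(_rc(template.upper()))
    return min(scan(t) for t in strands)


def permanova_f(d: list[list[float]], labels: list) -> float:
    """Pseudo-F from first principles with explicit loops."""
    n = len(labels)
    groups = sorted(set(labels))
    a = len(groups)
    ss_t = sum(d[i][j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_w = 0.0
    for g in groups:
        idx = [i for i in range(n) if labels[i] == g]
        ss_w += sum(d[i][j] ** 2 for i in idx for j in idx if i < j) / len(idx)
    ss_a = ss_t - ss_w
    return (ss_a / (a - 1)) / (ss_w / (n - a))


def permanova_exact_p(d: list[list[float]], labels: list) -> float:
    """Exact tail fraction over all distinct label arrangements."""
    f_obs = permanova_f(d, labels)
    seen = set()
    tail = total = 0
    for perm in itertools.permutations(labels):
        if perm in seen:
            continue
        seen.add(perm)
        total += 1
        if permanova_f(d, list(perm)) >= f_obs - 1e-12:
            tail += 1
    return tail / total


def upset_counts(core_sets: dict[str, set]) -> Counter:
    """Exclusive intersection patterns by per-taxon enumeration."""
    out: Counter = Counter()
    union = set().union(*core_sets.values())
    for taxon in union:
        pattern = frozenset(g for g, s in core_sets.items() if taxon in s)
        out[pattern] += 1
    return out
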