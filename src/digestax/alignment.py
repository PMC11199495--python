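"""Pairwise nucleotide identity from end-gap-free (semi-global) alignment.

Percent identity between 16S rRNA sequences is the quantity on which the
whole reference-expansion pipeline rests: sequence-novelty ranking,
deduplication and placeholder-taxonomy clustering all compare identities
against fixed per-rank thresholds.  Identity is defined here as

    100 x matches / alignment columns over the aligned span

of an optimal semi-global alignment in which the shorter sequence (the
query) is aligned in full while the longer sequence's terminal
overhangs are free and excluded from the span.  Internal gaps count as
non-match columns, and two IUPAC codes count as a match when their
nucleotide sets intersect.  Covering the query in full is what makes
the measure usable for database search: without it, two unrelated
sequences would score a spurious perfect identity on any short chance
overlap of their ends.

The dynamic program uses linear gap costs (match +1, mismatch -1, gap
-2) with a deterministic traceback (diagonal > up > left; the start cell
maximises score, then row index, then column index), so identical inputs
always yield identical identities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError

MATCH_SCORE = 1
MISMATCH_SCORE = -1
GAP_SCORE = -2

#: Canonical IUPAC nucleotide alphabet (order fixed; indices used below).
ALPHABET = "ACGTRYSWKMBDHVN"

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"),
    "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"),
    "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

_CHAR_INDEX = {c: i for i, c in enumerate(ALPHABET)}

#: compat[i, j] is True iff the code sets of ALPHABET[i] and ALPHABET[j]
#: intersect (the permissive matching rule shared with primer scoring).
COMPAT = np.array(
    [[bool(IUPAC_SETS[a] & IUPAC_SETS[b]) for b in ALPHABET]
     for a in ALPHABET], dtype=bool)


def reverse_complement(seq: str) -> str:
    """Reverse-complement an IUPAC nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str, what: str = "sequence") -> np.ndarray:
    """Validate and map an IUPAC string to alphabet indices.

    Input is uppercased first; an empty string or a character outside
    the IUPAC alphabet raises :class:`InvalidInputError`.
    """
    seq = seq.upper()
    if not seq:
        raise InvalidInputError(f"empty {what}")
    try:
        return np.array([_CHAR_INDEX[c] for c in seq], dtype=np.intp)
    except KeyError as exc:
        raise InvalidInputError(
            f"non-IUPAC character {exc.args[0]!r} in {what}") from None


@dataclass(frozen=True)
class AlignmentIdentity:
    """Identity decomposition of the best end-gap-free alignment."""

    identity: float        # percent in [0, 100]
    matches: int
    columns: int           # matches + mismatches + internal gap columns
    score: int


def _dp_matrix(ai: np.ndarray, bi: np.ndarray) -> np.ndarray:
    """Score matrix H of shape (len(a)+1, len(b)+1).

    Query-in-target semi-global: end gaps are free for the target
    (H[0, j] = 0) but the query must be consumed in full (H[i, 0]
    penalises a hanging query prefix).  The in-row dependency
    H[i,j] = max(..., H[i,j-1] + g) is resolved with a running-maximum
    transform (subtract g*j, cumulative max, add g*j back).
    """
    n, m = len(ai), len(bi)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    jg = GAP_SCORE * np.arange(m + 1, dtype=np.int32)
    for i in range(1, n + 1):
        sub = np.where(COMPAT[ai[i - 1], bi], MATCH_SCORE, MISMATCH_SCORE)
        cand = np.maximum(H[i - 1, :-1] + sub, H[i - 1, 1:] + GAP_SCORE)
        d = np.empty(m + 1, dtype=np.int32)
        d[0] = GAP_SCORE * i  # query prefix hanging off the target start
        d[1:] = cand
        H[i] = np.maximum.accumulate(d - jg) + jg
    return H


def _start_cell(H: np.ndarray) -> tuple[int, int]:
    """Best cell on the last row (query consumed): max score, then j."""
    n = H.shape[0] - 1
    row = H[n, :]
    j = int(np.flatnonzero(row == row.max())[-1])
    return n, j


def align_identity(seq_a: str, seq_b: str) -> AlignmentIdentity:
    """Optimal semi-global alignment identity between two sequences.

    The pair is canonically ordered (by length, then lexicographically)
    before aligning, so the reported identity is exactly symmetric even
    when several co-optimal alignments with different match counts
    exist.
    """
    if (len(seq_a), seq_a) > (len(seq_b), seq_b):
        seq_a, seq_b = seq_b, seq_a
    ai = encode(seq_a, "first sequence")
    bi = encode(seq_b, "second sequence")
    H = _dp_matrix(ai, bi)
    i, j = _start_cell(H)
    score = int(H[i, j])
    matches = columns = 0
    # Traceback preference: diagonal, then up (gap in b), then left.
    # The whole query is covered: a query prefix hanging off the target
    # start (j = 0) contributes penalised gap columns.
    while i > 0:
        if j == 0:
            columns += i
            break
        compat = COMPAT[ai[i - 1], bi[j - 1]]
        s = MATCH_SCORE if compat else MISMATCH_SCORE
        if H[i, j] == H[i - 1, j - 1] + s:
            matches += int(compat)
            columns += 1
            i -= 1
            j -= 1
        elif H[i, j] == H[i - 1, j] + GAP_SCORE:
            columns += 1
            i -= 1
        else:
            columns += 1
            j -= 1
    identity = 100.0 * matches / columns if columns else 0.0
    return AlignmentIdentity(identity, matches, columns, score)


def percent_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity in [0, 100] between two nucleotide sequences.

    Symmetric up to alignment tie-breaking; 100.0 iff the two sequences
    are IUPAC-compatible over the whole aligned span with no internal
    gaps.
    """
    return align_identity(seq_a, seq_b).identity


def sequences_equivalent(seq_a: str, seq_b: str) -> bool:
    """True iff equal length and position-wise IUPAC-compatible.

    This is exactly the condition under which two equal-length sequences
    reach 100% semi-global identity (any internal gap would add a
    non-match column), and is the duplicate criterion used when merging
    reference databases.
    """
    a = seq_a.upper()
    b = seq_b.upper()
    if len(a) != len(b):
        return False
    if a == b:
        return True
    ai = encode(a)
    bi = encode(b)
    return bool(COMPAT[ai, bi].all())
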