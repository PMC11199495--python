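"""In-silico PCR primer evaluation with 3'-weighted mismatch scoring.

Each primer is scored against every position of a template with a
weighted sum of mismatches and gaps, penalising errors in the 3'
region (the last bases of the primer, where polymerase extension
starts) more heavily.  The minimum score over all binding positions is
the primer's overall weighted score (OWS) for that template:

    perfect hit  OWS = 0
    partial hit  0 < OWS <= 1
    poor hit     OWS > 1

Taxon-level coverage of a primer pair is the percentage of references
with perfect hits for BOTH primers.  Degenerate IUPAC codes in primer
or template match whenever their nucleotide code sets intersect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment import COMPAT, IUPAC_SETS, encode, reverse_complement
from .errors import InvalidInputError
from .refdb import ReferenceRecord
from .taxonomy import RANKS


@dataclass(frozen=True)
class PrimerPair:
    """A named primer pair; both primers are written 5'->3'.

    The reverse primer anneals to the forward strand, so its binding
    site appears on a forward-oriented template as the primer's reverse
    complement.
    """

    name: str
    forward: str
    reverse: str
    region: str = ""

    def __post_init__(self) -> None:
        for label, p in (("forward", self.forward), ("reverse", self.reverse)):
            if len(p) < 10:
                raise InvalidInputError(
                    f"{label} primer shorter than 10 nt: {p!r}")
            if any(c not in IUPAC_SETS for c in p.upper()):
                raise InvalidInputError(
                    f"invalid IUPAC character in {label} primer {p!r}")


#: Primer pairs in common use for 16S amplicon profiling of digesters.
COMMON_PAIRS = {
    "V1-V3": PrimerPair("27F/534R", "AGAGTTTGATCCTGGCTCAG",
                        "ATTACCGCGGCTGCTGG", "V1-V3"),
    "V4": PrimerPair("515F/806R", "GTGYCAGCMGCCGCGGTAA",
                     "GGACTACNVGGGTWTCTAAT", "V4"),
    "V3-V5": PrimerPair("Arch-340F/Arch-915R", "CCCTAHGGGGYGCASCA",
                        "GWGCYCCCCCGYCAATTC", "V3-V5"),
}


@dataclass(frozen=True)
class PrimerScoreWeights:
    """Weights of the overall weighted score (OWS).

    3'-region errors weigh at least as much as their non-3'
    counterparts; the 3' region spans the last ``three_prime_len``
    bases of the primer.
    """

    non3_mismatch: float = 0.4
    three_mismatch: float = 1.0
    non3_gap: float = 1.0
    three_gap: float = 3.0
    three_prime_len: int = 5

    def __post_init__(self) -> None:
        if min(self.non3_mismatch, self.three_mismatch,
               self.non3_gap, self.three_gap) < 0:
            raise InvalidInputError("weights must be non-negative")
        if self.three_mismatch < self.non3_mismatch \
                or self.three_gap < self.non3_gap:
            raise InvalidInputError(
                "3' weights must be >= the non-3' weights")


@dataclass(frozen=True)
class PrimerHitScore:
    """Score decomposition of the best binding site for one primer."""

    offset: int
    strand: str                 # "+" or "-"
    non3_mismatches: int
    three_mismatches: int
    non3_gaps: int
    three_gaps: int
    ows: float

    @property
    def category(self) -> str:
        return categorize_hit(self.ows)


def iupac_matches(primer_char: str, template_char: str) -> bool:
    """True iff the IUPAC code sets of the two characters intersect."""
    try:
        return bool(IUPAC_SETS[primer_char.upper()]
                    & IUPAC_SETS[template_char.upper()])
    except KeyError as exc:
        raise InvalidInputError(
            f"invalid IUPAC character {exc.args[0]!r}") from None


def categorize_hit(ows: float) -> str:
    """Map an overall weighted score to perfect/partial/poor."""
    if ows < 0:
        raise InvalidInputError(f"negative OWS {ows}")
    if ows == 0:
        return "perfect"
    if ows <= 1:
        return "partial"
    return "poor"


def _scan_strand(pi: np.ndarray, ti: np.ndarray,
                 w: PrimerScoreWeights) -> tuple[float, int, tuple]:
    """Minimum OWS of the primer on one template strand.

    Enumerates every ungapped offset plus every single-gap variant
    within the primer span (one unpaired primer base, or one skipped
    template base between two primer bases).  Returns
    (ows, offset, (non3_mm, three_mm, non3_gap, three_gap)); ties keep
    the smallest offset, and a gapped variant only replaces an
    ungapped site when strictly better.
    """
    L = len(pi)
    n_off = len(ti) - L + 1
    three = np.arange(L) >= L - w.three_prime_len
    pos_w = np.where(three, w.three_mismatch, w.non3_mismatch)
    gap_w = np.where(three, w.three_gap, w.non3_gap)
    windows = np.lib.stride_tricks.sliding_window_view(ti, L)[:n_off]
    mism = ~COMPAT[pi[np.newaxis, :], windows]          # (n_off, L)
    ungapped = (mism * pos_w).sum(axis=1)

    best_ows = float(ungapped.min())
    best_off = int(np.argmin(ungapped))
    row = mism[best_off]
    t3 = int(row[three].sum())
    best_counts = (int(row.sum()) - t3, t3, 0, 0)

    # Any gapped variant costs at least one gap weight, so when the best
    # ungapped score is already that low no gap can improve on it.
    if best_ows <= min(w.non3_gap, w.three_gap) + 1e-12:
        return best_ows, best_off, best_counts

    def counts_at(score_vec, o, span_mism):
        k = int(np.argmin(score_vec))
        if score_vec[k] >= best_ows - 1e-12:
            return None
        m = span_mism(k)
        t3 = int(m[three].sum())
        gaps = (0, 1) if three[k] else (1, 0)
        return (float(score_vec[k]), o,
                (int(m.sum()) - t3, t3, gaps[0], gaps[1]))

    # Primer base k unpaired (template span L-1).
    for o in range(len(ti) - (L - 1) + 1):
        win = ti[o:o + L - 1]
        m1 = ~COMPAT[pi[:-1], win]            # primer[idx] vs t[o+idx]
        m2 = ~COMPAT[pi[1:], win]             # primer[idx] vs t[o+idx-1]
        pre = np.concatenate([[0.0], (m1 * pos_w[:-1]).cumsum()])
        suf = np.concatenate([(m2 * pos_w[1:])[::-1].cumsum()[::-1], [0.0]])
        score = pre[:L] + suf + gap_w         # score[k], k = 0..L-1

        def span(k, o=o, win=win):
            a = ~COMPAT[pi[:k], win[:k]]
            b = ~COMPAT[pi[k + 1:], win[k:]]
            out = np.zeros(L, dtype=bool)
            out[:k] = a
            out[k + 1:] = b
            return out

        hit = counts_at(score, o, span)
        if hit is not None:
            best_ows, best_off, best_counts = hit

    # One skipped template base between primer positions k-1 and k
    # (template span L+1), k = 1..L-1.
    for o in range(len(ti) - (L + 1) + 1):
        win = ti[o:o + L + 1]
        m1 = ~COMPAT[pi, win[:L]]             # primer[idx] vs t[o+idx]
        m2 = ~COMPAT[pi, win[1:]]             # primer[idx] vs t[o+idx+1]
        pre = np.concatenate([[0.0], (m1 * pos_w).cumsum()])
        suf = np.concatenate([(m2 * pos_w)[::-1].cumsum()[::-1], [0.0]])
        score = pre[1:L] + suf[1:L] + gap_w[1:L]   # k = 1..L-1

        def span(kk, o=o, win=win):
            k = kk + 1
            out = np.zeros(L, dtype=bool)
            out[:k] = ~COMPAT[pi[:k], win[:k]]
            out[k:] = ~COMPAT[pi[k:], win[k + 1:]]
            return out

        hit = counts_at(score, o, lambda kk: span(kk))
        if hit is not None:
            s, oo, c = hit
            # counts_at reported k relative to the sliced score vector;
            # the gap-weight position is k+1, already handled in span.
            k = int(np.argmin(score)) + 1
            gaps = (0, 1) if three[k] else (1, 0)
            best_ows, best_off, best_counts = s, oo, c[:2] + gaps

    return best_ows, best_off, best_counts


def best_hit_score(primer: str, template: str,
                   weights: PrimerScoreWeights | None = None,
                   search_revcomp: bool = True) -> PrimerHitScore:
    """Best (minimum-OWS) binding site of *primer* on *template*.

    Both strands of the template are searched by default (the primer
    may anneal to either); the forward strand wins ties.  Raises for a
    template shorter than the primer.
    """
    w = weights or PrimerScoreWeights()
    p = primer.upper()
    t = template.upper()
    if len(t) < len(p):
        raise InvalidInputError("template shorter than primer")
    pi = encode(p, "primer")
    strands = [("+", encode(t, "template"))]
    if search_revcomp:
        strands.append(("-", encode(reverse_complement(t), "template")))
    best = None
    for strand, ti in strands:
        ows, off, counts = _scan_strand(pi, ti, w)
        cand = PrimerHitScore(off, strand, *counts, ows=ows)
        if best is None or cand.ows < best.ows - 1e-12:
            best = cand
    return best


def pair_coverage(pair: PrimerPair,
                  references: Sequence[ReferenceRecord],
                  weights: PrimerScoreWeights | None = None,
                  rank: str = "phylum",
                  reverse_only: bool = False) -> pd.DataFrame:
    """Per-taxon percentage of references hit perfectly by the pair.

    For each taxon at *rank* (references with a blank name there are
    skipped): 100 x |references with OWS = 0 for both primers| /
    |references in taxon|, plus an ``Overall`` row across all
    references.  ``reverse_only`` evaluates only the reverse primer,
    for templates whose 5' end was created with the forward primer.
    """
    if rank not in RANKS:
        raise InvalidInputError(f"unknown rank {rank!r}")
    w = weights or PrimerScoreWeights()
    r_idx = RANKS.index(rank)
    perfect = {}
    for rec in references:
        rev_ok = best_hit_score(pair.reverse, rec.sequence, w).ows == 0
        if reverse_only:
            perfect[rec.accession] = rev_ok
        else:
            fwd_ok = best_hit_score(pair.forward, rec.sequence, w).ows == 0
            perfect[rec.accession] = fwd_ok and rev_ok
    rows = []
    groups: dict[str, list[bool]] = {}
    for rec in references:
        name = rec.taxonomy.names[r_idx] if rec.taxonomy is not None else ""
        if name:
            groups.setdefault(name, []).append(perfect[rec.accession])
    for taxon in sorted(groups):
        hits = groups[taxon]
        rows.append({"taxon": taxon, "rank": rank, "n": len(hits),
                     "pct_perfect": 100.0 * sum(hits) / len(hits)})
    allv = list(perfect.values())
    rows.append({"taxon": "Overall", "rank": "all", "n": len(allv),
                 "pct_perfect": (100.0 * sum(allv) / len(allv))
                 if allv else float("nan")})
    return pd.DataFrame(rows, columns=["taxon", "rank", "n", "pct_perfect"])


def extract_amplicon(template: str, pair: PrimerPair,
                     weights: PrimerScoreWeights | None = None,
                     max_ows: float = 0.0) -> tuple[str | None, str]:
    """Inter-primer region of *template*, oriented 5'->3', or None.

    Both orientations of the template are tried.  The forward primer
    site must appear upstream of the reverse-complemented reverse
    primer site, each at OWS <= *max_ows* (default: perfect sites
    only); otherwise ``(None, reason)`` is returned.  Coordinates are
    0-based half-open; the primers themselves are excluded.
    """
    w = weights or PrimerScoreWeights()
    rev_site = reverse_complement(pair.reverse)
    for oriented in (template.upper(),
                     reverse_complement(template.upper())):
        if len(oriented) < len(pair.forward) + len(pair.reverse):
            continue
        fwd = best_hit_score(pair.forward, oriented, w,
                             search_revcomp=False)
        if fwd.ows > max_ows:
            continue
        fwd_end = fwd.offset + len(pair.forward)
        downstream = oriented[fwd_end:]
        if len(downstream) < len(rev_site):
            continue
        rev = best_hit_score(rev_site, downstream, w, search_revcomp=False)
        if rev.ows > max_ows:
            continue
        amplicon = downstream[:rev.offset]
        return amplicon, "ok"
    fwd_found = False
    try:
        fwd_found = best_hit_score(pair.forward, template, w).ows <= max_ows
    except InvalidInputError:
        pass
    reason = "missing reverse site" if fwd_found else "missing forward site"
    return None, reason
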