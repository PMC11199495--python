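"""Evaluate short-read ASV sets against a reference database.

Three per-sample quantities summarise how well a reference database
covers an amplicon survey:

* the fraction of reads retained after removing the rare biosphere
  (features below 0.01% relative abundance in a sample);
* the percentage of retained ASVs whose nearest database neighbour is a
  high-identity (>=99%) hit;
* the percentage of retained ASVs that receive a genus- or
  species-level classification from a k-mer bootstrap classifier.

The classifier follows the SINTAX scheme: 100 bootstrap iterations each
draw 32 of the query's unique 8-mers with replacement and vote for the
reference sharing most of them; per-rank confidence is the fraction of
bootstraps whose winner carries the predicted lineage down to that
rank, and ranks below the confidence cutoff (default 0.8) are blanked.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import reverse_complement
from .errors import InvalidInputError
from .refdb import ReferenceRecord, nearest_neighbor
from .taxonomy import RANKS, TaxonomyPath


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the evaluation pipeline (percent scales)."""

    min_rel_abundance_pct: float = 0.01
    high_identity_pct: float = 99.0
    confidence_cutoff: float = 0.8
    min_sample_depth: int = 10_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_rel_abundance_pct <= 100.0 \
                or not 0.0 <= self.high_identity_pct <= 100.0:
            raise InvalidInputError("percent thresholds must be in [0, 100]")
        if not 0.0 < self.confidence_cutoff <= 1.0:
            raise InvalidInputError("confidence cutoff must be in (0, 1]")


def relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    """Convert a samples x features count table to per-sample fractions."""
    totals = table.sum(axis=1)
    zero = totals[totals <= 0]
    if len(zero):
        raise InvalidInputError(
            f"samples with zero total counts: {list(zero.index)}")
    return table.div(totals, axis=0)


def discard_low_depth(table: pd.DataFrame,
                      params: FilterParams | None = None,
                      ) -> tuple[pd.DataFrame, list[str]]:
    """Drop samples whose total reads fall below the minimum depth."""
    params = params or FilterParams()
    totals = table.sum(axis=1)
    kept = totals >= params.min_sample_depth
    return table.loc[kept], list(table.index[~kept])


def filter_rare(table: pd.DataFrame,
                params: FilterParams | None = None,
                ) -> tuple[pd.DataFrame, pd.Series]:
    """Per-sample rare-biosphere mask.

    A feature is kept in a sample iff its relative abundance there is
    >= the threshold (default 0.01%); masking is per sample, not a
    table-wide feature removal.  Returns the masked count table and the
    per-sample fraction of reads retained.
    """
    params = params or FilterParams()
    rel = relative_abundance(table)
    keep = rel >= params.min_rel_abundance_pct / 100.0
    masked = table.where(keep, 0)
    retained = masked.sum(axis=1) / table.sum(axis=1)
    return masked, retained


def high_identity_fraction(table: pd.DataFrame,
                           sequences: Mapping[str, str],
                           db: Sequence[ReferenceRecord],
                           params: FilterParams | None = None) -> pd.Series:
    """Percentage of a sample's retained ASVs with a >=99% database hit.

    *table* should already be rare-filtered; every ASV with a nonzero
    count anywhere needs a sequence.  Each distinct ASV is aligned
    once.  Samples with zero retained ASVs are reported as NaN.
    """
    params = params or FilterParams()
    active = table.columns[(table > 0).any(axis=0)]
    missing = [a for a in active if a not in sequences]
    if missing:
        raise InvalidInputError(f"ASVs without sequences: {missing[:5]}")
    is_high = {a: nearest_neighbor(sequences[a], db).identity
               >= params.high_identity_pct for a in active}
    out = {}
    for sample in table.index:
        present = table.columns[table.loc[sample] > 0]
        out[sample] = (100.0 * sum(is_high[a] for a in present) / len(present)
                       if len(present) else float("nan"))
    return pd.Series(out, name="pct_high_identity")


@dataclass(frozen=True)
class ClassificationResult:
    """Taxonomy truncated at the confidence cutoff, with confidences."""

    path: TaxonomyPath
    confidences: tuple[float, ...]
    strand: str


class KmerClassifier:
    """Bootstrap k-mer classifier over a taxonomically labelled database.

    k-mers containing ambiguity codes are ignored on both sides.  Votes
    within a bootstrap go to the reference with most shared drawn
    k-mers; equal counts fall back to the lexicographically smallest
    accession.  Strand choice precedes bootstrapping: the orientation
    whose best reference shares more k-mers overall wins (forward on
    ties).  Deterministic under a fixed seed.
    """

    def __init__(self, db: Sequence[ReferenceRecord], k: int = 8,
                 n_draw: int = 32, n_boot: int = 100,
                 cutoff: float = 0.8) -> None:
        if not db:
            raise InvalidInputError("reference database is empty")
        for rec in db:
            if rec.taxonomy is None:
                raise InvalidInputError(
                    f"reference {rec.accession!r} lacks a taxonomy")
        self.k = k
        self.n_draw = n_draw
        self.n_boot = n_boot
        self.cutoff = cutoff
        self.refs = sorted(db, key=lambda r: r.accession)
        self._sets = [self._kmer_set(r.sequence) for r in self.refs]

    def _kmer_set(self, seq: str) -> frozenset[int]:
        comp = {"A": 0, "C": 1, "G": 2, "T": 3}
        out = set()
        code = 0
        run = 0  # valid-bases run length
        mask = (1 << (2 * self.k)) - 1
        for c in seq.upper():
            v = comp.get(c)
            if v is None:
                run = 0
                code = 0
                continue
            code = ((code << 2) | v) & mask
            run += 1
            if run >= self.k:
                out.add(code)
        return frozenset(out)

    def classify(self, seq: str, seed: int | np.random.Generator = 0,
                 ) -> ClassificationResult:
        if len(seq) < self.k:
            raise InvalidInputError(
                f"query shorter than k = {self.k}")
        rng = np.random.default_rng(seed) \
            if isinstance(seed, (int, np.integer)) else seed

        strands = []
        for label, s in (("+", seq), ("-", reverse_complement(seq))):
            kmers = np.array(sorted(self._kmer_set(s)), dtype=np.int64)
            if len(kmers) == 0:
                continue
            member = np.stack([np.isin(kmers, np.fromiter(rs, np.int64,
                                                          len(rs)))
                               if rs else np.zeros(len(kmers), bool)
                               for rs in self._sets])
            strands.append((label, kmers, member))
        if not strands:
            raise InvalidInputError("query contains no unambiguous k-mers")
        # Strand with the larger best total k-mer overlap wins; "+" on tie.
        label, kmers, member = max(
            strands, key=lambda t: (int(t[2].sum(axis=1).max()),
                                    t[0] == "+"))

        draws = rng.integers(0, len(kmers), size=(self.n_boot, self.n_draw))
        counts = member[:, draws].sum(axis=2)        # (n_refs, n_boot)
        winners = counts.argmax(axis=0)              # first max = lex smallest

        # Per-rank prefix votes along the winning lineage.
        names: list[str] = []
        confidences: list[float] = []
        active = np.ones(self.n_boot, dtype=bool)
        for depth in range(len(RANKS)):
            votes: dict[str, int] = {}
            for b in np.flatnonzero(active):
                name = self.refs[winners[b]].taxonomy.names[depth]
                votes[name] = votes.get(name, 0) + 1
            best_name = min(votes, key=lambda n: (-votes[n], n))
            conf = votes[best_name] / self.n_boot
            names.append(best_name)
            confidences.append(conf)
            keep = np.array([
                self.refs[winners[b]].taxonomy.names[depth] == best_name
                for b in range(self.n_boot)])
            active &= keep

        kept = [n if c >= self.cutoff else ""
                for n, c in zip(names, confidences)]
        for i in range(1, len(kept)):  # blanks propagate downward
            if kept[i - 1] == "":
                kept[i] = ""
        return ClassificationResult(TaxonomyPath(tuple(kept)),
                                    tuple(confidences), label)


def classify_table(table: pd.DataFrame, sequences: Mapping[str, str],
                   classifier: KmerClassifier,
                   seed: int = 0) -> dict[str, ClassificationResult]:
    """Classify every ASV with a nonzero count, in column order."""
    rng = np.random.default_rng(seed)
    out = {}
    for asv in table.columns[(table > 0).any(axis=0)]:
        out[asv] = classifier.classify(sequences[asv], rng)
    return out


def classification_rate(assignments: Mapping[str, TaxonomyPath
                                             | ClassificationResult],
                        table: pd.DataFrame, rank: str) -> pd.Series:
    """Percentage of a sample's retained ASVs named at *rank*.

    ASVs are weighted equally (presence, not abundance); samples with
    zero retained ASVs are NaN.
    """
    if rank not in RANKS:
        raise InvalidInputError(f"unknown rank {rank!r}")
    r = RANKS.index(rank)
    named = {}
    for asv, a in assignments.items():
        path = a.path if isinstance(a, ClassificationResult) else a
        named[asv] = path.names[r] != ""
    out = {}
    for sample in table.index:
        present = [a for a in table.columns if table.at[sample, a] > 0]
        out[sample] = (100.0 * sum(named[a] for a in present) / len(present)
                       if present else float("nan"))
    return pd.Series(out, name=f"pct_{rank}_classified")


def aggregate_by_rank(table: pd.DataFrame,
                      assignments: Mapping[str, TaxonomyPath
                                           | ClassificationResult],
                      rank: str,
                      unclassified_label: str = "__unclassified__",
                      ) -> pd.DataFrame:
    """Sum feature columns into taxa at *rank*.

    Features with a blank name at the rank are pooled under
    *unclassified_label* (pass ``None`` to drop them instead).
    """
    if rank not in RANKS:
        raise InvalidInputError(f"unknown rank {rank!r}")
    r = RANKS.index(rank)
    groups: dict[str, list[str]] = {}
    for asv in table.columns:
        a = assignments.get(asv)
        path = a.path if isinstance(a, ClassificationResult) else a
        name = path.names[r] if path is not None else ""
        if name == "":
            if unclassified_label is None:
                continue
            name = unclassified_label
        groups.setdefault(name, []).append(asv)
    data = {taxon: table[cols].sum(axis=1)
            for taxon, cols in sorted(groups.items())}
    return pd.DataFrame(data, index=table.index)
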