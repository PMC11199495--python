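"""Reference-database expansion for full-length 16S rRNA gene ASVs.

A curated reference database grows by merging newly sequenced
full-length amplicon sequence variants (FL-ASVs) into an existing set,
deduplicating, ranking the novelty of each newcomer against per-rank
identity thresholds, and assigning a seven-rank taxonomy in which
lineages without an official name receive systematic placeholder names.

The per-rank identity thresholds are the classical 16S cut-offs for
sharing a taxon at each rank (phylum 75.0, class 78.5, order 82.0,
family 86.5, genus 94.5, species 98.7 percent identity): a query whose
best database hit falls strictly below a rank's threshold has no
homolog at that rank and is "novel" there.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .alignment import align_identity, percent_identity, sequences_equivalent
from .errors import InvalidInputError
from .taxonomy import (PLACEHOLDER_PREFIX, RANK_LETTERS, RANKS, TaxonomyPath,
                       is_placeholder)

#: Ranks that carry an identity threshold (kingdom is always inherited).
THRESHOLD_RANKS = RANKS[1:]


@dataclass(frozen=True)
class ReferenceRecord:
    """A full-length 16S rRNA reference sequence with its taxonomy."""

    accession: str
    sequence: str
    taxonomy: TaxonomyPath | None = None
    source: str = "existing"  # "existing" or "new"

    def __post_init__(self) -> None:
        if not self.accession:
            raise InvalidInputError("empty accession")
        if not self.sequence:
            raise InvalidInputError(f"empty sequence for {self.accession!r}")
        object.__setattr__(self, "sequence", self.sequence.upper())


@dataclass(frozen=True)
class YarzaThresholds:
    """Minimum percent identity for sharing a taxon at each rank."""

    phylum: float = 75.0
    class_: float = 78.5
    order: float = 82.0
    family: float = 86.5
    genus: float = 94.5
    species: float = 98.7

    def __post_init__(self) -> None:
        vals = self.as_tuple()
        if any(not 0.0 < v <= 100.0 for v in vals):
            raise InvalidInputError("thresholds must lie in (0, 100]")
        if any(a >= b for a, b in zip(vals, vals[1:])):
            raise InvalidInputError(
                "thresholds must increase strictly from phylum to species")

    def as_tuple(self) -> tuple[float, ...]:
        return (self.phylum, self.class_, self.order,
                self.family, self.genus, self.species)

    def for_rank(self, rank: str) -> float:
        if rank == "kingdom":
            return 0.0
        return self.as_tuple()[THRESHOLD_RANKS.index(rank)]


class NoveltyRank(enum.Enum):
    """Highest rank at which a query lacks a database homolog."""

    none = "none"
    species_novel = "species_novel"
    genus_novel = "genus_novel"
    family_novel = "family_novel"
    order_novel = "order_novel"
    class_novel = "class_novel"
    phylum_novel = "phylum_novel"


@dataclass(frozen=True)
class IdentityHit:
    """Best-identity database hit for one query."""

    query: str
    reference: str
    identity: float
    tie_count: int = 1


def nearest_neighbor(query: ReferenceRecord | str,
                     db: Sequence[ReferenceRecord]) -> IdentityHit:
    """Maximum-identity reference for *query* with deterministic ties.

    Ties (equal best identity within 1e-9) are broken by the
    lexicographically smallest accession; ``tie_count`` reports how many
    references reached the best identity.
    """
    if not db:
        raise InvalidInputError("reference database is empty")
    qname = query.accession if isinstance(query, ReferenceRecord) else "query"
    qseq = query.sequence if isinstance(query, ReferenceRecord) else query
    best_acc = None
    best_id = -1.0
    ties = 0
    for rec in sorted(db, key=lambda r: r.accession):
        ident = percent_identity(qseq, rec.sequence)
        if ident > best_id + 1e-9:
            best_acc, best_id, ties = rec.accession, ident, 1
        elif abs(ident - best_id) <= 1e-9:
            ties += 1
    return IdentityHit(qname, best_acc, best_id, ties)


@dataclass
class MergeReport:
    """Bookkeeping for a deduplicating database merge."""

    n_existing: int
    n_incoming: int
    n_duplicates: int
    containment_warnings: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_added(self) -> int:
        return self.n_incoming - self.n_duplicates

    @property
    def n_merged(self) -> int:
        return self.n_existing + self.n_added


def merge_dereplicate(
    existing: Sequence[ReferenceRecord],
    incoming: Sequence[ReferenceRecord],
) -> tuple[list[ReferenceRecord], MergeReport]:
    """Merge *incoming* into *existing*, dropping redundant sequences.

    An incoming record is a duplicate iff it has 100% identity with an
    already-retained record AND equal ungapped length (equivalently:
    equal length and position-wise IUPAC compatibility).  Existing
    records are always retained and take precedence; the operation is
    idempotent.  A shorter sequence fully contained in a retained one is
    NOT merged away but reported as a containment warning.
    """
    for name, records in (("existing", existing), ("incoming", incoming)):
        accs = [r.accession for r in records]
        if len(accs) != len(set(accs)):
            raise InvalidInputError(f"duplicate accessions within {name} set")
    by_acc = {r.accession: r for r in existing}
    by_len: dict[int, list[ReferenceRecord]] = {}
    merged = list(existing)
    for rec in existing:
        by_len.setdefault(len(rec.sequence), []).append(rec)

    report = MergeReport(len(existing), len(incoming), 0)
    for rec in incoming:
        prior = by_acc.get(rec.accession)
        if prior is not None:
            if prior.sequence != rec.sequence:
                raise InvalidInputError(
                    f"accession {rec.accession!r} present in both sets "
                    "with different sequences")
            report.n_duplicates += 1
            continue
        if any(sequences_equivalent(rec.sequence, other.sequence)
               for other in by_len.get(len(rec.sequence), [])):
            report.n_duplicates += 1
            continue
        for other in merged:
            if len(rec.sequence) < len(other.sequence) \
                    and rec.sequence in other.sequence:
                report.containment_warnings.append(
                    (rec.accession, other.accession))
                break
        merged.append(rec)
        by_acc[rec.accession] = rec
        by_len.setdefault(len(rec.sequence), []).append(rec)
    return merged, report


def classify_novelty(identity: float,
                     thresholds: YarzaThresholds | None = None) -> NoveltyRank:
    """Novelty rank of a query from its best-hit identity.

    Returns the most inclusive rank whose threshold is not met (strict
    ``<`` comparison, so a hit at exactly 94.5% identity is NOT novel at
    the genus rank); identity at or above the species threshold means no
    novelty.
    """
    thresholds = thresholds or YarzaThresholds()
    if not 0.0 <= identity <= 100.0:
        raise InvalidInputError(f"identity {identity} outside [0, 100]")
    for rank in THRESHOLD_RANKS:  # phylum first = most inclusive
        if identity < thresholds.for_rank(rank):
            key = "class" if rank == "class" else rank
            return NoveltyRank[f"{key}_novel"]
    return NoveltyRank.none


def novelty_table(counts: Mapping[str, int], n_incoming: int,
                  thresholds: YarzaThresholds | None = None) -> pd.DataFrame:
    """Format per-rank novelty counts as the survey-style summary table.

    *counts* maps each thresholded rank (phylum..species) to the number
    of incoming sequences whose best-hit identity falls strictly below
    that rank's threshold; rows are cumulative by construction (every
    genus-novel sequence is also species-novel).  Percentages are
    reported to two decimals.
    """
    if n_incoming <= 0:
        raise InvalidInputError("empty incoming set")
    thresholds = thresholds or YarzaThresholds()
    rows = []
    for rank in THRESHOLD_RANKS:
        n = int(counts.get(rank, 0))
        rows.append({
            "rank": rank,
            "threshold": thresholds.for_rank(rank),
            "count": n,
            "percentage": round(100.0 * n / n_incoming, 2),
        })
    return pd.DataFrame(rows).set_index("rank")


def summarize_novelty(incoming: Sequence[ReferenceRecord],
                      db: Sequence[ReferenceRecord],
                      thresholds: YarzaThresholds | None = None,
                      ) -> pd.DataFrame:
    """Cumulative per-rank novelty counts of *incoming* against *db*.

    A sequence below the genus threshold is counted in the genus row
    AND the species row (species counts >= genus counts).
    """
    if not incoming:
        raise InvalidInputError("empty incoming set")
    thresholds = thresholds or YarzaThresholds()
    counts = {rank: 0 for rank in THRESHOLD_RANKS}
    for rec in incoming:
        ident = nearest_neighbor(rec, db).identity
        for rank in THRESHOLD_RANKS:
            if ident < thresholds.for_rank(rank):
                counts[rank] += 1
    return novelty_table(counts, len(incoming), thresholds)


class PlaceholderRegistry:
    """Mutable state for minting and reusing placeholder taxon names.

    Per rank it holds the next free integer and the greedy clusters
    created so far: the first query that mints a name becomes the
    cluster centroid, and a later query reuses the name iff its identity
    to the centroid reaches that rank's threshold.  Scanning order is
    creation order, so placeholder numbering is a deterministic function
    of query input order.
    """

    def __init__(self, thresholds: YarzaThresholds | None = None,
                 prefix: str = PLACEHOLDER_PREFIX) -> None:
        self.thresholds = thresholds or YarzaThresholds()
        self.prefix = prefix
        self.counters: dict[str, int] = {r: 1 for r in RANKS}
        self.clusters: dict[str, list[tuple[str, str]]] = {r: [] for r in RANKS}

    @classmethod
    def from_database(cls, db: Iterable[ReferenceRecord],
                      thresholds: YarzaThresholds | None = None,
                      prefix: str = PLACEHOLDER_PREFIX) -> "PlaceholderRegistry":
        """Initialise counters past any placeholder names already in *db*."""
        reg = cls(thresholds, prefix)
        for rec in db:
            if rec.taxonomy is None:
                continue
            for i, name in enumerate(rec.taxonomy.names):
                if is_placeholder(name, i, prefix):
                    n = int(name.rsplit("_", 1)[1])
                    rank = RANKS[i]
                    reg.counters[rank] = max(reg.counters[rank], n + 1)
        return reg

    def name_for(self, rank: str, query_seq: str,
                 identity_cache: dict[str, float]) -> str:
        threshold = self.thresholds.for_rank(rank)
        for centroid_seq, name in self.clusters[rank]:
            ident = identity_cache.get(centroid_seq)
            if ident is None:
                ident = percent_identity(query_seq, centroid_seq)
                identity_cache[centroid_seq] = ident
            if ident >= threshold:
                return name
        letter = RANK_LETTERS[RANKS.index(rank)]
        name = f"{self.prefix}_{letter}_{self.counters[rank]}"
        self.counters[rank] += 1
        self.clusters[rank].append((query_seq, name))
        return name


def assign_taxonomy(query: ReferenceRecord | str,
                    db: Sequence[ReferenceRecord],
                    thresholds: YarzaThresholds | None = None,
                    registry: PlaceholderRegistry | None = None,
                    ) -> TaxonomyPath:
    """Seven-rank taxonomy for a query by threshold-gated inheritance.

    For each rank from kingdom to species the nearest neighbour's name
    is inherited iff the best-hit identity reaches that rank's threshold
    (the kingdom is always inherited).  From the first failing rank
    downward, placeholder names are minted from (or reused via) the
    registry's greedy clusters, so near-identical queries processed in
    sequence share the same placeholder lineage.
    """
    thresholds = thresholds or YarzaThresholds()
    if registry is None:
        registry = PlaceholderRegistry(thresholds)
    hit = nearest_neighbor(query, db)
    nn = next(r for r in db if r.accession == hit.reference)
    if nn.taxonomy is None:
        raise InvalidInputError(
            f"reference {nn.accession!r} lacks a taxonomy")
    qseq = query.sequence if isinstance(query, ReferenceRecord) else query
    cache: dict[str, float] = {}
    names: list[str] = []
    inherited = True
    for rank, nn_name in zip(RANKS, nn.taxonomy.names):
        if inherited and hit.identity >= thresholds.for_rank(rank):
            names.append(nn_name)
        else:
            inherited = False
            names.append(registry.name_for(rank, qseq, cache))
    return TaxonomyPath(tuple(names), registry.prefix)


def taxa_inventory_delta(before: Iterable[TaxonomyPath | ReferenceRecord],
                         after: Iterable[TaxonomyPath | ReferenceRecord],
                         ) -> pd.DataFrame:
    """Per-rank taxon totals and additions between two database versions.

    ``total`` counts distinct non-blank names at each rank in *after*,
    ``new`` those absent from *before*; ``pct_increase`` is
    100 x new / (total - new) to one decimal, or NaN when every taxon at
    the rank is new (undefined, not an error).
    """
    def paths(records):
        for r in records:
            yield r.taxonomy if isinstance(r, ReferenceRecord) else r

    before_names: list[set[str]] = [set() for _ in RANKS]
    after_names: list[set[str]] = [set() for _ in RANKS]
    for store, records in ((before_names, before), (after_names, after)):
        for path in paths(records):
            if path is None:
                raise InvalidInputError("record without taxonomy")
            for i, name in enumerate(path.names):
                if name:
                    store[i].add(name)
    rows = []
    for i, rank in enumerate(RANKS):
        total = len(after_names[i])
        new = len(after_names[i] - before_names[i])
        old = total - new
        pct = round(100.0 * new / old, 1) if old else float("nan")
        rows.append({"rank": rank, "total": total, "new": new,
                     "pct_increase": pct})
    return pd.DataFrame(rows).set_index("rank")
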