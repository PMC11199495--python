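"""Core and conditionally rare-or-abundant taxon (CRAT) profiling.

A taxon is "abundant" in a sample when it exceeds 0.1% relative read
abundance.  Within a metadata group (e.g. digesters sharing a primary
substrate and temperature class) the occupancy — the fraction of the
group's samples where the taxon is abundant — sorts taxa into nested
core categories:

    strict core   abundant in > 80% of the group's samples
    general core  abundant in > 50%
    loose core    abundant in > 20%
    CRAT          not core, but > 1% relative abundance in >= 1 sample
    other         everything else

All comparisons are strict (``>``).  Aggregating assignments across
groups and primer sets under the order strict > general > loose > CRAT
yields the "most wanted" list of taxa for the ecosystem.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .errors import InvalidInputError

CATEGORY_ORDER = ("strict", "general", "loose", "crat", "other")
_CATEGORY_RANK = {c: i for i, c in enumerate(CATEGORY_ORDER)}


@dataclass(frozen=True)
class CoreThresholds:
    """Cut-offs of the core/CRAT classification (percent scales)."""

    abundant_pct: float = 0.1
    loose_occupancy: float = 20.0
    general_occupancy: float = 50.0
    strict_occupancy: float = 80.0
    crat_single_sample_pct: float = 1.0

    def __post_init__(self) -> None:
        occ = (self.loose_occupancy, self.general_occupancy,
               self.strict_occupancy)
        if any(not 0.0 < v < 100.0 for v in occ) \
                or any(a >= b for a, b in zip(occ, occ[1:])):
            raise InvalidInputError(
                "occupancy cutoffs must increase strictly within (0, 100)")
        if not 0.0 < self.abundant_pct < 100.0 \
                or not 0.0 < self.crat_single_sample_pct < 100.0:
            raise InvalidInputError("abundance cutoffs must be in (0, 100)")


def group_samples(metadata: pd.DataFrame, keys: Sequence[str],
                  min_size: int = 2,
                  ) -> tuple[dict[tuple, list[str]], pd.DataFrame]:
    """Partition samples by the metadata *keys*.

    Samples with an unknown/missing value in any key field are excluded
    (and listed in the returned log frame); groups below *min_size* are
    flagged there too, but still returned.
    """
    unknown_tokens = {"unknown", "", "nan"}
    for key in keys:
        if key not in metadata.columns:
            raise InvalidInputError(f"unknown metadata field {key!r}")
    groups: dict[tuple, list[str]] = {}
    log_rows = []
    for sample, row in metadata.iterrows():
        vals = tuple(str(row[k]) for k in keys)
        if any(v.lower() in unknown_tokens for v in vals):
            log_rows.append({"item": sample, "event": "excluded",
                             "detail": "unknown value in grouping keys"})
            continue
        groups.setdefault(vals, []).append(sample)
    for key, members in groups.items():
        if len(members) < min_size:
            log_rows.append({"item": "/".join(key), "event": "small_group",
                             "detail": f"{len(members)} samples"})
    log = pd.DataFrame(log_rows, columns=["item", "event", "detail"])
    return groups, log


def classify_core(rel: pd.DataFrame,
                  thresholds: CoreThresholds | None = None,
                  group: str = "") -> pd.DataFrame:
    """Core/CRAT assignment for every taxon observed in one group.

    *rel* holds relative abundances (fractions summing to 1 per row)
    for the samples of a single group.  Taxa absent from every sample
    are omitted.  Returns one row per taxon: occupancy (fraction of
    samples above the abundance cut), maximum single-sample abundance,
    category, and a flag for taxa sitting exactly on an occupancy
    boundary (where the strict ``>`` decides).
    """
    t = thresholds or CoreThresholds()
    if rel.shape[0] < 2:
        raise InvalidInputError("a group needs at least 2 samples")
    n = rel.shape[0]
    abundant = rel > t.abundant_pct / 100.0
    occupancy = abundant.sum(axis=0) / n
    max_abund = rel.max(axis=0)
    observed = rel.columns[(rel > 0).any(axis=0)]

    rows = []
    for taxon in observed:
        occ = occupancy[taxon]
        if occ > t.strict_occupancy / 100.0:
            cat = "strict"
        elif occ > t.general_occupancy / 100.0:
            cat = "general"
        elif occ > t.loose_occupancy / 100.0:
            cat = "loose"
        elif max_abund[taxon] > t.crat_single_sample_pct / 100.0:
            cat = "crat"
        else:
            cat = "other"
        on_boundary = any(
            abs(occ - cut / 100.0) < 1e-12
            for cut in (t.loose_occupancy, t.general_occupancy,
                        t.strict_occupancy))
        rows.append({"taxon": taxon, "group": group, "category": cat,
                     "occupancy": float(occ),
                     "max_abundance": float(max_abund[taxon]),
                     "on_boundary": on_boundary})
    return pd.DataFrame(
        rows, columns=["taxon", "group", "category", "occupancy",
                       "max_abundance", "on_boundary"])


def most_wanted(assignments: pd.DataFrame) -> pd.DataFrame:
    """Highest category per taxon across groups (and primer sets).

    *assignments* concatenates :func:`classify_core` outputs; the total
    order is strict > general > loose > CRAT > other.  Taxa whose best
    category is "other" are excluded.  Output is sorted by category
    then taxon name, with the (first) group achieving the best category
    as provenance.
    """
    if assignments.empty:
        return pd.DataFrame(columns=["taxon", "category", "group"])
    best: dict[str, tuple[int, str, str]] = {}
    for row in assignments.itertuples(index=False):
        rank = _CATEGORY_RANK[row.category]
        cur = best.get(row.taxon)
        if cur is None or rank < cur[0]:
            best[row.taxon] = (rank, row.category, row.group)
    rows = [{"taxon": taxon, "category": cat, "group": grp}
            for taxon, (rank, cat, grp) in best.items() if cat != "other"]
    out = pd.DataFrame(rows, columns=["taxon", "category", "group"])
    out["__order"] = out["category"].map(_CATEGORY_RANK)
    out = out.sort_values(["__order", "taxon"]).drop(columns="__order")
    return out.reset_index(drop=True)


def shared_core_counts(core_sets: Mapping[str, set[str]]) -> pd.DataFrame:
    """Exclusive intersection-pattern counts (UpSet semantics).

    Every taxon in the union of the per-group core sets is counted in
    exactly one pattern — the exact set of groups whose core contains
    it — so pattern counts sum to the union size.  All non-empty
    patterns are listed, including those with zero count.
    """
    if len(core_sets) < 2:
        raise InvalidInputError("need at least 2 groups")
    names = sorted(core_sets)
    membership: dict[str, frozenset[str]] = {}
    for g in names:
        for taxon in core_sets[g]:
            membership[taxon] = membership.get(taxon, frozenset()) | {g}
    counts: dict[frozenset, int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            counts[frozenset(combo)] = 0
    for taxon, pattern in membership.items():
        counts[pattern] += 1
    rows = [{"pattern": "&".join(sorted(p)), "n_groups": len(p),
             "count": c} for p, c in counts.items()]
    out = pd.DataFrame(rows).sort_values(
        ["n_groups", "pattern"]).reset_index(drop=True)
    return out


def category_abundance_fractions(rel: pd.DataFrame,
                                 categories: Mapping[str, str],
                                 unclassified_label: str = "__unclassified__",
                                 ) -> pd.Series:
    """Mean accumulated relative abundance per category, in percent.

    Per taxon the mean relative abundance across the group's samples;
    per category the sum of member means.  Taxa pooled under the
    unclassified label count as "unclassified"; taxa without an entry
    in *categories* count as "other".  Fractions total 100%.
    """
    means = rel.mean(axis=0) * 100.0
    out = {c: 0.0 for c in ("strict", "general", "loose", "crat",
                            "other", "unclassified")}
    for taxon, mean in means.items():
        if taxon == unclassified_label:
            out["unclassified"] += mean
        else:
            out[categories.get(taxon, "other")] += mean
    return pd.Series(out, name="pct_abundance")
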