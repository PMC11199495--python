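"""Seeded generators for reference sets, survey tables and primer templates.

Every downstream stage of the pipeline is exercised against data with
known ground truth: a rank-calibrated reference "phylogeny" whose
pairwise identities straddle the per-rank thresholds, survey count
tables with planted strict/general/loose-core, conditionally rare or
abundant (CRAT) and rare taxa, and primer template sets with planted
mismatch patterns.  All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import IUPAC_SETS, reverse_complement
from .errors import InvalidInputError
from .refdb import ReferenceRecord, YarzaThresholds
from .taxonomy import RANKS, TaxonomyPath

_BASES = np.array(list("ACGT"))

#: Sub-kingdom ranks in root-to-leaf order, as used by the tree spec.
_TREE_RANKS = RANKS[1:]


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def mutate_to_identity(seq: str, target_identity: float,
                       seed: int | np.random.Generator) -> str:
    """Substitute exactly round((100 - target)/100 * len) positions.

    Positions are drawn without replacement and every substitution
    changes the base, so the planted Hamming identity to the parent is
    analytically controlled (an aligner may report a slightly different
    value when substitutions happen to re-create compatible columns).
    """
    if not 0.0 < target_identity <= 100.0:
        raise InvalidInputError(
            f"target identity {target_identity} outside (0, 100]")
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) \
        else seed
    n_sub = round((100.0 - target_identity) / 100.0 * len(seq))
    if n_sub == 0:
        return seq
    positions = rng.choice(len(seq), size=n_sub, replace=False)
    out = list(seq)
    for pos in positions:
        choices = [b for b in "ACGT" if b != out[pos]]
        out[pos] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def _default_divergences(thresholds: YarzaThresholds) -> dict[str, float]:
    """Per-rank sibling divergence: midway between adjacent thresholds.

    Two sibling species of one genus should share an identity between
    the genus and species thresholds, two sibling genera of one family
    an identity between the family and genus thresholds, and so on.
    Sibling phyla sit 5 points below the phylum threshold.
    """
    t = (thresholds.phylum, thresholds.class_, thresholds.order,
         thresholds.family, thresholds.genus, thresholds.species)
    identities = [t[0] - 5.0] + [(lo + hi) / 2.0 for lo, hi in zip(t, t[1:])]
    return {rank: 100.0 - ident
            for rank, ident in zip(_TREE_RANKS, identities)}


@dataclass
class ReferenceSimSpec:
    """Layout of a rank-calibrated synthetic reference set.

    ``branching`` gives the number of children per node at each
    sub-kingdom rank; ``divergence`` the target pairwise percent
    difference between siblings at that rank (strictly decreasing from
    phylum to species).  Default divergences put sibling identities
    midway between adjacent rank thresholds.
    """

    n_phyla: int = 2
    branching: Mapping[str, int] = field(
        default_factory=lambda: {"class": 1, "order": 1, "family": 2,
                                 "genus": 2, "species": 2})
    divergence: Mapping[str, float] | None = None
    length: int = 1400
    kingdom: str = "Bacteria"
    seed: int = 0

    def resolved_divergence(self) -> dict[str, float]:
        div = dict(self.divergence) if self.divergence is not None \
            else _default_divergences(YarzaThresholds())
        vals = [div[r] for r in _TREE_RANKS]
        if any(a <= b for a, b in zip(vals, vals[1:])):
            raise InvalidInputError(
                "divergences must decrease strictly from phylum to species")
        if self.n_phyla < 1 or any(self.branching.get(r, 1) < 1
                                   for r in _TREE_RANKS[1:]):
            raise InvalidInputError("branching factors must be >= 1")
        return div


def simulate_reference_phylogeny(
        spec: ReferenceSimSpec) -> list[ReferenceRecord]:
    """Reference records with a true taxonomy per record.

    Each internal node mutates its parent's representative sequence by
    half the rank divergence, so two siblings differ by approximately
    the full rank divergence.  Names encode the lineage (``Phy1``,
    ``Cla1_1``, ... ``Sp1_1_1_1_1_1``); accessions are sequential.
    Deterministic under a fixed seed.
    """
    div = spec.resolved_divergence()
    rng = np.random.default_rng(spec.seed)
    abbrev = {"phylum": "Phy", "class": "Cla", "order": "Ord",
              "family": "Fam", "genus": "Gen", "species": "Sp"}
    records: list[ReferenceRecord] = []
    counter = 1

    def descend(seq: str, rank_idx: int, lineage: list[str],
                index_path: list[int]) -> None:
        nonlocal counter
        rank = _TREE_RANKS[rank_idx]
        n_children = spec.n_phyla if rank == "phylum" \
            else spec.branching.get(rank, 1)
        for child in range(1, n_children + 1):
            child_seq = mutate_to_identity(
                seq, 100.0 - div[rank] / 2.0, rng)
            label = abbrev[rank] + "_".join(map(str, index_path + [child]))
            if rank == "species":
                path = TaxonomyPath(tuple([spec.kingdom] + lineage + [label]))
                records.append(ReferenceRecord(
                    f"FLASV{counter}", child_seq, path, source="new"))
                counter += 1
            else:
                descend(child_seq, rank_idx + 1, lineage + [label],
                        index_path + [child])

    root = _random_sequence(rng, spec.length)
    descend(root, 0, [], [])
    return records


@dataclass
class GroupPlan:
    """Planted community structure for one metadata group."""

    substrate: str
    temperature: str = "Mesophilic"
    n_samples: int = 20
    n_strict: int = 3
    n_general: int = 3
    n_loose: int = 3
    n_crat: int = 2
    n_rare: int = 2
    n_background: int = 30


@dataclass
class SurveySimSpec:
    """Survey of count tables with planted core/CRAT/rare taxa.

    Planted occupancies sit safely inside each category's band: strict
    taxa are present (well above the 0.1% abundance cut) in 85% of the
    group's samples, general in 65%, loose in 35%; CRAT taxa appear in
    a single sample at >1%; rare taxa stay below the 0.01% rare-
    biosphere filter.  Abundance when present is drawn log-normally
    around the per-category level, mirroring typical rank-abundance
    shapes.  Counts are multinomial at each sample's depth.
    """

    groups: Sequence[GroupPlan] = field(
        default_factory=lambda: [GroupPlan("Wastewater sludge")])
    depth: int = 50_000
    replicate_pairs: bool = False
    seed: int = 0
    occupancy: Mapping[str, float] = field(
        default_factory=lambda: {"strict": 0.85, "general": 0.65,
                                 "loose": 0.35})
    present_abundance: Mapping[str, float] = field(
        default_factory=lambda: {"strict": 0.008, "general": 0.006,
                                 "loose": 0.005, "crat": 0.025,
                                 "rare": 0.00003})
    lognormal_sigma: float = 0.3

    def validate(self) -> None:
        occ = self.occupancy
        if not occ["strict"] > 0.8 or not 0.5 < occ["general"] <= 0.8 \
                or not 0.2 < occ["loose"] <= 0.5:
            raise InvalidInputError(
                "planted occupancies inconsistent with category bands")
        if self.present_abundance["crat"] <= 0.01:
            raise InvalidInputError("CRAT abundance must exceed 1%")
        if self.present_abundance["rare"] >= 0.0001:
            raise InvalidInputError("rare abundance must stay below 0.01%")


def simulate_survey(spec: SurveySimSpec) -> tuple[
        pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Counts (samples x taxa), metadata, and the planted truth table.

    Returns ``(counts, metadata, truth)`` where ``truth`` has one row
    per planted taxon per group with its intended category.  With
    ``replicate_pairs`` every profile is sampled twice (suffixes ``_r1``
    and ``_r2``), differing only by multinomial noise.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    profiles: dict[str, dict[str, float]] = {}
    meta_rows = []
    truth_rows = []
    all_taxa: list[str] = []

    for g_idx, group in enumerate(spec.groups, start=1):
        gkey = f"g{g_idx}"
        planted: list[tuple[str, str]] = []
        for cat, n in (("strict", group.n_strict),
                       ("general", group.n_general),
                       ("loose", group.n_loose),
                       ("crat", group.n_crat),
                       ("rare", group.n_rare)):
            for t_idx in range(1, n + 1):
                planted.append((f"{gkey}_{cat}_{t_idx}", cat))
        background = [f"{gkey}_bg_{i}"
                      for i in range(1, group.n_background + 1)]
        for taxon, cat in planted:
            truth_rows.append({"taxon": taxon, "group": gkey,
                               "substrate": group.substrate,
                               "temperature": group.temperature,
                               "category": cat})
        all_taxa.extend([t for t, _ in planted] + background)

        # Which samples carry each planted taxon.
        presence: dict[str, np.ndarray] = {}
        n = group.n_samples
        for taxon, cat in planted:
            if cat in spec.occupancy:
                k = round(spec.occupancy[cat] * n)
                idx = rng.choice(n, size=k, replace=False)
            elif cat == "crat":
                idx = rng.choice(n, size=1)
            else:  # rare: sprinkle through half the samples
                idx = rng.choice(n, size=max(1, n // 2), replace=False)
            presence[taxon] = np.zeros(n, dtype=bool)
            presence[taxon][idx] = True

        bg_weights = rng.lognormal(0.0, 1.0, size=len(background))
        for s_idx in range(n):
            sample = f"{gkey}_s{s_idx + 1}"
            profile: dict[str, float] = {}
            for taxon, cat in planted:
                if presence[taxon][s_idx]:
                    level = spec.present_abundance[cat]
                    profile[taxon] = level * rng.lognormal(
                        0.0, spec.lognormal_sigma)
            remainder = 1.0 - sum(profile.values())
            bg = bg_weights * rng.lognormal(
                0.0, spec.lognormal_sigma, size=len(background))
            bg = bg / bg.sum() * remainder
            for taxon, w in zip(background, bg):
                profile[taxon] = w
            profiles[sample] = profile
            meta_rows.append({"sample": sample, "group": gkey,
                              "substrate": group.substrate,
                              "temperature": group.temperature,
                              "technology": "CSTR",
                              "continent": "Europe",
                              "primer_set": "V4"})

    taxa = sorted(set(all_taxa))
    samples = []
    count_rows = []
    meta_out = []
    for row in meta_rows:
        base = row["sample"]
        p = np.array([profiles[base].get(t, 0.0) for t in taxa])
        p = p / p.sum()
        reps = ("_r1", "_r2") if spec.replicate_pairs else ("",)
        for suffix in reps:
            name = base + suffix
            samples.append(name)
            count_rows.append(rng.multinomial(spec.depth, p))
            out = dict(row)
            out["sample"] = name
            out["replicate_of"] = base
            meta_out.append(out)

    counts = pd.DataFrame(count_rows, index=samples, columns=taxa,
                          dtype=np.int64)
    meta_cols = ["sample", "group", "substrate", "temperature",
                 "technology", "continent", "primer_set", "replicate_of"]
    metadata = pd.DataFrame(meta_out, columns=meta_cols).set_index("sample")
    truth = pd.DataFrame(
        truth_rows,
        columns=["taxon", "group", "substrate", "temperature", "category"])
    return counts, metadata, truth


@dataclass
class PlantedSite:
    """One template's planted mismatch design for a primer pair."""

    fwd_mismatches: int = 0
    fwd_mismatches_3prime: int = 0
    rev_mismatches: int = 0
    rev_mismatches_3prime: int = 0


def _realize(primer: str, rng: np.random.Generator) -> str:
    """Pick one concrete base within each IUPAC code of *primer*."""
    out = []
    for c in primer.upper():
        options = sorted(IUPAC_SETS[c])
        out.append(options[rng.integers(0, len(options))])
    return "".join(out)


def _plant_mismatches(site: str, primer: str, n_total: int, n_3prime: int,
                      rng: np.random.Generator,
                      three_prime_len: int = 5) -> str:
    """Mutate *site* so it mismatches *primer* at planted positions."""
    L = len(primer)
    if n_total > L or n_3prime > min(n_total, three_prime_len):
        raise InvalidInputError("requested mismatches exceed primer length")
    three = list(range(L - three_prime_len, L))
    non3 = list(range(0, L - three_prime_len))
    chosen = list(rng.choice(three, size=n_3prime, replace=False)) + \
        list(rng.choice(non3, size=n_total - n_3prime, replace=False))
    out = list(site)
    for pos in chosen:
        allowed = [b for b in "ACGT"
                   if b not in IUPAC_SETS[primer[pos].upper()]]
        if not allowed:  # primer base is N; cannot force a mismatch there
            raise InvalidInputError(
                f"cannot plant a mismatch against N at position {pos}")
        out[pos] = allowed[rng.integers(0, len(allowed))]
    return "".join(out)


def simulate_primer_templates(
        forward: str, reverse: str,
        designs: Sequence[PlantedSite],
        seed: int = 0,
        insert_length: int = 250,
        pad_length: int = 30) -> tuple[list[ReferenceRecord], pd.DataFrame]:
    """Templates embedding both primer sites with planted mismatches.

    The reverse primer is given 5'->3' on the opposite strand; its
    binding site appears on the template as its reverse complement.
    Returns the templates plus a truth table with the planted offsets
    and mismatch counts.  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    records = []
    rows = []
    for i, d in enumerate(designs, start=1):
        fwd_site = _plant_mismatches(
            _realize(forward, rng), forward,
            d.fwd_mismatches, d.fwd_mismatches_3prime, rng)
        rev_site = _plant_mismatches(
            _realize(reverse, rng), reverse,
            d.rev_mismatches, d.rev_mismatches_3prime, rng)
        pad5 = _random_sequence(rng, pad_length)
        insert = _random_sequence(rng, insert_length)
        pad3 = _random_sequence(rng, pad_length)
        template = pad5 + fwd_site + insert + reverse_complement(rev_site) \
            + pad3
        acc = f"TPL{i}"
        records.append(ReferenceRecord(acc, template, source="new"))
        rows.append({
            "accession": acc,
            "fwd_offset": pad_length,
            "rev_offset": pad_length + len(forward) + insert_length,
            "fwd_mismatches": d.fwd_mismatches,
            "fwd_mismatches_3prime": d.fwd_mismatches_3prime,
            "rev_mismatches": d.rev_mismatches,
            "rev_mismatches_3prime": d.rev_mismatches_3prime,
        })
    return records, pd.DataFrame(rows)
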