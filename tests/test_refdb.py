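"""Database expansion: neighbours, merge, novelty, placeholder taxonomy."""

import numpy as np
import pandas as pd
import pytest

from digestax import (InvalidInputError, NoveltyRank, PlaceholderRegistry,
                      ReferenceRecord, TaxonomyPath, YarzaThresholds,
                      assign_taxonomy, classify_novelty, merge_dereplicate,
                      mutate_to_identity, nearest_neighbor, percent_identity,
                      summarize_novelty, taxa_inventory_delta)

from ._oracles import exhaustive_best_accession


def _rand(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _db(seqs: dict[str, str]) -> list[ReferenceRecord]:
    return [ReferenceRecord(acc, seq) for acc, seq in seqs.items()]


class TestNearestNeighbor:
    def test_exact_member_hits_itself(self, tiny_refs):
        hit = nearest_neighbor(tiny_refs[0], tiny_refs)
        assert hit.reference == tiny_refs[0].accession
        assert hit.identity == 100.0
        assert hit.tie_count == 1

    def test_tie_broken_lexicographically(self):
        rng = np.random.default_rng(5)
        seq = _rand(rng, 400)
        db = _db({"B": seq, "A": seq})
        hit = nearest_neighbor(seq, db)
        assert hit.reference == "A"
        assert hit.tie_count == 2

    def test_planted_97pct_query(self):
        rng = np.random.default_rng(6)
        db = _db({f"R{i}": _rand(rng, 500) for i in range(5)})
        query = mutate_to_identity(db[2].sequence, 97.0, 9)
        hit = nearest_neighbor(query, db)
        assert hit.reference == "R2"
        assert hit.identity == pytest.approx(97.0, abs=0.5)

    def test_agrees_with_exhaustive_oracle(self):
        """All-pairs scan on a small set matches the explicit-loop oracle."""
        rng = np.random.default_rng(7)
        base = _rand(rng, 300)
        seqs = {}
        for i in range(10):
            ident = 85.0 + 1.5 * i
            seqs[f"S{i:02d}"] = mutate_to_identity(base, ident, 100 + i)
        db = _db(seqs)
        for probe in ("S03", "S07"):
            rest = [r for r in db if r.accession != probe]
            hit = nearest_neighbor(seqs[probe], rest)
            acc, ident, ties = exhaustive_best_accession(
                seqs[probe], {r.accession: r.sequence for r in rest})
            assert hit.reference == acc
            assert hit.identity == pytest.approx(ident, abs=1e-9)
            assert hit.tie_count == ties

    def test_empty_db_raises(self):
        with pytest.raises(InvalidInputError):
            nearest_neighbor("ACGT", [])


class TestMergeDereplicate:
    def test_copy_under_new_accession_is_duplicate(self):
        rng = np.random.default_rng(8)
        seq = _rand(rng, 300)
        merged, rep = merge_dereplicate(_db({"A": seq}), _db({"Z": seq}))
        assert len(merged) == 1
        assert rep.n_duplicates == 1
        assert rep.n_merged == 1

    def test_counts_conserved_with_planted_duplicates(self):
        rng = np.random.default_rng(9)
        existing = _db({f"E{i}": _rand(rng, 250) for i in range(6)})
        fresh = {f"N{i}": _rand(rng, 250) for i in range(4)}
        dupes = {f"D{i}": existing[i].sequence for i in range(3)}
        incoming = _db({**fresh, **dupes})
        merged, rep = merge_dereplicate(existing, incoming)
        assert rep.n_duplicates == 3
        assert rep.n_added == 4
        assert len(merged) == rep.n_merged == 10
        assert len(merged) - rep.n_existing + rep.n_duplicates \
            == rep.n_incoming

    def test_idempotent(self):
        rng = np.random.default_rng(10)
        existing = _db({f"E{i}": _rand(rng, 250) for i in range(4)})
        incoming = _db({f"N{i}": _rand(rng, 250) for i in range(3)})
        merged, _ = merge_dereplicate(existing, incoming)
        merged2, rep2 = merge_dereplicate(merged, incoming)
        assert rep2.n_added == 0
        assert [r.accession for r in merged2] == [r.accession for r in merged]

    def test_existing_order_stable_and_precedent(self):
        rng = np.random.default_rng(11)
        seqs = {f"E{i}": _rand(rng, 200) for i in range(5)}
        merged, _ = merge_dereplicate(_db(seqs), _db({"N": seqs["E2"]}))
        assert [r.accession for r in merged] == list(seqs)

    def test_accession_collision_with_different_sequence_raises(self):
        with pytest.raises(InvalidInputError):
            merge_dereplicate(_db({"A": "ACGTACGTAC"}),
                              _db({"A": "ACGTACGTAG"}))

    def test_containment_reported_not_merged(self):
        rng = np.random.default_rng(12)
        long = _rand(rng, 400)
        merged, rep = merge_dereplicate(_db({"L": long}),
                                        _db({"S": long[50:350]}))
        assert len(merged) == 2
        assert rep.containment_warnings == [("S", "L")]


class TestClassifyNovelty:
    @pytest.mark.parametrize("identity,expected", [
        (100.0, "none"), (98.7, "none"), (98.6999, "species_novel"),
        (94.5, "species_novel"), (94.4999, "genus_novel"),
        (93.0, "genus_novel"), (86.5, "genus_novel"),
        (86.4999, "family_novel"), (82.0, "family_novel"),
        (81.9999, "order_novel"), (78.5, "order_novel"),
        (78.4999, "class_novel"), (75.0, "class_novel"),
        (74.9999, "phylum_novel"), (74.9, "phylum_novel"),
        (0.0, "phylum_novel"),
    ])
    def test_step_function_with_strict_boundaries(self, identity, expected):
        assert classify_novelty(identity) == NoveltyRank[expected]

    def test_monotone_in_identity(self):
        order = ["phylum_novel", "class_novel", "order_novel",
                 "family_novel", "genus_novel", "species_novel", "none"]
        grid = np.linspace(0, 100, 401)
        ranks = [order.index(classify_novelty(float(i)).value)
                 for i in grid]
        assert ranks == sorted(ranks)

    def test_out_of_range_raises(self):
        for bad in (-0.1, 100.1):
            with pytest.raises(InvalidInputError):
                classify_novelty(bad)

    def test_recovers_planted_rank_away_from_boundaries(self):
        """Mutated queries a full point off a threshold classify correctly."""
        rng = np.random.default_rng(13)
        base = _rand(rng, 1400)
        expectations = [
            (99.8, "none"), (96.5, "species_novel"), (90.0, "genus_novel"),
            (84.2, "family_novel"), (80.0, "order_novel"),
            (76.7, "class_novel"), (72.0, "phylum_novel")]
        for i, (target, expected) in enumerate(expectations):
            q = mutate_to_identity(base, target, 50 + i)
            ident = percent_identity(q, base)
            assert classify_novelty(ident).value == expected


class TestSummarizeNovelty:
    def test_cumulative_rows_on_planted_identities(self):
        rng = np.random.default_rng(14)
        base = _rand(rng, 1000)
        db = _db({"REF": base})
        # planted: one per novelty stratum, plus one non-novel
        targets = [99.5, 97.0, 90.0, 84.0, 80.0, 76.5, 72.0]
        incoming = [ReferenceRecord(f"Q{i}",
                                    mutate_to_identity(base, t, 200 + i))
                    for i, t in enumerate(targets)]
        table = summarize_novelty(incoming, db)
        assert table.loc["species", "count"] == 6   # all but 99.5
        assert table.loc["genus", "count"] == 5
        assert table.loc["family", "count"] == 4
        assert table.loc["order", "count"] == 3
        assert table.loc["class", "count"] == 2
        assert table.loc["phylum", "count"] == 1
        counts = table["count"].to_numpy()
        assert (counts == np.sort(counts)).all()  # cumulative: rows nest

    def test_identical_incoming_all_zero(self, tiny_refs):
        sub = tiny_refs[:2]
        table = summarize_novelty(sub, tiny_refs)
        assert (table["count"] == 0).all()
        assert (table["percentage"] == 0.0).all()

    def test_empty_incoming_raises(self, tiny_refs):
        with pytest.raises(InvalidInputError):
            summarize_novelty([], tiny_refs)


class TestAssignTaxonomy:
    def test_identical_query_inherits_full_path(self, tiny_refs):
        path = assign_taxonomy(tiny_refs[0], tiny_refs)
        assert path == tiny_refs[0].taxonomy

    def test_90pct_query_gets_placeholder_genus_species(self, tiny_refs):
        q = mutate_to_identity(tiny_refs[0].sequence, 90.0, 21)
        path = assign_taxonomy(q, tiny_refs)
        ref_path = tiny_refs[0].taxonomy
        assert path.names[:5] == ref_path.names[:5]     # family inherited
        assert path.names[5].startswith("midas_g_")
        assert path.names[6].startswith("midas_s_")
        assert path.placeholder_flags[5] and path.placeholder_flags[6]

    def test_near_identical_queries_share_placeholders(self, tiny_refs):
        """Greedy clustering: 99.5%-identical novelties share names."""
        reg = PlaceholderRegistry()
        q1 = mutate_to_identity(tiny_refs[0].sequence, 90.0, 22)
        q2 = mutate_to_identity(q1, 99.5, 23)
        assert percent_identity(q1, q2) > 98.7
        p1 = assign_taxonomy(q1, tiny_refs, registry=reg)
        p2 = assign_taxonomy(q2, tiny_refs, registry=reg)
        assert p1.names[5] == p2.names[5]
        assert p1.names[6] == p2.names[6]

    def test_distant_novelties_get_distinct_names(self, tiny_refs):
        reg = PlaceholderRegistry()
        q1 = mutate_to_identity(tiny_refs[0].sequence, 90.0, 24)
        q2 = mutate_to_identity(tiny_refs[0].sequence, 90.0, 25)
        assert percent_identity(q1, q2) < 94.5  # different planted genera
        p1 = assign_taxonomy(q1, tiny_refs, registry=reg)
        p2 = assign_taxonomy(q2, tiny_refs, registry=reg)
        assert p1.names[5] != p2.names[5]

    def test_numbering_deterministic_under_input_order(self, tiny_refs):
        queries = [mutate_to_identity(tiny_refs[i % 4].sequence, 90.0, 30 + i)
                   for i in range(6)]

        def run():
            reg = PlaceholderRegistry()
            return [assign_taxonomy(q, tiny_refs, registry=reg).names
                    for q in queries]

        assert run() == run()

    def test_registry_resumes_past_existing_placeholders(self):
        db = [ReferenceRecord(
            "R1", "ACGT" * 100,
            TaxonomyPath(("Bacteria", "P", "C", "O", "F",
                          "midas_g_41", "midas_s_77")))]
        reg = PlaceholderRegistry.from_database(db)
        assert reg.counters["genus"] == 42
        assert reg.counters["species"] == 78


class TestTaxaInventoryDelta:
    def _paths(self, genera):
        return [TaxonomyPath(("Bacteria", "P", "C", "O", "F", g, f"{g}_sp"))
                for g in genera]

    def test_no_change_gives_zero_increase(self):
        paths = self._paths(["G1", "G2"])
        table = taxa_inventory_delta(paths, paths)
        assert (table["new"] == 0).all()
        assert (table["pct_increase"].fillna(0.0) == 0.0).all()

    def test_counts_and_percentage(self):
        before = self._paths(["G1", "G2", "G3"])
        after = before + self._paths(["G4"])
        table = taxa_inventory_delta(before, after)
        assert table.loc["genus", "total"] == 4
        assert table.loc["genus", "new"] == 1
        assert table.loc["genus", "pct_increase"] == pytest.approx(33.3)

    def test_all_new_is_nan_not_error(self):
        table = taxa_inventory_delta([], self._paths(["G1"]))
        assert np.isnan(table.loc["genus", "pct_increase"])


class TestYarzaThresholds:
    def test_defaults_strictly_increasing(self):
        t = YarzaThresholds().as_tuple()
        assert list(t) == sorted(t)
        assert len(set(t)) == len(t)

    def test_invalid_ordering_rejected(self):
        with pytest.raises(InvalidInputError):
            YarzaThresholds(genus=99.0)
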