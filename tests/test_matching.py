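"""Matching schemes: triple-criterion threshold, priority order, batching."""

import itertools
import random

import pytest

from biosync.datastore import Datastore
from biosync.matching import (
    CONFLICT,
    MATCHED,
    NEW,
    GeneIndex,
    IncomingGene,
    PriorityPolicy,
    classify_batch,
    match_by_priority,
    match_gene_triple,
    normalize_accession,
)
from conftest import seed_gene


def make_index(store):
    return GeneIndex(store.snapshot())


def brute_force_triple(incoming, store):
    """Independent oracle: score every (incoming, gene) pair on all three
    criteria and classify by the best-scoring gene's criterion count."""
    snap = store.snapshot()
    best = {}
    for rec in snap.records:
        if rec.status != "active" or rec.species != incoming.species:
            continue
        xrefs = [x for x in snap.xrefs if x.owner == rec.stable_id]
        met = set()
        if incoming.stable_id_claim == rec.stable_id:
            met.add("stable_id")
        if incoming.ncbi_gene_id and any(
            x.xref_db == "NCBIGene" and x.accession == incoming.ncbi_gene_id for x in xrefs
        ):
            met.add("ncbi_id")
        stored = {
            normalize_accession(x.accession) for x in xrefs if x.xref_db == "SeqAccession"
        }
        if any(normalize_accession(a) in stored for a in incoming.seq_accessions):
            met.add("seq_acc")
        if met:
            best[rec.stable_id] = met
    if not best:
        return NEW, None
    if len(best) > 1:
        return CONFLICT, None
    ((gene, met),) = best.items()
    return (MATCHED if len(met) == 3 else CONFLICT), gene


class TestTripleCriterion:
    def test_full_agreement_is_a_match(self, store):
        g = seed_gene(store, ncbi="100", accessions=("NM_1",))
        inc = IncomingGene("k1", "rat", "Abc1", stable_id_claim=g,
                           ncbi_gene_id="100", seq_accessions=("NM_1",))
        result = match_gene_triple(inc, make_index(store))
        assert result.outcome == MATCHED
        assert result.stable_id == g
        assert result.criteria_met == frozenset({"stable_id", "ncbi_id", "seq_acc"})

    def test_agreement_on_ncbi_alone_is_a_conflict(self, store):
        g = seed_gene(store, ncbi="100", accessions=("NM_1",))
        inc = IncomingGene("k1", "rat", "Abc1", ncbi_gene_id="100",
                           seq_accessions=("NM_999",))
        result = match_gene_triple(inc, make_index(store))
        assert result.outcome == CONFLICT
        assert result.candidates == (g,)
        assert result.criteria_met == frozenset({"ncbi_id"})

    def test_unknown_identifiers_are_new(self, store):
        seed_gene(store, ncbi="100", accessions=("NM_1",))
        inc = IncomingGene("k1", "rat", "Abc1", ncbi_gene_id="777",
                           seq_accessions=("NM_777",))
        assert match_gene_triple(inc, make_index(store)).outcome == NEW

    @pytest.mark.parametrize(
        "subset", list(itertools.product([False, True], repeat=3)),
        ids=lambda s: "".join("SNA"[i] if s[i] else "-" for i in range(3)),
    )
    def test_all_criterion_subsets_classify_by_cardinality(self, store, subset):
        """Merge only at 3/3; 1-2 criteria conflict; 0 criteria new."""
        claim_ok, ncbi_ok, acc_ok = subset
        g = seed_gene(store, ncbi="100", accessions=("NM_1",))
        inc = IncomingGene(
            "k1", "rat", "Abc1",
            stable_id_claim=g if claim_ok else None,
            ncbi_gene_id="100" if ncbi_ok else "999",
            seq_accessions=("NM_1",) if acc_ok else ("NM_999",),
        )
        result = match_gene_triple(inc, make_index(store))
        expected_outcome, expected_gene = brute_force_triple(inc, store)
        assert result.outcome == expected_outcome
        n_met = sum(subset)
        assert result.outcome == (MATCHED if n_met == 3 else CONFLICT if n_met else NEW)

    def test_criteria_pointing_at_different_genes_conflict_with_all_candidates(self, store):
        a = seed_gene(store, ncbi="100", accessions=("NM_1",))
        b = seed_gene(store, ncbi="200", accessions=("NM_2",))
        inc = IncomingGene("k1", "rat", "Abc1", ncbi_gene_id="100",
                           seq_accessions=("NM_2",))
        result = match_gene_triple(inc, make_index(store))
        assert result.outcome == CONFLICT
        assert set(result.candidates) == {a, b}

    def test_cross_species_identifier_hit_is_a_conflict_not_a_merge(self, store):
        seed_gene(store, species="human", ncbi="100", accessions=("NM_1",))
        inc = IncomingGene("k1", "rat", "Abc1", ncbi_gene_id="100",
                           seq_accessions=("NM_1",))
        assert match_gene_triple(inc, make_index(store)).outcome == CONFLICT

    def test_retired_genes_are_invisible_to_matching(self, store):
        g = seed_gene(store, ncbi="100", accessions=("NM_1",))
        store.retire_object(g, "retired")
        inc = IncomingGene("k1", "rat", "Abc1", ncbi_gene_id="100",
                           seq_accessions=("NM_1",))
        assert match_gene_triple(inc, make_index(store)).outcome == NEW

    def test_accession_version_suffix_is_ignored(self, store):
        g = seed_gene(store, ncbi="100", accessions=("NM_1.2",))
        inc = IncomingGene("k1", "rat", "Abc1", stable_id_claim=g,
                           ncbi_gene_id="100", seq_accessions=("NM_1.5",))
        assert match_gene_triple(inc, make_index(store)).outcome == MATCHED

    def test_random_instances_agree_with_brute_force_oracle(self):
        """Triple scheme ≡ exhaustive pairwise scoring on instances ≤ 50 genes."""
        rng = random.Random(42)
        for trial in range(20):
            store = Datastore()
            n = rng.randint(1, 50)
            genes = [
                seed_gene(store, ncbi=str(100 + i), accessions=(f"NM_{i}",))
                for i in range(n)
            ]
            index = make_index(store)
            for _ in range(10):
                pick = rng.choice(genes)
                inc = IncomingGene(
                    "k", "rat", "X",
                    stable_id_claim=pick if rng.random() < 0.5 else None,
                    ncbi_gene_id=str(100 + rng.randrange(n)) if rng.random() < 0.8 else None,
                    seq_accessions=(f"NM_{rng.randrange(n)}",) if rng.random() < 0.8 else (),
                )
                got = match_gene_triple(inc, index)
                expected_outcome, expected_gene = brute_force_triple(inc, store)
                assert got.outcome == expected_outcome
                if got.outcome == MATCHED:
                    assert got.stable_id == expected_gene


class TestPriorityMatching:
    def test_hgnc_wins_over_disagreeing_ensembl_and_discrepancy_is_logged(self, store):
        a = seed_gene(store, hgnc="HGNC:1", species="human")
        b = seed_gene(store, ensembl="ENSG2", species="human")
        inc = IncomingGene("PA1", "human", "X", hgnc_id="HGNC:1", ensembl_id="ENSG2")
        result = match_by_priority(inc, make_index(store))
        assert result.outcome == MATCHED and result.stable_id == a
        assert any("disagrees" in note for note in result.notes)

    def test_falls_through_to_ncbi_when_hgnc_absent(self, store):
        c = seed_gene(store, ncbi="300", species="human")
        inc = IncomingGene("PA1", "human", "X", ncbi_gene_id="300")
        result = match_by_priority(inc, make_index(store))
        assert result.outcome == MATCHED and result.stable_id == c
        assert result.criteria_met == frozenset({"NCBIGene"})

    def test_no_identifiers_is_new(self, store):
        seed_gene(store, ncbi="300", species="human")
        assert match_by_priority(IncomingGene("PA1", "human", "X"),
                                 make_index(store)).outcome == NEW

    def test_ambiguous_identifier_is_a_conflict_listing_candidates(self, store):
        a = seed_gene(store, hgnc="HGNC:1", species="human")
        b = seed_gene(store, hgnc="HGNC:1", species="human")
        inc = IncomingGene("PA1", "human", "X", hgnc_id="HGNC:1")
        result = match_by_priority(inc, make_index(store))
        assert result.outcome == CONFLICT
        assert set(result.candidates) == {a, b}

    def test_policy_rejects_duplicates(self):
        with pytest.raises(ValueError):
            PriorityPolicy(ordered_dbs=("HGNC", "HGNC"))


class TestClassifyBatch:
    def test_partition_sizes_match_construction(self, store):
        for i in range(7):
            seed_gene(store, ncbi=str(i), accessions=(f"NM_{i}",))
        index = make_index(store)
        incomings = []
        snap_ids = sorted(index.records)
        for i in range(7):  # full agreement
            incomings.append(IncomingGene(f"m{i}", "rat", "X", stable_id_claim=snap_ids[i],
                                          ncbi_gene_id=str(i), seq_accessions=(f"NM_{i}",)))
        for i in range(2):  # partial agreement
            incomings.append(IncomingGene(f"c{i}", "rat", "X", ncbi_gene_id=str(i)))
        incomings.append(IncomingGene("n0", "rat", "X", ncbi_gene_id="999"))
        report = classify_batch(incomings, lambda g: match_gene_triple(g, index))
        assert report.sizes() == (7, 2, 1)
        assert sum(report.sizes()) == len(incomings)

    def test_empty_input_gives_empty_report(self):
        report = classify_batch([], lambda g: (_ for _ in ()).throw(AssertionError))
        assert report.sizes() == (0, 0, 0)

    def test_duplicate_source_keys_first_wins_later_skipped(self, store):
        g = seed_gene(store, ncbi="1", accessions=("NM_1",))
        index = make_index(store)
        inc = IncomingGene("dup", "rat", "X", stable_id_claim=g, ncbi_gene_id="1",
                           seq_accessions=("NM_1",))
        report = classify_batch([inc, inc], lambda x: match_gene_triple(x, index))
        assert report.sizes() == (1, 0, 0)
        assert report.skipped == ["dup"]

    def test_resolution_forces_outcome(self, store):
        g = seed_gene(store, ncbi="1", accessions=("NM_1",))
        index = make_index(store)
        inc = IncomingGene("k", "rat", "X", ncbi_gene_id="1")  # would conflict
        report = classify_batch([inc], lambda x: match_gene_triple(x, index),
                                resolutions={"k": f"merge:{g}"})
        assert report.sizes() == (1, 0, 0)
        assert report.matched[0][1].stable_id == g
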