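"""End-to-end pipelines: gene sync, xref sync, conflicts log, partitions."""

import datetime

import pytest

from biosync import (
    Datastore,
    DriftParams,
    IncomingGene,
    PipelineConfig,
    drift,
    generate_universe,
    write_gene_file,
    write_xref_file,
)
from biosync.matching import MatchResult
from biosync.pipelines import (
    ParseError,
    current_assignments,
    parse_gene_file,
    parse_xref_file,
    resolve_conflict,
    run_gene_sync,
    run_xref_sync,
    write_conflicts_log,
)
from conftest import seed_gene


@pytest.fixture
def gene_setup(gene_config):
    store = Datastore()
    state = generate_universe(50, species="rat", seed=7)
    config = gene_config()
    return store, state, config


def sync_and_write_back(store, config, state, **kwargs):
    summary = run_gene_sync(store, config, state, **kwargs)
    return summary, state.with_stable_ids(current_assignments(store, state))


class TestGeneFileDialect:
    def test_round_trip_through_the_tsv_dialect(self, tmp_path, universe):
        path = write_gene_file(universe, tmp_path / "genes.tsv")
        parsed = parse_gene_file(path)
        assert len(parsed) == len(universe)
        by_key = {g.source_key: g for g in parsed}
        for rec in universe.records.values():
            g = by_key[rec.source_key]
            assert g.ncbi_gene_id == rec.ncbi_gene_id
            assert g.seq_accessions == rec.seq_accessions
            assert len(g.positions) == len(rec.positions)

    def test_mutated_header_is_a_parse_error(self, tmp_path, universe):
        path = write_gene_file(universe, tmp_path / "genes.tsv")
        lines = path.read_text().splitlines()
        lines[0] = lines[0].replace("symbol", "gene_symbol")
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ParseError, match="header"):
            parse_gene_file(path)

    def test_xref_dialect_round_trip_plain_and_zipped(self, tmp_path, universe):
        plain = write_xref_file(universe, tmp_path / "xrefs.tsv")
        zipped = write_xref_file(universe, tmp_path / "xrefs.zip", zip_container=True)
        assert parse_xref_file(plain) == parse_xref_file(zipped)


class TestGeneSync:
    def test_first_run_loads_everything_as_new(self, gene_setup):
        store, state, config = gene_setup
        summary = run_gene_sync(store, config, state)
        assert summary.status == "success"
        assert summary.counters.new == 50
        assert summary.counters.matched == 0
        active = [r for r in store.snapshot().records if r.status == "active"]
        assert len(active) == 50

    def test_second_run_on_unchanged_source_is_idempotent(self, gene_setup):
        store, state, config = gene_setup
        _, state = sync_and_write_back(store, config, state)
        second, _ = sync_and_write_back(store, config, state)
        c = second.counters
        assert (c.inserted, c.updated, c.deleted) == (0, 0, 0)
        assert c.matched == 50 and c.unchanged > 0

    def test_engineered_overlap_counts_and_conflict_rows(self, gene_config, tmp_path):
        """45 matched / 3 conflicts / 2 new by construction."""
        store = Datastore()
        state = generate_universe(50, species="rat", seed=7)
        config = gene_config(output_dir=str(tmp_path))
        _, state = sync_and_write_back(store, config, state)
        # 2 removed + 2 added keeps incoming at 50 with 2 genuinely new
        state2, manifest = drift(state, DriftParams(f_new=0.04, f_removed=0.04), seed=1)
        # break the stable-id claim on 3 survivors -> 2/3 criteria -> conflict
        import dataclasses

        records = dict(state2.records)
        survivors = sorted(k for k in records if k not in manifest.added)
        conflict_keys = survivors[:3]
        for key in conflict_keys:
            records[key] = dataclasses.replace(records[key], stable_id=None)
        state2 = type(state2)(records, state2.version, state2.species,
                              state2.assemblies, state2.next_serial)
        summary = run_gene_sync(store, config, state2)
        c = summary.counters
        assert (c.matched, c.conflicts, c.new) == (45, 3, 2)
        log = (tmp_path / "gene_sync_conflicts.tsv").read_text().splitlines()
        assert len(log) == 1 + 3
        assert [line.split("\t")[0] for line in log[1:]] == conflict_keys  # sorted

    def test_conflicts_never_mutate_the_store(self, gene_setup):
        store, state, config = gene_setup
        _, state = sync_and_write_back(store, config, state)
        import dataclasses

        records = {
            k: dataclasses.replace(v, stable_id=None, symbol=v.symbol + "X")
            for k, v in state.records.items()
        }
        fp = store.fingerprint()
        conflicted = type(state)(records, state.version, state.species,
                                 state.assemblies, state.next_serial)
        summary = run_gene_sync(store, config, conflicted)
        assert summary.counters.conflicts == 50
        # conflicted records were not touched: second-run sweep would see them
        # stale, but nothing was updated either
        snap = store.snapshot()
        assert not any("X" in r.symbol for r in snap.records)

    def test_unregistered_assembly_warns_and_applies_the_rest(self, gene_config):
        store = Datastore()
        state = generate_universe(10, species="rat", seed=7, assemblies=("GRCr8", "GRCr9"))
        config = gene_config(registered_assemblies=("GRCr8",))
        summary = run_gene_sync(store, config, state)
        assert summary.status == "success"
        assert any("unrecognized assembly" in w for w in summary.warnings)
        positions = store.snapshot().positions
        assert positions and all(p.assembly == "GRCr8" for p in positions)

    def test_file_source_and_state_source_agree(self, gene_setup, tmp_path):
        store_a, state, config = gene_setup
        store_b = Datastore()
        path = write_gene_file(state, tmp_path / "genes.tsv")
        run_gene_sync(store_a, config, state)
        run_gene_sync(store_b, config, path)
        assert store_a.fingerprint() == store_b.fingerprint()

    def test_removed_gene_is_retired_not_deleted(self, gene_setup):
        store, state, config = gene_setup
        _, state = sync_and_write_back(store, config, state)
        drifted, manifest = drift(state, DriftParams(f_removed=0.04), seed=3)
        ids_before = current_assignments(store, state)
        summary = run_gene_sync(store, config, drifted)
        assert summary.status == "success"
        for key in manifest.removed:
            rec = store.get_record(ids_before[key])
            assert rec is not None and rec.status == "retired"

    def test_adaptive_fetch_source_matches_direct_load(self, gene_setup):
        from biosync.adaptive_fetcher import FetchPolicy
        from biosync.synthetic_source import mock_endpoint

        store_a, state, config = gene_setup
        store_b = Datastore()
        run_gene_sync(store_a, config, state)
        endpoint = mock_endpoint(state, capacity=10, p_fail=0.1, seed=4)
        run_gene_sync(store_b, config, endpoint=endpoint,
                      fetch_ids=list(state.records),
                      fetch_policy=FetchPolicy(initial_batch=4, shuffle_seed=4))
        assert store_a.fingerprint() == store_b.fingerprint()


class TestPartitionedRuns:
    def make_two_species(self, n=10):
        rat = generate_universe(n, species="rat", seed=1)
        human = generate_universe(n, species="human", seed=2)
        records = {}
        for i, rec in enumerate(rat.records.values()):
            records[f"R{i}"] = rec.__class__(**{**rec.__dict__, "source_key": f"R{i}"})
        for i, rec in enumerate(human.records.values()):
            import dataclasses

            records[f"H{i}"] = dataclasses.replace(
                rec, source_key=f"H{i}", ncbi_gene_id=str(500_000 + i)
            )
        return type(rat)(records, 0, "mixed", rat.assemblies, 2 * n)

    def test_partitions_run_independently_on_failure(self, gene_config):
        store = Datastore()
        state = self.make_two_species()
        config = gene_config(species_processed=("human", "rat"),
                             partition_key="species")

        def fail_rat_apply(ctx):
            if ctx.get("partition") == "rat":
                raise RuntimeError("injected")

        summary = run_gene_sync(store, config, state, hooks={"apply": fail_rat_apply})
        assert summary.status == "failed"
        assert summary.failed_phase == "apply[rat]"
        # partition 1 (human sorts first) fully applied; rat untouched
        species_present = {r.species for r in store.snapshot().records}
        assert species_present == {"human"}

    def test_partitioned_and_unpartitioned_runs_agree_on_content(self, gene_config):
        """Stable-ID allocation order differs between the two modes (by
        design); the loaded content must not."""
        from biosync.reference import store_content

        state = self.make_two_species()
        contents = []
        for key in (None, "species"):
            store = Datastore()
            config = gene_config(species_processed=("human", "rat"), partition_key=key)
            summary = run_gene_sync(store, config, state)
            assert summary.status == "success"
            contents.append(store_content(store, "gene_sync"))
        assert contents[0] == contents[1]


class TestXrefSync:
    @pytest.fixture
    def human_store(self, gene_config):
        """Store pre-loaded with human genes the xref file can hit."""
        store = Datastore()
        state = generate_universe(20, species="human", seed=9)
        config = gene_config(species_processed=("human",))
        run_gene_sync(store, config, state)
        return store, state

    def xref_config(self, **overrides):
        kwargs = dict(pipeline_name="xref_sync", species_processed=("human",))
        kwargs.update(overrides)
        return PipelineConfig(**kwargs)

    def test_fresh_store_inserts_all_matchable_rows(self, human_store, tmp_path):
        store, state = human_store
        path = write_xref_file(state, tmp_path / "xrefs.tsv")
        summary = run_xref_sync(store, self.xref_config(), path)
        assert summary.status == "success"
        assert summary.counters.inserted == 20
        assert summary.counters.deleted == 0

    def test_rerun_on_identical_file_is_idempotent(self, human_store, tmp_path):
        store, state = human_store
        path = write_xref_file(state, tmp_path / "xrefs.tsv")
        run_xref_sync(store, self.xref_config(), path)
        second = run_xref_sync(store, self.xref_config(), path)
        c = second.counters
        assert (c.inserted, c.updated, c.deleted) == (0, 0, 0)
        assert c.unchanged == 20

    def test_single_removed_accession_is_swept_at_the_cap(self, human_store, tmp_path):
        store, state = human_store
        path = write_xref_file(state, tmp_path / "xrefs.tsv")
        run_xref_sync(store, self.xref_config(), path)
        # drop exactly 1 of 20 accessions: 5% == cap, sweep proceeds
        lines = path.read_text().splitlines()
        removed_accession = lines[1].split("\t")[0]
        path.write_text("\n".join([lines[0]] + lines[2:]) + "\n")
        summary = run_xref_sync(store, self.xref_config(), path)
        assert summary.status == "success"
        assert summary.counters.deleted == 1
        remaining = {x.accession for x in store.snapshot(attribution="xref_sync").xrefs}
        assert removed_accession not in remaining

    def test_two_removed_accessions_abort_the_sweep(self, human_store, tmp_path):
        store, state = human_store
        path = write_xref_file(state, tmp_path / "xrefs.tsv")
        run_xref_sync(store, self.xref_config(), path)
        lines = path.read_text().splitlines()
        path.write_text("\n".join([lines[0]] + lines[3:]) + "\n")  # 2/20 = 10% > 5%
        summary = run_xref_sync(store, self.xref_config(), path)
        assert summary.status == "failed"
        assert summary.failed_phase == "sweep"
        assert len(store.snapshot(attribution="xref_sync").xrefs) == 20  # nothing deleted

    def test_unparseable_file_fails_at_parse_with_no_mutations(self, human_store, tmp_path):
        store, state = human_store
        path = tmp_path / "xrefs.tsv"
        path.write_text("Totally\twrong\theader\n")
        fp = store.fingerprint()
        summary = run_xref_sync(store, self.xref_config(), path)
        assert summary.status == "failed" and summary.failed_phase == "parse"
        assert store.fingerprint() == fp


class TestConflictsLogAndResolution:
    def test_zero_conflicts_writes_header_only(self, tmp_path):
        path = write_conflicts_log([], tmp_path / "conflicts.tsv")
        assert path.read_text().splitlines()[0].startswith("source_key\t")
        assert len(path.read_text().splitlines()) == 1

    def test_multi_candidate_conflicts_join_candidates(self, tmp_path):
        inc = IncomingGene("k1", "rat", "X", ncbi_gene_id="1")
        res = MatchResult("conflict", candidates=(4, 9), criteria_met=frozenset({"ncbi_id"}))
        path = write_conflicts_log([(inc, res)], tmp_path / "conflicts.tsv")
        row = path.read_text().splitlines()[1].split("\t")
        assert row[3] == "4;9"

    def test_resolution_merge_forces_match_on_next_run(self, gene_config):
        store = Datastore()
        gene = seed_gene(store, ncbi="100", accessions=("NM_1",))
        config = gene_config()
        inc_state = generate_universe(0, seed=1)
        import dataclasses

        from biosync.synthetic_source import SourceRecord

        rec = SourceRecord(
            source_key="K1", species="rat", symbol="Abc1", name="n",
            ncbi_gene_id="100", hgnc_id=None, ensembl_id=None, pharmgkb_id=None,
            seq_accessions=("NM_999",), positions=(),
        )
        state = dataclasses.replace(inc_state)
        state.records["K1"] = rec
        first = run_gene_sync(store, config, state)
        assert first.counters.conflicts == 1  # ncbi hit only
        resolve_conflict(store, "K1", f"merge:{gene}")
        second = run_gene_sync(store, config, state)
        assert second.counters.matched == 1 and second.counters.conflicts == 0

    def test_resolution_to_missing_record_rejected(self, store):
        with pytest.raises(ValueError):
            resolve_conflict(store, "K1", "merge:999")
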