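# biosync

An incremental synchronization framework for biological knowledgebase
import pipelines — the machinery a model-organism database uses to keep a
local store of stably identified gene records and cross-references in
sync with large external sources (NCBI Gene, HGNC, Ensembl,
PharmGKB-style association files) that drift a little every week.

## Who this is for

Developers and data engineers of curated biological resources who import
third-party data on a schedule and need the imports to be *safe*:
identifiers must persist, curator-entered data must be untouchable by
automation, a truncated download must never silently gut the database,
and a failed run must leave no half-applied state behind.

## The model

Instead of dropping and reloading a dataset on every run, each pipeline:

1. **Snapshots** its slice of the store into memory in one bulk query.
2. **Matches** each incoming record against resident records.  Gene
   records merge automatically only when all three identifier criteria
   agree — the echoed stable ID, the NCBI Gene ID, and at least one
   sequence accession; partial agreement (1–2 criteria) is routed to a
   conflicts log for curator review, zero agreement creates a new record
   with a freshly allocated, never-reused stable ID.  Association files
   instead match by identifier priority: HGNC, then NCBI Gene, then
   Ensembl.
3. **Plans** a minimal field-level delta: an update appears only where
   old ≠ new; records equal field-by-field are recorded as unchanged.
4. **Applies** the plan as one atomic batch, *touching* (timestamping
   with the run-start tick) every record it compared, changed or not.
5. **Sweeps** stale rows: anything still attributed to the pipeline
   whose timestamp predates the run start is, by elimination, gone from
   the source — and is deleted, *unless* the stale fraction of any
   object class exceeds the cap (default 5%), in which case the sweep
   aborts with zero deletions and leaves the decision to a human.
6. **Reports** counters, warnings, conflicts, and archives the incoming
   file.

Runs are short-circuit: the first failing phase stops everything after
it.  Downloads go through an adaptive batcher that doubles its request
size on success and requeue-shuffle-halves on failure, oscillating
around the source's unpublished rate limit.

A seeded synthetic source (`biosync.synthetic_source`) emulates the
remote databases — including weekly drift with a ground-truth manifest
and an intermittently failing endpoint — so every test and example runs
without a network.

## Worked example

```sh
python examples/02_gene_sync_drift.py
```

prints:

```
week 0: 500 new records, 3185 rows inserted
week 1 (unchanged source): matched=500 inserted=0 updated=0 deleted=0 unchanged=500
week 2 (drifted source): new=10 updated=19 deleted=51 rows
  drift manifest said: +10 / ~25 / -10 records
  10 genes retired (still queryable; IDs never reused)
```

Week 0 is a cold load: 500 incoming gene records are all new, expanding
to 3185 store rows (records, xrefs, positions).  Week 1 re-runs on the
identical source: all 500 match and nothing is written — the idempotence
signature.  Week 2 drifts the source (2% new, 5% changed, 2% removed):
only the drifted fraction is written, the sweep deletes exactly the rows
of the 10 vanished genes (51 rows), and those genes are retired — still
retrievable by stable ID, with their IDs never reused.  (Of the ~25
changed records, only those whose mutated field maps to a store update
produce write operations.)

Other examples cover source generation (`01`), the sweep cap boundary
(`03`), adaptive fetching (`04`), and association-file import (`05`).
A thin CLI wraps the same calls: `biosync gen-source`, `biosync
sync-genes`, `biosync sync-xref`, `biosync sweep --dry-run`, `biosync
resolve`.

## Layout

- `src/biosync/datastore.py` — SQLite-backed store: stable IDs, atomic
  mutation batches, snapshots, manual-attribution protection
- `src/biosync/matching.py` — triple-criterion and priority matchers
- `src/biosync/sync_engine.py` — diff planning, touch semantics, phase
  orchestration, properties-file config
- `src/biosync/stale_sweeper.py` — capped touch-and-sweep deletion
- `src/biosync/adaptive_fetcher.py` — grow/halve batched downloading
- `src/biosync/pipelines.py` — gene-record and xref-association pipelines
- `src/biosync/synthetic_source.py` — seeded universe, drift, mock endpoint
- `src/biosync/reporting.py` — run summaries, changelogs, archiving
- `src/biosync/reference.py` — drop-and-reload oracle (tests only)
- `docs/methods.md` — model, parameters, design decisions, limitations
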