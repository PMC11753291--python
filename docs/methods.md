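# Methods

## The synchronization model

`biosync` implements incremental-update ETL for a curated knowledgebase.
The store is the system of record for *identity* (stable IDs, statuses,
curator-entered rows); external sources are the system of record for
*content* (gene attributes, cross-references, positions).  Each pipeline
run reconciles the two under four safety obligations:

1. **Identity persistence.**  Stable IDs are allocated from a strictly
   increasing counter and never reused, even when a record is retired or
   an allocation is burned by a failed run.  Records are never physically
   deleted; they move `active → withdrawn | retired` and remain
   retrievable forever.
2. **Provenance protection.**  Every xref and position carries an
   attribution — the pipeline that created it, or `manual`.  Any batch
   containing a delete, update, or touch of a `manual` row is rejected
   whole; the sweep never considers `manual` rows and refuses to run for
   the `manual` attribution.
3. **Atomicity.**  All writes flow through one `apply_atomic` batch per
   phase inside a single SQLite transaction: a failure anywhere rolls the
   store back exactly, including the touch timestamps.  Phases run in the
   fixed order download → parse/QC → plan → apply → sweep → report, and
   the first failure short-circuits the rest — in particular, the sweep
   never runs after a failed apply, because sweeping against a store
   whose touches did not land would delete live data.
4. **Bounded automation.**  Stale-data deletion is capped (below).

### Touch-and-sweep

Stale detection needs no tombstones and no full diff of the previous
file: every row the pipeline *compares* against incoming data gets its
last-modified timestamp set to the run-start tick, whether or not it
changed.  After a successful apply, rows still attributed to the
pipeline with an older timestamp were not in the source; they are
deleted in one atomic batch.  Timestamps are integer run ticks from a
store-internal logical clock, not wall-clock time, which makes every
touch/sweep scenario exactly reproducible in tests.

The **cap** guards the failure mode this design is exposed to: a
truncated or half-transferred source file makes untouched rows — and
thus mass deletion — look legitimate.  If the stale fraction exceeds
`stale_cap_fraction` (default 0.05, per-pipeline overridable), the sweep
aborts and deletes nothing; exactly-at-cap proceeds, strictly-above
aborts.  The denominator is the pipeline's pre-sweep row count, and the
fraction is evaluated separately per object class (xrefs vs positions),
so a class with few rows cannot be wiped out under cover of a large one;
any class over its cap aborts the whole sweep, keeping the outcome
all-or-nothing.  Candidates of an aborted sweep stay stale and reappear
next run.

Two refinements follow from the semantics rather than the mechanism:

- **Conflict candidates are not stale.**  A record routed to the
  conflicts log was present in the source but unmatchable, and it is
  deliberately not touched (conflicts must not mutate the store).  A
  literal timestamp sweep would garbage-collect its rows while a curator
  reviews it, so pipelines exclude the run's conflict candidates from
  both the sweep's candidate set and its denominator.
- **Record retirement.**  When the sweep deletes a gene's
  pipeline-attributed NCBI Gene xref, the gene itself has left the
  source; the pipeline retires the record (status change, ID retained)
  rather than deleting it.

### Matching

Gene records merge automatically only on full agreement of three
criteria against a single candidate: the stable ID the source echoes
back, the NCBI Gene ID, and at least one sequence accession (compared
case-sensitively after whitespace trimming and version-suffix stripping,
so `NM_1.2 ≡ NM_1`).  Candidate resolution order is stable-ID claim,
else NCBI ID, else any accession; identifiers pointing at two or more
distinct genes always produce a conflict listing every candidate —
cross-record agreement must never auto-merge.  Species is checked before
identifiers; a cross-species hit is a conflict.  1–2 criteria → conflicts
log; 0 → new record.  Duplicate source keys within a file: first wins,
later occurrences are flagged and skipped.

Association files use priority matching instead: the first identifier in
HGNC → NCBI Gene → Ensembl order that resolves to exactly one resident
gene wins; lower-priority disagreement is logged but does not change the
outcome; an ambiguous winning identifier is a conflict.

Curator decisions are recorded as resolutions (`merge:<id>` or `new`)
and force the outcome on subsequent runs; conflicts are re-reported every
run until resolved.

### Planning granularity

Scalar record fields (symbol, name, description) diff field-by-field.
Cross-references split by cardinality: classes where a gene carries at
most one accession (HGNC, NCBI Gene, Ensembl, PharmGKB) update in place
when the accession changes — one changed external ID costs exactly one
update operation — while the multi-valued sequence-accession class uses
set difference: missing accessions are inserted, vanished ones are left
untouched for the sweep, present ones are touched.  Positions are keyed
by (assembly, chromosome); an interval change on the same key is an
in-place update.  Positions on an assembly not registered in the config
are skipped with a prominent run warning, mirroring how a new genome
assembly is detected: a human registers the assembly and reruns.

The planner can compare against the bulk in-memory snapshot (default) or
issue per-record queries, and can split diffing across worker threads;
both switches exist because they are classic places for nondeterminism
to creep in, and the test suite pins the plan and final store state to be
identical across all four combinations.

### Adaptive fetching

Remote sources cap request sizes without publishing the cap.  The
fetcher starts small (default 10 IDs) and grows multiplicatively on
success (`ceil(prev × growth_factor)`, factor 2.0 — the natural
multiplicative-increase choice where the source only promises
"proportionally more"); on failure — an endpoint error *or* a response
missing some requested IDs — it keeps whatever was returned, folds the
missing IDs back into the queue, shuffles the queue with a seeded
generator, and halves the batch (`max(min_batch, floor(prev / 2))`),
continuing to grow from the halved value.  Any ID failing more than
`max_attempts_per_id` (default 10) times aborts the run naming the IDs.
Every request is recorded in a trace whose scheduled sizes must replay
exactly through the pure schedule function — the audit trail used by the
determinism tests.

## The synthetic source

The generator emulates the *shape* of weekly gene-database exports, not
their biology: numeric NCBI-style IDs, `HGNC:n` on ~60% of records,
`ENSG…` on ~80%, 1–3 `NM_…` accessions, one position per registered
assembly on chromosomes 1–20, and a `PA…` accession for the association
dialect.  Drift per step removes `round(f_removed·n)` records, mutates
one field on `round(f_changed·n)` survivors, and appends
`round(f_new·n)` new ones, returning an exact manifest — the oracle the
sweep and plan are checked against.  Default drift fractions used by the
acceptance scenarios are 2% new / 5% changed / 2% removed per step,
weekly-scale drift under which most data do not change.

Change mutations are conservative by construction: accession mutations
*append* (old accessions remain valid), position shifts keep the
(assembly, chromosome) key, symbol changes rename.  A changed record
therefore still satisfies all three match criteria next run; without
this, a changed single-accession record would strand its old accession
into the swept set and no drift manifest could be an exact deletion
oracle.

The gene-file dialect carries an optional `stable_id` column: real
upstream gene records echo the knowledgebase's own accessions back
(NCBI gene records carry RGD-style xrefs), and the triple-criterion
scheme is only satisfiable with that loop.  `SourceState.with_stable_ids`
models the write-back after each run.

What the generator does **not** emulate — and hence what passing tests
do not show: realistic identifier churn (renames vs true removals),
split/merge events where one source record becomes two, inter-field
correlations, transcript/exon structure, and real file-format quirks
(encodings, quoting, partial lines).  Matching quality on real data is
therefore not a claim; the claims are about the synchronization
machinery around the matcher.

Seeding: one global seed expands into per-component streams by stable
hashing of the component name (SHA-256, reduced below 2³¹), so adding a
generator never perturbs existing streams and every simulation is
replayable.

## Parameters that matter

| Parameter | Default | Units | Why |
|---|---|---|---|
| `stale_cap_fraction` | 0.05 | fraction of pipeline rows | deletion safety boundary; at-cap proceeds, above aborts |
| `FetchPolicy.initial_batch` | 10 | IDs/request | cheap capacity probe |
| `FetchPolicy.growth_factor` | 2.0 | — | multiplicative increase toward the hidden cap |
| `FetchPolicy.max_attempts_per_id` | 10 | attempts | distinguishes flaky from missing |
| `DriftParams` | 0.02 / 0.05 / 0.02 | fraction/step | weekly-scale drift in the acceptance scenarios |
| `RetentionPolicy.keep_days` | 365 | days | incoming-file troubleshooting window |
| timestamps | run ticks | logical clock | deterministic touch/sweep tests |

Coordinates are 1-based fully closed intervals (NCBI convention).

## Numerical and degenerate-input choices

Empty sweep denominator ⇒ fraction 0, completed.  Drift counts use
Python `round`.  Batch size is capped at the remaining queue.  Conflict
candidate lists are ordered by resolution order; conflict logs sort by
source key; partition keys process in sorted order.  The store
fingerprint used by atomicity checks hashes the data tables only — the
logical clock and ID counter advance even across failed runs, by design
(burned IDs are the price of never-reuse).  Withdrawn and retired are
both treated as "non-active, invisible to matching"; no pipeline
distinction is attached to the two labels.

## Problem sizes

The test and acceptance scenarios run at 10,000 records (idempotence),
5,000 records × 5 drift steps (reload equivalence), 1,000 IDs
(fetching), and 100-row boundary fixtures — sizes at which every
scenario's arithmetic can be checked exactly against constructed ground
truth.

## Known limitations

- One pipeline writer at a time; no concurrent-writer story (SQLite
  single-file store, swappable behind the data-access layer).
- The priority matcher trusts the winning identifier even when
  lower-priority identifiers disagree (logged only) — faithful to the
  scheme it implements, but a known source of silent mis-association if
  the high-priority identifier itself is wrong upstream.
- Retirement is triggered only via the swept NCBI Gene xref; a source
  that drops a record while a conflict is pending leaves the record
  active-but-stale until the conflict is resolved.
- The drop-and-reload oracle keys content on NCBI Gene IDs and is only
  meaningful for sources where that ID is stable — which the synthetic
  generator guarantees.
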