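"""Incremental diff-and-apply with touch semantics, and run orchestration.

The engine embodies the incremental-update paradigm: rather than dropping
and reloading a dataset on every run, the whole incoming dataset is
quality-controlled, compared in memory against a bulk snapshot of the
store, and only the small fraction that is new or changed is written.  A
record whose incoming copy is identical still gets its last-modified
timestamp advanced to the run start — it is "touched" — so that anything
*not* touched by the end of the run is, by elimination, no longer present
in the source and becomes a candidate for the stale sweep.

Runs follow a fixed phase order — download, parse/QC, plan, apply, sweep,
report — under a short-circuit discipline: the first failing phase aborts
the run, later phases (including the sweep) never execute, and the apply
phase is a single atomic batch, so a failed run leaves the store exactly
as it found it.  Large datasets may be partitioned (by species, or by
species + assembly + chromosome); the plan/apply/sweep phases then run
once per partition, independently, so one partition's failure does not
roll back another's completed work.
"""

from __future__ import annotations

import concurrent.futures
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Optional, Sequence

from .datastore import (
    Datastore,
    DeletePosition,
    DeleteXref,
    InsertPosition,
    InsertRecord,
    InsertXref,
    Mutation,
    Snapshot,
    TouchPosition,
    TouchRecord,
    TouchXref,
    UpdatePosition,
    UpdateRecordField,
    UpdateXref,
)
from .matching import GenePosition, IncomingGene, normalize_accession

#: xref classes where a gene carries at most one accession; a changed
#: accession is an in-place update.  Multi-valued classes (sequence
#: accessions) diff by set difference instead: missing accessions are
#: inserted and vanished ones are left untouched for the sweep.
SINGLE_VALUED_DBS = ("HGNC", "NCBIGene", "EnsemblGene", "PharmGKB")

_FIELD_FOR_DB = {"HGNC": "hgnc_id", "NCBIGene": "ncbi_gene_id", "EnsemblGene": "ensembl_id"}


class PhaseFailure(Exception):
    """Wraps the underlying error with the phase where it occurred."""

    def __init__(self, phase: str, cause: Exception):
        super().__init__(f"{phase}: {cause}")
        self.phase = phase
        self.cause = cause


@dataclass
class PipelineConfig:
    """Per-pipeline settings, normally read from a flat properties file.

    Keys in the file are namespaced by pipeline name
    (``gene_sync.speciesProcessed=rat,human``); command-line options
    override file values.
    """

    pipeline_name: str
    species_processed: tuple[str, ...] = ("rat",)
    source_paths: dict = field(default_factory=dict)
    stale_cap_fraction: float = 0.05
    partition_key: Optional[str] = None  # None | "species" | "species+assembly+chromosome"
    seed: int = 0
    registered_assemblies: tuple[str, ...] = ()
    output_dir: Optional[str] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.pipeline_name:
            raise ValueError("pipeline_name must be nonempty")
        if not (0.0 <= self.stale_cap_fraction <= 1.0):
            raise ValueError("stale_cap_fraction must lie in [0, 1]")

    @classmethod
    def from_properties(cls, path, pipeline_name: str, **overrides) -> "PipelineConfig":
        props = read_properties(path)

        def get(key, default=None):
            return props.get(f"{pipeline_name}.{key}", default)

        kwargs: dict = {"pipeline_name": pipeline_name}
        if get("speciesProcessed"):
            kwargs["species_processed"] = tuple(
                s.strip() for s in get("speciesProcessed").split(",") if s.strip()
            )
        if get("staleCapFraction"):
            kwargs["stale_cap_fraction"] = float(get("staleCapFraction"))
        if get("partitionKey"):
            kwargs["partition_key"] = get("partitionKey")
        if get("seed"):
            kwargs["seed"] = int(get("seed"))
        if get("assemblies"):
            kwargs["registered_assemblies"] = tuple(
                a.strip() for a in get("assemblies").split(",") if a.strip()
            )
        if get("outputDir"):
            kwargs["output_dir"] = get("outputDir")
        sources = {
            k.split(".", 2)[2]: v
            for k, v in props.items()
            if k.startswith(f"{pipeline_name}.source.")
        }
        if sources:
            kwargs["source_paths"] = sources
        kwargs.update(overrides)
        return cls(**kwargs)


def read_properties(path) -> dict[str, str]:
    """Parse a flat ``key=value`` properties file; ``#`` starts a comment."""
    props: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"malformed properties line: {raw!r}")
        key, _, value = line.partition("=")
        props[key.strip()] = value.strip()
    return props


@dataclass
class RunCounters:
    incoming: int = 0
    matched: int = 0
    conflicts: int = 0
    new: int = 0
    inserted: int = 0
    updated: int = 0
    unchanged: int = 0
    deleted: int = 0
    skipped: int = 0

    def validate(self) -> None:
        for name, v in self.__dict__.items():
            if v < 0:
                raise ValueError(f"counter {name} is negative")
        if self.matched + self.conflicts + self.new != self.incoming:
            raise ValueError("matched + conflicts + new must equal incoming")


@dataclass
class SyncPlan:
    """The computed delta between incoming data and the store.

    The plan is minimal: an update appears only where old and new actually
    differ, and a record identical to its incoming copy lands in
    ``unchanged``.  Every compared-and-matched target — updated or not —
    is in ``touch_set`` and receives a touch mutation, which is what makes
    the stale sweep sound.
    """

    run_tick: int
    inserts: list[Mutation] = field(default_factory=list)
    updates: list[Mutation] = field(default_factory=list)
    unchanged: list[tuple] = field(default_factory=list)  # target keys
    touches: list[Mutation] = field(default_factory=list)
    touch_set: set = field(default_factory=set)
    warnings: list[str] = field(default_factory=list)
    new_ids: dict[str, int] = field(default_factory=dict)  # source_key -> stable id
    #: matched records none of whose rows needed any mutation — the
    #: "required no updates" population at record granularity
    fully_unchanged: list[int] = field(default_factory=list)

    def mutation_count(self) -> int:
        return len(self.inserts) + len(self.updates)


# ---------------------------------------------------------------------------
# Planning


class _GeneView:
    """Current state of one resident gene, however it was fetched."""

    __slots__ = ("record", "xrefs", "positions")

    def __init__(self, record, xrefs, positions):
        self.record = record
        self.xrefs = xrefs
        self.positions = positions


def _cached_lookup(snapshot: Snapshot):
    xref_by_owner: dict[int, list] = {}
    for x in snapshot.xrefs:
        xref_by_owner.setdefault(x.owner, []).append(x)
    pos_by_owner: dict[int, list] = {}
    for p in snapshot.positions:
        pos_by_owner.setdefault(p.owner, []).append(p)
    recs = {r.stable_id: r for r in snapshot.records}

    def lookup(stable_id: int) -> _GeneView:
        return _GeneView(
            recs[stable_id], xref_by_owner.get(stable_id, []), pos_by_owner.get(stable_id, [])
        )

    return lookup


def _direct_lookup(store: Datastore):
    def lookup(stable_id: int) -> _GeneView:
        return _GeneView(
            store.get_record_threadsafe(stable_id),
            list(store.xrefs_of(stable_id)),
            list(store.positions_of(stable_id)),
        )

    return lookup


def plan_sync(
    matched: Sequence[tuple[IncomingGene, int]],
    new: Sequence[tuple[IncomingGene, int]],
    snapshot: Snapshot,
    *,
    attribution: str,
    run_tick: int,
    registered_assemblies: Sequence[str] = (),
    store: Optional[Datastore] = None,
    use_cache: bool = True,
    workers: int = 1,
) -> SyncPlan:
    """Diff matched incoming genes against their resident counterparts and
    stage inserts for new ones.

    ``use_cache`` selects between comparing against the bulk in-memory
    snapshot (the default) and issuing per-record queries against the
    store; the resulting plan is identical either way.  ``workers`` splits
    the diffing across threads; the merge order is deterministic, so the
    plan does not depend on the worker count.
    """
    if not use_cache and store is None:
        raise ValueError("per-record comparison requires the store")
    lookup = _cached_lookup(snapshot) if use_cache else _direct_lookup(store)
    plan = SyncPlan(run_tick=run_tick)
    assemblies = set(registered_assemblies)

    pairs = list(matched)
    if workers <= 1 or len(pairs) < 2:
        chunks_out = [
            [_diff_gene(inc, sid, lookup, attribution, run_tick, assemblies) for inc, sid in pairs]
        ]
    else:
        size = (len(pairs) + workers - 1) // workers
        chunks = [pairs[i : i + size] for i in range(0, len(pairs), size)]
        with concurrent.futures.ThreadPoolExecutor(max_workers=workers) as pool:
            chunks_out = list(
                pool.map(
                    lambda ch: [
                        _diff_gene(inc, sid, lookup, attribution, run_tick, assemblies)
                        for inc, sid in ch
                    ],
                    chunks,
                )
            )
    for chunk in chunks_out:
        for diff in chunk:
            plan.updates.extend(diff["updates"])
            plan.inserts.extend(diff["inserts"])
            plan.unchanged.extend(diff["unchanged"])
            plan.touches.extend(diff["touches"])
            plan.touch_set.update(diff["touch_set"])
            plan.warnings.extend(diff["warnings"])
            if not diff["updates"] and not diff["inserts"]:
                plan.fully_unchanged.append(diff["stable_id"])

    for inc, stable_id in new:
        plan.new_ids[inc.source_key] = stable_id
        plan.inserts.append(
            InsertRecord(
                stable_id=stable_id, species=inc.species, symbol=inc.symbol,
                name=inc.name, description=inc.description, ts=run_tick,
            )
        )
        for db, fieldname in _FIELD_FOR_DB.items():
            value = getattr(inc, fieldname)
            if value:
                plan.inserts.append(InsertXref(stable_id, db, value, attribution, run_tick))
        for acc in inc.seq_accessions:
            plan.inserts.append(
                InsertXref(stable_id, "SeqAccession", normalize_accession(acc), attribution, run_tick)
            )
        for pos in inc.positions:
            if pos.assembly not in assemblies:
                plan.warnings.append(
                    f"unrecognized assembly {pos.assembly!r} on {inc.source_key}; positions skipped"
                )
                continue
            plan.inserts.append(
                InsertPosition(stable_id, pos.assembly, pos.chrom, pos.start, pos.stop,
                               pos.strand, attribution, run_tick)
            )
    return plan


def _diff_gene(inc: IncomingGene, stable_id: int, lookup, attribution: str,
               run_tick: int, assemblies: set) -> dict:
    """Field-level diff of one matched gene; pure given the lookup."""
    view = lookup(stable_id)
    updates: list[Mutation] = []
    inserts: list[Mutation] = []
    unchanged: list[tuple] = []
    touches: list[Mutation] = [TouchRecord(stable_id, ts=run_tick)]
    touch_set: set = set()
    warnings: list[str] = []

    rec = view.record
    rec_changed = False
    for fieldname in ("symbol", "name", "description"):
        old, newv = getattr(rec, fieldname), getattr(inc, fieldname)
        if old != newv:
            updates.append(UpdateRecordField(stable_id, fieldname, old, newv, ts=run_tick))
            rec_changed = True
    rkey = ("record", stable_id)
    touch_set.add(rkey)
    if not rec_changed:
        unchanged.append(rkey)

    ours = [x for x in view.xrefs if x.attribution == attribution]
    anybody = view.xrefs

    for db, fieldname in _FIELD_FOR_DB.items():
        value = getattr(inc, fieldname)
        stored_ours = [x for x in ours if x.xref_db == db]
        stored_any = [x for x in anybody if x.xref_db == db]
        if not value:
            continue  # absent in source: existing row goes stale, sweep handles it
        hit = next((x for x in stored_any if x.accession == value), None)
        if hit is not None:
            key = ("xref",) + hit.key
            unchanged.append(key)
            if hit.attribution == attribution:
                touches.append(TouchXref(*hit.key, ts=run_tick))
                touch_set.add(key)
        elif len(stored_ours) == 1:
            old = stored_ours[0]
            updates.append(UpdateXref(stable_id, db, old.accession, value, ts=run_tick))
            touch_set.add(("xref", stable_id, db, value))
        else:
            inserts.append(InsertXref(stable_id, db, value, attribution, run_tick))

    stored_acc = {x.accession: x for x in anybody if x.xref_db == "SeqAccession"}
    for acc in inc.seq_accessions:
        nacc = normalize_accession(acc)
        hit = stored_acc.get(nacc)
        if hit is not None:
            key = ("xref",) + hit.key
            unchanged.append(key)
            if hit.attribution == attribution:
                touches.append(TouchXref(*hit.key, ts=run_tick))
                touch_set.add(key)
        else:
            inserts.append(InsertXref(stable_id, "SeqAccession", nacc, attribution, run_tick))

    stored_pos = {(p.assembly, p.chrom): p for p in view.positions}
    for pos in inc.positions:
        if pos.assembly not in assemblies:
            warnings.append(
                f"unrecognized assembly {pos.assembly!r} on {inc.source_key}; positions skipped"
            )
            continue
        hit = stored_pos.get((pos.assembly, pos.chrom))
        key = ("position", stable_id, pos.assembly, pos.chrom)
        if hit is None:
            inserts.append(
                InsertPosition(stable_id, pos.assembly, pos.chrom, pos.start, pos.stop,
                               pos.strand, attribution, run_tick)
            )
        elif (hit.start, hit.stop, hit.strand) == (pos.start, pos.stop, pos.strand):
            unchanged.append(key)
            if hit.attribution == attribution:
                touches.append(TouchPosition(stable_id, pos.assembly, pos.chrom, ts=run_tick))
                touch_set.add(key)
        else:
            if hit.attribution == attribution:
                updates.append(
                    UpdatePosition(stable_id, pos.assembly, pos.chrom, pos.start, pos.stop,
                                   pos.strand, ts=run_tick)
                )
                touch_set.add(key)
            else:
                warnings.append(
                    f"position {pos.assembly}:{pos.chrom} on gene {stable_id} differs but is"
                    f" owned by {hit.attribution!r}; left alone"
                )
    return {
        "stable_id": stable_id,
        "updates": updates, "inserts": inserts, "unchanged": unchanged,
        "touches": touches, "touch_set": touch_set, "warnings": warnings,
    }


def execute_plan(plan: SyncPlan, store: Datastore, run_start: Optional[int] = None) -> RunCounters:
    """Apply a plan as one atomic batch: inserts, then updates, then
    touches.  If anything in the batch fails, nothing persists — not even
    the touches, so an aborted apply leaves no record looking fresher than
    it is."""
    batch: list[Mutation] = list(plan.inserts) + list(plan.updates) + list(plan.touches)
    applied = store.apply_atomic(batch)
    counters = RunCounters(
        inserted=applied.inserted,
        updated=applied.updated,
        unchanged=len(plan.unchanged),
    )
    return counters


# ---------------------------------------------------------------------------
# Orchestration


@dataclass
class PhaseSet:
    """Phases of a pipeline run, in their fixed order.

    ``pre`` phases (download, parse/QC) run once; ``partitioned`` phases
    (plan, apply, sweep) run once per partition when the config sets a
    partition key; ``post`` phases (report) run once at the end.
    """

    pre: list[tuple[str, Callable[[dict], None]]]
    partitioned: list[tuple[str, Callable[[dict], None]]]
    post: list[tuple[str, Callable[[dict], None]]]
    partitioner: Optional[Callable[[dict], dict[str, dict]]] = None


def run_pipeline(config: PipelineConfig, phase_set: PhaseSet, store: Datastore):
    """Execute a pipeline run under the short-circuit discipline.

    The first failing phase stops the run; later phases — in particular
    the sweep — never execute.  With partitioning enabled, partitions
    already applied before a failure stay applied; the failing partition
    itself is atomic.  Returns a :class:`~biosync.reporting.RunSummary`.
    """
    from .reporting import RunSummary  # local import; reporting owns RunSummary

    run_start = store.tick()
    ctx: dict = {
        "config": config,
        "store": store,
        "run_start": run_start,
        "counters": RunCounters(),
        "warnings": [],
        "conflicts": [],
        "new_ids": {},
        "sweep_outcomes": [],
    }

    def fail(phase: str, exc: Exception) -> RunSummary:
        return RunSummary(
            pipeline_name=config.pipeline_name,
            start_tick=run_start,
            end_tick=store.clock,
            status="failed",
            failed_phase=phase,
            counters=ctx["counters"],
            warnings=list(ctx["warnings"]),
            exception_text=f"{type(exc).__name__}: {exc}",
            sweep_outcomes=list(ctx["sweep_outcomes"]),
        )

    for name, fn in phase_set.pre:
        try:
            fn(ctx)
        except Exception as exc:
            return fail(name, exc)

    if phase_set.partitioner is not None:
        try:
            partitions = phase_set.partitioner(ctx)
        except Exception as exc:
            return fail("partition", exc)
    else:
        partitions = {"": ctx}

    for pkey in sorted(partitions):
        part_ctx = partitions[pkey]
        if part_ctx is not ctx:
            # partition contexts share the store, counters and logs
            for shared in ("config", "store", "run_start", "counters", "warnings",
                           "conflicts", "new_ids", "sweep_outcomes"):
                part_ctx.setdefault(shared, ctx[shared])
            part_ctx["partition"] = pkey
        for name, fn in phase_set.partitioned:
            try:
                fn(part_ctx)
            except Exception as exc:
                label = f"{name}[{pkey}]" if pkey else name
                return fail(label, exc)

    for name, fn in phase_set.post:
        try:
            fn(ctx)
        except Exception as exc:
            return fail(name, exc)

    ctx["counters"].validate()
    return RunSummary(
        pipeline_name=config.pipeline_name,
        start_tick=run_start,
        end_tick=store.clock,
        status="success",
        failed_phase=None,
        counters=ctx["counters"],
        warnings=list(ctx["warnings"]),
        exception_text=None,
        sweep_outcomes=list(ctx["sweep_outcomes"]),
    )
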