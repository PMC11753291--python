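"""Persistent record store with stable identifiers and atomic mutation batches.

The store holds three kinds of rows:

* **records** — gene-like objects carrying a stable, never-reused integer
  identifier.  Records are never physically deleted; they leave service by
  moving to ``withdrawn`` or ``retired`` status and remain retrievable
  forever.
* **cross-references (xrefs)** — links from a record to an identifier in an
  external database (HGNC, NCBI Gene, Ensembl, PharmGKB, sequence
  accessions, ...).  Each xref carries an *attribution*: the name of the
  pipeline that created it, or the reserved value ``"manual"`` for
  curator-entered data that no pipeline may delete or modify.
* **positions** — per-assembly genomic intervals, 1-based fully closed.

Every row carries a *last-modified* timestamp measured on a monotonic
logical clock (integer run ticks, not wall-clock) so that touch-and-sweep
stale detection is deterministic and testable.

All writes go through :meth:`Datastore.apply_atomic`, which applies an
ordered batch of mutations all-or-nothing: a failure anywhere in the batch
(dangling target, attempt to modify a ``"manual"`` row) rolls the store
back to its exact pre-batch state.
"""

from __future__ import annotations

import hashlib
import sqlite3
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

MANUAL = "manual"

ACTIVE = "active"
WITHDRAWN = "withdrawn"
RETIRED = "retired"

#: Well-known external database names.  The vocabulary is open: unknown
#: names are accepted by the store and flagged by pipelines in their run
#: summaries rather than rejected here.
KNOWN_XREF_DBS = ("HGNC", "NCBIGene", "EnsemblGene", "PharmGKB", "SeqAccession")


class DatastoreError(Exception):
    """Base class for store-level failures."""


class BatchAborted(DatastoreError):
    """An atomic batch was rejected; the store is unchanged."""


class ManualRecordError(BatchAborted):
    """A mutation tried to delete or modify a ``"manual"``-attributed row."""


class InjectedFailure(DatastoreError):
    """Raised by the test-only failure injection hook."""


# ---------------------------------------------------------------------------
# Frozen row types returned by snapshots and getters


@dataclass(frozen=True)
class StableRecord:
    stable_id: int
    object_type: str
    species: str
    symbol: str
    name: str
    description: str
    status: str
    created_ts: int
    last_modified_ts: int


@dataclass(frozen=True)
class CrossReference:
    owner: int
    xref_db: str
    accession: str
    attribution: str
    last_modified_ts: int

    @property
    def key(self) -> tuple:
        return (self.owner, self.xref_db, self.accession)


@dataclass(frozen=True)
class Position:
    """1-based fully closed genomic interval on a named assembly."""

    owner: int
    assembly: str
    chrom: str
    start: int
    stop: int
    strand: str
    attribution: str
    last_modified_ts: int

    def __post_init__(self):
        if not (1 <= self.start <= self.stop):
            raise ValueError(f"invalid interval {self.start}-{self.stop} (1-based closed)")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def key(self) -> tuple:
        return (self.owner, self.assembly, self.chrom)


@dataclass(frozen=True)
class Snapshot:
    """Immutable bulk view of the store taken at a point in time.

    Comparisons between incoming data and the store are done against a
    snapshot held in memory, so one bulk query replaces per-record
    round-trips.  Later store mutations never alter a taken snapshot.
    """

    tick: int
    records: tuple[StableRecord, ...]
    xrefs: tuple[CrossReference, ...]
    positions: tuple[Position, ...]

    def record_by_id(self, stable_id: int) -> Optional[StableRecord]:
        return self._rec_index().get(stable_id)

    def xrefs_of(self, owner: int) -> tuple[CrossReference, ...]:
        return tuple(x for x in self.xrefs if x.owner == owner)

    def positions_of(self, owner: int) -> tuple[Position, ...]:
        return tuple(p for p in self.positions if p.owner == owner)

    def _rec_index(self):
        idx = getattr(self, "_idx", None)
        if idx is None:
            idx = {r.stable_id: r for r in self.records}
            object.__setattr__(self, "_idx", idx)
        return idx


# ---------------------------------------------------------------------------
# Mutation vocabulary for apply_atomic


@dataclass(frozen=True)
class InsertRecord:
    stable_id: int
    species: str
    symbol: str
    name: str = ""
    description: str = ""
    object_type: str = "gene"
    ts: int = 0


@dataclass(frozen=True)
class InsertXref:
    owner: int
    xref_db: str
    accession: str
    attribution: str
    ts: int = 0


@dataclass(frozen=True)
class InsertPosition:
    owner: int
    assembly: str
    chrom: str
    start: int
    stop: int
    strand: str
    attribution: str
    ts: int = 0


@dataclass(frozen=True)
class UpdateRecordField:
    stable_id: int
    fieldname: str  # symbol | name | description
    old: str
    new: str
    ts: int = 0


@dataclass(frozen=True)
class UpdateXref:
    """In-place accession change for a single-valued xref class."""

    owner: int
    xref_db: str
    old_accession: str
    new_accession: str
    ts: int = 0


@dataclass(frozen=True)
class UpdatePosition:
    owner: int
    assembly: str
    chrom: str
    start: int
    stop: int
    strand: str
    ts: int = 0


@dataclass(frozen=True)
class DeleteXref:
    owner: int
    xref_db: str
    accession: str


@dataclass(frozen=True)
class DeletePosition:
    owner: int
    assembly: str
    chrom: str


@dataclass(frozen=True)
class TouchRecord:
    stable_id: int
    ts: int = 0


@dataclass(frozen=True)
class TouchXref:
    owner: int
    xref_db: str
    accession: str
    ts: int = 0


@dataclass(frozen=True)
class TouchPosition:
    owner: int
    assembly: str
    chrom: str
    ts: int = 0


@dataclass(frozen=True)
class RetireRecord:
    stable_id: int
    mode: str  # withdrawn | retired
    ts: int = 0


@dataclass(frozen=True)
class FailHere:
    """Test-only mutation that raises mid-batch, for atomicity checks."""


Mutation = Union[
    InsertRecord, InsertXref, InsertPosition,
    UpdateRecordField, UpdateXref, UpdatePosition,
    DeleteXref, DeletePosition,
    TouchRecord, TouchXref, TouchPosition,
    RetireRecord, FailHere,
]

_INSERTS = (InsertRecord, InsertXref, InsertPosition)
_UPDATES = (UpdateRecordField, UpdateXref, UpdatePosition, RetireRecord)
_DELETES = (DeleteXref, DeletePosition)
_TOUCHES = (TouchRecord, TouchXref, TouchPosition)


@dataclass
class ApplyCounters:
    inserted: int = 0
    updated: int = 0
    deleted: int = 0
    touched: int = 0

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.inserted, self.updated, self.deleted, self.touched)


_SCHEMA = """
CREATE TABLE IF NOT EXISTS meta (
    key TEXT PRIMARY KEY, value INTEGER NOT NULL);
CREATE TABLE IF NOT EXISTS records (
    stable_id INTEGER PRIMARY KEY,
    object_type TEXT NOT NULL DEFAULT 'gene',
    species TEXT NOT NULL,
    symbol TEXT NOT NULL,
    name TEXT NOT NULL DEFAULT '',
    description TEXT NOT NULL DEFAULT '',
    status TEXT NOT NULL DEFAULT 'active',
    created_ts INTEGER NOT NULL,
    last_modified_ts INTEGER NOT NULL,
    CHECK (status IN ('active','withdrawn','retired')),
    CHECK (last_modified_ts >= created_ts));
CREATE TABLE IF NOT EXISTS xrefs (
    owner INTEGER NOT NULL REFERENCES records(stable_id),
    xref_db TEXT NOT NULL,
    accession TEXT NOT NULL,
    attribution TEXT NOT NULL,
    last_modified_ts INTEGER NOT NULL,
    PRIMARY KEY (owner, xref_db, accession));
CREATE TABLE IF NOT EXISTS positions (
    owner INTEGER NOT NULL REFERENCES records(stable_id),
    assembly TEXT NOT NULL,
    chrom TEXT NOT NULL,
    start INTEGER NOT NULL,
    stop INTEGER NOT NULL,
    strand TEXT NOT NULL CHECK (strand IN ('+','-')),
    attribution TEXT NOT NULL,
    last_modified_ts INTEGER NOT NULL,
    PRIMARY KEY (owner, assembly, chrom),
    CHECK (start >= 1 AND start <= stop));
CREATE TABLE IF NOT EXISTS resolutions (
    source_key TEXT PRIMARY KEY,
    action TEXT NOT NULL);
"""


class Datastore:
    """Single-file (or in-memory) embedded relational store.

    This class is the only component that touches storage; everything else
    in the framework goes through its operations, so the backend could be
    swapped without disturbing pipeline code.

    Parameters
    ----------
    path:
        SQLite database path; the default ``":memory:"`` gives a fresh
        transient store, convenient for tests and examples.
    """

    def __init__(self, path: str = ":memory:"):
        # check_same_thread off: the planner may issue read-only per-record
        # queries from worker threads, serialized by _read_lock.
        self._conn = sqlite3.connect(path, check_same_thread=False)
        import threading

        self._read_lock = threading.Lock()
        self._conn.execute("PRAGMA foreign_keys = ON")
        self._conn.executescript(_SCHEMA)
        for key in ("next_stable_id", "clock"):
            self._conn.execute(
                "INSERT OR IGNORE INTO meta (key, value) VALUES (?, ?)",
                (key, 1 if key == "next_stable_id" else 0),
            )
        self._conn.commit()
        self._fail_after: Optional[int] = None  # test hook: fail after N mutations

    # -- logical clock ------------------------------------------------------

    @property
    def clock(self) -> int:
        return self._meta("clock")

    def tick(self) -> int:
        """Advance the logical clock by one run tick and return it."""
        value = self._meta("clock") + 1
        self._conn.execute("UPDATE meta SET value = ? WHERE key = 'clock'", (value,))
        self._conn.commit()
        return value

    def _meta(self, key: str) -> int:
        (value,) = self._conn.execute("SELECT value FROM meta WHERE key = ?", (key,)).fetchone()
        return value

    # -- stable id allocation -----------------------------------------------

    def allocate_stable_id(self) -> int:
        """Return a fresh stable identifier, strictly greater than every one
        allocated before.  Allocated values are never reused, even when the
        record they were assigned to is later retired (or was never
        inserted at all)."""
        value = self._meta("next_stable_id")
        self._conn.execute("UPDATE meta SET value = ? WHERE key = 'next_stable_id'", (value + 1,))
        self._conn.commit()
        return value

    # -- reads ---------------------------------------------------------------

    def get_record(self, stable_id: int) -> Optional[StableRecord]:
        row = self._conn.execute(
            "SELECT stable_id, object_type, species, symbol, name, description,"
            " status, created_ts, last_modified_ts FROM records WHERE stable_id = ?",
            (stable_id,),
        ).fetchone()
        return StableRecord(*row) if row else None

    def snapshot(
        self,
        attribution: Optional[str] = None,
        object_type: Optional[str] = None,
        species: Optional[str] = None,
    ) -> Snapshot:
        """Bulk-read the store into an immutable in-memory view.

        ``attribution`` filters xrefs and positions (records are not
        attributed); ``object_type`` and ``species`` filter records.
        """
        rq = ("SELECT stable_id, object_type, species, symbol, name, description,"
              " status, created_ts, last_modified_ts FROM records")
        conds, args = [], []
        if object_type is not None:
            conds.append("object_type = ?")
            args.append(object_type)
        if species is not None:
            conds.append("species = ?")
            args.append(species)
        if conds:
            rq += " WHERE " + " AND ".join(conds)
        records = tuple(StableRecord(*r) for r in self._conn.execute(rq + " ORDER BY stable_id", args))
        owner_set = {r.stable_id for r in records} if (object_type or species) else None

        xq = "SELECT owner, xref_db, accession, attribution, last_modified_ts FROM xrefs"
        xargs: list = []
        if attribution is not None:
            xq += " WHERE attribution = ?"
            xargs.append(attribution)
        xrefs = tuple(
            CrossReference(*r)
            for r in self._conn.execute(xq + " ORDER BY owner, xref_db, accession", xargs)
            if owner_set is None or r[0] in owner_set
        )

        pq = ("SELECT owner, assembly, chrom, start, stop, strand, attribution,"
              " last_modified_ts FROM positions")
        pargs: list = []
        if attribution is not None:
            pq += " WHERE attribution = ?"
            pargs.append(attribution)
        positions = tuple(
            Position(*r)
            for r in self._conn.execute(pq + " ORDER BY owner, assembly, chrom", pargs)
            if owner_set is None or r[0] in owner_set
        )
        return Snapshot(tick=self.clock, records=records, xrefs=xrefs, positions=positions)

    def xrefs_of(self, owner: int) -> tuple[CrossReference, ...]:
        """Per-record xref query (the uncached counterpart of snapshot())."""
        with self._read_lock:
            rows = self._conn.execute(
                "SELECT owner, xref_db, accession, attribution, last_modified_ts"
                " FROM xrefs WHERE owner = ? ORDER BY xref_db, accession",
                (owner,),
            ).fetchall()
        return tuple(CrossReference(*r) for r in rows)

    def positions_of(self, owner: int) -> tuple[Position, ...]:
        with self._read_lock:
            rows = self._conn.execute(
                "SELECT owner, assembly, chrom, start, stop, strand, attribution,"
                " last_modified_ts FROM positions WHERE owner = ?"
                " ORDER BY assembly, chrom",
                (owner,),
            ).fetchall()
        return tuple(Position(*r) for r in rows)

    def get_record_threadsafe(self, stable_id: int) -> Optional[StableRecord]:
        with self._read_lock:
            return self.get_record(stable_id)

    def fingerprint(self) -> str:
        """SHA-256 digest of the full data content (records, xrefs,
        positions, resolutions).  The meta table — logical clock and ID
        counter — is excluded: both advance monotonically even across failed
        runs, by design."""
        h = hashlib.sha256()
        for table, order in (
            ("records", "stable_id"),
            ("xrefs", "owner, xref_db, accession"),
            ("positions", "owner, assembly, chrom"),
            ("resolutions", "source_key"),
        ):
            for row in self._conn.execute(f"SELECT * FROM {table} ORDER BY {order}"):
                h.update(repr(row).encode())
            h.update(b"|")
        return h.hexdigest()

    # -- resolutions (curator conflict decisions) ---------------------------

    def record_resolution(self, source_key: str, action: str) -> None:
        """Record a curator decision for a conflicted source record:
        ``merge:<stable_id>`` or ``new``."""
        if not (action == "new" or action.startswith("merge:")):
            raise ValueError(f"unknown resolution action {action!r}")
        self._conn.execute(
            "INSERT OR REPLACE INTO resolutions (source_key, action) VALUES (?, ?)",
            (source_key, action),
        )
        self._conn.commit()

    def resolutions(self) -> dict[str, str]:
        return dict(self._conn.execute("SELECT source_key, action FROM resolutions"))

    # -- lifecycle -----------------------------------------------------------

    def retire_object(self, stable_id: int, mode: str = RETIRED) -> StableRecord:
        """Move an active record to ``withdrawn`` or ``retired`` status.

        Records leave service this way; they are never physically deleted,
        and they remain retrievable by stable ID afterwards.
        """
        if mode not in (WITHDRAWN, RETIRED):
            raise ValueError(f"mode must be 'withdrawn' or 'retired', got {mode!r}")
        rec = self.get_record(stable_id)
        if rec is None:
            raise DatastoreError(f"no record with stable id {stable_id}")
        if rec.status != ACTIVE:
            raise DatastoreError(
                f"record {stable_id} is not active (current status: {rec.status})"
            )
        ts = max(self.clock, rec.last_modified_ts)
        self._conn.execute(
            "UPDATE records SET status = ?, last_modified_ts = ? WHERE stable_id = ?",
            (mode, ts, stable_id),
        )
        self._conn.commit()
        return self.get_record(stable_id)

    # -- atomic mutation batches --------------------------------------------

    def inject_failure_after(self, n: Optional[int]) -> None:
        """Test hook: make the next apply_atomic raise after ``n`` mutations."""
        self._fail_after = n

    def apply_atomic(self, mutations: Sequence[Mutation]) -> ApplyCounters:
        """Apply an ordered batch of mutations, all-or-nothing.

        Returns counters equal to the multiset of applied mutation kinds.
        Any rejected mutation — a dangling target, or a delete/update/touch
        aimed at a ``"manual"``-attributed row — aborts the whole batch and
        leaves the store exactly as it was.
        """
        counters = ApplyCounters()
        cur = self._conn.cursor()
        try:
            cur.execute("BEGIN")
            for i, m in enumerate(mutations):
                if self._fail_after is not None and i >= self._fail_after:
                    raise InjectedFailure(f"injected failure before mutation {i}")
                self._apply_one(cur, m, counters)
        except Exception:
            self._conn.rollback()
            self._fail_after = None
            raise
        self._conn.commit()
        self._fail_after = None
        return counters

    # internal: one mutation inside the open transaction
    def _apply_one(self, cur: sqlite3.Cursor, m: Mutation, c: ApplyCounters) -> None:
        if isinstance(m, FailHere):
            raise InjectedFailure("FailHere mutation reached")

        if isinstance(m, InsertRecord):
            cur.execute(
                "INSERT INTO records (stable_id, object_type, species, symbol, name,"
                " description, status, created_ts, last_modified_ts)"
                " VALUES (?,?,?,?,?,?, 'active', ?, ?)",
                (m.stable_id, m.object_type, m.species, m.symbol, m.name,
                 m.description, m.ts, m.ts),
            )
            c.inserted += 1
        elif isinstance(m, InsertXref):
            self._require_record(cur, m.owner)
            cur.execute(
                "INSERT INTO xrefs (owner, xref_db, accession, attribution,"
                " last_modified_ts) VALUES (?,?,?,?,?)",
                (m.owner, m.xref_db, m.accession, m.attribution, m.ts),
            )
            c.inserted += 1
        elif isinstance(m, InsertPosition):
            self._require_record(cur, m.owner)
            cur.execute(
                "INSERT INTO positions (owner, assembly, chrom, start, stop, strand,"
                " attribution, last_modified_ts) VALUES (?,?,?,?,?,?,?,?)",
                (m.owner, m.assembly, m.chrom, m.start, m.stop, m.strand,
                 m.attribution, m.ts),
            )
            c.inserted += 1
        elif isinstance(m, UpdateRecordField):
            if m.fieldname not in ("symbol", "name", "description"):
                raise BatchAborted(f"unknown record field {m.fieldname!r}")
            self._require_record(cur, m.stable_id)
            cur.execute(
                f"UPDATE records SET {m.fieldname} = ?, last_modified_ts = ?"
                " WHERE stable_id = ?",
                (m.new, m.ts, m.stable_id),
            )
            c.updated += 1
        elif isinstance(m, UpdateXref):
            attribution = self._xref_attribution(cur, m.owner, m.xref_db, m.old_accession)
            self._guard_manual(attribution, "update", f"xref {m.xref_db}:{m.old_accession}")
            cur.execute(
                "UPDATE xrefs SET accession = ?, last_modified_ts = ?"
                " WHERE owner = ? AND xref_db = ? AND accession = ?",
                (m.new_accession, m.ts, m.owner, m.xref_db, m.old_accession),
            )
            c.updated += 1
        elif isinstance(m, UpdatePosition):
            if not (1 <= m.start <= m.stop):
                raise BatchAborted(f"invalid interval {m.start}-{m.stop}")
            attribution = self._position_attribution(cur, m.owner, m.assembly, m.chrom)
            self._guard_manual(attribution, "update", f"position {m.assembly}:{m.chrom}")
            cur.execute(
                "UPDATE positions SET start = ?, stop = ?, strand = ?,"
                " last_modified_ts = ? WHERE owner = ? AND assembly = ? AND chrom = ?",
                (m.start, m.stop, m.strand, m.ts, m.owner, m.assembly, m.chrom),
            )
            c.updated += 1
        elif isinstance(m, DeleteXref):
            attribution = self._xref_attribution(cur, m.owner, m.xref_db, m.accession)
            self._guard_manual(attribution, "delete", f"xref {m.xref_db}:{m.accession}")
            cur.execute(
                "DELETE FROM xrefs WHERE owner = ? AND xref_db = ? AND accession = ?",
                (m.owner, m.xref_db, m.accession),
            )
            c.deleted += 1
        elif isinstance(m, DeletePosition):
            attribution = self._position_attribution(cur, m.owner, m.assembly, m.chrom)
            self._guard_manual(attribution, "delete", f"position {m.assembly}:{m.chrom}")
            cur.execute(
                "DELETE FROM positions WHERE owner = ? AND assembly = ? AND chrom = ?",
                (m.owner, m.assembly, m.chrom),
            )
            c.deleted += 1
        elif isinstance(m, TouchRecord):
            self._require_record(cur, m.stable_id)
            cur.execute(
                "UPDATE records SET last_modified_ts = ? WHERE stable_id = ?",
                (m.ts, m.stable_id),
            )
            c.touched += 1
        elif isinstance(m, TouchXref):
            attribution = self._xref_attribution(cur, m.owner, m.xref_db, m.accession)
            self._guard_manual(attribution, "touch", f"xref {m.xref_db}:{m.accession}")
            cur.execute(
                "UPDATE xrefs SET last_modified_ts = ? WHERE owner = ? AND xref_db = ?"
                " AND accession = ?",
                (m.ts, m.owner, m.xref_db, m.accession),
            )
            c.touched += 1
        elif isinstance(m, TouchPosition):
            attribution = self._position_attribution(cur, m.owner, m.assembly, m.chrom)
            self._guard_manual(attribution, "touch", f"position {m.assembly}:{m.chrom}")
            cur.execute(
                "UPDATE positions SET last_modified_ts = ? WHERE owner = ?"
                " AND assembly = ? AND chrom = ?",
                (m.ts, m.owner, m.assembly, m.chrom),
            )
            c.touched += 1
        elif isinstance(m, RetireRecord):
            if m.mode not in (WITHDRAWN, RETIRED):
                raise BatchAborted(f"invalid retire mode {m.mode!r}")
            row = cur.execute(
                "SELECT status FROM records WHERE stable_id = ?", (m.stable_id,)
            ).fetchone()
            if row is None:
                raise BatchAborted(f"dangling record reference {m.stable_id}")
            if row[0] != ACTIVE:
                raise BatchAborted(f"record {m.stable_id} is not active ({row[0]})")
            cur.execute(
                "UPDATE records SET status = ?, last_modified_ts = ? WHERE stable_id = ?",
                (m.mode, m.ts, m.stable_id),
            )
            c.updated += 1
        else:  # pragma: no cover
            raise BatchAborted(f"unknown mutation {m!r}")

    def _require_record(self, cur, stable_id: int) -> None:
        if cur.execute("SELECT 1 FROM records WHERE stable_id = ?", (stable_id,)).fetchone() is None:
            raise BatchAborted(f"dangling record reference {stable_id}")

    def _xref_attribution(self, cur, owner, xref_db, accession) -> str:
        row = cur.execute(
            "SELECT attribution FROM xrefs WHERE owner = ? AND xref_db = ? AND accession = ?",
            (owner, xref_db, accession),
        ).fetchone()
        if row is None:
            raise BatchAborted(f"dangling xref reference ({owner}, {xref_db}, {accession})")
        return row[0]

    def _position_attribution(self, cur, owner, assembly, chrom) -> str:
        row = cur.execute(
            "SELECT attribution FROM positions WHERE owner = ? AND assembly = ? AND chrom = ?",
            (owner, assembly, chrom),
        ).fetchone()
        if row is None:
            raise BatchAborted(f"dangling position reference ({owner}, {assembly}, {chrom})")
        return row[0]

    @staticmethod
    def _guard_manual(attribution: str, verb: str, what: str) -> None:
        if attribution == MANUAL:
            raise ManualRecordError(f"refusing to {verb} manual {what}")

    def close(self) -> None:
        self._conn.close()
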