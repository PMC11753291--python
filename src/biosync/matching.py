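"""Reconcile incoming source records against the datastore.

Two matching schemes are provided:

* :func:`match_gene_triple` — the gene-record scheme.  An incoming gene is
  automatically merged with a resident gene only when all three identifier
  criteria agree: the stable ID the source echoes back, the NCBI Gene ID,
  and at least one sequence accession.  Agreement on one or two criteria is
  a *conflict*: the record is routed to a conflicts log for curator review
  and nothing is mutated.  Agreement on none means the record is *new*.
* :func:`match_by_priority` — the xref-association scheme.  Identifiers are
  tried in a configured order of preference (HGNC, then NCBI Gene, then
  Ensembl by default); the first one that resolves to exactly one resident
  gene wins, and disagreement from lower-priority identifiers is logged but
  does not change the outcome.

Both schemes are deterministic pure functions of the incoming record and an
index built over the *active* genes of the store.  Species is checked
before identifiers: a cross-species identifier hit is a conflict, never a
merge.

Accession normalisation: comparisons trim whitespace, are case-sensitive,
and strip trailing version suffixes from sequence accessions, so
``NM_1.2`` and ``NM_1`` compare equal.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

from .datastore import Snapshot

MATCHED = "matched"
CONFLICT = "conflict"
NEW = "new"

CRIT_STABLE_ID = "stable_id"
CRIT_NCBI_ID = "ncbi_id"
CRIT_SEQ_ACC = "seq_acc"

_VERSION_SUFFIX = re.compile(r"\.\d+$")


def normalize_accession(acc: str) -> str:
    """Trim whitespace and strip a trailing ``.N`` version suffix."""
    return _VERSION_SUFFIX.sub("", acc.strip())


@dataclass(frozen=True)
class GenePosition:
    assembly: str
    chrom: str
    start: int
    stop: int
    strand: str


@dataclass(frozen=True)
class IncomingGene:
    """A gene record as presented by the source, before reconciliation."""

    source_key: str
    species: str
    symbol: str
    name: str = ""
    description: str = ""
    stable_id_claim: Optional[int] = None
    ncbi_gene_id: Optional[str] = None
    hgnc_id: Optional[str] = None
    ensembl_id: Optional[str] = None
    seq_accessions: tuple[str, ...] = ()
    positions: tuple[GenePosition, ...] = ()

    def __post_init__(self):
        if not self.source_key:
            raise ValueError("source_key must be nonempty")
        # dedupe accessions, preserving first-seen order
        seen, deduped = set(), []
        for a in self.seq_accessions:
            a = a.strip()
            if a and a not in seen:
                seen.add(a)
                deduped.append(a)
        object.__setattr__(self, "seq_accessions", tuple(deduped))


@dataclass(frozen=True)
class MatchResult:
    """Outcome of reconciling one incoming record.

    ``outcome`` is ``"matched"`` (merge with ``stable_id``), ``"conflict"``
    (partial agreement or ambiguity; ``candidates`` lists every resident
    gene implicated), or ``"new"`` (no identifier known to the store).
    """

    outcome: str
    stable_id: Optional[int] = None
    candidates: tuple[int, ...] = ()
    criteria_met: frozenset = frozenset()
    notes: tuple[str, ...] = ()


@dataclass(frozen=True)
class PriorityPolicy:
    ordered_dbs: tuple[str, ...] = ("HGNC", "NCBIGene", "EnsemblGene")

    def __post_init__(self):
        if not self.ordered_dbs:
            raise ValueError("priority order must be nonempty")
        if len(set(self.ordered_dbs)) != len(self.ordered_dbs):
            raise ValueError("priority order must not contain duplicates")


_ID_FIELD_FOR_DB = {"HGNC": "hgnc_id", "NCBIGene": "ncbi_gene_id", "EnsemblGene": "ensembl_id"}


class GeneIndex:
    """Identifier lookup over the active genes of a snapshot.

    Built once per run from a bulk snapshot; all lookups are pure and keyed
    by (species-checked) external identifiers.
    """

    def __init__(self, snapshot: Snapshot):
        active = {r.stable_id: r for r in snapshot.records
                  if r.status == "active" and r.object_type == "gene"}
        self.records = active
        self.by_db: dict[str, dict[str, list[int]]] = {}
        for x in snapshot.xrefs:
            if x.owner not in active:
                continue
            acc = normalize_accession(x.accession) if x.xref_db == "SeqAccession" else x.accession.strip()
            self.by_db.setdefault(x.xref_db, {}).setdefault(acc, []).append(x.owner)

    def lookup(self, xref_db: str, accession: str, species: Optional[str] = None) -> list[int]:
        acc = normalize_accession(accession) if xref_db == "SeqAccession" else accession.strip()
        owners = self.by_db.get(xref_db, {}).get(acc, [])
        if species is None:
            return sorted(set(owners))
        return sorted({o for o in owners if self.records[o].species == species})

    def lookup_any_species(self, xref_db: str, accession: str) -> list[int]:
        return self.lookup(xref_db, accession)

    def gene_accessions(self, stable_id: int, xref_db: str) -> set[str]:
        out = set()
        for acc, owners in self.by_db.get(xref_db, {}).items():
            if stable_id in owners:
                out.add(acc)
        return out


def match_gene_triple(incoming: IncomingGene, index: GeneIndex) -> MatchResult:
    """Classify an incoming gene by the three-criterion scheme.

    Candidate resolution order: the stable-ID claim, else the NCBI Gene ID,
    else any sequence accession.  The three criteria are then evaluated
    against the single candidate; a merge requires all three.  Identifiers
    pointing at two or more distinct resident genes are always a conflict
    with every candidate listed.
    """
    hits: list[int] = []  # distinct candidate genes, in resolution order

    def add(owners: Iterable[int]):
        for o in owners:
            if o not in hits:
                hits.append(o)

    cross_species: list[str] = []
    if incoming.stable_id_claim is not None:
        rec = index.records.get(incoming.stable_id_claim)
        if rec is not None:
            if rec.species == incoming.species:
                add([rec.stable_id])
            else:
                cross_species.append(f"stable id {incoming.stable_id_claim} is {rec.species}")
    if incoming.ncbi_gene_id:
        same = index.lookup("NCBIGene", incoming.ncbi_gene_id, incoming.species)
        add(same)
        for o in index.lookup_any_species("NCBIGene", incoming.ncbi_gene_id):
            if o not in same:
                cross_species.append(f"NCBI id hits {index.records[o].species} gene {o}")
    for acc in incoming.seq_accessions:
        add(index.lookup("SeqAccession", acc, incoming.species))

    if not hits:
        if cross_species:
            # identifier known, but on another species: conflict, not merge
            return MatchResult(CONFLICT, candidates=(), notes=tuple(cross_species))
        return MatchResult(NEW)

    if len(hits) > 1:
        return MatchResult(
            CONFLICT, candidates=tuple(hits),
            criteria_met=_criteria_met(incoming, hits[0], index),
            notes=("identifiers resolve to multiple genes",) + tuple(cross_species),
        )

    gene = hits[0]
    met = _criteria_met(incoming, gene, index)
    if len(met) == 3:
        return MatchResult(MATCHED, stable_id=gene, criteria_met=met, notes=tuple(cross_species))
    return MatchResult(CONFLICT, candidates=(gene,), criteria_met=met, notes=tuple(cross_species))


def _criteria_met(incoming: IncomingGene, gene: int, index: GeneIndex) -> frozenset:
    met = set()
    if incoming.stable_id_claim == gene:
        met.add(CRIT_STABLE_ID)
    if incoming.ncbi_gene_id and gene in index.lookup("NCBIGene", incoming.ncbi_gene_id):
        met.add(CRIT_NCBI_ID)
    stored = index.gene_accessions(gene, "SeqAccession")
    if any(normalize_accession(a) in stored for a in incoming.seq_accessions):
        met.add(CRIT_SEQ_ACC)
    return frozenset(met)


def match_by_priority(
    incoming: IncomingGene,
    index: GeneIndex,
    policy: PriorityPolicy = PriorityPolicy(),
) -> MatchResult:
    """Classify by the first identifier, in order of preference, that
    resolves to exactly one resident gene.  Lower-priority identifiers that
    disagree are recorded in ``notes`` but do not change the outcome."""
    chosen: Optional[tuple[str, int]] = None
    notes: list[str] = []
    for db in policy.ordered_dbs:
        value = getattr(incoming, _ID_FIELD_FOR_DB.get(db, ""), None) if db in _ID_FIELD_FOR_DB else None
        if not value:
            continue
        owners = index.lookup(db, value, incoming.species)
        if not owners:
            continue
        if chosen is None:
            if len(owners) > 1:
                return MatchResult(
                    CONFLICT, candidates=tuple(owners), criteria_met=frozenset({db}),
                    notes=(f"{db} id {value} is ambiguous",),
                )
            chosen = (db, owners[0])
        elif owners != [chosen[1]]:
            notes.append(f"{db} id {value} disagrees (points at {owners})")
    if chosen is None:
        return MatchResult(NEW)
    return MatchResult(
        MATCHED, stable_id=chosen[1], criteria_met=frozenset({chosen[0]}), notes=tuple(notes)
    )


@dataclass
class MatchReport:
    """Partition of a batch of incoming records by match outcome."""

    matched: list[tuple[IncomingGene, MatchResult]] = field(default_factory=list)
    conflicts: list[tuple[IncomingGene, MatchResult]] = field(default_factory=list)
    new: list[tuple[IncomingGene, MatchResult]] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)  # duplicate source_keys

    def sizes(self) -> tuple[int, int, int]:
        return (len(self.matched), len(self.conflicts), len(self.new))


def classify_batch(
    incomings: Sequence[IncomingGene],
    matcher: Callable[[IncomingGene], MatchResult],
    resolutions: Optional[dict[str, str]] = None,
) -> MatchReport:
    """Run ``matcher`` over a batch, deduplicating source keys (first
    occurrence wins; later ones are flagged and skipped) and honouring
    recorded curator resolutions (``merge:<id>`` forces a match, ``new``
    forces a fresh record).  Per-record matcher failures become conflicts,
    so matched + conflicts + new always partitions the deduplicated input.
    """
    report = MatchReport()
    resolutions = resolutions or {}
    seen: set[str] = set()
    for inc in incomings:
        if inc.source_key in seen:
            report.skipped.append(inc.source_key)
            continue
        seen.add(inc.source_key)
        action = resolutions.get(inc.source_key)
        if action == "new":
            report.new.append((inc, MatchResult(NEW, notes=("forced new by resolution",))))
            continue
        if action is not None and action.startswith("merge:"):
            target = int(action.split(":", 1)[1])
            report.matched.append(
                (inc, MatchResult(MATCHED, stable_id=target,
                                  notes=("forced merge by resolution",)))
            )
            continue
        try:
            result = matcher(inc)
        except Exception as exc:  # per-record failure is a conflict, not a crash
            result = MatchResult(CONFLICT, notes=(f"matcher error: {exc}",))
        getattr(report, {MATCHED: "matched", CONFLICT: "conflicts", NEW: "new"}[result.outcome]).append(
            (inc, result)
        )
    return report
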