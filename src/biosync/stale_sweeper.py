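"""Touch-and-sweep stale-record deletion with a fractional safety cap.

Everything a pipeline compares against incoming data gets its
last-modified timestamp set to the run start ("touched").  After a
successful apply phase, any row still attributed to the pipeline whose
timestamp predates the run start was, by elimination, absent from the
source — it is stale and gets deleted.

The safety cap guards against a truncated or broken source file silently
gutting the store: if the stale fraction of the pipeline's data exceeds
the cap (default 5%), the sweep aborts and deletes nothing, leaving the
stale rows for a human to look at.  The fraction is evaluated per object
class (xrefs and positions separately), so a small class cannot be wiped
out under cover of a large one; exactly-at-cap proceeds, strictly-above
aborts.  Rows attributed ``"manual"`` are never sweep candidates, and the
sweep refuses to run for the ``"manual"`` attribution outright.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from typing import Iterable

from .datastore import Datastore, DeletePosition, DeleteXref, MANUAL, Mutation


@dataclass(frozen=True)
class ClassOutcome:
    object_class: str
    would_delete: int
    attributed_total: int
    fraction: float
    over_cap: bool


@dataclass
class SweepOutcome:
    status: str  # completed | aborted
    deleted_ids: list[tuple] = field(default_factory=list)
    would_delete: int = 0
    attributed_total: int = 0
    fraction: float = 0.0
    classes: list[ClassOutcome] = field(default_factory=list)

    def __post_init__(self):
        if self.status == "aborted" and self.deleted_ids:
            raise ValueError("aborted sweep must not report deletions")


def sweep(
    store: Datastore,
    attribution: str,
    run_start: int,
    cap_fraction: float = 0.05,
    dry_run: bool = False,
    species: Optional[Iterable[str]] = None,
    exclude_owners: Optional[Iterable[int]] = None,
) -> SweepOutcome:
    """Delete rows attributed to ``attribution`` whose last-modified tick
    predates ``run_start``, unless any object class would lose more than
    ``cap_fraction`` of its rows — then abort with zero deletions.

    ``dry_run`` computes the outcome without mutating the store.  The
    per-class fractions use the pipeline's pre-sweep row count as the
    denominator (0 candidates over 0 rows counts as fraction 0).
    ``species`` restricts the sweep — candidates and denominators alike —
    to rows owned by records of those species, which is how partitioned
    runs keep their sweeps independent.  ``exclude_owners`` removes the
    named records' rows from consideration entirely: a record routed to
    the conflicts log this run is present in the source but unmatchable,
    not stale, and must not be garbage-collected while a curator reviews
    it.
    """
    if attribution == MANUAL:
        raise ValueError("the manual attribution is never swept")
    if not (0.0 <= cap_fraction <= 1.0):
        raise ValueError("cap_fraction must lie in [0, 1]")

    snap = store.snapshot(attribution=attribution)
    xrefs, positions = snap.xrefs, snap.positions
    if species is not None:
        wanted = set(species)
        owners = {r.stable_id for r in snap.records if r.species in wanted}
        xrefs = tuple(x for x in xrefs if x.owner in owners)
        positions = tuple(p for p in positions if p.owner in owners)
    if exclude_owners:
        excluded = set(exclude_owners)
        xrefs = tuple(x for x in xrefs if x.owner not in excluded)
        positions = tuple(p for p in positions if p.owner not in excluded)
    stale_x = [x for x in xrefs if x.last_modified_ts < run_start]
    stale_p = [p for p in positions if p.last_modified_ts < run_start]

    classes = []
    for name, stale, total in (
        ("xref", stale_x, len(xrefs)),
        ("position", stale_p, len(positions)),
    ):
        fraction = (len(stale) / total) if total else 0.0
        classes.append(
            ClassOutcome(name, len(stale), total, fraction, over_cap=fraction > cap_fraction)
        )

    would = len(stale_x) + len(stale_p)
    total = len(xrefs) + len(positions)
    overall_fraction = (would / total) if total else 0.0

    if any(c.over_cap for c in classes):
        return SweepOutcome(
            status="aborted", deleted_ids=[], would_delete=would,
            attributed_total=total, fraction=overall_fraction, classes=classes,
        )

    deletions: list[Mutation] = [DeleteXref(*x.key) for x in stale_x]
    deletions += [DeletePosition(*p.key) for p in stale_p]
    if deletions and not dry_run:
        store.apply_atomic(deletions)
    deleted = [("xref",) + x.key for x in stale_x] + [("position",) + p.key for p in stale_p]
    return SweepOutcome(
        status="completed",
        deleted_ids=deleted if not dry_run else list(deleted),
        would_delete=would,
        attributed_total=total,
        fraction=overall_fraction,
        classes=classes,
    )
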