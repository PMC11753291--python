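"""Adaptive batched download from a rate-limited, flaky endpoint.

Remote gene databases cap how much can be requested at once, and the cap
is not published — so the fetcher probes for it.  Each successful request
is followed by a proportionally larger one (multiplicative growth, factor
2 by default).  When a request fails — the endpoint errors, or returns
only a strict subset of what was asked — the records that did come back
are kept, the missing IDs are folded back into the remaining queue, the
queue is shuffled with a seeded generator, and the next request is half
the size.  The grow/halve cycle repeats until every requested ID has been
fetched exactly once.

The full request/response history is recorded in a :class:`FetchTrace`
whose batch sizes can be replayed through the pure
:func:`next_batch_size` function — the trace is the audit trail that the
scheduler did what it says.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Protocol, Sequence


class FetchError(Exception):
    """Some IDs kept failing past the attempt budget; names them."""

    def __init__(self, failed_ids: Sequence[str]):
        self.failed_ids = tuple(sorted(failed_ids))
        super().__init__(f"ids exceeded attempt budget: {', '.join(self.failed_ids[:10])}"
                         + ("…" if len(self.failed_ids) > 10 else ""))


class Endpoint(Protocol):
    """Contract a source endpoint must satisfy.

    ``request`` returns ``(records, ok)``: a mapping of id to record for
    everything it served, and a flag that is False when the endpoint
    considers the request failed.  A response missing some requested ids
    is treated as a failure by the fetcher even if ``ok`` is True.
    """

    def request(self, ids: Sequence[str]) -> tuple[dict, bool]: ...


@dataclass(frozen=True)
class FetchPolicy:
    initial_batch: int = 10
    growth_factor: float = 2.0
    min_batch: int = 1
    max_attempts_per_id: int = 10
    shuffle_seed: int = 0

    def __post_init__(self):
        if self.initial_batch < 1:
            raise ValueError("initial_batch must be >= 1")
        if self.growth_factor <= 1.0:
            raise ValueError("growth_factor must exceed 1")
        if self.min_batch < 1:
            raise ValueError("min_batch must be >= 1")
        if self.max_attempts_per_id < 1:
            raise ValueError("max_attempts_per_id must be >= 1")


@dataclass(frozen=True)
class TraceEntry:
    requested_ids: tuple[str, ...]
    returned_ids: tuple[str, ...]
    failed: bool
    batch_size_next: int


@dataclass
class FetchTrace:
    entries: list[TraceEntry] = field(default_factory=list)

    def batch_sizes(self) -> list[int]:
        return [len(e.requested_ids) for e in self.entries]


def next_batch_size(prev: int, outcome: str, policy: FetchPolicy = FetchPolicy()) -> int:
    """Pure batch-size schedule: grow by the policy factor on success,
    halve (never below ``min_batch``) on failure."""
    if prev < 1:
        raise ValueError("prev must be >= 1")
    if outcome == "success":
        return math.ceil(prev * policy.growth_factor)
    if outcome == "failure":
        return max(policy.min_batch, prev // 2)
    raise ValueError(f"outcome must be 'success' or 'failure', got {outcome!r}")


def fetch_all(
    ids: Sequence[str],
    source: Endpoint,
    policy: FetchPolicy = FetchPolicy(),
) -> tuple[dict, FetchTrace]:
    """Fetch every id exactly once, adapting the batch size as described
    in the module docstring.

    Returns the records keyed by id and the trace.  Raises
    :class:`FetchError` naming the ids once any id has failed more than
    ``policy.max_attempts_per_id`` times (a run-level, short-circuit
    condition).
    """
    if len(set(ids)) != len(ids):
        raise ValueError("ids must be deduplicated")
    queue: list[str] = list(ids)
    rng = random.Random(policy.shuffle_seed)
    records: dict = {}
    failures: dict[str, int] = {}
    trace = FetchTrace()
    batch = policy.initial_batch

    while queue:
        size = min(batch, len(queue))
        requested, queue = queue[:size], queue[size:]
        returned, ok = source.request(requested)
        # keep whatever came back, even from a failed request
        for rid, rec in returned.items():
            if rid in requested and rid not in records:
                records[rid] = rec
        missing = [rid for rid in requested if rid not in returned]
        failed = (not ok) or bool(missing)
        if failed:
            exhausted = []
            for rid in missing:
                failures[rid] = failures.get(rid, 0) + 1
                if failures[rid] > policy.max_attempts_per_id:
                    exhausted.append(rid)
            if exhausted:
                raise FetchError(exhausted)
            queue.extend(missing)
            rng.shuffle(queue)
            batch = next_batch_size(size, "failure", policy)
        else:
            batch = next_batch_size(size, "success", policy)
        trace.entries.append(
            TraceEntry(
                requested_ids=tuple(requested),
                returned_ids=tuple(sorted(returned)),
                failed=failed,
                batch_size_next=batch,
            )
        )
    return records, trace


def replay_batch_sizes(trace: FetchTrace, policy: FetchPolicy = FetchPolicy()) -> bool:
    """Check that the trace's scheduled sizes are a pure replay of
    :func:`next_batch_size` over the recorded outcome sequence."""
    for entry in trace.entries:
        expected = next_batch_size(
            len(entry.requested_ids), "failure" if entry.failed else "success", policy
        )
        if entry.batch_size_next != expected:
            return False
    return True
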