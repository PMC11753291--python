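"""The stale-sweep safety cap at its boundary.

A store holds 100 xrefs attributed to a pipeline.  If 5 go stale (5%,
exactly at the default cap) the sweep proceeds; if 6 go stale (>5%) the
sweep refuses to delete anything — the signature of a truncated source
file is a suddenly large stale fraction, and mass deletion needs a human
decision, not automation.
"""

from biosync import Datastore
from biosync.datastore import InsertRecord, InsertXref
from biosync.stale_sweeper import sweep


def store_with_stale(n_stale):
    store = Datastore()
    store.apply_atomic([InsertRecord(stable_id=store.allocate_stable_id(),
                                     species="rat", symbol="G", ts=0)])
    # rows with ts=0 predate the run (stale); ts=1 were touched this run
    store.apply_atomic([
        InsertXref(1, "PharmGKB", f"PA{i}", "pipe", 0 if i < n_stale else 1)
        for i in range(100)
    ])
    return store


for n_stale in (5, 6):
    outcome = sweep(store_with_stale(n_stale), "pipe", run_start=1, cap_fraction=0.05)
    print(f"{n_stale}/100 stale -> {outcome.status}: deleted "
          f"{len(outcome.deleted_ids)} (fraction {outcome.fraction:.1%})")
# 5% deletes 5 rows; 6% aborts and deletes zero — strictly-above-cap is
# the refusal boundary.
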