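"""Adaptive batched download against a rate-limited, flaky endpoint.

The endpoint caps requests at 100 IDs and fails 10% of requests at
random (seeded).  The fetcher probes upward from 10 IDs, doubling on
success, halving and reshuffling on failure, until every record is
fetched exactly once.  The printed trace shows the schedule discovering
the unpublished capacity.
"""

from biosync import FetchPolicy, fetch_all, generate_universe, mock_endpoint

state = generate_universe(1000, seed=17)
endpoint = mock_endpoint(state, capacity=100, p_fail=0.1, seed=17)
policy = FetchPolicy(initial_batch=10, growth_factor=2.0, shuffle_seed=17)

records, trace = fetch_all(list(state.records), endpoint, policy)

print(f"fetched {len(records)} of {len(state)} records"
      f" in {len(trace.entries)} requests")
sizes = trace.batch_sizes()
flags = ["FAIL" if e.failed else "ok" for e in trace.entries]
print("request sizes:", ", ".join(f"{s}({f})" for s, f in zip(sizes, flags)))
served = sum(len(e.returned_ids) for e in trace.entries)
print(f"total records served: {served} (== {len(records)}: nothing fetched twice)")
# Sizes grow 10, 20, 40, 80, then overshoot the hidden capacity of 100,
# halve, and oscillate around it — minimal requests without knowing the cap.
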