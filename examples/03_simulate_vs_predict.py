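"""Observed vs predicted profile on simulated sequences.

Generates replicate Bernoulli sequences, measures their leaf-depth
profiles with the suffix-array profiler, and compares the mean observed
counts B(k+1) with the exact expectation mu(n, k).  Rows departing by
more than 5*sqrt(mu) would be flagged — for genuinely random data none
should be.
"""

from trieprofile import compare, compute_ratios, make_model, run_replicates

model = make_model([0.7, 0.3])
n = 200_000
summary = run_replicates(model, n, reps=5, base_seed=42)

r = compute_ratios(model, n)
ks = range(int(r.k_min), int(r.k_ext) + 1)
report = compare(model, n, ks, summary)

print(report.to_tsv(None))
print(f"flagged departures: {len(report.flagged)} (expect 0 for random data)")
print(f"extinction levels by replicate: {summary.extinction_histogram}")
print(f"predicted extinction length k_ext = {r.k_ext:.2f}")
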