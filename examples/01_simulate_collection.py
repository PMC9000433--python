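"""Simulate a synthetic isolate collection with planted taxonomic groups.

Each isolate gets true protein-region peaks (mostly shared within its
group) and small-molecule peaks (a group core plus private accessories),
observed through three noisy technical replicates.
"""

from strainselect import SynthParams, simulate_collection

params = SynthParams(n_groups=3, isolates_per_group=4, seed=42)
peaklists, truth = simulate_collection(params)

n_reps = sum(len(reps) for reps in peaklists.values())
print(f"isolates: {len(peaklists)}  replicate spectra: {n_reps}")
first = sorted(peaklists)[0]
pl = peaklists[first]["r1"]
print(f"{first} replicate r1: {len(pl)} peaks, "
      f"m/z {pl.mz[0]:.2f} .. {pl.mz[-1]:.2f} Da")
for g, universe in truth.np_universe_mz.items():
    members = [i for i, gg in truth.group_of.items() if gg == g]
    print(f"group {g}: {len(members)} isolates, "
          f"{len(universe)} distinct true small-molecule features")
# The per-group universe sizes are what the greedy selection will later
# have to cover; the replicate peak counts include dropout and noise.
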