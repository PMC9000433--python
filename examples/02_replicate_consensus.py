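"""Replicate consensus and mass-region splitting for one isolate.

Peaks seen in fewer than 2 of 3 technical replicates are discarded;
the survivors are split into the protein fingerprint region
(2000-15000 Da) and the small-molecule region (200-2000 Da).
"""

from strainselect import Peak, PeakList, merge_replicates, split_regions

replicates = [
    PeakList("isoA", "r1", [Peak(500.10, 40), Peak(1200.05, 80), Peak(3001.2, 150)]),
    PeakList("isoA", "r2", [Peak(500.14, 55), Peak(1200.02, 70), Peak(3000.1, 160)]),
    PeakList("isoA", "r3", [Peak(500.08, 45), Peak(890.00, 10)]),  # 890 is private
]

consensus = merge_replicates(replicates, tol=2.0, min_presence=2 / 3)
print(f"consensus peaks: {len(consensus)} (the replicate-private 890 Da peak is gone)")
for p, pres in zip(consensus.peaks, consensus.presence):
    print(f"  m/z {p.mz:9.3f}  intensity {p.intensity:6.1f}  presence {pres:.2f}")

protein, np_part = split_regions(consensus)
print(f"protein region: {len(protein)} peaks; small-molecule region: {len(np_part)} peaks")
# The consensus m/z is the intensity-weighted mean of the matched
# replicate peaks; presence is the fraction of replicates containing it.
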