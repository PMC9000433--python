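# Methods

## Pipeline model and assumptions

`strainselect` operates entirely on centroided peak lists. It assumes that
(i) an isolate's small-protein spectrum (2000–15000 Da) is a reproducible
taxonomic fingerprint, so binary presence/absence of protein features
suffices to group isolates near species level; and (ii) its small-molecule
spectrum (200–2000 Da) is a usable proxy for natural-product capacity, so
covering a fraction of distinct small-molecule m/z features covers a
comparable fraction of the chemistry. Neither spectrum is deisotoped or
adduct-collapsed: several mass features may represent one compound, which
inflates feature counts uniformly but does not bias selection between
isolates. The 2000.0 Da boundary belongs to the protein region only, so
every peak has exactly one region.

## Replicate consensus

Peaks from an isolate's technical replicates are pooled, sorted, and
grouped by one-dimensional single-linkage clustering: a new cluster starts
where the gap between consecutive m/z values exceeds the tolerance. Each
cluster yields one consensus peak (intensity-weighted mean m/z, mean
intensity) with a presence fraction; clusters below `min_presence`
(default 2/3 — seen in at least 2 of 3 replicates) are dropped. Because
replicate-private noise peaks almost never co-occur within tolerance
across replicates, the 2-of-3 rule removes them in expectation; that is
the testable rationale for the default. Consensus is permutation-invariant
in replicate order.

Matching tolerances default to 2.0 Da in the protein region and 0.2 Da in
the small-molecule region, reflecting the much poorer mass accuracy of
linear-mode TOF above 2 kDa. Both are configurable; the same values are
the defaults for cross-isolate binning. Single-linkage can in principle
chain peaks across a long run of sub-tolerance gaps; at these peak
densities that is rare, and it is the deterministic, order-independent
choice.

## Peak picking (optional)

For profile-mode input, a point is a peak if it is the maximum within
±`halfwindow` points (default 10) and its baseline-subtracted intensity
exceeds `snr_min` times the noise. The baseline is a rolling median
(window 101 points); the noise is 1.4826 × the median absolute deviation
of the baseline-subtracted residual (the Gaussian-consistent robust scale;
using the residual rather than raw intensity keeps baseline drift out of
the noise estimate). Defaults: `snr_min` 4 (protein), 10 (small-molecule).
These are this package's declared defaults for pre-picked-list-free use,
not values taken from any particular instrument workflow.

## Feature binning

Features are defined collection-wide by one single-linkage gap-split pass
per region, rather than per group or on a fixed grid: grid bins introduce
phase artifacts at bin edges, and a shared feature space is required for
collection-level totals and cross-library comparisons. Incidence is
binary; intensities are deliberately unused downstream because the
selection objective counts distinct features, not abundance.

## Clustering and cut

Distances between binary protein rows: cosine (default), Jaccard, or
Dice. An all-zero row (an isolate with no protein features) is defined to
be at distance 1 from every other isolate, avoiding 0/0. Agglomeration is
scipy's hierarchical clustering (UPGMA/average by default; Ward and
complete available), which is deterministic for a fixed input; tie
ordering among exactly equal merge heights follows scipy's internal
(nearest-neighbor-chain) order. The k-cut is implemented directly as
union-find over the first n−k merges, so "remove the k−1 highest merges,
ties by merge order" holds exactly and height- and k-cuts agree between
merge heights. Cut selection (height or k) is left to the user by design:
choosing a species-level cut automatically is an open problem and the
package does not pretend to solve it.

## Greedy selection

Within a group with feature universe U and threshold t, the loop picks the
unselected member with the largest count of *uncovered* features,
breaking ties by lexicographically smallest isolate id, and stops when
covered/|U| ≥ t (inclusive, so t = 1.0 terminates exactly at full
coverage). Counting uncovered rather than raw features is the reading
consistent with removing a selected isolate's features from the group
before iterating; the two coincide on the first pick. Members offering
zero uncovered features are never selected, even at t = 1.0. A group with
no small-molecule features selects nothing and reports captured fraction
1.0 by convention; `min_per_group=1` optionally forces one representative
(lexicographically smallest) to preserve taxonomic coverage. Reported
percentages are rounded half-up to integers.

Consequences tested as invariants: per-group coverage always reaches t;
coverage can strictly overshoot t; removing the last pick drops coverage
below t; the number of selected isolates is non-decreasing in t; identical
inputs give bit-identical outputs.

## Synthetic collections

The generator plants `n_groups` groups. Protein feature positions are
drawn uniformly in 2000–15000 Da (30 per group by default) and inherited
by group members with probability 0.9, by non-members with probability
0.05. Small-molecule features are a 10-feature group core (all members)
plus 5 private accessories per isolate, drawn in 200–2000 Da. All
positions respect a minimum pairwise separation of 5× the matching
tolerance so that binning is unambiguous when noise is off. Each of 3
replicates observes each true peak with dropout probability 0.1, Gaussian
m/z jitter (sd 0.3 Da protein / 0.03 Da small-molecule), and adds 3
replicate-private uniform noise peaks. Defaults were chosen once as
plausible for linear-mode MALDI-TOF colony spectra.

What the generator does *not* emulate: isotope envelopes and adducts,
intensity structure (intensities are uniform draws), detector saturation,
mass-calibration drift between plates, and correlated (non-private) noise.
Tests passing on this generator therefore demonstrate the pipeline's
logic — consensus, binning, grouping, coverage — not robustness to every
real-data artifact.

## Problem sizes and numerical choices

The test suite and the acceptance script use collections of 5 groups × 8
isolates × 3 replicates (40 isolates, ≈240 small-molecule features) and
seed sweeps of 20 runs; the greedy core is additionally checked
exhaustively against a brute-force oracle on all 3-isolate × 4-feature
incidence patterns and on random instances up to 6 × 8. These sizes
exercise every code path while keeping the whole suite in seconds.
Floating-point specifics: bin centers are clamped into [mz_min, mz_max]
(the mean can overshoot by one ulp); file round-trips are guaranteed to 6
significant digits and written at 10; Newick branch lengths are parent
height minus child height, clipped at 0 against ulp-negative differences.

## Known limitations

- No deisotoping or adduct collapsing; feature counts overstate distinct
  chemistry by a roughly constant factor.
- Absolute-Da tolerances only; no ppm mode (adequate over 200–15000 Da at
  linear-TOF accuracy, and simpler to reason about).
- The per-group greedy is not a minimum set cover and performs no
  cross-group optimization — by design, matching the selection procedure
  it automates.
- mzML support covers centroided (or force-passed profile) spectra with
  32/64-bit float arrays, zlib or no compression; vendor raw formats must
  be converted externally.
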