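# strainselect

Automated prioritization of environmental bacterial isolate libraries from
MALDI-TOF mass spectra.

## The problem

Natural-product drug discovery screens libraries of cultured bacteria, and
those libraries are chronically redundant: many isolates from an expedition
are the same species making the same metabolites, so the same known
compounds are re-discovered again and again. MALDI-TOF MS read directly off
a colony yields, in one acquisition series, a small-protein fingerprint
(2000–15000 Da) that tracks taxonomy and a small-molecule profile
(200–2000 Da) that tracks natural-product (NP) capacity. `strainselect`
turns per-colony replicate peak lists into a minimal isolate library that
still covers a user-chosen fraction of the observed chemical space — the
job a researcher would otherwise do by eyeballing hundreds of network
diagrams.

## The method

1. **Replicate consensus.** Peaks from the technical replicates of an
   isolate are matched by single-linkage grouping within a tolerance;
   peaks present in fewer than `min_presence` of replicates (default 2/3)
   are discarded.
2. **Feature binning.** Consensus peaks are pooled across isolates per mass
   region and split into shared m/z features wherever the gap between
   consecutive values exceeds the tolerance — a binary isolate × feature
   incidence matrix per region.
3. **Pseudo-phylogenetic grouping.** Protein-region rows are compared by
   cosine distance and clustered by UPGMA; cutting the dendrogram at a
   height or into *k* groups yields the pseudo-phylogenetic groups, each
   with its bipartite metabolite association network (MAN) of isolates and
   small-molecule features.
4. **Greedy coverage selection.** Per group with feature universe *U* and
   threshold *t* ∈ (0, 1]: repeatedly select the isolate carrying the most
   not-yet-covered features (lexicographic tie-break), add its features to
   the covered set *C*, and stop as soon as |C|/|U| ≥ t. This is greedy
   maximum coverage with an inclusive stopping rule; coverage is guaranteed
   to reach *t* in every group and may overshoot it, because features
   arrive in per-isolate blocks.

The deliverable is the ordered per-group selections plus collection totals:
percent reduction `100·(N−n)/N` of library size and percent of distinct
small-molecule features captured.

## Worked example

Isolate A carries features {1,2,3}, B {3,4}, C {5}; threshold 75%
(`examples/04_greedy_prioritization.py`):

```
universe: 5 distinct features
selected (in order): ['A', 'B']
cumulative captured: [3, 4]
captured fraction: 0.80 (threshold 0.75)
missed features (column ids): [4]  -- isolate C's private feature
```

A captures 3/5 = 60% < 75%, so the loop continues; B and C each offer one
uncovered feature and B wins the lexicographic tie, bringing coverage to
4/5 = 80% ≥ 75% — stop. C's private feature is the price of the 75%
threshold.

A full synthetic run (`examples/05_full_pipeline.py`, 5 planted groups × 8
isolates, seed 1) prints:

```
{
  "n_isolates_total": 40,
  "n_selected_total": 30,
  "n_features_total": 240,
  "n_features_captured": 197,
  "percent_reduction": 25,
  "percent_captured": 82
}
```

i.e. a quarter of the isolates can be dropped while the library keeps 82%
of the distinct small-molecule features, and every group individually
meets the 75% floor.

The `strainselect` command exposes the same stages from a shell
(`strainselect simulate`, `strainselect run --input-dir … --cut-k … --threshold …`,
`strainselect compare` for three-way library comparisons).

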