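# Methods

## Problem and model

A directed acyclic network connects one genetic variant (source, in-degree 0)
through molecular nodes (gene expression) to one disease outcome (sink,
out-degree 0). Every directed edge *i → j* carries a nonnegative connection
strength *r<sub>ij</sub>*; the effect of a simple source→sink chain is the
product of its edge strengths. Because log(1/r) turns products into sums and
reverses order, ranking chains by descending effect is identical to ranking
them by ascending total weight *Σ log(1/r<sub>ij</sub>)* — an exact identity
asserted on every returned list, not an approximation. The K best chains are
found with a deviation-path (Yen) search. Cyclic networks are rejected up
front; the search and the weight transform are only defined on DAGs.

The pathway importance score of chain *i* is PIS<sub>i</sub> =
effect<sub>i</sub> / q₅₀ with q₅₀ the median effect over **all** Q
source→sink chains (not only the K returned ones), so PIS > 1 exactly for
above-median chains and the median chain of an odd-sized set scores exactly 1.
When a network has more than 10⁶ chains, full enumeration is skipped and PIS
is reported unavailable rather than silently redefined on the top-K.

No significance test accompanies the ranking; the score is descriptive, and
pathways with PIS comparable to the top one should be treated as equally
ranked for follow-up.

## The six edge-strength estimators

Signed measures enter as absolute values, since log(1/r) needs r > 0 and
only the magnitude of association is meaningful for a chain product.

- **pearson / spearman** — textbook definitions; Spearman uses mid-ranks for
  ties. Constant vectors raise a degenerate-input error rather than return 0,
  so a misaligned data matrix surfaces immediately.
- **distance** — the empirical distance correlation from double-centred
  pairwise |Δ| matrices, computed vectorised in O(n²) memory; a constant
  margin is the defined value 0 (not an error). Verified in the tests against
  an independent element-by-element double loop to 1e−10.
- **mi** — plug-in kernel-density mutual information: 1-D Gaussian kernels
  with Silverman bandwidths (0.9·min(sd, IQR/1.34)·n^(−1/5)) for the
  marginals, a bivariate Gaussian kernel with diagonal bandwidth matrix
  H = diag(h_x², h_y²) for the joint, and the estimate taken as the sample
  mean of log(p̂(x,y)/(p̂(x)p̂(y))) at the observed points. The estimate is
  in nats, unbounded above, and may be slightly negative under independence;
  for edge-strength use it is clipped at 0 and otherwise left unnormalised —
  only within-method ordering matters downstream, and log(1/r) preserves it
  for any positive r. Values above 1 produce negative path weights, which the
  topological-order relaxation handles exactly on DAGs.
- **mic** — maximal information coefficient with B(n) = n^0.6 and the
  standard approximate search: one axis equipartitioned into q rows, the
  other partitioned by a dynamic program over clumps (maximal runs of points
  sharing a row, never split; pre-merged into at most c·p superclumps,
  c = 5 by default), maximised over all grids with p·q ≤ B(n) and both
  orientations, normalised by log min(p, q) (base-free). The inner loops are
  numba-compiled; a call at n = 500 costs ~2 ms after JIT. The tests compare
  it at small n against a brute-force enumeration of every possible cut
  placement.
- **mcc** — maximal correlation via alternating conditional expectations:
  alternately replace each transform by the smoothed conditional expectation
  of the other, re-standardise, and stop once E[(θ−φ)²] stops decreasing by
  more than 1e−6 (or at 100 sweeps, with a warning). The smoother is a
  nearest-neighbour local *linear* regression (span 0.5, i.e. a window of
  half the sample) for continuous variables — local linear rather than a
  running mean so that a truly linear relationship is fitted without boundary
  bias and the estimator degenerates to |Pearson| within estimator noise —
  and exact per-level conditional means for variables with ≤ 10 distinct
  values, which handles 0/1 genotype and disease nodes without assumptions.
  The span is the "large" span of the classic variable-span smoother family;
  smaller spans inflate the MCC of independent data noticeably (overfitting
  of the backfit), larger ones start missing high-frequency structure such
  as sin(2x).

## Synthetic-data generator

`make_scenario` / `generate_population` reproduce the benchmark design:
a 56-node / 82-edge DAG whose source feeds 4 designated effective pathways
(jointly 23 distinct edges, strengths drawn U(0.75, 1)) and a 35-node weak
background (strengths U(0, 0.25)). Nodes are generated in topological order
as x_child = Σ_p β_p φ_p(x_parent) + ε with Gaussian noise and standardised
to mean 0 / variance 1 on the population. Edge shapes φ: linear, quadratic,
cosine, sin(2x), arcuate √(C − x²) with C = 25 and the parent clipped to
[−5, 5], exponential, and reciprocal 1/(x ± 0.5) (shifted off its
singularity). Mixed nonlinear scenarios place fixed shape counts on the
effective edges — 30%: 5 cosine + 2 quadratic; 40%: 6 + 3; 50%: 8 + 4;
60%: 8 + 5 + 1 arcuate — with the selected subset seed-fixed and identical
across replicates.

Numerical choices worth recording:

- **Coefficients by linear solve.** φ(parent) columns are standardised
  empirically on the population and β is solved from the empirical
  correlation matrix of those columns (β = Σ⁻¹w), so corr(φ_p(parent_p),
  child) equals each edge's target *w* exactly up to Monte-Carlo error
  (~0.005 at N = 50,000) even for multi-parent nodes with correlated
  parents. For a single parent this reduces to the closed form β = w,
  σ = √(1 − w²) — for a quadratic edge with a standard-normal parent,
  exactly σ₂ = √(1 − 2β₁₂²) in raw-φ coordinates.
- **Feasibility at convergence nodes.** All 4 effective paths end at the
  sink, so the sink has several strong parents, and no unit-variance child
  can be correlated ≈ 0.9 with each of them (it would need variance > 1).
  When the solved coefficients would leave the noise variance below 0.02,
  they are scaled back proportionally and the reduced strengths are recorded
  as those edges' effective targets. Only sink-in edges are affected in
  practice; truth is computed from realised population correlations either
  way, so all comparisons stay internally valid.
- **Background topology.** The background is a 35-node chain plus 23
  seed-drawn skip edges, never touching effective intermediate nodes, so
  every non-designated path has ≥ 2 weak edges and the designated paths
  provably dominate the true ranking. Two 3-edge variant→gene→gene→disease
  detours are always present (and 2-edge detours excluded): a 3-edge product
  of weak strengths stays below every effective path for estimators whose
  small-dependence values are inflated (MIC ≈ 0.14 on independent data at
  n = 500), yet overtakes an effective path whose estimated strength
  collapses under nonlinearity — the regime the benchmark is meant to
  discriminate.
- **Replicates.** Each replicate draws n of the N population rows without
  replacement from its own seed-derived substream ([seed, 3, replicate]);
  scenario construction, strengths and population use disjoint substreams of
  the same master seed, so one integer reproduces an entire study.
  Estimator failures inside a replicate are counted as misses for both
  criteria, never dropped, so denominators always equal R.

The fan fixture (`fan_network` / `simulate_fan_data`) mirrors the real
six-chain genotype→expression→disease layout with a binary source and a
binary sink (thresholded liability). It emulates the *structure* of cohort
data, not its realism: no linkage disequilibrium, no measurement error
model, no confounding, and Gaussian intermediates. Passing tests on it show
the pipeline's mechanics, not that any particular biological pathway ranking
is correct.

## Scale of the shipped experiments

The test suite and the acceptance script run the all-linear n = 500 scenario
at the full 500 replicates for Pearson and at 100 replicates (rescaled per
500) for the slower MCC, and the 40%/50% mixed scenarios at 50 replicates
per method; these sizes give binomial standard errors well below the effects
being asserted (the MCC–Pearson range-right gap exceeds 0.6). Mid-range
counts (e.g. the all-right row at n = 100) depend on the particular random
strength draw and network fixture and are reported, not asserted.

## Known limitations

- The benchmark DAG honours the published node/edge/path counts but not any
  particular biological wiring; truth is always derived from the fixture
  itself.
- q₅₀ (hence PIS) requires enumerating all chains; beyond 10⁶ chains it is
  reported unavailable.
- Strengths ≤ 1e−12 are treated as absent edges (infinite weight): log(1/0)
  is undefined and such edges cannot lie on a top path.
- The MCC permutation behaviour under independence is estimated, not exact;
  no p-values are provided for any measure.
- Summary-statistic (rather than individual-level) input is out of scope:
  the nonlinear measures cannot be computed from correlation matrices alone.
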