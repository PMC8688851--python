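# Methods

## Model and assumptions

A trait network is a marginal-correlation graph: nodes are traits,
edges are pairwise Pearson correlations that pass a significance gate,
weighted by |r|. Nothing conditional or causal is inferred — two traits
correlated only through a third still get a direct edge if the marginal
correlation is significant. The method assumes approximately linear
trait–trait relationships on the analysis scale (hence the log10
default for right-skewed traits) and treats rows as independent
species-level records; phylogenetic non-independence is not modelled,
and duplicate species names are kept as independent rows (no
aggregation rule is imposed).

Node-pair distances come from a separate construction: a
correlation-matrix PCA of the standardised traits, with each trait
placed at its coordinates across *all* components and distances taken
as Euclidean. Because the full component space is retained, the
embedding loses no information; with variance-scaled coordinates the
squared distance reduces to d²ᵢⱼ = 2(1 − rᵢⱼ) on the complete-case
correlation, which makes "close" mean "strongly positively correlated"
and puts distances on a bounded, dimension-free scale.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| `alpha` | 0.05 | — | conventional edge gate; strict `p < alpha`, no multiple-testing correction by default (a Bonferroni/BH switch exists) because the method's convention is raw p-values — at 15 pairs the family-wise inflation is real and users comparing many networks should turn BH on |
| `transform` | log10 for strictly positive traits | — | leaf economic traits are log-normally spread over orders of magnitude; correlation on the log scale is the field's convention |
| `length_mode` | `pca_distance` | PCA units | D, AL and closeness are written in terms of d; `inverse_weight` (1/\|r\|) and `unit` modes are provided because the path-cost convention cannot be pinned down in general, and every output records which mode produced it |
| `betweenness_mode` | `count` | paths | the definition counts shortest paths through a node, so all co-shortest paths count as one each (integer counts, unordered end pairs, endpoints excluded); `fraction` gives Brandes-style fractional credit |
| `n_replicates` | 9999 (library), 999 (CLI) | — | 9999 matches the field convention for bootstrap uncertainty; the CLI default trades a digit of SE stability for interactive turnaround |
| `sample_fraction` / `with_replacement` | None / True | — | classic bootstrap at full pool size; group subpools use without-replacement draws of ceil(0.75·N)+1 so each replicate keeps more than three-quarters of a small pool and can still form a network |
| `min_edges` | 1 | edges | replicates below it are *degenerate*: counted and reported, excluded from summaries — silently dropping them would bias ED upward, silently keeping them would put NaN paths into D/AL |

## Numerical choices

- **Pairwise-complete correlation, complete-case PCA.** Correlations
  use each pair's complete rows (sparse trait coverage then costs one
  cell, not the whole matrix); the PCA needs a single row space, so it
  uses rows complete across all traits. The asymmetry is deliberate and
  recorded (`n_pairs` per cell).
- **Undefined cells are non-edges, never errors**: fewer than 3
  complete rows, or a constant column on them, yields NaN r/p and no
  edge. A network with zero edges is a legal result, flagged in `meta`.
- **PCA determinism.** Components come from `eigh` on the correlation
  matrix; each component's sign is fixed so its largest-|loading| entry
  is positive. Distances are invariant to consistent per-component
  sign flips (asserted in tests).
- **Shortest paths.** Lengths from Dijkstra over significant edges;
  path *counts* by dynamic programming over each source's shortest-path
  DAG. Two float path lengths tie when equal to relative tolerance
  1e-9 (absolute 1e-12) — the tolerance exists for constructed
  equal-length examples; continuous weights make accidental ties
  measure-zero.
- **Disconnected networks.** D and AL run over connected pairs only;
  closeness restricts to reachable peers with (n−1) replaced by their
  count; fully isolated nodes get closeness 0 plus an `isolated` flag;
  a `connected` flag is always reported. An `al_denominator="all"`
  switch divides by n(n−1) regardless, for users who want unreachable
  pairs to penalise the mean.
- **Statistics.** Welch (unequal-variance) t-test for group contrasts —
  the safer default when only "independent t-test" is conventional; SE
  of a bootstrapped parameter is the replicate standard deviation;
  paired mean differences use percentile bootstrap CIs (2000 resamples)
  over replicate indices, independently per group.

## What the generator emulates — and what it does not

`synthetic_data` draws multivariate normal deviates with an exact
target correlation matrix, back-transforms them (10^(loc + scale·z) by
default) to positive, log-normally spread trait-like values, applies
missing-completely-at-random masking, and concatenates groups with
their own coupling matrices. The leaf-economics preset encodes the
fast–slow sign structure (positive coupling within
{A_mass, N_mass, P_mass, R_mass}, positive LMA–LL, negative between
the blocks, nearest-positive-definite repaired) with marginal
locations/scales giving realistic spreads (LMA ≈ 100 g m⁻²,
N_mass ≈ 18 mg g⁻¹, LL ≈ 11 months). The block-bridge preset plants a
single trait whose removal disconnects two tight blocks — a known
betweenness ground truth; the group-contrast preset differs two pools
only in coupling strength.

Real trait tables additionally carry phylogenetic signal, non-normal
and heteroscedastic residuals, missingness that is *not* at random
(rare traits are measured on non-random species subsets), and
site/biome structure. Passing tests on the generator therefore
demonstrate that the machinery is correct and calibrated under its own
assumptions — not that any particular empirical dataset satisfies
those assumptions.

## Problem sizes

The test suite and the reproduction script run the method at sizes
chosen to make each property decisive at desk scale: 1000 random
graphs of ≤ 6 nodes against exhaustive path enumeration, 2000
null datasets of n = 30 for edge-test calibration, 200 seeded runs at
n = 1000 for bridge recovery, and 400 species per group with 500
bootstrap replicates for the group contrast. At these sizes every
stochastic assertion has comfortable statistical margin (binomial ±2–3
SD bands, ≥95% win rates).

## Known limitations

- Marginal correlations conflate direct and indirect coupling; no
  partial-correlation or graphical-model inference is attempted (out of
  scope by design).
- Group-contrast t-tests run on bootstrap pseudo-replicates. With
  hundreds of replicates this makes p-values almost arbitrarily small
  for real differences; read them together with effect sizes, which is
  why means, SEs and paired-difference CIs are always reported
  alongside.
- The PCA "score" convention (variance-scaled variable coordinates vs
  raw eigenvector loadings) changes distance magnitudes but not their
  ordering-by-correlation on the leading structure; both are offered
  and stamped into provenance since field usage is not uniform.
- MCAR is the only missingness mechanism generated or assumed.
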