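# Methods

## Model and assumptions

The learner treats every variable — gene expression and trait phenotype
alike — as a node of a Bayesian network whose joint density factorizes into
per-node conditionals, `p(X) = Π p(x_i | pa(x_i))`. Structure learning is
constraint-based: edges are decided purely by (conditional) independence
tests, not by a search over scored structures. The independence tests use
the Gaussian-entropy estimator, which is exact when the data are jointly
normal and degrades gracefully into a test of (partial) linear correlation
otherwise. Two assumptions follow:

* **Second-moment sufficiency.** Dependence is measured through covariance
  determinants, so purely nonlinear, zero-correlation dependence is
  invisible to the tests.
* **Faithfulness.** A vanishing conditional mutual information is read as
  conditional independence in the generating structure. As in every
  constraint-based learner, near-cancelling paths can defeat this.

Both MI and CMI are reported in nats (natural log). The equations write an
unspecified `log`; a threshold such as 0.01 is only meaningful once the base
is fixed, so the base is documented here and a `--log-base 2` CLI flag
rescales the stage logs for readers who think in bits.

## Discretization

Continuous columns are coded into `N` ordered levels:

* **Interval** (equal width): bins of width `(max − min)/N`, half-open with
  the last bin closed, so the maximum maps to code `N − 1`. A constant
  column codes to all zeros. Codes are invariant under positive affine
  transforms of the column.
* **Quantile** (equal frequency): interior cut points at the
  linear-interpolation empirical quantiles `k/N`; a value's code is the
  number of cut points strictly below it, so values equal to a cut point
  fall in the lower bin and ties always share a code.

Traits are discretized with the same method and `N` as genes. `N = 1` is
accepted by the column-level functions (degenerate all-zero coding) but
rejected for whole datasets, where it would make learning vacuous.

By default the information estimates are computed on the integer codes,
treated as numeric — this is what makes the learned network change with
`N`, which is the observed and intended behaviour of the pipeline; the
codes are ordered so their covariance still carries the monotone part of
the dependence. `mi_on="raw"` switches the estimates to the continuous
values (used, e.g., by the exact-covariance oracle checks).

## The three phases

**Drafting.** All pairwise MIs are computed in one pass from the correlation
matrix (`MI = −½ ln(1 − r²)` for scalar pairs, algebraically identical to
the determinant form). Pairs with MI above `draft_eps` are sorted by MI
descending, ties broken lexicographically so the ranking is a total order.
Walking the ranking, a pair already connected by an open path is deferred
(the classical R set); otherwise the edge joins the draft network.

**Thickening.** Deferred pairs are revisited in order. For a pair (a, b) a
cut set is taken as the smaller of: neighbours of a lying on at least one
simple skeleton path to b, and the analogous set for b (ties favour a's
side). Removing that set provably disconnects the pair. The pair's CMI
given the cut set is then minimized by a greedy refinement — repeatedly
dropping the conditioning node whose removal lowers the CMI most, stopping
when no drop helps or the value falls to the threshold. If the minimized
CMI still exceeds `thicken_eps`, the dependence cannot be explained away
and the edge is inserted.

The refinement step matters: conditioning on *all* neighbours can open a
collider path (conditioning on a common child induces dependence between
its parents) and would leave spurious edges in dense structures such as the
diamond `a→b→d, a→c→d`, where b and c are separated by {a} but not by
{a, d}. The greedy shrink restores the behaviour of the full three-phase
procedure, which likewise refines its conditioning sets.

**Thinning.** Every edge whose endpoints remain connected without it is
removed temporarily, a cut set is recomputed on the reduced skeleton, and
the edge is deleted permanently iff the (refined) CMI is at or below
`thin_eps`. Dependence always requires a strictly greater statistic, so a
value exactly on the threshold counts as independent. Edges are processed
in insertion order; restored edges keep their original provenance.

**Orientation.** Traits are declared root nodes: every trait–gene edge is
directed trait → gene. Gene–gene edges are left undirected — the procedure
never determines their direction, and inventing one would overstate the
result. A trait–trait edge cannot be oriented without violating the root
constraint on one side, so it is dropped with a logged warning rather than
silently.

## Parameters

| Parameter | Default | Meaning |
|---|---|---|
| `draft_eps, thicken_eps, thin_eps` | 0.01 nats each | Minimum information for an edge at each stage; 0.01 nats ≈ r ≈ 0.14 for scalar pairs |
| `method` | quantile | Discretization family |
| `n` | 5 | Discretization levels (N-value) |
| `mi_on` | codes | Whether information sees the integer codes or raw values |

The defaults are the best-performing operating point of the experimental
grid the method was characterized on (thresholds 0.01/0.01/0.01, mid-range
N); the CLI accepts any positive triple.

## Numerical choices

* Covariances use the unbiased (n − 1) denominator.
* Determinants go through `slogdet`. A conditioning-block covariance whose
  condition number exceeds 1e12 receives a ridge of `1e-10 × mean(diag)` on
  the diagonal before the determinant — near-duplicate gene codes are the
  typical cause.
* A *perfectly* collinear pair (the joint x, y block singular even
  numerically) returns `+inf` with a warning: maximal dependence, never a
  crash; such a pair simply ranks first in drafting.
* A constant variable carries no information: MI/CMI involving it is 0 by
  definition, avoiding log-of-zero.
* A degenerate numerator block (x or y fully explained by the conditioning
  set) yields CMI 0.
* MI/CMI are clamped at 0 from below; exact d-separation cancels
  algebraically and lands within 1e-10 of zero before clamping.
* Symmetry `MI(x, y) = MI(y, x)` holds exactly (not just to roundoff): the
  pair is stacked in a canonical order before the covariance is formed.

## Conditional probability tables

After structure learning, each node's CPT is estimated over its directed
in-neighbours only (undirected gene–gene edges contribute no parents — the
factorization requires a DAG and gene–gene direction is undetermined).
Probabilities are add-1 (Laplace) smoothed relative frequencies over the
observed parent configurations; unobserved configurations fall back to the
uniform distribution. This keeps the joint probability strictly positive on
observed support and normalized over the full code space.

## The synthetic generator

`sample_linear_gaussian` draws from a linear structural-equation model:
each node is the coefficient-weighted sum of its parents plus independent
Gaussian noise, generated in topological order from a single seeded
generator. The population covariance `(I − A)⁻¹ D (I − A)⁻ᵀ` is available
in closed form (`analytic_covariance`), and `dataset_from_covariance`
produces data whose *sample* covariance equals a target exactly (empirical
whitening followed by colouring), which turns finite-sample tests into
exact-population tests.

`generate_maize_like` emulates the layout of the motivating panel: 527
samples × 109 variables — 5 trait roots, 4 reported genes each loading on
one trait with population correlation 0.5 (unit-variance parameterization:
coefficient `b = effect`, noise sd `√(1 − b²)`), and 100 background genes.
Five percent of the background genes carry a weak true trait link at half
the effect, because real panels contain genuinely trait-associated genes
beyond the documented ones — a fixture without them would make the
false-positive metric meaningless. The generator does **not** emulate
RNA-seq count distributions, population structure, linkage disequilibrium,
or trait–trait correlation; the learner only consumes second-moment
structure, so passing tests demonstrate recovery of linear-Gaussian signal
at realistic sample sizes, not robustness to those real-data features.

`small_dag_catalogue` fixes 20 models on ≤ 5 nodes (chains, forks,
colliders, stars, a diamond, an M-structure, disconnected pieces, negative
coefficients) with every edge at population |r| ≥ 0.3, used by the
oracle-equivalence checks against brute-force conditional-independence
enumeration.

## Problem sizes used in the checks

The validation suite runs the estimator calibration on 1,000 random pairs,
the large-sample MI and chain-CMI checks on 100,000 draws, the invariant
sweep on 200 randomized 6–12-node pipelines, and the recovery benchmark on
ten 527 × 109 panels; these sizes give stable statistics while keeping the
whole suite fast on a single CPU.

## Known limitations

* Gene–gene edges are never oriented; downstream CPTs therefore condition
  on trait parents only.
* The A/B evaluation of an *external* edge list cannot recover isolated
  nodes from the file; supply the node universe (`--nodes-from`) for
  correct denominators.
* The cut-set search is heuristic; it is exact on the catalogue structures
  but carries no general minimality guarantee.
* Information thresholds are absolute, not calibrated p-values; the same
  eps implies different false-positive rates at different sample sizes.
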