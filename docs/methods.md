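# Methods

## Range overlap and its summary

Overlap between two species ranges is the area of sympatry divided by
the area of the smaller range, an index on [0, 1] that equals 1
whenever the smaller range is nested in the larger. Indices below 0.05
are classified as complete allopatry and above 0.95 as complete
sympatry; both thresholds are strict inequalities, so exactly 0.05 or
0.95 is "partial". The buffer absorbs sampling incompleteness and small
mapping errors at the extremes.

A collection of n pairwise indices is summarised by z (count of
completely sympatric pairs), c (completely allopatric) and the
bimodality score (z·c)/((n/2)·(n/2)). The denominator uses n/2 as a
real number, not an integer floor, so the score is well defined for odd
n; it reaches 1 only when the data split evenly between the two extreme
states. Observed polygons are simple rings in planar equal-area
coordinates (GeoJSON or WKT); area and intersection go through shapely.
Holes, multi-part ranges and any map-projection handling are out of
scope — inputs are assumed preprocessed.

## The range-movement null model

Speciation is modelled as the division of a square ancestral range of
area f·100² on a 100 × 100 domain, f being the ancestral-range fraction
(default 0.16; the medians observed for heliconiines motivate 0.082,
0.108, 0.135, 0.16 and, because the simulation starts by halving the
ancestor, their doubles). Non-peripatric splits draw the split fraction
Uniform(0, 1) — the maximal-entropy reading of a "random division in
two"; a different sampler can be injected through
`SimConfig.split_sampler`. Daughters are squares:

* **sympatric** — the smaller daughter is placed uniformly inside the
  larger, which is itself placed uniformly on the domain (the larger
  box's own position is a modelling choice; it does not affect the
  initial overlap of 1);
* **vicariant** — the smaller daughter sits exactly 2 units to the
  right of the larger; its bottom edge is drawn uniformly over the
  positions whose vertical interval intersects the larger's vertical
  extent, redrawing when the domain is overrun;
* **parapatric** — as vicariant with a 0 gap (ranges abut);
* **peripatric** — the split is 95:5 and both daughters are placed
  uniformly at random, rejecting placements that overlap.

Movement adds four independent N(μ, σ²) deviates per box per step,
signed outward (top and right add, bottom and left subtract), so
μ = 0.1 gives ranges a tendency to grow; at μ = 0 the sign convention
is distributionally irrelevant. σ is explored over 0.25–2 length units
per step. Boxes are clipped to the domain; a reflecting boundary is
available as `boundary="reflect"` since the original edge behaviour is
a genuinely open choice, but clipping (a hard limit on total available
area) is the default. A box whose width or height reaches zero is
extinct and the whole pair restarts from the split, up to 1000 restarts
before an error names the parameter combination. A pair takes
round(10 × branch length) steps, minimum 1; branch lengths (My) are
assigned to pairs by permutation without replacement. All replicates of
a sweep cell are stepped as one flat batch of edge vectors, which keeps
a 23-mixture × 1000-replicate sweep for one parameter set near 6 s on
one CPU; each cell draws from its own RNG stream spawned from the sweep
seed, making sweep tables bit-reproducible.

## Percentile inference of the sympatric fraction

For the observed data and every simulated replicate, the three indices
(z, c, bimodality) are computed with the same thresholds. A (parameter
combination, k sympatric events) cell is consistent with an observed
index when the observed value lies within the 2.5–97.5 percentile band
of its replicate distribution — linear-interpolation quantiles, with
boundary equality counting as consistent ("outside" read strictly). The
headline interval is the min and max of k/n over cells consistent for
all three indices *in the same parameter combination*; per-index
union ranges are also reported. Percentile bands can be precomputed
(`sweep_percentile_bounds`) so many observed summaries can be screened
against one sweep.

The packaged recovery experiment (`parameter_recovery`) freezes a
protocol sized for a desk run: a grid of σ ∈ {0.25, 0.5, 1, 2} ×
μ ∈ {0, 0.1} × {vicariant, peripatric} at ancestral fraction 0.16 with
500 replicates per cell (a representative subset of the full study
grid, which also varied ancestral sizes and included parapatry and 1000
replicates), with observed datasets generated at σ = 0.5, vicariant.
Because a 22-pair dataset can only realize whole counts of sympatric
events, coverage is judged against the realized truth k/n with
k = round(fraction × n): asking the interval to cover an unrealizable
fraction like 0.75 (16.5 pairs) would conflate discretisation with
inference error.

## Age-range correlation

OLS of arcsin(√overlap) on phylogenetic branch length, sister pairs
only (no ancestral-range reconstruction). The angular transform is a
bijection [0, 1] ↔ [0, π/2], so overlap values of exactly 0 or 1 are
ordinary data points. The slope p-value is the two-sided t-test with
n − 2 df. The back-transformed intercept sin²(β₀) — the crude sympatric
fraction — truncates the intercept into [0, π/2] first, since a noisy
fit can stray outside the transform's range.

## Trait and niche divergence

Similarity in mimicry rings or host plants is x/y: shared labels over
the repertoire size of the sister with fewer labels (labels are
case-normalised; upstream record filtering such as dropping dubious or
captive records is expected in the input tables). Similarity versus
branch length is a binomial GLM on (shared, unshared) counts with logit
link, fitted by IRLS via statsmodels. Overdispersion is detected as
φ > 1 with φ = Pearson χ²/(n − 2) (two fitted parameters), and then —
the quasi-GLM with variance φμ — standard errors are scaled by √φ while
point estimates stay untouched. Degenerate likelihoods (all proportions
0 or 1, separation, non-convergence, or |coefficient| > 30 on the logit
scale) return a flagged fit with NaN estimates rather than numbers that
look healthy. Climatic niche overlap uses the same angular OLS as the
ARC. The range-overlap multiple regression (angular overlap on branch
length and the three similarities) keeps complete cases only and warns
on rank deficiency.

Niche space is the first three principal components of the correlation
matrix of the environmental layer stack: layers are standardised over
cells and the correlation matrix eigendecomposed; exactly three
components are retained regardless of the variance profile, with the
explained fractions reported so the adequacy of three can be judged per
dataset. A species' niche is the 3-D convex hull of its occurrence-cell
scores (scipy Qhull); fewer than four points or a coplanar cloud raises
a degenerate-niche error rather than returning a zero volume. Pairwise
niche overlap is intersection volume over the smaller volume — the
"area" of intersecting 3-D bodies is read as volume — computed exactly
by stacking both hulls' facet halfspaces, locating an interior point as
the Chebyshev centre by linear programming (no interior ⇒ overlap 0),
and taking the hull volume of the halfspace intersection.

## Synthetic data

The generators exist so every stage runs without downloads, and their
defaults state the study conditions: 22 sister pairs, branch lengths
Uniform(0.1, 10) My (the observed sister splits span roughly this
scale; the true distribution is not published, so uniform is the
assumption-light choice with `max_age` exposed), trait repertoire sizes
uniform on 1–8, and 19 climate layers on a 60 × 60 grid. Pair tables
come from the simulator itself under a known mode mixture, so the truth
is exact by construction. Trait sets share each label of the smaller
repertoire with probability s, making expected similarity equal s.
Climate layers mix a shared smoothed Gaussian field (weight √c) with
independent ones, so the between-layer correlation c tunes how much
variance the leading components absorb; occurrences are drawn uniformly
within per-species range boxes, so range overlap induces niche overlap.

What the synthetic data does not emulate: real biogeographic structure
(Andes/Amazon asymmetries), non-rectangular or fragmented ranges,
spatially biased sampling, phylogenetic signal in branch lengths, or
competition between sisters. Passing tests therefore demonstrate that
the estimators recover truth under the null model's own assumptions,
not that those assumptions hold for real butterflies — the same caveat
the inference itself carries.

## Numerical notes and limitations

* Quantiles everywhere are numpy's linear-interpolation type; with
  fewer than 40 replicates per cell a warning flags unstable tails.
* The overlap index clips at 1 to absorb floating-point excess;
  intersection areas up to 1 part in 10⁹ above the smaller area are
  tolerated before an inconsistency error.
* Sweeps and recoveries are deterministic given a seed (per-cell
  spawned RNG streams); scalar convenience wrappers (`simulate_pair`,
  `step_move`) share the engine but not the draw order of the batched
  path.
* Peripatric placement and vicariant vertical placement use rejection
  sampling capped at 1000 rounds; structural infeasibility (daughters
  that cannot fit) raises immediately.
* The simulator does not model habitat heterogeneity, range
  fragmentation, or interactions between species; mixtures combine
  sympatric events with a single non-sympatric geometry per run.
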