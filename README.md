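# sympatry

Tools for inferring the geography of speciation — how often new species
arise in sympatry rather than allopatry — from the present-day range
overlap of sister species, with heliconiine butterflies as the
motivating system.

Classic age-range correlations (ARC) regress range overlap on time
since divergence and read the intercept as the fraction of speciation
that was sympatric, but intermediate intercepts are ambiguous: they can
reflect a mixture of speciation modes or a single mode followed by
rapid range movement. This package implements the complementary
simulation approach: a stochastic null model of post-speciation range
movement under four speciation geometries generates the distribution of
overlap summaries expected for every possible mixture of sympatric and
non-sympatric speciation, and the mixtures whose simulated
distributions are consistent with the observed data (two-tailed
percentile rule) bound the frequency of sympatric speciation.

## The model and statistics

**Overlap index.** For a sister pair with range areas $A_1, A_2$ and
area of sympatry $A_\cap$, overlap is $A_\cap / \min(A_1, A_2) \in
[0, 1]$. An index $< 0.05$ counts as complete allopatry and $> 0.95$ as
complete sympatry. A set of $n$ pairs is summarised by the counts $z$
(completely sympatric) and $c$ (completely allopatric) and the
bimodality score

$$B = \frac{z \cdot c}{(n/2)(n/2)} \in [0, 1].$$

**Simulator.** On a $100 \times 100$ domain, an ancestral range of area
$f \cdot 100^2$ splits into two square daughters: inside one another
(sympatric), separated by a 2-unit gap (vicariant), abutting
(parapatric), or 95:5 and placed disjointly at random (peripatric).
Each range edge then receives an independent $N(\mu, \sigma^2)$ deviate
outward per time step ($\sigma \in [0.25, 2]$, $\mu \in \{0, 0.1\}$);
a pair runs for $10 \times$ its branch length (My) in steps, and pairs
losing a daughter to extinction are re-simulated.

**Inference.** For each parameter combination and each number $k$ of
sympatric speciation events, 500–1000 replicate datasets yield
distributions of $(z, c, B)$; observed values inside the 2.5–97.5
percentile band in the same combination for all three indices mark
$k/n$ as consistent. ARC fits use OLS of $\arcsin\sqrt{p}$ on branch
length; trait similarity (shared labels over the smaller repertoire)
uses a binomial GLM with quasi-binomial SE inflation
($\mathrm{Var} = \phi\mu$) under overdispersion; climatic niches are
3-D convex polyhedra in correlation-matrix PCA space of 19 bioclim-like
layers, with overlap = intersection volume / smaller volume.

## Worked example

```python
import numpy as np
from sympatry.simulator import SimConfig, run_sweep
from sympatry.synthetic import gen_branch_lengths, gen_pair_table
from sympatry.geometry import summarize_overlaps
from sympatry.inference import consistent_sympatric_range, arc_regression

rng = np.random.default_rng(42)
bl = gen_branch_lengths(22, rng=rng)
cfg = SimConfig(movement_sd=0.5)
table, truth = gen_pair_table(22, 0.5, cfg, rng, branch_lengths=bl)

obs = summarize_overlaps(table["overlap_index"])
fit = arc_regression(table["branch_length_my"], table["overlap_index"])
sweep = run_sweep(bl, [cfg], n_replicates=500, seed=43)
res = consistent_sympatric_range(obs, sweep)
```

Output for this seed:

```
observed: n=22 z=7 c=11 bimodality=0.64
ARC intercept 0.72 +/- 0.38 (back-transformed 0.44), slope 0.001 (P=0.98)
jointly consistent sympatric fraction: 36%-50%
```

Of the 22 synthetic sister pairs (11 truly sympatric in origin), 7 end
completely overlapped and 11 completely disjoint after range movement.
The ARC intercept back-transforms to 0.44 — a crude sympatry estimate
close to the true 50 % — while the percentile inference brackets the
truth with an interval of 36–50 % of speciation events being sympatric.

The same pipeline is scriptable from the shell:

```bash
sympatry synth --seed 7 --out-dir study/
sympatry simulate --pairs study/pairs.csv --seed 5 --out sweep.csv
sympatry infer --pairs study/pairs.csv --sweep sweep.csv --out cells.csv
sympatry arc --pairs study/pairs.csv
```

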