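# Methods

## Generative model

`arraysim` simulates an `n × (m1 + m2)` matrix of log2 expression values
for a two-condition (control vs test) design. Each gene's values decompose
as `x = a + s + n`: a within-gene sampling component `a`, a DE shift `s`
that is non-zero only for DE genes' test samples, and additive noise `n`.
Technical artefacts (spatial effects, saturation, outlier spikes) are not
modelled; the output is "post-normalization" data.

The generation proceeds in six steps:

1. `z ~ Beta(shape1, shape2)`, one draw per gene. `shape1` is fixed at 2
   by convention; `shape2` (default 4, sensible range 4–8) controls the
   right skew, i.e. the excess of weakly expressed genes.
2. `z̄ = lb + ub·z`. Means therefore lie in `[lb, lb + ub]` — with the
   defaults `lb = 4`, `ub = 14`, in `[4, 18]`. The scaling is deliberately
   `lb + ub·z` (not `lb + (ub − lb)·z`): observed maxima approach
   `lb + ub`, and the defaults were characterised under this reading.
3. For each gene, `m1 + m2 + 1` draws from
   `U((1 − α)z̄, (1 + α)z̄)` with `α = λ1·e^(−λ1 z̄)`. The exponential
   decay ties relative variability to mean level: at `λ1 = 0.13`,
   α ≈ 10.0% at `z̄ = 2` and ≈ 3.54% at `z̄ = 10`. Small `λ1` (≈ 0.01)
   makes variability nearly level-independent. The extra first draw is the
   reference column used in ratio mode.
4. DE assignment: each gene is DE with probability exactly `pde`
   (a `U(0,1) < pde` comparison), and a DE gene is up-regulated with
   probability `1 − sym`. Shift means are `μde = μde_min + Exp(rate λ2)`
   — the *rate* convention, so larger `λ2` concentrates shifts near the
   minimum (mean excess `1/λ2`). Test-sample values of a DE gene get
   `±N(μde, σde²)` added, sign by direction; controls and the reference
   are never shifted.
5. If `σn > 0`, independent `N(0, σn²)` noise is added to every entry of
   the full `n × (m1 + m2 + 1)` matrix, reference column included. In
   ratio mode the shared noisy reference therefore induces correlation
   across samples, as it would on a real two-color design with one
   reference hybridisation. `σn = 0` skips this step entirely (and
   consumes no random draws, so noisy and noise-free runs share their
   base stream).
6. Intensity mode drops the reference column; ratio mode subtracts it
   from every remaining column.

### Parameter guidance

| parameter | default | meaning / units |
|---|---|---|
| `n` | 10000 | genes (probes) |
| `m1`, `m2` | 7, 7 | control / test samples; ≥ 3 recommended for testing |
| `shape1`, `shape2` | 2, 4 | beta shapes; `shape2` ∈ [4, 8] |
| `lb`, `ub` | 4, 14 | log2 scaling bounds; `lb` ∈ [2, 6], `ub` ∈ [8, 16] |
| `pde` | 0.02 | DE fraction |
| `sym` | 0.5 | P(up) = 1 − sym among DE genes |
| `lambda1` | 0.13 | width-decay rate (per log2 unit) |
| `lambda2` | 2 | shift-excess rate (per log2 unit) |
| `mu_de_min` | 1.0 | minimum shift mean (log2 units) |
| `sd_de` | 0.5 | shift SD (log2 units) |
| `sd_n` | 0.4 | additive noise SD (log2 units) |
| `rseed` | 50 | generator seed |

A one-sample argument bounds `sd_de`: the shift statistic
`√m2·μde_min/σde` stays above the 5% critical value 1.96 when
`σde ≤ √m2·μde_min/1.96 ≈ 0.51·√m2·μde_min` (`sd_de_bound`). The CLI
warns — never errors — when the setting exceeds it. Large `σn` similarly
erodes detectability; `run_study` warns when realized power falls below
50%.

## Randomness and reproducibility

A single `numpy.random.Generator` (PCG64) seeded from `rseed` is consumed
in a fixed order: base-level beta draws; per-gene uniform profiles (gene
order, sample order within gene); DE decision uniforms (all genes); DE
direction uniforms (DE genes, gene order); shift-mean exponentials (DE
genes, gene order); shift normals (gene order, sample order); noise matrix
in row-major order. Two consequences are load-bearing and tested:

- identical parameters reproduce the matrix bit for bit;
- the `ratio` flag consumes no draws, so a ratio-mode run equals the
  same-seed intensity run minus its reference column.

Draw-for-draw compatibility with any other implementation's random stream
is *not* promised, only internal reproducibility. A scalar, loop-based
transcription of the six steps lives in the test suite as an independent
oracle and must agree bit for bit with the vectorized path on small
instances.

### Degenerate inputs

With seed data (user-supplied per-gene means replacing steps 1–2;
`shape2`, `lb`, `ub` then have no effect), a non-positive mean can push
`α = λ1·e^(−λ1 z̄)` to 1 or beyond, which would let the uniform interval
cross zero. Such widths are clamped to 0.99 with a warning. `sample_gene_profile`
refuses `α ≥ 1` outright. Genes with zero variance in both groups get
p = 1 in the t-test rather than NaN.

## Evaluation harness

`run_study` simulates `n_replicates` datasets with seeds
`base_seed, base_seed + 1, …` (default base seed = `rseed` = 50), applies
a per-gene two-sided two-sample t-test (controls vs tests) and selects
genes with `p` strictly below the threshold (default 0.006). Selected
genes are split by the *simulated* truth into true-down, true-up and
false; medians over replicates use the midpoint convention (hence
half-integer values), and power is
`(median down + median up)/(pde·n)`. No multiple-testing correction is
applied; the raw threshold's implied expected FDR, `p_threshold/pde`
(30% at defaults), is reported alongside.

**t-test flavor.** The default is the Welch/Satterthwaite form,
`equal_var=False`, matching the convention of R's `t.test` under which
the reference study's counts were produced. This choice is empirically
forced: on default-parameter data the pooled-variance form selects a
median of ~59–60 false DE genes — the nominal `0.006 × 9800` — whereas
Welch's mild conservatism on these uniform-plus-normal genes gives ~49–51,
reproducing the reference median of 49 (true-DE counts barely differ
between the two). The pooled classical form remains available via
`gene_t_test(..., equal_var=True)`; it is exact under a normal null and
is used as the calibration cross-check in the tests.

## What the simulator does and does not emulate

The generator reproduces the first-order features relevant to benchmarking
selection methods: mean-dependent variability, skewed expression levels,
controllable DE fraction/asymmetry/effect sizes, and seed-reproducibility.
It does **not** model probe-level or image-level effects, dye bias,
intensity-dependent normalization curvature, outlier spikes, or
correlation between genes (all genes are independent). Passing tests
therefore demonstrate correctness of the model and harness, not that any
selection method's ranking on this data transfers to data with gene-gene
correlation or heavy-tailed artefacts.

## Problem sizes

The repeated-study checks use the design's native scale — 10,000 genes,
7 + 7 samples, 100 replicates per study — which runs in about a second
per study; the acceptance script's six studies complete in well under a
minute. Monte-Carlo distribution checks (beta/exponential/uniform/normal
moments, DE-fraction calibration) pool at least 10⁶ draws, giving
binomial/normal standard errors far below the asserted tolerances.
Stochastic comparisons against the reference study's medians use a 10%
relative tolerance (2 absolute points near 100% power), the observed
spread between independent 100-replicate studies.

## Design choices on open points

- The DE and direction decisions are continuous-uniform comparisons
  (`U < pde`, `U > sym`): the expected DE count is then exactly `pde·n`,
  consistent with the reference study's expected counts (e.g. 200 at the
  defaults, a (60, 140) down/up split at `sym = 0.3`).
- The shift-excess distribution is `Exponential(rate = λ2)`; the rate
  reading is the only one under which increasing `λ2` shrinks the shifts.
- Noise covers the whole matrix including the reference column; the
  alternative (noise-free reference) is indistinguishable in intensity
  mode and was rejected for ratio mode as a real reference channel is
  itself noisy.
- Volcano fold change is `2^(mean test − mean control)` over *group
  means* (not a single sample pair), with strict thresholds on both the
  p-value (0.01) and the fold change (2 and 0.5): a gene exactly on a
  threshold is not highlighted.
- Plot rendering is out of scope; the package computes coordinates
  (MA, volcano) that any plotting layer can consume.
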