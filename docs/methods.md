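# Methods

## The model

`mitoflow` quantifies how labelled cellular material — in the motivating
experiment, quantum-dot-loaded endosomes in U2-OS (human osteosarcoma)
cells — is partitioned between daughter cells at mitosis, using only two
high-throughput fluorescence measurements of the same population taken a
fixed interval apart.

A dividing cell splits its labelled material between its two daughters in
proportion `x : (1 - x)`. Across the population the splitting ratio is
modelled as an equal-weight mixture of two normal densities with means
`α` and `1 - α` and common standard deviation `Δα`,

    P(x) = [ N(x; α, Δα²) + N(x; 1 − α, Δα²) ] / (2 Z),   x ∈ [0, 1],

truncated to the physical range `[0, 1]` and renormalized (`Z` is the
in-range mass of the untruncated mixture; by the `α ↔ 1 − α` symmetry
both components carry equal in-range mass). `α = 0.5` is symmetric
division. The truncation is symmetric about 1/2, so `E[x] = 1/2` holds
exactly — every division halves the *expected* daughter intensity
regardless of asymmetry.

Because `α` and `1 − α` parameterize the same model, `α` is always
reported in the canonical half `[0.5, 1]`; `PartitionParams.canonical`
folds values below 0.5.

### The transfer operator

Let `N_i(I)` and `N_f(I)` be the intensity histograms at the two
measurements, and `f_t` the fraction of cells that divided exactly once
during the interval `t`. The later histogram is the image of the earlier
one under a transfer operator,

    N_f(I) = ∫ N_i(I') T(I, I', t) dI',
    T(I, I', t) = f_t · (1/I') P(I/I') + (1 − f_t) · δ(I − I').

The `1/I'` factor is the change-of-variables Jacobian that makes the
daughter-intensity density of one parent integrate to 1. Discretized on
histogram bins, each source bin is represented by its arithmetic
midpoint `I'`; the divided component deposits the exact CDF increment of
`P` across each destination bin, and the undivided (Dirac) component
deposits `1 − f_t` on the destination bin containing `I'`. Columns are
renormalized to sum to exactly 1, so each sampled parent cell is
accounted for exactly once and total cell count is conserved — the
cytometer measures a fixed number of cells, so the operator models the
intensity distribution of a randomly sampled post-interval cell (one
daughter per division, not both).

A side effect of column normalization worth recording: the `1/I'`
Jacobian is constant within a column, so kernels built with and without
it are *identical* after normalization. The convention question is
therefore moot at the histogram level and no switch is exposed.

Destination-range truncation: daughters always have `I ≤ I'`, so when
the destination edges cover the source range no divided mass is lost.
If a caller supplies a narrower destination range and more than 5% of
any column's divided mass falls outside it, the kernel builder raises an
error rather than silently renormalizing a distorted column.

### Moment estimator of the dividing fraction

Since each division halves the expected intensity of a sampled
descendant,

    <I_t> = (1 − f_t) <I_0> + f_t <I_0>/2   ⇒   f_t = 2 (1 − <I_t>/<I_0>),

valid when both measurements sample equal cell numbers. The estimate is
clamped to `[0, 1]` and the clamping is reported; a raw value above 1
means the later mean fell below half the initial mean, which the
single-division model cannot produce (degradation, multiple rounds of
division, or unequal sampling).

### Multiple generations

If the interval spans `k` division rounds, the cumulative ratio retained
by a sampled descendant is the product of `k` independent draws from
`P`. `multigeneration_ratio_pdf` computes this product density by FFT
convolution in log-ratio space (`L = −log x` is additive over
generations); the forward model applies the single-generation kernel
once per generation with that generation's dividing fraction. The two
routes agree with each other and with the event-level simulator (KS
< 0.02 at 10^5 cells), which is the package's cross-check that the
iterated-kernel extension is consistent.

## Fitting

`fit_transfer` minimizes the sum of squared differences between the
normalized model output and the normalized observed histogram over
`(α, Δα, f_t)` (or `(α, Δα)` with `f_t` fixed, e.g. at the moment
estimate). The optimizer is SciPy differential evolution — population
based, bound constrained, seeded — with a local polish, restarted from
`n_restarts = 5` independent sub-seeds; the maximum pairwise distance
between restart optima (`restart_spread`) is reported as a convergence
diagnostic. Identical inputs and seed give bit-identical results.

Default bounds are `α ∈ [0.5, 1]`, `Δα ∈ [0.005, 0.5]`,
`f_t ∈ [0, 1]`; default budget 30 population members × ≤ 60 generations
per restart, stopping early at relative population convergence 0.01.
The objective surface is smooth and, with the symmetry folded away,
effectively single-basin: the undivided high-intensity remnant pins
`f_t` while the divided peak shapes `α` and `Δα`.

`1 − Pearson r` is available as an alternative objective
(`neg_correlation`); SSE is the default because correlation is
scale-blind and degenerates on near-uniform tails. An optional per-bin
Poisson weighting (`1 / max(count, 1)`) is available for count
heteroscedasticity; it is off by default.

### Goodness of fit

`goodness_of_fit` reports, over the bins where the observed histogram is
non-empty, the Pearson correlation of normalized bin counts and the
p-value of a paired two-sided t-test on the per-bin differences. The
p-value is a *descriptive index*, not a calibrated inferential test:
two normalized histograms have near-zero mean per-bin difference by
construction, so the statistic registers systematic displacement of
mass off the observed support (high p: none detectable) but is
insensitive to pure shape misfit. Shape misfit is what the SSE
objective and the correlation measure; the test suite verifies that a
halved `Δα` multiplies the SSE several-fold and depresses the
correlation while the well-specified model scores p > 0.5 in the large
majority of runs. No single number decides adequacy.

## The simulator

`simulate_pair` draws parent intensities log-normally, divides each cell
with probability `f_t`, draws the ratio from the truncated mixture
(component choice + inverse-CDF truncated-normal draw — exact, fully
deterministic given the seed), and retains one daughter uniformly at
random, keeping the sample size constant. `keep_both_daughters=True`
retains both (population grows) for sensitivity studies.

Organelle mode makes the material discrete: per-cell organelle counts
are Poisson with a log-normally mixed mean (mean-preserving, so the
population stays broad and unimodal while counts stay integral), each
organelle goes to daughter A independently with probability `x`, and
measured intensity is exactly `count × unit_intensity` — the
fluorescence-vs-organelle-count linearity that the method assumes is
built in, and the empirical ratio distribution converges to the
continuous mixture as the mean organelle count grows. `fixed_bias=True`
replaces the mixture draw with a constant bias `x ≡ α`
(pure-binomial partitioning).

### Default study conditions

Chosen once to emulate the motivating experiment, and used by the test
suite and the acceptance script:

| parameter | default | rationale |
| --- | --- | --- |
| parent distribution | log-normal, ln-mean `log(1000)` AU, ln-sd 0.5 | broad unimodal shape spanning ~1.5 decades, as in measured parent histograms; AU scale is arbitrary |
| interval | 19 h | one division round for U2-OS (intermitotic time ≈ 20 h) |
| operating point | `α = 0.71`, `Δα = 0.11`, `f_t = 0.98` | the reported best-fit values for QD-labelled U2-OS endosome inheritance |
| histogram bins | 256 linear bins from 0 to the sample maximum | typical cytometer resolution; a free configuration parameter |
| organelle mode | 50 organelles/cell, 20 AU each | tens of labelled endosomes per cell at the same intensity scale |

What the simulator does *not* emulate: cell-cycle phase structure and
intermitotic-time distributions (divisions are a per-interval Bernoulli
event), cell death and quiescence, fluorophore bleaching or degradation,
instrument noise, debris/doublets, and any deviation of the parent
distribution from log-normality. Passing the recovery tests therefore
shows the inverse problem is well posed and correctly solved *under the
model's own assumptions*; it does not validate those assumptions against
real cytometry, and the fitting module makes no log-normality
assumption of its own (it uses whatever `N_i` is supplied).

## Numerical choices

- **Binning**: half-open `[lo, hi)` bins, final bin closed; integer
  counts partition in-range events exactly. Fractional counts appear
  only after rebinning or forward-model application.
- **Representative points**: arithmetic midpoint for linear bins,
  geometric midpoint for log bins (unbiased for log-uniform in-bin
  mass, matching the log-amplifier model). Log-to-linear rebinning
  spreads each bin's mass uniformly in intensity; total mass is
  conserved to machine precision.
- **Mixture truncation**: computed with the normal CDF in closed form;
  the density integrates to 1 within 1e-8 over the full parameter box.
- **Product-density grid**: log-ratio step `Δα/100`, extent to where the
  single-division density is negligible (capped at 2^18 points); the
  per-generation grid density is renormalized to unit trapezoidal mass
  before convolution so the k-fold result keeps unit integral within
  1e-6.
- **Degenerate inputs**: empty histograms, all-invalid event files,
  non-covering bin ranges and out-of-range parameters raise typed
  errors; the moment estimator reports clamping instead of silently
  saturating.
- **Determinism**: every stochastic component (simulator, optimizer
  restarts) is driven by `numpy` `SeedSequence` spawning, so runs are
  reproducible bit-for-bit from a single integer seed.

## Problem sizes

The test suite and the acceptance script use 10^4-cell pairs for
parameter recovery (20 seeds, matching the scale of the cytometry data
sets the method targets, > 10^4 cells per measurement) and 10^5-cell
pairs for distribution-level oracle comparisons and the moment
estimator, where Monte-Carlo noise must sit well below the 0.02 KS and
1% mean tolerances.

## Known limitations

- Exactly one division round is modelled unless per-generation fractions
  are supplied explicitly; generation fractions are not themselves
  fitted.
- No uncertainty quantification beyond the restart spread (point
  estimates only, as in the underlying method).
- No photostability correction: a label that degrades measurably during
  the interval biases `f_t` upward in both estimators.
- The moment estimator and the forward model assume equal numbers of
  sampled cells at both measurements; `fit_transfer` warns when totals
  differ by more than 5%.
- FCS (binary cytometry standard) files are not read; inputs are plain
  CSV event lists or histograms.
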