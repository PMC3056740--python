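# mitoflow

Transfer-function analysis of mitotic partitioning from paired
flow-cytometry measurements.

## The problem

When a cell divides, its labelled material — organelles carrying a
stable fluorescent marker such as quantum-dot-loaded endosomes —
is split between the two daughters in some proportion `x : (1 − x)`.
Whether that split is symmetric matters for lineage fate, stem-cell
differentiation and drug-carrier dilution, but time-lapse microscopy
captures too few division events to measure it with statistical weight.

`mitoflow` implements a population-level alternative for cell biologists
with access to a flow or imaging cytometer: measure the per-cell
fluorescence histogram of a labelled population twice, one division
interval apart, and deconvolve the splitting-ratio distribution from how
the histogram transforms. No single-cell tracking, no cell-cycle model —
just two histograms of > 10⁴ cells each.

## The model

The splitting ratio across the population is an equal-weight Gaussian
mixture with means `α` and `1 − α` and spread `Δα`, truncated to [0, 1]:

    P(x) = [ N(x; α, Δα²) + N(x; 1 − α, Δα²) ] / (2Z)

The later histogram `N_f` is the image of the earlier one `N_i` under a
transfer operator mixing divided and undivided cells:

    N_f(I) = ∫ N_i(I′) T(I, I′, t) dI′
    T(I, I′, t) = f_t (1/I′) P(I/I′) + (1 − f_t) δ(I − I′)

where `f_t` is the fraction of cells that divided during the interval.
Fitting `(α, Δα, f_t)` by seeded global optimization recovers the
partition asymmetry; independently, `f_t = 2(1 − ⟨I_t⟩/⟨I_0⟩)` because
each division halves the expected intensity of a sampled daughter. A
Monte-Carlo single-cell simulator generates synthetic data and serves as
the event-level oracle for every operator-level claim.

See `docs/methods.md` for assumptions, numerical choices and limits.

## Worked example

Simulate a 10⁴-cell dye-dilution experiment at the operating point
measured for QD-labelled U2-OS cells (`α = 0.71`, `Δα = 0.11`,
`f_t = 0.98`, 19 h interval), then fit it back blind:

```
$ mitoflow simulate --out-prefix demo --n-cells 10000 --seed 11
INFO mitoflow: wrote demo_t0.csv and demo_t.csv (10000 cells)

$ mitoflow fit --h0 demo_t0.csv --ht demo_t.csv --seed 1 --out demo_fit.json
alpha=0.7062 delta_alpha=0.1124 ft=0.9895 ft_moment=0.9886 objective=7.301e-05 p=0.760 r=0.9977

$ mitoflow estimate-ft --h0 demo_t0.csv --ht demo_t.csv
ft=0.9886
```

Reading the fit line: the recovered mean splitting ratio is 0.706 — the
average division sends ~71% of the labelled material to one daughter and
~29% to the other — with population spread 0.112; 99% of cells divided
during the interval, and the independent moment estimate of the dividing
fraction (0.9886) agrees with the fitted value to 0.001. The objective
is the summed squared difference of the normalized histograms;
`r`/`p` are descriptive agreement indices between the fitted model and
the observed histogram (high is good). All recovered values are within
sampling error of the generating ones.

The same operations are available as library calls (`simulate_pair`,
`apply_transfer`, `fit_transfer`, `estimate_dividing_fraction`), and the
CLI also exposes the forward model (`mitoflow forward`) for predicting a
later histogram from an earlier one at given parameters. Event lists
and histograms are plain CSV; log-amplifier histograms are converted
with `log_to_linear_rebin` before modelling.

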