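# Methods

## Model and assumptions

All four block size laws describe the same conditional experiment: given
that a breakpoint ("cut") has occurred at a reference inter-gene region,
what is the probability that exactly `n - 1` consecutive neighboring
regions carry no cut, followed by one that does? The shared assumptions
are:

- The ancestral chromosome is effectively infinite: the laws carry no
  information about initial chromosome sizes, so they are accurate once
  `t` is large enough that no starting chromosome survives intact. At
  short times simulations show an excess of full-chromosome blocks that
  the theory cannot reproduce; this is an expected, documented deviation
  (exercised in the test suite at t = 0.05 subs/site).
- Cuts occur only between genes and the physical length of inter-gene
  regions is ignored; block sizes are gene counts, never base pairs.
- Cut counts per region are Poisson in the evolutionary distance `t`
  (mean amino-acid substitutions per site summed over both lineages), so
  every law depends on rates only through `rate * t` products. With `t`
  supplied per pair the rates themselves are identified; without it only
  the products would be.
- The two_cut law makes two explicit approximations: overlapping paired
  cut spans are neglected, and at most one initial paired cut per region
  is assumed. Both are quantified by the diagnostics `overlap_error`
  (ε_O = (1 - e^{-γt}) e^{-θ}) and `multicut_error`
  (ε_M = 1 - e^{-γt} - γt e^{-γt}); fits should be trusted only where
  these are small.

## Parameters

| parameter | units | meaning | typical magnitude |
|---|---|---|---|
| κ | cuts / (sub/site) / region | uniform single-cut rate | 0.1–1 |
| γ | cuts / (sub/site) / region | initial paired-cut rate | 0.05–0.5 |
| θ | per region (dimensionless) | geometric decay of the paired-cut span; mean span 1/(1-e^{-θ}) genes | ~0.5 |
| κ_H, κ_C | cuts / (sub/site) / region | hotspot / coldspot single-cut rates, κ_H ≥ κ_C | 0.3–3 / ~0.01 |
| r_HC, r_CH | per region | hot→cold / cold→hot switch probabilities; mean tract lengths 1/r regions | 0.01–0.2 |

Hotspot labelling is a gauge freedom; `HotspotParams` canonicalizes to
κ_H ≥ κ_C by swapping `(κ_H, r_HC)` with `(κ_C, r_CH)`, which leaves the
distribution unchanged.

## Hotspot-model identifiability

The hotspot law is exactly a two-geometric mixture
`P(n) = A λ1^{n-1} + B λ2^{n-1}` whose ratios are the eigenvalues of the
survival matrix `T ⊙ U` and whose second weight is fixed by
normalization. Only three combinations — `(λ1, λ2, A)`, exposed as
`models.hotspot_spectrum` — are identifiable from a block size
distribution; the four parameters drift along a one-dimensional
equal-likelihood ridge (verified numerically: distinct parameter vectors
produce pointwise-identical PMFs to ~1e-12). Consumers of fitted
hotspot parameters should therefore interpret κ_C and the individual
switch probabilities with caution, while λ1, λ2 and the mixture weight
(and functions dominated by them, such as the fitted distribution
itself, the hotspot fraction's order of magnitude, and κ_H·t) are
well-determined. The test suite asserts spectral recovery; a stricter
per-parameter recovery check is included and documents this limit.

## Numerical choices

- Geometric mixture PMFs are evaluated in log space (`log1p`/`expm1`,
  `logsumexp` normalization), so truncated fits never underflow. The
  hotspot law is computed by iterative row-vector propagation through
  the 2×2 survival matrix — one left-to-right pass yields every `n` in a
  window at O(n_max) cost (repeated squaring would not help since whole
  windows are always needed) — with an explicit running log-scale
  rescaling the 2-vector when its mass drops below 1e-260.
- Degenerate parameters that imply zero cut probability raise
  `DegenerateModelError` instead of returning a defective distribution:
  the conditional law is undefined when no cut can occur.
- KL divergence follows the convention `0·log 0 = 0`; if a model puts
  zero mass on an observed size the divergence is `+inf` (returned, not
  raised) so optimizers retreat. Parameter bounds (rates in
  `[1e-8, 100]`, probabilities in `[1e-8, 1]`) keep exact zeros out.
- Optimization is best-of-R bounded SLSQP with numerically estimated
  gradients, objective tolerance 1e-10, 300 iteration cap, ties among
  restarts broken by lowest start index (fully deterministic given the
  seed). Starting points are drawn half uniformly on the linear scale of
  the bounds and half log-uniformly (`start_scale="mixed"`): rates far
  above ~1/t concentrate all mass at the window minimum, where the
  finite-difference gradient vanishes and purely linear-uniform starts
  stall, while log-uniform draws cover the responsive small-rate
  decades. Purely linear or purely log draws remain selectable.
- `fit_all_models` additionally seeds each model with deterministic warm
  starts embedding the already-fitted simpler models (combined from
  one_cut/two_cut, two_cut from one_cut at θ → 0, hotspot from
  κ_H = κ_C and from a rare-switch mapping of the two_cut optimum), so
  the nesting inequality — a model with more parameters never fits worse
  — holds up to optimizer slack by construction rather than by luck.
- Truncation for fitting uses the shared window `[n_min, N_max]` with
  `N_max` the pair's largest observed block. `n_min` defaults to 3 for
  empirical tables, since upstream synteny callers cannot resolve
  shorter blocks; fits to simulator output use `n_min = 1` because the
  generator has no such artifact and short blocks carry most of the
  hotspot/paired-cut signal.

## Simulator

The simulator removes edges from a graph whose nodes are genes and whose
edges are within-chromosome gene adjacencies. Exponential cut clocks are
attached to the *original* edge set; a cut on an already-removed edge
advances time but changes nothing, which preserves the per-edge Poisson
process the analytical laws assume. The event loop samples the
superposition directly (waiting time ~ Exponential(total rate), edge
chosen proportionally to its rate); a literal per-edge-minimum reference
implementation is kept and the two are verified distributionally
identical by a chi-square test on a small genome. Paired cuts draw a
geometric span and remove the partner edge `span` positions to the right
iff it exists on the same original chromosome; partners always fall
rightward. Hotspot simulations label every edge by the two-state chain,
starting each chromosome from the stationary distribution (matching the
equilibrium assumption of the analytical law) and following the
transition probabilities along the chromosome. Events at or beyond
`t_max` are not applied. Replicate generators are spawned from one seed
sequence, so ensembles are exactly reproducible.

### What the generator does and does not emulate

Simulated genomes (default 20 chromosomes × 1000 genes, t = 0.25
subs/site, the validation-protocol scale) reproduce the breakage process
the models assume — nothing more. Real data additionally contain gene
gain/loss, translocations and fusions, synteny-calling artifacts
(motivating `n_min = 3`), annotation error, and phylogenetic
non-independence between pairs. Passing tests therefore demonstrate the
mathematical self-consistency of laws, simulator and fitter, not that
any model is true of real genomes; with real tables the package reports
fits and diagnostics, and model choice rests on the comparative KL
values.

## Derived quantities

Breakpoint rates per million years multiply the expected cuts per region
over the path (`κt`, `2γt`, or `(π_H κ_H + π_C κ_C)t`) by the pair's
syntenic gene count S and divide by the full path time in million years
(twice the one-way time to the common ancestor; a helper doubles
one-way split times, and the CLI records whether doubling was applied).
No rate formula is defined for the combined model. Lengths in genes are
converted at 90 kb per gene, the genome-wide mean gene spacing; the
conversion is exact and only display values are rounded (half up).
Per-pair hotspot quantities (κ_H·t inter-cut distance, tract lengths)
are reported per pair; any cross-pair aggregation is left to the user,
medians being the natural choice given the skewed distributions.

## Problem sizes

Default test and acceptance runs use 50–100 replicate ensembles on the
20 × 1000-gene genome, 10-replicate pooled datasets for the
nesting sweep, and 50 optimizer restarts — the full suite and the
acceptance script each complete in a few minutes on one CPU while
keeping Monte-Carlo noise well below the asserted tolerances.

## Known limitations

- No circular chromosomes, no gene-content evolution, no exact
  treatment of overlapping paired-cut spans (ε_O quantifies the error);
  the span-dependent cut probability is documented but unused, matching
  the span-independent approximation of the closed-form law.
- No confidence intervals or profile likelihoods; point estimates only.
- No phylogenetic correction: pairs sharing branches are not
  independent, and per-branch extensions are out of scope.
- The hotspot parameter ridge above: four reported parameters, three
  identifiable combinations.
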