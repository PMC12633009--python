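# syndecay

Models of synteny decay: analytical block size distributions, stochastic
genome-breakage simulation, and Kullback–Leibler model fitting.

## The problem

When two genomes are compared, runs of genes in conserved order
(*synteny blocks*) are the remnants of their common ancestor's gene
order. Chromosomal rearrangements introduce breakpoints between adjacent
ancestral genes, fragmenting synteny; the size distribution of the
surviving blocks therefore encodes how breakpoints arise. `syndecay` is
for comparative genomicists who have per-pair block size tables (from an
upstream microsynteny caller) and want to ask *which breakage process
explains them*: uniform random breakage, inversion-like correlated
breakpoint pairs, or breakpoint hotspots.

## The models

Let `t` be the evolutionary distance between the two genomes (mean
amino-acid substitutions per site, summed over both lineages), and let a
"cut" be a breakpoint at an inter-gene region. Conditioning on a cut,
the probability of a block of exactly `n` genes is:

- **one_cut** (random breakage): cuts arrive as a Poisson process at
  uniform rate κ, so

      P1(n) = e^{-κt(n-1)} (1 - e^{-κt})

- **two_cut** (correlated breakage): cuts come in pairs — an initial
  cut at rate γ plus a partner a geometric span away (decay θ, mean span
  1/(1-e^{-θ}) genes), mimicking inversions:

      P2(n) = ½ e^{-(γt+θ)(n-1)}(1 - e^{-(γt+θ)}) + ½ e^{-γt(n-1)}(1 - e^{-γt})

- **combined**: both cut types; the mixture weights γ/(κ+2γ) and
  (κ+γ)/(κ+2γ) follow from the relative abundance of initial paired
  cuts versus everything else.

- **hotspot** (fragile breakage): single cuts at rate κ_H in hotspots
  and κ_C in coldspots, the two region types laid out along the
  chromosome by a two-state Markov chain with switch probabilities r_HC
  and r_CH:

      P_hs(n) = σ (T ⊙ U)^{n-1} (T ⊙ C) 1

  where T is the chain's transition matrix, U and C hold per-state
  no-cut / at-least-one-cut probabilities, and σ is the posterior state
  of the conditioning cut.

The models are nested (1, 2, 3, 4 parameters), so a richer model always
fits at least as well. Fitting minimizes the Kullback–Leibler divergence
between the empirical distribution and the model PMF, both truncated and
renormalized on `[n_min, N_max]` (`n_min = 3` by default for real data,
`N_max` = largest observed block), by bounded multi-start SLSQP.

A forward simulator (`syndecay.simulate`) evolves a genome of
gene-adjacency edges under each model and doubles as the synthetic-data
generator for the test suite.

## Worked example

Simulate correlated breakage on a 20-chromosome × 1000-gene genome to
t = 0.25 subs/site, pool 100 replicates, and fit all four models:

```python
import syndecay as sd

params = sd.TwoCutParams(gamma=0.1, theta=0.5)
config = sd.SimConfig("two_cut", params, t_max=0.25, seed=7, replicates=100)
ens = sd.run_ensemble(config, [1000] * 20)
emp = sd.empirical_pmf(ens.pooled_counts(), t=0.25, n_min=1)
fits = sd.fit_all_models(emp, sd.FitConfig(restarts=50, seed=0))
for f in fits:
    print(f"{f.model_id:>8}  KL = {f.kl:.5f}  params = "
          + ", ".join(f"{k}={v:.4g}" for k, v in f.params_dict().items()))

best = next(f for f in fits if f.model_id == "two_cut")
span = sd.mean_geometric_size(best.params.theta)
print(f"mean 2-cut span: {span:.2f} genes ({sd.genes_to_kb(span):.0f} kb)")
```

prints

```
 one_cut  KL = 0.42809  params = kappa=0.2033
 two_cut  KL = 0.00215  params = gamma=0.1051, theta=0.527
combined  KL = 0.00215  params = kappa=1e-08, gamma=0.1051, theta=0.527
 hotspot  KL = 0.00195  params = kappa_h=1.413, kappa_c=0.02207, r_hc=0.1621, r_ch=0.0288
mean 2-cut span: 2.44 genes (220 kb)
```

The random-breakage model misses the excess of short blocks created by
paired cuts (KL two orders of magnitude worse); the two_cut fit recovers
the generating parameters (γ = 0.105 vs 0.1, θ = 0.527 vs 0.5) and the
fitted mean span of 2.44 genes ≈ 220 kb is the inferred typical
inversion-like event size. The combined model collapses onto two_cut
(κ → 0), and the four-parameter hotspot model edges it out slightly, as
expected for nested families.

The same pipeline is available from the shell:

```sh
syndecay fixtures --protocol fig2 --seed 42 --out-dir fx/
syndecay fit --input fx/fig2_pairs.tsv --n-min 1 --restarts 50 \
         --seed 0 --out-jsonl fits.jsonl
syndecay compare --fits fits.jsonl
syndecay diagnostics --fits fits.jsonl
syndecay rates --fits fits.jsonl --times times.tsv --out rates.tsv
```

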