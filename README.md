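# methmf

Modelling large-scale DNA methylation patterns with a nearest-neighbour
collaborative reaction system and cluster mean-field theory.

## The problem

Each CpG dyad on a DNA molecule is unmethylated (*u*), hemimethylated (*h*)
or fully methylated (*m*). Methylation patterns are maintained by enzymes
whose recruitment can be *collaborative*: a mediator CpG encourages a
methylation or demethylation reaction at a neighbouring target CpG.
Stochastic simulation of such lattices is exact but scales poorly — a few
hundred CpGs is already expensive — while genome-scale features of
methylomes (megabase-sized hypomethylated blocks in cancer and ageing, for
example) involve thousands to millions of CpGs. Mean-field (MF)
approximations close this gap: they trade the full configuration space for
self-consistent low-dimensional equations whose cost is independent of
system size.

`methmf` implements, for a circular lattice of `N` CpGs:

* the twelve-reaction nearest-neighbour collaborative model with rates
  `k3 = k4 = a`, `k1 = k2 = a·y`, `k9 = … = k12 = a·x`,
  `k5 = … = k8 = a·x·y`, where `x ≥ 0` is the collaborativity strength and
  `y ≥ 0` the methylation strength (`y > 1` favours methylation);
* an exact Gillespie simulator with steady-state detection and snapshot
  sampling (`simulator`), plus hairpin-bisulfite-style read emulation
  (30 reads per CpG drawn at independent random timepoints);
* the exact stationary distribution of the chemical master equation for
  `N ≤ 8`, used as ground truth in tests (`oracle`);
* three mean-field models (`meanfield`): a one-site model, a
  distinct-pairs cluster model (DPMF) and an overlapping-pairs cluster
  model (OPMF), each solved as a self-consistent fixed point; the OPMF
  model is the accurate one and the workhorse for inference;
* the steady-state pattern statistics `μ_u, μ_h, μ_m, μ_z, σ²(z),
  Covar(z), ρ(z)` under the `z = 1/2/3` encoding (`sumstats`);
* ABC-SMC inference of `(x, y)` from read data using OPMF moments as the
  deterministic forward model (`inference`), with uniform priors
  `U(0, 100)` and `U(0, 2)` and the distance
  `d = |μ_model − μ_data|/μ_data + |σ²_model − σ²_data|/σ²_data`;
* a CLI (`methmf simulate | summarize | reads | meanfield | sensitivity |
  infer | scan`) over plain TSV/CSV/JSON artifacts.

## Worked example

Steady-state OPMF predictions at strong collaborativity (`x = 5`):

```sh
methmf meanfield --model opmf --x 5 --y 0.7 --y 1.0 --y 1.3 --out mf.tsv
```

produces (columns abridged):

| x | y | mu_u | mu_h | mu_m | var_z | rho_z |
|---|---|------|------|------|-------|-------|
| 5 | 0.7 | 0.8005 | 0.1309 | 0.0686 | 0.3335 | 0.4697 |
| 5 | 1.0 | 0.3949 | 0.2102 | 0.3949 | 0.7898 | 0.5969 |
| 5 | 1.3 | 0.1096 | 0.1555 | 0.7349 | 0.4536 | 0.5169 |

Reading the `y = 1.0` row: when methylation and demethylation are equally
strong the lattice splits into balanced *u* and *m* clusters
(`mu_u = mu_m = 0.39`), hemimethylation is an interface state (`mu_h`
drops as `x` grows), and the neighbour correlation `rho_z` peaks — the
transition at `y = 1` is where adjacent CpGs are most alike. A replicated
stochastic simulation of the same system (`methmf scan`) reproduces these
numbers to a few parts in a thousand at `N = 200`.

Inference round trip — simulate at `(x, y) = (1, 1)`, emulate 30× hairpin
reads for 1000 CpGs, then infer the parameters back from the read moments:

```python
from methmf import recover_parameters

res = recover_parameters(1.0, 1.0, seed=11)
print(res.summary["x"]["mean"], res.summary["y"]["mean"])
```

prints `x ≈ 1.00, y ≈ 1.00` (e.g. `0.997`, `0.996` at seed 11), with a 95%
interval of about ±0.06 on `x` and ±0.005 on `y` — the methylation
strength `y` is consistently the better-recovered parameter, matching the
model's lower relative sensitivity to `x`.

## Layout

```
src/methmf/
  reaction_model.py   rates and per-site propensities
  _kernels.py         numba Gillespie kernels
  simulator.py        runs, burn-in detection, read emulation
  sumstats.py         pattern statistics and replicate aggregation
  oracle.py           exact stationary law for small N
  meanfield.py        one-site / DPMF / OPMF solvers and sensitivities
  inference.py        ABC-SMC and posterior summaries
  io.py, cli.py       serialization and command-line surface
docs/methods.md       modelling and numerical choices in detail
```
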