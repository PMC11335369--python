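# wfdms

Inference of mutation effects and pairwise epistasis from deep
mutational scanning (DMS) time series, using population genetics.

DMS / MAVE experiments pass a large library of protein variants
through rounds of selection and read out variant frequencies by
sequencing. The classic analysis — log enrichment ratios between
post- and pre-selection counts — is noisy when counts are low, and
inferred effects often correlate modestly between experimental
replicates. `wfdms` instead treats each selection round as one
generation of a Wright–Fisher population and estimates a selection
coefficient s_i for every mutation by maximizing the path likelihood
of the observed frequency trajectory under a Gaussian prior.

## The estimator

Under the diffusion approximation of the Wright–Fisher model, the
log-likelihood of an observed trajectory z(t_0), …, z(t_K) is
quadratic in the selection coefficients, with sufficient statistics

- **A** = ∫ C(t) dt, the time-integrated allele-frequency covariance
  (within a site: C_aa = z_a(1 − z_a), C_ab = −z_a z_b), and
- **b** = z(t_K) − z(t_0), the net frequency change.

With a zero-mean Gaussian prior of precision γ (an L2 / ridge
penalty), the maximum-a-posteriori estimate across replicates r is the
solution of the symmetric positive-definite system

    ŝ = (Σ_r A_r + γI)⁻¹ Σ_r b_r .

Summing sufficient statistics pools evidence across replicates —
replicates are weighted by the information they carry, not averaged.
The same closed form, applied to an extended feature vector containing
single substitutions and co-occurring substitution pairs, yields
pairwise epistatic coefficients; the sum of squared pair coefficients
per site pair gives an interaction map.

Supported inputs: dms_tools-format codon count tables and
MaveDB-format variant counts (HGVS protein strings). A forward
simulator (multinomial Wright–Fisher rounds, additive fitness,
negative-binomial read sampling) provides ground truth for validation.

## Worked example

```python
import numpy as np
from wfdms import (SimulationConfig, simulate_wf, sample_reads,
                   counts_to_frequencies, SelectionModel,
                   replicate_correlation)

# 10 sites x 5 alleles, N=10^4, 5 rounds, depth 10^5, NB dispersion 10
dataset = sample_reads(simulate_wf(SimulationConfig(seed=1)))
trajs = [counts_to_frequencies(dataset.to_aa_count_tables(r))
         for r in dataset.replicate_ids]
model = SelectionModel(trajs)
result = model.fit()                      # joint across 3 replicates
print(result.summary())
wtzero = result.gauge_to_reference()      # report relative to wild type
r = replicate_correlation(dataset.true_s, wtzero.params, "pearson",
                          wildtype=dataset.wildtype)
print(f"Pearson R vs truth: {r:.4f}")
```

Output:

```
Wright-Fisher MAP selection-coefficient estimates
=================================================
coefficients:      50
sites:             10
replicate scope:   joint (n=3)
gauge:             raw
ridge penalty γ:   0.459068 (adaptive)
mean |s|:          0.0335119
max s:             0.113309  min s: -0.0735561
Pearson R vs truth: 0.8739
```

The joint fit recovers the rank and sign structure of the true
coefficients (here R ≈ 0.87 against ground truth under heavy
negative-binomial read noise); the adaptive ridge penalty shrinks
effects with little support in the data toward zero.

A command-line front end is installed as `wfdms` with subcommands
`simulate`, `infer`, `epistasis`, `compare` and `convert`; see
`wfdms --help`.

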