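# Methods

## Model

A deep mutational scanning experiment is modelled as a Wright–Fisher
population of variant sequences passing through discrete selection
rounds. Each mutation i carries a selection coefficient s_i, the
per-round relative advantage (s_i > 0) or disadvantage (s_i < 0) of
that mutation for surviving selection; the fitness of a sequence is
additive in its mutations, w(g) = 1 + Σ_i s_i(g), optionally extended
by pairwise terms s_ij for epistasis. Under the diffusion (Gaussian)
approximation of the Wright–Fisher path likelihood, the log-likelihood
of an observed frequency trajectory is quadratic in s with sufficient
statistics A (the time-integrated allele-frequency covariance) and
b = z(t_K) − z(t_0) (the net frequency change: intermediate
increments telescope out of the drift term). With a zero-mean Gaussian
prior of precision γ, the MAP estimate solves

    (Σ_r A_r + γ I) ŝ = Σ_r b_r

over replicates r. The solve uses a Cholesky factorization and fails
loudly on a singular system rather than regularizing silently; at
γ = 0 an explicit eigenvalue check rejects exactly singular systems
that round-off would let slip through the factorization.

Assumptions worth keeping in mind:

- **No de novo mutation.** Library diversity is fixed at the first
  timepoint, so the mutational-flux term of the full path likelihood
  is dropped.
- **Site factorization (default).** Codon-count tables carry no
  co-occurrence information, so cross-site covariance is set to zero
  (block-diagonal A). When variant-level (MaveDB-style) tables are
  available, the haplotype route estimates cross-site covariance from
  variant co-occurrence; restricted to single features it is the same
  linear system the epistasis module solves.
- **Gauge freedom.** At each site, shifting all allele coefficients by
  a constant leaves the likelihood unchanged up to the prior. Raw
  estimates come out (approximately) sum-zero per site because both A
  and b annihilate the uniform vector; `gauge_to_reference` re-reports
  them with the wild-type allele at zero. Correlations computed over
  non-WT alleles after a common gauge are unaffected by the shift, but
  cross-method comparisons must use matching gauges.

## Parameters

- **γ (ridge penalty, prior precision).** Default mode is
  data-adaptive: γ* = mean diagonal of Σ_r A_r, which scales the prior
  with the typical information content per coefficient and falls back
  to 1 (with a warning) on all-zero statistics. This heuristic is
  deliberately simple and is exposed for override; a fixed γ can be
  supplied instead. Note that strong shrinkage (γ comparable to the
  diagonal of A) leaves ŝ approximately proportional to the raw
  frequency change, which is convex rather than linear in the true s
  over ±0.3 — for truth-recovery studies a smaller fixed γ gives a
  slightly more linear readout (noise, not shrinkage, dominates the
  recovery error under the default study conditions; see below).
- **Pseudocount α (default 0.5 per allele).** Haldane–Anscombe
  half-count smoothing of frequencies, (count + α)/(depth + α·n);
  α = 0 gives raw frequencies.
- **time_unit (default 1).** Generations per unit of sample time;
  samples are labelled by selection round by default.
- **Integration rule.** The covariance integral uses the trapezoid
  rule over sampled timepoints; a left-endpoint rule is available
  behind a flag.
- **Stop codons** are included by default (they carry strong
  deleterious signal); a flag drops them from counts and depth.

## Error correction

When a wild-type-only control sample is available, each non-WT
allele's frequency is corrected by subtracting the control's frequency
of the same allele at the same site (clipped at zero), and the WT
frequency absorbs the remainder. This subtractive rule assumes most
miscalls flow out of the abundant wild type, so it is accurate in the
rare-mutant regime; when mutant frequencies are large, miscalls out of
the mutants themselves (not modelled) are of comparable size and the
correction can overshoot. The correction is isolated behind one
function so a rate-based estimator can be swapped in.

## Epistasis

Features are indicator functions on variants: single features mark a
substitution, pair features mark two substitutions at different sites
that co-occur in at least one library variant (unobserved pairs are
reported as absent, not zero — "no evidence" is distinguished from
"inferred ≈ 0"). Covariances follow from carriage frequencies,
C_fg = z_fg − z_f z_g, and the same ridge MAP solve applies; γ > 0 is
required because the extended system is rank-deficient in practice.
Site-pair interaction scores are sums of squared pair coefficients,
optionally min-max normalized to [0, 1]. Within-site pairs are
excluded (two alleles at one site are mutually exclusive). Epistasis
is defined in the raw gauge.

## Synthetic data

The simulator emulates: a variant library (wild type at 20%, the
remainder uniform over single mutants, optionally a double-mutant
fraction), multinomial Wright–Fisher selection rounds of size N with
additive linear fitness (floored at zero; exponential fitness
available), and per-variant independent negative-binomial read
sampling with variance mean + mean²/r (r = ∞ gives Poisson). Default
study conditions: 10 sites × 5 alleles, true s ~ Normal(0, 0.1²),
N = 10⁴, 5 rounds, depth 10⁵ reads per sample, dispersion r = 10,
3 replicates. A uniform per-read miscall option generates corrupted
counts plus a WT-only control for testing error correction.

What the simulator does **not** emulate: PCR jackpotting, barcode
collapsing, machine-specific substitution-error profiles, correlated
(library-prep) sampling noise, fitness non-additivity beyond pairwise
terms, and variable per-site coverage. Passing the synthetic studies
therefore demonstrates correctness of the estimator under its own
model class, not performance on any particular real dataset.

## What the validation studies show

All numbers below are recomputed by `scripts/acceptance.py` and the
test suite; none are copied in from elsewhere.

- **Optimizer oracle.** On random small instances the closed-form
  solve agrees with direct numerical maximization of the regularized
  quadratic objective to ~1e-8 per coordinate.
- **Truth recovery.** Under the default study conditions the joint
  fit reaches a mean Pearson R ≈ 0.82–0.87 against the true
  coefficients. The per-variant negative-binomial noise at r = 10
  (coefficient of variation ≈ 0.32 per count) propagates directly into
  the endpoint difference b and bounds attainable R below ~0.9 at
  these settings regardless of γ: in the noise-free limit with small
  γ the estimator is essentially exact (R > 0.998, slope ≈ 0.98).
- **Replicate consistency.** Under these uniform-library conditions
  (all mutants seeded at equal frequency and depth) the WF estimator
  and the enrichment-ratio baseline are nearly equivalent in
  inter-replicate correlation; the WF gain is small and can sit within
  seed-to-seed variation. The regularization advantage grows when
  variant information content is heterogeneous, which a uniform
  library deliberately lacks.
- **Epistasis sparsity.** With zero true epistasis, shrinkage keeps
  essentially all pair coefficients below the upper tail of the naive
  log-ratio epistasis estimate computed on the same data.

## Numerical choices and degenerate inputs

- Alleles absent at every timepoint contribute exactly zero rows to A
  and b and are returned with ŝ shrunk to 0 by the prior.
- Frequencies must sum to one within 1e-12 per site and timepoint;
  times must be strictly increasing; mismatched site or allele sets
  across a replicate's timepoints raise alignment errors naming the
  site.
- The amino-acid alphabet order "ACDEFGHIKLMNPQRSTVWY*" fixes matrix
  indexing and output row order; output tables round-trip at full
  float precision (the CLI prints six significant digits).
- Simulated amino-acid variants are written to codon tables on the
  first lexicographic codon encoding the residue.

## Limitations

- No posterior uncertainty intervals on ŝ.
- The data-adaptive γ rule is a pragmatic default, not an estimate of
  the true prior width.
- Sequencing-error correction supports a control-sample subtractive
  form only.
- Higher-order (three-way and beyond) interactions are out of scope.
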