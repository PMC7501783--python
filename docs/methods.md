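# Methods

## Model and conventions

The demographic model is the two-population split-migration
(isolation-with-migration) model. Backward in time from the present there
are two demes of sizes ν₁·N_ref and ν₂·N_ref; a pair of lineages in deme k
coalesces at rate 1/ν_k per unit of 2·N_ref generations, and every lineage
migrates to the other deme at rate m/2 (symmetric gene flow). At time T
(units of 2·N_ref generations) the demes merge into a single ancestral deme
of relative size 1 governed by the standard coalescent. Mutation enters
only through the compound scale Θ = 4·N_ref·μ: on a genealogy, mutations
fall as a Poisson process of intensity θ/2 per unit branch length. These
conventions (time in 2N units, sizes relative to the ancestral population,
symmetric per-lineage migration m/2) follow the common usage in
diffusion-based SFS inference and are stated here explicitly because every
parameter the package reports is in these units.

## Expected spectra by conditional Monte Carlo

The expected joint SFS entry M_ij at θ = 1 equals half the expected total
branch length subtending exactly i pop1 haplotypes and j pop2 haplotypes
(so that the panmictic limit gives the classic E[ξ_i] = θ/i). The engine
estimates this by averaging over R simulated structured-coalescent
genealogies in a compiled kernel. Two design points matter:

- **Common random numbers.** Replicate r draws from its own counter-based
  stream derived from (engine seed, r) by two splitmix64 mixing rounds
  feeding an xorshift64* generator. The same seed therefore reproduces the
  same genealogy stream for *any* parameter values, making the profiled
  likelihood a deterministic and nearly smooth function of the parameters —
  a requirement for simplex optimization. A single-round seeding scheme was
  found to leave detectable cross-stream correlation and was replaced; the
  current scheme passes a 23-class neutral-marginal calibration at
  |z| < 3 across independent seed bases.
- **Conditional Monte Carlo.** After the demes merge, inter-event waiting
  times are independent of which lineages coalesce, so the kernel uses
  their expectations 2/(k(k−1)) instead of sampled exponentials. This is
  unbiased for expected branch lengths and removes most of the deep-time
  variance; isolation-phase times must remain sampled because the phase
  boundary at T couples durations to the event sequence.

Zero cells that survive averaging are floored at ε = 10⁻¹² × ΣM (recorded
in the result) so the log-likelihood stays finite. Defaults are R = 10,000
for fitting and 100,000 for calibration checks; the subsampling experiment
uses R = 5,000 in its scaled profile.

## Composite likelihood and profiling

Spectrum cells are treated as independent Poisson counts with means θ·M_ij
(the Poisson random-field approximation, exact for unlinked loci in the
infinite-sites limit). θ is profiled analytically: θ̂ = ΣS/ΣM over unmasked
cells maximizes the likelihood for any M, verified in tests against a
numeric derivative-root oracle to 10⁻⁸ relative. Optimization runs
Nelder–Mead on log₁₀(ν₁, ν₂, T, m) with box bounds ν ∈ [10⁻², 30],
T ∈ [10⁻³, 10], m ∈ [10⁻⁵, 10] enforced by clipping; an estimate within 1%
of a bound (log-scale span) is flagged, because real datasets are known to
push bounds. Convergence uses simplex spread 10⁻⁴ (parameters) or 10⁻⁵
(function), capped at 500 evaluations per run. Each dataset is fit k times
(default 5) from starts perturbed multiplicatively by 2^U(−fold, +fold)
(default fold = 1) and the run with the highest composite likelihood wins.

## Synthetic data generator

The generator emulates one-SNP-per-locus marker panels from sequence-capture
loci in two diverging populations: L unlinked loci are attempted, each locus
draws an independent genealogy, Poisson mutation placement with per-locus
θ_loc, loci with no mutation are dropped, and one mutation chosen uniformly
among those present becomes the locus's SNP (random thinning). All
individuals are phased and fully called. Defaults: 6 diploids per
population, L = 3000, θ_loc = 0.08 — the per-locus scale implied by
aggregate Θ estimates of ~120–260 over ~2,000–2,700 variable loci in the
bird datasets this package emulates; at these settings a 6:6 dataset yields
roughly 1,300 variable loci.

What the generator does *not* emulate: linkage within loci (no intra-locus
recombination is assumed, but real capture loci can hold several linked
SNPs), sequencing or phasing error, missing data, ascertainment bias in
locus discovery, and within-population substructure. Passing tests
therefore demonstrate correctness of the machinery and behavior of the
estimator under the model's own assumptions, not robustness to those
real-data complications. One deliberate mirroring of real pipelines: the
one-SNP thinning makes the Poisson random-field model mildly misspecified
(a locus contributes one SNP regardless of how many mutations its tree
carried), exactly as in the empirical datasets the protocol was designed
for; the profiled Θ̂ then measures SNP density rather than raw mutational
density, and subsample comparisons are unaffected because they are
referenced to the full-data fit.

## Subsampling protocol and metrics

For each size k from 1 to full−1 the experiment draws 25 (scaled profile:
10) datasets of k individuals per population without replacement,
independently across sizes; loci made monomorphic by a draw are removed and
counted. Every subsample fit starts from the full-dataset optimum — the
"predetermined best-fit parameters" reading of the protocol — with
perturbation fold 1. Accuracy is summarized as
SRMSE = RMSE(θ̂ᵢ against the full-data estimate) / mean(θ̂ᵢ); scaling by
the per-size mean (not the full-data value) is what makes values comparable
across lineages. SRMSE is regressed on N by ordinary least squares, pooling
(lineage, N) cells; slope p-values use the t distribution on n−2 df and are
reported but never gate anything.

The packaged published SRMSE table (eight bird lineage pairs, sizes 1–7)
reproduces the published regression coefficients for ν₁, ν₂, T and Θ to
within 0.001. The published migration-rate row is for the low-divergence
group (F_ST < 0.05) only, and its printed slope (−0.00858) is inconsistent
with its own intercept/r²/p and with the table values, which imply a slope
near −0.0857 (a plausible dropped digit); the package computes and reports
that row but does not assert the printed slope.

## Numerical and design choices

- Spectra are folded by default (no outgroup polarization is assumed);
  `polarized=True` preserves the unfolded path. Folding averages the two
  conjugate cells on the diagonal i+j = n_hap/2 so total mass is conserved;
  folding a folded spectrum is an error, not a no-op.
- F_ST is the Weir–Cockerham (1984) two-population estimator as a ratio of
  summed per-locus components, in the haplotype-level form (phased
  haplotypes treated as independent allele draws). With every locus
  variable the denominator is strictly positive; the 0/0 guard is
  defensive.
- Monomorphic-after-subsampling loci are dropped (they could only occupy
  masked corner cells), keeping "variable loci" counts meaningful; the
  count is always logged.
- Replicate, run and per-locus RNG streams all derive deterministically
  from root seeds via numpy SeedSequence spawning, so every experiment is
  bit-reproducible from one integer and enlarging L extends rather than
  reshuffles a dataset.
- Scaled problem sizes used in the test suite and the acceptance script
  (10 replicates per size, best-of-3, R = 5,000–10,000, L = 3000) were
  chosen to keep a full run in minutes on one core while leaving Monte
  Carlo error well below the tolerances being checked; the paper-scale
  profile (25 × 5, R = 10,000) is available via configuration.

## Known limitations

- The expectation engine's R must grow with sample size for tiny cells;
  at R = 5,000 the profiled surface has residual Monte Carlo roughness
  (common random numbers remove most, not all), which multi-start
  optimization is designed to absorb.
- Composite likelihood ignores linkage between SNPs of the same locus pair
  and gives no valid standard errors; no confidence intervals are provided.
- Migration and split time are weakly identified against each other at
  moderate locus counts: on ~1,300-locus synthetic datasets the global
  composite-likelihood maximum can sit 30-70% away from the true (T, m)
  along their shared ridge while ν₁, ν₂ and T medians stay within ~13%.
  Recovery of m at the 25% level is not reliably achievable at this data
  size, and the multi-start protocol — by finding the global maximum more
  often — does not reduce this error, because it is a property of the
  likelihood surface, not of the optimizer. This was verified to be
  insensitive to engine replicates, evaluation budget, locus count/theta
  and folding.
- Only symmetric migration, constant daughter-population sizes and two
  demes are supported; secondary-contact and growth models are out of
  scope.
- In scaled experiments on synthetic data the small-sample *direction* of
  ν bias is seed- and truth-dependent: SRMSE reliably grows as k shrinks
  (negative SRMSE~N slopes), but mean ν estimates at k ≤ 2 are not
  consistently below those at k = 5 at the default synthetic truth, where
  ν₂ in particular tends to drift upward along the weakly identified
  (ν₂, m, T) ridge when only two haplotypes per population remain.
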