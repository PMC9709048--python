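# Methods

## Model

Let X[j, h] be haplotype counts sampled at rookery j (J rookeries, H
haplotypes) and Y[i, h] counts at mixed stock i (M mixed stocks). The
many-to-many model is parameterized rookery-centrically:

- f[j] ∈ Δ^H — haplotype frequencies of rookery j, prior Dirichlet(α_f);
- δ[j] ∈ Δ^{M+1} — the probability that an individual from rookery j ends
  up at each sampled mixed stock or at an unsampled sink (UNK), prior
  Dirichlet(α_δ).

Rookery sizes S[j] (annual nest counts) and the scaled inverse-distance
matrix P[i, j] = (1/D[i,j]) / Σ_j' (1/D[i,j']) are fixed covariates, not
parameters. Mixed-stock-centric contributions are derived inside the
likelihood:

    theta[i, j] ∝ S[j] · δ[j, i] · P[i, j]        (normalized over j)

with expected mixed-stock frequencies q[i, h] = Σ_j θ[i, j] f[j, h], and

    X[j, ·] ~ Multinomial(n_j, f[j]),   Y[i, ·] ~ Multinomial(n_i, q[i]).

θ is invariant to rescaling S, so only relative rookery sizes matter. The
**base** mode drops P (θ ∝ S·δ), recovering the classic many-to-many
structure; a row-uniform P is algebraically identical to base mode, which
gives the ground-truthing property the tests exercise. The placement of P
*multiplicatively inside the θ normalization* is a modelling choice — it is
the reading under which the covariate reshapes both point estimates and
credible intervals rather than acting as a cosmetic reweighting; the
alternative **distance_prior** mode instead drops δ and puts
Dirichlet(κ·P[i]) priors directly on each θ[i] (κ defaults to J, a
unit-information-style total mass of J per stock). That mode exists for
comparison experiments, not as the primary model. UNK receives no size or
distance weight: it stands for everywhere not sampled, for which no single
distance is defined.

### Assumptions

- Haplotype frequencies are in migration–drift balance over the sampling
  window; every mixed-stock individual originates from one of the listed
  rookeries or UNK.
- Samples are independent multinomial draws (no family structure).
- Effective distances are measured upstream and treated as known; the two
  route scenarios are just alternative input files.
- Mixed-stock haplotypes never observed in any rookery are unrepresentable
  under the model and are filtered out (with a report) before fitting.

## Sampler

Each mixed-stock individual is augmented with its latent source rookery.
Given assignments, the f-update is conjugate (Dirichlet); the assignment
counts N[i, j] reduce the δ-update to a Metropolis step per rookery on
additive-log-ratio coordinates (free coordinates bounded at ±30, a region
outside which the posterior carries negligible mass; the bound keeps
softmax/log exact in double precision). Step sizes adapt toward 35%
acceptance during burn-in only, so post-burn-in transitions are a fixed
Markov kernel. All chains advance together through vectorized numpy ops;
chain c is initialized from the priors with seed `seed + c`, and the joint
update stream is seeded from `seed` separately, making runs bit-reproducible.
The distance_prior mode is fully conjugate (pure Gibbs).

Defaults: 3 chains, 20,000 iterations, 10,000 burn-in, symmetric
Dirichlet(1) priors on f and δ, thinning 1.

## Diagnostics and summaries

- **PSRF**: classic univariate Gelman–Rubin, Vhat = (n−1)/n·W + B/n,
  without the degrees-of-freedom correction; the variance ratio is floored
  at 1 (sub-1 values are estimation noise, and identical chains then report
  exactly 1). A fit is "converged" when the maximum PSRF over monitored
  contribution parameters (θ and δ) is ≤ 1.08; the CLI exits 3 otherwise
  unless `--allow-nonconverged`.
- **Credible intervals**: equal-tailed, median-unbiased quantile rule
  (Hyndman–Fan type 8), 95% by default in reports.
- **MCSE / ESS**: arviz effective sample sizes; MCSE = sd/√ESS.

## Model comparison

Pooled post-burn-in draws of two fits are differenced by draw index (chains
are independent, so index pairing is equivalent to random pairing),
truncated to the shorter draw count. The Test of Practical Equivalence
forms the 89% HDI of each difference (shortest contiguous window of sorted
draws; ties to the smallest left endpoint) and reports the proportion of
the interval's *length* inside the ROPE −0.05..0.05 — the geometric
estimator; a draw-counting estimator is available behind a flag. Decisions:
proportion 1 → accepted, 0 → rejected, otherwise undecided. 89% (rather
than 95%) is the conventional level for posteriors with fewer than ~10,000
draws. A zero-width interval counts as 1 inside the ROPE, 0 outside.

## Diversity summaries

Haplotype diversity uses Nei's unbiased estimator h = n/(n−1)(1 − Σp²) with
the Nei (1987, eq. 8.12) variance for its SD. Nucleotide diversity is
π = n/(n−1)·Σ p_a p_b d_ab / L and requires the pairwise-difference matrix
and fragment length as explicit inputs, since sequences are upstream of
this package.

## Simulator

The generator draws f[j] ~ Dirichlet(0.5) per haplotype (sparse, mimicking
the skewed haplotype spectra of mtDNA control-region data), δ[j] ~
Dirichlet(1) over M+1 destinations, sizes log-normal around ~5,000 nests
(spanning orders of magnitude, as real rookery tables do), distances
uniform on 500–8,000 km, then samples multinomial counts at the
model-implied frequencies. Defaults are 4 rookeries, 2 mixed stocks, 6
haplotypes and 100 samples per site — the package's standard synthetic
example. Because a haplotype can by chance be sampled at a mixed stock but
in no rookery, simulated datasets are assembled through the same orphan
filter as real data; removals are recorded in the ground-truth record.

What the simulator does *not* emulate: haplotype sharing structured by
geography, temporal drift within a sampling period, sequencing error, or
overdispersion from family groups arriving together. Passing recovery
tests therefore demonstrates correctness of the inference machinery under
the model's own assumptions, not robustness to their violation.

## Problem sizes and numerical choices

Validation experiments use the standard synthetic example (4×2×6, n = 100
per site). The grid-integration cross-check reduces to 2 rookeries fixed
for disjoint haplotypes and one mixed stock, where the exact posterior is a
4-D integral evaluated by midpoint rule on a 60⁴ grid. Recovery runs 20
replicates with 3,000-iteration chains (1,500 burn-in); the matrix-of-ones
check uses 6,000/3,000 and compares θ means at 3 combined Monte-Carlo
standard errors; the convergence check uses the full default 20,000/10,000.
Zero counts are handled through the kernel convention 0·log 0 = 0; the
multinomial coefficient, constant in the parameters, is excluded from the
log-likelihood by default. An optional floor on P entries (off by default)
guards against a single enormous distance numerically extinguishing a
rookery; P is always recomputed over the rookeries present in a run.

## Known limitations

- Identifiability of δ for rookeries contributing little to any sampled
  stock rests on the prior; their UNK share is correspondingly
  prior-dominated.
- The equivalence-test decision is a convention on interval overlap, not a
  posterior probability statement.
- No many-to-one model, no F_ST/AMOVA, no route estimation: distances are
  inputs.
- MSA experiment presets label mode and size period; assembling the old/new
  sampling-period datasets is data curation left to the caller's input
  files.
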