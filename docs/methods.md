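# Methods

This note documents the models behind `epimsap`, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the numerical decisions a maintainer would want written down.

## 1. The latent methylation model behind the MSAP generator

Each CCGG locus in a line founder carries one of four methylation states —
unmethylated, internal-CG methylated (C⁵mCGG), external-CHG methylated
(⁵mCCGG), or fully methylated. Band presence in each enzyme digest is a
deterministic function of state (see the mapping table in the README):
*Hpa*II cuts only unmethylated sites, *Msp*I cuts unmethylated and
internal-CG sites. Hemimethylated states are not modelled because MSAP
scoring is binary band presence/absence; the *Eco*RI partner site and
fragment-size selection are abstracted away (every cut locus is assumed
amplifiable), since all statistics start from the scored 0/1 matrix.

**Founders and treatment.** Founder states are i.i.d. draws from
`state_frequencies` (default `(0.5, 0.3, 0.1, 0.1)`, i.e. ~50% of loci
methylated, inside the 16–57% range of published MSAP estimates for
*Brassica*). 5-AzaC efficacy is modelled at two levels, reflecting the
observation that the chemical takes effect stochastically per plant:

- `n_effective_treated` — in how many treated lines the treatment worked at
  all (the generator labels these, giving ground truth for the screen);
- `p_demeth` — per-locus probability that a methylated founder locus
  reverts to unmethylated in an effective line. Demethylation only ever
  moves states toward unmethylated.

Default `p_demeth = 1.0`: an *effective* line is modelled as fully
demethylated at the assayed loci. This is deliberate. With 10 seedlings per
enzyme and 500 loci the permutation test resolves even ~2% residual
internal-CG loci as significant divergence, so lines with substantial
residual methylation would never be classified as converged — consistent
with the screen's biology, where flagged lines are those whose two digests
read essentially the same template. Partial demethylation remains available
through the parameter for sensitivity analyses.

**Within-line noise.** Each seedling perturbs the founder epigenotype by
resampling each locus state from the base frequencies with probability
`p_epi_noise` (default 0.02). This is an exchangeable, non-lineage-structured
noise model — the simplest mechanism that produces non-zero within-line
variability (SSWP) and realistic permutation-null behaviour. Real
within-line variation is lineage-structured (meiotic transmission,
re-methylation); the generator does not emulate that, so passing tests say
nothing about transgenerational dynamics. Crucially, one realised state
vector per seedling drives *both* enzyme digests, preserving the paired
structure of the assay.

**Closed forms used in testing.** The per-locus probability that the two
digests disagree equals the frequency of the internal-CG state; increasing
`p_demeth` weakly decreases it in treated lines. Both are verified by
Monte-Carlo against the closed form.

## 2. Distances, PCoA

Binary profiles are compared by Euclidean distance (ordination) or squared
Euclidean distance (AMOVA sums of squares, where the squared distance is the
count of discordant loci). Both conventions are exposed because the choice
made by legacy population-genetics software is not always documented.

PCoA is the Gower double-centring of −d²/2 followed by a symmetric
eigendecomposition; coordinates are eigenvectors scaled by √λ on the
positive-eigenvalue axes. Negative eigenvalues are reported (diagnostics for
non-Euclidean input) but excluded from coordinates, and explained-variance
shares are relative to the positive total. Axis sign is made deterministic
by forcing each axis's largest-magnitude coordinate positive. The
implementation is cross-checked in the test suite against scikit-bio's
independent PCoA.

Missing cells are handled by pairwise-complete locus exclusion with a logged
warning; an all-missing profile is an error. The TSV dialect is UTF-8,
samples as rows, loci as columns, 0/1 integers, empty cell = missing, with
metadata columns (sample, line, generation, enzyme); a GenAlEx-style CSV
export (two header rows of counts and population names) is provided for
interoperability.

## 3. AMOVA, ΦPT, permutation test, screen

The two-level AMOVA formulas are given in the README. Numerical choices:

- Negative Va (possible under the moment estimator) is clamped to 0 before
  ΦPT, the standard convention; ΦPT is therefore always in [0, 1].
- The permutation test permutes whole-sample labels between groups with
  group sizes fixed; for the screen this treats a seedling's two digests as
  independent samples, matching how two-enzyme MSAP data are conventionally
  analysed in GenAlEx-style AMOVA.
- Tie handling uses ≥ (conservative) and the add-one convention
  p = (b+1)/(n+1), which is never anti-conservative and reproduces the
  1/10⁴ floor at 9,999 permutations. Under a true null the p-value is
  stochastically ≥ uniform; the suite checks this at 500 null replicates.
- `screen_lines` classifies a line hypomethylated when p > α (default
  α = 0.05). The magnitude of ΦPT and both per-enzyme SSWP values are
  always reported alongside, so a user can apply a ΦPT-based cut instead;
  the published account of this screen is ambiguous about the exact
  decision rule, and α is deliberately configurable.
- No multiple-testing correction across lines is applied (raw per-line p
  values, as in the original analysis); at 14 lines and α = 0.05 the
  expected false-flag count under the null is ~0.7, which the specificity
  tests bound empirically.

## 4. Constrained logistic dose–response

The fitted form is the log-logistic

    y(x) = A + (100 − A) / (1 + (x/m)^b)

chosen because it passes *exactly* through 100% at dose 0 (the defining
constraint of a curve "starting at 100%") and has the named interpretable
parameters: lower asymptote A (%), rate b, and midpoint m (mM) with
y(m) = (100+A)/2. A logistic-in-x form cannot satisfy y(0) = 100 exactly
with a free lower asymptote, which is why the log-logistic parameterisation
was adopted. With A = 40% the survival at the half-reduction dose is 70%.

Fitting is unweighted nonlinear least squares on percentages (the analysis
one would run on replicate-mean percentages; binomial weighting changes
little at n = 100 per replicate and is easy to add upstream by passing
weighted percentages). Multistart: rates {0.5, 1, 2, 4} × positive-dose
quartiles for m, A initialised at the minimum observed response; each start
runs bounded trust-region least squares (0 ≤ A < 100, b, m > 0) with
xtol = ftol = gtol = 1e-12, and the best converged solution wins. scipy's
trust-region implementation guarantees monotone cost decrease within each
start. A flat response surface (all observations equal) is flagged
non-identifiable rather than fitted. Asymptotic parameter covariance comes
from the Gauss-Newton approximation at the optimum.

The lower-asymptote test is the extra-sum-of-squares F between the A-free
and A = 0 fits on 1 and N − 3 df; lack of fit partitions the residual SS
into pure replicate error (df = N − n_doses) and lack-of-fit
(df = n_doses − n_params). At the study design these strata contain 24
observations (6 doses × 4 reps) or 20 (5 × 4).

Simulated responses are Binomial(n_per_rep, y(dose)/100) per replicate;
defaults follow the study design (doses 0, 0.01, 0.1, 0.5, 1.0, 1.5 mM;
4 × 100 seedlings) with true parameters A = 40, b = 3, m = 0.32 mM. The
rate b is not recoverable from the published account; b = 3 gives a curve
whose practical features (mild response below 0.1 mM, saturation by
~1 mM) match the qualitative description. Recovery behaviour at this scale
(median relative error of m ≈ 7%, asymptote-test power ≈ 1, type-I ≈ 0 at
5%) is established by simulation in the test suite.

## 5. Trait variance analysis

The REML analysis of the original workflow is replaced by the one-way
random-effects method-of-moments decomposition (between-line component
(MS_B − MS_W)/ñ with the average-group-size coefficient ñ, clamped at 0
with a flag). On balanced data this coincides with ANOVA-REML; on
unbalanced data it differs slightly, so published REML numbers are treated
as calibration magnitudes, not exact targets. The likelihood-ratio variance
tests are correspondingly replaced by a seeded parametric bootstrap on the
log-ratio of the two groups' components.

A caution frozen into the tests: with 50 lines the between-line component's
sampling CV is ≈ 21% (MS_B has ~2/(k−1) relative variance), so individual
estimates land within ±25% of truth only ~80% of the time; the suite
asserts the median relative error (≈ 12%) instead of an over-tight coverage
claim.

Treatment contrasts use line means as the replication unit (difference of
group averages of line means, SE = √(s₁²/k₁ + s₂²/k₂), Wald = (est/SE)² on
1 df) — equivalent to a cluster-robust analysis when lines are the
clusters. Composition correlations are Pearson correlations of line means
with Fisher-z 95% intervals.

**Trait generator.** Each line draws a latent desaturation score
Z ~ N(0,1); fatty-acid between-line effects are
sd_b·(l·Z + √(1−l²)·ε) with standardised loadings l = (+0.794 palmitic,
+0.944 linoleic, −0.932 erucic). These are the unique single-factor
solution reproducing the three observed line-mean correlations
(erucic:linoleic −0.88, palmitic:linoleic +0.75, palmitic:erucic −0.74),
since r_ij = l_i·l_j. `latent_desaturation_effect` scales the loadings
(0 decorrelates). Group means for seed area, oil, protein and the three
fatty acids are the published group summaries; seed-area variance
components are the published 0.125/0.122 (treated) and 0.009/0.083
(control). Oil/protein and fatty-acid dispersions are unpublished; defaults
are field-realistic magnitudes with treated lines roughly twice as
dispersed, chosen once and documented here. Oil+protein feasibility is
validated at the spec level (means must sum ≤ 100) and fatty-acid fractions
are clipped at 0; at the default means and dispersions clipping is a
>6-sigma event.

## 6. Pedigree bookkeeping

`build_population_pedigree` reproduces the population structure
arithmetic: each E1 plant yields `siliques_per_plant` single-silique E2
seed accessions plus `pooled_per_plant` pooled accessions (473 × 4 = 1,892),
and `n_selected_lines × seeds_sown_per_selected_line` E2 plants
(100 × 10 = 1,000). Selection of lines is positional (first k), since the
phenotypic selection criteria are outside the data model.

## 7. Pipeline and reproducibility

Every stochastic operation draws from one `numpy.random.Generator` seeded
by the spec's `rng_seed`, with a fixed draw order (founders, efficacy,
noise); identical specs give bit-identical outputs. The `run` pipeline
writes a manifest of SHA-256 checksums plus the seed, and the determinism
test asserts two runs produce identical checksums. Stage outputs carry the
seed in a comment header line; a failed stage is recorded in the manifest
and earlier outputs are retained.

Problem sizes used by the test suite — 14 lines × 10 seedlings × 500 loci
for the screen, 9,999 permutations, 100–200 simulation replicates for the
recovery experiments, 500 null replicates at 199 permutations for p-value
calibration — are the study's own sampling design where one exists, and
otherwise sizes at which the Monte-Carlo error of the checked quantity is
small relative to the asserted tolerance.

## 8. Known limitations

- The generator's per-sample noise is exchangeable, not lineage-structured;
  SSWP magnitudes are therefore calibrated only in order, not in value.
- Fragment-level artefacts (comigration, size homoplasy, peak-calling
  error) are not modelled; real MSAP matrices are noisier than simulated
  ones in locus-specific ways.
- The dose–response functional form is one of several curves consistent
  with "a logistic starting at 100%"; an exact numeric match to legacy
  software output is not a goal, and the 0.23/0.32 mM doses are recovery
  targets on synthetic data, not reproductions.
- The moment variance decomposition is not REML on unbalanced designs.
- The screen treats the two digests of one seedling as independent samples
  in the permutation scheme; a paired permutation variant would be more
  conservative and is not implemented.
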