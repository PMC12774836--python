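# Methods

## The model

`polyhybrid` predicts the expected fitness of a hybrid from summaries of
its genomic composition.  Number the parental lineages `i = 1..P` and let
`h_i` be the proportion of the `K` alleles at a locus that descend from
lineage `i`; angle brackets denote averages across loci.  The expected
fitness of a hybrid, on a transformed scale that is bounded above but
unbounded below (a log-fitness-like scale), is

    E(W) = Σ_i ⟨h_i⟩ W_i  +  Σ_{i<j} ⟨h_i h_j⟩ M_ij  +  Σ_{i<j} ⟨h_i⟩⟨h_j⟩ I_ij

with three ingredients:

- `W_i` — the transformed fitness of parental line `i`, weighted by its
  share of the hybrid's ancestry;
- `M_ij ≥ 0` — a *masking* (dominance/complementation) coefficient: the
  benefit of carrying alleles from both lineages at the same locus;
- `I_ij` — an *epistasis* coefficient for the effect of admixed ancestry
  independent of heterozygosity; it can take either sign but is bounded
  below by `−M_ij` under the model's derivation from quadratic
  optimizing selection on additive traits.

Ploidy does not appear in the fitness function; it enters only through
the dynamics of the ancestry moments under segregation.  This separation
is the basis of every prediction in the package.

Key assumptions: hybrids carry an effectively random sample of parental
alleles (only first and second ancestry moments matter); fitness effects
come from pairwise allelic interactions; even ploidy with polysomic
(random-chromosome) segregation and no double reduction.

The matrices `M` and `I` are treated as free parameters; nothing in the
package derives them from underlying allelic effects.  Their diagonals
are unused by construction and never read.

## Closed forms

*Selfing.*  With random chromosome segregation, the inbreeding
coefficient follows `F_t = (1−β) + β F_{t−1}` with retention rate
`β = 1 − 1/(2K−2)` (1/2 for diploids, 5/6 for tetraploids), and the
two-parent pair moment decays geometrically, `⟨h_A h_B⟩_t = β^t/4`.  The
expected fitness change from the F1 is `(β^t − 1) M_AB/4`.  The F1
starting condition uses `F_0 = (K−2)/(2(K−1))` — the IBD probability of
a genotype with `K/2` alleles from each parent — which makes
`⟨h_A h_B⟩_0 = 1/4` at every even ploidy.

*Tetraploid heterozygote classes.*  A selfed tetraploid locus splits
into balanced (AABB) and unbalanced (AAAB/ABBB) heterozygotes with
per-locus pair products 4/16 and 3/16.  Their probabilities have the
closed forms `Pr_t(AABB) = ((5/6)^t + (1/6)^t)/2` and
`Pr_t(unbalanced) = (2/3)((5/6)^t − (1/6)^t)`; the class-weighted sum
recovers `β^t/4` exactly, which the test suite asserts in rational
arithmetic.

*F2 composition.*  For the F2 designs of a multi-line panel (selfed F1,
half-sib F1 cross, outcrossed F1 pair; `P ∈ {2,3,4}`), the inbreeding
coefficient decomposes as `F = (1−p_d)φ_s + p_d φ_d` with
`p_d = (K/2)/(K−1)`, `φ_s = (K/2−1)/(K−1)`, `φ_d = 1 − P/4`, giving
`Σ⟨h_i h_j⟩ = P/16 + (K−2)/(8(K−1))` and `Σ⟨h_i⟩⟨h_j⟩ = P/16 + 1/8`.
`φ_d` is specific to these designs, so other `P` are rejected rather
than extrapolated.

*Heterosis relations.*  F1 heterosis is `(M̄+Ī)/4` (non-negative under
the model's bound); F2 breakdown is `(β−1)M̄/4`, hence 3× slower in
tetraploids; the gain per added F2 parent is `(M̄+Ī)/16` — a quarter of
the F1 heterosis at any ploidy — and progressive heterosis follows
`(1/8)[((K−2)/(K−1))M̄ + Ī] − (1/4)(1−P/4)(M̄+Ī)`.

All probability-valued closed forms are computed with
`fractions.Fraction` so identities can be tested exactly; prediction and
fitting paths use floats.

## The segregation simulator

The simulator is deliberately minimal so that it can serve as a
brute-force oracle.  A genotype is `L` unlinked loci × `K` lineage
labels; a gamete samples `K/2` of the `K` homologues per locus without
replacement (so double reduction is impossible by construction); crosses
unite one gamete from each parent.  One chromosome is one locus label:
there is no within-chromosome structure, no linkage map, no mutation and
no selection during line maintenance.  Observed values add the landscape
prediction at the genotype's realised moments, a constant polyploidy
cost for `K > 2`, a maternal boost when the seed parent was an F1 (a
pedigree property, never inferred from the genotype), and Gaussian
per-plant noise.

## Estimation

*Selfing decay.*  `E(y_t) = b_c + (β^t − 1) m_c` with one retention rate
per fit, a cross-specific amplitude `m_c = M_c/4`, and a cross-specific
nuisance baseline `b_c`.  The baseline is not in the decay law itself;
it is included so the fit is exactly invariant to affine changes of the
response scale (as induced by a Box–Cox step) — without it a shifted
response would bias β.  At fixed β the linear parameters have closed
forms, so β is profiled by bounded scalar minimisation (tolerance
1e−12); confidence intervals come from the asymptotic covariance at the
optimum (Gauss–Newton Jacobian), matching the CI style of classical
nonlinear least-squares analyses; no bootstrap.  Fits are unweighted:
replicate-level precision weights are not available in mean-reported
designs.

*Ploidy scan.*  Gaussian profile log-likelihood `−(n/2)·log(RSS/n)`
(constants dropped) with β fixed at its theoretical value for each
candidate `K ∈ {2,4,6}`; only differences are meaningful.

*Heterozygote-class weights.*  Linear regression of the deviations on
`Pr_t(AABB) − 1` and `Pr_t(unbalanced)` (plus per-cross baselines).  The
two coefficients absorb the masking coefficient, so only their ratio is
interpretable; the model predicts 3/4.  The ratio CI uses the
first-order delta method on the coefficient covariance, reported as
ratio ± 1.96·SE.  Pooling crosses assumes a shared `M`; with unequal
masking the pooled ratio is still exactly 3/4 for balanced designs, but
the residual term inflates, so per-cross fits are preferred for
inference and the pooled fit is reported alongside.

*Box–Cox transforms.*  Two selection criteria are implemented, on a
grid `λ ∈ [−2, 2]` step 0.01 with ties broken toward `λ = 1`.  The
skew-minimising criterion pools *centred* cells within each generation
before computing the (adjusted Fisher–Pearson) skewness: per-cell
skewness of a handful of replicates is noise, and — being scale
invariant — cannot see a transform that is nearly singular inside the
data range.  Non-positive data are shifted additively.  For signed
deviation data the zero is not a data feature, and replicate cohort
means are near-Gaussian by averaging, so the skewness criterion is
weakly identified; the default therefore anchors shifted data fifty
ranges from zero, where every exponent on the grid acts near-affinely
and an unlucky exponent cannot bend the response (a small `eps_frac`
restores full leverage, and strictly positive data are never shifted).
The SMA criterion maximises the r² of a standardized major axis
regression between the diploid and tetraploid means of the fixed
genotypes (parents and F1), both axes sharing one exponent and shift.

*SMA regression.*  `|slope| = SD(y)/SD(x)` with the sign of the
correlation; symmetric in x and y; used both for the cross-ploidy scale
and to impute a missing tetraploid F1 from the fitted line.

*Heterosis contrasts and jackknife.*  Contrasts are differences of
cohort means normalized by the diploid parent→F1 difference; the
parameter-free predictions (1 for F1 heterosis, 1/4 per added F2
parent) are attached.  Uncertainty comes from delete-group jackknives:
6 resamples dropping every cross with ancestry from one line, and 15
dropping crosses containing both lines of a pair.  A resample on which
the statistic fails is flagged, never silently dropped.

*Model selection on cross means.*  Each cross mean is predicted from
per-line fitness columns plus shared masking/epistasis terms through
the exact ancestry sums of its cross type.  The nested family crosses
three optional terms — tetraploid intercept (polyploidization cost),
constant F2 offset (maternal effect), and free tetraploid slope
(separate tetraploid `M̄, Ī`, relaxing the hypothesis that the genetic
parameters are ploidy-invariant) — giving 8 OLS models compared by
`AIC = n·log(RSS/n) + 2(k+1)` on equal-weight cross means.  RSS is
floored at the numerical precision of the response scale so that
exactly-fitting nested models are ranked by parsimony rather than by
floating-point noise.  Note that AIC retains its intrinsic
`P(χ²₂ > 4) ≈ 14%` chance of admitting two superfluous parameters, so a
single dataset does not always prefer the generating model; stability
statements should be made over replicate datasets (the test suite
asserts the modal choice over 15).

## Synthetic study designs

*Selfing series* (two biparental crosses × ploidies {2, 4} × selfing
generations {0, 1, 3, 5, 7} × 5 replicates, values reported as
deviations from the expected F1 mean).  Defaults, chosen once as
plausible magnitudes on a transformed (log-like) fitness scale:
masking `M = 2.0` and `1.6` for the two crosses (identical across
ploidies), epistasis `I = 0.4` (cancels in deviations), per-plant noise
SD 0.2, replicate cohorts of 100 plants, 100 unlinked loci.  Each
replicate follows independent single-seed-descent chains through the
simulator; deviations are taken from the *expected* F1 value, with
measurement noise on every reported cell including generation 0, so the
reported errors are i.i.d. as the fitting model assumes.

*Multi-line panel* (6 inbred lines, 15 F1, 120 F2 with `P ∈ {2,3,4}`,
both ploidies, cross means only; one tetraploid F1 deleted by default to
mirror a panel with a single missing cross, later imputed by the
pipeline).  Defaults: per-line fitness `(1.0, 1.8, 2.6, 3.4, 4.2, 5.0)`
— inbred lines differ severalfold, and that spread is what identifies
the common fitness scale across ploidies — `M̄ = 2.0`, `Ī = 0.4`,
polyploidy cost −0.5, maternal boost +0.3, per-plant noise SD 0.3 with
150-plant cohorts per cross.  F2 cohorts are simulated from their
stated pedigrees (not sampled from theoretical moments), so the
pipeline is exercised end to end.

With noise set to zero both generators emit the deterministic
infinite-cohort theory means, so noiseless data round-trip exactly
through the pipelines; this is the regime in which closure is asserted
to solver tolerance.

The trait is emitted on the model scale by default.  A raw-scale option
(`exp` of the model scale) exists but is off: a constant cost on the
model scale is an exact rescaling of the raw trait, making the
cross-ploidy r² criterion unable to distinguish the two scales (both
relations are perfectly linear), with the tie-break then landing on the
raw scale.

What the generators do *not* emulate: experiment-level random effects
(replicates are i.i.d.; real "replicate experiments" likely share
year/field effects), linkage and chromosome-scale inheritance,
selection during line maintenance, reciprocal-cross differences, and
skewed measurement error.  Passing tests therefore show that the
estimation chain recovers the generating process under these idealised
conditions, not that it is robust to the full error structure of field
data.

## Problem sizes and numerical choices

Simulator-versus-theory checks use 10,000-individual cohorts and a 3
Monte-Carlo-SE tolerance; coverage checks use 200 generated datasets per
ploidy against the binomial 99% band around the nominal 95%.  Scalar
optimisation is bounded in `β ∈ (1e−6, 1−1e−6)`; residual sums of
squares are clipped away from zero before logs; the class-weight ratio
is flagged undefined when the balanced coefficient is numerically zero;
zero-variance groups contribute zero skewness; SMA requires non-zero
variance on both axes and at least 3 points.

## Limitations

- The decay model assumes i.i.d. Gaussian errors on the analysis scale;
  heteroskedastic or correlated replicate structure is not modelled.
- `φ_d = 1 − P/4` (and everything downstream of `f2_composition`) is
  limited to the three F2 designs; other mating schemes need their own
  derivation.
- The per-pair second moments of asymmetric three-parent F2s are not
  available in closed form here; constant-`M̄/Ī` generation covers them
  through the pair-sum identities, and heterogeneous parameters require
  the simulator path.
- Transform selection on near-symmetric deviation data is weakly
  identified by construction; the package's answer is to make the
  transform harmless there, not to pretend the exponent is estimable.
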