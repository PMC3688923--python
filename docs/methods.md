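# Methods

## The model

Relative quantification by qPCR compares crossing points (Cp): the number of
amplification cycles needed for a target's fluorescence to reach threshold.
One cycle corresponds to one multiplication by the assay's amplification
factor *E* (ideally 2), so Cp differences are log-scale template differences.
All modelling happens on the efficiency-adjusted scale

    y = Cp · log2(E_g)

with a per-gene *E_g* from a standard curve. On this scale one unit is one
template doubling for every gene, and contrasts convert to fold changes as
`FC = 2^(−diff)` (negative contrasts mean *fewer* cycles, hence more
template).

The joint mixed model for target and reference genes is

    y = P_j + [S_k] + TG + B_gim + D_im + e

- `P_j`: fixed plate effect (dummy-coded, first plate as reference; the term
  is omitted when only one plate is present).
- `S_k`: fixed sex effect, included only on request — it matters only for
  designs that mix sexes, such as the 51-animal genotype validation analysis.
- `TG`: fixed cell means, tissue×gene for tissue profiling or
  genotype×tissue×gene for genotype-conditional analyses. Cell-means coding
  (no intercept) keeps every contrast a simple difference of coefficients.
- `B_gim`: gene-specific random effect of a biological sample
  (gene×animal×tissue), one variance σ²_B.
- `D_im`: random sample effect (animal×tissue) shared by all genes measured
  on that sample, variance σ²_D.
- `e`: homogeneous residual, variance σ²_e. Heterogeneous residuals are out
  of scope by design.

Estimation is REML (statsmodels `MixedLM`: grouping by sample, a random
intercept for D and a per-gene variance component for B), with BFGS and
Powell/Nelder-Mead fallbacks. Fixed effects are the GLS solutions at the
REML variance estimates; their covariance feeds contrast standard errors.

### Identifiability of σ²_B

When every gene×sample combination is measured exactly once — the normal
situation, since triplicate wells are averaged into one Cp per sample and
gene — B is statistically indistinguishable from the residual: within a
sample block the covariance is σ²_D on off-diagonals and σ²_B + σ²_e on the
diagonal, whatever the split. `fit_reml` detects such designs and folds B
into the residual (σ²_B reported as 0, `b_confounded=True`). Contrast
estimates and standard errors are unaffected; only the decomposition is.
With replicated measurements (a gene×sample run on two plates) all three
components are identifiable and are estimated separately.

### Degenerate inputs

Noise-free data (zero residual after OLS) short-circuits to ordinary least
squares with all variance components zero — REML is undefined at zero scale.
Variance components are clamped at zero at the boundary. Designs where plate
is perfectly confounded with the modelled cells are rejected as singular
rather than silently repaired.

## Contrasts, fold changes, intervals

The normalized contrast for target *t* between classes *a, b* with *K*
references is

    diff = [TG(t,a) − TG(t,b)] − (1/K) Σ_r [TG(r,a) − TG(r,b)]

Its SE comes from the fixed-effect covariance. The default reference
distribution for p-values and intervals is the standard normal with the 95%
multiplier 1.959964 — the convention that reproduces the published interval
arithmetic exactly. Degrees-of-freedom corrections for so small a crossed
design are genuinely ambiguous; rather than commit to one, a Student-t
reference is available by passing an explicit `df`, and p-values should be
read as descriptive either way. No multiplicity adjustment is applied by
default (matching the source analysis); Benjamini–Hochberg is available per
profile via `bh=True`.

The asymmetric CI is computed on the log2 scale and back-transformed, so
`ci_low · ci_high = FC²` holds identically — a useful internal consistency
check that also holds (to printed rounding) for the published tables.

Tissue profiles orient each pair so the reported FC is ≥ 1 relative to the
lower-expressing tissue; genotype profiles emit surviving genotype pairs in
lexicographic order. Genotype classes with fewer than 2 animals (the
near-empty homozygote class that a low-MAF SNP produces in a backcross) are
dropped with a warning before fitting.

## Reference-gene stability (geNorm)

For candidates measured on a common sample panel, the pairwise variation
V_jk is the sample SD (n−1) of per-sample log2 ratios, and M_j is the mean
V_jk over the other candidates; the highest-M gene is excluded each round
until two remain. Relative quantities are computed per gene as
`(1+eff)^(Cp_min − Cp)` — geNorm operates on linear-scale quantities, and
this is the standard efficiency-corrected conversion. Selection takes every
gene whose final M is below a threshold (default 1.1, the value used to
screen the porcine panel) and picks the two lowest-M genes, with
amplification efficiency breaking ties within a configurable margin
(default: exact ties only, then lexicographic). The trade-off between M and
efficiency has no canonical formula, so it is a parameter rather than a
hard-wired rule.

## Linkage disequilibrium

Haplotype frequencies for a SNP pair come from the 3×3 unphased genotype
table by EM: all cells except the double heterozygote contribute unambiguous
gametes; the double-heterozygote count is split between coupling and
repulsion phase proportionally to the current frequency estimates.
Initialization is linkage equilibrium (product of allele frequencies);
convergence when no frequency moves by more than 1e−8 (max 1000 iterations).
r² = D²/(p_A p_a p_B p_b) is clamped to [0,1]; D′ is exposed as a secondary
statistic. Missing genotypes are handled pairwise-complete. Cosegregation
groups are connected components of the graph of pairs with r² ≥ 1 − 1e−9;
the EM is exact for blocks that are literal copies, so constructed founder
blocks produce exactly unit r². Pedigree-aware phasing is deliberately not
used: the standard unrelated-individual EM is what the usual LD software
reports.

## Synthetic data

The generator and the fitter share one model family. Per measurement it
draws plate, sex, cell, B, D and residual effects on the transformed scale,
converts to Cp through the per-gene efficiency, then adds well-level noise
(`replicate_sd`, default 0.15 cycles) to each of 3 technical replicates and
stores their mean — mirroring how a thermocycler run is reduced before
analysis. Undetectable gene×tissue combinations (e.g. the long receptor
isoform outside hypothalamus) are emitted as missing wells so that the
validation screen flags them exactly as it would in a real dataset. Plates
are assigned to samples at random so plate effects stay estimable alongside
the tissue×gene cells. Genotypes are Hardy–Weinberg draws at configured
MAFs; SNPs within a founder block copy one draw (within-block r² = 1 by
construction). Everything derives from a single integer seed via
`SeedSequence`, so outputs are bit-reproducible.

Default parameters: 40 animals, five tissues, (σ²_B, σ²_D, σ²_e) =
(0.25, 0.25, 0.5) on the transformed scale, plate-effect SD 0.2, gene
baselines near Cp 25. Reference efficiencies use the published estimates
(80% ACTB, 93% B2M); target efficiencies are unpublished and set to a
typical 90%. What the generator does *not* emulate: amplification-curve
artefacts, inhibitor-driven efficiency shifts between samples, pedigree
transmission beyond block structure, and non-Gaussian outliers — so passing
recovery tests demonstrates correctness of the estimator under its own
assumptions, not robustness to assay pathology.

## Calibration results the suite verifies

At the study design (40 animals, 5 tissues, 2 reference + 2 target genes,
500 simulation replicates) the suite checks that the null-contrast rejection
rate lies inside the exact binomial 95% band around 0.05 ([0.032, 0.072]),
that 95% CI coverage lies in [0.925, 0.972] for null and planted contrasts,
and that planted 2-fold and 8-fold changes are recovered with |log2 bias| <
0.05. geNorm ranking and the LD EM are verified against independent
brute-force oracles (100 random matrices at 1e−10; gamete counting and
phase-known simulations), standard-curve inversion to 8 significant digits,
and the REML fit against lme4 and closed-form balanced ANOVA estimators.
The 500-replicate run takes about two minutes on one core; examples use 50
replicates for responsiveness.

## Known limitations

- Satterthwaite/Kenward–Roger degrees of freedom are not implemented; the
  normal reference slightly understates uncertainty in very small designs
  (observed coverage ≈ 0.94 at the study size — within the tested band).
- One variance each for B and D; gene-specific variances are not estimable
  at this design and are not offered.
- Cp values are consumed as produced by the instrument; second-derivative
  curve calling and raw fluorescence parsing are out of scope.
- The published tables contain a few rows whose printed fold change and
  estimator signs are mutually inconsistent; the transforms here follow the
  convention consistent with the large majority of rows (`FC = 2^(−diff)`),
  and the inconsistent rows are excluded from validation rather than
  reinterpreted.
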