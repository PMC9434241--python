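# Methods

`mfblup` implements single-step genomic BLUP (ssGBLUP, "HBLUP") for breeding
populations founded from several distinct base populations, with the base
structure carried either as fixed unknown-parent groups (UPG) or as random
*metafounders* (MF). This note records the models, the estimators, the
numerical choices, and what the synthetic-data generator does and does not
emulate.

## The linear mixed model

All variants fit

```
y = X b + Z1 a + Z2 f + e
```

where `y` are per-trial-standardized phenotypes, `b` site (trial) fixed
effects, `a` additive genetic effects, `f` full-sib family effects with
`var(f) = I sigma_f2` (capturing dominance/SCA and common environment), and
`e ~ N(0, I sigma_e2)` (per-site residual variances are available as an
option; the homogeneous form is the default). The five variants differ only
in `var(a)`:

| variant    | var(a)              | base-population structure |
|------------|---------------------|---------------------------|
| ABLUP      | `A sigma_a2`        | none (founders unrelated) |
| ABLUP_UPG  | `A`, groups fixed   | Quaas–Pollak group equations |
| ABLUP_MF   | `A_Gamma sigma_a2`  | metafounders, random      |
| HBLUP      | `H sigma_a2`        | none                      |
| HBLUP_MF   | `H_Gamma sigma_a2`  | metafounders, random      |

Fixed effects use one coefficient per site (cell-means coding; the site
design is full rank without an intercept, which is the same fit as an
intercept plus reference-level drop). In the UPG variant the group equations
are unpenalized and rank deficiency against the site effects is removed by
constraining the last group to zero; LR statistics depend only on solution
differences and are unaffected by the constraint choice.

## Relationship matrices

**A and A⁻¹.** The numerator relationship matrix is built by the tabular
recursion; the sparse inverse by Henderson's rules with Mendelian-sampling
variances from parental inbreeding. Inbreeding is obtained from a dense
tabular pass restricted to the ancestor closure of the parent set (everyone
who appears as a parent), which is equivalent to the Meuwissen–Luo recursion
and cheap even for large pedigrees because the parent set is small.

**Metafounders.** A metafounder is a pseudo-individual standing for a finite
base population; the K×K matrix `Gamma` holds self- (diagonal) and
cross-relationships, defined as 8×the covariance of base allele frequencies.
`A_Gamma` treats metafounders as base individuals related by `Gamma`, each
pedigree founder being the offspring of its metafounder(s); a founder with
both unknown parents in group g has diagonal `1 + Gamma_gg/2`. The sparse
`A_Gamma^{-1}` uses the same Henderson assembly with Gamma-consistent
Mendelian-sampling variances (`d_i = a_ii − (a_ss + 2 a_sd + a_dd)/4`, where
the parent slots of base individuals point at metafounders) plus
`Gamma^{-1}` added on the metafounder block. Individuals with exactly one
known parent take 0.5 from the known parent and 0.5 from the labeled
metafounder — the standard UPG/MF convention for half-known parentage.

**Genomic matrices.** `G_obs` is VanRaden's first method at observed allele
frequencies (monomorphic markers dropped; missing genotypes mean-imputed —
deterministic and adequate at the low missing rates the pipeline expects).
`G_obs` is rescaled so its mean diagonal and overall mean match `A22`
(standard compatibility tuning; the moment conditions are a design choice)
and blended `0.95 G_scaled + 0.05 A22`. `G05` uses 0.5 frequencies
(`c = m/2`, monomorphic markers retained) and is blended with `A_Gamma22`,
because the two share the 0.5-frequency base and the single-step correction
subtracts `A_Gamma22^{-1}`.

**H inverses.** `H^{-1} = A^{-1} + [0 0; 0 G^{-1} − A22^{-1}]` on the
genotyped block; the metafounder version adds the `G05^{-1} − A_Gamma22^{-1}`
correction inside `A_Gamma^{-1}` with metafounder rows untouched. No τ/ω
scaling is applied to the correction (defaults 1/1); a dense `H` builder
exists for inspection and testing (refused above 20,000 entities).

## Estimating Gamma

Per marker, base-population frequencies are estimated by GLS:
`p_j = (Q' A22^{-1} Q)^{-1} Q' A22^{-1} m_j / 2`, with `Q` the expected
metafounder contributions of the genotyped individuals and `A22` the plain
(unaugmented) pedigree relationships among them — `Gamma` is the quantity
being estimated, so it cannot appear in its own estimator. Then
`Gamma = 8/m * sum_j (p_j − c)(p_j − c)'`.

The centering `c` defaults to 0.5 (second moment about the ideal-population
frequency), consistent with `G05` and with the classical expectation that
uniformly distributed base frequencies give diagonal values of 2/3;
per-metafounder marker-mean centering is available (`center="mean"`). An
indefinite estimate can be repaired by eigenvalue clipping at 1e-6
(`psd_repair`), which is logged; repair is required before `Gamma` is
inverted in `A_Gamma^{-1}`.

Derived summaries: the scalar `k = 1 + mean(diag Gamma)/2 − mean(Gamma)`
divides `sigma_a2` in MF variants so the genetic variance is comparable with
the classical parameterization; per-metafounder implied inbreeding is
`Gamma_gg − 1` (negative for diverse base populations); and a UPGMA tree is
built from the covariance-derived distances
`d_ij = (Gamma_ii + Gamma_jj)/2 − Gamma_ij` (clipped at zero), with node
heights at half the merge distance so the tree is ultrametric.

## Solving and variance components

The mixed-model equations are assembled sparse and solved either by sparse
LU (default; relative residual checked against 1e-10) or by Jacobi-
preconditioned conjugate gradients (1e-8). The UPG variant uses the
Quaas–Pollak transformed equations, whose additive solutions already include
the group contributions; MF solutions are reported separately from
individual (G)EBVs and are never summed into them automatically.

EM-REML estimates `(sigma_a2, sigma_f2, sigma_e2)` for desk-scale runs, with
the variance-component workflow mirroring applied practice: estimate once on
a base variant, then fix for all variants of a population set. The E-step
needs `tr(A^{-1} C_aa)` and `tr(C_ff)` from the inverse coefficient matrix;
these are exact (dense inverse) up to 2,500 unknowns and otherwise use a
Hutchinson estimator with 64 Rademacher probes on a sparse LU factorization.
Probes are drawn once from a seeded generator and held fixed across
iterations, so the iteration is deterministic given the seed and its fixed
point carries an O(1/sqrt(probes)) trace-estimation error (well under the
sampling error of the components at the problem sizes involved). Components
are floored at 1e-8; a component with no signal decays toward the floor
(EM approaches a boundary only asymptotically). Convergence is declared when
the largest relative parameter change falls below `tol` (default 1e-5;
1e-6 for recovery experiments, typically ~1,000–2,000 iterations at
n≈10,000 — EM's terminal crawl is slow for low-heritability traits).

## LR cross-validation

A focal group is formed by deleting the phenotypes of all progeny of a
chosen parent set; the model is refit and the focal group's whole- vs
partial-data solutions compared:

- `ACC = sqrt(cov(a_w, a_p) / ((1 − Fbar) sigma_a2))` — the accuracy of the
  partial-data predictions. The square root follows the LR method's
  definition; the raw ratio is also exposed. A negative covariance yields a
  missing ACC with the raw ratio logged.
- `STAB = corr(a_w, a_p)` (the "ratio of accuracies").
- `DISP = cov(a_w, a_p) / var(a_p)` — regression slope, 1 = no dispersion.
- `BIAS = mean(a_p) − mean(a_w)`, also reported in genetic-SD units.

`Fbar` is the focal group's mean inbreeding from the diagonal of the
*group-free* H matrix (for every variant of a population set, including MF
variants), evaluated row-wise so no dense H is formed. Covariances use the
n−1 divisor. For synthetic runs focal parents are a seeded sample stratified
by dominant metafounder origin, 20 parents by default. One covariance
computation feeds all three second-moment statistics, so the degenerate
whole=partial comparison returns STAB=1, DISP=1, BIAS=0 exactly.

Single-replicate DISP carries sampling noise dominated by the focal
*parents'* prediction errors (shared across model variants fit to the same
data), with SD ≈ 0.15–0.2 at desk scale; model-level dispersion statements
are therefore made on means over seeded replicates.

## The synthetic-data generator

`simulate_dataset` builds, with one seed: (1) K base populations whose
allele frequencies drift from a common ancestor (uniform on [0.05, 0.95])
along a random bifurcating tree by Balding–Nichols steps (`fst` per level,
default 0.05, depth 3 — giving the nested Gamma structure of hierarchically
related provenances; a star option exists); (2) founder genotypes
Binomial(2, p) and a multi-generation pedigree over two programs with
population-dependent program assignment, occasional cross-program matings
(5%), and per-locus Mendelian gene dropping; (3) phenotypes as additive +
full-sib family + residual effects over several sites, standardized per
site. The genotyped subset is all founders, all parents, and a fraction of
remaining progeny.

True breeding values come from normal marker effects on 0.5-centered gene
content, so base-population means diverge with allele frequencies and
genomic models hold a genuine information advantage; effects are rescaled so
the realized TBV variance equals the nominal `sigma_a2` exactly (the
convention of standard breeding-program simulators, and what makes
variance-recovery experiments well-posed). The desk preset is K=6, m=2,000,
two programs, three generations, 120 families of 25, 30% of non-parent
progeny genotyped, four sites, components (0.17, 0.04, 0.80) — chosen to
keep a full simulate → Gamma → H → solve → LR cycle around ten seconds on
one CPU while leaving family and provenance structure estimable.

What the generator does **not** emulate: linkage and LD (markers segregate
independently, so marker-based and pedigree expectations align faster than
in real genomes), selection (no trend, no selective genotyping bias),
mutation, genotyping error, spatial/trial-design effects (phenotypes are
emitted pre-adjusted and pre-standardized), and GxE beyond site main
effects. Passing tests therefore demonstrate the correctness of the
algebra and the statistical behavior of the estimators under the stated
model, not robustness to those real-data complications.

## Numerical and design details

- Entity orderings are carried with every matrix and checked before any
  algebra; metafounders always sit after individuals.
- Matrices are written with 17 significant digits so write/read round trips
  are byte-stable; delimiter detection accepts comma/tab/whitespace and
  treats ambiguity as an error.
- Opposing-homozygote screening flags declared parent-offspring pairs above
  a 2% conflict rate by default (configurable); true pairs have rate 0 up to
  genotyping error, unrelated pairs about `2 * sum p^2 (1-p)^2 / m`.
- `G` blending weight defaults to 0.95; `rescale_g` refuses degenerate
  inputs (mean diagonal equal to overall mean).
- The `gamma → 0` limit is not invertible; a small ridge (e.g. 1e-8 on the
  diagonal) recovers plain-A behavior and is used in tests of that limit.

## Known limitations

- EM-REML is a desk-scale tool: plain EM with slow terminal convergence,
  not AI-REML, and no standard errors of the variance components.
- No multi-trait models, dominance/epistasis relationship matrices, APY or
  other large-scale G⁻¹ approximations, marker-effect back-solving, or
  genotype imputation beyond marker means.
- LR validation implements the single whole/partial split of the design it
  follows, not k-fold or forward validation.
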