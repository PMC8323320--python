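# Methods

`beegs` simulates honey-bee breeding populations, estimates breeding
values with pedigree and single-step genomic BLUP, and predicts the
genetic gain of breeding schemes that combine colony-based selection
with genomic preselection. This note documents the models, the
numerical choices, and what the scaled-down simulations used in the
test suite do and do not demonstrate.

## Colony trait model

A colony phenotype is modelled as

    y = mean(a_W) + m_Q + year + e,

the mean *direct* (worker) breeding value of the colony's worker group
plus the *maternal* breeding value of the queen heading it, a year fixed
effect, and a residual with variance `sigma_e2`. Direct and maternal
effects are correlated with additive covariance matrix

    V_a = [[sigma_a2, sigma_am], [sigma_am, sigma_m2]].

Because the workers of one colony are a mixture of super-sisters and
half-sisters, the phenotypic variance weights the direct variance by the
mean worker-worker relationship `A_ii`:

    sigma_ph2 = A_ii*sigma_a2 + sigma_m2 + sigma_am + sigma_e2.

All derived parameters (direct/maternal heritabilities, genetic
correlation, queen-criterion and colony-criterion variances and
heritabilities) follow in closed form; two presets are shipped, `MOD`
(sigma_a2=2, sigma_m2=1, sigma_am=-0.5, sigma_e2=1) and `HGC` (same with
sigma_am=-1), both with `A_ii = 0.32`. `A_ii` is an input constant here;
the relationship module reproduces it from the mating parameters (see
below), which is checked by the test suite.

## Relationship framework

The numerator relationship is `a = 2f` with kinship `f` defined by
honey-bee transmission rules: drones are haploid gametes of their dam
(all sperm of one drone identical), a queen inherits a dam gamete plus
the genome of one sire drone, the pedigree "sire" is a *pseudo-father*
(the group of 8 sister DPQ on the mating station, acting as a uniform
mixture because the true sire drone's dam is unknown), and a worker
group is the expectation over infinitely many workers. These rules
reproduce the three standard anchor values: dam-daughter 0.5,
worker-worker 0.3203 (`A_ii`), and daughter-to-pseudo-father 0.2026
under the default parameters (12 drones, 8 DPQ per station).

Two entities whose paternal contribution comes from the *same mating*
(daughter queens, the worker group, and a pseudo-father of daughter DPQ
all draw from one dam's spermatheca) can share the very same stored
drone. The plain parent-average recursion cannot express this, so the
builder inserts one latent **mating node** per mating: its relationships
to all other entities equal the station's, but its self-relationship is
the shared-spermatheca grid value

    a_CC = 2/n_drones + (1 - 1/n_drones) * a(S, S),

where `a(S, S)` is the station's group self-relationship (`1/n` for an
unrecorded base station of `n` unrelated DPQ). Offspring recurse on
(dam, mating node). This is the exchangeable-family common-factor
decomposition, so the resulting matrix is positive semidefinite by
construction, independent of entity ordering, and robust to dams with
offspring in several years. The matrix returned contains only real
entities (queens, pseudo-fathers, worker groups); matrices are stored
dense — at the problem sizes this package targets, sparse bookkeeping
would buy nothing.

Correctness is anchored by a Monte-Carlo **gene-dropping oracle** that
realizes single-locus founder alleles through the same transmission
rules (including shared spermathecae and anonymous base stations) and
estimates `2*P(IBD)`; the tabular builder agrees with it on randomized
pedigrees within Monte-Carlo error.

A pedigree may also be built with pseudo-fathers expanded into their
individual member DPQ (`sire_group` references); merged and expanded
representations agree exactly (pseudo-father rows are member means,
diagonals full member-grid means).

## Genome and QTL simulation

The genome is 16 chromosomes totalling 220 Mb with a uniform
recombination rate of 19 cM/Mb. Crossovers follow a Haldane model
(Poisson count with mean equal to the genetic length in Morgans,
uniform positions, no interference); mutation is a symmetric allele
flip with probability 0.0005 per locus per transmission. Linkage
disequilibrium is built by drifting a closed population of queens
(historically 50 per year over 20,000 years at full scale) under bee
mating rules, expanding it (to 2400 queens for six years at full
scale), and discarding loci with minor-allele frequency below 0.05.

QTL effects are bivariate (direct, maternal) draws from
`0.95*Laplace(0, V_a) + 0.05*Normal(0, V_a)`; the elliptical Laplace is
realized as a normal scale mixture with an Exponential(1) variance
factor so each component's covariance is exactly `V_a`. The preliminary
effects are then centered and linearly transformed (Cholesky map from
the empirical to the target covariance) so that the base population's
mean TBV is exactly (0, 0) and its empirical TBV covariance (ddof=1)
exactly `V_a`; downstream results are therefore insensitive to the
Laplace construction. New QTL are drawn per replicate.

## Breeding population

The reference program runs years 0-9: 1000 BQ per year mated on 50
stations of 8 sister DPQ, 12 drones per queen (drone dams uniform over
the station's DPQ), colonies phenotyped the year after establishment.
From year 2 the top 200 two-year-old BQ (ranked by pedigree-BLUP
worker-group EBV sum, ties broken by ascending id) become dams of BQ
(5 daughters each), from year 3 the top 50 become dams of DPQ (8
daughters each, forming next year's stations). Burn-in cohorts (years
0-1) and the first DPQ cohort use base/random dams; stations of the
first three years host unrelated base DPQ and are not recorded, so
queens mated there have an unknown sire. Sister BQ always share a
mating station. The final default pedigree holds 10,000 BQ, 10,000
worker groups, and 2,800 DPQ on 350 recorded stations.

Daughters are reared from the dam's stored sperm, so a daughter's
expected TBV equals her dam colony's worker-group TBV — this identity
drives both the selection response accounting and the replacement-queen
rescaling. Worker groups are simulated as `n_W` individual workers
(default 100; the relationship model uses the infinite-group limit, so
tests targeting `sigma_W2` use `n_W >= 500` where the finite-size excess
`(1 - mean relationship)*sigma/n_W` is negligible). Worker genomes are
simulated at QTL loci only, which is exact for TBV purposes because the
crossover process marginalizes cleanly onto any locus subset. The year
fixed effect is simulated as 0 by default but always fitted.

## Breeding value estimation

The mixed model `y = Xb + Z_a a + Z_m m + e` links every phenotype to
its worker group's direct effect and its queen's maternal effect, with
`Var(a, m)` the Kronecker structure of `V_a` with the relationship
kernel `K` and year fixed effects in cell-means coding (equivalent to a
reference-level parameterization). Henderson's equations are assembled
densely and solved by Cholesky; a generalized-least-squares oracle built
from the full covariance of `y` verifies the solver on small fixtures to
1e-8.

For single-step analyses the kernel is `H` with

    H^-1 = A^-1 + [[0, 0], [0, G_w^-1 - A_g^-1]].

`G` is the VanRaden method-1 GRM over the genotyped queens with allele
frequencies computed from the genotyped set itself; the subsequent
mean-adjustment of `G` to the pedigree submatrix `A_g` (matching mean
diagonal and mean off-diagonal) compensates the base-frequency
mismatch, and blending `G_w = 0.95*G_adj + 0.05*A_g` restores full rank.
For the DPQ+BQ analysis, individual DPQ genotypes enter the GRM and are
then merged into one row/column per pseudo-father (member means; the
diagonal is the full member-grid mean), keeping the genomic and
pedigree matrices structurally aligned. Merging is exactly neutral: the
analysis with individual DPQ kept in both matrices yields identical EBV
for all other animals (verified to 1e-8), *provided* the adjustment
constants of the merged system are used in both pipelines, since
merging and mean-adjustment only commute at fixed constants.

## Evaluation and gain prediction

Accuracy is the Pearson correlation of TBV and EBV within a cohort;
dispersion bias the OLS slope of TBV on EBV. Cohorts follow the
reference design: unfertilized queens = final-year BQ, phenotyped
colonies = the previous year's worker groups. Colony accuracies are
rescaled to replacement-queen accuracies by
`rho_pR = (sigma_pW / sigma_pQ) * rho_pW`. For single-step analyses the
queen-cohort accuracy is conventionally evaluated over genotyped
members; at the scaled-down test sizes these subsets are too small for a
stable correlation, so the directional tests evaluate over the whole
cohort instead (noted in the tests).

One cycle of truncation selection responds with `R = i*rho*sigma` per
pathway, half-weighted for the gene share of each parent path:

    R_CBS = (i_DPQ_CBS/2 + i_BQ_CBS/2) * rho_pW * sigma_pW
    R_GPS = (i_DPQ_GPS*p_DPQ/2 + i_BQ_GPS*p_BQ/2) * rho_uQ * sigma_uQ
    R_GS  = R_CBS + R_GPS

with infinite-population intensities `i = phi(z)/p` (this choice
reproduces every published intensity value to its printed precision).
The generation interval is deliberately excluded: it is identical
across compared schemes. Note that the *year-over-year* TBV trend of a
steady-state program is the annualized Rendel-Robertson rate (pathway
superiorities divided by summed generation intervals, a factor 2/5
smaller here); the quantity the formula predicts, and the one validated
against the stochastic simulator, is the transmitted one-cycle pathway
superiority: offspring-cohort mean TBV minus the candidate colonies'
mean worker-group TBV, per pathway.

Scheme search: the genotyping budget `n_gpy` (0-4000 in steps of 500)
is split between preselection candidates (`N_DPQ_GPS` dams x
`n_DPQ_GPS` candidate DPQ of which 8 per dam are kept; `N_BQ_GPS` x
`n_BQ_GPS` of which 5 are kept) and additional phenotyped BQ; the
reference proportion is `p_ref = (N_rest + 5*N_BQ_GPS)/1000`, capped at
1 (surplus genotypes beyond the 1000 yearly phenotyped BQ have nowhere
to go). Accuracies are interpolated linearly over `p_ref` between the
simulated grid points, with the PBLUP value anchoring `p_ref = 0`; when
all DPQ are preselected the DPQ+BQ accuracies are also evaluated and
the better scheme kept. The enumeration is vectorized over the full
four-parameter grid; per-budget optima break ties toward fewer
genotypes; IGG is the difference between consecutive budget optima.

## Scaled-down study conditions

Simulation-backed tests run the full program structure at reduced size:
40 BQ/year on 4 stations of 8 DPQ, 8/4 selected dams, ~2400-loci panels
drifted for 150 generations (25 queens, expansion to 60), 150 QTL, 20
replicates. These sizes keep the whole suite within a few minutes on
one CPU while preserving every structural feature (haplodiploidy,
pseudo-fathers, shared spermathecae, burn-in, truncation selection).
What they demonstrate: exact closed-form and structural properties,
oracle agreement, calibration of simulated variances, the one-cycle
response identity, and the *direction* of the genomic-accuracy
benefits. What they do not: the full-scale magnitudes (e.g. the
published accuracy gains of +160%/+126% for unfertilized queens or the
absolute gains of the budget table), which require the 1000-BQ,
~48k-SNP, 100-replicate experiment; at 40 BQ/year the per-replicate
accuracy noise is of the same order as some of those contrasts. The
generator also idealizes real data: no genotyping errors, no missing
pedigree links, variance components known exactly, and a closed
population without migration.

## Known limitations

* The relationship builder augments the matrix with one latent node per
  mating; memory is quadratic in (entities + matings), which is
  comfortable up to a few tens of thousands of entities but not beyond.
* Unrecorded base stations are modelled as independent per mating; two
  base-year queens mated at the same physical station are treated as
  unrelated, consistent with the unrecorded-pedigree convention.
* Variance components are inputs, never estimated (no REML).
* The deterministic gain model covers the initial selection cycle only;
  multi-generation dynamics (Bulmer effect, inbreeding accumulation)
  are out of scope.
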