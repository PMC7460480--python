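# Methods

`mdagwas` implements a multivariate discriminant strategy for genome-wide
association in small genotyped cohorts, the single-marker comparator it is
usually judged against, and a forward-time livestock simulator that supplies
calibrated test beds for both. This note records the models, the defaults
and why they were chosen, the numerical decisions, and what the simulated
benchmarks can and cannot show.

## The association model

Animals are ranked by a mixed-model-corrected phenotype and split into
equal low- (LP) and high-phenotype (HP) halves. The premise is that animals
at the two phenotypic extremes carry different allelic combinations at the
loci controlling the trait, so the markers that best *discriminate* the two
groups are candidates for association — no per-marker significance test is
involved in the selection itself.

With two groups, canonical discriminant analysis (CDA) yields a single
canonical function `CAN = d1 X1 + ... + dp Xp` over marker dosages
`Xi ∈ {0,1,2}`. The raw direction is `d ∝ W⁻(m_HP − m_LP)`, with `W` the
pooled within-group covariance; `d` is scaled to unit pooled within-group
score variance and oriented so the HP centroid exceeds the LP centroid.
Marker importance is ranked by the within-standardized coefficient
`CNC_i = d_i √(W_ii)` (a flag exposes the raw coefficient instead; which
variant the original SAS workflow thresholded is not determinable, so both
are available). Group separation is measured by the Mahalanobis distance
`D² = (m_HP−m_LP)' W⁻ (m_HP−m_LP)`, tested via Hotelling's
`T² = n₁n₂/(n₁+n₂) · D²` transformed to an F statistic with
`(p, n−p−1)` degrees of freedom. Classification (DA) assigns an animal to
LP when its canonical score falls below the group-size-weighted mean of the
two centroids, to HP otherwise (ties go to HP; measure-zero in practice).

When `p ≥ n` the within matrix is singular. All inverses are Moore–Penrose
pseudo-inverses with a relative eigenvalue cutoff of 1e-10 (an optional
ridge `W + λI` is exposed), and the *rank actually inverted* — not the
nominal marker count — is the effective `p` of the F transform, which keeps
the test well defined after pseudo-inversion.

## The four-step pipeline

1. **Per-chromosome CDA.** Fit the CDA on each chromosome's markers
   (markers monomorphic in the analysed sample are dropped first, with a
   logged count). Retain markers with `|CNC|` strictly greater than the
   chromosome's mean + 1 sample SD of `|CNC|`. A single-marker chromosome
   retains its marker by convention (the SD of one value is undefined);
   all-equal `|CNC|`s retain nothing under the strict inequality.
2. **Stepwise reduction (SDA).** Pool the retained markers and run
   forward-with-removal stepwise selection on Wilks' lambda
   (entry/stay significance 0.15/0.15, the standard stepwise-discriminant
   defaults). For two groups `Λ_S = 1/(1 + c D²_S)` with
   `c = n₁n₂/((n₁+n₂)(n₁+n₂−2))`, so subset statistics are tracked through
   incremental Mahalanobis updates (within-group residualization for
   entries, a maintained `W_S⁻¹` for removals). Candidates whose
   within-group variance after residualization falls below 1e-8 of their
   original variance are ineligible (no exact collinearity); the selected
   set is at most `n−2` markers.
3. **Validation.** A genome-wide CDA on the selected set gives the
   Hotelling test and the DA training accuracy.
4. **Recursive pruning.** Refit the CDA, delete the marker with the
   smallest `|CNC|` (batch size configurable; one at a time is the most
   conservative reading and the default), revalidate, repeat. CNCs are
   re-estimated after every deletion. The returned minimal set satisfies
   Hotelling `p < 0.001` *and* 100% training accuracy, and deleting its
   current-lowest-`|CNC|` marker would break one of the two. A "top"
   subset keeps minimal-set markers with `|CNC| ≥ 0.25` (inclusive),
   ranked descending.

Two implementation choices in step 4 deserve justification. First, when
the stepwise set has `k` close to `n`, the Hotelling F has almost no error
degrees of freedom and the *starting* set can classify perfectly yet not
test significant; deleting low-`|CNC|` markers frees degrees of freedom and
strictly improves the test. Pruning therefore first *descends* until both
criteria hold and only then searches for the minimal satisfying set; it
errors if the criteria are never reached, or if perfect classification is
lost before they are first met. Second, markers collinear with the rest of
the set within floating precision (the stepwise tolerance admits sets whose
`W` is numerically singular) carry no discriminant information and are
removed up front by a pivoted-QR rank filter. The maintained inverse is
refreshed by a fresh Cholesky factorization every 32 deletions to stop
round-off accumulation; a full prune costs O(k³).

A deliberate caveat: the 100%-training-accuracy criterion is an in-sample
statement. When `p` approaches `n` a CDA can separate *any* labelling of
the animals perfectly — a label-permutation rerun of the pipeline will also
reach 100% training accuracy. The method's false-positive rate is
therefore assessed through the QTL-window scoring on simulated data, not
through the classification accuracy, and no cross-validated accuracy is
reported (the original workflow uses training-set assignment).

## Phenotype pre-adjustment

The mixed model is `y = Xβ + g + e` with `g ~ N(0, σ²_g K)`, `K` the
VanRaden method-1 genomic relationship matrix
(`K = MM'/(2Σp_k(1−p_k))`, `M` column-centered at twice the allele
frequency; monomorphic markers skipped). REML profiles the likelihood in
the single ratio `λ = σ²_g/σ²_e` over the eigenbasis of `K`, so each
evaluation is O(n); the 1-D bounded search runs on `log λ` over
`[1e-6, 1e6]` with tolerance 1e-8. An optional i.i.d. random intercept
(e.g. herd) is fitted by a two-ratio Nelder–Mead search on the dense
covariance, intended for moderate n. The corrected phenotype is the pure
residual `ê = y − Xβ̂ − ĝ` by default; a flag switches to `y − Xβ̂`
(which of the two the original analysis used is not determinable, so both
are exposed). The LP/HP split sorts by (residual, id) — the id makes
boundary ties deterministic — and drops the single median animal at odd n
so the groups stay exactly equal.

## Single-marker comparator

Per SNP, ordinary least squares of the corrected phenotype on allele count
plus an intercept and the first 10 principal components of the
column-standardized genotype matrix of the analysis subsample (PCA on
centered data gives the classical-MDS axes; standardization can be
disabled). Monomorphic SNPs get effect 0 and p = 1. P-values are adjusted
by Benjamini–Hochberg (statsmodels' step-up implementation); the default
significance level is q ≤ 0.05, a field convention since the original
threshold is not printed. No MAF filter is applied by default.

## The simulator

A QMSim-style two-phase protocol.

**Genome.** 29 equal autosomes of 1e8 bp; SNPs evenly spaced per
chromosome (remainders spread one per chromosome from chromosome 1), QTLs
at uniform-random unique positions. Meiosis is a Markov walk: the
transmitted haplotype switches between the two parental haplotypes in each
inter-locus interval with probability equal to the interval's genetic
length, with random phase at each chromosome start and no interference.
Per 1-Morgan chromosome the crossover count is then Binomial(#intervals, d)
≈ Poisson(1). Recurrent two-way mutation flips alleles at 2.5e-5 per locus
per meiosis.

**Historical phase.** Discrete-generation random mating (no selfing) at
`hist_pop_size` (default 1000) for `n_hist_generations` (default 1000)
from founders at allele frequency 0.5 (the original study does not report
its historical settings; Ne = 1000 over 1000 generations gives cattle-like
LD). When the breeding scheme needs more founders than the historical
population holds — the full design needs 4100 parents from 1000
historicals — the final generation is expanded by one extra random-mating
round.

**Breeding phase.** 100 sires × 4000 dams (1:40), one offspring per dam
per generation for 10 generations, sexes Bernoulli(0.5), the last 3
generations genotyped (12,000 animals). Sire/dam replacement rates 0.2/0.3
per generation, replacements drawn at random from the newest male/female
offspring. Mating is positive assortative: selected sires and dams are
each ranked by phenotype and paired rank against rank. Because QTL effects
are only calibrated after the population exists, the ranking uses a
provisional phenotype = polygenic value + N(0, var_phen − var_polygenic) —
this gives exactly the same mate–polygenic-value correlation as ranking on
the final phenotype would, since corr²(pg, y) = var_pg/var_y regardless of
the other components.

**Genetic effects.** QTL allele-substitution effects are gamma(shape 0.4)
magnitudes with random signs — QMSim's documented default, a heavy-tailed
distribution in which a few QTLs carry most of the variance — rescaled so
the realized QTL-score variance among genotyped animals equals
`h2_qtl · var_phen` exactly. The polygenic background is genome-realized:
a tiny normal effect at every SNP locus, scaled to
`(h2_total − h2_qtl) · var_phen` among the breeding founders. This has the
same first two moments as the classical pedigree polygenic model (offspring
value = parent average + Mendelian-sampling deviate of half the founder
variance) but realizes the Mendelian sampling by meiosis, so marker-based
relationship matrices capture the polygenic variance; with an abstract
pedigree-normal polygenic, the within-family half of that variance is
independent of realized genome sharing and a GRM-REML misattributes it to
the residual (we measured recovery of only ~0.13 of 0.29 in that setting).
Phenotype = QTL score + polygenic value + normal residual. All three
components are variance-calibrated in-sample among genotyped animals — the
same enforced scaling the QTL score receives — because with few sire
families the realized variances drift noticeably around their nominal
values, and the nominal variances define the study conditions.

**What the simulator does not model.** Sex chromosomes, selection on
estimated breeding values, overlapping historical generations, litter
sizes > 1, inbreeding corrections in the polygenic variance, mutation-rate
heterogeneity, and any QMSim file-format compatibility beyond PLINK output.

## Desk-scale study conditions

The full design (57k SNPs, 12,000 animals, 1000 historical generations) is
far beyond an interactive budget, so the replicated benchmarks run a scaled
configuration chosen to preserve the *statistical regime*, not the raw
sizes: 5,000 SNPs / 50 QTLs on 29 autosomes (the full SNP:QTL ratio's
order of magnitude); 17 sires × 667 dams (the 1:40 mating ratio), 5 recent
generations with the last 3 genotyped (2,001 animals); historical Ne = 300
for 100 generations. Crucially the genetic map shrinks with the marker
count — 0.3 Morgan per chromosome — so that `4·Ne·c` per marker interval
(≈ 2.0), and hence both adjacent-marker LD and QTL-to-flanking-SNP tagging,
match the full design; keeping 1 Morgan with 29× fewer markers would put
every marker in near-linkage-equilibrium with its neighbours and no
marker-based analysis could see the genetic variance. Method-comparison
replicates use independent simulations (5 by default) at n ∈ {250, 500,
750}, each analysed exactly as the full pipeline prescribes.

One scale artifact is reported rather than hidden: at n = 750 the step-1
retained pool (~780 markers) barely exceeds n, so the stepwise set often
cannot reach 100% training accuracy and no minimal set exists under the
stopping rule; such cells report zero associations with the failure
recorded, and enter the summary medians as zeros. In the full-scale regime
the retained pool exceeds n several-fold at every sample size and this does
not arise.

## Numerical and tie-breaking decisions (collected)

- Pseudo-inverse eigenvalue cutoff 1e-10 (relative); optional ridge.
- Hotelling's effective dimension = rank of the inverted within matrix.
- Stepwise tolerance 1e-8 on relative residual within-group variance;
  entry/stay levels 0.15/0.15; cycle guard on repeated selection states.
- Pruning: batch 1; inverse refreshed every 32 deletions; pivoted-QR rank
  filter at entry; descent phase as described above.
- Classification tie at the cutoff → HP.
- LP/HP split: sort by (residual, id); odd n drops the median animal.
- Minor-allele dosage coding; frequency-0.5 ties broken by lexicographic
  allele order; missing genotypes mean-imputed per marker before any
  multivariate step (the simulator emits none).
- QTL window ±250,000 bp, boundary inclusive, in physical coordinates.
- REML: ratio bounds [1e-6, 1e6], tolerance 1e-8, eigenvalues clipped at 0.
- All randomness flows from a single integer seed through per-stage
  `SeedSequence` keys; equal seeds give bit-identical populations.

## Known limitations

- Training-set accuracy is the stopping criterion by design; it is not an
  estimate of out-of-sample classification performance.
- A marker with zero pooled within-group variance but distinct group means
  (every LP animal identical, every HP animal identical at that locus) is a
  perfect classifier that the stepwise tolerance must exclude, since it
  makes the within matrix exactly singular; at realistic sample sizes this
  configuration essentially never occurs.
- The two-random-component REML path scales cubically and is meant for
  cohorts of a few hundred; the single-GRM path handles thousands.
- Detected-QTL counts at desk scale are not comparable in absolute terms
  with a 57k-SNP genome: with the shrunken genetic map, markers in strong
  LD with a QTL can lie beyond the fixed 250-kb physical window, so scaled
  counts understate full-scale detection. The benchmarks therefore assert
  the *contrast between methods*, not absolute counts.
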