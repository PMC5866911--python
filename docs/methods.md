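# Methods

`heatgwas` quantifies how grow-finish pigs change feeding activity under heat
load and maps the genetic basis of that response. This note documents the
models, the synthetic-data generator, the numerical choices, and what the
test suite does and does not establish.

## Heat-load phenotyping

Hourly heat load is the temperature-humidity index

    THI(°C) = T − (0.55 − 0.0055·RH)·(T − 14.5),

with T the dry-bulb temperature (°C) and RH relative humidity in percent.
The formula is evaluated exactly, with no clamping; RH must lie in [0, 100].
Each calendar day is summarised by its maximum hourly THI and assigned one of
four categories with lower-inclusive boundaries: Normal (< 23.33 °C), Alert
(23.33–26.11), Danger (26.11–28.88), Emergency (≥ 28.88). Days with fewer
than `min_hours` hourly records (default 18 of 24) are dropped rather than
imputed: a day's class depends on its maximum, which partial coverage biases
downward.

Feeding activity is the daily count of RFID pings — 20-second detections of
an ear tag at a feeder slot, at most 86 400/20 = 4320 per day. For each
animal the mean daily count is computed per THI category, expressed as a
deviation from the mean of its sire-breed × sex contemporaries in that
category, and standardized to mean 0 / SD 1 (sample SD, n−1) within the
category. The heat-response traits are differences of these z-scores for
the six ordered category pairs, cooler minus hotter (`Normal-Alert`, …,
`Danger-Emergency`): a positive value means the animal reduced its relative
feeding activity as heat load rose more than its contemporaries did. An
animal contributes a pair only when it has data in both categories; animals
observed in a single category are excluded. Standardization is pooled
across grow-finish groups (contemporary group enters the GWAS model
instead); a per-group alternative would change the deviations only through
group-level mean differences, which the breed-sex centering already absorbs
in balanced designs.

## Whole-genome regression

Each pairwise trait is analysed under

    y = Xβ + Zu + e,

where X holds the intercept and dummy-coded sex, sire breed and contemporary
group (farrowing group × pen, first level of each factor dropped), Z the
column-centered SNP dosages, and e ~ N(0, σ²ₑI). Bayes-C places a
spike-and-slab prior on each marker: u_j = 0 with probability π, otherwise
u_j ~ N(0, σ²ᵤ) with a variance common to all included markers. Bayes-Cπ
additionally samples π under a uniform prior from its Beta(m−k+1, k+1) full
conditional, k being the number of currently included markers.

The Gibbs cycle samples: fixed effects coordinate-wise under flat priors;
each marker's (indicator, effect) pair jointly from the marginal likelihood
with the effect integrated out, visiting markers in a fresh random
permutation each iteration; σ²ᵤ and σ²ₑ from scaled-inverse-chi-square full
conditionals; and π when estimated. The residual vector is maintained
incrementally, and the kernel (numba-compiled) is resumable so Bayes-Cπ
chains can be extended block-wise — after the initial run (default 8100
iterations, 100 burn-in) the chain grows in 8000-iteration blocks until the
split-half difference of the mean sampled π falls below 1e-4, up to a cap.
The long Bayes-C protocol is 41 000 iterations, 1000 burn-in, one state
saved every 40 (1000 saved states); per-trait π flows from the Bayes-Cπ
stage into Bayes-C.

**Priors.** The user supplies variances on the genomic/residual scale
(defaults 0.10 and 0.10, with prior π = 0.98). The genomic prior is
converted to the per-marker effect scale by dividing by
max(1−π, 1/m)·Σⱼ2pⱼ(1−pⱼ) — i.e. it is spread over the markers *expected to
be included*, not over all markers. In Bayes-Cπ this scale tracks the
currently sampled π, floored at the value implied by the prior π. The floor
matters: without it a transient over-inclusion shrinks the prior scale,
σ²ᵤ collapses, the inclusion gate goes neutral and the chain falls into a
dense, non-informative mode. Variance priors use 4 degrees of freedom with
the scale set so the prior mode equals the supplied variance; the degrees of
freedom are a weakly-informative default, and a `fix_variances` switch holds
both components at their priors (the df → ∞ limit), under which the sampler
with π = 0 is exactly Bayesian ridge regression — the core correctness test
compares its posterior means to the closed-form solution.

**A note on π under null data.** With the effect integrated out, a null
marker's Bayes factor has expectation exactly 1, so on a trait with no
genetic signal the included count has no systematic drift and π is only
weakly identified under a uniform prior. π is informative precisely when
signal exists (it concentrates near 1 − k_true/m in simulations with planted
architectures). Null calibration of heritability therefore rests on the
two-stage protocol, not on π alone.

**Summaries.** Per saved state: genomic variance = variance across animals
of Zu (n−1 denominator), and h² = var(Zu)/(var(Zu)+σ²ₑ). The reported
heritability is the posterior mean over all saved states; its uncertainty is
the SD of the final 100 saved states. Genomic variance is decomposed into
non-overlapping 1-Mb windows anchored at genome coordinates (window index =
floor(bp/10⁶)): per saved state, the share of var(Zu) attributable to the
window's markers is computed (states with zero total genomic variance are
skipped and counted), and 100 × the posterior mean share is reported.
Windows above 1% of genomic variance are flagged "reported", above 3% "top";
within maximal runs of adjacent above-threshold windows only the window with
the greatest share is kept for gene-list construction, where "greatest
estimated effect" is read as greatest variance share.

## Marker QC

Markers with minor allele frequency strictly below 5% are removed — MAF
exactly 5% survives, and MAF is computed from non-missing dosages (allele
label swaps do not change the outcome). Markers without a known, unique
(chromosome, position) are removed; both members of a duplicated position
are dropped, because uniqueness is a property of the position and keep-first
rules are input-order-dependent. Remaining missing dosages are filled with
the marker's mean dosage: the sampler accepts continuous dosages, so this
simple fill replaces pedigree-aware imputation without constraining the
model; it shrinks missing genotypes to the population mean and therefore
slightly attenuates effect estimates at high missingness.

## Gene-ontology over-representation

Genes overlapping a reported window by at least one base pair (coordinates
1-based inclusive; BED input converted internally) form the test list,
de-duplicated across windows. For each term with K annotated genes in a
background of N, the observed count k in a list of n genes is compared with
the expectation nK/N; the p-value is the exact two-sided binomial tail
(minimum-likelihood method, `scipy.stats.binomtest`) with success
probability K/N and n trials, Bonferroni-corrected by the number of terms
tested within the same ontology aspect. The background is an explicit
input, by default every gene with at least one annotation — published
expected-count columns are often inconsistent with their stated background
size, so the background is logged rather than guessed. No graph
propagation (true-path rule) is applied.

## Synthetic-data generator

The generator produces a full synthetic study whose ground truth is known:

* **Population** — litters of 6 full sibs cycle through the three sire
  breeds (Duroc, Landrace, Yorkshire); each sire serves 4 litters (~24
  paternal half-sibs), echoing the family structure of a US grow-finish
  herd. Offspring are assigned round-robin to groups and six pens (balanced
  pen sizes); sexes are balanced within litter and shuffled so sex is not
  confounded with pen; two farrowing groups alternate within each group.
* **Genotypes** — founder allele frequencies uniform on the MAF range
  (default 0.1–0.5), Bernoulli founder haplotypes, Mendelian gene-drop with
  independent transmission per locus (no linkage), dosages in {0,1,2}, on a
  default map of 5 chromosomes × 20 Mb with unique positions.
* **Phenotypes** — daily ping counts are negative-binomial with mean
  baseline(breed, sex, category) + permanent animal effect + g·c(category),
  where c is the ordered contrast Normal=0 … Emergency=3 and g is the
  animal's genetic heat-response value built from `n_qtl` planted marker
  effects, rescaled so var(g) hits `var_genetic` exactly. The negative
  binomial reflects the overdispersion visible in real daily feeder counts
  (standard errors exceed Poisson expectation). Default baselines are the
  observed breed × sex × category cell means of a real herd (e.g. Landrace
  gilts fall from 129.3 pings/day in Normal to 62.4 in Emergency, while
  Duroc and Yorkshire activity rises with heat load). Defaults for
  quantities no study reports: dispersion θ = 30 (day-to-day SD ≈ 27 at 134
  pings/day), permanent-animal variance 100 pings²/day², category day
  counts 60/25/20/15, and 10% per-category tag-loss dropout.
* **Calibration** — `target_h2` (default 0.15, inside the 0.02–0.21 range
  typical of these traits) sets `var_genetic` by root-finding on an
  analytic variance decomposition of the standardized pair trait: within
  category c the between-animal variance of deviations is
  var_animal + var_genetic·c² + (day variance)/n_days, and the z-scaling of
  each component gives the genetic share of the pair difference. The
  realized h² recorded in the `TruthSet` is the squared correlation between
  the derived calibration-pair trait and the true genetic values; at
  n ≥ 800 it lands within ±0.1 of the target.

What the generator does **not** emulate: linkage disequilibrium and
recombination hotspots, chip-specific marker panels, feeder-slot
competition, seasonal confounding between weather and group, and
genotype-by-pen interaction. Passing tests therefore establish the
correctness of the estimators under the stated generative model, not
robustness to LD structure or to shared-environment confounding in real
herds.

## Problem sizes and numerical choices

The test suite and the acceptance script run the sampler at reduced scale
chosen to exercise every code path with stable statistics: the ridge
equivalence on a 50 × 100 instance; heritability recovery at n = 800
animals × 2000 markers with 20 QTL and true h² = 0.30 (Bayes-Cπ at 8100+
iterations, then Bayes-C at 10 000), with a permuted-phenotype null;
window decomposition over 10 seeded 300 × 500 runs with one major planted
QTL. Monte-Carlo standard errors use batch means (20 batches). All
randomness flows from explicit seeds; identical configurations reproduce
byte-identical outputs. Degenerate inputs fail loudly: zero-variance
standardization categories, ping dates missing from the day classification,
rank-deficient fixed-effect designs, and non-finite sampler states all
raise with context rather than propagating silently.

## Known limitations

* Mean-dosage filling is not pedigree imputation; at high missingness it
  attenuates marker effects.
* The sampler stores the centered dosage matrix with the posterior samples
  to support window decomposition; at much larger marker counts a
  streaming decomposition would be needed.
* Window shares ignore inter-window covariance, which is near zero for
  unlinked markers but not under strong LD.
* The binomial test treats genes as exchangeable; gene length and marker
  density are not modelled in the background.
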