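# Methods

This note documents the models, defaults and numerical choices behind
`dysbiota`, and what the synthetic cohort does and does not establish.

## Synthetic cohort generator

The generator emulates a single-ward gastroenterology study: 121
hospitalized patients split over five diagnosis groups (CD 15, UC 25,
Infection 23, Tumor 22, Other 36) and 162 non-hospitalized controls.
Per-group age means/SDs, sex ratios and antibiotic-exposure rates follow
the study's host-factor table (e.g. controls: age 45.1 ± 15.5, 64.2%
female, 5.6% on antibiotics). Ages are truncated to [18, 80] because the
emulated cohort is *post*-exclusion (subjects over 80 were removed
upstream); the pipeline's exclusion stage therefore normally fires zero
times on simulated data but is fully functional for real rosters.

**Community model.** Each subject carries a latent community state:
controls are always C1; patients draw C1/C2/C3 with probabilities
conditioned on their antibiotic flag ((0.32, 0.42, 0.26) under
antibiotics, (0.74, 0.22, 0.04) otherwise), reproducing both the
expected state sizes (≈70/36/15 of 121) and the steep antibiotic
gradient across states. Counts are Dirichlet-multinomial: cluster and
hospitalization log-fold-changes are added to the log base profile, the
composition is renormalized (so arbitrary effect sizes keep valid
compositions), a Dirichlet draw with concentration
`overdispersion × composition` (default 50, interindividual variability
comparable to real 16S data) individualizes the subject, and reads are
drawn multinomially at a depth uniform in the configured range
(bacteria 3,000–60,000; fungi 800–30,000, letting a few fungal samples
fall below the 1,000-read rarefaction depth, as happens with real ITS2
libraries).

Default effects: C2 blooms *Escherichia/Shigella* (+4.5 log units) and
other *Enterobacteriaceae* (+4.0) with moderate anaerobe loss; C3 blooms
*Enterococcus* (+6.5) and *Streptococcus* (+3.0) with strong loss of
*Faecalibacterium*, *Roseburia* and *Blautia*; every hospitalized
subject additionally receives a mild disruption (−0.7 on
*Faecalibacterium*/*Roseburia*, +1.0 *Streptococcus*, fungal shift from
*S. cerevisiae* toward *C. albicans*), so healthy-like patients differ
subtly from controls. C2 also carries a small *Enterococcus* increase
(+1.2): without it, compositional renormalization under the
*Enterobacteriaceae* bloom would push C2's *Enterococcus* share *below*
C1's, inverting the intended C3 > C2 ≥ C1 ordering. Magnitudes were
chosen so that (i) PAM recovers exactly three clusters by silhouette on
the default cohort, and (ii) bloom taxa score in the LDA ≈ 4.5–5.7 range
on per-million scaling — the regime the analysis is meant to operate in.

**Inflammation.** CRP (mg/L) is linear in the realized *Enterococcus*
relative abundance: `max(0, 25 + 90·x + N(0, 34))`. The slope/noise pair
was calibrated once so the sample Pearson correlation over 121 patients
averages the configured target 0.463 across seeds (the zero-truncation
and the skewed abundance distribution make the naive closed-form
slope/noise relation inaccurate, hence the Monte-Carlo calibration).
Leukocytes and neutrophils (10⁹/L) are Gaussian around 7.0 and 4.5 with
a +5.0/+4.0 shift in C3. Controls have all three markers missing-coded,
mirroring the study's retrospective collection for inpatients only.

**Randomness.** One stream per cohort, split by subject index
(`SeedSequence(seed, spawn_key=(i,))`): appending subjects never
perturbs earlier subjects' draws, and a fixed seed reproduces the cohort
bit-exactly.

**What the generator does not emulate:** sequencing error, chimeras,
strain-level structure, longitudinal sampling, inter-taxon ecological
correlations beyond compositional closure, or diagnosis-specific
community signatures (cluster membership is diagnosis-independent by
design, matching the study's central observation). Passing recovery
tests on this cohort therefore demonstrates that the estimators detect
the planted structure at realistic noise levels — not that real
communities behave this way.

## Preprocessing

Stage order is fixed: exclusion → rare-OTU filter → rarefaction. The
0.01% filter is interpreted dataset-wide (an OTU is dropped iff its
total count / grand total < 10⁻⁴, strictly), applied before rarefaction.
Rarefaction subsamples without replacement (multivariate hypergeometric,
the mothur convention) to 3,000 (bacteria) / 1,000 (fungi) reads;
shallower samples are dropped and logged. Exclusion uses first-match
accounting so per-rule counts are disjoint and sum to the number
excluded.

## Community statistics

* **Shannon** in natural log.
* **AMOVA** in the distance-based form (pairwise squared Bray-Curtis
  distances partitioned among/within groups), not the
  haplotype-frequency AMOVA of population genetics.
* **PERMANOVA** is sequential (Type-I, order as given, adonis-style) on
  the Gower-centered squared-distance matrix; p-values come from freely
  permuting raw observations, the simplest standard scheme. Reported
  "joint" R² is the sum of term R²s.
* **Dispersion** is measured to the group *medoid* (stays in distance
  space) rather than a PCoA centroid; this is an approximation of the
  centroid-based homogeneity test and is labeled as such.
* All permutation p-values use (hits + 1)/(n_perm + 1); default
  n_perm = 999.

## PAM and silhouette

PAM is the deterministic Kaufman-Rousseeuw BUILD + steepest-descent SWAP
(ties broken by input order, so results are seed-free). Single-exchange
SWAP occasionally converges one or two exchanges short of the optimum on
small instances — the R reference implementation shows the identical
behavior — so instances with at most 20,000 candidate medoid sets are
finished with an exhaustive scan, making desk-scale results provably
optimal; cohort-scale instances (e.g. 283 samples) use pure BUILD+SWAP.
Silhouettes follow the R `cluster` conventions (singletons score 0);
`select_k` scans k = 2..10 and breaks ties toward smaller k.

## Effect sizes

The differential-abundance screen reimplements the spirit of the LDA
effect-size procedure, not a bit-compatible port: Kruskal-Wallis at
α = 0.05 per feature, then 30 bootstrap rounds (2/3 of each class,
drawn from per-class streams keyed by class membership so relabeling
classes only flips the sign) fitting a ridged Fisher discriminant
(ridge 10⁻⁶ × mean feature variance); a feature's effect is the mean of
its share of the projected class-mean difference and its raw class-mean
difference, and the score is log10(1 + mean |effect|) — finite at zero
effect. The subclass (Wilcoxon) stage is omitted because no contrast
here defines subclasses. Multi-class contrasts are scored one-vs-rest.
Scores of strong planted effects land in ≈3–6 on per-million scaling;
they are dataset-bound quantities, not transferable constants.

## PCT forests

Label vectors over the diagnosis tree are weighted by w₀^depth with
w₀ = 0.75 (the customary default of the PCT literature; configurable).
Splits maximize weighted-variance reduction over midpoint thresholds;
binary host factors (sex, antibiotics) are 0/1-encoded, for which the
0.5 threshold is exactly a one-vs-rest split. Growth stops on
homogeneity, fewer than 2·min_leaf samples (min_leaf = 2), or no
positive reduction — a simpler stop than the original F-test pre-pruning
(forests rarely pre-prune). Note the strict positive-reduction stop
means an exact XOR interaction is not split (the classic greedy-tree
limitation). Forests bag 100 trees (bootstrap at original n, per-node
mtry = ⌈√p⌉ feature subsets); per-tree streams derive from
`SeedSequence(seed, spawn_key=(tree,))`. Missing feature values are
mean-imputed before training. Predictions average leaf prototypes and
are hierarchy-consistent by closure (means of consistent vectors are
consistent). Genie3 importance accumulates n × variance-reduction over
each tree's splits, averaged over the forest.

## Evaluation

Per-node precision-recall curves take one point per distinct threshold
(positive iff score ≥ t); AUPRC integrates by linear interpolation over
achievable points, left-anchored at (0, first precision). Linear PR
interpolation is optimistic between sparse points in general; tests pin
the implementation to a dense-threshold numerical oracle at 10⁻⁹. The
pooled curve micro-averages TP/FP over all non-root nodes (the root is
always positive, hence uninformative and excluded). The default protocol
is out-of-bag — natural for bagged ensembles: each sample is scored only
by the trees that did not see it; samples in every bootstrap (rare at
100 trees) are dropped and logged. Stratified k-fold (k = 10) is
available as an alternative. ΔAUPRC is a node-wise difference against
the host-only report from the same protocol and sample set; the four
feature sets are evaluated on the intersection of samples surviving both
rarefactions so the contrast is like-for-like.

## Pipeline

`run_full_analysis` fixes the stage order (exclude → filter → rarefy →
Bray-Curtis → select_k → PAM → split C1 by hospitalization → cluster
characterization → LEfSe contrasts → four-feature-set forests → ΔAUPRC →
Genie3) and derives each stage's seed as `(seed·1009 + stage) mod 2³¹`,
so a rerun with the same config and seed is bit-identical. Clustering
runs on the bacterial distance matrix only (the community types are
bacterial; fungal patterns are described per type). Cluster labels are
assigned by size (largest = C1), matching the convention that the
control-containing cluster is first. Post-hoc group comparisons use
Kruskal-Wallis followed by pairwise Mann-Whitney with Benjamini-Hochberg
correction; printed percentages round half-away-from-zero to one
decimal. Every bundle table carries the seed and a config hash in a
header comment.

## Known limitations

* PR interpolation is linear (documented divergence from the nonlinear
  achievable-precision envelope).
* PERMANOVA permutes raw observations; residual-permutation schemes can
  be better calibrated with strong covariates.
* The dispersion test's medoid approximation slightly understates
  centroid distances for very diffuse groups.
* DAG-shaped label hierarchies, CLARA-style subsampled PAM, cladogram
  output and NMDS ordination are out of scope.
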