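# Methods

This note records the models implemented in `phagetx`, the assumptions they
make, the defaults they ship with, and the design decisions taken where the
methodology admitted more than one reasonable choice.

## Study design and data model

The package analyses a fixed transplantation design: `n_donors` wild mice
(one fecal sample each, day D0, trapped at `n_localities` localities), each
donating a virome filtrate to one recipient per captive strain, plus
non-transplanted controls per strain; captive mice sampled at D-1, D2 and
D7. All tables are plain TSV. Counts are raw mapped-read counts; Bray–Curtis
works on total-sum-scaled proportions (no rarefaction, no length
normalization), and presence/absence means `count ≥ min_reads` with
`min_reads = 2` by default — one mapped read is treated as noise. The same
threshold feeds the Jaccard distance, the transmission filter and the
exclusivity analysis, so "present" means one thing everywhere.

## Community metrics

* **Shannon** uses the natural log over proportions of all nonzero counts;
  richness applies the `min_reads` threshold. A zero-total sample yields
  richness 0 / Shannon 0 with a warning rather than an error.
* **PCoA** double-centers `−½ d²`; axes with eigenvalue > 1e-10 are kept and
  scaled by √eigenvalue; each axis's sign is fixed so its largest-magnitude
  loading is positive (determinism). No Cailliez/Lingoes correction is
  applied; the full signed spectrum is retained internally because the
  dispersion test needs it.
* **PERMANOVA** uses the direct-from-distance pseudo-F
  `(SS_A/(g−1))/(SS_W/(N−g))` with `R² = SS_A/SS_T`, free label
  permutation by default, and the `(1 + #{F* ≥ F})/(1 + m)` p-value
  convention. A `strata` argument permutes within strata (e.g. within
  strain) for designs with repeated measures; the free permutation is the
  default because the published analyses do not state a restriction.
* **PERMDISP** uses group *centroids* (one of the published method's two
  variants) computed in the full PCoA space where negative-eigenvalue axes
  contribute negatively to squared distances; the permutation redistributes
  the distance-to-centroid values across groups. The centroid variant was
  cross-checked against the R reference implementation (`vegan`'s
  dispersion analysis) in the test suite.

## Exact k-mer dissimilarities

Sketch-based estimation is pointless at desk scale, so `Jexact` (set
Jaccard), `probWJ` (weighted Jaccard `1 − Σmin/Σmax`) and the containment
index (`|A∩B|/|A|`, asymmetric) are computed on exact canonical k-mer
multisets (lexicographic min of k-mer and reverse complement; non-ACGT
windows skipped). K-mers are 2-bit-packed into `uint64`, which limits `k`
to odd values in [3, 31]; the default `k = 31` is the common genomic
choice. Both containment directions (donor-in-recipient and
recipient-in-donor) are available because the published direction for the
pre-transplant overlap values is unstated.

## The GLMM engine

A single Laplace-approximated ML engine backs every mixed model: Gamma/log,
binomial/logit (0/1 or successes/trials), negative-binomial NB2/log, and
Gaussian/identity, with any number of crossed random intercepts.

* Inner problem: Newton iteration for the conditional modes `b̂` (damped,
  warm-started; diagonal shortcut for a single factor).
* Marginal likelihood: `log p(y|b̂) − ½b̂'D⁻¹b̂ − ½log|D| − ½log|Z'WZ + D⁻¹|`,
  exact for the Gaussian family.
* Outer problem: L-BFGS-B over (β, log σ_j, log aux) with numeric
  gradients; the Gamma shape, NB size and Gaussian residual SD are profiled
  jointly rather than moment-estimated. Because numeric-gradient L-BFGS-B
  can stall in the flat valley that opens as a variance component
  approaches zero, the optimizer restarts from its incumbent up to twice
  (restarting resets the curvature model); invariance of likelihood-ratio
  statistics to factor-level relabeling was the acceptance check for this.
* Initialization is deterministic: a GLM fit for β and `σ_b = 0.1`, so fits
  are reproducible for given data. ML (never REML) is used throughout, so
  LR tests of nested fixed-effect structures are valid.
* Standard errors come from the finite-difference observed information over
  all outer parameters; 95% Wald CI coverage for the Gamma/log family is
  asserted at 200 replicates in the test suite.
* Post-hoc comparisons are Holm-adjusted Wald tests of estimated marginal
  means on the link scale, with a compact-letter display derived from the
  adjusted decisions. Single-step studentized-range (Tukey) theory does not
  transfer cleanly to GLMM link scales, so Holm — slightly conservative,
  assumption-light — is used instead.

Validation: balanced Gaussian closed form (1e-6), degenerate `σ_b = 0`
against GLM (1e-6), aggregated-vs-expanded binomial equivalence, crossed
variance-component recovery, LR-p uniformity under the null, and agreement
with an independent mixed-model implementation.

## Convergence analysis

Each recipient contributes its dissimilarity to its own donor at each of
D-1/D2/D7; each control contributes its dissimilarity to *every* donor at
each day (the all-donors reading of the comparison set). The Gamma/log GLMM
has crossed random intercepts for captive mouse and donor. The ladder:
combined `day × treatment × strain` (three-way LR test), combined
`day × treatment` (two-way), per-strain `day × treatment`, then per
treatment arm day-only models with pairwise day contrasts. Zero
dissimilarities (only possible for degenerate inputs) are replaced by half
the smallest positive value to stay in the Gamma support, flagged in the
output.

The temperate-fraction time course uses per-sample (temperate reads,
lifestyle-assigned reads) with undetermined-lifestyle contigs excluded from
both numerator and denominator (they are reported separately in the source
analyses; a flag switches to the all-reads denominator). The binomial GLMM
carries an observation-level random intercept for extra-binomial noise plus
the mouse intercept.

## Pooled Fst

Sample pools are summed into one all-donors pool and one pool per
strain × treatment × day. SNP calling (per two-pool comparison) keeps
positions with ≥ `min_cov` (default 10) A/C/G/T coverage in both pools and
exactly two alleles with combined count ≥ `min_minor_count` (default 2);
sub-threshold third alleles are discarded with a flag. These thresholds are
package defaults — the source analyses state none. Read counts stand in
for pool sizes (the Pool-seq convention; true pool sizes are not
recoverable from a sync table). Per SNP:

    π_pool = n/(n−1) · 2p(1−p),  π_W = (π_A + π_B)/2,  π_T from summed counts
    Fst = (π_T − π_W)/π_T, clipped to [0, 1]; π_T = 0 → record dropped

Identical pools clip to 0 (the finite-n correction makes the raw value
negative); reciprocal fixation gives exactly 1. The low/high split uses the
*global* median across the full comparison set (ties to low) so classes are
comparable across strains and days; the binomial GLMM then has a random
intercept per SNP and fixed `strain × treatment × day`.

## Transmission detection

Candidate = present in ≥1 donor, absent in every recipient at D-1, absent
in every control at every day, present in ≥1 recipient at D2 or D7.
Matched = present in a donor together with ≥1 of *that donor's own*
recipients post-transplant (post-transplant days pooled — per-day matching
was rejected because the counted quantity pools D2/D7). Exclusive = matched,
in exactly one donor, and in no captive sample outside that donor's own
recipients. The null reshuffles each candidate's presence vector across the
donor samples independently per permutation (presence totals conserved),
recomputing the matched fraction; the empirical permutation p is the
primary decision statistic, with a per-contig Wilcoxon signed-rank test of
observed-vs-permutation-mean matched indicators reported alongside (the
pairing of the original analysis is ambiguous). The temperate-enrichment
2×2 (group × temperate/not, undetermined counted as not-temperate) uses
Pearson χ² without continuity correction and a Haldane–Anscombe-corrected
odds ratio. Note: the χ² printed in the source for its 2×2 (7.35) is not
reproducible from its printed counts (the standard statistic on those
counts is ≈12.3); the package reports the standard statistic.

## Stability bootstrap

For a phase pair (D-1→D2 or D2→D7), self-dissimilarities pair each captive
mouse with itself across the two days; other-dissimilarities pair it with
every other mouse of the *same strain* (cross-strain pairs excluded). The
contrast `delta = mean(other) − mean(self)` is bootstrapped by resampling
mice with replacement within strain (`n_boot = 2000` default, percentile
95% CI). The mouse — not the dissimilarity pair — is the resampling unit
because pairs sharing a mouse are dependent; resampling pairs would
understate the CI. Pooled and per-strain results are both available.

## Association

Procrustes: both configurations are centered and scaled to unit
sum-of-squares (symmetric scaling), `m² = 1 − (Σ singular values)²` from
the SVD of the cross-product, `correlation = √(1−m²)`, significance by
permuting sample rows of one configuration. The default axis count is the
minimum common number of positive axes. Co-occurrence: per (contig, ASV)
pair, an NB2 GLMM of contig counts on `log1p` ASV relative abundance with
log total phage reads as offset and a mouse random intercept;
Benjamini–Hochberg across pairs. The upstream sparse-regression feature
selection of the original workflow is out of scope; `select_features`
provides deterministic variance/abundance top-k and a validated user list
instead.

## The synthetic-data generator

The generator is the package's test bed: it emulates the design and the
statistical *structure* of the real data with planted, recoverable truth.
Effect sizes are the package's own choices — the source reports no
quantitative effect sizes — selected once so that every downstream property
is decidable at desk scale, and fixed.

Community model: per-mouse carrier sets drawn from five contig classes —
a shared core (occupancy 0.95 wild / 0.70 captive), wild-associated and
captive-associated sets (abundance bonus `wild_captive_effect` in their
matching group, trace-level presence in the other), *patchy* wild contigs
(sparse across donors, occupancy 0.25), and wild individual-specific
contigs private to one donor (abundant in their carrier, +2.5 log). Latent
log-abundances add contig baselines, strain and locality loadings,
per-mouse individual effects (SD 0.9 wild vs 0.6 captive — wild
communities are more individual), small day-to-day noise, mouse-level
latent factors shared with the ASV community at `coupling_strength`, and
planted per-pair contig–ASV couplings. A handful of captive-core contigs
get a +3 log dominance bonus in captive mice, mirroring the single-family
dominance of conventional-facility phageomes and giving captive samples
their lower evenness. Reads are multinomial at Poisson depth (30 000
default), so low-abundance contigs flicker around the presence threshold
exactly like real mapping counts.

Randomness is split into a community-template stream (all contig/ASV-level
parameters, controlled by `seed`) and a cohort stream (everything indexed
by mouse or sample, controlled by `mouse_seed` when given). Replicate
cohorts of the *same* community can therefore be generated, which is what
makes bootstrap-coverage experiments well-posed: the stability contrast is
a property of a community, and its truth can be pinned by one very large
cohort of that community.

Two features exist specifically so the transmission test has a
non-degenerate null: group-mismatched carriers of wild-associated classes
persist at trace abundance (penalty 4.25 log), and the patchy class is
sparse across donors. Together they produce candidate contigs under
`transmission_rate = 0` whose donor presence is variable — the chance
co-occurrence mass that a reshuffling null needs (the real study's neutral
expectation was ~27%, implying exactly this patchiness). Verified operating
point at defaults: type-I rejection 3.5% (200 replicate studies, 999
permutations), candidate recovery 93% and power 100% at
`transmission_rate = 0.5`, wild−captive Shannon gap +0.6, wild
interindividual Bray–Curtis exceeding captive by 0.18.

Transmission is planted only from donor-private contigs into that donor's
own recipients at D2/D7 (at `transmitted_abundance_factor = 0.1` times the
donor relative abundance — low-level engraftment), so controls and
pre-transplant samples are transfer-free by construction, not just with
high probability. Sync tables plant a wild/captive allele-frequency gap
(`snp_divergence = 0.6`) at A/T sites of shared contigs; recipient pools
drift toward donor frequencies post-transplant at a per-strain
`convergence_rate` (default 0.7 for one strain, 0 for the other, mirroring
the strain-dependent subcontig convergence the design anticipates), with
60% of the drift realized by D2 and all of it by D7.

What the generator does *not* emulate: sequence evolution, lysogeny
dynamics (lifestyle is a static label), read-level errors, compositional
biases of library preparation, and any feedback of phages on bacteria.
Passing tests therefore demonstrate the statistics are implemented
correctly and calibrated under the stated model — not that the model
captures every property of real phageome data.

## Problem sizes and numerical choices

Defaults: 1000 contigs, 150 ASVs, 88 samples (10 donors + 26 captive mice
× 3 days), 30 sync contigs × 20 SNPs at 30× pooled coverage. Calibration
and coverage checks in the acceptance suite use 100–500 replicates with
99–999 permutations; the stability coverage run uses 40-mouse-per-strain
replicate cohorts (percentile intervals need moderate cohort sizes) and a
360-mouse reference cohort of the same community template to pin the true
contrast. GLMM convergence tolerance is
1e-8 on the projected gradient with at most 500 outer iterations per
start; inner Newton stops at gradient 1e-9. Permutation p-values can never
be zero (the `+1` convention); all randomness flows through explicit seeds
and `SeedSequence`-derived child streams, so every analysis is exactly
reproducible.

## Known limitations

* The Laplace approximation can bias variance components for binary
  responses with few observations per random-effect level; the Fst model
  mitigates this with many SNPs but very sparse designs should be read
  with care.
* Holm-adjusted Wald contrasts replace single-step Tukey tests; letters may
  occasionally be more conservative than studentized-range letters.
* `k ≤ 31` for k-mer metrics (2-bit packing).
* No BIOM/HDF5 input, no rarefaction, no db-RDA, no multivariate
  differential-abundance GLMs, no sliding-window Fst, no per-SNP
  significance tests — all deliberately out of scope.
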