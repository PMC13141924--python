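# Methods

This note records the statistical model, the defaults and the design
choices made where several defensible options existed. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Design and core model

The data are a partially paired two-tissue cohort: every patient has a
tumor (LUAD) sample and a subset also has a distal noncancerous (NC)
sample. Within-patient correlation is handled throughout by one of two
mechanisms, never by dropping unpaired samples:

1. **Random-intercept LMM.** For a per-sample response `y` (a CLR
   abundance, an alpha index, a module score),
   `y = β0 + β·1[LUAD] + u_patient + ε` is fitted by REML
   (statsmodels `MixedLM`); inference on β is a Wald t test with residual
   degrees of freedom (n − 2), a light small-sample correction over the
   asymptotic z reference. The REML
   optimizer is lbfgs with a powell retry; if neither converges, or the
   random-intercept variance is estimated at the zero boundary, the fit
   falls back to (or provably equals) OLS and is flagged
   (`converged` / `boundary` columns). The fixed t reference rather than
   Satterthwaite/Kenward-Roger degrees of freedom is a deliberate choice;
   its measured null type-I error at the cohort sizes used is ~0.05–0.07
   (see the calibration test), mildly anti-conservative, which BH
   adjustment downstream does not amplify.
2. **Patient-level resampling.** Bootstrap and leave-one-patient-out
   procedures always move whole patients, so paired samples travel
   together and out-of-bag (OOB) predictions are leakage-free.

CLR transform: `ln(x + pc) − mean_features ln(x + pc)` per sample. Genus
marker analyses use `pc = 1` on counts. KO/pathway abundances (float,
PICRUSt2-style) are first converted to per-sample relative abundances and
use `pc =` half the smallest nonzero value, configurable.

Multiplicity: Benjamini–Hochberg step-up, applied across features within a
screen, across indices within an alpha level, and within each direction
separately for module scores.

## Diversity

- Rarefaction: one seeded multivariate-hypergeometric draw per sample to
  the minimum sample depth (single draw by default; multi-draw averaging is
  intentionally out of scope).
- Alpha indices: Sobs; bias-corrected Chao1 `S + F1(F1−1)/(2(F2+1))`; ACE
  with rare-abundance cutoff 10 (falling back to Chao1 when coverage is
  zero); Shannon with natural log; Simpson as the unbiased dominance
  `Σ n(n−1)/(N(N−1))`. Variant choices are fixed and re-checked against
  scikit-bio in the tests.
- Beta distances: Bray–Curtis on relative abundances; binary-Hamming as
  the presence/absence mismatch fraction with **all table features** as
  denominator (literal Hamming on fixed-length vectors; pairwise-union
  denominator available by flag); unweighted and normalized weighted
  UniFrac via scikit-bio. In the pipeline, UniFrac runs on the filtered
  ASV table because the simulated phylogeny is defined over ASVs;
  non-phylogenetic metrics run at genus level.
- PCoA: Gower double-centering and eigendecomposition; negative
  eigenvalues are reported as-is (no Lingoes/Cailliez correction);
  explained variance is taken over positive eigenvalues only.
- PERMANOVA: Anderson's distance-based pseudo-F with
  `p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm)`, default 999 permutations.
  Permutations are **unrestricted** (free relabeling) by design, with the
  caveat that this assumes exchangeability across patients; the measured
  null type-I error under the generator's clustered null is ~0.03–0.05.

## Differential abundance

Prevalence filter (presence = count > 0, pooled over both tissues,
default 15%) → CLR(pc=1) → per-genus LMM → BH q-values; significance at
q < 0.05. This is a CLR-scale linear analog of a compound-Poisson
(Tweedie) mixed model: it preserves the paired design and the sign
semantics of the tissue coefficient while remaining light and exactly
reproducible. Every results file carries the engine note.

## Marker stability selection

Per bootstrap iteration (default 500): draw patients with replacement to
the original patient count; all samples of a drawn patient enter training
(duplicated per draw); OOB = samples of undrawn patients. Features are
CLR(pc=1) (a per-sample map, computed once) and Z-scored with
**training-set statistics only**; zero-variance features are left at 0 for
that iteration. The elastic-net logistic model (mixing 0.5) has its
penalty chosen per iteration by patient-grouped cross-validation (3 folds)
over a 20-point logarithmic grid of inverse penalties, using a
**one-standard-error rule**: the strongest penalty whose mean validation
AUC is within one SE of the best. The parsimony rule matters: choosing the
raw AUC maximizer keeps penalties so weak that nearly every feature is
nonzero and selection frequencies saturate even for noise. "Selected"
means a nonzero coefficient at the chosen penalty.

Selection frequency = times selected / iterations; the panel is frequency
> 0.60. OOB score per sample = mean predicted probability over iterations
where the sample's patient was OOB (median by flag); samples never OOB are
excluded from the OOB ROC with a logged count. The panel is refit once on
all samples with a light ridge penalty (C = 100) so coefficients exist
under separation; that fit supplies the log-odds table and the apparent
ROC. AUC confidence intervals use the DeLong variance (a patient-level
bootstrap CI is available by flag).

A caveat the tests make explicit: under label permutation the **OOB AUC**
is correctly at chance, but the maximum null selection frequency is not
small — a chance association present in a fixed dataset persists under
patient resampling and is then "stably" selected. Selection frequencies
rank features within a dataset; they are not a calibrated error rate.

## Co-occurrence networks

Within each tissue group, nodes are genera passing within-group filters
(default prevalence ≥ 0.2; mean relative abundance threshold 0 —
the filter values are package defaults, recorded in output metadata).
Edges are Spearman correlations on within-group relative abundances with
|ρ| ≥ 0.7 and two-sided p < 0.05 (t approximation), uncorrected by design.
Topology: density `2E/(N(N−1))`, mean degree `2E/N`, mean local clustering
with degree-<2 nodes contributing 0. Centralities: degree/(N−1); harmonic
closeness scaled by (N−1), chosen because conventional closeness is
undefined on disconnected graphs; normalized betweenness with unit
weights. Bootstrap-stable core nodes: per patient-level resample the
network is rebuilt with identical thresholds, nodes are ranked by the mean
of their degree- and closeness-centrality ranks, and a node's stability is
the fraction of iterations it lands in the top k (defaults k = 10,
stability ≥ 0.6, 500 iterations). Betweenness is reported separately as
connector evidence rather than entering the composite rank.

## KO / module functional screening

Per KO: full-data LMM β, then one refit per held-out patient (LOPO).
`β_median` is the median LOPO effect; sign consistency is the fraction of
LOPO effects sharing the sign of `β_median` (defined 0 when the median is
exactly 0). Prevalence is the fraction of samples with raw abundance > 0.
Retention is conjunctive and boundary-inclusive: prevalence ≥ 0.20,
|β_median| ≥ 0.30, sign consistency ≥ 0.90; retained KOs are partitioned
up/down by the sign of `β_median`. Module scores are the **unweighted
mean** CLR abundance over a (module, direction) subset per sample
(abundance weighting by flag); subsets are disjoint by construction, so
opposite-direction significance within one module indicates redistribution
rather than uniform shift. Module-score LMMs are BH-corrected within each
direction; pathway-level screening is CLR + LMM + BH across pathways.

## Synthetic cohort generator

The generator defines the study conditions the tests run under; its
defaults mirror the cohort design (34 patients, each with a LUAD sample,
NC sample with probability 14/34):

- **Counts**: logistic-normal-multinomial. Log-scale genus abundance =
  baseline (N(0, 2)) + patient intercept (σ = 0.5) + planted tissue effect
  + residual noise (σ = 0.6); softmax; multinomial draw with log-normal
  library size (ln-mean 9.2 ≈ 10⁴ reads, ln-SD 0.4).
- **Planted differential genera** (default 7, |logFC| = 1.5, alternating
  signs) draw mid-range baselines (N(0.5, 0.75)) so they are prevalent
  enough to pass the 15% filter — planted effects are meant to be
  recoverable, not hidden by rarity.
- **Rare-expansion taxa** (default 15) are presence/absence-modulated:
  low baseline (N(−3.5, 0.5)), Bernoulli presence 0.10 in NC vs 0.50 in
  LUAD. This makes membership metrics (binary-Hamming, unweighted UniFrac,
  richness indices) separate the groups while abundance-weighted metrics
  need not.
- **ASVs** partition each genus's counts multinomially with fixed
  Dirichlet proportions, so the genus table equals the aggregated ASV
  table exactly.
- **Tree**: random joins with exponential(1)+0.01 branch lengths —
  reproducible, no biological claim.
- **KO tables**: nonnegative sparse genus→KO loadings (5 donor genera per
  KO, gamma(2,1) weights) applied to relative genus abundances with
  log-normal noise (σ = 0.3); planted KOs scaled by exp(±1·1[LUAD]);
  pathways are grouped KO sums; each KO belongs to exactly one of 10 named
  host-interaction modules.

What the generator does **not** emulate: contamination and negative
controls, taxonomy misassignment, overdispersion beyond the
logistic-normal, phylogenetic signal in abundances, and multi-module KOs.
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated model, not robustness to those artifacts.

## Numerical and reproducibility choices

- All randomness flows through `numpy.random.default_rng`; the generator
  keys independent substreams per component, and the pipeline derives
  per-stage seeds from the global seed so skipping stages never shifts
  another stage's stream. The saga solver gets a fixed `random_state`.
- Same config + seed ⇒ byte-identical fixture bundles, result TSVs and
  `report.json`; wall-clock timings go to `run_log.txt`, the one
  intentionally non-deterministic artifact.
- Degenerate inputs: constant responses → β = 0, p = 1; constant vectors
  in Spearman → NaN with a warning; bootstrap resamples missing a class
  are redrawn and logged; empty networks count as no-top-k iterations.
- Test and acceptance problem sizes (e.g. 200 null replicates at 30
  patients, 50 recovery replicates at 60 patients, 100–200 bootstrap
  iterations) are chosen as the smallest cohorts at which the asserted
  properties hold with comfortable Monte-Carlo margins.

## Known limitations

- Wald t inference with residual df is still mildly anti-conservative
  at very small n (no Satterthwaite correction).
- The CLR-LMM differential-abundance engine estimates log-ratio shifts,
  not absolute-abundance Tweedie effects; coefficients are comparable in
  sign and order, not in units, with compound-Poisson models.
- Unrestricted PERMANOVA permutations assume patient exchangeability;
  a within-patient-restricted mode exists but is off by default.
- Selection frequencies are not calibrated error rates (see above).
- UniFrac in the bundled pipeline is ASV-level; genus-level UniFrac would
  require a genus tree, which the bundle does not define.
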