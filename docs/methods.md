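# Methods

This note documents the models, formulas, numerical choices and known
limitations of `oralmicro`. The cohort design throughout is: patients
sampled at three oral sites (GCF, OM, SB) at five timepoints relative to
stem-cell infusion (day 0): P (day −10), A (day 7), E (day 14), E30 (day
44), E75 (day 89). Days are configurable per cohort.

## Depth filtering and SRS normalization

Samples with fewer than `min_reads` total reads (default 3,000) are
excluded before analysis; the filter retains samples *at* the cutoff
(`total >= min_reads`) — the comparator is configurable since conventions
differ — and reports excluded ids rather than dropping them silently.

Scaling with ranked subsampling (SRS) normalizes each retained library to
a common depth `C_min`, which defaults to the minimum retained library
size. Counts are scaled by `C_min/total`; integer parts are kept; the
remaining `C_min − Σ⌊·⌋` units are assigned one each to taxa ranked by
descending fractional part, ties broken by descending scaled value and
then by a seeded random draw. The output therefore sums exactly to `C_min`
and the per-taxon deviation from exact proportionality is bounded by one
count. Alpha diversity is computed on SRS-normalized counts; beta
diversity uses relative abundances of the unnormalized counts (UniFrac is
scale-free, so rarefaction noise would only hurt).

## Diversity indices

Gini-Simpson diversity `D = 1 − Σ pᵢ²`. Longitudinal dynamics are
condensed per patient-site into

* resistance `= D_E / D_P` — fraction of baseline diversity retained
  through the transplant perturbation (1 = no loss);
* resilience `= (D_E30 − D_E) / (day_E30 − day_E)` — signed per-day
  recovery rate after engraftment (negative when diversity keeps falling);
* stability `= D_E30 / D_P` — net retention a month after engraftment.

These ratio/rate forms implement the verbal definitions (resistance
inversely proportional to loss up to E; resilience a rate of gain after E;
stability their combined effect) directly. Bounded alternatives (e.g.
Orwin-Wardle-style indices) can be substituted through the same interface.
A patient-site is evaluable only when P, E and E30 are all present and
`D_P > 0`; resistance alone is still reported when only E30 is missing.
When E30 is missing we do not substitute the last available sample — the
indices are left unevaluable rather than redefined per patient.

## Weighted UniFrac and distance statistics

For relative-abundance vectors `p, q` on a rooted tree with branch lengths
`l_b`, raw weighted UniFrac is `W = Σ_b l_b |P_b − Q_b|` with `P_b` the
fraction of community `p` below branch `b`. The normalized form divides by
`D = Σ_leaves depth_leaf (p_leaf + q_leaf)` and is bounded in [0, 1]; it is
the default because the 0.5 recovery threshold presupposes a bounded
scale (the raw form is available by flag). The implementation builds one
branch × taxon incidence matrix per tree and computes all pairwise
distances by vectorized L1 sums; tests verify it against branch-by-branch
enumeration and against scikit-bio's independent implementation.

PCoA is classical scaling (Gower double-centering, eigendecomposition, via
scikit-bio); axes with non-positive eigenvalues are dropped. PERMANOVA uses
`pseudo-F = (SS_B/(k−1)) / (SS_W/(n−k))` with sums of squares from squared
distances, 999 seeded permutations by default and the add-one p estimator
`(1 + #{F* ≥ F}) / (1 + n_perm)` (unbiased, resolution `1/(n_perm+1)`).
Distance to a group centroid uses the Gower identity
`d²(x, c_G) = mean_g d²(x,g) − (1/2|G|²) Σ_{g,g'} d²(g,g')`, needing no
embedding; small negative values arising from non-Euclidean matrices are
clipped to zero with a warning. Compositional stability is `1 − d(P, E30)`
(the single-interval definition; an average over post-E timepoints would
be a drop-in alternative). Consecutive shift rates divide each adjacent
timepoint pair's distance by its day gap and never bridge a missing
middle timepoint.

## Blooms and antibiotic exposure

A bloom requires relative abundance strictly below 1% at P and at least
30% at a later sampled timepoint of the same patient-site; a maximal run
of consecutive dominant sampled timepoints is a single event dated at its
first timepoint (per-timepoint counting is available by flag). Patient-
sites without a P sample are reported as unevaluable, never silently
scanned.

Antibiotic courses are closed integer-day intervals. Within an analysis
window (default each patient's P day through E30 day), LOT is the size of
the union of covered days and DOT the sum over agents of covered days, so
`LOT ≤ DOT` always, with equality when no two agents overlap. Prophylaxis
agents (default: levofloxacin, sulfamethoxazole-trimethoprim) are excluded
by a configurable deny-list. Classes used by at least `⌈0.2 · n⌉` patients
enter association testing: one 2×2 Fisher test per class (conditional-MLE
odds ratio — the estimate R's `fisher.test` prints, chosen because the
reported odds ratios in this literature are conditional MLEs, not sample
cross-product ratios), Bonferroni-adjusted over the retained classes.

## Survival models

Both hazard models share one Newton-Raphson maximizer of the weighted Cox
partial likelihood in counting-process `(entry, exit]` form with case
weights and the Efron approximation for ties (day-resolution data make
ties likely; Efron is more accurate than Breslow at negligible cost).
Convergence is declared at a step sup-norm below 1e-10; step halving keeps
the likelihood non-decreasing; |log HR| > 20 or a singular information
matrix flags monotone likelihood (separation) and returns the bounded
estimate. Wald 95% CIs come from the inverse observed information.
Zero-variance covariates are reported as HR 1, p 1 rather than an error.

The Fine-Gray model reduces to this likelihood by risk-set expansion:
subjects with a competing event remain at risk after their event time with
inverse-probability-of-censoring weights `w(t) = G(t−)/G(T−)`, `G` the
Kaplan-Meier estimate of the censoring distribution; follow-up after the
competing event is split at subsequent event-of-interest times, which is
sufficient because the partial likelihood only evaluates weights there.
With no competing events all weights are 1 and the fit coincides exactly
with the Cox fit. The coefficient agrees with R's `cmprsk::crr` to 1e-6 on
test fixtures (standard errors differ slightly: ours are model-based,
`crr`'s robust).

Recovery-outcome association uses a landmark design: recovery is
classified at each patient's own E30 day (`d(P, E30) < 0.5`, strict
comparator), and patients whose follow-up ends before that day are
excluded from every fit. Multivariate adjustment enters exactly the
confounders with univariate p < 0.05 (threshold configurable), flags
rank-deficient designs, and reports the primary covariate's adjusted HR.
Kaplan-Meier and Aalen-Johansen estimators come from lifelines.

## Synthetic cohort generator

The generator emulates the processed level of such a study and carries
ground truth for every downstream claim. Defaults are chosen to mirror a
study-sized cohort: 30 patients, 120 genus-level taxa, 3 sites, 5
timepoints, library sizes uniform in [5,000, 60,000].

* **Phylogeny.** `generate_tree` draws a random coalescent topology with
  positive branch lengths. The cohort tree joins two such trees at the
  root: a commensal clade and a smaller opportunist clade (taxa count
  `max(3, n/6)`). Opportunistic dominators and bloomers (enterococci,
  lactobacilli, staphylococci in the real system) are phylogenetically
  coherent and distant from abundant commensals; giving them a basal clade
  of their own makes dysbiotic displacement register on the UniFrac scale
  instead of depending on the accident of a random tree's deepest split.
* **Compositions.** A lognormal rank-abundance backbone with site tilts
  (opportunists down-weighted 10⁻⁴) gives site means; patient baselines
  are Dirichlet draws around them. Each patient-site also owns a
  low-diversity dysbiotic target (2–4 opportunist taxa carry nearly all
  mass). Timepoint compositions are Dirichlet draws around the mixture
  `(1−w)·baseline + w·dysbiotic` with `w = perturbation_depth ×
  (0, 0.6, 1.0)` at P, A, E — the diversity nadir and dispersion maximum
  land at engraftment, the many-unhappy-families structure the dispersion
  statistics assume. After engraftment, recoverers decay back
  (`w = depth × {0.20, 0.08}` at E30/E75) while true non-recoverers
  *remain* in their dysbiotic state (`w = 1.0, 0.9`, not scaled by depth:
  persistence is an alternative stable state, not a dose of the original
  perturbation — though with `perturbation_depth = 0` there is nothing to
  fail to recover from and `w = 0`). Dirichlet noise concentration
  interpolates the same way, lowest at E. With `perturbation_depth = 0`
  and `bloom_rate = 0` all timepoints are exchangeable draws.
* **Blooms.** Poisson(`bloom_rate`, default 2.6 per patient — about the
  event rate such cohorts report) events, at most one per patient-site,
  onset mostly at E; the bloom taxon is rare at baseline (<0.1%, clamped
  below 0.2% in the realized P composition) and raised to
  `bloom_dominance` (default 50%) for the run; injected samples are exempt
  from dropout so truth labels stay well-defined.
* **Antibiotics.** Per-class Bernoulli usage with probabilities mirroring
  reported usage mixes (cephalosporins 0.73, carbapenems 0.63,
  glycopeptides 0.60, penicillins 0.23, quinolones 0.16, macrolides 0.10),
  1–2 courses of Poisson-distributed length inside the P→E30 window, plus
  a universal prophylactic levofloxacin course that exercises the
  deny-list.
* **Outcomes.** Latent cause-specific exponential hazards with
  administrative censoring at 365 days; the event-of-interest hazard
  (baseline 1/400 per day) is multiplied by `exp(log 5)` for true
  non-recoverers.
* **Missingness.** Post-engraftment samples drop out with probability
  `dropout_rate` (default 3%), mimicking samples lost to early death.

What the generator does *not* emulate: sequencing error, chimeras,
taxonomy mis-assignment, compositional correlation between sites of one
patient beyond shared baselines, time-varying antibiotic effects on
compositions (antibiotic exposure and blooms are generated independently,
so exposure-bloom association tests on synthetic data estimate a true
null), and informative censoring. Passing tests therefore certify the
estimators and the plumbing, not biological effect sizes.

## Problem sizes and numerical conventions

Test and acceptance runs use cohorts of 8–100 patients and 40–120 taxa,
200 random tree/abundance pairs for kernel oracles, 1,000 label-shuffling
trials for the PERMANOVA type-I rate, and 100 replicates for estimator
recovery; these sizes give Monte-Carlo error comfortably inside the
asserted bounds. The Cox recovery check uses 300 subjects per arm, where
the sampling sd of the log hazard ratio (≈0.11 at true HR 0.2) makes the
±0.2 recovery band hold in ≳90% of replicates. All simulations are seeded;
identical seeds give byte-identical cohort bundles. Probabilities are
validated to [0, 1], day offsets must increase strictly, and degenerate
inputs (all-zero samples, empty groups, zero-day gaps, zero-variance
covariates, zero Fisher margins) raise named errors or documented
sentinels rather than propagating NaNs.

## Known limitations

* The ecological indices use the plain ratio/rate definitions; when a
  study's supplementary material fixes different formulas, configure or
  substitute accordingly.
* The bounded-UniFrac recovery threshold of 0.5 is meaningful only on the
  normalized kernel; raw-kernel users must supply their own threshold.
* The Fine-Gray implementation assumes independent censoring when
  estimating `G`; covariate-dependent censoring weights are not
  implemented.
* Differential-abundance analysis is out of scope; only the input/output
  contract (per-taxon effect tables) of external tools is accommodated.
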