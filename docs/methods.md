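# Methods

## Scope and data model

The pipeline analyzes a blunt-trauma cohort sampled longitudinally for
circulating inflammatory mediators: per patient, three plasma draws in
the first 24 h post-injury and daily draws through day 7, over a
32-analyte panel (cytokines, chemokines, soluble receptors, cortisol,
NO2-/NO3-, TGF-β1), in pg/mL. Two tidy tables carry everything: a
patients table (demographics, AIS/ISS severity, injury clock time,
outcomes) and a long measurements table
(`patient_id, mediator, time_h, value_pg_ml`). Long format was chosen
over wide because missed draws are the norm in registry data.

## Cohort construction

**Injury-time windows.** Day is 08:00–17:00 and Night 22:00–05:00 (the
shortest annual daylight and night periods at the study's latitude);
everything else is "Neither" and excluded. Both windows are half-open
`[start, end)` so that 17:00 and 05:00 belong to no window and the three
classes partition the 1440-minute dial into 540/420/480 minutes. The
published definition gives no boundary semantics; half-open is the
convention that avoids double assignment.

**Severity filter and matching.** Only patients with ISS > 20
(moderate/severe injury) are match candidates. "Propensity matching" on
age, sex and an ISS cut, with sex matched exactly and ISS reduced to a
hard filter, degenerates to nearest-neighbor matching on age within sex
strata — a logistic propensity score over those covariates is monotone
in age once sex is stratified and ISS filtered — so no fitted model is
involved. The implementation ranks all cross-cohort candidate pairs by
(|Δage|, |ΔISS|, ids) and greedily accepts the best available pair,
rejecting pairs beyond a 10-year age caliper. Ranking pairs globally
(rather than iterating over one cohort) makes the result symmetric under
swapping the two cohorts whenever ages are distinct, and the
deterministic tie-breaking makes runs reproducible.

**Summaries and exact tests.** Continuous variables are reported as
mean ± SEM (sample SD / √n); categorical ones as n (%) with percentages
rounded half-up to one decimal, matching clinical-table style. The 2×2
Fisher test enumerates the full hypergeometric support of the table's
margins and sums the probabilities of all tables no more probable than
the observed one (relative tolerance 1e-7 on the comparison). This
sum-of-small-probabilities convention is the most common two-sided
definition; mid-p and doubling conventions would give different values.

## Mediator statistics

**Two-way ANOVA.** Per mediator, a fixed-effects ANOVA of
log10(concentration + 0.01) on group, time and their interaction.
Because missed draws unbalance the design, Type II sums of squares are
the default (each main effect adjusted for the other, the interaction
for both), computed by model comparison on least-squares fits with
rank-based degrees of freedom; Type III via sum-to-zero contrasts is
available behind a flag. Empty cells abort unless the caller requests a
main-effects-only fit. Repeated measures are deliberately treated as
independent observations — the same simplification as the desktop
two-way ANOVA the original analysis used — so p-values are
anti-conservative for strongly autocorrelated subjects; this is a known
limitation, not a bug. No multiplicity adjustment is applied across the
32 mediators by default (per-mediator reporting); Benjamini–Hochberg is
available behind a flag.

**Nonparametric confirmation.** The published analysis pairs the ANOVA
with a Mann–Whitney U test "to compare the P-values" where data are
non-normal — an ambiguous prescription. It is implemented here as a
per-time-point two-sample U test between groups, pooled per mediator by
the minimum p across time points, and reported alongside the ANOVA as a
confirmation column; this interpretation is flagged as such. The U test
uses midranks, exact enumeration when `n_x·n_y ≤ 400` with no ties, and
a tie- and continuity-corrected normal approximation otherwise. Spearman
correlation is Pearson on midranks with the t-approximation p
(df = n − 2); pairs with missing values are dropped and constant vectors
raise an error rather than propagating NaN.

## DyNA

Within each adjacent window (0–8, 8–16, 16–24 h, half-open), each
patient contributes the mean of their in-window samples per mediator.
Correlations are computed across patients on pairwise-complete values
(≥ 3 pairs per edge) on log10-transformed concentrations by default —
the published account does not state the coefficient or transform, so
Pearson-on-logs is the default with Spearman and raw values behind
flags. An edge requires |r| ≥ 0.7; magnitude thresholding is the default
because inverse co-regulation is biologically meaningful, with
signed-only thresholding available. The density statistic is
E·N / (N(N−1)/2) = 2E/(N−1), where N counts the mediators *evaluable* in
the window (≥ 3 values, non-constant) rather than the panel size, so the
statistic remains comparable across windows with missing assays; the
panel-size convention is a flag. Time origin is hours post-injury, with
a configurable injury-vs-presentation offset.

## DyBN

**Model.** A first-order, homogeneous, linear-Gaussian dynamic Bayesian
network: mediator levels at slice *t+1* are conditioned on a bounded
parent set at slice *t*; self-edges are allowed and reported as feedback
motifs. Transitions from the 8-h early steps and the 24-h daily steps
are pooled into one Markov kernel (per-gap weighting exists behind a
flag but defaults off, since no spacing correction is prescribed for
this design). A change-point / non-homogeneous sampler was deliberately
not used: with ≤ 10 time slices and n = 15 per group there is no support
for inferring regime switches, while bounded-fan-in exact enumeration is
deterministic and testable.

**Transitions.** Samples snap to the nearest grid level within 2 h;
repeats in a slot are averaged. Each patient's consecutive *occupied*
slots form one observation pair; a missed draw breaks the chain (no
imputation across gaps — bridging 8 h → 24 h would fabricate dynamics).
Pairs with any missing variable are dropped (complete case), constant
variables are dropped with a warning, and all columns are z-scored over
the retained pairs, which makes the score exactly invariant to affine
rescaling of any mediator.

**Scoring and inference.** Parent sets are scored by Gaussian BIC,
`−n/2·log(RSS/n) − (|S|+2)/2·log n`, from the least-squares regression
of the child on the parents plus intercept (residual variance floored at
1e-12 to keep noise-free fits finite; collinear sets fall through to the
pseudo-inverse). Since all edges cross slices, the structure decomposes
over children: per child, *every* parent set of size ≤ fan_in (default 3,
≈ 5.5k sets for 32 mediators) is enumerated, so the per-child argmax
composes into the exact global optimum and the softmax of scores is
exact Bayesian model averaging under a uniform structure prior. Edge
posteriors sum the mass of sets containing the parent; "central nodes"
are ranked by total outgoing posterior mass, ties lexicographic. The
per-child regressions reuse a single precomputed Gram matrix; an
independent naive re-enumeration serves as the test oracle.

## Synthetic cohorts

The generator's defaults are the study conditions: 15 + 15 patients,
injury clock times uniform within the correct window per group, the
32-mediator panel, draws at 0/8/16/24/48/.../168 h. Log concentrations
follow `μ_m(t, group) + σ·(Lz)_m` with: per-mediator baselines
log-uniform over e^0–e^7 pg/mL (≈ 1–1100 pg/mL, the span of a multiplex
panel); a post-injury elevation of 1.5 ln-units at t = 0 decaying with a
48-h time constant (the qualitative shape of published trauma
time-courses — peak early, settle within days; not fitted to any
figure); group effects as ln-scale mean shifts active over
`[onset, offset)`; σ = 0.8 ln-units of log-normal noise (right-skewed,
positive — consistent with the need for nonparametric confirmation in
such data); and an optional block correlation structure on the noise
(Cholesky factor of a block-constant correlation matrix), scoped by
group and time window so that, e.g., the night group can be more
co-regulated early. Values are floored at 0.01 pg/mL (assay floor) and
thinned by i.i.d. missingness, default 2% — low enough that the
complete-case DyBN transition stage of a default run retains a usable
pair count, and in the range of observed multiplex dropout. The VAR(1)
panel generator (`x_{t+1} = c·A·x_t + ε`) rejects unstable processes
(`|c|·max row sum ≥ 1`) and exists purely as a DyBN benchmark.

What the generator does **not** emulate: pharmacokinetic realism,
mediator-specific kinetics fitted to data, informative (below-detection)
missingness, within-patient noise autocorrelation, or outcome-coupled
inflammation. Passing tests therefore demonstrate the *statistical
machinery* — calibration, power against planted effects, structure
recovery — under the study's design, not clinical validity on real
cohorts.

## Verification conditions and problem sizes

The test suite and acceptance script use: an exhaustive Fisher sweep
over all 2×2 tables with N ≤ 40 against a combinatorial enumeration
oracle; 100 random unbalanced designs against a least-squares ANOVA
oracle (agreement to 1e-8); 200 null-generator seeds (6400 mediator
tests) for type-I calibration at α = 0.05 within binomial 99% bounds;
100 seeds for power against a 1.0-ln IL-17A night effect; 50 seeds for
DyBN recovery of a planted 6-node, 8-edge VAR(1) network (30 subjects ×
10 time points, coefficient 0.5, unit noise; rows with two parents are
weighted 0.9 so the stability condition `|c|·max row sum < 1` holds) and
for the night-vs-day early-density pattern under night-scoped ρ = 0.9
correlation blocks. These sizes were chosen as the smallest that make
the binomial/recovery bounds meaningful.

## Known limitations

* Independence across repeated measures in the ANOVA (above).
* The published p-value for the matched orthopedic-intervention
  comparison (5/15 vs 2/15) is not reproducible by any standard Fisher
  convention (exact enumeration gives ≈ 0.39); the enumeration is taken
  as authoritative.
* The original DyBN's scoring family, fan-in, discretization and
  normalization are unpublished; the choices here (BIC, fan-in 3,
  grid snapping, z-scoring) are this package's own, so inferred
  topologies are comparable within the package, not with the original
  figures.
* DyNA edge significance is not assessed (no permutation null), and
  network layout/visualization is out of scope.
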