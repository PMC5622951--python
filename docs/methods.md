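# Methods

## The S-score on PM-only arrays

The classical S-score standardizes PM−MM probe-pair differences within a
chip. Modern transcriptome arrays carry perfect-match probes only, so this
package realizes the statistic as a *between-chip per-probe* difference: for
a treated/control pair,

    z_j = (s_T I_{j,T} − s_C I_{j,C}) / ε_j,   ε_j = γ (s_T I_{j,T} + s_C I_{j,C}) + α,
    S_g = Σ_{j∈g} z_j / √(n_g).

This construction preserves the statistic's defining properties: probe-level
relative change, intensity-equalized errors, a per-cluster sum scaled by
√n_g, and standard-normal null behavior. The error model ε linear in summed
intensity with a floor α is the simplest form that equalizes errors under a
multiplicative-plus-additive noise mechanism.

**Parameter fitting.** Scale factors equalize 2%-trimmed mean intensities
(geometric-mean target, so the pair is treated symmetrically). γ is
calibrated so the median |d_j|/s_j over the central 50% of summed
intensities equals 0.6745 (Φ⁻¹(0.75)); medians are used rather than least
squares because differentially expressed probes are outliers under the null
fit. α is then set from the lowest summed-intensity quartile so dim probes
are not over-dispersed: α = max(0, σ̂_low − γ·median(s)_low) with σ̂_low a
MAD-based scale. Degenerate inputs (all-zero chips) raise rather than
returning nonsense.

**Post-hoc standardization.** After summation, the per-pair score vector is
centered on its median and scaled by MAD/0.6745 (on by default,
`standardize=False` to disable). This guarantees the advertised N(0,1) null
even when the error model is misspecified; whether the historical
adaptation standardized post hoc or relied purely on its error model is not
documented, so both behaviors are exposed and standardization is the
default contract. The standardization is median/MAD-based, so it does not
mask genuine signal in a minority of clusters.

**Replicates.** Each treated↔control pair (pair_id) is one biological
replicate and contributes one S-score column; pairs are within sex by
construction and sexes enter as separate columns, collapsed only in the SAM
stage. When one biological replicate corresponds to one pairwise score no
averaging occurs; this reading of "averaged per biological replicate" is
deliberate. Columns are not rescaled by √k after any averaging — variance
consequences are absorbed by SAM's s0 and permutation null.

## One-class SAM

d_i = x̄_i/(se_i + s0) per cluster. s0 is chosen on the grid of se
percentiles {0, 5, …, 100}, minimizing the coefficient of variation of the
d statistic's MAD across 100 se-quantile windows. Windows and candidates use
inverted-CDF quantiles, making the selection exactly invariant to row
duplication; among candidates within 5% of the minimal CV the smallest s0
is taken (on homoscedastic inputs the criterion is flat in s0 — window
spread is MAD(x̄)/(se_w + s0), which any large s0 flattens — so the
tie-break, not the criterion, decides there, and the smallest stabilizer is
the conservative choice). With fewer than two usable windows the median se
is the documented fallback.

The null is sign-flip permutation (a one-class design has no labels to
permute): all 2^k sign patterns are enumerated exactly whenever 2^k ≤
n_perm — with the study's k = 9 replicates and the default n_perm, the 512
patterns are exhaustive and the result is seed-independent. FDR at a
symmetric threshold Δ is π̂₀ · median_b #{|d^b| ≥ Δ} / #{|d| ≥ Δ} (median,
not mean, per SAM convention — robust to heavy-tailed permutations), with
π̂₀ the fraction of observed d inside the null interquartile range divided
by 0.5, capped at 1 to avoid anti-conservative estimates when many true
positives exist. A cluster's q-value is the smallest estimated FDR over all
thresholds at or below its own |d|; Δ is the smallest threshold meeting the
target. Calling is two-sided with one symmetric Δ; SAM's asymmetric cutoffs
are out of scope.

## Gene-level track

Probe intensities are log2(x+1)-transformed, quantile-normalized across
samples, and median-polished per cluster (probe + sample effects; sample
effects returned). This is a deliberate, documented stand-in for vendor
signal generation, not a reimplementation of it: the downstream statistics
are the subject here. The +1 offset and quantile normalization make the
noise-free fold-recovery identity (log2 difference = log2 fold) exact only
in the high-intensity limit with normalization disabled; both are exposed
as arguments.

The 2×2 treatment × sex model uses sum-to-zero (±1) contrasts, under which
each term has one degree of freedom and the Type-III F equals the squared
coefficient t — valid under imbalance (the study's cells differ, e.g. 5 vs
4 pairs). The fit is vectorized across clusters; equality with a
closed-form two-way ANOVA is enforced by test. Residual variances are
moderated by default: a scaled-inverse-χ² prior is fitted by moment
matching on log variances (digamma/trigamma moments; the trigamma inverse
by Newton iteration), giving moderated F with df + d₀ denominator degrees
of freedom; d₀ = ∞ degenerates to complete pooling with a χ²₁ reference.
Ordinary per-cluster ANOVA is available with `moderated=False`; whether the
original gene-level analysis moderated the interaction term is unknown, so
both are first-class.

Significant lists use uncorrected p < 0.01 by design (matching the
gene-level track's convention); cross-method/cross-age comparisons use set
intersection with counts.

## Enrichment

Hypergeometric upper tail P[X ≥ k] per set, universe = all clusters on the
array (the standard array-background convention; the original service's
background is undocumented, so this choice is stated rather than assumed).
One-sided over-representation only; BH adjustment across tested sets. Exact
agreement with combinatorial enumeration is tested for N ≤ 25.

## Behavioral statistics

Endpoints are pure arithmetic: discrimination index
(novel − familiar)/(novel + familiar) with an explicit error when total
interaction time is zero; training-phase exclusion drops animals with
investigation ≤ 10 s (the boundary case is excluded — the retention rule is
strictly "more than 10 s"); LORR duration = recovery − onset with negative
durations rejected; light–dark metrics as percentages of totals.

Factorial ANOVA (2 or 3 factors) uses Type-III sums of squares with
sum-to-zero contrasts via statsmodels; a constant response returns F = 0,
p = 1 for all terms rather than 0/0. SNK post hoc compares ordered means
stepwise: critical difference q(α, r, df_e)·√(MSE/ñ) with studentized-range
quantiles computed numerically (validated against published tables, so any
df is supported) and ñ the harmonic mean cell size (the standard unbalanced
extension; the original stats package's exact variant is undocumented).
The protection rule is enforced structurally: spans are examined widest
first and any pair inside a non-significant span is blocked.

## Assays

qPCR: technical replicates averaged per sample×gene; ΔCt against the
*arithmetic mean* of the reference-gene Cts (equivalently the geometric
mean of reference expressions — the standard multi-reference convention,
since only the reference genes, not the combination rule, are documented);
relative quantity 2^−ΔCt rescaled so the baseline group's mean is exactly 1.
The scheme is invariant to adding a constant to all Cts of one sample.
ELISA: ordinary least-squares line through the standards; back-calculation
(OD − intercept)/slope, divided by protein input to ng/μg. Extrapolation
beyond the standards' OD range is rejected by default. A 4PL curve would be
the natural extension; linear is the documented minimal choice.

## Synthetic data

The probe generator draws cluster baselines log-normally
(log-mean 5.5, log-sd 1 → median ≈ 245 fluorescence units), per-probe
affinities a_j ~ logN(0, 0.5²) fixed across chips, multiplicative noise
exp(N(0, 0.15²)), and additive background N(50, 10²), truncated at zero
(truncation rather than resampling: simpler, and negligible at these
defaults). Differential clusters carry a multiplicative fold change in
ethanol-treated samples. The default design mirrors the study scale — two
ages × two sexes × treatment with 5 male + 4 female pairs per age — and the
default array size (5,000 clusters × 4 probes) is a desk-scale stand-in for
a full transcriptome array; no probe-level noise parameters are published
for the real platform, so the defaults are calibration targets for the
pipeline, not platform estimates.

What the generator does *not* emulate: spatial chip artifacts, batch
effects across hybridization dates, sex-chromosome dosage, probe-sequence
affinity structure, or heavy-tailed outlier probes. Passing tests therefore
demonstrate the pipeline's correctness and calibration under its assumed
noise mechanism, not performance on real arrays.

Behavioral cohorts are Gaussian per group; qPCR wells are
Ct = base_Ct − log2(expression) + N(0, ct_sd) in triplicate; ELISA plates
are linear in concentration with Gaussian OD noise. All generators are
pure functions of (parameters, seed).

## Problem sizes and numerics

Simulation-backed tests run at 2,000–5,000 clusters with 9 replicate pairs;
FDR calibration averages 20 seeds at fold 2 and 5 seeds per fold for the
monotonicity check — sizes chosen as the smallest at which the distributional
claims are sharp (Monte-Carlo error well under the asserted tolerances).
Exact-arithmetic claims are asserted at 1e-10–1e-12; distributional claims
at the tolerances stated in the tests. Ties in SNK means are ordered by the
sort's stable order; SAM thresholds at tied |d| receive identical q-values.

## Known limitations

No CEL/CDF parsing, array QC, or vendor signal reconstruction; no
repeated-measures ANOVA; no 4PL ELISA curves; no amplification-efficiency
correction in qPCR; enrichment ships no term database (bring your own GMT).
The gene-level and S-score tracks share the synthetic generator's noise
model — conclusions about their relative power on real arrays are outside
what the test suite can support.
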