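# Methods

## Scope and data model

The package synthesizes study-level evidence on ALDH2 (rs671, rs674) and
ADH1B (rs1229984, rs1042026) variants and ESCC risk.  The atom of every
computation is an `EffectEstimate` — a log odds ratio θ with standard error
s recovered from the published 95% CI as s = (ln U − ln L)/(2z).  The normal
quantile z is fixed at 1.959964 (not the rounded 1.96) so that converting an
OR/CI to (θ, s) and reconstructing the CI with the same z is an exact
round-trip; at the 2-decimal precision of reported ORs the difference from
1.96 is far below visibility.

The curated evidence base ships as package data: 50 effect records (one per
study × gene × variant × genetic model that reports an OR) and five
analysis-set membership lists.  Membership is *data, not inference*: the
source table reports only study counts per analysis, so the member lists
were fixed by finding the unique subsets whose pooled OR, CI and I²
reproduce the published values, and are validated by exactly that check in
the test suite.  Four ALDH2 rows published without an rs number (Wang 2011,
Yokoyama 2002/2003/2006, Yang 2007) are assigned to rs674, and Yokoyama
2006's unnamed ADH1B row to rs1229984, per those validated memberships.
Two published analyses are *not* reconstructible from printed data — the
8-study allelic rs1229984 analysis (only 5 allelic ORs are printed) and the
gene–smoking interaction table (its stratified inputs are unpublished) — so
they carry no fixture sets; the subgroup/interaction machinery is exercised
on synthetic data instead.

## Pooling and heterogeneity

Fixed-effect pooling uses inverse-variance weights wᵢ = 1/sᵢ²; Cochran's
Q = Σwᵢ(θᵢ − μ̂)² with k − 1 df and I² = max(0, 100(Q − df)/Q).  The
random-effects model is the DerSimonian–Laird moment estimator, τ̂²
truncated at zero, with weights 1/(sᵢ² + τ̂²).  No iterative estimator
(REML, Paule–Mandel) and no Hartung–Knapp adjustment is provided: the DL
estimator reproduces every reconstructible published value exactly, and a
single flavor keeps results unambiguous.  Q, its p-value and I² are always
reported from the fixed-weight pass, also under the random model.

Model choice follows the I² rule: fixed when I² ≤ 50%, random above.  The
published rule leaves I² = 50 unassigned; it is assigned to the fixed side
(moderate heterogeneity per the usual I² bands).  A single estimate passes
through as k = 1 with Q = 0, df = 0.

Subgroup analysis pools each group with per-group model selection.  The
interaction p-value for two groups is the normal z-test on the difference of
pooled log-ORs (the source names no method; this is the standard two-sample
comparison); for more groups it is the Q-between chi-square on G − 1 df.
Meta-regression is single-covariate weighted least squares with the
method-of-moments residual τ² (truncated at zero) and a t reference with
k − 2 df for the slope; the model-based covariance treats study variances
as known.  Knapp–Hartung inflation is deliberately off, matching the plain
WLS convention.

## Publication-bias tests

Begg–Mazumdar: deviates tᵢ = (θᵢ − μ̂_fixed)/√(sᵢ² − se²_fixed) are rank-
correlated with the variances sᵢ².  For k ≤ 6 the two-sided p comes from
the exact permutation distribution of Kendall's S (all k! orderings);
otherwise from the tie-corrected normal approximation with continuity
correction z = (|S| − 1)/√Var(S).  The continuity-corrected test is
conservative for small k — at k = 10 its true type-I error at α = 0.1 is
≈ 0.055 — which is inherent to the discrete statistic, not a defect.  A
study whose variance does not exceed the pooled variance (numerically
possible) gets a floored denominator and a warning.

Egger: OLS of the standardized effect θᵢ/sᵢ on precision 1/sᵢ; the
intercept is the bias statistic, tested two-sided against t with k − 2 df.
The classic unweighted form is used; when the fit is numerically exact the
p-value is defined as 1 for a zero intercept (no evidence of asymmetry) and
0 otherwise, and an all-equal-SE panel (rank-deficient design) is handled
with a pseudoinverse rather than rejected.

Funnel plots are emitted as coordinate tables; nothing is drawn by default.

## Credibility grading

Venice letters: amount of evidence A/B/C at > 1000 / 100–1000 / < 100
summed minor alleles; replication A/B/C at I² < 25 / 25–50 / > 50;
protection from bias A unless observable bias (any Begg/Egger p ≤ 0.1 in
the pipeline) or substantial missing information.  Per-analysis minor-allele
counts are not recoverable from study-level ORs, so the packaged analysis
sets carry their published amount letters as data; for new data a helper
approximates the count as 2·N·MAF and is flagged as approximate.

FPRP uses the "at the observed p" convention: α is the observed two-sided
p-value at z = |μ̂|/s, power = Φ(ln(OR₁)/s − z) is the one-sided probability
of attaining that significance under the alternative OR₁ = 1.5 in the
observed direction (protective effects enter via |μ̂|, i.e. against 1/1.5),
and FPRP = α(1−π)/(α(1−π) + power·π) with π = 0.05.  The computation runs
in log space so overwhelming evidence underflows to FPRP → 0 rather than
0/0.  BFDP uses V = s², prior variance W = (ln 1.5 / 1.959964)² (97.5th
prior percentile at OR 1.5), ABF = √((V+W)/V)·exp(−z²W/(2(V+W))), and
posterior null probability ABF·PO/(ABF·PO + 1) with prior odds PO = 19.
Both conventions were chosen because they reproduce the published
credibility figures; note that the published BFDP for the additive
rs1229984 analysis prints 0.098 while exact recomputation gives 0.0967 —
a one-unit-in-the-last-digit difference attributable to upstream rounding
in the source, and the tolerance used by the corresponding test.

Evidence synthesis: base level Strong if all letters are A, Weak if any is
C, else Moderate; FPRP < 0.2 upgrades one step (never past Strong, never
down); on FPRP/BFDP disagreement FPRP prevails.  Thresholds (0.2, 0.8) and
priors are configuration with these defaults.

## Mendelian randomization

Instruments are pre-harmonized summary statistics (no allele flipping or
palindromic handling — inputs must already refer to the same effect
allele).  Selection keeps p < 5×10⁻⁸ and greedily prunes, in ascending
p-order with snp_id tie-breaks, any SNP within 10 Mb of a kept same-
chromosome SNP at r² ≥ 0.05.

IVW is the fixed-effect form: β̂ = Σ(βXβY/σY²)/Σ(βX²/σY²), algebraically
the inverse-variance pool of per-SNP Wald ratios; a multiplicative
random-error variant (SE inflated by √(Q/df) when Q > df) is optional, off
by default since the source does not state which was used.  The weighted
median interpolates the ratio at cumulative weight 0.5 (weights βX²/σY²)
and takes its SE from a parametric bootstrap with an explicit seed
(default 1000 resamples) — identical seeds give bit-identical SEs.
MR-Egger orients all βX ≥ 0, fits WLS of βY on βX with weights 1/σY²
(residual-based scale, t tests with k − 2 df), and reports the intercept as
average directional pleiotropy with Q over the weighted residuals.

The published MR numbers derive from external biobank summary data that are
not redistributable, so the estimators are validated by simulation and
closed-form oracles instead of by reproducing that table.

## Synthetic-data generators

`gen_meta_studies` draws per-study true log-ORs from Normal(θ, τ²), control
genotypes from Hardy–Weinberg at the given MAF, and case genotypes by
tilting the control distribution with exp(β·dosage), where β = θᵢ/2 for the
additive contrast and β = θᵢ for the allelic one — under HWE this makes the
study's own contrast estimate exactly θᵢ in expectation, so pooled
estimates are directly comparable to the generating θ.  Each study reports
the OR/CI of its 2×2 table with the Haldane–Anscombe 0.5-on-all-cells
correction when any cell is empty (and a warning when expected cell counts
fall below 1).  Defaults mirror the curated evidence base: k = 8, OR 2.5,
τ² = 0.26, MAF 0.25, case/control sizes spanning 37–2098 / 31–2763.

`gen_mr_instruments` draws true instrument effects |Normal(0, σ²_strength)|
— oriented to the exposure-increasing allele, the harmonized convention;
with random signs the Egger βX ≥ 0 orientation would convert directional
pleiotropy into balanced — adds observation noise, and builds outcomes as
causal·γ + pleiotropy + noise with pleiotropy none / balanced
(mean-zero normal) / directional (constant shift).  Defaults: 5 SNPs and a
null causal effect, the published analysis's shape.

What the generators do *not* emulate: covariate confounding, population
stratification, LD beyond a supplied block matrix, genotyping error, or
selective reporting.  Passing the recovery and calibration tests therefore
shows the estimators are correct under their own assumptions, not that
those assumptions hold in any real study.

## Numerical choices and problem sizes

All CIs are 95% with z = 1.959964; no continuity corrections in pooling;
τ² estimates truncated at zero; I² clipped to [0, 100).  Simulation-based
tests use fixed seeds throughout and sizes chosen to keep the whole suite
fast while leaving Monte-Carlo error well inside the asserted bands:
500 replicates for the DL parameter-recovery and CI-coverage checks,
1000 for interaction/IVW/Egger-intercept type-I error, 2000 for the
bias-test null calibration, and k ≤ 10 instances for all closed-form oracle
comparisons (exact permutation for Begg up to k = 6, i.e. 720 orderings).

## Known limitations

Only additive and allelic genetic models are supported (no dominant or
recessive contrasts).  Crude, unadjusted ORs are pooled — as in the source
evidence base — so confounding adjustments differ across member studies.
The amount-of-evidence letter for packaged analyses is stored, not
recomputed.  MR offers no MR-PRESSO, mode-based or robust-regression
estimators and no reference-panel clumping.
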