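# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `pafskit`, in the order the two workflows run.

## Dose-response model and EC50

Raw well readings are transformed to relative response by dividing each
replicate column by its own zero-dose (untreated) reading, then averaged
per dose over the finite replicates; the mean response at dose 0 is 1 by
construction. The modified Hill model

R(D) = m·Dⁿ/(kⁿ+Dⁿ), with k, m ≥ 0 and n ≤ 0,

is evaluated internally as m/(1+(D/k)^(−n)), which is finite at D = 0
(limit m) and stable at extreme doses. Fitting uses bounded
trust-region least squares (`scipy.optimize.least_squares`, method
`trf`) from the initial guess (1000 nM, 1, −1), parameter tolerance
1e−10, at most 10,000 function evaluations. Dose-0 points are excluded
from the fitted set: Dⁿ is singular at D = 0 for n < 0, and the
zero-dose wells already serve as the normalization reference. Optimizer
failure is reported as `converged=False`, never an exception. Responses
are not clipped to [0, 1] before fitting; m above 1 is allowed by the
bounds.

EC50 is the closed form k·(2m−1)^(−1/n), the exact solution of
R(D) = 0.5. When 2m−1 ≤ 0 the curve never reaches half-maximal response
and the EC50 is *not reached*; a numerically flat fit (n > −1e−6) is
treated the same way, since the crossing would be an artifact of a
degenerate parameter ridge. Not-reached EC50s serialize as the literal
`NA` with a reason string, never infinity. Only this absolute
definition (half of the untreated reference) is implemented; a
"relative EC50" (half of the fitted span) is a distinct quantity that
the API deliberately does not conflate with it.

Responder classification uses a strict cutoff: responder ⇔ EC50 reached
and < 1000 nM. The boundary value 1000 nM classifies as non-responder;
the underlying rule is stated with strict inequalities on both sides,
so the boundary assignment is a package convention, documented here.

In `ec50_shift_profile` (EC50 of drug A re-fitted at each fixed dose of
drug B), each slice is re-normalized to its own a = 0 response, and a
fitted EC50 that falls beyond the tested dose range of drug A is
reported as `NA` rather than extrapolated — flat slices otherwise
produce arbitrarily large, meaningless crossings.

## Loewe additivity and synergy scores

The equivalent-dose transform converts a dose of drug A into the dose
of drug B with the same single-agent response and evaluates B's curve
at the summed B-scale dose. The transform is asymmetric (A is converted
into B); this direction is the default, and a `symmetrize` flag averages
both directions for users who want a direction-free score. Two edge
cases are made explicit rather than silent: when drug B cannot reach
drug A's response level (R_a(a) ≥ m_b) the equivalent dose is clamped
to 0 and flagged; when R_a(a) → 0 no finite dose of B is equivalent and
the expected response is B's high-dose limit, 0.

`synergy_matrix` estimates both single-agent fits from the grid's own
b = 0 and a = 0 margins (injectable externally), so the operation is
self-contained; a margin whose fit fails raises an error naming the
drug. Because the margins are noise-free images of the single-agent
curves in the synthetic forward model, additive grids score 0 to within
optimizer precision (≈1e−12 observed, 1e−9 contracted).

## Synthetic viability data

The plate generator emulates the assay geometry: 11 doses in a 3-fold
dilution series from a 10 µM top dose plus a zero-dose reference
column, four replicate wells per dose. Treated readings are
reference_level·(R(D)+ε) with additive Gaussian ε on the relative
response scale (the noise model is a package choice; replicate noise
magnitude is a free simulation parameter, defaulting to 2% where the
workflows need a realistic value). Untreated wells read the full
reference level: they define 100% viability, while m is the fitted
dose→0 intercept of the treated response — this is what makes m
identifiable from normalized data. Readings are clipped at 0 from
below, as raw fluorescence cannot be negative.

The synthetic patient cohort (`gen_patient_cohort`) is a stand-in for a
per-patient clinical table that is not distributed with the package. It
fixes the census structure — 44 patients, 18 responders and 26
non-responders; a 20-sample phosphoproteome subset of 9 responders and
11 non-responders; subset risk groups 9/8/3 (45/40/15%) — and
randomizes everything within strata under the seed. True EC50s are
drawn log-uniformly on [50, 600] nM (responders) and [1800, 20000] nM
(non-responders): well separated from the 1 µM cutoff, as the
underlying per-patient values are, so that 2% replicate noise cannot
flip a classification. What the recomputed censuses demonstrate is that
normalization → fit → closed-form EC50 → cutoff reproduces the correct
calls end to end, not that the cohort composition is itself predicted.

## Phosphosite table model

`PhosphoSiteTable` keeps a sites × samples value matrix (raw positive
intensities or log2, flagged), per-site metadata (protein, position,
residue ∈ {S, T, Y}, localization probability, ±6 aa sequence window)
and per-sample metadata (TMT batch, condition, optional group and
fraction index 1–6). Fractions are ordinal indices; mapping them to
compartment names is annotation, not computation. The synthetic
generator plants exactly round(frac_regulated·n_sites) effects of
±effect_size log2 units, per-(site, batch) offsets ~N(0, batch_sd), and
residuals ~N(0, residual_sd); defaults (4 samples per group, effect 1.5,
residual SD 0.3, batch SD 0.5) are the conditions the differential
contract is stated under. Localization probabilities are a mixture —
an exact count of sites uniform below 0.75, the rest Beta-concentrated
near 1 rescaled to [0.75, 1] — so the class-I filter is exercised on
both sides of its inclusive threshold. The generator does not simulate
MS acquisition, peptide-level identification, isotope impurity or
intensity-dependent missingness; only an optional
missing-completely-at-random mask. Conclusions from passing tests are
therefore about the statistical pipeline, not about raw-data artifacts.

## Variance stabilization

The per-batch transform is a two-step estimator of the usual
affine + generalized-log calibration h(x) = glog2(a_s + b_s·x):

1. per sample, b_s = MAD_pool/MAD_s and a_s = med_pool − b_s·med_s
   (median/MAD are robust to the minority of regulated sites);
2. one glog2 offset c per batch, chosen on a 25-point geometric grid
   between the 0.5% and 50% quantiles of the calibrated values to
   minimize the |slope| of the per-site SD-versus-mean regression.

glog2(u) = log2((u+√(u²+c²))/2) → log2(u) for u ≫ c, so high-intensity
values land on an ordinary log2 scale. The contract is the
variance-stabilization *property* (flat SD-vs-mean trend, scale
invariance between samples, monotonicity), verified by regression
oracles in the tests — not bit-identity with any particular
maximum-likelihood implementation. A known cost: the glog compresses
the lowest-intensity tail, which slightly attenuates fold changes (and
hence sensitivity) for dim sites.

## Batch correction

Per site, an additive linear model with condition covariates and
sum-to-zero batch contrasts is fitted by least squares and the batch
component subtracted — the removeBatchEffect model; one test
cross-checks numerically against the Bioconductor implementation via
Rscript. A single batch is an identity map. A batch perfectly
confounded with condition raises an error instead of silently absorbing
the treatment effect. Sites with missing values are corrected row-wise
when the reduced design remains full rank, otherwise left uncorrected.
On balanced designs the batch terms are orthogonal to the contrast, so
correction leaves per-site group differences unchanged (tested to
1e−9).

## Differential test

Per site with groups of ≥ 2 finite values: Δ = mean difference (log2
fold change), s = pooled two-sample standard error by default (Student;
Welch with Satterthwaite df via `equal_var=False`), ordinary t = Δ/s
giving the two-sided p-value that is BH-adjusted across tested sites,
and the moderated statistic t′ = Δ/(s + s0) with s0 = 0.1 log2 units.
A site is significant when q < fdr **and** |t′| ≥ t_crit(df, fdr) — the
analytic rendering of the hyperbolic volcano boundary: as s → 0 the
second condition imposes the fold-change floor |Δ| ≥ t_crit·s0 that s0
exists to provide, while at s0 = 0 it is implied by q < fdr (q ≥ p), so
the test reduces exactly to the plain two-sample t-test. This design
was chosen over referring t′ itself to the t distribution, which is so
conservative at n = 4 that realistic planted effects (1.5 log2 units at
SD 0.3) drop below 50% recall; the measured operating point of the
default test is ≈96% sensitivity with an empirical false-discovery
proportion around 3% at the 5% target. A permutation mode
(`permute_fdr=True`) replaces analytic p-values with sample-label
permutation p-values of |t′| pooled across sites (250 permutations by
default, seeded); its achievable p floor is limited by the planted
sites' own relabelings, so it is a ranking-faithful but conservative
alternative. Degenerate sites: zero variance in both groups with Δ = 0
are untested; with Δ ≠ 0 and s0 > 0 the moderated statistic is finite
and the ordinary-t p-value is 0 in the limit, so the site is tested.
Missing-value imputation is not applied by default (complete-case
testing); the spatial-proteomics workflows it would serve are exercised
here with complete synthetic data.

## Fraction profiles and translocation

Scaled profiles divide each protein's per-fraction mean intensity by
its maximum across fractions (rows in [0, 1], max exactly 1); proteins
with no finite intensities are dropped with a warning. Translocation
calls intersect {significant down in the depleted fraction} with
{significant up in the accumulated fraction} under the same contrast at
the protein level, and report the three set sizes for overlap diagrams.
Coordination is the point: drift in a single fraction never produces a
call.

## Annotation statistics

- **PAFS**: significant sites joined to functional scores on (protein
  accession, position) after stripping isoform suffixes (`-N`), sorted
  by descending score; selection is strictly greater than the 0.6
  threshold, and unscored significant sites are counted and warned
  about, not silently dropped. Output order is invariant to input row
  order (deterministic tie-breaks on protein/position).
- **KSEA**: z = (s̄ − p̄)·√m/δ per kinase with m ≥ 3 measured substrates
  by default, where the background (p̄, δ, sample SD with ddof = 1) is
  *all* measured sites, not only significant ones; two-sided normal p.
  Shuffled substrate assignments give z with mean ≈ 0 and SD ≈ 1.
- **Motifs**: per (flank position −6..+6 except 0, residue) one
  upper-tail hypergeometric p of the foreground count given the
  background composition; `_` padding at sequence ends contributes no
  counts; fixed α = 0.01 by default matching logo-tool convention, BH
  optional. Rows are emitted for residues observed in the foreground at
  that position. The default foreground is the regulated sites, the
  background all quantified class-I sites.
- **ORA**: upper-tail hypergeometric per gene set with BH across sets;
  exact against brute-force enumeration on small universes.
- **Overlap coefficient** (Szymkiewicz–Simpson): |A∩B|/min(|A|,|B|);
  two empty sets are an error, one empty set returns 0.

## Pipeline, I/O and determinism

The orchestrated order is: class-I filter → per-batch variance
stabilization → batch correction → differential test → annotation. The
filter runs first by default so calibration sees only confidently
localized sites (switchable via `filter_first=False`, since the
evidence for either order is not decisive). All writers emit '.'
decimals at 6 significant digits regardless of locale, with a
`# seed=...` header; identical config + seed produces byte-identical
TSV outputs. Any stage error aborts the run naming the stage and
removes partial outputs. Readers validate their dialects and fail with
the offending header or row; zero intensities are read as missing (a
zero reporter intensity is below quantification, and the log scale
requires positivity), with a warning.

## Problem sizes

Tests and the acceptance script run at desk scale, chosen so the whole
suite completes in well under a minute while keeping every stochastic
check comfortably powered: 1,000 random draws for the EC50 closed-form
check, 100 noisy plates for EC50 error, 50 × 400-site null tables and
one 1,000-site planted table for differential calibration, 1,000
shuffled kinases over 2,000 sites for the KSEA null, 500 proteins for
translocation. These sizes are package choices and scale up linearly.

## Known limitations

- The significance machinery approximates a permutation-calibrated
  hyperbolic cutoff analytically; exact agreement with any specific
  permutation implementation is not claimed.
- The VSN estimator trades maximum-likelihood efficiency for
  robustness and transparency; its low-intensity compression slightly
  reduces power for dim sites.
- The synthetic cohort and annotation tables (functional scores,
  kinase-substrate map) are structural stand-ins; analyses of real
  cohorts must supply the corresponding measured tables.
- Relative-vs-absolute EC50 variants, Bliss/ZIP/HSA synergy models,
  three-drug combinations, peptide-to-site roll-up and protein-level
  quantification are out of scope.
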