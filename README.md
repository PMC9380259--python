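# pafskit

Dose-response modelling, Loewe-additivity synergy scoring and
phosphoproteomics functional-site analysis (PAFS) for drug-response
studies — the analytical stack used to characterize how AML cells
respond to the nuclear-export inhibitor selinexor, packaged as a tested,
reusable Python library.

It is written for computational biologists who have (a) cell-viability
plate data for single drugs or two-drug combination grids, and/or (b)
multi-batch TMT-style phosphosite quantification tables, and want to go
from raw readings to responder calls, synergy maps, differentially
regulated phosphosites, prioritized functional sites, inferred kinase
activities and subcellular translocation calls — with every stage
testable against synthetic data with known ground truth.

## The models

**Dose response.** Viability relative to untreated wells is fitted to a
modified Hill model

    R(D) = m · Dⁿ / (kⁿ + Dⁿ),   n ≤ 0

with intercept `m` (the dose→0 limit), steepness `n` and curvature `k`
(nM), by bounded least squares from the initial guess (k, m, n) =
(1000 nM, 1, −1). Solving R = 0.5 gives the closed-form

    EC50 = k · (2m − 1)^(−1/n)

which is *not reached* when the fitted curve never drops to half the
untreated response (m ≤ 0.5). A sample is a **responder** when its EC50
is finite and strictly below 1 µM.

**Loewe synergy.** For drugs *a* and *b* with single-agent Hill fits
(k_a, m_a, p) and (k_b, m_b, q), the dose of *b* equivalent to a dose of
*a* is

    b̂(a) = [ m_a aᵖ k_b^q / (k_aᵖ m_b − m_a aᵖ + m_b aᵖ) ]^(1/q)

and the Loewe-expected combination response is R_b(b + b̂(a)). The
synergy score S_ab = expected − measured is positive for superadditivity
(synergy) and negative for antagonism; an additive grid scores 0.

**Differential phosphosites.** Class-I sites (localization probability
≥ 0.75) are variance-stabilized per TMT batch (affine calibration +
generalized log2), batch-corrected with an additive per-site linear
model, and tested per site with a two-sided t-test (BH-FDR < 0.05)
subject to an s0 = 0.1 hyperbolic fold-change boundary via the moderated
statistic t′ = Δ/(s + s0). Significant sites are ranked by a functional
score in [0, 1], selecting score > 0.6 (PAFS); kinase activities follow
z = (s̄ − p̄)·√m / δ against the all-site background (KSEA); motif,
gene-set and overlap-coefficient statistics round out the annotation.

## Worked example

```python
from pafskit.dose_response import classify_responder, compute_ec50, fit_hill, normalize_plate
from pafskit.simulate import GroundTruthCurve, gen_viability_plate

truth = GroundTruthCurve(k=420.0, m=1.0, n=-1.3, noise_sd=0.02)
plate = gen_viability_plate(truth, seed=11, sample_id="AML01", drug="selinexor")
fit = fit_hill(*normalize_plate(plate))
ec50 = compute_ec50(fit)
print(f"{fit.k:.1f}  {fit.m:.3f}  {fit.n:.3f}  {ec50.serialize()}  "
      f"{classify_responder('AML01', ec50).responder}")
```

prints

```
418.7  0.987  -1.267  410.366  True
```

The fitted parameters recover the generating curve to within the 2%
replicate noise, the closed-form EC50 (410 nM) sits close to the true
420 nM, and EC50 < 1000 nM classifies the sample as a selinexor
responder. The `examples/` directory has one narrative script per
capability (dose response, synergy grids, differential testing,
functional scoring/KSEA, translocation), each printing the numbers it
computes and what they mean.

A thin CLI mirrors the two workflows
(`pafskit simulate | fit-dose-response | synergy | phospho-diff | pafs |
ksea | motif | translocate | run`); `pafskit run --config cfg.yaml`
drives the full pipeline from a YAML config and writes seed-stamped,
byte-reproducible TSV outputs plus a structured run log.

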