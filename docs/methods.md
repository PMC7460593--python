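# Methods

This note documents the models, defaults and numerical choices behind
`protonrbe`, and what the synthetic data do and do not emulate.

## Study design being modelled

The pipeline mirrors an in vitro comparison of two clinical proton
delivery modes — pencil beam scanning (PBS, active) and double scattering
(DS, passive) — on a single adherent tumour cell line. Samples sit at two
depths along the percentage depth-dose curve: 2 cm (entrance plateau,
"position 1") and 23.6 cm (Bragg peak, "position 2") in water. Doses of
1, 3 and 5 Gy (plus unirradiated controls) are delivered in two
independent experimental runs with six-well plates per condition; a Co-60
gamma source irradiated at 1–5 Gy provides the reference survival curve.
The plating efficiency of the cell line is 30%.

## Synthetic data generators

The generators' defaults *are* these study conditions; they exist so the
analysis chain can be exercised and calibrated end to end.

**Colony counts.** Expected colonies per well are
`seeded × PE × exp(−αD − βD²)`; observed counts are Poisson (counting
statistics) clipped at the seeded number. The plating efficiency `PE` is
per run, with an optional log-normal inter-run jitter (off by default).
Seeding is dose-adaptive by default (330/500/1500/5000 cells at
0/1/3/5 Gy) so expected counts stay near 100 colonies per well at every
dose, the countable regime the assay targets. Generative (α, β) per
condition default to the published fit values of the study being
emulated, bundled in `protonrbe.reference`.

**Endpoint measurements.** Total apoptosis (%, 24/48/96 h) is binomial
over 1000 scored cells with probability `control + slope·D` (defaults 5%
+ 2%/Gy); %BNC-with-MN is binomial over 400 binucleated cells with a
linear-quadratic dose response; micronuclei per cell are Poisson with a
linear-quadratic mean (read out at 3 and 5 Gy, where induction clears the
control level); γH2AX foci per nucleus are Poisson with mean
`0.5 + 30·D`, giving ~25–35 foci at 1 Gy — the double-strand-break yield
the assay is used at — read out at 1 Gy only. Replicate values are
per-population means (or percentages), two replicates per run.

**LET spectra.** Per species, 50 log-normally scattered LET lines with
log-normal dose weights; a single multiplicative rescale of the LET axis
pins the dose average exactly to the configured per-species target. The
per-species dose shares are not published; `solve_dose_shares` fixes
small shares for the rare species (positrons 2×10⁻³ down to alphas 10⁻⁴
of dose) and solves the proton/electron split in closed form so the
pooled "all particles" dose average matches its published value.
Infeasible targets raise. These spectra reproduce first moments only —
they are *not* Monte-Carlo spectral shapes.

**Neutron spectra.** Class membership (≤1, 1–50, ≥50 MeV) is multinomial
with configured fractions; energies are log-uniform within per-class
sampling ranges. The lowest class samples (10⁻⁹, 10⁻³) MeV by default:
beam-line neutron fields are overwhelmingly thermalized at the sample
position, sitting on the w_R = 2.5 plateau, and only the class fractions
are externally constrained. The ranges are configurable for harder
spectra.

Not emulated anywhere: cell-cycle structure, repair kinetics, dose-rate
effects, imaging/segmentation artefacts, well-to-well plating
inhomogeneity beyond Poisson noise, and true transport-code spectra.
Passing tests therefore demonstrate correctness and calibration of the
*analysis* under the stated noise families, not fidelity of real assays
to those families.

## Survival fitting

Fitting is weighted least squares of `y = −ln(mean SF)` on `(D, D²)`,
linear in (α, β), with non-negativity enforced by non-negative least
squares. Two variance models:

* **Counting statistics (default for colony data).** With surviving
  fractions formed as `(colonies/seeded)/PE` and PE from the same
  condition's controls, `var(y) ≈ 1/(total colonies at D) +
  1/(total control colonies)`. The 0 Gy observations are excluded here:
  their log-SF is identically 0 against the very controls that define PE,
  so they carry no information beyond the control term. In simulations at
  all five bundled truth sets (2 runs × 6 wells) this gives 2-standard-
  error coverage of 95.8–96.2% and parameter bias below 0.5%.
* **Replicate SDs.** `var(y) = (SD/(mean·√n))²`, for inputs that are
  summary means only (e.g. digitized survival curves). With few dose
  points the noisy variance estimates make these SEs anti-conservative
  (~80% two-SE coverage in the same simulation), which is why it is the
  fallback, not the default.

Parameter covariance is `(XᵀWX)⁻¹` with W the inverse observation
variances; when a parameter sits at the zero boundary the SE comes from
the unconstrained curvature and is approximate. R² is reported on the
fitting scale (log-survival). An untransformed-scale nonlinear fit
(`scale="linear"`, sigma = SD/√n) is available for sensitivity checks.
Observations with mean SF ≤ 0 cannot enter a log fit and are dropped with
a warning.

## Isoeffect dose and RBE

The isoeffect dose uses the cancellation-free root
`D = 2L/(α + √(α² + 4βL))`, `L = ln(1/S)`, valid down to β = 0. RBE at
survival level S (default 0.5) is the ratio of reference to test
isoeffect doses. Its standard error is first-order (delta-method)
propagation through both fits, treated as independent, with central
finite-difference gradients (relative step 10⁻⁶); each fit's full (α, β)
covariance is used when available, else the published standard errors
with zero covariance. Against a 10⁴-draw parametric bootstrap on the
bundled fit configurations the delta SE agrees within ~6–11% relative.

## Two-stage comparison procedure

The variance-equality gate is an F-test with the larger sample variance
in the numerator and a two-sided p-value (doubled upper tail); the
criterion "F below 0.05" is implemented as the F-test's *p-value* below
0.05 — a raw F statistic below 0.05 would be meaningless as an
equality-of-variance criterion. Below the gate, Welch's t-test; at or
above it, the pooled Student t-test; both two-tailed with significance at
p < 0.05 per comparison. Sample (n−1) standard deviations are used
throughout. No multiplicity correction is applied by default, matching
the per-comparison convention of the studies this mirrors; `holm_adjust`
is available. Empirical type-I error of the full procedure at n = 6 per
group is ~0.046 over 10⁴ null simulations. Survival comparisons default
to run-level replicate means (the two runs are the independent units);
well-level pooling is available.

## Beam model

A pedagogical analytic stand-in, not a transport calculation:
Bragg–Kleeman range `R = aE^p` with water constants `a = 0.0022`,
`p = 1.77` (chosen to pair 190.6 MeV with the 23.9 g/cm² clinical range);
inverse relation for residual energy at depth; Bethe electronic stopping
power in water (I = 75 eV, no shell/density corrections, validity window
1–250 MeV) as an *unrestricted-LET* proxy; depth dose from per-bin CSDA
energy loss convolved with Gaussian range straggling
(σ = 0.012·R^0.935 cm by default). No nuclear interactions, secondary
buildup, lateral profiles or scattering-nozzle physics. Because the LET
proxy is unrestricted stopping power while transport codes score LET with
their own delta-ray conventions, the model is used for *contrasts* (the
peak/plateau LET ratio exceeds 5) rather than absolute reproduction of
scored LET tables.

## Classification and weighting conventions

Neutron classes are half-open: [0, 1), [1, 50), [50, ∞) MeV; printed
summaries of this kind ("≤1 / 1–50 / ≥50") are ambiguous at the
boundaries, and boundary atoms here go to the lower class. w_R(E) is the
ICRP-103 continuous function (three log-Gaussian branches, continuous at
1 and 50 MeV to <0.01, bounded in [2.5, 20.7]).

## Degenerate inputs and tie-breaks

Zero-colony dosed wells yield SF = 0 and are retained (they only drop
from a log-scale fit, with a warning). A spectrum with all-zero dose
weights is representable but has no dose average (error on use). One
zero-variance group sends the comparison to the Welch branch (F = ∞);
two zero-variance groups are an error. Doses between configured seeding
keys fall back to the next lower key.

## Problem sizes in tests

Simulation-based checks use sizes chosen to make Monte-Carlo error small
relative to the tolerance being asserted: 500 replicates per truth set
for parameter-recovery coverage, 10⁴ null simulations for the type-I
calibration, 10⁵ samples for distributional checks, 10⁴ wells for
mean-structure convergence (2% tolerance).

## Known limitations

Published parameter sets are rounded to two decimals, so RBE values
recomputed from them differ from values computed from unrounded fits by a
few percent — agreement is therefore assessed within the published
standard errors. The delta-method RBE SE ignores any α–β covariance when
only marginal SEs are known, which tends to overstate the SE (α̂ and β̂
are negatively correlated in LQ fits). The F-test gate assumes
normality; with n = 2 run-level replicates the t-tests have a single
degree of freedom and little power, which faithfully reflects the design
it models.
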