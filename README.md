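# protonrbe

A reusable, tested analysis pipeline for in vitro radiobiological
comparisons of **passive (double scattering, DS)** and **active (pencil
beam scanning, PBS)** proton beam delivery. It reproduces the full
computational chain of such a study — from raw colony counts and
Monte-Carlo-style particle spectra to relative biological effectiveness
(RBE) with propagated uncertainties — and ships a synthetic-data module
that emulates every input, so the whole chain runs and is testable
without any external data.

Intended users: radiobiologists and medical physicists analysing
clonogenic survival and cytogenetic endpoint data from proton beam
experiments, and methodologists who want a calibrated sandbox for the
statistics involved.

## What it computes

**Linear-quadratic survival.** The clonogenic surviving fraction at
absorbed dose $D$ (Gy) is modelled as

$$S(D) = e^{-\alpha D - \beta D^2},$$

fitted by weighted least squares on the log-survival scale with
$\alpha,\beta \ge 0$; weights come from counting statistics (or replicate
standard deviations for summary-only data).

**RBE at fixed survival.** For a survival level $S$, the isoeffective
dose solves $\alpha D + \beta D^2 = \ln(1/S)$, and

$$\mathrm{RBE}_S = \frac{D_{\mathrm{ref}}(S)}{D_{\mathrm{test}}(S)},$$

with a Co-60 gamma reference and a delta-method standard error propagated
from both fit covariances.

**Dose-averaged LET.** Over a particle spectrum with component LET values
$\mathrm{LET}^i$ and dose contributions $D_i$,

$$\mathrm{LET}_d = \frac{\sum_i \mathrm{LET}^i D_i}{\sum_i D_i},$$

per species and pooled over all charged species.

**Neutron weighting.** Neutron spectra are categorized into the ICRP-103
energy classes (≤1, 1–50, ≥50 MeV) and weighted with the continuous
radiation weighting factor $w_R(E)$ (2.5 in the thermal and high-energy
limits, peaking at ~20.7 near 1 MeV).

**Two-stage comparisons.** Replicate sets are compared with a variance
F-test (two-sided, larger variance in the numerator) that gates the
choice between pooled Student and Welch t-tests; significance at
$p_t < 0.05$ per comparison.

A simplified analytic beam model (Bragg–Kleeman range–energy relation,
Bethe stopping power in water, CSDA depth-dose with Gaussian range
straggling) provides the plateau/peak geometry: a 190.6 MeV beam has a
23.9 g/cm² water range, with samples at 2 cm (plateau, position 1) and
23.6 cm (Bragg peak, position 2).

## Worked example

Simulate the study design (2 modes × 2 positions × 0/1/3/5 Gy, two runs
of six wells, plating efficiency 30%, plus a Co-60 reference curve at
1–5 Gy), fit every survival curve and estimate RBE at 50% survival:

```bash
$ protonrbe rbe --seed 1 --outdir out
RBE_50% PBS1: 1.353 +/- 0.059
RBE_50% PBS2: 1.551 +/- 0.065
RBE_50% DS1: 1.216 +/- 0.052
RBE_50% DS2: 1.298 +/- 0.051
```

Each line is the ratio of the Co-60 isoeffective dose at 50% survival to
that of the proton condition, from curves fitted to one simulated
realization of the experiment; the ± value is the delta-method standard
error. Peak positions (PBS2, DS2) show higher RBE than plateau positions,
as the harder LET spectrum at the peak predicts. The same chain is
available in Python:

```python
from protonrbe import load_config, run_pipeline
summary = run_pipeline(load_config(seed=1), "out")
```

Other subcommands run individual stages with the same config/seed
handling: `simulate`, `beam`, `letd`, `neutrons`, `survival`, `stats`,
and `all` for the full report bundle (CSV tables mirroring the study's
summary tables, a JSON summary and a log). For example:

```bash
$ protonrbe letd --seed 1 --outdir out
LET_d all particles DS1: 0.44 keV/um
LET_d all particles DS2: 3.34 keV/um
LET_d all particles PBS1: 0.44 keV/um
LET_d all particles PBS2: 3.11 keV/um
```

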