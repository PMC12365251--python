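# Methods

`pdtrace` quantifies ~200 nm polystyrene nanoplastics doped with ~0.3 wt.%
palladium (Pd-NPs) after oral administration to mice, by three
complementary modalities — scanning X-ray fluorescence imaging (XFI),
ICP-MS of acid digests, and imaging mass cytometry (IMC) — and folds the
results into percent-of-dose mass-balance accounting.  Because raw
per-animal instrument data are not distributable, the package ships a
synthetic-data generator that reproduces the statistical structure each
analysis stage assumes; every quantification routine is exercised
end-to-end against that generator's known ground truth.

## Ground-truth transit model

An oral bolus moves through a linear chain of first-order compartments,

    stomach → small intestine → cecum → colon → feces,

with rate constants k₁…k₄ (1/h) and a systemic pool fed by a fraction
f of the small-intestinal outflow.  The system is linear with constant
coefficients, so each gavage is propagated by the matrix exponential
exp(At) and doses superpose; the generator matrix has zero column sums,
which conserves mass to floating-point precision (the test bound is
1e-9 relative).  This is deliberately the simplest model that shows the
observed "fast front, slow bulk" transit; it is not a physiologically
based pharmacokinetic model, and the systemic pool has no elimination.

Defaults: k = (0.8, 0.75, 0.65, 0.6)/h and f = 0.01.  The rates were
chosen once so that roughly 30% of a single dose is excreted by 4 h with
only a small fecal signal at 2 h (forward simulation gives 30.2% and
5.2%).  A four-stage chain cannot make the 2 h signal arbitrarily small
while keeping the 4 h fraction at 30% — the front of a four-exponential
cascade is too smooth — so the 4 h fraction was treated as the binding
calibration and the 2 h value as qualitative.  The uptake fraction is a
free scenario parameter; 1% is a conservative default for intact
intestinal barriers.

Rate recovery (`biodist.fit_transit_rates`) does nonlinear least squares
on log-rates against the closed-form solution.  A single fecal curve
identifies the four rates only as a poorly conditioned unordered set;
sampling each GI compartment at several sacrifice times — the design the
quantification stages emulate — identifies each rate individually, and
recovery from virtual ICP-MS measurements is well within 10%.

## Virtual XFI and spectral quantification

Forward model, per pixel and K line:

    E[counts] = Φ · t · (m·N_A/A_Pd) · σ_F · (Ω/4π) · ε

with beam flux Φ (default 5×10¹¹ ph/s), dwell t, pixel Pd mass m,
fluorescence-production cross section σ_F (K-shell photoionisation at
53 keV × fluorescence yield × branching; packaged as 1.45×10⁻²² cm² for
Kα with Kβ/Kα = 0.20), solid-angle fraction Ω/4π for ten 0.5 cm² SDDs at
6 cm (flat-disc approximation n·A/4πd², verified against numerical
integration to <1%), and detector efficiency ε = 0.6.  Line photons are
spread over a Gaussian of width σ(E)² = σ_noise² + c·E (defaults tuned to
≈180 eV FWHM at 21 keV), a flat continuum background is added per bin,
and observed counts are Poisson draws.  Compton/Rayleigh continua, escape
peaks and pile-up are out of scope.

Quantification never uses σ_F directly.  Reference targets of known
areal mass are measured in the same geometry; the system constant
K = net Kα counts / (µg in beam · s) is their inverse-variance weighted
ratio, and pixel mass is net counts/(K·t).  Multiplying the simulated
flux by any constant and recalibrating therefore leaves masses unchanged
(ratio-method invariance, tested).

Peak fitting: Gaussians with centroids fixed at Pd Kα 21.12 keV and Kβ
23.82 keV, shared width from the resolution model, plus a linear
background over a 19.5–25.5 keV window.  With centroids and width fixed
the model is linear in its four parameters, so the fit is a linear least
squares solve — exact on noise-free input (round-trip error ≤0.1%,
dominated by the finite fit window) and unbiased under Poisson noise.
Parameter uncertainties use the sandwich covariance with per-bin Poisson
variance.  Negative fitted areas are clipped to zero and flagged;
failed solves return NaN with `converged=False`, never a silent zero.

Detection limit: LOD_mass = 3·√B/(K·t) with B the fitted background
counts in the window — the usual 3σ counting criterion.  With background
accumulating at a fixed rate, LOD falls as 1/√t.

Attenuation: 2D scans apply no per-pixel self-absorption correction, so
reconstructed masses are biased low.  The bias bound is Beer–Lambert,
loss = 1 − exp(−(µ/ρ)·ρ·L), using the NIST liquid-water mass-attenuation
table (15–60 keV grid) with log-log interpolation.  At 21.1 keV through
3 mm of water the loss is 19.7%, inside the expected 10–25% band for
representative sample geometries.  The loss is reported, not applied,
matching how the measurements are interpreted; energies outside the
packaged table are rejected rather than extrapolated.

## Virtual ICP-MS and censored quantification

Acquisition model: standards on the daily calibration grid (0, 0.1, 0.5,
1.0, 2.5, 5.0, 12.5, 25.0 µg Pd/L), then blanks, then samples.  A linear
sensitivity drift (default 5% per run) multiplies both the analyte
response slope·c + intercept and the Y/Sc internal-standard channel;
Gaussian noise with the blank standard deviation (default 40 counts at
slope 5000 counts per µg/L, i.e. instrument LOD ≈ 24 ng/L — within the
14–43 ng/L range the assay reports day to day) is added to every
intensity.

Analysis: intensities are divided by (record IS / mean IS over
standards), which cancels any common multiplicative drift exactly;
records with non-positive internal standard are rejected with a
diagnostic.  Calibration is ordinary least squares.  Instrument limits
default to the conventional blank rule LOD = 3·sd(blank)/slope,
LOQ = 10·sd(blank)/slope; the assay's own printed LOD/LOQ pairs have a
ratio near 1.3, which no simple blank rule reproduces, so both factors
are configurable and no other formula is guessed.

Back-calculation: measured concentration × dilution factor (13:3 read as
multiply by 13/3; the alternative 16/3 reading is a config option) gives
the digest concentration; × digest volume (mL) gives the sample mass
(ng, since µg/L ≡ ng/mL).  Sample LOD/LOQ are the instrument limits ×
digest volume.  Censoring: mass below the sample LOD (or ≤0) reports the
sentinel `bdl`, never zero; between LOD and LOQ reports exactly the LOD
value.  In downstream sums bdl contributes 0 and "between" contributes
its LOD value, both flagged, so totals carry a censoring annotation.
Half-organ digests scale value and limits by total/partial weight with
status preserved.  Only the ¹⁰⁶Pd channel is quantified; other isotopes
ride along for QC.

## Virtual IMC and pixel statistics

Each isotope channel (¹⁰²Pd…¹¹⁰Pd) of each 1 µm pixel draws uniform
detector noise on [0, noise_max) with noise_max = 1 dual count — the
detector's empirical noise band; the uniform shape is this package's
choice and is configurable.  A pixel holding n particles adds
Poisson(n · ions_per_particle) integer ion counts, split multinomially
across channels by natural Pd abundance.  ions_per_particle = 1 encodes
the empirical one-ion-per-particle sensitivity, not transmission
physics.  Dual counts equal ion numbers only below 30; larger values
pass through with a warning.

Consequences used as tests: with a ceiling of 1 dual count, noise alone
never produces a positive in any channel (false-positive rate exactly
zero), while a particle is detected — some channel exceeds 1 — exactly
when it yields ≥1 ion, so single-particle detection probability is
1 − e⁻¹ ≈ 0.632.  Channel totals rank ¹⁰⁶Pd and ¹⁰⁸Pd on top on
abundance-faithful input.  The 1.0 ceiling is the default profile;
stricter 1.5 and 2.0 read-offs are presets, none asserted as canonical.
Particle-per-pixel bounds use linear (diameter-wise) packing,
floor(pixel/diameter) = 5 at 1 µm and 200 nm; area packing would allow
~25 and does not match the reported 1–5 range.

Titration: spot k of a two-fold series holds start_conc × spot_volume /
2^(k−1) (91 ng/µL × 0.2 µL = 18.2 ng in spot 1).  The cumulative factor
is reported, by default, relative to the pre-dilution suspension
(2^k, so spot 40 is 2⁴⁰ ≈ 1.0995×10¹²); the spot-1-relative convention
2^(k−1) sits behind a flag.  The two conventions are mutually
inconsistent with an undiluted 18.2 ng spot 1 — the package implements
both rather than resolving the ambiguity — and the 11/10 Trypan-blue
dilution is ignored by default to match the 18.2 ng figure.  Factors use
exact integer arithmetic.  The empirical imager LOD is the most dilute
spot with at least one positive pixel; an all-empty series flags the LOD
as undefined.

## Mass-balance accounting

Percent of dose is 100·m/dose with the per-gavage (daily) dose as the
denominator, encoded on the regimen rather than inferred.  Values above
100% are legal (counting noise, pooled samples) and flagged, never
clipped.  Cumulative excretion curves are running sums of per-interval
fecal masses with censored entries handled by the ICP-MS rules; total
recovery per mouse sums whole-organ percent-of-dose for one method and
rejects mixed units.  Group comparison is the unpaired pooled-variance
t-test (Welch behind a flag), with the degenerate equal-constant-groups
case returning p = 1 by convention; tests verify it against the closed
form and an exact permutation oracle.  Method agreement on paired
uncensored masses reports the through-origin slope Σab/Σa², mean
relative difference and ratio statistics.

## Problem sizes and reproducibility

All randomness descends from one integer seed via
`numpy.random.SeedSequence`; per-instrument child streams are spawned
deterministically, and identical seed + config gives bit-identical
outputs (tested on full pipeline runs).  The test suite uses scan grids
of 2×2–4×4 pixels with 400-bin spectra, 100-seed coverage runs for XFI,
500-seed batches for ICP-MS bias, and a 10⁴-pixel ROI for the IMC
detection probability — sizes chosen so each Monte-Carlo bound has
comfortable statistical power while the whole suite runs in well under a
minute.

## Known limitations

- The transit chain has no stochastic inter-animal variability, no
  enterohepatic recirculation and no systemic elimination.
- XFI spectra contain only the two Pd K lines over a flat continuum; no
  scatter physics, no cross-element interference, and calibration is
  restricted to Pd-equivalent references (cross-element transfer of the
  reference calibration is not modelled).
- The attenuation bound assumes a uniform water slab; real samples have
  3D density structure the 2D scans cannot resolve.
- ICP-MS censoring reproduces the reporting rule, not a statistical
  treatment of left-censored data (no maximum-likelihood imputation).
- IMC spillover between isotope channels and cell segmentation are out
  of scope; the MCD binary format is unsupported (TXT dialect only).
- Passing tests demonstrate correctness of the quantification chain on
  data matching the generator's assumptions (Poisson counting, linear
  response, uniform noise); they cannot establish accuracy on real
  instrument data with unmodelled systematics.
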