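# pdtrace

Multi-modal quantification of palladium-doped polystyrene nanoplastics
(Pd-NPs) in biological samples.  Micro- and nanoplastics are hard to
trace in tissue because carbon-based particles are invisible to most
elemental techniques; doping ~200 nm polystyrene particles with ~0.3 wt.%
Pd makes them quantifiable by X-ray fluorescence imaging (XFI), ICP-MS
and imaging mass cytometry (IMC).  `pdtrace` implements the full
analysis chain for such studies — for analytical chemists and
nanotoxicologists who need per-organ Pd masses, excretion kinetics and
percent-of-dose mass balance from these three instrument families — plus
a synthetic-data generator that emulates gastrointestinal transit of an
oral bolus and the statistics of each virtual instrument, so the whole
chain can be validated against known ground truth.

## What it computes

**XFI** (`pdtrace.xfi`) — per-pixel spectra are fit with fixed-centroid
Gaussians at Pd Kα (21.12 keV) and Kβ (23.82 keV) over a linear
background; reference targets of known areal mass give the system
constant K (counts per µg·s), and pixel mass is

    m = N_Kα / (K · t_dwell),   LOD = 3·√B / (K · t_dwell)

with B the background counts in the fit window.  Self-absorption in 2D
scans is reported as a Beer–Lambert bias bound,
loss = 1 − exp(−(µ/ρ)ρL), from the packaged NIST water attenuation table.

**ICP-MS** (`pdtrace.icpms`) — internal-standard drift correction, OLS
calibration on the 0–25 µg/L daily standard series, dilution and
digest-volume back-calculation to ng Pd per sample, and censoring:
below the sample LOD → `bdl` (never 0), between LOD and LOQ → set to the
LOD value.

**IMC** (`pdtrace.imc`) — per-pixel dual-count thresholding above the
0–1 dual-count detector noise band, particle-per-pixel estimates at the
one-ion-per-particle sensitivity, isotope-channel combination, and
titration-based empirical detection limits.

**Biodistribution** (`pdtrace.biodist`) — percent-of-dose accounting,
cumulative excretion curves, total recovery per mouse, unpaired t-tests
between treatment groups, XFI-vs-ICP-MS agreement, and transit-rate
recovery from compartment time courses.

**Synthetic data** (`pdtrace.synthetic`) — first-order GI transit chain
(stomach → small intestine → cecum → colon → feces, with a systemic
uptake fraction) solved by matrix exponential, plus virtual XFI scans
(Poisson photon counting), ICP-MS batches (linear response, drift,
Gaussian baseline noise) and IMC ROIs (uniform sub-1 noise, Poisson ion
counts split by natural Pd isotope abundance).

See `docs/methods.md` for models, defaults and limitations.

## Worked example

```python
import numpy as np
from pdtrace import synthetic, xfi, icpms

# GI transit of a single 9.976 ug Pd gavage (acute regimen defaults)
study = synthetic.simulate_biodistribution(
    synthetic.ACUTE_REGIMEN, uptake_fraction=0.01, times_h=[2, 4, 8, 24])
print(study.pd_mass_ug.round(3))
```

```
        stomach  small_intestine  cecum  colon  feces  systemic
time_h
2.0       2.014            3.389  2.739  1.270  0.518     0.046
4.0       0.407            1.441  2.543  2.523  2.981     0.081
8.0       0.017            0.130  0.554  1.265  7.911     0.098
24.0      0.000            0.000  0.000  0.001  9.876     0.100
```

By 4 h about 30% of the dose has reached the feces; by 24 h the gut is
essentially cleared, with 1% taken up systemically (the chosen uptake
fraction).  Mass is conserved at every time point to 1e-9 relative.

```python
# virtual XFI scan of a 2x2 sample, flux calibration, mass reconstruction
truth = np.array([[0.5, 0.0], [1.0, 2.0]])           # ug Pd per pixel
scan = synthetic.generate_xfi_scan(truth, seed=1,
    reference_areal_masses_ug_cm2=(20.0,), reference_dwell_s=100.0)
calib = xfi.calibrate_from_scan(scan)
mass_map = xfi.build_mass_map(scan, calib)
print(f"K = {calib.k_counts_per_ug_s:.0f} counts/(ug s)")
print(mass_map.mass_ug.round(3), f"total {mass_map.total_ug:.3f} ug")
print(f"attenuation bound: {100 * xfi.estimate_attenuation_bias(21.1, 0.3):.1f}%")
```

```
K = 2729 counts/(ug s)
[[0.499 0.   ]
 [1.033 2.048]] total 3.579 ug
attenuation bound: 19.7%
```

The Poisson-noise scan reconstructs the 3.5 µg ground truth within
counting statistics, and a 3 mm water-equivalent path would absorb
19.7% of the Kα photons — the reconstructed masses are biased low by
about that much, inside the 10–25% band expected for these geometries.

```python
# ICP-MS: three digests at 1.0, 0.02 and 0 ug/L with drift and noise
batch = synthetic.generate_icpms_batch([1.0, 0.02, 0.0], drift=0.05, seed=4)
print(icpms.quantify_batch(batch)[
    ["id", "display", "status", "sample_lod_ng", "sample_loq_ng"]].round(3))
```

```
      id  display          status  sample_lod_ng  sample_loq_ng
sample_0   13.035      quantified          0.094          0.313
sample_1 0.361923      quantified          0.094          0.313
sample_2      bdl below_detection          0.094          0.313
```

1.0 µg/L measured in the 13:3-diluted digest back-calculates to 13 ng in
the 3 mL digest; the blank sample falls below the 0.094 ng sample LOD
and is reported `bdl`, never zero.

The same workflow is scriptable end-to-end:

```sh
pdtrace run --seed 1 --out results/demo
pdtrace xfi attenuation --path-mm 3 --energy-kev 21.1
```

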