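"""Physical constants and reference tables used across the package.

The fluorescence-production cross sections are effective single numbers
(K-shell photoionisation at 53 keV excitation x K fluorescence yield x
line branching) assembled from standard compilations (XCOM photoionisation
cross sections; Krause fluorescence yields).  Quantification is calibrated
against reference targets measured in the same geometry, so downstream
results depend only on the Kbeta/Kalpha ratio, not on the absolute scale.
"""

AVOGADRO = 6.02214076e23
PD_MOLAR_MASS_G_MOL = 106.42

# Pd K-line centroids (keV); Kalpha is the intensity-weighted Ka1/Ka2 blend.
PD_KALPHA_KEV = 21.12
PD_KBETA_KEV = 23.82

# Effective fluorescence-production cross sections at 53 keV, cm^2 per atom.
PD_SIGMA_F_CM2 = {
    "kalpha": 1.45e-22,
    "kbeta": 0.29e-22,  # Kbeta/Kalpha branching ratio ~0.20 for Pd
}

#: Natural isotopic abundances of palladium (mass number -> fraction).
PD_ISOTOPE_ABUNDANCE = {
    102: 0.0102,
    104: 0.1114,
    105: 0.2233,
    106: 0.2733,
    108: 0.2646,
    110: 0.1172,
}

#: IMC channel names in the conventional order.
PD_CHANNELS = tuple(f"Pd{m}" for m in sorted(PD_ISOTOPE_ABUNDANCE))

# Mass attenuation coefficient mu/rho of liquid water, cm^2/g, on the
# NIST standard reference energy grid restricted to 15-60 keV.  Values are
# the published NIST tabulation for liquid water; interpolation between
# grid points is log-log (see xfi.estimate_attenuation_bias).
WATER_MU_RHO_CM2_G = {
    15.0: 1.673,
    20.0: 0.8096,
    30.0: 0.3756,
    40.0: 0.2683,
    50.0: 0.2269,
    60.0: 0.2059,
}

#: Density of water/soft-tissue equivalent used for attenuation bounds (g/cm^3).
WATER_DENSITY_G_CM3 = 1.0

#: ICP-MS daily calibration grid (ug Pd / L).
ICPMS_CALIBRATION_GRID_UG_L = (0.0, 0.1, 0.5, 1.0, 2.5, 5.0, 12.5, 25.0)

#: Dual counts equal detected ion numbers only below this value.
IMC_ION_COUNT_REGIME_MAX = 30.0
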