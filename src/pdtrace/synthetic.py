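"""Ground-truth biodistribution scenarios and virtual instrument readouts.

The generator produces (i) a first-order compartmental transit of an oral
Pd-nanoplastic bolus through the GI tract with partial systemic uptake,
and (ii) virtual measurements of the resulting Pd masses by the three
modalities the analysis stages quantify: scanning XFI spectra (Poisson
photon counting on the Pd K lines over a continuum background), ICP-MS
intensity batches (linear calibration response with instrument drift and
Gaussian baseline noise), and IMC regions of interest (uniform sub-1
detector noise plus integer ion counts at particle sites, split across
isotope channels by natural Pd abundance).

All randomness flows from a single integer seed through
``numpy.random.SeedSequence``; identical seeds and configurations give
bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .constants import (
    AVOGADRO,
    ICPMS_CALIBRATION_GRID_UG_L,
    PD_CHANNELS,
    PD_ISOTOPE_ABUNDANCE,
    PD_MOLAR_MASS_G_MOL,
    PD_SIGMA_F_CM2,
)
from .xfi import (
    DEFAULT_LINES,
    DetectorGeometry,
    ReferenceTarget,
    Spectrum,
    XfiScan,
)
from .icpms import IcpmsBatch
from .imc import ImcRoi, TitrationSeries, TitrationSpot

COMPARTMENTS = ("stomach", "small_intestine", "cecum", "colon", "feces", "systemic")


@dataclass(frozen=True)
class ParticleBatch:
    """Physical description of the Pd-doped polystyrene tracer particles."""

    diameter_nm: float = 200.0
    polymer_density_g_cm3: float = 1.05
    pd_mass_fraction: float = 9.976 / 3381.7  # ~0.295 wt.%
    stock_concentration_ug_ml: float = 99.76

    def __post_init__(self) -> None:
        if self.diameter_nm <= 0:
            raise ValueError("diameter must be positive")
        if not 0 < self.pd_mass_fraction < 1:
            raise ValueError("pd_mass_fraction must be a fraction in (0, 1)")
        if self.stock_concentration_ug_ml < 0:
            raise ValueError("stock concentration must be non-negative")

    @property
    def particle_mass_g(self) -> float:
        d_cm = self.diameter_nm * 1e-7
        return self.polymer_density_g_cm3 * math.pi / 6.0 * d_cm**3


@dataclass(frozen=True)
class DoseRegimen:
    """Gavage schedule and per-gavage (daily) dose."""

    daily_np_mass_mg: float
    daily_pd_mass_ug: float
    schedule_h: tuple[float, ...] = (0.0,)
    gavage_volume_ul: float = 100.0

    def __post_init__(self) -> None:
        if self.daily_np_mass_mg <= 0 or self.daily_pd_mass_ug <= 0:
            raise ValueError("doses must be positive")
        sched = tuple(float(t) for t in self.schedule_h)
        object.__setattr__(self, "schedule_h", sched)
        if any(b <= a for a, b in zip(sched, sched[1:])):
            raise ValueError("gavage schedule must be strictly increasing")

    @property
    def implied_pd_fraction(self) -> float:
        return self.daily_pd_mass_ug / (self.daily_np_mass_mg * 1000.0)

    def check_consistency(self, batch: ParticleBatch, rtol: float = 0.01) -> None:
        """Verify daily Pd mass = NP mass x batch Pd fraction within ``rtol``."""
        expected = self.daily_np_mass_mg * 1000.0 * batch.pd_mass_fraction
        if not math.isclose(self.daily_pd_mass_ug, expected, rel_tol=rtol):
            raise ValueError(
                f"daily Pd dose {self.daily_pd_mass_ug} ug inconsistent with "
                f"NP mass x Pd fraction = {expected:.4g} ug (rtol {rtol})"
            )


#: Acute regimen: single 100 uL gavage of the measured stock.
ACUTE_REGIMEN = DoseRegimen(daily_np_mass_mg=3.3817, daily_pd_mass_ug=9.976, schedule_h=(0.0,))


@dataclass(frozen=True)
class TransitRates:
    """First-order rate constants (1/h) along the GI chain."""

    stomach_to_si: float = 0.8
    si_to_cecum: float = 0.75
    cecum_to_colon: float = 0.65
    colon_to_feces: float = 0.6

    def __post_init__(self) -> None:
        for name, k in self.as_dict().items():
            if k < 0:
                raise ValueError(f"rate {name} must be non-negative, got {k}")

    def as_dict(self) -> dict[str, float]:
        return {
            "stomach_to_si": self.stomach_to_si,
            "si_to_cecum": self.si_to_cecum,
            "cecum_to_colon": self.cecum_to_colon,
            "colon_to_feces": self.colon_to_feces,
        }


@dataclass
class GroundTruthStudy:
    """Per-compartment Pd mass time series for one simulated subject."""

    compartments: tuple[str, ...]
    times_h: np.ndarray
    pd_mass_ug: pd.DataFrame  # index times_h, columns compartments
    transfer_rates: TransitRates
    uptake_fraction: float
    regimen: DoseRegimen
    seed: int

    def administered_ug(self, time_h: float) -> float:
        return self.regimen.daily_pd_mass_ug * sum(1 for t in self.regimen.schedule_h if t <= time_h)

    def mass_balance_error(self) -> float:
        """Max relative |administered - sum of compartments| over output times."""
        worst = 0.0
        for t in self.times_h:
            admin = self.administered_ug(float(t))
            if admin == 0:
                continue
            total = float(self.pd_mass_ug.loc[t].sum())
            worst = max(worst, abs(total - admin) / admin)
        return worst

    def to_table(self) -> pd.DataFrame:
        """Long-format (compartment, time_h, pd_mass_ug) table."""
        long = self.pd_mass_ug.reset_index(names="time_h").melt(
            id_vars="time_h", var_name="compartment", value_name="pd_mass_ug"
        )
        return long[["compartment", "time_h", "pd_mass_ug"]].sort_values(
            ["compartment", "time_h"], ignore_index=True
        )


def _transit_matrix(rates: TransitRates, uptake_fraction: float) -> np.ndarray:
    """Generator matrix of the linear chain with systemic uptake from the SI.

    States: stomach, small_intestine, cecum, colon, feces, systemic.
    The SI outflow splits: ``uptake_fraction`` to the systemic pool, the
    rest onward to the cecum.  Columns sum to zero, so total mass is
    conserved exactly by the matrix exponential.
    """
    k1, k2, k3, k4 = (
        rates.stomach_to_si,
        rates.si_to_cecum,
        rates.cecum_to_colon,
        rates.colon_to_feces,
    )
    f = uptake_fraction
    A = np.zeros((6, 6))
    A[0, 0] = -k1
    A[1, 0] = k1
    A[1, 1] = -k2
    A[2, 1] = (1.0 - f) * k2
    A[2, 2] = -k3
    A[3, 2] = k3
    A[3, 3] = -k4
    A[4, 3] = k4
    A[5, 1] = f * k2
    return A


def simulate_biodistribution(
    regimen: DoseRegimen,
    rates: TransitRates | None = None,
    uptake_fraction: float = 0.01,
    times_h: list[float] | np.ndarray = (0.5, 1, 2, 4, 8, 12, 24),
    seed: int = 0,
) -> GroundTruthStudy:
    """Integrate the dosed transit chain at the requested output times.

    The system is linear with constant coefficients, so each gavage bolus
    is propagated by the closed-form matrix exponential and superposed.
    Deterministic given the configuration; the seed is carried so that
    downstream virtual instruments derive their noise streams from it.
    """
    rates = rates or TransitRates()
    if not 0 <= uptake_fraction <= 1:
        raise ValueError("uptake_fraction must be in [0, 1]")
    times = np.asarray(list(times_h), dtype=float)
    if times.ndim != 1 or len(times) == 0:
        raise ValueError("times must be a non-empty 1-D sequence")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(times < 0):
        raise ValueError("times must be non-negative")

    A = _transit_matrix(rates, uptake_fraction)
    e0 = np.zeros(6)
    e0[0] = 1.0
    # propagate each bolus by expm over its elapsed time, superpose
    states = np.zeros((len(times), 6))
    propagated: dict[float, np.ndarray] = {}
    for i, t in enumerate(times):
        for t_dose in regimen.schedule_h:
            if t_dose > t:
                continue
            dt = float(t - t_dose)
            if dt not in propagated:
                propagated[dt] = expm(A * dt) @ e0
            states[i] += regimen.daily_pd_mass_ug * propagated[dt]
    frame = pd.DataFrame(states, index=pd.Index(times, name="time_h"), columns=COMPARTMENTS)
    return GroundTruthStudy(
        compartments=COMPARTMENTS,
        times_h=times,
        pd_mass_ug=frame,
        transfer_rates=rates,
        uptake_fraction=uptake_fraction,
        regimen=regimen,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Virtual XFI
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BeamConfig:
    """Monochromatic pencil-beam parameters."""

    energy_kev: float = 53.0
    flux_ph_s: float = 5e11
    dwell_s: float = 1.0
    beam_area_mm2: float = 1.0

    def __post_init__(self) -> None:
        if self.flux_ph_s <= 0 or self.dwell_s <= 0 or self.beam_area_mm2 <= 0:
            raise ValueError("flux, dwell and beam area must be positive")


@dataclass(frozen=True)
class SpectralGrid:
    """Shared energy binning of the virtual SDD spectra."""

    e_min_kev: float = 18.0
    e_max_kev: float = 26.0
    bin_kev: float = 0.02

    def centers(self) -> np.ndarray:
        n = int(round((self.e_max_kev - self.e_min_kev) / self.bin_kev))
        return self.e_min_kev + (np.arange(n) + 0.5) * self.bin_kev


def expected_line_counts(
    mass_ug: float,
    beam: BeamConfig,
    detector: DetectorGeometry,
    dwell_s: float | None = None,
) -> dict[str, float]:
    """Forward model: expected net counts per Pd K line for a pixel mass.

    counts = flux * dwell * N_atoms * sigma_F * (Omega/4pi) * efficiency,
    per line, with N_atoms = mass * N_A / A_Pd.
    """
    dwell = beam.dwell_s if dwell_s is None else dwell_s
    n_atoms = mass_ug * 1e-6 / PD_MOLAR_MASS_G_MOL * AVOGADRO
    geom = detector.solid_angle_fraction * detector.efficiency
    return {
        line: beam.flux_ph_s * dwell * n_atoms * PD_SIGMA_F_CM2[line] * geom
        for line in PD_SIGMA_F_CM2
    }


def _line_spectrum(
    mass_ug: float,
    energy: np.ndarray,
    beam: BeamConfig,
    detector: DetectorGeometry,
    grid: SpectralGrid,
    background_rate: float,
    dwell_s: float,
) -> np.ndarray:
    """Noise-free expected spectrum (counts per bin) for one pixel."""
    expected = expected_line_counts(mass_ug, beam, detector, dwell_s=dwell_s)
    spec = np.full_like(energy, background_rate, dtype=float)
    for line, area in expected.items():
        centroid = DEFAULT_LINES[line]
        sigma = detector.resolution.sigma_kev(centroid)
        g = np.exp(-0.5 * ((energy - centroid) / sigma) ** 2)
        spec += area * g * grid.bin_kev / (sigma * math.sqrt(2.0 * math.pi))
    return spec


def generate_xfi_scan(
    truth_map: np.ndarray,
    beam: BeamConfig | None = None,
    detector: DetectorGeometry | None = None,
    background_rate: float = 2.0,
    seed: int = 0,
    grid: SpectralGrid | None = None,
    reference_areal_masses_ug_cm2: tuple[float, ...] = (5.0,),
    reference_dwell_s: float = 10.0,
    poisson: bool = True,
) -> XfiScan:
    """Virtual raster scan of a per-pixel Pd mass grid (ug/pixel).

    Per pixel the expected Pd-line counts follow the forward model; the
    observed counts are Poisson draws over the continuum background
    (``background_rate`` counts/bin).  Reference-target spectra of known
    areal mass are appended for flux calibration.  ``poisson=False``
    returns the noise-free expectation (floats), used for exact
    round-trip checks.
    """
    beam = beam or BeamConfig()
    detector = detector or DetectorGeometry()
    grid = grid or SpectralGrid()
    truth = np.asarray(truth_map, dtype=float)
    if truth.ndim != 2:
        raise ValueError("truth_map must be 2-D (ny, nx)")
    if np.any(truth < 0):
        raise ValueError("truth_map masses must be non-negative")
    if background_rate < 0:
        raise ValueError("background rate must be non-negative")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    energy = grid.centers()
    ny, nx = truth.shape
    counts = np.empty((ny, nx, len(energy)))
    for iy in range(ny):
        for ix in range(nx):
            mu = _line_spectrum(
                truth[iy, ix], energy, beam, detector, grid, background_rate, beam.dwell_s
            )
            counts[iy, ix] = rng.poisson(mu) if poisson else mu

    references = []
    for areal_mass in reference_areal_masses_ug_cm2:
        mass_in_beam = areal_mass * beam.beam_area_mm2 / 100.0
        mu = _line_spectrum(
            mass_in_beam, energy, beam, detector, grid, background_rate, reference_dwell_s
        )
        obs = rng.poisson(mu).astype(float) if poisson else mu
        references.append(
            ReferenceTarget(
                element="Pd",
                areal_mass_ug_cm2=areal_mass,
                spectrum=Spectrum(energy, obs, reference_dwell_s),
            )
        )

    return XfiScan(
        energy_kev=energy,
        counts=counts,
        dwell_s=beam.dwell_s,
        pixel_size_mm=math.sqrt(beam.beam_area_mm2),
        beam_energy_kev=beam.energy_kev,
        beam_area_mm2=beam.beam_area_mm2,
        detector=detector,
        references=references,
    )


# ---------------------------------------------------------------------------
# Virtual ICP-MS
# ---------------------------------------------------------------------------


def generate_icpms_batch(
    sample_concs_ug_l: list[float],
    slope: float = 5000.0,
    intercept: float = 100.0,
    blank_sd: float = 40.0,
    drift: float = 0.05,
    seed: int = 0,
    n_blanks: int = 5,
    dilution_factor: float = 13.0 / 3.0,
    digest_volume_ml: float = 3.0,
    internal_standard_base: float = 1e5,
) -> IcpmsBatch:
    """Virtual ICP-MS acquisition: standards, blanks, then samples.

    Standards sit on the daily calibration grid (0-25 ug/L).  The internal
    standard channel decays linearly by ``drift`` (fraction per run) across
    acquisition order, and the same sensitivity decay multiplies the
    analyte response slope*conc + intercept.  Gaussian noise with sd
    ``blank_sd`` is added to every intensity.
    """
    if slope <= 0:
        raise ValueError("slope must be positive")
    if blank_sd < 0:
        raise ValueError("blank_sd must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    concs = list(ICPMS_CALIBRATION_GRID_UG_L)
    n_total = len(concs) + n_blanks + len(sample_concs_ug_l)

    def drift_factor(order: int) -> float:
        if n_total <= 1:
            return 1.0
        return 1.0 - drift * order / (n_total - 1)

    order = 0
    for conc in concs:
        f = drift_factor(order)
        rows.append(
            {
                "record_type": "standard",
                "id": f"std_{conc:g}",
                "nominal_conc": conc,
                "intensity_106": (slope * conc + intercept) * f + rng.normal(0.0, blank_sd),
                "intensity_IS": internal_standard_base * f + rng.normal(0.0, blank_sd),
                "dilution_factor": 1.0,
                "digest_volume_mL": digest_volume_ml,
                "order": order,
            }
        )
        order += 1
    for i in range(n_blanks):
        f = drift_factor(order)
        rows.append(
            {
                "record_type": "blank",
                "id": f"blank_{i}",
                "nominal_conc": 0.0,
                "intensity_106": intercept * f + rng.normal(0.0, blank_sd),
                "intensity_IS": internal_standard_base * f + rng.normal(0.0, blank_sd),
                "dilution_factor": 1.0,
                "digest_volume_mL": digest_volume_ml,
                "order": order,
            }
        )
        order += 1
    for i, conc in enumerate(sample_concs_ug_l):
        f = drift_factor(order)
        rows.append(
            {
                "record_type": "sample",
                "id": f"sample_{i}",
                "nominal_conc": conc,
                "intensity_106": (slope * conc + intercept) * f + rng.normal(0.0, blank_sd),
                "intensity_IS": internal_standard_base * f + rng.normal(0.0, blank_sd),
                "dilution_factor": dilution_factor,
                "digest_volume_mL": digest_volume_ml,
                "order": order,
            }
        )
        order += 1
    return IcpmsBatch(records=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Virtual IMC
# ---------------------------------------------------------------------------


def generate_imc_roi(
    width: int,
    height: int,
    particle_pixels: list[tuple[int, int, int]],
    ions_per_particle: float = 1.0,
    noise_max: float = 1.0,
    seed: int = 0,
    roi_id: str = "roi_0",
    tissue: str = "synthetic",
) -> ImcRoi:
    """Virtual IMC region of interest at 1 um/pixel.

    Background: each isotope channel of each pixel draws uniform dual
    counts in [0, noise_max).  Each (x, y, n_particles) site adds
    Poisson(n_particles * ions_per_particle) integer ion counts,
    multinomially split across the six Pd channels by natural abundance.
    """
    if ions_per_particle <= 0:
        raise ValueError("ions_per_particle must be positive")
    if not 0 <= noise_max <= 1:
        raise ValueError("noise_max must lie in [0, 1]")
    for x, y, n in particle_pixels:
        if not (0 <= x < width and 0 <= y < height):
            raise ValueError(f"particle pixel ({x}, {y}) outside {width}x{height} grid")
        if n < 0:
            raise ValueError("particle counts must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    abundances = np.array([PD_ISOTOPE_ABUNDANCE[int(ch[2:])] for ch in PD_CHANNELS])
    channels = {
        ch: rng.uniform(0.0, noise_max, size=(height, width)) if noise_max > 0 else np.zeros((height, width))
        for ch in PD_CHANNELS
    }
    for x, y, n in particle_pixels:
        total_ions = rng.poisson(n * ions_per_particle)
        if total_ions > 0:
            split = rng.multinomial(total_ions, abundances)
            for ch, ions in zip(PD_CHANNELS, split):
                channels[ch][y, x] += ions
    return ImcRoi(channels=channels, roi_id=roi_id, tissue=tissue)


# ---------------------------------------------------------------------------
# Titration series
# ---------------------------------------------------------------------------


def generate_titration_series(
    start_conc_ng_ul: float = 91.0,
    n_dilutions: int = 39,
    spot_volume_ul: float = 0.2,
    factor_convention: str = "suspension",
) -> TitrationSeries:
    """Two-fold dilution series spotted at fixed volume.

    Spot 1 holds start_conc x spot_volume of Pd; each later spot halves
    the previous mass.  The cumulative dilution factor of spot k is
    2^(k-1) relative to spot 1; under the default ``"suspension"``
    convention the reported factor is 2^k (spot 1 counted as the first
    two-fold dilution of the pre-dilution suspension), under ``"spot1"``
    it is 2^(k-1).  Factors are exact integers.
    """
    if start_conc_ng_ul <= 0:
        raise ValueError("start concentration must be positive")
    if n_dilutions < 0:
        raise ValueError("n_dilutions must be non-negative")
    if spot_volume_ul <= 0:
        raise ValueError("spot volume must be positive")
    if factor_convention not in ("suspension", "spot1"):
        raise ValueError("factor_convention must be 'suspension' or 'spot1'")
    spot1_mass = start_conc_ng_ul * spot_volume_ul
    spots = []
    for k in range(1, n_dilutions + 2):
        rel_spot1 = 2 ** (k - 1)
        factor = 2**k if factor_convention == "suspension" else rel_spot1
        spots.append(
            TitrationSpot(index=k, pd_mass_ng=spot1_mass / rel_spot1, dilution_factor=factor)
        )
    return TitrationSeries(
        spots=tuple(spots),
        start_conc_ng_ul=start_conc_ng_ul,
        spot_volume_ul=spot_volume_ul,
        factor_convention=factor_convention,
    )
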