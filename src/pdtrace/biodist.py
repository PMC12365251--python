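"""Dose-fraction mass balance and biokinetic summaries.

All organ burdens and excreted masses are expressed as a percentage of
the applied (acute) or daily (repeated-gavage) Pd dose.  The module
aggregates per-organ censored masses into recovery rates per mouse,
builds cumulative excretion curves, compares treatment groups with an
unpaired t-test, quantifies cross-method agreement (XFI vs ICP-MS), and
recovers transit-chain rate constants from excretion curves.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import icpms

METHODS = ("XFI", "ICPMS", "IMC")


@dataclass
class StudyLedger:
    """Doses, organ burdens and excretion series for one study.

    ``organ_masses`` columns: mouse, organ, method, mass, unit ("ng" or
    "ug"), status (censoring per the ICP-MS rules; empty = quantified).
    ``excretion_series`` columns: subject, time_h, pd_mass_ug, method.
    """

    applied_dose_ug: float
    organ_masses: pd.DataFrame
    excretion_series: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        required = {"mouse", "organ", "method", "mass", "unit", "status"}
        missing = required - set(self.organ_masses.columns)
        if missing:
            raise ValueError(f"organ_masses missing columns: {sorted(missing)}")
        bad = set(self.organ_masses["method"]) - set(METHODS)
        if bad:
            raise ValueError(f"unknown method tags: {sorted(bad)}")
        bad_units = set(self.organ_masses["unit"]) - {"ng", "ug"}
        if bad_units:
            raise ValueError(f"unknown mass units: {sorted(bad_units)}")


@dataclass
class RecoveryReport:
    """Derived %-of-dose accounting for one study."""

    per_organ_pct: pd.DataFrame  # mouse, organ, method, pct_dose, censored
    cumulative_excretion: pd.DataFrame  # subject, time_h, cumulative_pct
    total_recovery_pct: pd.DataFrame  # mouse, method, pct_dose, n_censored
    method_agreement: "MethodAgreement | None" = None


def percent_of_dose(mass_ug: float, dose_ug: float) -> float:
    """Express a Pd mass as percent of the applied/daily dose.

    Values above 100% are legal (counting noise, pooled samples) and are
    flagged with a warning rather than clipped.
    """
    if dose_ug <= 0:
        raise ValueError("dose must be positive")
    pct = 100.0 * mass_ug / dose_ug
    if pct > 100.0:
        warnings.warn(f"recovery {pct:.2f}% exceeds the applied dose", stacklevel=2)
    return pct


def pd_dose_from_np_mass(np_mass_mg: float, pd_fraction: float) -> float:
    """Pd dose (ug) from a nanoparticle mass (mg) and Pd mass fraction."""
    if np_mass_mg <= 0 or pd_fraction <= 0:
        raise ValueError("mass and fraction must be positive")
    return np_mass_mg * 1000.0 * pd_fraction


def np_count_from_mass(
    np_mass_mg: float, diameter_nm: float = 200.0, density_g_cm3: float = 1.05
) -> float:
    """Number of particles in a nanoparticle mass (sphere volume x density)."""
    if np_mass_mg <= 0 or diameter_nm <= 0 or density_g_cm3 <= 0:
        raise ValueError("inputs must be positive")
    d_cm = diameter_nm * 1e-7
    particle_mass_g = density_g_cm3 * math.pi / 6.0 * d_cm**3
    return np_mass_mg * 1e-3 / particle_mass_g


def cumulative_excretion(
    series: pd.DataFrame, dose_ug: float
) -> pd.DataFrame:
    """Running excreted mass as cumulative percent of dose.

    ``series`` columns: time_h, pd_mass_ug (per-interval mass), optional
    status (censoring: bdl rows contribute 0, between rows their value,
    both flagged).  Times must be sorted strictly increasing.
    """
    if dose_ug <= 0:
        raise ValueError("dose must be positive")
    times = series["time_h"].to_numpy(dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("excretion series times must be strictly increasing")
    masses = series["pd_mass_ug"].to_numpy(dtype=float).copy()
    censored = np.zeros(len(series), dtype=bool)
    if "status" in series.columns:
        status = series["status"].fillna("").to_numpy()
        bdl = status == icpms.STATUS_BDL
        masses[bdl] = 0.0
        censored = bdl | (status == icpms.STATUS_BETWEEN)
    cum = np.cumsum(masses)
    return pd.DataFrame(
        {
            "time_h": times,
            "cumulative_pct": 100.0 * cum / dose_ug,
            "censored": censored,
        }
    )


def total_recovery(
    ledger: StudyLedger, mouse: str, method: str = "ICPMS"
) -> tuple[float, int]:
    """Sum of whole-organ %dose for one mouse and method.

    Returns (percent of dose, number of censored rows entering the sum).
    bdl rows contribute 0; "between" rows contribute their substituted
    LOD value; both count as censored.  Mixed mass units are rejected.
    """
    rows = ledger.organ_masses
    rows = rows[(rows["mouse"] == mouse) & (rows["method"] == method)]
    if len(rows) == 0:
        raise ValueError(f"no rows for mouse {mouse!r} with method {method!r}")
    units = set(rows["unit"])
    if len(units) > 1:
        raise ValueError(f"mixed mass units for mouse {mouse!r}: {sorted(units)}")
    unit = units.pop()
    scale = 1e-3 if unit == "ng" else 1.0  # -> ug
    total_ug = 0.0
    n_censored = 0
    for _, row in rows.iterrows():
        status = row["status"] or icpms.STATUS_QUANTIFIED
        if status == icpms.STATUS_BDL:
            n_censored += 1
            continue
        if status == icpms.STATUS_BETWEEN:
            n_censored += 1
        total_ug += float(row["mass"]) * scale
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pct = percent_of_dose(total_ug, ledger.applied_dose_ug)
    return pct, n_censored


def compare_groups(
    values_a, values_b, welch: bool = False
) -> tuple[float, float]:
    """Unpaired two-sided t-test (pooled variance; Welch optional).

    Degenerate case: both groups constant with equal means returns
    (t=0, p=1) by convention.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0 and a.mean() == b.mean():
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


@dataclass(frozen=True)
class MethodAgreement:
    """Cross-method agreement statistics on paired per-sample masses."""

    n_pairs: int
    n_excluded_censored: int
    slope_through_origin: float
    mean_relative_difference: float
    mean_ratio: float
    ratio_sd: float


def method_agreement(paired: pd.DataFrame) -> MethodAgreement:
    """Agreement between two quantification methods on paired samples.

    ``paired`` columns: sample, mass_a, mass_b (same unit); optional
    status_a/status_b mark censored entries, which are excluded with a
    note.  Slope is the least-squares line through the origin
    (sum(ab)/sum(a^2)); relative difference is (b - a)/a.
    """
    df = paired.copy()
    n_censored = 0
    for col in ("status_a", "status_b"):
        if col in df.columns:
            censored = df[col].fillna("").isin([icpms.STATUS_BDL, icpms.STATUS_BETWEEN])
            n_censored += int(censored.sum())
            df = df[~censored]
    if len(df) < 3:
        raise ValueError("method agreement needs at least 3 uncensored pairs")
    a = df["mass_a"].to_numpy(dtype=float)
    b = df["mass_b"].to_numpy(dtype=float)
    if np.any(a <= 0):
        raise ValueError("mass_a must be positive for ratio statistics")
    slope = float(np.sum(a * b) / np.sum(a * a))
    rel = (b - a) / a
    ratio = b / a
    return MethodAgreement(
        n_pairs=len(df),
        n_excluded_censored=n_censored,
        slope_through_origin=slope,
        mean_relative_difference=float(rel.mean()),
        mean_ratio=float(ratio.mean()),
        ratio_sd=float(ratio.std(ddof=1)) if len(ratio) > 1 else 0.0,
    )


def fit_transit_rates(
    observed: pd.DataFrame,
    regimen,
    uptake_fraction: float = 0.0,
    initial_rates: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0),
) -> "TransitRates":
    """Recover chain rate constants from measured compartment time courses.

    ``observed`` is indexed by time (h) with one column per measured
    compartment (any subset of the transit chain, e.g. the GI organs and
    feces sampled at successive sacrifice times).  Least squares on
    log-rates (enforcing positivity) against the closed-form solution of
    the first-order chain.  A single fecal curve alone identifies the
    rates only as an unordered, poorly conditioned set; per-organ
    sampling as in the study design identifies each rate individually.
    """
    from .synthetic import TransitRates, simulate_biodistribution

    times = observed.index.to_numpy(dtype=float)
    cols = list(observed.columns)
    target = observed.to_numpy(dtype=float)

    def residuals(log_k):
        rates = TransitRates(*np.exp(log_k))
        study = simulate_biodistribution(
            regimen, rates=rates, uptake_fraction=uptake_fraction, times_h=times
        )
        return (study.pd_mass_ug[cols].to_numpy() - target).ravel()

    sol = optimize.least_squares(residuals, np.log(initial_rates), method="lm")
    if not sol.success:
        raise RuntimeError(f"transit-rate fit failed: {sol.message}")
    return TransitRates(*np.exp(sol.x))
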