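"""ICP-MS quantification of Pd with drift correction and LOD/LOQ censoring.

Samples are microwave acid digests diluted 13:3 before measurement; the
instrument is calibrated daily against a 0-25 ug Pd/L standard series and
monitored with Y/Sc internal standards.  Intensities are converted to
concentrations by ordinary least squares, back-calculated through the
dilution and digest volume to a per-sample Pd mass (ng), and censored:
masses below the sample LOD are reported "bdl" (never zero), masses
between LOD and LOQ are set to the LOD value.  Only the 106Pd channel is
used for reporting; other isotopes are retained for QC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = (
    "record_type",
    "id",
    "nominal_conc",
    "intensity_106",
    "intensity_IS",
    "dilution_factor",
    "digest_volume_mL",
    "order",
)

STATUS_QUANTIFIED = "quantified"
STATUS_BETWEEN = "between_lod_loq_set_to_lod"
STATUS_BDL = "below_detection"

#: Sentinel used wherever a below-detection value is rendered as text.
BDL_SENTINEL = "bdl"


@dataclass
class IcpmsBatch:
    """One acquisition run: standards, blanks and samples in one table."""

    records: pd.DataFrame
    diagnostics: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"batch table missing columns: {missing}")
        if (self.records["dilution_factor"] < 1).any():
            raise ValueError("dilution factors must be >= 1")
        if (self.records["digest_volume_mL"] <= 0).any():
            raise ValueError("digest volumes must be positive")

    def of_type(self, record_type: str) -> pd.DataFrame:
        return self.records[self.records["record_type"] == record_type]

    @property
    def standards(self) -> pd.DataFrame:
        return self.of_type("standard")

    @property
    def blanks(self) -> pd.DataFrame:
        return self.of_type("blank")

    @property
    def samples(self) -> pd.DataFrame:
        return self.of_type("sample")


@dataclass(frozen=True)
class CalibrationCurve:
    """OLS calibration intensity ~ concentration plus blank-based limits."""

    slope: float  # counts per (ug/L)
    intercept: float  # counts
    r_squared: float
    residual_sd: float
    lod_ug_l: float
    loq_ug_l: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")
        if self.lod_ug_l > self.loq_ug_l:
            raise ValueError("LOD must not exceed LOQ")


@dataclass(frozen=True)
class MeasuredMass:
    """A censored per-sample Pd mass.

    ``value_ng`` is NaN for below-detection results; render them with
    ``display`` which yields the "bdl" sentinel, never 0.
    """

    value_ng: float
    status: str
    sample_lod_ng: float
    sample_loq_ng: float

    @property
    def display(self) -> str:
        if self.status == STATUS_BDL:
            return BDL_SENTINEL
        return f"{self.value_ng:.6g}"

    def contribution_ng(self) -> tuple[float, bool]:
        """Value entering downstream sums, plus a censored flag.

        bdl contributes 0 (flagged); between contributes its LOD value
        (flagged); quantified contributes its value (unflagged).
        """
        if self.status == STATUS_BDL:
            return 0.0, True
        return self.value_ng, self.status == STATUS_BETWEEN


def drift_correct(batch: IcpmsBatch) -> IcpmsBatch:
    """Normalise analyte intensities by the internal-standard channel.

    Each record's analyte intensity is divided by (record IS / mean IS
    over the standards), removing a common multiplicative sensitivity
    drift.  Records with non-positive internal standard are rejected and
    reported in the returned batch's diagnostics.
    """
    records = batch.records.copy()
    std_is = records.loc[records["record_type"] == "standard", "intensity_IS"]
    if len(std_is) == 0:
        raise ValueError("drift correction requires standards in the batch")
    reference = float(std_is.mean())
    if reference <= 0:
        raise ValueError("mean internal-standard intensity over standards must be positive")
    bad = records["intensity_IS"] <= 0
    diagnostics = list(batch.diagnostics)
    for rid in records.loc[bad, "id"]:
        diagnostics.append(f"record {rid}: non-positive internal standard, rejected")
    records = records[~bad].copy()
    factor = records["intensity_IS"] / reference
    records["intensity_106"] = records["intensity_106"] / factor
    records["intensity_IS"] = reference
    return IcpmsBatch(records=records, diagnostics=diagnostics)


def fit_calibration(
    standards: pd.DataFrame,
    blanks: pd.DataFrame,
    lod_factor: float = 3.0,
    loq_factor: float = 10.0,
) -> CalibrationCurve:
    """OLS fit of standard intensities vs nominal concentration.

    Instrument limits come from the blank scatter: LOD = lod_factor *
    sd(blanks) / slope and LOQ = loq_factor * sd(blanks) / slope (in
    ug/L).  The 3/10 defaults are the conventional blank-based rule; both
    factors are configurable.
    """
    conc = standards["nominal_conc"].to_numpy(dtype=float)
    intensity = standards["intensity_106"].to_numpy(dtype=float)
    if len(np.unique(conc[conc > 0])) < 3:
        raise ValueError("calibration needs at least 3 distinct non-zero standards")
    X = np.column_stack([conc, np.ones_like(conc)])
    if np.linalg.matrix_rank(X) < 2:
        raise ValueError("singular calibration design")
    beta, *_ = np.linalg.lstsq(X, intensity, rcond=None)
    slope, intercept = float(beta[0]), float(beta[1])
    fitted = slope * conc + intercept
    ss_res = float(np.sum((intensity - fitted) ** 2))
    ss_tot = float(np.sum((intensity - intensity.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    dof = max(len(conc) - 2, 1)
    residual_sd = math.sqrt(ss_res / dof)
    blank_sd = float(np.std(blanks["intensity_106"].to_numpy(dtype=float), ddof=1)) if len(blanks) > 1 else 0.0
    return CalibrationCurve(
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        residual_sd=residual_sd,
        lod_ug_l=lod_factor * blank_sd / slope,
        loq_ug_l=loq_factor * blank_sd / slope,
    )


def quantify_sample(
    intensity: float,
    curve: CalibrationCurve,
    dilution_factor: float = 13.0 / 3.0,
    digest_volume_ml: float = 3.0,
) -> MeasuredMass:
    """Back-calculate a censored Pd mass (ng) from a sample intensity.

    conc_measured = (I - intercept)/slope on the diluted solution;
    conc_digest = conc_measured * dilution_factor; mass = conc_digest
    (ug/L == ng/mL) * digest volume (mL).  Sample LOD/LOQ are the
    instrument limits scaled by the digest volume, and censoring follows
    the rule: below sample LOD -> bdl, between LOD and LOQ -> set to LOD.
    """
    if dilution_factor < 1:
        raise ValueError("dilution factor must be >= 1")
    if digest_volume_ml <= 0:
        raise ValueError("digest volume must be positive")
    conc_measured = (intensity - curve.intercept) / curve.slope
    mass_ng = conc_measured * dilution_factor * digest_volume_ml
    sample_lod = curve.lod_ug_l * digest_volume_ml
    sample_loq = curve.loq_ug_l * digest_volume_ml
    if mass_ng <= 0 or mass_ng < sample_lod:
        return MeasuredMass(float("nan"), STATUS_BDL, sample_lod, sample_loq)
    if mass_ng < sample_loq:
        return MeasuredMass(sample_lod, STATUS_BETWEEN, sample_lod, sample_loq)
    return MeasuredMass(float(mass_ng), STATUS_QUANTIFIED, sample_lod, sample_loq)


def scale_half_organ(
    measured: MeasuredMass, partial_weight_g: float, total_weight_g: float
) -> MeasuredMass:
    """Scale a half-organ measurement to the whole organ by weight ratio.

    Value and sample LOD/LOQ scale by total/partial; status is preserved.
    """
    if partial_weight_g <= 0:
        raise ValueError("partial weight must be positive")
    if partial_weight_g > total_weight_g:
        raise ValueError("partial weight cannot exceed total weight")
    ratio = total_weight_g / partial_weight_g
    return replace(
        measured,
        value_ng=measured.value_ng * ratio,
        sample_lod_ng=measured.sample_lod_ng * ratio,
        sample_loq_ng=measured.sample_loq_ng * ratio,
    )


def quantify_batch(
    batch: IcpmsBatch,
    lod_factor: float = 3.0,
    loq_factor: float = 10.0,
    apply_drift_correction: bool = True,
) -> pd.DataFrame:
    """Full pipeline for one batch: drift-correct, calibrate, quantify.

    Returns a per-sample table (id, mass_ng, status, sample_lod_ng,
    sample_loq_ng) with bdl values rendered by the sentinel in the
    ``display`` column.
    """
    if apply_drift_correction:
        batch = drift_correct(batch)
    curve = fit_calibration(batch.standards, batch.blanks, lod_factor, loq_factor)
    rows = []
    for _, rec in batch.samples.iterrows():
        m = quantify_sample(
            rec["intensity_106"], curve, rec["dilution_factor"], rec["digest_volume_mL"]
        )
        rows.append(
            {
                "id": rec["id"],
                "mass_ng": m.value_ng,
                "status": m.status,
                "sample_lod_ng": m.sample_lod_ng,
                "sample_loq_ng": m.sample_loq_ng,
                "display": m.display,
            }
        )
    return pd.DataFrame(rows)
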