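"""End-to-end pipeline: simulate -> quantify (XFI, ICP-MS, IMC) -> report.

Each stage writes its tables under the output directory and registers
them in a run manifest (config hash, package version, seed, per-stage
file lists).  Report headers echo the censoring and thresholding choices
so the outputs are self-describing.  Runs are deterministic given the
seed: per-instrument noise streams are spawned from one SeedSequence.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, biodist, icpms, imc, io, synthetic, xfi
from .config import PipelineConfig

log = logging.getLogger("pdtrace.pipeline")

#: Compartments measured as "organs" by the virtual instruments.
ORGAN_COMPARTMENTS = ("stomach", "small_intestine", "cecum", "colon", "systemic")


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunManifest:
    config_hash: str
    package_version: str
    seed: int
    started_at: str
    finished_at: str = ""
    stages: dict[str, list[str]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "package_version": self.package_version,
            "seed": self.seed,
            "started_at": self.started_at,
            "finished_at": self.finished_at,
            "stages": self.stages,
        }


def _child_seeds(seed: int, n: int) -> list[int]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % 2**31) for c in children]


def run_pipeline(config: PipelineConfig, outdir: Path) -> RunManifest:
    """Execute the full workflow and return its manifest.

    Re-running with the same config and output directory reproduces
    bit-identical tables (manifest timestamps excepted).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=hashlib.sha256(config.canonical_yaml().encode()).hexdigest(),
        package_version=__version__,
        seed=config.seed,
        started_at=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    seeds = _child_seeds(config.seed, 3)
    state: dict = {}
    for stage, func in (
        ("simulate", _stage_simulate),
        ("xfi", _stage_xfi),
        ("icpms", _stage_icpms),
        ("imc", _stage_imc),
        ("report", _stage_report),
    ):
        log.info("running stage %s", stage)
        try:
            files = func(config, outdir, seeds, state)
        except Exception as exc:  # noqa: BLE001 - stage-tagged diagnostic
            io.write_manifest(outdir / "manifest.json", manifest.to_dict())
            raise StageError(stage, exc) from exc
        manifest.stages[stage] = [str(f.relative_to(outdir)) for f in files]
    manifest.finished_at = time.strftime("%Y-%m-%dT%H:%M:%S")
    io.write_manifest(outdir / "manifest.json", manifest.to_dict())
    return manifest


def _stage_simulate(config, outdir, seeds, state) -> list[Path]:
    sc = config.scenario
    regimen = synthetic.DoseRegimen(
        daily_np_mass_mg=sc.daily_np_mass_mg,
        daily_pd_mass_ug=sc.daily_pd_mass_ug,
        schedule_h=tuple(sc.schedule_h),
        gavage_volume_ul=sc.gavage_volume_ul,
    )
    rates = synthetic.TransitRates(**sc.rates.model_dump())
    study = synthetic.simulate_biodistribution(
        regimen,
        rates=rates,
        uptake_fraction=sc.uptake_fraction,
        times_h=sc.times_h,
        seed=config.seed,
    )
    state["study"] = study
    state["regimen"] = regimen
    path = outdir / "ground_truth.tsv"
    io.write_ground_truth(path, study.to_table())
    return [path]


def _final_organ_masses(state) -> pd.Series:
    study = state["study"]
    return study.pd_mass_ug.iloc[-1]


def _stage_xfi(config, outdir, seeds, state) -> list[Path]:
    masses = _final_organ_masses(state)
    beam = synthetic.BeamConfig(flux_ph_s=config.xfi.flux_ph_s, dwell_s=config.xfi.dwell_s)
    files: list[Path] = []
    results = []
    rng_seeds = _child_seeds(seeds[0], len(ORGAN_COMPARTMENTS))
    for organ_seed, organ in zip(rng_seeds, ORGAN_COMPARTMENTS):
        truth = np.zeros((config.xfi.grid_ny, config.xfi.grid_nx))
        mass = float(masses[organ])
        # deterministic split of the organ burden over two pixels
        truth[0, 0] = 0.6 * mass
        truth[-1, -1] = 0.4 * mass
        scan = synthetic.generate_xfi_scan(
            truth,
            beam=beam,
            background_rate=config.xfi.background_rate,
            seed=organ_seed,
            reference_areal_masses_ug_cm2=tuple(config.xfi.reference_areal_masses_ug_cm2),
        )
        calib = xfi.calibrate_from_scan(scan)
        mass_map = xfi.build_mass_map(scan, calib)
        map_path = outdir / "xfi" / f"{organ}_mass_map.tsv"
        io.write_mass_map(map_path, mass_map)
        files.append(map_path)
        results.append(
            {"organ": organ, "mass_ug": mass_map.total_ug, "truth_ug": mass, "k": calib.k_counts_per_ug_s}
        )
    table = pd.DataFrame(results)
    path = outdir / "xfi" / "organ_masses.tsv"
    ledger = pd.DataFrame(
        {
            "mouse": "m1",
            "organ": table["organ"],
            "method": "XFI",
            "mass": table["mass_ug"],
            "unit": "ug",
            "status": "",
        }
    )
    io.write_generic(path, ledger, "ledger-organs")
    state["xfi_organs"] = table
    files.append(path)
    return files


def _stage_icpms(config, outdir, seeds, state) -> list[Path]:
    study = state["study"]
    masses = _final_organ_masses(state)
    ic = config.icpms
    # organ digests, then per-interval feces samples
    feces = study.pd_mass_ug["feces"].to_numpy()
    feces_intervals = np.diff(np.concatenate([[0.0], feces]))
    organ_concs = [
        float(masses[o]) * 1000.0 / (ic.dilution_factor * ic.digest_volume_ml)
        for o in ORGAN_COMPARTMENTS
    ]
    feces_concs = [
        max(m, 0.0) * 1000.0 / (ic.dilution_factor * ic.digest_volume_ml) for m in feces_intervals
    ]
    batch = synthetic.generate_icpms_batch(
        organ_concs + feces_concs,
        slope=ic.slope,
        intercept=ic.intercept,
        blank_sd=ic.blank_sd,
        drift=ic.drift,
        seed=seeds[1],
        dilution_factor=ic.dilution_factor,
        digest_volume_ml=ic.digest_volume_ml,
    )
    batch_path = outdir / "icpms" / "batch.csv"
    io.write_icpms_batch(batch_path, batch)
    results = icpms.quantify_batch(
        batch, lod_factor=config.analysis.lod_factor, loq_factor=config.analysis.loq_factor
    )
    labels = list(ORGAN_COMPARTMENTS) + [f"feces_{t:g}h" for t in study.times_h]
    results.insert(0, "label", labels)
    res_path = outdir / "icpms" / "results.csv"
    io.write_generic(
        res_path,
        results,
        "icpms-results",
        meta={
            "censoring": "bdl->sentinel, between->LOD",
            "lod_factor": config.analysis.lod_factor,
            "loq_factor": config.analysis.loq_factor,
        },
    )
    state["icpms_results"] = results
    return [batch_path, res_path]


def _stage_imc(config, outdir, seeds, state) -> list[Path]:
    masses = _final_organ_masses(state)
    im = config.imc
    si_mass = float(masses["small_intestine"])
    n_sites = min(im.max_particle_pixels, max(int(round(si_mass * im.particles_per_ug)), 1))
    rng = np.random.default_rng(np.random.SeedSequence(seeds[2]))
    xs = rng.integers(0, im.width, size=n_sites)
    ys = rng.integers(0, im.height, size=n_sites)
    sites = [(int(x), int(y), int(rng.integers(1, 4))) for x, y in zip(xs, ys)]
    roi = synthetic.generate_imc_roi(
        im.width,
        im.height,
        sites,
        ions_per_particle=im.ions_per_particle,
        noise_max=im.noise_max,
        seed=seeds[2],
        roi_id="si_roi_1",
        tissue="small_intestine",
    )
    roi_path = outdir / "imc" / "si_roi_1.txt"
    io.write_imc_roi(roi_path, roi)
    summary = imc.threshold_pixels(roi, "Pd108", config.analysis.noise_ceiling)
    positives = pd.DataFrame(
        [
            {"roi": roi.roi_id, "channel": "Pd108", "x": x, "y": y, "dual_counts": v}
            for x, y, v in summary.positives
        ],
        columns=["roi", "channel", "x", "y", "dual_counts"],
    )
    pos_path = outdir / "imc" / "positives.tsv"
    io.write_generic(
        pos_path,
        positives,
        "imc-positives",
        meta={"noise_ceiling": config.analysis.noise_ceiling},
    )
    state["imc_summary"] = summary
    return [roi_path, pos_path]


def _stage_report(config, outdir, seeds, state) -> list[Path]:
    study = state["study"]
    dose = study.regimen.daily_pd_mass_ug
    xfi_organs = state["xfi_organs"]
    ic_results = state["icpms_results"]

    organ_rows = []
    for _, row in xfi_organs.iterrows():
        organ_rows.append(
            {"mouse": "m1", "organ": row["organ"], "method": "XFI", "mass": row["mass_ug"], "unit": "ug", "status": ""}
        )
    ic_organ = ic_results.iloc[: len(ORGAN_COMPARTMENTS)]
    for organ, (_, row) in zip(ORGAN_COMPARTMENTS, ic_organ.iterrows()):
        mass_ng = 0.0 if row["status"] == icpms.STATUS_BDL else float(row["mass_ng"])
        organ_rows.append(
            {"mouse": "m1", "organ": organ, "method": "ICPMS", "mass": mass_ng, "unit": "ng", "status": row["status"] if row["status"] != icpms.STATUS_QUANTIFIED else ""}
        )
    organ_masses = pd.DataFrame(organ_rows)

    ic_feces = ic_results.iloc[len(ORGAN_COMPARTMENTS) :]
    feces_mass_ug = [
        0.0 if s == icpms.STATUS_BDL else m / 1000.0
        for m, s in zip(ic_feces["mass_ng"], ic_feces["status"])
    ]
    excretion = pd.DataFrame(
        {
            "subject": "m1",
            "time_h": study.times_h,
            "pd_mass_ug": feces_mass_ug,
            "method": "ICPMS",
            "status": ic_feces["status"].to_numpy(),
        }
    )
    ledger = biodist.StudyLedger(
        applied_dose_ug=dose, organ_masses=organ_masses, excretion_series=excretion
    )

    import warnings as _warnings

    per_organ = organ_masses.copy()
    scale = np.where(per_organ["unit"] == "ng", 1e-3, 1.0)
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        per_organ["pct_dose"] = [
            biodist.percent_of_dose(m * s, dose) for m, s in zip(per_organ["mass"], scale)
        ]
    per_organ["censored"] = per_organ["status"].isin(
        [icpms.STATUS_BDL, icpms.STATUS_BETWEEN]
    )

    cumulative = biodist.cumulative_excretion(excretion, dose)
    totals = []
    for method in ("XFI", "ICPMS"):
        pct, n_cens = biodist.total_recovery(ledger, "m1", method)
        totals.append({"mouse": "m1", "method": method, "pct_dose": pct, "n_censored": n_cens})
    totals = pd.DataFrame(totals)

    paired = pd.DataFrame(
        {
            "sample": ORGAN_COMPARTMENTS,
            "mass_a": [
                float(per_organ[(per_organ["organ"] == o) & (per_organ["method"] == "XFI")]["pct_dose"].iloc[0])
                for o in ORGAN_COMPARTMENTS
            ],
            "mass_b": [
                float(per_organ[(per_organ["organ"] == o) & (per_organ["method"] == "ICPMS")]["pct_dose"].iloc[0])
                for o in ORGAN_COMPARTMENTS
            ],
        }
    )
    paired = paired[(paired["mass_a"] > 0)]
    agreement = biodist.method_agreement(paired) if len(paired) >= 3 else None

    header = {
        "applied_dose_ug": dose,
        "censoring": "bdl->0 flagged, between->LOD flagged",
        "noise_ceiling": config.analysis.noise_ceiling,
    }
    files = []
    for name, df, kind in (
        ("per_organ_pct.tsv", per_organ.assign(mass=per_organ["mass"]), "ledger-organs"),
        ("cumulative_excretion.tsv", cumulative.assign(subject="m1", pd_mass_ug=np.nan, method="ICPMS")[["subject", "time_h", "pd_mass_ug", "method", "cumulative_pct", "censored"]], "excretion-series"),
    ):
        path = outdir / "report" / name
        io.write_generic(path, df, kind, meta=header)
        files.append(path)
    totals_path = outdir / "report" / "total_recovery.tsv"
    io.write_generic(totals_path, totals.rename(columns={"pct_dose": "mass"}).assign(organ="total", unit="ug", status="")[["mouse", "organ", "method", "mass", "unit", "status", "n_censored"]], "ledger-organs", meta=header)
    files.append(totals_path)
    if agreement is not None:
        agree_path = outdir / "report" / "method_agreement.json"
        io.write_manifest(agree_path, agreement.__dict__)
        files.append(agree_path)
    state["report"] = biodist.RecoveryReport(
        per_organ_pct=per_organ,
        cumulative_excretion=cumulative,
        total_recovery_pct=totals,
        method_agreement=agreement,
    )
    return files
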