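"""Delimited-text dialects used by the pipeline.

Every file starts with a versioned header comment ``# pdtrace-format:
<kind> <version>``; readers refuse unknown versions.  The IMC ROI reader
additionally accepts headerless TXT exports (the field dialect: one row
per pixel, columns X, Y, then channel columns such as "Pd108", extra
columns tolerated).
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .icpms import REQUIRED_COLUMNS as ICPMS_COLUMNS
from .icpms import IcpmsBatch
from .imc import ImcRoi, TitrationSeries, TitrationSpot
from .xfi import DetectorGeometry, ReferenceTarget, Spectrum, XfiMassMap, XfiScan

FORMAT_KEY = "# pdtrace-format:"
FORMAT_VERSION = 1

KNOWN_KINDS = (
    "spectrum",
    "scan-index",
    "mass-map",
    "imc-roi",
    "icpms-batch",
    "ground-truth",
    "ledger-organs",
    "excretion-series",
    "titration-series",
    "imc-positives",
    "icpms-results",
)


def _header_line(kind: str) -> str:
    return f"{FORMAT_KEY} {kind} {FORMAT_VERSION}"


def _check_header(first_line: str, kind: str, path: Path) -> None:
    parts = first_line.strip().split()
    if len(parts) != 4 or " ".join(parts[:2]) != FORMAT_KEY:
        raise ValueError(f"{path}: missing '{FORMAT_KEY}' header")
    found_kind, version = parts[2], parts[3]
    if found_kind != kind:
        raise ValueError(f"{path}: expected format {kind!r}, found {found_kind!r}")
    if version != str(FORMAT_VERSION):
        raise ValueError(f"{path}: unsupported {kind} format version {version}")


def _read_table(path: Path, kind: str, sep: str = "\t") -> tuple[pd.DataFrame, dict]:
    text = Path(path).read_text()
    lines = text.splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    _check_header(lines[0], kind, Path(path))
    meta = {}
    body_start = 1
    for line in lines[1:]:
        if not line.startswith("#"):
            break
        body_start += 1
        key, _, value = line.lstrip("# ").partition(":")
        meta[key.strip()] = value.strip()
    df = pd.read_csv(_io.StringIO("\n".join(lines[body_start:])), sep=sep)
    return df, meta


def _write_table(path: Path, df: pd.DataFrame, kind: str, meta: dict | None = None, sep: str = "\t") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write(_header_line(kind) + "\n")
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep=sep, index=False)


# ---------------------------------------------------------------------------
# XFI spectra and scans
# ---------------------------------------------------------------------------


def write_spectrum(path: Path, spectrum: Spectrum, pixel: tuple[int, int] | None = None) -> None:
    """Two-column (energy_keV, counts) text file with dwell/pixel header."""
    meta = {"dwell_s": spectrum.dwell_s}
    if pixel is not None:
        meta["pixel"] = f"{pixel[0]} {pixel[1]}"
    df = pd.DataFrame({"energy_keV": spectrum.energy_kev, "counts": spectrum.counts})
    _write_table(path, df, "spectrum", meta)


def read_spectrum(path: Path) -> tuple[Spectrum, dict]:
    df, meta = _read_table(path, "spectrum")
    if list(df.columns) != ["energy_keV", "counts"]:
        raise ValueError(f"{path}: spectrum files need columns energy_keV, counts")
    dwell = float(meta.get("dwell_s", 1.0))
    return Spectrum(df["energy_keV"].to_numpy(), df["counts"].to_numpy(), dwell), meta


def write_scan(directory: Path, scan: XfiScan) -> list[Path]:
    """A scan directory: per-pixel spectrum files plus an index table."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ny, nx = scan.shape
    rows = []
    written = []
    for iy in range(ny):
        for ix in range(nx):
            name = f"pixel_{iy}_{ix}.tsv"
            write_spectrum(directory / name, scan.pixel(iy, ix), pixel=(iy, ix))
            rows.append({"kind": "pixel", "iy": iy, "ix": ix, "areal_mass_ug_cm2": "", "file": name})
            written.append(directory / name)
    for i, ref in enumerate(scan.references):
        name = f"reference_{i}.tsv"
        write_spectrum(directory / name, ref.spectrum)
        rows.append(
            {"kind": "reference", "iy": "", "ix": "", "areal_mass_ug_cm2": ref.areal_mass_ug_cm2, "file": name}
        )
        written.append(directory / name)
    meta = {
        "ny": ny,
        "nx": nx,
        "dwell_s": scan.dwell_s,
        "pixel_size_mm": scan.pixel_size_mm,
        "beam_energy_kev": scan.beam_energy_kev,
        "beam_area_mm2": scan.beam_area_mm2,
    }
    index = directory / "index.tsv"
    _write_table(index, pd.DataFrame(rows), "scan-index", meta)
    written.append(index)
    return written


def read_scan(directory: Path, detector: DetectorGeometry | None = None) -> XfiScan:
    directory = Path(directory)
    index, meta = _read_table(directory / "index.tsv", "scan-index")
    ny, nx = int(meta["ny"]), int(meta["nx"])
    energy = None
    counts = None
    references = []
    for _, row in index.iterrows():
        spec, _ = read_spectrum(directory / row["file"])
        if row["kind"] == "pixel":
            if counts is None:
                energy = spec.energy_kev
                counts = np.zeros((ny, nx, len(energy)))
            counts[int(row["iy"]), int(row["ix"])] = spec.counts
        else:
            references.append(
                ReferenceTarget(
                    element="Pd",
                    areal_mass_ug_cm2=float(row["areal_mass_ug_cm2"]),
                    spectrum=spec,
                )
            )
    if counts is None:
        raise ValueError(f"{directory}: scan index lists no pixels")
    return XfiScan(
        energy_kev=energy,
        counts=counts,
        dwell_s=float(meta["dwell_s"]),
        pixel_size_mm=float(meta["pixel_size_mm"]),
        beam_energy_kev=float(meta["beam_energy_kev"]),
        beam_area_mm2=float(meta["beam_area_mm2"]),
        detector=detector or DetectorGeometry(),
        references=references,
    )


def write_mass_map(path: Path, mass_map: XfiMassMap) -> None:
    """Mass map as a TSV grid (ug/pixel), one row per scan row."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write(_header_line("mass-map") + "\n")
        fh.write(f"# pixel_size_mm: {mass_map.pixel_size_mm}\n")
        fh.write(f"# total_ug: {mass_map.total_ug!r}\n")
        np.savetxt(fh, mass_map.mass_ug, delimiter="\t")


def read_mass_map(path: Path) -> XfiMassMap:
    lines = Path(path).read_text().splitlines()
    _check_header(lines[0], "mass-map", Path(path))
    meta = {}
    body = []
    for line in lines[1:]:
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition(":")
            meta[key.strip()] = value.strip()
        else:
            body.append(line)
    grid = np.loadtxt(_io.StringIO("\n".join(body)), delimiter="\t", ndmin=2)
    return XfiMassMap(
        mass_ug=grid,
        sigma_ug=np.zeros_like(grid),
        lod_ug=np.zeros_like(grid),
        pixel_size_mm=float(meta.get("pixel_size_mm", 1.0)),
    )


def export_mass_map_tiff(path: Path, mass_map: XfiMassMap) -> None:
    """Optional single-channel 32-bit TIFF export of the mass grid."""
    import tifffile

    tifffile.imwrite(str(path), mass_map.mass_ug.astype(np.float32))


# ---------------------------------------------------------------------------
# IMC ROI TXT
# ---------------------------------------------------------------------------


def write_imc_roi(path: Path, roi: ImcRoi) -> None:
    meta = {"roi_id": roi.roi_id, "tissue": roi.tissue}
    _write_table(path, roi.to_frame(), "imc-roi", meta)


def read_imc_roi(path: Path, roi_id: str | None = None) -> ImcRoi:
    """Read the IMC TXT dialect; tolerates a headerless field export."""
    path = Path(path)
    first = path.read_text().splitlines()[0] if path.read_text() else ""
    if first.startswith("#"):
        df, meta = _read_table(path, "imc-roi")
        roi_id = roi_id or meta.get("roi_id", path.stem)
        tissue = meta.get("tissue", "")
    else:
        df = pd.read_csv(path, sep="\t")
        roi_id = roi_id or path.stem
        tissue = ""
    for col in ("X", "Y"):
        if col not in df.columns:
            raise ValueError(f"{path}: IMC ROI table missing column {col!r}")
    channel_cols = [c for c in df.columns if c.startswith("Pd")]
    if not channel_cols:
        raise ValueError(f"{path}: no Pd channel columns found")
    w = int(df["X"].max()) + 1
    h = int(df["Y"].max()) + 1
    channels = {}
    for ch in channel_cols:
        grid = np.zeros((h, w))
        grid[df["Y"].to_numpy(dtype=int), df["X"].to_numpy(dtype=int)] = df[ch].to_numpy(dtype=float)
        channels[ch] = grid
    return ImcRoi(channels=channels, roi_id=roi_id, tissue=tissue)


# ---------------------------------------------------------------------------
# ICP-MS batches, titration, study tables
# ---------------------------------------------------------------------------


def write_icpms_batch(path: Path, batch: IcpmsBatch) -> None:
    _write_table(path, batch.records, "icpms-batch", sep=",")


def read_icpms_batch(path: Path) -> IcpmsBatch:
    df, _ = _read_table(path, "icpms-batch", sep=",")
    missing = [c for c in ICPMS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: batch table missing columns {missing}")
    return IcpmsBatch(records=df)


def write_titration_series(path: Path, series: TitrationSeries) -> None:
    df = pd.DataFrame(
        [
            {"spot": s.index, "pd_mass_ng": s.pd_mass_ng, "dilution_factor": s.dilution_factor}
            for s in series.spots
        ]
    )
    meta = {
        "start_conc_ng_ul": series.start_conc_ng_ul,
        "spot_volume_ul": series.spot_volume_ul,
        "factor_convention": series.factor_convention,
    }
    _write_table(path, df, "titration-series", meta)


def read_titration_series(path: Path) -> TitrationSeries:
    df, meta = _read_table(path, "titration-series")
    spots = tuple(
        TitrationSpot(
            index=int(r["spot"]),
            pd_mass_ng=float(r["pd_mass_ng"]),
            dilution_factor=int(r["dilution_factor"]),
        )
        for _, r in df.iterrows()
    )
    return TitrationSeries(
        spots=spots,
        start_conc_ng_ul=float(meta["start_conc_ng_ul"]),
        spot_volume_ul=float(meta["spot_volume_ul"]),
        factor_convention=meta.get("factor_convention", "suspension"),
    )


def write_ground_truth(path: Path, table: pd.DataFrame) -> None:
    _write_table(path, table, "ground-truth")


def read_ground_truth(path: Path) -> pd.DataFrame:
    df, _ = _read_table(path, "ground-truth")
    return df


def write_generic(path: Path, df: pd.DataFrame, kind: str, meta: dict | None = None) -> None:
    if kind not in KNOWN_KINDS:
        raise ValueError(f"unknown format kind {kind!r}")
    _write_table(path, df, kind, meta)


def read_generic(path: Path, kind: str) -> tuple[pd.DataFrame, dict]:
    return _read_table(path, kind)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Diagnostic:
    path: str
    line: int  # 1-based; 0 when the problem is file-level
    message: str

    def __str__(self) -> str:
        return f"{self.path}:{self.line}: {self.message}"


_REQUIRED_TABLE_COLUMNS = {
    "icpms-batch": list(ICPMS_COLUMNS),
    "ground-truth": ["compartment", "time_h", "pd_mass_ug"],
    "ledger-organs": ["mouse", "organ", "method", "mass", "unit", "status"],
    "excretion-series": ["subject", "time_h", "pd_mass_ug", "method"],
    "titration-series": ["spot", "pd_mass_ng", "dilution_factor"],
    "imc-positives": ["roi", "channel", "x", "y", "dual_counts"],
    "icpms-results": ["id", "mass_ng", "status", "sample_lod_ng", "sample_loq_ng"],
    "imc-roi": ["X", "Y"],
    "scan-index": ["kind", "iy", "ix", "areal_mass_ug_cm2", "file"],
    "spectrum": ["energy_keV", "counts"],
}

_UNIT_COLUMN_VALUES = {"ledger-organs": ("unit", {"ng", "ug"})}


def validate_formats(paths: list[Path]) -> list[Diagnostic]:
    """Schema-check supported text dialects; diagnostics carry line numbers."""
    diags: list[Diagnostic] = []
    for path in paths:
        path = Path(path)
        if not path.exists():
            diags.append(Diagnostic(str(path), 0, "file does not exist"))
            continue
        lines = path.read_text().splitlines()
        if not lines:
            diags.append(Diagnostic(str(path), 0, "empty file"))
            continue
        parts = lines[0].split()
        if not lines[0].startswith(FORMAT_KEY) or len(parts) != 4:
            diags.append(Diagnostic(str(path), 1, f"missing '{FORMAT_KEY} <kind> <version>' header"))
            continue
        kind, version = parts[2], parts[3]
        if kind not in KNOWN_KINDS:
            diags.append(Diagnostic(str(path), 1, f"unknown format kind {kind!r}"))
            continue
        if version != str(FORMAT_VERSION):
            diags.append(Diagnostic(str(path), 1, f"unsupported {kind} version {version}"))
            continue
        header_end = 1
        for line in lines[1:]:
            if not line.startswith("#"):
                break
            header_end += 1
        if header_end >= len(lines):
            diags.append(Diagnostic(str(path), header_end, "no column header row"))
            continue
        sep = "," if kind == "icpms-batch" else "\t"
        if kind == "mass-map":
            for i, line in enumerate(lines[header_end:], start=header_end + 1):
                try:
                    [float(tok) for tok in line.split("\t")]
                except ValueError:
                    diags.append(Diagnostic(str(path), i, "non-numeric entry in mass grid"))
            continue
        columns = lines[header_end].split(sep)
        required = _REQUIRED_TABLE_COLUMNS.get(kind, [])
        for col in required:
            if col not in columns:
                diags.append(Diagnostic(str(path), header_end + 1, f"missing column {col!r}"))
        if kind == "imc-roi" and not any(c.startswith("Pd") for c in columns):
            diags.append(Diagnostic(str(path), header_end + 1, "no Pd channel column"))
        if any(col not in columns for col in required):
            continue
        unit_rule = _UNIT_COLUMN_VALUES.get(kind)
        numeric_cols = [
            c
            for c in required
            if c not in ("record_type", "id", "compartment", "mouse", "organ", "method", "unit", "status", "subject", "kind", "file")
        ]
        for i, line in enumerate(lines[header_end + 1 :], start=header_end + 2):
            if not line.strip():
                continue
            values = dict(zip(columns, line.split(sep)))
            for col in numeric_cols:
                tok = values.get(col, "")
                if tok == "":
                    continue
                try:
                    float(tok)
                except ValueError:
                    diags.append(Diagnostic(str(path), i, f"non-numeric value {tok!r} in column {col!r}"))
            if unit_rule:
                col, allowed = unit_rule
                tok = values.get(col, "")
                if tok and tok not in allowed:
                    diags.append(
                        Diagnostic(str(path), i, f"unit mismatch: {tok!r} not in {sorted(allowed)}")
                    )
    return diags


def write_manifest(path: Path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
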