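"""Delimited-text I/O for cycle tables, spectral scans and protein tables.

All readers autodetect comma vs tab delimiters and raise parse errors that
name the offending file and column. Formats are deliberately plain so
simulator output is a drop-in analysis input.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import CycleSeries
from .pigments import SpectralScan
from .proteomics import ProteinAbundanceTable

__all__ = [
    "read_cycle_table",
    "write_cycle_table",
    "read_scan",
    "write_scan",
    "read_protein_table",
    "write_table",
]

CYCLE_COLUMNS = [
    "condition_W_m2",
    "cycle_id",
    "time_min",
    "biomass_gVSS_L",
    "acetate_mmol_L",
]


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return "\t" if "\t" in line else ","
    return ","


def read_cycle_table(path) -> list[CycleSeries]:
    """Read cycle time series from a flat table.

    Required columns: condition_W_m2, cycle_id, time_min, biomass_gVSS_L,
    acetate_mmol_L (blank = missing). Returns one CycleSeries per
    (condition, cycle_id), times converted to hours.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), comment="#")
    missing = [c for c in CYCLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    out = []
    for (cond, cid), grp in df.groupby(["condition_W_m2", "cycle_id"], sort=False):
        grp = grp.sort_values("time_min")
        out.append(
            CycleSeries(
                condition_irradiance=float(cond),
                cycle_id=str(cid),
                time=grp["time_min"].to_numpy(dtype=float) / 60.0,
                biomass=grp["biomass_gVSS_L"].to_numpy(dtype=float),
                acetate=grp["acetate_mmol_L"].to_numpy(dtype=float),
            )
        )
    return out


def write_cycle_table(cycles: list[CycleSeries], path) -> None:
    frames = []
    for cyc in cycles:
        f = cyc.to_frame()
        f["time_min"] = f.pop("time_h") * 60.0
        frames.append(f[CYCLE_COLUMNS])
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_scan(path) -> SpectralScan:
    """Read a two-column (wavelength_nm, absorbance) scan.

    An optional leading metadata block of ``# key = value`` lines may set
    sample_kind, pathlength_cm, biomass_g and solvent_L.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "=" in line:
                key, _, val = line.lstrip("# ").partition("=")
                meta[key.strip()] = val.strip()
    df = pd.read_csv(path, sep=_sniff_sep(path), comment="#")
    for col in ("wavelength_nm", "absorbance"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column '{col}'")
    return SpectralScan(
        wavelengths=df["wavelength_nm"].to_numpy(dtype=float),
        absorbance=df["absorbance"].to_numpy(dtype=float),
        sample_kind=meta.get("sample_kind", "extract"),
        pathlength=float(meta.get("pathlength_cm", 0.5)),
        biomass_g=float(meta["biomass_g"]) if "biomass_g" in meta else None,
        solvent_L=float(meta["solvent_L"]) if "solvent_L" in meta else None,
    )


def write_scan(scan: SpectralScan, path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# sample_kind = {scan.sample_kind}\n")
        fh.write(f"# pathlength_cm = {scan.pathlength}\n")
        if scan.biomass_g is not None:
            fh.write(f"# biomass_g = {scan.biomass_g}\n")
        if scan.solvent_L is not None:
            fh.write(f"# solvent_L = {scan.solvent_L}\n")
        writer = csv.writer(fh)
        writer.writerow(["wavelength_nm", "absorbance"])
        for wl, ab in zip(scan.wavelengths, scan.absorbance):
            writer.writerow([f"{wl:g}", f"{ab:.6g}"])


def read_protein_table(
    areas_path, sample_sheet_path, annotations_path=None
) -> ProteinAbundanceTable:
    """Assemble a ProteinAbundanceTable from delimited files.

    ``areas``: first column = protein ID, remaining columns = sample areas.
    ``sample sheet``: columns sample, condition, replicate.
    ``annotations`` (optional): columns protein, taxon, category.
    """
    areas_path = Path(areas_path)
    areas = pd.read_csv(areas_path, sep=_sniff_sep(areas_path), index_col=0)
    sheet_path = Path(sample_sheet_path)
    sheet = pd.read_csv(sheet_path, sep=_sniff_sep(sheet_path))
    for col in ("sample", "condition"):
        if col not in sheet.columns:
            raise ValueError(f"{sheet_path}: missing column '{col}'")
    conditions = sheet.set_index("sample")["condition"]
    taxa = categories = None
    if annotations_path is not None:
        ann_path = Path(annotations_path)
        ann = pd.read_csv(ann_path, sep=_sniff_sep(ann_path))
        if "protein" not in ann.columns:
            raise ValueError(f"{ann_path}: missing column 'protein'")
        ann = ann.set_index("protein")
        taxa = ann["taxon"] if "taxon" in ann.columns else None
        categories = ann["category"] if "category" in ann.columns else None
    return ProteinAbundanceTable(
        areas=areas, conditions=conditions, taxa=taxa, categories=categories
    )


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
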