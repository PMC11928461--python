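"""File I/O: TIFF images with pixel-size metadata, fixed-column CSV
tables and JSON ground-truth sidecars.

Column names are fixed per modality so files round-trip without extra
configuration: spectra ``wavenumber_cm1, absorbance``; FRAP traces
``time_s, intensity`` (bleach index in a JSON sidecar); deformation
series ``pressure_Pa, strain, direction, condition``; diffusion profiles
``x_um, intensity, position_index``; phase points
``conc_x_uM, conc_y_uM, mean_area_um2, count_per_90um2, state``.
Ground truth is written next to its data file as ``<stem>.truth.json``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import ParameterError
from .imaging import ImageChannel, RegionMask
from .kinetics import FRAPTrace
from .mechanics import DeformationSeries
from .phase_diagram import PhasePoint
from .sizing import ChannelGeometry, Conditions, DiffusionProfileSet
from .spectra import Spectrum
from .synth import GroundTruth

__all__ = [
    "write_tiff",
    "read_tiff",
    "write_mask_tiff",
    "write_truth",
    "read_truth",
    "write_spectrum_csv",
    "read_spectrum_csv",
    "write_trace_csv",
    "read_trace_csv",
    "write_deformation_csv",
    "read_deformation_csv",
    "write_profiles_csv",
    "read_profiles_csv",
    "write_phase_points_csv",
    "read_phase_points_csv",
]


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParameterError(f"{path}: missing column(s) {', '.join(missing)}")


def write_tiff(path: str | Path, channels: Sequence[ImageChannel]) -> None:
    """Write one or more channels as a multi-page TIFF; the pixel size is
    recorded in the TIFF resolution tags and echoed in a JSON sidecar."""
    path = Path(path)
    if not channels:
        raise ParameterError("no channels to write")
    px = channels[0].pixel_size_um
    stack = np.stack([c.intensities.astype(np.float32) for c in channels])
    tifffile.imwrite(path, stack, resolution=(1.0 / px, 1.0 / px),
                     photometric="minisblack",
                     metadata={"unit": "um", "pixel_size_um": px,
                               "labels": [c.label for c in channels]})
    sidecar = {"pixel_size_um": px, "labels": [c.label for c in channels]}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_tiff(path: str | Path, pixel_size_um: Optional[float] = None) -> list[ImageChannel]:
    """Read a (multi-page) TIFF written by :func:`write_tiff`; the pixel
    size comes from the JSON sidecar unless overridden."""
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    labels = [""] * len(data)
    if pixel_size_um is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise ParameterError(f"{path}: no pixel size given and no sidecar found")
        meta = json.loads(sidecar.read_text())
        pixel_size_um = float(meta["pixel_size_um"])
        labels = list(meta.get("labels", labels))[: len(data)] + [""] * max(
            0, len(data) - len(meta.get("labels", [])))
    return [ImageChannel(np.asarray(page, dtype=float), pixel_size_um, label)
            for page, label in zip(data, labels)]


def write_mask_tiff(path: str | Path, mask: RegionMask) -> None:
    """Export a mask as an 8-bit TIFF (0/255)."""
    tifffile.imwrite(Path(path), (mask.flags.astype(np.uint8) * 255))


def _jsonable(value):
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    if isinstance(value, dict):
        return {k: _jsonable(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_jsonable(v) for v in value]
    return value


def write_truth(stem: str | Path, truth: GroundTruth) -> Path:
    """Write a ground-truth sidecar ``<stem>.truth.json``."""
    out = Path(f"{stem}.truth.json")
    payload = {"generator": truth.generator, "data": _jsonable(truth.data)}
    out.write_text(json.dumps(payload, indent=1))
    return out


def read_truth(stem: str | Path) -> GroundTruth:
    payload = json.loads(Path(f"{stem}.truth.json").read_text())
    return GroundTruth(payload["generator"], payload["data"])


def write_spectrum_csv(path: str | Path, spectrum: Spectrum) -> None:
    pd.DataFrame({"wavenumber_cm1": spectrum.wavenumbers_cm1,
                  "absorbance": spectrum.absorbance}).to_csv(path, index=False)


def read_spectrum_csv(path: str | Path, instrument: str = "afmir") -> Spectrum:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["wavenumber_cm1", "absorbance"], path)
    return Spectrum(df["wavenumber_cm1"].to_numpy(), df["absorbance"].to_numpy(),
                    instrument=instrument)


def write_trace_csv(path: str | Path, trace: FRAPTrace) -> None:
    path = Path(path)
    pd.DataFrame({"time_s": trace.times_s,
                  "intensity": trace.intensities}).to_csv(path, index=False)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps({"bleach_index": trace.bleach_index}))


def read_trace_csv(path: str | Path, bleach_index: Optional[int] = None) -> FRAPTrace:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["time_s", "intensity"], path)
    if bleach_index is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise ParameterError(f"{path}: no bleach_index given and no sidecar found")
        bleach_index = int(json.loads(sidecar.read_text())["bleach_index"])
    return FRAPTrace(df["time_s"].to_numpy(), df["intensity"].to_numpy(),
                     bleach_index=bleach_index)


def write_deformation_csv(path: str | Path, series: Sequence[DeformationSeries]) -> None:
    frames = [pd.DataFrame({"pressure_Pa": s.pressures_Pa, "strain": s.strains,
                            "direction": s.direction, "condition": s.condition})
              for s in series]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_deformation_csv(path: str | Path) -> list[DeformationSeries]:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["pressure_Pa", "strain"], path)
    if "direction" not in df.columns:
        df["direction"] = "forth"
    if "condition" not in df.columns:
        df["condition"] = ""
    df["condition"] = df["condition"].fillna("")
    out = []
    for (condition, direction), grp in df.groupby(["condition", "direction"], sort=True):
        out.append(DeformationSeries(grp["pressure_Pa"].to_numpy(),
                                     grp["strain"].to_numpy(),
                                     direction=str(direction), condition=str(condition)))
    return out


def write_profiles_csv(path: str | Path, profiles: DiffusionProfileSet) -> None:
    path = Path(path)
    rows = []
    for i, prof in enumerate(profiles.profiles):
        rows.append(pd.DataFrame({"x_um": profiles.x_um, "intensity": prof,
                                  "position_index": i}))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
    meta = {"geometry": dataclasses.asdict(profiles.geometry),
            "conditions": dataclasses.asdict(profiles.conditions)}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(_jsonable(meta), indent=1))


def read_profiles_csv(
    path: str | Path,
    geometry: Optional[ChannelGeometry] = None,
    conditions: Optional[Conditions] = None,
) -> DiffusionProfileSet:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["x_um", "intensity", "position_index"], path)
    if geometry is None or conditions is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise ParameterError(f"{path}: geometry/conditions not given and no sidecar found")
        meta = json.loads(sidecar.read_text())
        geometry = geometry or ChannelGeometry(**meta["geometry"])
        conditions = conditions or Conditions(**meta["conditions"])
    groups = [grp.sort_values("x_um") for _, grp in df.groupby("position_index", sort=True)]
    x = groups[0]["x_um"].to_numpy()
    profiles = np.stack([g["intensity"].to_numpy() for g in groups])
    return DiffusionProfileSet(x_um=x, profiles=profiles,
                               geometry=geometry, conditions=conditions)


def write_phase_points_csv(path: str | Path, points: Sequence[PhasePoint]) -> None:
    pd.DataFrame([dataclasses.asdict(p) for p in points]).to_csv(path, index=False)


def read_phase_points_csv(path: str | Path) -> list[PhasePoint]:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["conc_x_uM", "conc_y_uM", "mean_area_um2",
                          "count_per_90um2", "state"], path)
    return [PhasePoint(row.conc_x_uM, row.conc_y_uM, row.mean_area_um2,
                       row.count_per_90um2, row.state)
            for row in df.itertuples()]
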