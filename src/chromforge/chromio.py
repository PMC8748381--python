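"""Reading and writing chromatographic raw data in open text formats.

A run is a time x channel intensity matrix (DAD-UV absorbances over
wavelengths, or MS full-scan intensities binned onto an m/z grid) plus
acquisition metadata: the elution program, temperature, flow, column id and
the run's role (calibration or validation) in the screening campaign.

UV matrices are delimited text with the channel values in the first row and
times in the first column; MS data arrives as long-format ``time,mz,intensity``
rows and is accumulated into half-open m/z bins.  Metadata travels in a JSON
sidecar per run.  Vendor formats are out of scope: only exported text is read.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .gradsim import ElutionProgram

__all__ = [
    "ChannelKind",
    "Detector",
    "RunRole",
    "ChannelAxis",
    "RunMeta",
    "Chromatogram",
    "FormatError",
    "MetadataError",
    "read_uv_matrix",
    "write_uv_matrix",
    "read_ms_scans",
    "read_run_meta",
    "write_run_meta",
]


class FormatError(ValueError):
    """Malformed raw-data file."""


class MetadataError(ValueError):
    """Missing or invalid run metadata."""


class ChannelKind(str, Enum):
    wavelength_nm = "wavelength_nm"
    mz = "mz"


class Detector(str, Enum):
    UV = "UV"
    MS = "MS"


class RunRole(str, Enum):
    calibration = "calibration"
    validation = "validation"


@dataclass(frozen=True)
class ChannelAxis:
    """Strictly increasing detector channel values (nm or m/z)."""

    kind: ChannelKind
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 1:
            raise ValueError("channel axis must be a non-empty vector")
        if np.any(np.diff(v) <= 0):
            raise ValueError("channel values must be strictly increasing")
        if self.kind is ChannelKind.wavelength_nm and np.any(v <= 0):
            raise ValueError("wavelengths must be positive")

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class RunMeta:
    program: ElutionProgram
    temperature: float
    flow: float
    column_id: str
    role: RunRole

    def __post_init__(self) -> None:
        if self.flow <= 0:
            raise MetadataError("flow must be positive")


@dataclass
class Chromatogram:
    """One run: times (minutes), channel axis, intensity matrix, metadata."""

    run_id: str
    time: np.ndarray
    axis: ChannelAxis
    intensity: np.ndarray
    detector: Detector
    meta: RunMeta | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time.ndim != 1:
            raise ValueError("time must be a vector")
        if np.any(np.diff(self.time) <= 0):
            raise FormatError("time must be strictly increasing")
        if self.intensity.shape != (self.time.size, len(self.axis)):
            raise ValueError(
                f"intensity shape {self.intensity.shape} does not match "
                f"(n_time={self.time.size}, n_channel={len(self.axis)})"
            )
        if np.isnan(self.intensity).any():
            raise FormatError("intensity contains NaN")

    @property
    def sampling_interval(self) -> float:
        """Median time step in minutes."""
        return float(np.median(np.diff(self.time)))


def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters=",;\t ").delimiter
    except csv.Error:
        return "\t"


def read_uv_matrix(path: str | Path, meta_path: str | Path | None = None) -> Chromatogram:
    """Load a DAD-UV time x wavelength matrix from delimited text.

    Row 1 holds the wavelength channels (its first field is ignored or blank),
    column 1 the times.  Negative intensities are preserved as read; clipping
    to non-negative values happens later, as part of curve-resolution
    preprocessing.
    """
    path = Path(path)
    text = path.read_text()
    delim = _sniff_delimiter(text[:2048])
    try:
        df = pd.read_csv(
            io.StringIO(text), sep=delim, index_col=0, float_precision="round_trip"
        )
    except Exception as exc:  # pragma: no cover - pandas error wrapped
        raise FormatError(f"{path}: cannot parse delimited matrix: {exc}") from exc
    if df.isna().any().any():
        raise FormatError(f"{path}: ragged rows or missing fields")
    try:
        channels = df.columns.to_numpy(dtype=float)
        times = df.index.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric header or time column") from exc
    if np.any(np.diff(times) <= 0):
        raise FormatError(f"{path}: time column is not strictly increasing")
    meta = None
    time_unit = "min"
    if meta_path is not None:
        meta, time_unit = _read_meta_file(meta_path)
    if time_unit == "s":
        times = times / 60.0
    return Chromatogram(
        run_id=path.stem,
        time=times,
        axis=ChannelAxis(ChannelKind.wavelength_nm, channels),
        intensity=df.to_numpy(dtype=float),
        detector=Detector.UV,
        meta=meta,
    )


def write_uv_matrix(chrom: Chromatogram, path: str | Path) -> Path:
    """Write a UV chromatogram as tab-separated text, re-readable at full
    float precision."""
    if chrom.detector is not Detector.UV:
        raise ValueError("write_uv_matrix expects a UV chromatogram")
    if chrom.intensity.size == 0:
        raise ValueError("refusing to write an empty matrix")
    path = Path(path)
    df = pd.DataFrame(
        chrom.intensity,
        index=chrom.time,
        columns=chrom.axis.values,
    )
    # default float formatting is the shortest round-trip repr: exact
    df.to_csv(path, sep="\t", index_label="time")
    return path


def read_ms_scans(
    path: str | Path,
    meta_path: str | Path | None = None,
    mz_bin: float = 1.0,
) -> Chromatogram:
    """Bin long-format MS scans (``time,mz,intensity``) onto a common grid.

    Intensities are accumulated into half-open bins
    ``[mz0 + i*mz_bin, mz0 + (i+1)*mz_bin)`` anchored at the smallest observed
    m/z; one matrix row per distinct scan time.  Total ion current is
    conserved exactly.
    """
    if mz_bin <= 0:
        raise ValueError("mz_bin must be positive")
    path = Path(path)
    df = pd.read_csv(path)
    required = {"time", "mz", "intensity"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}")
    if len(df) == 0:
        raise FormatError(f"{path}: no scans")
    times = np.sort(df["time"].unique())
    mz0 = float(np.floor(df["mz"].min() / mz_bin) * mz_bin)
    bins = np.floor((df["mz"].to_numpy() - mz0) / mz_bin).astype(int)
    n_bins = int(bins.max()) + 1
    t_index = {t: i for i, t in enumerate(times)}
    rows = df["time"].map(t_index).to_numpy()
    matrix = np.zeros((times.size, n_bins))
    np.add.at(matrix, (rows, bins), df["intensity"].to_numpy(dtype=float))
    centers = mz0 + (np.arange(n_bins) + 0.5) * mz_bin
    meta = None
    time_unit = "min"
    if meta_path is not None:
        meta, time_unit = _read_meta_file(meta_path)
    times = times.astype(float)
    if time_unit == "s":
        times = times / 60.0
    return Chromatogram(
        run_id=path.stem,
        time=times,
        axis=ChannelAxis(ChannelKind.mz, centers),
        intensity=matrix,
        detector=Detector.MS,
        meta=meta,
    )


_META_REQUIRED = ("program", "temperature", "flow", "column_id", "role")


def _read_meta_file(meta_path: str | Path) -> tuple[RunMeta, str]:
    data = json.loads(Path(meta_path).read_text())
    for key in _META_REQUIRED:
        if key not in data:
            raise MetadataError(f"{meta_path}: missing metadata field '{key}'")
    prog = data["program"]
    nodes = tuple((float(n["time"]), float(n["phi"])) for n in prog["nodes"])
    program = ElutionProgram(
        nodes=nodes,
        temperature=float(data["temperature"]),
        t0=float(prog.get("t0", 1.0)),
        t_dwell=float(prog.get("t_dwell", 0.0)),
        flow=float(data["flow"]),
    )
    meta = RunMeta(
        program=program,
        temperature=float(data["temperature"]),
        flow=float(data["flow"]),
        column_id=str(data["column_id"]),
        role=RunRole(data["role"]),
    )
    return meta, data.get("time_unit", "min")


def read_run_meta(meta_path: str | Path) -> RunMeta:
    """Load a run's JSON sidecar metadata."""
    return _read_meta_file(meta_path)[0]


def write_run_meta(meta: RunMeta, meta_path: str | Path) -> Path:
    """Serialize run metadata to the JSON sidecar format."""
    data = {
        "program": {
            "nodes": [{"time": t, "phi": p} for t, p in meta.program.nodes],
            "t0": meta.program.t0,
            "t_dwell": meta.program.t_dwell,
        },
        "temperature": meta.temperature,
        "flow": meta.flow,
        "column_id": meta.column_id,
        "role": meta.role.value,
        "time_unit": "min",
    }
    path = Path(meta_path)
    path.write_text(json.dumps(data, indent=2))
    return path
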