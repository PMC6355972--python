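"""Image-stack, trace and table I/O.

All format handling lives here.  Conventions enforced package-wide:

* Arrays are indexed ``(z, y, x)`` or ``(z, y, x, channel)``, 0-based,
  with pixel-center coordinates.
* Physical units at the API boundary are micrometres (spacing), kilopascals
  (stress/modulus) and seconds (time).  ``spacing_um`` is ``(dz, dy, dx)``.
* 2D images are represented as stacks of z-depth 1.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImageStack",
    "TraceRecord",
    "read_stack",
    "write_stack",
    "read_trace",
    "write_trace",
    "read_table",
    "write_table",
]


@dataclass
class ImageStack:
    """A (multi-channel) intensity grid with physical voxel spacing.

    Parameters
    ----------
    data
        Non-negative intensities, shape ``(z, y, x)`` or ``(z, y, x, c)``.
    spacing_um
        ``(dz, dy, dx)`` in micrometres, all strictly positive.
    channel_names
        One name per channel; empty for single-channel ``(z, y, x)`` data.
    meta
        Free-form metadata carried through I/O round-trips.
    """

    data: np.ndarray
    spacing_um: tuple[float, float, float]
    channel_names: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise ValueError(
                f"stack data must be (z, y, x[, c]), got ndim={self.data.ndim}"
            )
        self.spacing_um = tuple(float(s) for s in self.spacing_um)
        if len(self.spacing_um) != 3 or any(s <= 0 for s in self.spacing_um):
            raise ValueError(f"spacing_um must be 3 positive floats, got {self.spacing_um}")
        self.channel_names = list(self.channel_names)
        if self.data.ndim == 4:
            if len(self.channel_names) != self.data.shape[-1]:
                raise ValueError(
                    f"{len(self.channel_names)} channel names for "
                    f"{self.data.shape[-1]} channels"
                )
        elif self.channel_names:
            raise ValueError("channel_names given for single-channel data")

    @property
    def n_channels(self) -> int:
        return self.data.shape[-1] if self.data.ndim == 4 else 1

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.spacing_um
        return dz * dy * dx

    def channel(self, name: str) -> np.ndarray:
        """Return the ``(z, y, x)`` array for a named channel."""
        if self.data.ndim == 3:
            raise ValueError("stack has no channel axis")
        try:
            i = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None
        return self.data[..., i]


@dataclass
class TraceRecord:
    """A stress-relaxation / compression trace.

    ``phase`` labels each sample ``"ramp"`` (strain increasing) or
    ``"hold"`` (constant strain).  ``strain`` is a fraction (0.15 = 15%).
    """

    time_s: np.ndarray
    stress_kPa: np.ndarray
    strain: np.ndarray
    phase: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.stress_kPa = np.asarray(self.stress_kPa, dtype=float)
        self.strain = np.asarray(self.strain, dtype=float)
        self.phase = np.asarray(self.phase, dtype=object)
        n = self.time_s.size
        if not (self.stress_kPa.size == self.strain.size == self.phase.size == n):
            raise ValueError("trace columns must have equal length")
        for ph in ("ramp", "hold"):
            sel = self.phase == ph
            if sel.any():
                t = self.time_s[sel]
                if t.size >= 2 and not np.all(np.diff(t) > 0):
                    raise ValueError(f"time not strictly increasing within {ph} phase")

    def hold(self) -> "TraceRecord":
        """Sub-trace restricted to the hold phase."""
        sel = self.phase == "hold"
        return TraceRecord(
            self.time_s[sel], self.stress_kPa[sel], self.strain[sel],
            self.phase[sel], dict(self.meta),
        )


# ---------------------------------------------------------------------------
# stacks

_OME_NS = "{http://www.openmicroscopy.org/Schemas/OME/2016-06}"


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write an :class:`ImageStack` as OME-TIFF with physical pixel sizes."""
    path = Path(path)
    dz, dy, dx = stack.spacing_um
    if stack.data.ndim == 4:
        data = np.moveaxis(stack.data, -1, 0)  # (c, z, y, x)
        axes = "CZYX"
    else:
        data = stack.data
        axes = "ZYX"
    metadata = {
        "axes": axes,
        "PhysicalSizeX": dx,
        "PhysicalSizeXUnit": "µm",
        "PhysicalSizeY": dy,
        "PhysicalSizeYUnit": "µm",
        "PhysicalSizeZ": dz,
        "PhysicalSizeZUnit": "µm",
    }
    if stack.channel_names:
        metadata["Channel"] = {"Name": stack.channel_names}
    tifffile.imwrite(path, data, ome=True, metadata=metadata)
    return path


def _spacing_from_ome(xml: str) -> tuple[float | None, list[str]]:
    root = ET.fromstring(xml)
    pixels = root.find(f"{_OME_NS}Image/{_OME_NS}Pixels")
    if pixels is None:
        return None, []
    sx = pixels.get("PhysicalSizeX")
    sy = pixels.get("PhysicalSizeY")
    sz = pixels.get("PhysicalSizeZ")
    spacing = None
    if sx is not None and sy is not None:
        # 2D data may omit Z; fall back to 1 µm nominal slice for depth-1
        spacing = (float(sz) if sz is not None else 1.0, float(sy), float(sx))
    names = [
        ch.get("Name", f"ch{i}")
        for i, ch in enumerate(pixels.findall(f"{_OME_NS}Channel"))
    ]
    return spacing, names


def read_stack(
    path: str | Path,
    spacing_um: Sequence[float] | None = None,
    channel_names: Sequence[str] | None = None,
) -> ImageStack:
    """Read a TIFF / OME-TIFF into an :class:`ImageStack`.

    Spacing is taken from OME metadata when present; for plain TIFFs it must
    be supplied via ``spacing_um`` — there is no silent default.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes
        meta_spacing, meta_channels = (None, [])
        if tf.ome_metadata:
            meta_spacing, meta_channels = _spacing_from_ome(tf.ome_metadata)

    if spacing_um is not None:
        spacing = tuple(float(s) for s in spacing_um)
    elif meta_spacing is not None:
        spacing = meta_spacing
    else:
        raise ValueError(
            f"{path}: no voxel spacing in metadata; pass spacing_um explicitly"
        )

    # normalize axis order to (z, y, x[, c])
    axes = axes.replace("S", "C").replace("Q", "Z").replace("I", "Z")
    order = [a for a in axes]
    arr = data
    for ax in ("T",):
        if ax in order:
            raise ValueError(f"{path}: time series not supported here")
    if "Z" not in order:
        arr = arr[np.newaxis]
        order.insert(0, "Z")
    if "C" in order:
        perm = [order.index(a) for a in ("Z", "Y", "X", "C")]
    else:
        perm = [order.index(a) for a in ("Z", "Y", "X")]
    arr = np.transpose(arr, perm)

    if channel_names is not None:
        names = list(channel_names)
    elif arr.ndim == 4:
        names = meta_channels or [f"ch{i}" for i in range(arr.shape[-1])]
    else:
        names = []
    return ImageStack(arr, spacing, names, {"source": str(path)})


# ---------------------------------------------------------------------------
# traces

def write_trace(trace: TraceRecord, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_s": trace.time_s,
            "stress_kPa": trace.stress_kPa,
            "strain": trace.strain,
            "phase": trace.phase,
        }
    )
    df.to_csv(path, index=False)
    return path


def read_trace(path: str | Path, hold_strain: float | None = None) -> TraceRecord:
    """Parse a delimited time/stress trace.

    Accepts the full four-column CSV written by :func:`write_trace`, or a bare
    two-column ``time, stress`` text file (header optional, comma or
    whitespace separated), in which case every sample is labelled ``hold`` at
    ``hold_strain`` (default 0.15, the standard hold strain).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if df.columns.size and not all(_is_number(c) for c in df.columns):
        cols = [str(c).strip().lower() for c in df.columns]
        df.columns = cols
    else:  # headerless: first row was data
        df = pd.read_csv(path, sep=None, engine="python", comment="#", header=None)
        df.columns = ["time_s", "stress_kpa"][: df.shape[1]] + [
            f"col{i}" for i in range(max(0, df.shape[1] - 2))
        ]
    colmap = {}
    for c in df.columns:
        lc = str(c).lower()
        if "time" in lc:
            colmap["time"] = c
        elif "stress" in lc:
            colmap["stress"] = c
        elif "strain" in lc:
            colmap["strain"] = c
        elif "phase" in lc:
            colmap["phase"] = c
    if "time" not in colmap or "stress" not in colmap:
        if df.shape[1] < 2:
            raise ValueError(f"{path}: need at least time and stress columns")
        colmap.setdefault("time", df.columns[0])
        colmap.setdefault("stress", df.columns[1])
    t = np.asarray(df[colmap["time"]], dtype=float)
    s = np.asarray(df[colmap["stress"]], dtype=float)
    if t.size >= 2 and not np.all(np.diff(t) > 0):
        raise ValueError(f"{path}: time column is not strictly increasing")
    if "strain" in colmap:
        strain = np.asarray(df[colmap["strain"]], dtype=float)
    else:
        strain = np.full_like(t, 0.15 if hold_strain is None else hold_strain)
    if "phase" in colmap:
        phase = np.asarray(df[colmap["phase"]], dtype=object)
    else:
        phase = np.full(t.shape, "hold", dtype=object)
    return TraceRecord(t, s, strain, phase, {"source": str(path)})


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False


# ---------------------------------------------------------------------------
# tables & sidecars

def write_table(records, path: str | Path, float_format: str = "%.6g") -> Path:
    """Write records (DataFrame or list of dicts/dataclasses) to CSV.

    Floats are fixed at 6 significant digits so that re-runs with identical
    seeds produce byte-identical files.
    """
    path = Path(path)
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        rows = []
        for r in records:
            if hasattr(r, "__dataclass_fields__"):
                rows.append(
                    {k: getattr(r, k) for k in r.__dataclass_fields__}
                )
            else:
                rows.append(dict(r))
        df = pd.DataFrame(rows)
    df.to_csv(path, index=False, float_format=float_format)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify))
    return path


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
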