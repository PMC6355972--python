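"""3D single-cell morphometry: segmentation, volume, surface area, sphericity.

Volume is voxel counting times the physical voxel volume.  Surface area is
measured on a marching-cubes iso-surface of the lightly smoothed binary
field (raw binary meshes overestimate a sphere's area by ~8–12% through
staircase artifacts; a 0.2-µm Gaussian pre-smooth removes the bias without
eroding sharp shapes appreciably).  Sphericity is

    Ψ = π^(1/3) · (6 V)^(2/3) / A

which is 1 for a sphere and tends to 0 for a line; digitization can push
measured values slightly above 1 (mesh allowance ≤ 0.02).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import feature, filters, measure

from .stack_io import ImageStack

__all__ = [
    "LabeledMask",
    "MorphometryRecord",
    "select_threshold",
    "segment_cells",
    "measure_volume",
    "measure_surface_area",
    "sphericity",
    "measure_cells",
    "threshold_sensitivity",
    "bead_calibration",
]

#: default minimum object volume — a sphere of ~2.5 µm radius; smaller
#: supra-threshold components are treated as debris
MIN_VOLUME_UM3 = 65.0

#: default Gaussian pre-smooth (µm) for iso-surfacing
SURFACE_SMOOTH_UM = 0.2

#: mesh discretization allowance on the sphericity upper bound
EPS_MESH = 0.02


@dataclass
class LabeledMask:
    """Integer label grid aligned to its source stack; 0 is background."""

    labels: np.ndarray
    spacing_um: tuple[float, float, float]
    provenance: dict = field(default_factory=dict)
    qc_flags: dict = field(default_factory=dict)  # label -> {flag: bool}

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.min() < 0:
            raise ValueError("labels must be >= 0")

    @property
    def label_ids(self) -> list[int]:
        ids = np.unique(self.labels)
        return [int(i) for i in ids if i != 0]


@dataclass
class MorphometryRecord:
    cell_id: int
    volume_um3: float
    area_um2: float
    sphericity: float
    threshold_used: float
    touches_border: bool = False
    touches_other_cell: bool = False
    below_min_size: bool = False
    degenerate_thin: bool = False

    @property
    def usable(self) -> bool:
        """Single, in-frame cell — included in summary statistics."""
        return not (self.touches_border or self.touches_other_cell
                    or self.below_min_size)


# ---------------------------------------------------------------------------

def select_threshold(stack: ImageStack | np.ndarray, method: str = "otsu",
                     k: float = 0.0, fixed_value: float | None = None) -> float:
    """Choose an intensity threshold.

    ``otsu`` minimizes intra-class variance; ``otsu_plus_k_sd`` adds
    ``k ×`` the global intensity SD (the threshold-robustness check);
    ``fixed`` returns ``fixed_value`` unchanged.
    """
    img = stack.data if isinstance(stack, ImageStack) else np.asarray(stack)
    if method == "fixed":
        if fixed_value is None:
            raise ValueError("fixed method requires fixed_value")
        return float(fixed_value)
    if img.max() == img.min():
        raise ValueError("constant image: Otsu threshold undefined")
    base = float(filters.threshold_otsu(img))
    if method == "otsu":
        return base
    if method == "otsu_plus_k_sd":
        return base + float(k) * float(img.std())
    raise ValueError(f"unknown threshold method {method!r}")


def _fill_holes_per_slice(mask: np.ndarray) -> np.ndarray:
    out = np.empty_like(mask)
    for z in range(mask.shape[0]):
        out[z] = ndimage.binary_fill_holes(mask[z])
    return out


def segment_cells(
    stack: ImageStack,
    threshold: float,
    min_volume_um3: float = MIN_VOLUME_UM3,
    fill_holes: bool = True,
) -> LabeledMask:
    """26-connected components of the supra-threshold set.

    Holes are filled per z-slice (membrane dyes outline cells more than they
    fill them, while voxel-count volumes presume solid objects).  Components
    below ``min_volume_um3`` are dropped; remaining labels are renumbered
    1..N.  QC flags:

    * ``touches_border`` — component touches the image frame;
    * ``touches_other_cell`` — component is within one voxel of another
      label, or shows two comparable-depth interior maxima (merged pair).
    """
    img = stack.data
    if img.ndim != 3:
        raise ValueError("segment a single channel; use stack.channel(name)")
    fg = img > threshold
    if not fg.any():
        warnings.warn("empty foreground at this threshold", stacklevel=2)
        return LabeledMask(
            np.zeros(img.shape, dtype=np.int32), stack.spacing_um,
            {"threshold": threshold, "method": "supra-threshold",
             "connectivity": 26},
        )
    if fill_holes:
        fg = _fill_holes_per_slice(fg)
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    raw, n = ndimage.label(fg, structure=structure)
    voxel_vol = float(np.prod(stack.spacing_um))
    counts = np.bincount(raw.ravel())

    keep = [i for i in range(1, n + 1) if counts[i] * voxel_vol >= min_volume_um3]
    labels = np.zeros_like(raw, dtype=np.int32)
    for new, old in enumerate(keep, start=1):
        labels[raw == old] = new

    qc = {}
    for lid in range(1, len(keep) + 1):
        m = labels == lid
        border = (
            m[0].any() or m[-1].any()
            or m[:, 0].any() or m[:, -1].any()
            or m[:, :, 0].any() or m[:, :, -1].any()
        )
        qc[lid] = {
            "touches_border": bool(border),
            "touches_other_cell": False,
            "below_min_size": False,
        }
    # adjacency between distinct labels: dilate each by one voxel
    for lid in range(1, len(keep) + 1):
        m = labels == lid
        dil = ndimage.binary_dilation(m, structure=structure)
        others = labels[dil & ~m]
        if np.any((others != 0) & (others != lid)):
            qc[lid]["touches_other_cell"] = True
    # merged-pair detection: two comparable-depth EDT maxima in one component
    for lid in range(1, len(keep) + 1):
        if qc[lid]["touches_other_cell"]:
            continue
        if _looks_merged(labels == lid, stack.spacing_um):
            qc[lid]["touches_other_cell"] = True

    return LabeledMask(
        labels, stack.spacing_um,
        {"threshold": float(threshold), "method": "supra-threshold",
         "connectivity": 26, "min_volume_um3": min_volume_um3,
         "fill_holes": fill_holes},
        qc,
    )


def _looks_merged(mask: np.ndarray, spacing_um, rel_depth: float = 0.6,
                  min_sep_um: float = 4.0, neck_frac: float = 0.8) -> bool:
    """Heuristic for two fused convex bodies.

    The physical-units distance transform of a merged pair has two
    comparable-depth maxima joined by a neck that is shallower than either
    core; a single elongated body has a flat interior ridge instead, and a
    thin protrusion only produces a shallow secondary peak (excluded by
    ``rel_depth``).  Flags when the EDT minimum along the segment between
    two deep peaks drops below ``neck_frac`` of the shallower peak.
    """
    edt = ndimage.distance_transform_edt(mask, sampling=spacing_um)
    min_dist = max(1, int(round(min_sep_um / min(spacing_um))))
    peaks = feature.peak_local_max(
        edt, min_distance=min_dist, threshold_rel=rel_depth, exclude_border=False
    )
    if len(peaks) < 2:
        return False
    depths = edt[tuple(peaks.T)]
    top = np.argsort(depths)[::-1][:4]
    for ii, i in enumerate(top):
        for j in top[ii + 1:]:
            n_samples = max(8, int(np.abs(peaks[i] - peaks[j]).max()) * 2)
            line = np.linspace(peaks[i], peaks[j], n_samples).T.astype(float)
            profile = ndimage.map_coordinates(edt, line, order=1)
            if profile.min() < neck_frac * min(depths[i], depths[j]):
                return True
    return False


# ---------------------------------------------------------------------------

def measure_volume(mask: LabeledMask, label: int,
                   spacing_um=None) -> float:
    """Volume = number of label voxels × voxel volume (µm³)."""
    spacing = mask.spacing_um if spacing_um is None else tuple(spacing_um)
    n = int(np.count_nonzero(mask.labels == label))
    if n == 0:
        raise ValueError(f"label {label} not present in mask")
    return n * float(np.prod(spacing))


def measure_surface_area(
    mask: LabeledMask, label: int, spacing_um=None,
    smooth_um: float = SURFACE_SMOOTH_UM,
) -> tuple[float, bool]:
    """Triangulated iso-surface area (µm²) of one label.

    The binary field is padded, Gaussian-smoothed by ``smooth_um`` (physical
    units, so anisotropic spacing is respected) and meshed with marching
    cubes at level 0.5.  Returns ``(area, degenerate_thin)`` where the flag
    marks labels under 2 voxels thick along some axis (area still computed,
    but unreliable).
    """
    spacing = mask.spacing_um if spacing_um is None else tuple(spacing_um)
    m = mask.labels == label
    if not m.any():
        raise ValueError(f"label {label} not present in mask")
    # crop to bounding box for speed
    sl = ndimage.find_objects(m.astype(np.int8))[0]
    m = m[sl]
    thin = min(m.shape) < 2
    f = np.pad(m.astype(np.float32), 3)
    if smooth_um > 0:
        f = ndimage.gaussian_filter(f, [smooth_um / s for s in spacing])
    if f.max() <= 0.5:  # over-smoothed tiny object: fall back to raw binary
        f = np.pad(m.astype(np.float32), 3)
    verts, faces, _, _ = measure.marching_cubes(f, level=0.5, spacing=spacing)
    area = float(measure.mesh_surface_area(verts, faces))
    if thin:
        warnings.warn(f"label {label} under 2 voxels thick; area unreliable",
                      stacklevel=2)
    return area, thin


def sphericity(volume_um3: float, area_um2: float) -> float:
    """Ψ = π^(1/3)·(6V)^(2/3)/A — 1 for a sphere, → 0 for a line."""
    if volume_um3 <= 0 or area_um2 <= 0:
        raise ValueError("volume and area must be positive")
    return math.pi ** (1.0 / 3.0) * (6.0 * volume_um3) ** (2.0 / 3.0) / area_um2


def measure_cells(mask: LabeledMask, threshold_used: float | None = None,
                  smooth_um: float = SURFACE_SMOOTH_UM) -> list[MorphometryRecord]:
    """One :class:`MorphometryRecord` per label in a mask."""
    thr = (mask.provenance.get("threshold", float("nan"))
           if threshold_used is None else threshold_used)
    records = []
    for lid in mask.label_ids:
        v = measure_volume(mask, lid)
        a, thin = measure_surface_area(mask, lid, smooth_um=smooth_um)
        flags = mask.qc_flags.get(lid, {})
        records.append(MorphometryRecord(
            cell_id=lid, volume_um3=v, area_um2=a,
            sphericity=sphericity(v, a), threshold_used=float(thr),
            touches_border=flags.get("touches_border", False),
            touches_other_cell=flags.get("touches_other_cell", False),
            below_min_size=flags.get("below_min_size", False),
            degenerate_thin=thin,
        ))
    return records


# ---------------------------------------------------------------------------

def threshold_sensitivity(
    stack: ImageStack, k_list=(0.0, 0.5, 1.0),
    min_volume_um3: float = MIN_VOLUME_UM3,
) -> pd.DataFrame:
    """Total foreground volume at Otsu + k·SD for each k.

    The supra-threshold sets nest, so volume is monotone non-increasing
    in k; the relative change across k quantifies threshold robustness
    of a volume estimate.
    """
    rows = []
    base = select_threshold(stack, "otsu")
    v0 = None
    for k in k_list:
        thr = select_threshold(stack, "otsu_plus_k_sd", k=k)
        mask = segment_cells(stack, thr, min_volume_um3=min_volume_um3)
        vol = float(np.count_nonzero(mask.labels) * np.prod(stack.spacing_um))
        if v0 is None:
            v0 = vol
        rows.append({
            "k": float(k), "threshold": thr, "otsu_base": base,
            "total_volume_um3": vol,
            "relative_volume": vol / v0 if v0 else float("nan"),
        })
    return pd.DataFrame(rows)


def bead_calibration(bead_truths, measurements) -> pd.DataFrame:
    """Bias and coefficient of variation of measured vs true bead volume.

    ``bead_truths``: mapping nominal size name -> true volume (µm³);
    ``measurements``: mapping nominal size name -> iterable of measured
    volumes.  Returns one row per nominal size with mean, bias (fraction)
    and CV.
    """
    rows = []
    for name, true_v in bead_truths.items():
        vals = np.asarray(list(measurements[name]), dtype=float)
        if vals.size == 0:
            raise ValueError(f"no measurements for bead size {name!r}")
        mean = float(vals.mean())
        rows.append({
            "nominal": name,
            "true_volume_um3": float(true_v),
            "mean_volume_um3": mean,
            "bias": mean / float(true_v) - 1.0,
            "cv": float(vals.std(ddof=1) / mean) if vals.size > 1 else 0.0,
            "n": int(vals.size),
        })
    return pd.DataFrame(rows)
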