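"""Per-cell ratiometric readouts.

Two measurements share the mean-then-ratio convention used throughout the
package:

* **Calcium** — relative intracellular calcium as the ratio of the mean
  Fluo-3 (calcium-brightening) to the mean Fura-red (calcium-dimming)
  intensity over the cell mask.  This is a *relative* readout only; it is
  never converted to molar concentration.
* **Matrix accumulation** — peri-cellular enrichment of fluorescent
  alginate: mean intensity within 3 µm of the cell border divided by the
  background intensity ~30 µm away (operationalized as the 28–32 µm shell;
  a measure-zero contour has no pixels).  Distances are Euclidean in
  physical units, so anisotropic spacing is respected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["RatioRecord", "calcium_ratio", "accumulation_ratio"]


@dataclass
class RatioRecord:
    cell_id: int | str
    kind: str  # "calcium" | "accumulation"
    value: float | None
    valid: bool = True
    n_pixels_numerator: int = 0
    n_pixels_denominator: int = 0
    band_definition: dict = field(default_factory=dict)
    note: str = ""


def calcium_ratio(
    fluo3: np.ndarray,
    furared: np.ndarray,
    cell_mask: np.ndarray,
    cell_id: int | str = 0,
    denominator_floor_sds: float = 5.0,
) -> RatioRecord:
    """Relative calcium = mean(Fluo-3 | cell) / mean(Fura-red | cell).

    Cells whose Fura-red mean falls below ``denominator_floor_sds`` times
    the background SD (estimated outside the mask) are flagged invalid —
    never silently dropped.
    """
    fluo3 = np.asarray(fluo3, dtype=float)
    furared = np.asarray(furared, dtype=float)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if fluo3.shape != furared.shape or fluo3.shape != cell_mask.shape:
        raise ValueError("channel / mask shapes differ")
    n = int(cell_mask.sum())
    if n == 0:
        raise ValueError(f"cell {cell_id}: empty cell mask")
    mu_fluo = float(fluo3[cell_mask].mean())
    mu_fura = float(furared[cell_mask].mean())
    outside = ~cell_mask
    bg_sd = float(furared[outside].std()) if outside.any() else 0.0
    floor = denominator_floor_sds * bg_sd
    if mu_fura <= max(floor, np.finfo(float).tiny):
        return RatioRecord(
            cell_id, "calcium", None, valid=False,
            n_pixels_numerator=n, n_pixels_denominator=n,
            note=f"Fura-red mean {mu_fura:.3g} below floor {floor:.3g}",
        )
    return RatioRecord(
        cell_id, "calcium", mu_fluo / mu_fura, valid=True,
        n_pixels_numerator=n, n_pixels_denominator=n,
    )


def accumulation_ratio(
    alginate_img: np.ndarray,
    cell_mask: np.ndarray,
    spacing_um,
    cell_id: int | str = 0,
    band_um: float = 3.0,
    background_center_um: float = 30.0,
    background_halfwidth_um: float = 2.0,
    other_cells_mask: np.ndarray | None = None,
) -> RatioRecord:
    """Peri-cellular enrichment relative to the far-field gel.

    numerator region: 0 < d ≤ ``band_um`` outside the cell border;
    denominator region: ``background_center_um ± background_halfwidth_um``,
    excluding pixels inside any other cell.  ``d`` is the Euclidean distance
    transform from the cell, computed with physical ``spacing_um``.
    """
    alg = np.asarray(alginate_img, dtype=float)
    cell = np.asarray(cell_mask, dtype=bool)
    if alg.shape != cell.shape:
        raise ValueError("image / mask shapes differ")
    if not cell.any():
        raise ValueError(f"cell {cell_id}: empty cell mask")
    spacing = tuple(float(s) for s in spacing_um)
    if alg.ndim == 2:
        spacing = spacing[-2:]
    d = ndimage.distance_transform_edt(~cell, sampling=spacing)

    inner = (d > 0) & (d <= band_um)
    lo = background_center_um - background_halfwidth_um
    hi = background_center_um + background_halfwidth_um
    bg = (d >= lo) & (d <= hi)
    if other_cells_mask is not None:
        bg &= ~np.asarray(other_cells_mask, dtype=bool)
    if not inner.any():
        raise ValueError(f"cell {cell_id}: empty peri-cellular band")
    if not bg.any():
        raise ValueError(
            f"cell {cell_id}: empty background shell at "
            f"{background_center_um} µm — cell too close to the image "
            "border or to neighbors"
        )
    value = float(alg[inner].mean() / alg[bg].mean())
    return RatioRecord(
        cell_id, "accumulation", value, valid=True,
        n_pixels_numerator=int(inner.sum()),
        n_pixels_denominator=int(bg.sum()),
        band_definition={
            "band_um": band_um,
            "background_center_um": background_center_um,
            "background_halfwidth_um": background_halfwidth_um,
        },
    )
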