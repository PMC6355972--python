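"""Nuclear:cytoplasmic localization of a target protein.

The nuclear domain comes from Otsu thresholding the DAPI channel, the whole
cellular domain from Otsu thresholding the phalloidin channel, and the
cytoplasm is the set difference (cell minus nucleus).  The N:C ratio is the
ratio of compartment *mean* intensities — the mean target-protein intensity
over the nuclear area (or volume, in 3D) divided by the mean over the
non-nuclear cytoplasmic area — with no background subtraction by default.
The identical contract applies in 2D and 3D, which is what makes the
2D-vs-3D concordance check meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from skimage import filters

__all__ = [
    "LocalizationRecord",
    "compartment_masks",
    "nc_ratio",
    "nc_ratio_3d",
    "compare_2d_3d",
]


@dataclass
class LocalizationRecord:
    cell_id: int | str
    mode: str  # "2D" | "3D"
    nuclear_mean: float
    cytoplasmic_mean: float
    nc_ratio: float
    nuclear_size: int
    cytoplasmic_size: int
    multi_nucleus: bool = False


def _largest_component(mask: np.ndarray) -> tuple[np.ndarray, bool]:
    lab, n = ndimage.label(mask)
    if n <= 1:
        return mask, False
    counts = np.bincount(lab.ravel())[1:]
    keep = int(np.argmax(counts)) + 1
    return lab == keep, True


def compartment_masks(dapi: np.ndarray, phalloidin: np.ndarray,
                      background_subtract: bool = False):
    """Nucleus / cell / cytoplasm masks from DAPI and phalloidin via Otsu.

    The nucleus is clipped to the cell mask; cells with more than one
    DAPI component keep the largest nucleus and are flagged.  Returns
    ``(nucleus_mask, cell_mask, cytoplasm_mask, multi_nucleus)``.
    """
    dapi = np.asarray(dapi)
    phal = np.asarray(phalloidin)
    if dapi.shape != phal.shape:
        raise ValueError("channel shapes differ")
    for name, ch in (("DAPI", dapi), ("phalloidin", phal)):
        if ch.max() == ch.min():
            raise ValueError(f"constant {name} channel: Otsu undefined")
    if background_subtract:
        dapi = np.clip(dapi - _corner_background(dapi), 0, None)
        phal = np.clip(phal - _corner_background(phal), 0, None)
    nucleus = dapi > filters.threshold_otsu(dapi)
    cell = phal > filters.threshold_otsu(phal)
    nucleus, multi = _largest_component(nucleus)
    nucleus = nucleus & cell  # clip to cell
    cytoplasm = cell & ~nucleus
    return nucleus, cell, cytoplasm, multi


def _corner_background(img: np.ndarray, frac: float = 0.05) -> float:
    """Background estimate from the image corner regions."""
    k = [max(1, int(s * frac)) for s in img.shape]
    corners = []
    for zsl in (slice(0, k[0]), slice(-k[0], None)):
        for ysl in (slice(0, k[-2]), slice(-k[-2], None)):
            for xsl in (slice(0, k[-1]), slice(-k[-1], None)):
                block = img[(zsl, ysl, xsl)] if img.ndim == 3 else img[(ysl, xsl)]
                corners.append(block.ravel())
    return float(np.median(np.concatenate(corners)))


def nc_ratio(protein: np.ndarray, nucleus_mask: np.ndarray,
             cytoplasm_mask: np.ndarray, cell_id: int | str = 0,
             mode: str = "2D", multi_nucleus: bool = False) -> LocalizationRecord:
    """N:C ratio = mean(protein | nucleus) / mean(protein | cytoplasm)."""
    protein = np.asarray(protein, dtype=np.float64)
    n_n = int(np.count_nonzero(nucleus_mask))
    n_c = int(np.count_nonzero(cytoplasm_mask))
    if n_n == 0:
        raise ValueError(f"cell {cell_id}: empty nuclear compartment")
    if n_c == 0:
        raise ValueError(f"cell {cell_id}: empty cytoplasm after subtraction")
    mu_n = float(protein[nucleus_mask].mean())
    mu_c = float(protein[cytoplasm_mask].mean())
    if mu_c <= 0:
        raise ValueError(f"cell {cell_id}: zero cytoplasmic mean intensity")
    return LocalizationRecord(
        cell_id=cell_id, mode=mode, nuclear_mean=mu_n, cytoplasmic_mean=mu_c,
        nc_ratio=mu_n / mu_c, nuclear_size=n_n, cytoplasmic_size=n_c,
        multi_nucleus=multi_nucleus,
    )


def nc_ratio_2d(protein_img, dapi_img, phalloidin_img,
                cell_id: int | str = 0,
                background_subtract: bool = False) -> LocalizationRecord:
    """Full 2D pipeline: Otsu compartments then ratio of compartment means.

    Operates on a single focal plane (pass a projection explicitly if
    wanted).  Intensity means are spacing-free, so no pixel size is needed.
    """
    nuc, _cell, cyto, multi = compartment_masks(
        dapi_img, phalloidin_img, background_subtract
    )
    return nc_ratio(protein_img, nuc, cyto, cell_id, "2D", multi)


def nc_ratio_3d(protein_stack, dapi_stack, phalloidin_stack,
                cell_id: int | str = 0,
                background_subtract: bool = False) -> LocalizationRecord:
    """Volumetric N:C ratio with the same contract as the 2D analysis."""
    nuc, _cell, cyto, multi = compartment_masks(
        dapi_stack, phalloidin_stack, background_subtract
    )
    return nc_ratio(protein_stack, nuc, cyto, cell_id, "3D", multi)


def compare_2d_3d(records_2d, records_3d) -> dict:
    """Concordance of paired 2D and 3D N:C ratios.

    Returns Pearson correlation, the paired mean difference (2D − 3D), and
    the paired-t p-value for that difference being zero.
    """
    r2 = np.asarray([r.nc_ratio for r in records_2d], dtype=float)
    r3 = np.asarray([r.nc_ratio for r in records_3d], dtype=float)
    if r2.size != r3.size:
        raise ValueError("unpaired record lists")
    if r2.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.allclose(r2, r3) and (r2.std() == 0 or r3.std() == 0):
        corr = 1.0  # identical constant pairs: perfect concordance
    else:
        corr = float(np.corrcoef(r2, r3)[0, 1])
    diff = r2 - r3
    if np.allclose(diff, 0):
        t_p = 1.0
    else:
        t_p = float(stats.ttest_rel(r2, r3).pvalue)
    return {
        "n": int(r2.size),
        "correlation": corr,
        "mean_difference": float(diff.mean()),
        "p_paired_t": t_p,
    }
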