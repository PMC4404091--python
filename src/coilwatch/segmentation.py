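"""Segmentation of vascular lumen and coil mass from 3DRA volumes.

Two chains mirror the two reconstruction types:

* ``segment_vascular`` — subtracted volumes: grayscale opening to remove
  small-scale noise, Otsu thresholding over a volume of interest, retention
  of the connected component holding a user seed placed inside the sac, and
  level-set refinement.  The seed only initializes: any seed inside the same
  component yields the identical mask.
* ``segment_coil`` — baseline (bone-scan) volumes: grayscale closing, Otsu,
  largest connected component, filling of internal cavities bounded by coil
  wire (through-going tunnels are retained, since nothing bounds them), and
  level-set refinement.  The result — coil wires plus interstitial thrombus —
  is the *coil mass*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology
from skimage.segmentation import (
    inverse_gaussian_gradient,
    morphological_geodesic_active_contour,
)
from skimage.segmentation import morphsnakes as _morphsnakes

from .volumes import BinaryMask, ImageVolume, mask_like

# Complementary connectivity pairing: 26-connected foreground, 6-connected
# background, avoiding the usual topological paradoxes.
FOREGROUND_STRUCT = ndimage.generate_binary_structure(3, 3)
BACKGROUND_STRUCT = ndimage.generate_binary_structure(3, 1)


class SeedError(ValueError):
    """Raised when the user seed does not land on segmented foreground."""


class DegenerateImageError(ValueError):
    """Raised when an image has no contrast to segment."""


# ---------------------------------------------------------------------------
# Morphological filters
# ---------------------------------------------------------------------------

def _check_radius(vol: ImageVolume, radius_vox: int) -> None:
    if radius_vox < 0:
        raise ValueError(f"radius must be >= 0, got {radius_vox}")
    if radius_vox > min(vol.shape) // 2:
        raise ValueError(
            f"structuring-element radius {radius_vox} exceeds half the grid "
            f"extent {min(vol.shape) // 2}"
        )


def grayscale_open(vol: ImageVolume, radius_vox: int = 1) -> ImageVolume:
    """Grayscale morphological opening with a ball structuring element.

    Removes bright structures smaller than the ball (small-scale noise on the
    subtracted scans).  Output <= input voxelwise; idempotent for a fixed
    radius; radius 0 is the identity.
    """
    _check_radius(vol, radius_vox)
    if radius_vox == 0:
        return vol
    footprint = morphology.ball(radius_vox)
    return vol.with_values(morphology.opening(vol.values, footprint))


def grayscale_close(vol: ImageVolume, radius_vox: int = 1) -> ImageVolume:
    """Grayscale closing (dilate then erode): bridges gaps between nearby
    bright structures, e.g. adjacent windings of a coil wire."""
    _check_radius(vol, radius_vox)
    if radius_vox == 0:
        return vol
    footprint = morphology.ball(radius_vox)
    return vol.with_values(morphology.closing(vol.values, footprint))


# ---------------------------------------------------------------------------
# Otsu threshold
# ---------------------------------------------------------------------------

def otsu_threshold(values: np.ndarray, max_candidates: int = 1024) -> float:
    """Between-class-variance-maximizing threshold of a 1D intensity sample.

    Exhaustively searches candidate cuts between consecutive distinct values
    (binned to 256 levels when the sample has more than ``max_candidates``
    distinct values).  Returns the midpoint between the optimal boundary value
    and the next distinct value, so foreground is ``values > threshold``.
    Ties in the between-class variance are broken toward the lower threshold.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size < 2:
        raise DegenerateImageError("need at least 2 samples for a threshold")
    uniq, counts = np.unique(values, return_counts=True)
    if uniq.size < 2:
        raise DegenerateImageError("all intensities identical; no threshold exists")
    if uniq.size > max_candidates:
        # classic histogram formulation at 256 levels
        counts, edges = np.histogram(values, bins=256)
        uniq = 0.5 * (edges[:-1] + edges[1:])
        keep = counts > 0
        uniq, counts = uniq[keep], counts[keep]

    n = counts.sum()
    w0 = np.cumsum(counts)[:-1]                     # class sizes below each cut
    w1 = n - w0
    csum = np.cumsum(counts * uniq)[:-1]
    mu0 = csum / w0
    mu1 = (counts @ uniq - csum) / w1
    between = w0 * w1 * (mu0 - mu1) ** 2
    best = int(np.argmax(between))                  # argmax takes the first (lowest) tie
    return float(0.5 * (uniq[best] + uniq[best + 1]))


# ---------------------------------------------------------------------------
# Hole filling
# ---------------------------------------------------------------------------

def fill_internal_holes(mask: BinaryMask, connectivity: int = 6) -> BinaryMask:
    """Fill background cavities fully enclosed by foreground.

    Background components connected to the grid boundary — including tunnels
    passing all the way through the solid — are retained, because no bounding
    surface exists to close them.  ``connectivity`` (6 or 26) applies to the
    background.
    """
    if mask.is_empty():
        raise ValueError("cannot fill holes of an empty mask")
    if connectivity == 6:
        structure = BACKGROUND_STRUCT
    elif connectivity == 26:
        structure = FOREGROUND_STRUCT
    else:
        raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")
    filled = ndimage.binary_fill_holes(mask.values, structure=structure)
    return mask.with_values(filled)


# ---------------------------------------------------------------------------
# Level-set refinement
# ---------------------------------------------------------------------------

@dataclass
class LevelSetParams:
    """Morphological geodesic active-contour parameters.

    iterations : number of evolution steps (front moves <= 1 voxel/step)
    curvature_weight : rounded to the smoothing-pass count per step
    propagation_weight : balloon force; positive expands, negative shrinks
    edge_sigma : Gaussian scale (voxels) of the edge map
    edge_alpha : steepness of the inverse-gradient edge map
    """

    iterations: int = 20
    curvature_weight: float = 1.0
    propagation_weight: float = 1.0
    edge_sigma: float = 1.0
    edge_alpha: float = 50.0


def levelset_refine(
    vol: ImageVolume, init: BinaryMask, params: LevelSetParams | None = None
) -> BinaryMask:
    """Evolve an initial mask against the image edge map.

    A morphological geodesic active contour: the front advances under a
    balloon force where the edge response is weak and halts on strong edges,
    with curvature smoothing.  Deterministic for fixed inputs and parameters.
    """
    params = params or LevelSetParams()
    if init.is_empty():
        raise ValueError("level-set initialization mask is empty")
    if not init.same_grid(vol):
        raise ValueError("init mask and image are on different grids")
    if params.iterations == 0:
        return init

    # The curvature smoothing operator in scikit-image alternates between
    # its two compositions through a module-global cycle, so the result of a
    # contour evolution depends on how many smoothing passes ran earlier in
    # the process.  Reset the cycle so every refinement is reproducible.
    _morphsnakes._curvop = _morphsnakes._fcycle(
        [
            lambda u: _morphsnakes.sup_inf(_morphsnakes.inf_sup(u)),
            lambda u: _morphsnakes.inf_sup(_morphsnakes.sup_inf(u)),
        ]
    )

    # Balloon force, image attachment and the smoothing pass each move the
    # front at most one voxel per iteration.  The evolution is windowed to
    # the init bounding box padded by 2 iterations + 2: on segmentation
    # inputs the front is edge-stopped long before the window, and anything
    # outside the window is clipped, bounding the result to a 3-voxel/iter
    # neighborhood of the init in the worst case.
    margin = 2 * params.iterations + 2
    bbox = ndimage.find_objects(init.values.astype(np.int8), max_label=1)[0]
    lo = np.maximum([s.start - margin for s in bbox], 0)
    hi = np.minimum([s.stop + margin for s in bbox], init.shape)
    window = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    img = vol.values[window]
    init_crop = init.values[window]

    vmin, vmax = float(img.min()), float(img.max())
    scale = (vmax - vmin) or 1.0
    gimage = inverse_gaussian_gradient(
        (img - vmin) / scale, alpha=params.edge_alpha, sigma=params.edge_sigma
    )
    balloon = int(np.sign(params.propagation_weight))
    evolved = morphological_geodesic_active_contour(
        gimage,
        num_iter=params.iterations,
        init_level_set=init_crop.astype(np.int8),
        smoothing=int(round(params.curvature_weight)),
        threshold="auto",
        balloon=balloon,
    )
    full = np.zeros(init.shape, dtype=bool)
    full[window] = evolved > 0
    out = init.with_values(full)
    if out.is_empty():
        # front collapsed (e.g. contrast-free input) — fall back to the init
        return init
    return out


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def _voi_slices(vol: ImageVolume, voi_mm: tuple | None) -> tuple[slice, slice, slice]:
    """((xmin,ymin,zmin),(xmax,ymax,zmax)) in mm -> index slices, clipped."""
    if voi_mm is None:
        return (slice(None),) * 3
    lo_mm, hi_mm = np.asarray(voi_mm[0], float), np.asarray(voi_mm[1], float)
    lo = np.floor(vol.physical_to_index(np.minimum(lo_mm, hi_mm))).astype(int)
    hi = np.ceil(vol.physical_to_index(np.maximum(lo_mm, hi_mm))).astype(int) + 1
    lo = np.clip(lo, 0, np.array(vol.shape))
    hi = np.clip(hi, 0, np.array(vol.shape))
    if np.any(hi - lo < 2):
        raise ValueError("VOI does not overlap the image grid")
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def _seed_index(vol: ImageVolume, seed_mm) -> tuple[int, int, int]:
    idx = np.round(vol.physical_to_index(np.asarray(seed_mm, float))).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.array(vol.shape)):
        raise SeedError(f"seed point {tuple(seed_mm)} mm lies outside the image grid")
    return tuple(int(i) for i in idx)


def _restrict_to_voi(fg: np.ndarray, sl: tuple[slice, slice, slice]) -> np.ndarray:
    out = np.zeros_like(fg)
    out[sl] = fg[sl]
    return out


# ---------------------------------------------------------------------------
# Full chains
# ---------------------------------------------------------------------------

def segment_vascular(
    subtracted: ImageVolume,
    seed_point_mm,
    voi_mm: tuple | None = None,
    opening_radius: int = 1,
    levelset: LevelSetParams | None = None,
    keep: str = "seed",
) -> BinaryMask:
    """Segment the contrast-filled lumen (vessels + sac / residual blood).

    Chain: grayscale opening -> Otsu threshold over the VOI -> component
    selection -> level-set refinement.  With ``keep="seed"`` (default) only
    the connected component containing the seed is retained; the seed serves
    purely as an initialization point, so its placement within the component
    does not affect the segmentation boundary.  ``keep="all"`` retains every
    foreground component — used post-treatment, where residual blood may
    form pockets detached from the contrast-filled vessel.
    """
    if subtracted.modality != "subtracted":
        raise ValueError("segment_vascular expects a subtracted volume")
    if keep not in ("seed", "all"):
        raise ValueError("keep must be 'seed' or 'all'")
    seed = _seed_index(subtracted, seed_point_mm)
    opened = grayscale_open(subtracted, opening_radius)
    sl = _voi_slices(opened, voi_mm)
    thr = otsu_threshold(opened.values[sl])
    fg = _restrict_to_voi(opened.values > thr, sl)
    if not fg[seed]:
        raise SeedError(
            f"seed {tuple(np.round(seed_point_mm, 2))} mm falls on background "
            f"after thresholding (threshold {thr:.3g}); place the seed inside "
            "the aneurysm sac and retry"
        )
    if keep == "all":
        refined = levelset_refine(opened, mask_like(opened, fg), levelset)
        return refined if not refined.is_empty() else mask_like(opened, fg)
    labels, _ = ndimage.label(fg, structure=FOREGROUND_STRUCT)
    comp = labels == labels[seed]
    refined = levelset_refine(opened, mask_like(opened, comp), levelset)
    # refinement may smooth off satellite voxels; keep the seed's component
    labels, _ = ndimage.label(refined.values, structure=FOREGROUND_STRUCT)
    if labels[seed] == 0:
        return refined.with_values(comp)
    return refined.with_values(labels == labels[seed])


def segment_coil(
    baseline: ImageVolume,
    voi_mm: tuple | None = None,
    closing_radius: int = 1,
    levelset: LevelSetParams | None = None,
) -> BinaryMask:
    """Segment the coil mass from a baseline (bone-scan) volume.

    Chain: grayscale closing (bridges the winding of the coil wire) -> Otsu
    threshold over the VOI -> largest connected component -> internal-cavity
    fill (through-tunnels retained) -> level-set refinement.  A VOI around
    the treated aneurysm excludes skull from the histogram and the candidate
    region.  The default refinement runs without curvature smoothing: a coil
    mass's boundary is inherently irregular, and smoothing it systematically
    shrinks the measured volume.
    """
    if baseline.modality != "baseline":
        raise ValueError("segment_coil expects a baseline volume")
    if levelset is None:
        levelset = LevelSetParams(curvature_weight=0.0)
    closed = grayscale_close(baseline, closing_radius)
    sl = _voi_slices(closed, voi_mm)
    thr = otsu_threshold(closed.values[sl])
    fg = _restrict_to_voi(closed.values > thr, sl)
    if not fg.any():
        raise DegenerateImageError("no foreground after thresholding: no coil in the field of view")
    labels, n = ndimage.label(fg, structure=FOREGROUND_STRUCT)
    largest = np.argmax(ndimage.sum_labels(fg, labels, index=range(1, n + 1))) + 1
    solid = fill_internal_holes(mask_like(closed, labels == largest))
    refined = levelset_refine(closed, solid, levelset)
    labels, n = ndimage.label(refined.values, structure=FOREGROUND_STRUCT)
    sizes = ndimage.sum_labels(refined.values, labels, index=range(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    return fill_internal_holes(refined.with_values(labels == largest))
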