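"""Spot quantification on digitized gel images.

Three stages, mirroring how 2-DE imaging systems quantify a gel:

1. background correction — a smooth background estimate (greyscale
   morphological opening with a window much larger than a spot) is
   subtracted and the result floored at zero;
2. spot detection — local-maximum seeding above a robust noise
   threshold, then marker-based watershed assignment of pixels to
   seeds, giving each spot a disjoint mask;
3. integration — the integrated optical density (IOD) of a spot is
   the sum of background-corrected intensities over its mask, and the
   centroid is mapped to (pI, apparent MW) via the axis calibration.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.restoration import estimate_sigma
from skimage.segmentation import watershed

from .model import DetectedSpot, GelImage, SpotRecord, SpotTable


class ParameterError(ValueError):
    pass


def correct_background(image: GelImage, radius: int = 25,
                       smooth_sigma: float | None = None) -> GelImage:
    """Subtract a smooth background estimated by morphological opening.

    The opening uses a square window of side ``2*radius + 1`` px,
    which must be much larger than the spot SD so spots are removed
    from the estimate; ``smooth_sigma`` (default ``radius / 4``)
    Gaussian-smooths the estimate to avoid block artefacts. Output is
    floored at zero; estimator parameters go into ``meta``.
    """
    size = 2 * radius + 1
    if size > min(image.shape):
        raise ParameterError("background window larger than the image")
    px = image.pixels
    bg = ndimage.maximum_filter(ndimage.minimum_filter(px, size=size), size=size)
    if smooth_sigma is None:
        smooth_sigma = radius / 4
    if smooth_sigma > 0:
        bg = ndimage.gaussian_filter(bg, smooth_sigma)
    residual = px - bg
    # the opening rides the lower noise envelope, leaving a positive
    # offset under noise; the residual median (background pixels
    # dominate) removes it, and its MAD is the noise estimate
    offset = float(np.median(residual))
    noise_sd = float(1.4826 * np.median(np.abs(residual - offset)))
    corrected = np.maximum(residual - offset, 0.0)
    meta = dict(image.meta)
    meta["background"] = {"method": "morphological_opening", "radius": radius,
                          "smooth_sigma": smooth_sigma, "offset": offset,
                          "noise_sd": noise_sd}
    return GelImage(pixels=corrected, bit_depth=image.bit_depth,
                    calibration=image.calibration, gel_id=image.gel_id, meta=meta)


def detect_spots(
    image: GelImage,
    min_separation: int = 8,
    threshold_k: float = 5.0,
    mask_k: float = 2.0,
    min_area: int = 5,
) -> list[DetectedSpot]:
    """Detect spots on a background-corrected image.

    Seeds are local maxima at least ``min_separation`` px apart and
    higher than ``threshold_k`` times a robust noise estimate; when
    two maxima fall closer than the separation the higher one is kept
    as the single seed (merge policy). Pixels above ``mask_k`` times
    the noise are then assigned to the nearest seed by watershed on
    the inverted image, so masks are disjoint by construction.
    Regions smaller than ``min_area`` px are discarded — a physical
    spot spans tens of pixels, a lone noise spike does not.
    Deterministic for a fixed image.
    """
    px = image.pixels
    if px.size == 0 or px.max() <= 0:
        return []
    sigma = image.meta.get("background", {}).get("noise_sd", 0.0)
    if not sigma:
        sigma = float(estimate_sigma(px))
    if sigma <= 0 or not np.isfinite(sigma):
        sigma = 1e-6
    peaks = peak_local_max(
        px, min_distance=min_separation, threshold_abs=threshold_k * sigma,
        exclude_border=False,
    )
    if len(peaks) == 0:
        return []
    markers = np.zeros(px.shape, dtype=np.int32)
    order = np.argsort(px[peaks[:, 0], peaks[:, 1]])  # lowest first; ids by height
    for label, idx in enumerate(order[::-1], start=1):
        markers[peaks[idx, 0], peaks[idx, 1]] = label
    mask = px > mask_k * sigma
    labels = watershed(-px, markers=markers, mask=mask)
    cal = image.calibration
    # ids carry the gel id so spots from different gels never collide
    # (cross-gel correspondence is by coordinates, not by label)
    prefix = f"{image.gel_id}-" if image.gel_id else ""
    spots = []
    for label in range(1, len(peaks) + 1):
        coords = np.argwhere(labels == label)
        if len(coords) < min_area:
            continue
        weights = px[coords[:, 0], coords[:, 1]]
        total = weights.sum()
        if total <= 0:
            continue
        r0 = float(np.average(coords[:, 0], weights=weights))
        c0 = float(np.average(coords[:, 1], weights=weights))
        spots.append(
            DetectedSpot(
                spot_id=f"{prefix}d{label:04d}",
                centroid=(r0, c0),
                pi_coord=cal.pi_of_col(c0),
                mw_coord=cal.mw_of_row(r0),
                mask=coords,
                iod=float(total),
            )
        )
    return spots


def integrate_iod(image: GelImage, spots: list[DetectedSpot]) -> SpotTable:
    """Sum corrected intensities over each spot's mask into a SpotTable.

    Masks must be pairwise disjoint (guaranteed by
    :func:`detect_spots`); a violation is an internal error.
    """
    seen = set()
    for s in spots:
        if s.mask is None:
            raise ValueError(f"spot {s.spot_id} has no mask")
        keys = {(int(r), int(c)) for r, c in s.mask}
        if seen & keys:
            raise RuntimeError("overlapping spot masks (violated invariant)")
        seen |= keys
    records = []
    for s in spots:
        iod = float(image.pixels[s.mask[:, 0], s.mask[:, 1]].sum()) if len(s.mask) else 0.0
        records.append(
            SpotRecord(
                spot_id=s.spot_id,
                gel_id=image.gel_id,
                pi_coord=s.pi_coord,
                mw_coord=s.mw_coord,
                iod_raw=iod,
            )
        )
    return SpotTable(gel_id=image.gel_id, records=records)


def quantify_gel(
    image: GelImage,
    background_radius: int = 25,
    min_separation: int = 8,
    threshold_k: float = 5.0,
    mask_k: float = 2.0,
) -> SpotTable:
    """Background-correct, detect and integrate in one call."""
    corrected = correct_background(image, radius=background_radius)
    spots = detect_spots(corrected, min_separation=min_separation,
                         threshold_k=threshold_k, mask_k=mask_k)
    return integrate_iod(corrected, spots)
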