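"""Wet-pellicle density from a side-view photograph and dry mass.

A pellicle grown in a cylindrical container of radius ``r`` is modelled as an
equivalent cylinder: the segmented side-view cross-section area ``A`` (mm²) is
equated to the rectangle ``2·r·h``, giving an equivalent height ``h = A/(2r)``,
a volume ``V = π r² h`` and a density ``ρ = W/V`` from the dry mass ``W``.
Densities are reported in mg/cm³.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label


class SegmentationError(ValueError):
    """Raised when no foreground can be segmented from a photograph."""


@dataclass(frozen=True)
class PellicleGeometry:
    """Equivalent-cylinder geometry and density of a single pellicle."""

    area_measured_mm2: float
    container_radius_mm: float
    equiv_height_mm: float
    volume_mm3: float
    dry_mass_mg: float
    density_mg_cm3: float


def segment_cross_section(
    photo: np.ndarray,
    scale_mm_per_px: float,
    threshold: float | None = None,
) -> float:
    """Segment the bright pellicle cross-section and return its area in mm².

    Parameters
    ----------
    photo
        Grayscale side-view image; the pellicle is brighter than the
        background.
    scale_mm_per_px
        Physical size of one pixel, in mm.
    threshold
        Manual intensity threshold. By default Otsu's global threshold is
        used.

    Only the largest connected foreground component is counted, which
    discards speckle from noise or reflections.
    """
    if scale_mm_per_px <= 0:
        raise ValueError("scale_mm_per_px must be positive")
    photo = np.asarray(photo, dtype=float)
    if photo.ndim != 2:
        raise ValueError("photo must be a 2D grayscale image")
    if np.ptp(photo) == 0:
        raise SegmentationError("image has no contrast; cannot segment")
    if threshold is None:
        threshold = threshold_otsu(photo)
    mask = photo > threshold
    if not mask.any():
        raise SegmentationError("empty foreground after thresholding")
    labels = label(mask)
    counts = np.bincount(labels.ravel())
    counts[0] = 0  # background label
    n_px = counts.max()
    return float(n_px) * scale_mm_per_px**2


def pellicle_density(
    area_mm2: float, r_mm: float, dry_mass_mg: float
) -> PellicleGeometry:
    """Compute the equivalent-cylinder geometry and density.

    ``h = A/(2r)``, ``V = π r² h`` (mm³) and ``ρ = W/V`` converted to
    mg/cm³ (1 cm³ = 1000 mm³).
    """
    if area_mm2 <= 0 or r_mm <= 0 or dry_mass_mg <= 0:
        raise ValueError("area, radius and mass must all be positive")
    h = area_mm2 / (2.0 * r_mm)
    volume = math.pi * r_mm**2 * h
    density = dry_mass_mg / (volume / 1000.0)
    return PellicleGeometry(
        area_measured_mm2=float(area_mm2),
        container_radius_mm=float(r_mm),
        equiv_height_mm=float(h),
        volume_mm3=float(volume),
        dry_mass_mg=float(dry_mass_mg),
        density_mg_cm3=float(density),
    )
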