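"""Wide-angle X-ray scattering reduction and crystallinity analysis.

2D detector frames are reduced to 1D diffractograms by azimuthal integration
(per-pixel 2θ binning on a flat detector at normal incidence). A smooth
amorphous background is fitted through local-minima anchor points between the
known cellulose Iβ reflections, and the crystallinity index over
2θ ∈ [10°, 45°] is

    crystallinity% = (area_sample − area_background) / area_sample × 100,

with both areas from trapezoidal quadrature on the same grid. Pseudo-Voigt
peaks fitted to the background-subtracted signal give per-reflection lattice
spacings via Bragg's law, d = 2π/q (first order), and crystallite sizes via
the Scherrer equation, τ = Kλ/(β cos θ), with shape factor K = 0.94.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from lmfit.models import PseudoVoigtModel
from scipy.interpolate import PchipInterpolator
from scipy.signal import savgol_filter

CRYSTALLINITY_RANGE_DEG = (10.0, 45.0)
SCHERRER_K = 0.94
CU_KALPHA_A = 1.54

#: Cellulose Iβ reflections for Cu Kα (standard powder-diffraction positions).
CELLULOSE_IBETA_PEAKS_DEG: dict[str, float] = {
    "(1-10)": 14.5,
    "(110)": 16.8,
    "(102)": 20.6,
    "(200)": 22.7,
    "(004)": 34.6,
}


class IntegrationError(ValueError):
    pass


class BackgroundFitError(ValueError):
    pass


@dataclass(frozen=True)
class DetectorGeometry:
    """Flat detector at normal incidence behind the sample.

    wavelength_A : X-ray wavelength in Å (Cu Kα default).
    distance_mm  : sample–detector distance.
    pixel_size_um: square pixel pitch.
    beam_center_px: (x, y) beam center in pixel coordinates; None means the
        frame center.
    """

    wavelength_A: float = CU_KALPHA_A
    distance_mm: float = 50.0
    pixel_size_um: float = 75.0
    beam_center_px: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if min(self.wavelength_A, self.distance_mm, self.pixel_size_um) <= 0:
            raise ValueError("wavelength, distance and pixel size must be positive")

    def center_for(self, shape: tuple[int, int]) -> tuple[float, float]:
        if self.beam_center_px is not None:
            return self.beam_center_px
        return ((shape[1] - 1) / 2.0, (shape[0] - 1) / 2.0)

    def twotheta_deg_of(self, shape: tuple[int, int]) -> np.ndarray:
        """Per-pixel scattering angle 2θ in degrees."""
        cx, cy = self.center_for(shape)
        yy, xx = np.indices(shape)
        r_mm = np.hypot(xx - cx, yy - cy) * self.pixel_size_um * 1e-3
        return np.degrees(np.arctan2(r_mm, self.distance_mm))

    def max_twotheta_deg(self, shape: tuple[int, int]) -> float:
        """Largest 2θ fully covered azimuthally (set by the nearest edge)."""
        cx, cy = self.center_for(shape)
        r_px = min(cx, cy, shape[1] - 1 - cx, shape[0] - 1 - cy)
        r_mm = r_px * self.pixel_size_um * 1e-3
        return math.degrees(math.atan2(r_mm, self.distance_mm))


def twotheta_to_q(twotheta_deg: np.ndarray, wavelength_A: float = CU_KALPHA_A) -> np.ndarray:
    """Scattering vector magnitude q = 4π sin(θ)/λ in Å⁻¹."""
    theta = np.radians(np.asarray(twotheta_deg, float) / 2.0)
    return 4.0 * np.pi * np.sin(theta) / wavelength_A


@dataclass(frozen=True)
class Diffractogram1D:
    """Azimuthally averaged intensity vs scattering angle."""

    twotheta_deg: np.ndarray
    intensity: np.ndarray
    wavelength_A: float = CU_KALPHA_A

    def __post_init__(self) -> None:
        object.__setattr__(self, "twotheta_deg", np.asarray(self.twotheta_deg, float))
        object.__setattr__(self, "intensity", np.asarray(self.intensity, float))
        if self.twotheta_deg.shape != self.intensity.shape or self.intensity.ndim != 1:
            raise ValueError("grid and intensity must be matching 1D arrays")
        if np.any(np.diff(self.twotheta_deg) <= 0):
            raise ValueError("2θ grid must be strictly increasing")

    @property
    def q_invA(self) -> np.ndarray:
        return twotheta_to_q(self.twotheta_deg, self.wavelength_A)


@dataclass(frozen=True)
class BackgroundFit:
    model: str
    anchors_deg: np.ndarray
    background: np.ndarray  # on the diffractogram grid, within the fit range
    range_deg: tuple[float, float]
    area_background: float


@dataclass(frozen=True)
class FittedPeak:
    center_deg: float
    fwhm_deg: float
    amplitude: float
    eta: float
    label: str | None = None


@dataclass(frozen=True)
class PeakFit:
    peaks: tuple[FittedPeak, ...]
    converged: bool
    report: str = field(repr=False, default="")


@dataclass(frozen=True)
class CrystallinityResult:
    area_sample: float
    area_background: float
    crystallinity_pct: float
    lattice_spacings_A: dict[str, float]
    crystallite_sizes_nm: dict[str, float]


def merge_line_eraser(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    mask_a: np.ndarray | None = None,
    mask_b: np.ndarray | None = None,
) -> np.ndarray:
    """Merge two exposures taken at shifted detector positions.

    Masked pixels (True = invalid, e.g. the module slit) are excluded; each
    output pixel is the mean of its unmasked contributions. Pixels masked in
    both frames come out as NaN and are excluded downstream.
    """
    frame_a = np.asarray(frame_a, float)
    frame_b = np.asarray(frame_b, float)
    if frame_a.shape != frame_b.shape:
        raise ValueError("frames must have identical shapes")
    mask_a = np.zeros(frame_a.shape, bool) if mask_a is None else np.asarray(mask_a, bool)
    mask_b = np.zeros(frame_b.shape, bool) if mask_b is None else np.asarray(mask_b, bool)
    weight = (~mask_a).astype(float) + (~mask_b).astype(float)
    total = np.where(mask_a, 0.0, frame_a) + np.where(mask_b, 0.0, frame_b)
    with np.errstate(invalid="ignore"):
        merged = np.where(weight > 0, total / np.maximum(weight, 1), np.nan)
    return merged


def integrate_azimuthal(
    frame: np.ndarray,
    geometry: DetectorGeometry,
    n_bins: int = 500,
    twotheta_range: tuple[float, float] | None = None,
    mask: np.ndarray | None = None,
) -> Diffractogram1D:
    """Reduce a 2D frame to intensity vs 2θ by equal-width angular binning.

    NaN pixels and masked pixels are excluded; empty bins are interpolated
    from their neighbours and flagged with a warning.
    """
    frame = np.asarray(frame, float)
    if n_bins < 50:
        raise ValueError("n_bins must be at least 50")
    tth = geometry.twotheta_deg_of(frame.shape)
    valid = np.isfinite(frame)
    if mask is not None:
        valid &= ~np.asarray(mask, bool)
    if not valid.any():
        raise IntegrationError("all pixels are masked or invalid")
    if twotheta_range is None:
        twotheta_range = (float(tth[valid].min()), geometry.max_twotheta_deg(frame.shape))
    lo, hi = twotheta_range
    sel = valid & (tth >= lo) & (tth < hi)
    idx = np.floor((tth[sel] - lo) / (hi - lo) * n_bins).astype(np.intp)
    idx = np.clip(idx, 0, n_bins - 1)
    sums = np.bincount(idx, weights=frame[sel], minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    centers = lo + (np.arange(n_bins) + 0.5) * (hi - lo) / n_bins
    with np.errstate(invalid="ignore"):
        profile = sums / counts
    empty = counts == 0
    if empty.any():
        warnings.warn(f"{empty.sum()} empty 2θ bins interpolated", stacklevel=2)
        profile[empty] = np.interp(centers[empty], centers[~empty], profile[~empty])
    return Diffractogram1D(centers, profile, geometry.wavelength_A)


def _range_slice(d: Diffractogram1D, range_deg: tuple[float, float]) -> np.ndarray:
    lo, hi = range_deg
    if lo < d.twotheta_deg[0] - 1e-9 or hi > d.twotheta_deg[-1] + 1e-9:
        raise ValueError(f"range {range_deg} outside the 2θ grid")
    return (d.twotheta_deg >= lo) & (d.twotheta_deg <= hi)


def fit_background(
    d: Diffractogram1D,
    range_deg: tuple[float, float] = CRYSTALLINITY_RANGE_DEG,
    peak_centers_deg: list[float] | None = None,
    exclusion_deg: float = 1.5,
    min_anchors: int = 4,
) -> BackgroundFit:
    """Fit the amorphous halo through local minima between the reflections.

    The signal is lightly smoothed; within each contiguous stretch of the
    range lying at least `exclusion_deg` away from every known peak position,
    local minima of the smoothed signal (one per ~2° sub-window) are taken as
    anchor points together with the range endpoints, and a shape-preserving
    cubic (PCHIP) is drawn through them. The background is clipped to be
    non-negative.
    """
    if peak_centers_deg is None:
        peak_centers_deg = list(CELLULOSE_IBETA_PEAKS_DEG.values())
    m = _range_slice(d, range_deg)
    x = d.twotheta_deg[m]
    y = d.intensity[m]
    step = x[1] - x[0]
    win = max(5, int(round(1.0 / step)) | 1)  # ~1° smoothing window, odd
    win = min(win, len(y) - (1 - len(y) % 2))
    ys = savgol_filter(y, win, 2)
    allowed = np.ones(len(x), bool)
    for c in peak_centers_deg:
        allowed &= np.abs(x - c) >= exclusion_deg
    keep: list[int] = []
    segment_deg = 2.0
    hood = max(1, int(round(0.25 / step)))  # anchor value averaged over ±0.25°
    run_start = None
    for i in range(len(x) + 1):
        inside = i < len(x) and allowed[i]
        if inside and run_start is None:
            run_start = i
        elif not inside and run_start is not None:
            seg = np.arange(run_start, i)
            n_sub = max(1, int(round((x[seg[-1]] - x[seg[0]]) / segment_deg)))
            for sub in np.array_split(seg, n_sub):
                if len(sub) >= 3:
                    keep.append(int(sub[np.argmin(ys[sub])]))
            run_start = None
    anchors = np.unique(np.concatenate(([0], keep, [len(x) - 1])).astype(int))
    if len(anchors) < min_anchors:
        raise BackgroundFitError(
            f"only {len(anchors)} background anchor candidates found (need {min_anchors})"
        )
    # averaging the smoothed signal around each anchor suppresses the
    # negative bias of picking noise minima
    anchor_vals = np.array([
        ys[max(0, a - hood): a + hood + 1].mean() for a in anchors
    ])
    bg = PchipInterpolator(x[anchors], anchor_vals)(x)
    bg = np.clip(bg, 0.0, None)
    area = float(np.trapezoid(bg, x))
    return BackgroundFit(
        model="smooth_spline_through_anchors",
        anchors_deg=x[anchors],
        background=bg,
        range_deg=range_deg,
        area_background=area,
    )


def fit_peaks(
    d: Diffractogram1D,
    bg: BackgroundFit,
    init_centers_deg: list[float] | dict[str, float] | None = None,
    center_window_deg: float = 1.0,
) -> PeakFit:
    """Nonlinear least-squares pseudo-Voigt fit to the background-subtracted signal."""
    if init_centers_deg is None:
        init_centers_deg = CELLULOSE_IBETA_PEAKS_DEG
    if isinstance(init_centers_deg, dict):
        labels, centers = list(init_centers_deg.keys()), list(init_centers_deg.values())
    else:
        labels, centers = [None] * len(init_centers_deg), list(init_centers_deg)
    m = _range_slice(d, bg.range_deg)
    x = d.twotheta_deg[m]
    resid = d.intensity[m] - bg.background
    lo, hi = bg.range_deg
    if any(not (lo <= c <= hi) for c in centers):
        raise ValueError("initial peak centers must lie inside the fit range")

    model = None
    for k in range(len(centers)):
        comp = PseudoVoigtModel(prefix=f"p{k}_")
        model = comp if model is None else model + comp
    params = model.make_params()
    for k, c in enumerate(centers):
        near = np.abs(x - c) <= center_window_deg
        amp0 = max(float(resid[near].max()), 1e-6) if near.any() else 1.0
        params[f"p{k}_center"].set(value=c, min=c - center_window_deg, max=c + center_window_deg)
        params[f"p{k}_sigma"].set(value=0.5, min=0.01, max=5.0)
        params[f"p{k}_amplitude"].set(value=amp0, min=0.0)
        params[f"p{k}_fraction"].set(value=0.3, min=0.0, max=1.0)
    result = model.fit(resid, params, x=x)
    peaks = tuple(
        FittedPeak(
            center_deg=float(result.params[f"p{k}_center"].value),
            fwhm_deg=float(result.params[f"p{k}_fwhm"].value),
            amplitude=float(result.params[f"p{k}_amplitude"].value),
            eta=float(result.params[f"p{k}_fraction"].value),
            label=labels[k],
        )
        for k in range(len(centers))
    )
    if not result.success:
        warnings.warn("peak fit did not converge; inspect the report", stacklevel=2)
    return PeakFit(peaks=peaks, converged=bool(result.success), report=result.fit_report())


def crystallinity_index(
    d: Diffractogram1D,
    bg: BackgroundFit,
) -> float:
    """Crystallinity% = (area_sample − area_background)/area_sample × 100,
    both areas by trapezoidal quadrature over the fit range on the same grid."""
    m = _range_slice(d, bg.range_deg)
    x = d.twotheta_deg[m]
    area_sample = float(np.trapezoid(d.intensity[m], x))
    if area_sample == 0:
        raise ValueError("zero total scattered intensity; crystallinity undefined")
    return 100.0 * (area_sample - bg.area_background) / area_sample


def bragg_spacing(q_invA: float) -> float:
    """First-order Bragg lattice spacing d = 2π/q, in Å."""
    if q_invA <= 0:
        raise ValueError("q must be positive")
    return 2.0 * math.pi / q_invA


def scherrer_size(
    beta_2theta_deg: float,
    center_2theta_deg: float,
    wavelength_A: float = CU_KALPHA_A,
    K: float = SCHERRER_K,
    instrument_fwhm_deg: float = 0.0,
) -> float:
    """Scherrer crystallite size τ = Kλ/(β cos θ), reported in nm.

    β is the peak FWHM in 2θ degrees (converted to radians); θ is half the
    peak position. An optional instrumental FWHM is removed in quadrature.
    """
    if beta_2theta_deg <= 0:
        raise ValueError("peak FWHM must be positive")
    if instrument_fwhm_deg:
        b2 = beta_2theta_deg**2 - instrument_fwhm_deg**2
        if b2 <= 0:
            raise ValueError("instrumental FWHM exceeds the measured FWHM")
        beta_2theta_deg = math.sqrt(b2)
    beta = math.radians(beta_2theta_deg)
    theta = math.radians(center_2theta_deg / 2.0)
    if math.cos(theta) <= 0:
        raise ValueError("cos θ must be positive")
    tau_A = K * wavelength_A / (beta * math.cos(theta))
    return tau_A / 10.0


def analyze_diffractogram(
    d: Diffractogram1D,
    init_centers_deg: dict[str, float] | None = None,
    range_deg: tuple[float, float] = CRYSTALLINITY_RANGE_DEG,
) -> CrystallinityResult:
    """Full 1D analysis: background, crystallinity index, peak fit, Bragg
    spacings and Scherrer sizes per reflection."""
    bg = fit_background(d, range_deg, peak_centers_deg=(
        list(init_centers_deg.values()) if init_centers_deg else None
    ))
    pct = crystallinity_index(d, bg)
    pf = fit_peaks(d, bg, init_centers_deg)
    spacings: dict[str, float] = {}
    sizes: dict[str, float] = {}
    for k, pk in enumerate(pf.peaks):
        key = pk.label or f"peak{k}"
        q = float(twotheta_to_q(pk.center_deg, d.wavelength_A))
        spacings[key] = bragg_spacing(q)
        sizes[key] = scherrer_size(pk.fwhm_deg, pk.center_deg, d.wavelength_A)
    m = _range_slice(d, range_deg)
    area_sample = float(np.trapezoid(d.intensity[m], d.twotheta_deg[m]))
    return CrystallinityResult(
        area_sample=area_sample,
        area_background=bg.area_background,
        crystallinity_pct=pct,
        lattice_spacings_A=spacings,
        crystallite_sizes_nm=sizes,
    )
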