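"""Synthetic inputs with stored ground truth for every pipeline stage.

Each generator emulates the statistical structure its analysis assumes, so
every stage can be tested end-to-end without raw instrument data:

* blinking-fluorophore fiber timelapses — fibers alternate labeled amorphous
  segments (stochastically blinking Gaussian emitters) and dark crystalline
  segments (the dye binds disordered cellulose far more efficiently);
* 1D diffractograms — crystalline reflections on a broad amorphous halo plus
  noise, with an area-based crystalline fraction over 2θ ∈ [10°, 45°];
* isotropic 2D detector frames whose azimuthal integration reproduces a given
  1D pattern, with an optional masked slit band for merge tests;
* tensile records with a nonlinear toe, a linear-elastic branch of stated
  slope and an abrupt rupture, exported as displacement/force;
* side-view pellicle photographs (bright rectangle of width 2r and height h).

All generators are seed-deterministic: identical inputs and seed give
bit-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import scipy.ndimage

from .mechanics import DogboneGeometry
from .waxs import CRYSTALLINITY_RANGE_DEG, DetectorGeometry, Diffractogram1D

CRYSTALLINE = "crystalline"
AMORPHOUS = "amorphous"

# Realistic default domain-length scales (nm): crystalline stretches around
# 510–600 nm and amorphous stretches around 167–192 nm, i.e. ≈75% crystallinity.
DEFAULT_CRYSTALLINE_NM = (510.0, 600.0)
DEFAULT_AMORPHOUS_NM = (167.0, 192.0)


class GeometryError(ValueError):
    """Raised when a requested geometry cannot be realized."""


# --------------------------------------------------------------------------
# single fibers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GroundTruthFiber:
    """Ground truth for one simulated fiber.

    domain_lengths alternates (state, length in nm) along the fiber; path is
    an (N, 2) polyline in (x, y) pixel coordinates. Emitters are laid only in
    amorphous segments at `emitter_density` per µm (crystalline segments get
    `emitter_density / contrast_ratio`, zero for the default infinite
    contrast) and blink independently each frame with probability
    `blink_prob`.
    """

    domain_lengths: tuple[tuple[str, float], ...]
    path: np.ndarray
    pixel_size_nm: float = 100.0
    emitter_density: float = 2000.0  # per µm of amorphous segment
    blink_prob: float = 0.35
    psf_sigma_px: float = 0.65
    contrast_ratio: float = 2.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "path", np.asarray(self.path, float))
        object.__setattr__(self, "domain_lengths", tuple(
            (str(s), float(l)) for s, l in self.domain_lengths
        ))
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        for state, length in self.domain_lengths:
            if state not in (CRYSTALLINE, AMORPHOUS):
                raise ValueError(f"unknown domain state {state!r}")
            if length <= 0:
                raise ValueError("all domain lengths must be positive")

    @property
    def total_length_nm(self) -> float:
        return sum(l for _, l in self.domain_lengths)

    @property
    def true_crystallinity(self) -> float:
        """Fraction of the fiber length in crystalline domains."""
        cryst = sum(l for s, l in self.domain_lengths if s == CRYSTALLINE)
        return cryst / self.total_length_nm

    def amorphous_intervals_nm(self) -> list[tuple[float, float]]:
        out = []
        pos = 0.0
        for state, length in self.domain_lengths:
            if state == AMORPHOUS:
                out.append((pos, pos + length))
            pos += length
        return out

    def arclength_to_px(self, s_nm: np.ndarray) -> np.ndarray:
        """Map arclength (nm along the fiber) to (x, y) pixel coordinates."""
        pts = self.path
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1) * self.pixel_size_nm
        cum = np.concatenate(([0.0], np.cumsum(seg)))
        if cum[-1] + 1e-9 < self.total_length_nm:
            raise GeometryError(
                f"path ({cum[-1]:.0f} nm) is shorter than the fiber ({self.total_length_nm:.0f} nm)"
            )
        s = np.asarray(s_nm, float)
        return np.column_stack([np.interp(s, cum, pts[:, 0]), np.interp(s, cum, pts[:, 1])])


def random_fiber_truth(
    seed: int,
    n_pairs: int = 10,
    frame_shape: tuple[int, int] = (24, 120),
    pixel_size_nm: float = 100.0,
    crystalline_range_nm: tuple[float, float] = DEFAULT_CRYSTALLINE_NM,
    amorphous_range_nm: tuple[float, float] = DEFAULT_AMORPHOUS_NM,
    **kwargs,
) -> GroundTruthFiber:
    """A straight horizontal fiber with domain lengths drawn uniformly from
    the stated ranges, fitted inside `frame_shape` with a safety margin."""
    rng = np.random.default_rng(seed)
    domains: list[tuple[str, float]] = []
    for _ in range(n_pairs):
        domains.append((CRYSTALLINE, float(rng.uniform(*crystalline_range_nm))))
        domains.append((AMORPHOUS, float(rng.uniform(*amorphous_range_nm))))
    total_nm = sum(l for _, l in domains)
    length_px = total_nm / pixel_size_nm
    h, w = frame_shape
    margin = 8.0
    if length_px > w - 2 * margin:
        raise GeometryError(
            f"fiber of {length_px:.0f} px does not fit a {w}-px-wide frame"
        )
    y0 = h / 2.0 + rng.uniform(-2, 2)
    x0 = margin + rng.uniform(0, (w - 2 * margin) - length_px)
    path = np.array([[x0, y0], [x0 + length_px, y0]])
    return GroundTruthFiber(tuple(domains), path, pixel_size_nm=pixel_size_nm, **kwargs)


def fixed_fiber_truth(
    crystalline_nm: float = 600.0,
    amorphous_nm: float = 200.0,
    n_pairs: int = 10,
    pixel_size_nm: float = 100.0,
    frame_shape: tuple[int, int] = (24, 120),
    **kwargs,
) -> GroundTruthFiber:
    """Deterministic fiber with identical repeating domains (600/200 nm
    defaults give exactly 75% crystallinity)."""
    domains = tuple(
        d for _ in range(n_pairs) for d in ((CRYSTALLINE, crystalline_nm), (AMORPHOUS, amorphous_nm))
    )
    total_px = n_pairs * (crystalline_nm + amorphous_nm) / pixel_size_nm
    h, w = frame_shape
    if total_px > w - 16:
        raise GeometryError("fiber does not fit the frame")
    x0 = (w - total_px) / 2.0
    path = np.array([[x0, h / 2.0], [x0 + total_px, h / 2.0]])
    return GroundTruthFiber(domains, path, pixel_size_nm=pixel_size_nm, **kwargs)


def _place_emitters(truth: GroundTruthFiber, rng: np.random.Generator) -> np.ndarray:
    """Poisson-process emitter arclength positions (nm)."""
    positions: list[np.ndarray] = []
    pos = 0.0
    for state, length in truth.domain_lengths:
        density = truth.emitter_density
        if state == CRYSTALLINE:
            density = 0.0 if math.isinf(truth.contrast_ratio) else density / truth.contrast_ratio
        n = rng.poisson(density * length / 1000.0)
        if n:
            positions.append(pos + rng.uniform(0.0, length, n))
        pos += length
    if not positions:
        return np.empty(0)
    return np.sort(np.concatenate(positions))


def gen_fiber_stack(
    truth: GroundTruthFiber,
    n_frames: int = 30,
    seed: int = 0,
    frame_shape: tuple[int, int] = (24, 120),
    photons_per_emitter: float = 40.0,
    background: float = 10.0,
    speckle_sd: float = 0.0,
    speckle_corr_px: float = 2.0,
    n_debris_spots: int = 40,
    debris_photons: float = 12.0,
) -> np.ndarray:
    """Simulate a blinking-fluorophore timelapse of one fiber.

    Emitters are placed once (a Poisson process along the segments, the
    crystalline ones attenuated by the dye contrast ratio), then blink
    independently per frame; each ON emitter contributes a Gaussian PSF
    spot, and every frame receives Poisson shot noise on top of a constant
    background. Two optional static nuisance components emulate a real TIRF
    background: `speckle_sd` adds a spatially correlated field (out-of-focus
    unbound-dye fluorescence) and `n_debris_spots` scatters dim,
    non-blinking point sources (non-specifically adsorbed dye aggregates)
    across the field of view; both are drawn once per stack. Returns a
    (T, H, W) stack.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    h, w = frame_shape
    margin = truth.psf_sigma_px
    if (
        truth.path[:, 0].min() < margin
        or truth.path[:, 1].min() < margin
        or truth.path[:, 0].max() > w - 1 - margin
        or truth.path[:, 1].max() > h - 1 - margin
    ):
        raise GeometryError("fiber path leaves the frame (or its PSF margin)")
    rng = np.random.default_rng(seed)
    s_nm = _place_emitters(truth, rng)
    xy = truth.arclength_to_px(s_nm) if len(s_nm) else np.empty((0, 2))

    base = np.full((h, w), float(background))
    if speckle_sd > 0:
        speckle = scipy.ndimage.gaussian_filter(rng.normal(size=(h, w)), speckle_corr_px)
        speckle *= speckle_sd / speckle.std()
        base = np.clip(base + speckle, 0.0, None)
    if n_debris_spots > 0:
        ov0 = 4
        fine0 = np.zeros((h * ov0, w * ov0))
        dx = rng.uniform(2.0, w - 2.0, n_debris_spots)
        dy = rng.uniform(2.0, h - 2.0, n_debris_spots)
        scale = rng.uniform(0.5, 1.5, n_debris_spots)
        np.add.at(
            fine0,
            (np.round(dy * ov0).astype(int), np.round(dx * ov0).astype(int)),
            debris_photons * scale,
        )
        fine0 = scipy.ndimage.gaussian_filter(fine0, truth.psf_sigma_px * ov0)
        base = base + fine0.reshape(h, ov0, w, ov0).sum(axis=(1, 3))

    # render on a 4× oversampled grid: bin ON emitters, convolve once with
    # the PSF, then block-sum back to the native pixel grid
    sigma = truth.psf_sigma_px
    ov = 4
    ix = np.clip(np.round(xy[:, 0] * ov).astype(int), 0, w * ov - 1) if len(xy) else None
    iy = np.clip(np.round(xy[:, 1] * ov).astype(int), 0, h * ov - 1) if len(xy) else None
    stack = np.empty((n_frames, h, w))
    for t in range(n_frames):
        fine = np.zeros((h * ov, w * ov))
        if len(xy):
            on = rng.random(len(xy)) < truth.blink_prob
            np.add.at(fine, (iy[on], ix[on]), photons_per_emitter)
            fine = scipy.ndimage.gaussian_filter(fine, sigma * ov)
        signal = fine.reshape(h, ov, w, ov).sum(axis=(1, 3))
        stack[t] = rng.poisson(base + signal)
    return stack


def gen_intensity_profile(
    truth: GroundTruthFiber,
    step_nm: float = 20.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    amplitude: float = 100.0,
    psf_sigma_nm: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Intensity profile bypassing the imaging simulation (for unit tests).

    The profile is the indicator of the amorphous segments, blurred with a
    Gaussian of the PSF width, scaled to `amplitude`, plus Gaussian noise.
    Returns (positions_nm, intensities).
    """
    if step_nm <= 0:
        raise ValueError("step_nm must be positive")
    total = truth.total_length_nm
    positions = np.arange(0.0, total + step_nm / 2, step_nm)
    indicator = np.zeros_like(positions)
    for lo, hi in truth.amorphous_intervals_nm():
        indicator[(positions >= lo) & (positions < hi)] = 1.0
    if psf_sigma_nm is None:
        psf_sigma_nm = truth.psf_sigma_px * truth.pixel_size_nm
    if psf_sigma_nm > 0:
        indicator = scipy.ndimage.gaussian_filter1d(indicator, psf_sigma_nm / step_nm)
    profile = amplitude * indicator
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        profile = profile + rng.normal(0.0, noise_sd, profile.shape)
    return positions, profile


# --------------------------------------------------------------------------
# diffraction
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GroundTruthPattern:
    """Ground truth for one simulated diffractogram.

    peaks: (center 2θ°, FWHM 2θ°, integrated area) Gaussian reflections;
    halo: (center 2θ°, sigma 2θ°, amplitude) broad amorphous components;
    the crystalline fraction is the area share of the peaks over
    2θ ∈ [10°, 45°], computed from the noiseless components.
    """

    peaks: tuple[tuple[float, float, float], ...]
    halo: tuple[tuple[float, float, float], ...]
    noise_sd: float = 2.0
    crystalline_fraction: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        for c, w, a in self.peaks:
            if not (CRYSTALLINITY_RANGE_DEG[0] < c < CRYSTALLINITY_RANGE_DEG[1]):
                raise ValueError(f"peak position {c}° outside (10°, 45°)")
            if w <= 0 or a < 0:
                raise ValueError("peak FWHM must be positive and area non-negative")
        if self.crystalline_fraction is None:
            object.__setattr__(self, "crystalline_fraction", self.recompute_fraction())
        if not 0.0 <= self.crystalline_fraction <= 1.0:
            raise ValueError("crystalline_fraction must lie in [0, 1]")

    def peak_intensity(self, twotheta_deg: np.ndarray) -> np.ndarray:
        x = np.asarray(twotheta_deg, float)
        y = np.zeros_like(x)
        for center, fwhm, area in self.peaks:
            sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
            y += area / (sigma * math.sqrt(2 * math.pi)) * np.exp(
                -0.5 * ((x - center) / sigma) ** 2
            )
        return y

    def background_intensity(self, twotheta_deg: np.ndarray) -> np.ndarray:
        x = np.asarray(twotheta_deg, float)
        y = np.zeros_like(x)
        for center, sigma, amp in self.halo:
            y += amp * np.exp(-0.5 * ((x - center) / sigma) ** 2)
        return y

    def recompute_fraction(self, n_grid: int = 20001) -> float:
        """Crystalline area fraction from the noiseless components by
        quadrature over [10°, 45°]."""
        x = np.linspace(*CRYSTALLINITY_RANGE_DEG, n_grid)
        peak_area = float(np.trapezoid(self.peak_intensity(x), x))
        bg_area = float(np.trapezoid(self.background_intensity(x), x))
        total = peak_area + bg_area
        return peak_area / total if total > 0 else 0.0


#: Default cellulose-like reflection set: (center 2θ°, FWHM 2θ°, relative area).
DEFAULT_PATTERN_PEAKS: tuple[tuple[float, float, float], ...] = (
    (14.5, 1.3, 1.0),
    (16.8, 1.4, 1.1),
    (22.7, 1.2, 3.0),
    (34.6, 1.6, 0.5),
)


def pattern_with_fraction(
    crystalline_fraction: float,
    peaks: tuple[tuple[float, float, float], ...] = DEFAULT_PATTERN_PEAKS,
    intensity_scale: float = 60.0,
    noise_sd: float = 2.0,
) -> GroundTruthPattern:
    """Build a pattern whose amorphous halo is scaled so that the peaks carry
    exactly `crystalline_fraction` of the [10°, 45°] area."""
    if not 0.0 <= crystalline_fraction <= 1.0:
        raise ValueError("crystalline_fraction must lie in [0, 1]")
    scaled_peaks = tuple((c, w, a * intensity_scale) for c, w, a in peaks)
    halo_shape = ((20.5, 7.0, 1.0), (35.0, 9.0, 0.35))
    x = np.linspace(*CRYSTALLINITY_RANGE_DEG, 20001)
    probe = GroundTruthPattern(scaled_peaks, halo_shape, noise_sd=0.0, crystalline_fraction=1.0)
    peak_area = float(np.trapezoid(probe.peak_intensity(x), x))
    halo_area_unit = float(np.trapezoid(probe.background_intensity(x), x))
    if crystalline_fraction == 0.0:
        scaled_peaks = ()
        halo_scale = intensity_scale  # arbitrary positive halo
    elif crystalline_fraction == 1.0:
        halo_scale = 0.0
    else:
        target_bg = peak_area * (1.0 - crystalline_fraction) / crystalline_fraction
        halo_scale = target_bg / halo_area_unit
    halo = tuple((c, s, a * halo_scale) for c, s, a in halo_shape)
    return GroundTruthPattern(scaled_peaks, halo, noise_sd=noise_sd)


def gen_diffractogram(
    truth: GroundTruthPattern,
    grid_deg: np.ndarray | None = None,
    seed: int = 0,
) -> Diffractogram1D:
    """Noisy 1D diffractogram: Σ peaks + halo + Gaussian noise on `grid_deg`
    (default 5°–50° at 0.05° spacing, covering the [10°, 45°] window)."""
    if grid_deg is None:
        grid_deg = np.arange(5.0, 50.0, 0.05)
    grid_deg = np.asarray(grid_deg, float)
    if grid_deg[0] > CRYSTALLINITY_RANGE_DEG[0] or grid_deg[-1] < CRYSTALLINITY_RANGE_DEG[1]:
        raise ValueError("grid must cover at least [10°, 45°]")
    intensity = truth.peak_intensity(grid_deg) + truth.background_intensity(grid_deg)
    if truth.noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, truth.noise_sd, intensity.shape)
    return Diffractogram1D(grid_deg, intensity)


def gen_detector_image(
    pattern: Diffractogram1D,
    geometry: DetectorGeometry | None = None,
    seed: int = 0,
    shape: tuple[int, int] = (1344, 1344),
    slit_rows: tuple[int, int] | None = None,
    poisson_noise: bool = True,
    floor: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Isotropic 2D detector frame realizing a 1D pattern.

    Each pixel draws its expected count from the pattern interpolated at the
    pixel's 2θ (plus a small positive floor so Poisson statistics are
    defined everywhere). Returns (frame, mask); the mask flags an optional
    horizontal slit band of dead rows (True = invalid).
    """
    if geometry is None:
        geometry = DetectorGeometry()
    tth = geometry.twotheta_deg_of(shape)
    corner_max = float(tth.max())
    if pattern.twotheta_deg[-1] > corner_max + 1e-9:
        raise GeometryError(
            f"pattern extends to {pattern.twotheta_deg[-1]:.1f}° but the detector "
            f"accepts only {corner_max:.1f}°"
        )
    expected = np.interp(tth, pattern.twotheta_deg, np.clip(pattern.intensity, 0.0, None))
    expected = expected + floor
    rng = np.random.default_rng(seed)
    frame = rng.poisson(expected).astype(float) if poisson_noise else expected
    mask = np.zeros(shape, bool)
    if slit_rows is not None:
        r0, r1 = slit_rows
        mask[r0:r1, :] = True
        frame[mask] = 0.0
    return frame, mask


# --------------------------------------------------------------------------
# mechanics
# --------------------------------------------------------------------------

def gen_tensile_curve(
    modulus_MPa: float = 10.0,
    strength_MPa: float = 1.5,
    toe_strain: float = 0.02,
    noise_sd_MPa: float = 0.0,
    seed: int = 0,
    geom: DogboneGeometry | None = None,
    n_points: int = 600,
    n_post_rupture: int = 5,
) -> dict:
    """Raw displacement/force tensile record with known modulus and strength.

    The stress law is a quadratic toe (slope rising from 0 to the modulus at
    `toe_strain`), then a linear branch of slope `modulus_MPa`, with an
    abrupt rupture when the stress reaches `strength_MPa`. Returns a dict
    with displacement_mm, force_N, the geometry and the noiseless truth
    (including the toe-free stress oracle on the same strain grid).
    """
    if modulus_MPa <= 0 or strength_MPa <= 0:
        raise ValueError("modulus and strength must be positive")
    if geom is None:
        geom = DogboneGeometry(thickness_mm=0.5)
    rupture_strain = strength_MPa / modulus_MPa + toe_strain / 2.0
    strain = np.linspace(0.0, rupture_strain, n_points)
    stress = np.where(
        strain < toe_strain,
        modulus_MPa * strain**2 / (2.0 * toe_strain) if toe_strain > 0 else modulus_MPa * strain,
        modulus_MPa * (strain - toe_strain / 2.0),
    )
    if toe_strain == 0:
        stress = modulus_MPa * strain
    # abrupt rupture tail
    d_strain = strain[1] - strain[0] if n_points > 1 else 1e-4
    tail_strain = strain[-1] + d_strain * np.arange(1, n_post_rupture + 1)
    tail_stress = np.full(n_post_rupture, 0.01 * strength_MPa)
    full_strain = np.concatenate([strain, tail_strain])
    full_stress = np.concatenate([stress, tail_stress])
    if noise_sd_MPa > 0:
        rng = np.random.default_rng(seed)
        full_stress = full_stress + rng.normal(0.0, noise_sd_MPa, full_stress.shape)
    displacement = full_strain * geom.gauge_length_mm
    force = full_stress * geom.cross_section_mm2
    return {
        "displacement_mm": displacement,
        "force_N": force,
        "geometry": geom,
        "truth": {
            "modulus_MPa": modulus_MPa,
            "strength_MPa": strength_MPa,
            "toe_strain": toe_strain,
            "rupture_strain": rupture_strain,
            "strain": full_strain,
            "stress_toe_free_MPa": np.concatenate(
                [modulus_MPa * strain, np.full(n_post_rupture, 0.01 * strength_MPa)]
            ),
        },
    }


# --------------------------------------------------------------------------
# pellicle photographs
# --------------------------------------------------------------------------

def gen_pellicle_photo(
    radius_mm: float = 20.0,
    height_mm: float = 5.0,
    scale_mm_per_px: float = 0.1,
    seed: int = 0,
    foreground: float = 200.0,
    background: float = 30.0,
    noise_sd: float = 8.0,
    blur_px: float = 0.8,
) -> tuple[np.ndarray, dict]:
    """Side-view photograph of a pellicle: bright 2r × h rectangle on a dark
    background with mild blur and Gaussian noise. Returns (image, truth)."""
    if min(radius_mm, height_mm, scale_mm_per_px) <= 0:
        raise ValueError("all geometry inputs must be positive")
    w_px = 2.0 * radius_mm / scale_mm_per_px
    h_px = height_mm / scale_mm_per_px
    W = int(round(w_px * 1.4)) + 8
    H = int(round(h_px * 2.0)) + 8
    img = np.full((H, W), background)
    # sub-pixel offset: a real photograph never aligns to the pixel grid,
    # and exact alignment makes every edge pixel ambiguously half-covered
    x0 = (W - w_px) / 2.0 + 0.37
    y0 = (H - h_px) / 2.0 + 0.37
    # anti-aliased rectangle via pixel-coverage fractions at the edges
    xs = np.clip(np.minimum(np.arange(W) + 0.5, x0 + w_px) - np.maximum(np.arange(W) - 0.5, x0), 0, 1)
    ys = np.clip(np.minimum(np.arange(H) + 0.5, y0 + h_px) - np.maximum(np.arange(H) - 0.5, y0), 0, 1)
    coverage = ys[:, None] * xs[None, :]
    img = img + (foreground - background) * coverage
    if blur_px > 0:
        img = scipy.ndimage.gaussian_filter(img, blur_px)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)
    truth = {
        "radius_mm": radius_mm,
        "height_mm": height_mm,
        "area_mm2": 2.0 * radius_mm * height_mm,
        "scale_mm_per_px": scale_mm_per_px,
        "noiseless_mask_area_mm2": float(coverage.sum()) * scale_mm_per_px**2,
    }
    return img, truth


# --------------------------------------------------------------------------
# export helpers
# --------------------------------------------------------------------------

def save_truth_json(truth, path: str | Path) -> None:
    """Write a ground-truth record as a JSON sidecar file."""
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if hasattr(o, "__dataclass_fields__"):
            return asdict(o)
        if o == math.inf:
            return "inf"
        raise TypeError(f"cannot serialize {type(o)}")

    record = asdict(truth) if hasattr(truth, "__dataclass_fields__") else truth
    Path(path).write_text(json.dumps(record, default=_default, indent=2))
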