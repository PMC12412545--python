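"""Independent brute-force oracles used by the tests.

These deliberately re-derive quantities from first principles (direct scans,
textbook definitions, analytic formulas) so they share no code with the
implementation paths they check.
"""

from __future__ import annotations

import numpy as np


def brute_force_peaks(y: np.ndarray) -> list[int]:
    """Strict interior local maxima by direct comparison."""
    return [i for i in range(1, len(y) - 1) if y[i - 1] < y[i] > y[i + 1]]


def brute_force_prominence(y: np.ndarray, i: int) -> tuple[float, float]:
    """Topographic prominence of peak i and its base level.

    Walk outward on each side until terrain higher than the peak (or the
    border); the side minima bound the peak, and the prominence is the height
    above the higher of the two.
    """
    n = len(y)
    lmin = y[i]
    j = i - 1
    while j >= 0 and y[j] <= y[i]:
        lmin = min(lmin, y[j])
        j -= 1
    rmin = y[i]
    j = i + 1
    while j < n and y[j] <= y[i]:
        rmin = min(rmin, y[j])
        j += 1
    base = max(lmin, rmin)
    return y[i] - base, base


def brute_force_half_crossings(y: np.ndarray, i: int, prom: float) -> tuple[float, float]:
    """Linear-interpolated crossings at half prominence below the peak."""
    eval_h = y[i] - 0.5 * prom
    j = i
    while j > 0 and y[j - 1] > eval_h:
        j -= 1
    if j > 0:
        left = (j - 1) + (eval_h - y[j - 1]) / (y[j] - y[j - 1])
    else:
        left = 0.0
    j = i
    n = len(y)
    while j < n - 1 and y[j + 1] > eval_h:
        j += 1
    if j < n - 1:
        right = j + (y[j] - eval_h) / (y[j] - y[j + 1])
    else:
        right = float(n - 1)
    return left, right


def brute_force_filtered_positions(
    y: np.ndarray,
    step_nm: float,
    min_fwhm_nm: float = 100.0,
    min_spacing_nm: float = 100.0,
) -> list[int]:
    """The three retention filters applied by exhaustive enumeration.

    Returns the sample indices of the retained peaks: FWHM cut, then greedy
    spacing cut (higher prominence wins), then the ≥-median prominence cut.
    """
    peaks = brute_force_peaks(y)
    info = []
    for i in peaks:
        prom, _ = brute_force_prominence(y, i)
        left, right = brute_force_half_crossings(y, i, prom)
        info.append({"i": i, "prom": prom, "fwhm": (right - left) * step_nm})
    info = [p for p in info if p["fwhm"] >= min_fwhm_nm]
    accepted: list[dict] = []
    for p in sorted(info, key=lambda p: -p["prom"]):
        if all(abs(p["i"] - q["i"]) * step_nm >= min_spacing_nm for q in accepted):
            accepted.append(p)
    if not accepted:
        return []
    med = float(np.median([p["prom"] for p in accepted]))
    return sorted(p["i"] for p in accepted if p["prom"] >= med)


def gaussian_radiality_score(
    center: tuple[float, float],
    sigma: float,
    point: tuple[float, float],
    ring_radius: float,
    n_axes: int,
) -> float:
    """Radiality of an analytic Gaussian emitter, from its exact gradient field.

    For intensity I = exp(-((x-x0)² + (y-y0)²)/(2σ²)), the gradient at any
    sample points exactly toward the emitter center, so the convergence score
    can be evaluated without any image or interpolation.
    """
    cy, cx = point
    y0, x0 = center
    total = 0.0
    for k in range(n_axes):
        a = 2.0 * np.pi * k / n_axes
        py, px = cy + ring_radius * np.sin(a), cx + ring_radius * np.cos(a)
        gy = -(py - y0)  # ∝ exact Gaussian gradient direction
        gx = -(px - x0)
        gnorm = np.hypot(gx, gy)
        if gnorm < 1e-12:
            continue
        vy, vx = cy - py, cx - px
        d = abs(gy * vx - gx * vy) / gnorm
        sign = 1.0 if gx * vx + gy * vy > 0 else -1.0
        total += sign * max(0.0, 1.0 - d / ring_radius) ** 2
    return max(0.0, total / n_axes)


def fwhm_of_profile(x: np.ndarray, y: np.ndarray) -> float:
    """FWHM of a single-peak profile by direct half-max crossing scan."""
    i = int(np.argmax(y))
    half = y[i] / 2.0
    j = i
    while j > 0 and y[j - 1] > half:
        j -= 1
    left = x[j - 1] + (half - y[j - 1]) / (y[j] - y[j - 1]) * (x[j] - x[j - 1]) if j > 0 else x[0]
    j = i
    while j < len(y) - 1 and y[j + 1] > half:
        j += 1
    right = (
        x[j] + (y[j] - half) / (y[j] - y[j + 1]) * (x[j + 1] - x[j]) if j < len(y) - 1 else x[-1]
    )
    return float(right - left)
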