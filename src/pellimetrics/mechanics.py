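"""Engineering stress–strain analysis of wet pellicle dogbone tensile tests.

Raw crosshead displacement/force records are converted to engineering
stress–strain using the dogbone gauge geometry. Curves are shifted so that
they start at the first sample reaching a small onset force (2.5 mN), which
removes the slack/toe offset of clamped wet films. The elastic modulus is the
least-squares slope over the window between 60% and 80% of the strain at
maximum stress; the tensile strength is the maximum engineering stress before
rupture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

ONSET_FORCE_N = 2.5e-3  # 2.5 mN


class OnsetError(ValueError):
    """Raised when no sample reaches the onset force."""


class WindowError(ValueError):
    """Raised when the modulus window contains too few samples."""


@dataclass(frozen=True)
class DogboneGeometry:
    """Tensile specimen geometry: gauge width, grip spacing and thickness (mm)."""

    width_mm: float = 2.0
    gauge_length_mm: float = 20.0
    thickness_mm: float = 1.0

    def __post_init__(self) -> None:
        if min(self.width_mm, self.gauge_length_mm, self.thickness_mm) <= 0:
            raise ValueError("all geometry dimensions must be positive")

    @property
    def cross_section_mm2(self) -> float:
        return self.width_mm * self.thickness_mm


@dataclass
class TensileCurve:
    """Engineering stress–strain curve with rupture bookkeeping.

    ``rupture_index`` is the index of the first post-rupture sample, or None
    if the record ends without a detected rupture (test stopped early).
    Stress maxima are evaluated over samples before rupture only.
    """

    strain: np.ndarray
    stress_MPa: np.ndarray
    onset_shift_applied: bool = True
    rupture_index: int | None = None
    _max_idx: int = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress_MPa = np.asarray(self.stress_MPa, dtype=float)
        if self.strain.shape != self.stress_MPa.shape or self.strain.ndim != 1:
            raise ValueError("strain and stress must be matching 1D arrays")
        if not np.all(np.isfinite(self.stress_MPa)):
            raise ValueError("stress contains non-finite values")
        if np.any(np.diff(self.strain) < 0):
            raise ValueError("strain must be non-decreasing")
        stop = self.rupture_index if self.rupture_index is not None else len(self.strain)
        self._max_idx = int(np.argmax(self.stress_MPa[:stop]))

    @property
    def max_stress_MPa(self) -> float:
        return float(self.stress_MPa[self._max_idx])

    @property
    def strain_at_max_stress(self) -> float:
        return float(self.strain[self._max_idx])


def _detect_rupture(stress: np.ndarray, drop_fraction: float = 0.5, lookback: int = 3) -> int | None:
    """First index where stress falls by ≥ drop_fraction of the running
    maximum within `lookback` samples. Drops in the near-zero noise floor
    (running maximum below 10% of the record's peak) are ignored. None if no
    such drop occurs."""
    running_max = np.maximum.accumulate(stress)
    floor = 0.1 * float(stress.max())
    for i in range(1, len(stress)):
        ref = running_max[max(0, i - lookback)]
        if ref > floor and stress[i] <= (1.0 - drop_fraction) * ref:
            return i
    return None


def load_curve(
    displacement_mm: np.ndarray,
    force_N: np.ndarray,
    geom: DogboneGeometry,
    onset_force_N: float = ONSET_FORCE_N,
) -> TensileCurve:
    """Convert a raw displacement/force record to engineering stress–strain.

    The curve is cropped to start at the first sample with force ≥
    ``onset_force_N`` and the displacement is re-zeroed there. Strain is
    Δdisplacement over the starting grip spacing; stress is force over the
    initial cross-section (N/mm² = MPa).
    """
    displacement_mm = np.asarray(displacement_mm, dtype=float)
    force_N = np.asarray(force_N, dtype=float)
    if displacement_mm.shape != force_N.shape or displacement_mm.ndim != 1:
        raise ValueError("displacement and force must be matching 1D arrays")
    if np.any(np.diff(displacement_mm) < 0):
        raise ValueError("displacement must be monotone non-decreasing")
    reached = np.nonzero(force_N >= onset_force_N)[0]
    if reached.size == 0:
        raise OnsetError(
            f"no sample reaches the {onset_force_N * 1e3:.1f} mN onset force; curve rejected"
        )
    i0 = int(reached[0])
    disp = displacement_mm[i0:] - displacement_mm[i0]
    force = force_N[i0:]
    strain = disp / geom.gauge_length_mm
    stress = force / geom.cross_section_mm2
    rupture = _detect_rupture(stress)
    if rupture is None:
        warnings.warn("no rupture detected; test may have stopped early", stacklevel=2)
    return TensileCurve(strain=strain, stress_MPa=stress, rupture_index=rupture)


def tensile_modulus(
    curve: TensileCurve, window: tuple[float, float] = (0.6, 0.8), min_samples: int = 5
) -> float:
    """Elastic modulus (MPa): least-squares slope of stress vs strain over the
    window [0.6·ε_max, 0.8·ε_max], where ε_max is the strain at maximum stress."""
    eps_max = curve.strain_at_max_stress
    lo, hi = window[0] * eps_max, window[1] * eps_max
    stop = curve.rupture_index if curve.rupture_index is not None else len(curve.strain)
    mask = (curve.strain[:stop] >= lo) & (curve.strain[:stop] <= hi)
    n = int(mask.sum())
    if n < min_samples:
        raise WindowError(
            f"modulus window [{lo:.4g}, {hi:.4g}] contains {n} samples "
            f"(minimum {min_samples})"
        )
    slope, _ = np.polyfit(curve.strain[:stop][mask], curve.stress_MPa[:stop][mask], 1)
    return float(slope)


def tensile_strength(curve: TensileCurve) -> dict:
    """Tensile strength (MPa) as the maximum engineering stress before rupture.

    Returns both the maximum stress (headline value) and the stress at the
    last retained sample before rupture; the two coincide for an abrupt
    rupture. ``ruptured`` is False when the record ends without a detected
    rupture.
    """
    ruptured = curve.rupture_index is not None
    last = (curve.rupture_index - 1) if ruptured else (len(curve.stress_MPa) - 1)
    return {
        "strength_MPa": curve.max_stress_MPa,
        "stress_at_rupture_MPa": float(curve.stress_MPa[last]),
        "strain_at_max_stress": curve.strain_at_max_stress,
        "ruptured": ruptured,
    }
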