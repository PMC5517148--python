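"""Guidance-cue gradients on the retina and on the target field.

The target field is a rectangular array of unit squares carrying ligand
(``L_T``, ephrin-A) and receptor (``R_T``, EphA) densities along its x-axis.
Retinal origins carry counter-graded sensor baselines (``L_F0``, ``R_F0``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "GradientSpec",
    "TargetField",
    "build_target_field",
    "retinal_sensor_levels",
]

_SHAPES = ("exponential_counter", "step", "uniform", "none")


@dataclass(frozen=True)
class GradientSpec:
    """Profile of one cue channel along a normalized [0, 1] axis.

    Parameters
    ----------
    shape
        One of ``exponential_counter`` (strictly monotone exponential),
        ``step`` (piecewise-constant plateaus given by ``segments``),
        ``uniform`` (constant ``level`` everywhere) or ``none`` (zero).
    steepness
        Exponent scale gamma of the exponential profile.
    level
        Amplitude: plateau value for step/uniform, prefactor for the
        exponential.
    rising
        Slope sign of the exponential along the axis.  The two channels of a
        counter-gradient use opposite signs.
    segments
        ``(x0, x1, level)`` triples on the normalized axis, half-open
        ``[x0, x1)``; outside all segments the value is 0.
    """

    shape: str = "none"
    steepness: float = 2.0
    level: float = 1.0
    rising: bool = True
    segments: Tuple[Tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.shape not in _SHAPES:
            raise ValueError(f"unknown gradient shape {self.shape!r}")
        if self.steepness <= 0:
            raise ValueError("steepness must be positive")
        if self.level < 0:
            raise ValueError("level must be non-negative")
        if self.shape == "step":
            segs = sorted(self.segments, key=lambda s: s[0])
            for (a0, a1, lev) in segs:
                if not (a0 < a1):
                    raise ValueError(f"degenerate segment interval ({a0}, {a1})")
                if lev < 0:
                    raise ValueError("segment level must be non-negative")
            for (_, a1, _), (b0, _, _) in zip(segs, segs[1:]):
                if b0 < a1:
                    raise ValueError("step segments overlap")

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        """Cue value at normalized axis positions ``x``."""
        x = np.asarray(x, dtype=float)
        if self.shape == "none":
            return np.zeros_like(x)
        if self.shape == "uniform":
            return np.full_like(x, self.level)
        if self.shape == "exponential_counter":
            sign = 1.0 if self.rising else -1.0
            return self.level * np.exp(sign * self.steepness * (x - 0.5))
        out = np.zeros_like(x)
        for (x0, x1, lev) in self.segments:
            out = np.where((x >= x0) & (x < x1), lev, out)
        return out


@dataclass
class TargetField:
    """Rectangular grid of unit squares carrying the target cues.

    ``L_T``/``R_T`` are (height, width) arrays of non-negative densities.
    Optional resident arrays hold the fiber-derived cue contribution of a
    pre-existing, static innervation (remnant scenarios).
    """

    width: int
    height: int
    L_T: np.ndarray
    R_T: np.ndarray
    resident_L_f: Optional[np.ndarray] = None
    resident_R_f: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        for name in ("L_T", "R_T"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (self.height, self.width):
                raise ValueError(
                    f"{name} has shape {arr.shape}, expected "
                    f"{(self.height, self.width)}"
                )
            if np.any(arr < 0):
                raise ValueError(f"{name} contains negative cue values")
            setattr(self, name, arr)
        for name in ("resident_L_f", "resident_R_f"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != (self.height, self.width):
                    raise ValueError(f"{name} has wrong shape {arr.shape}")
                setattr(self, name, arr)

    @property
    def cue_free_mask(self) -> np.ndarray:
        """Boolean (height, width) mask of squares without any cue."""
        total = self.L_T + self.R_T
        if self.resident_L_f is not None:
            total = total + self.resident_L_f
        if self.resident_R_f is not None:
            total = total + self.resident_R_f
        return total <= 0.0


def build_target_field(
    width: int,
    height: int,
    L_spec: GradientSpec,
    R_spec: GradientSpec,
) -> TargetField:
    """Evaluate cue specs at every unit square's x-center.

    Cues vary along x only and are constant along y.  For the counter-graded
    tectal field the convention is ephrin-A (``L_T``) low anterior (x = 0),
    high posterior, and EphA (``R_T``) the reverse.
    """
    if width < 1 or height < 1:
        raise ValueError("field dimensions must be >= 1")
    x_norm = (np.arange(width) + 0.5) / width
    L_row = L_spec.evaluate(x_norm)
    R_row = R_spec.evaluate(x_norm)
    L = np.tile(L_row, (height, 1))
    R = np.tile(R_row, (height, 1))
    return TargetField(width=width, height=height, L_T=L, R_T=R)


#: Default retinal counter-gradient (gamma = 3, unit amplitude).
DEFAULT_RETINAL_SPEC = GradientSpec(shape="exponential_counter", steepness=3.0)


def retinal_sensor_levels(
    u: float,
    retinal_spec: GradientSpec = DEFAULT_RETINAL_SPEC,
) -> Tuple[float, float]:
    """Baseline sensor amounts (R_F0, L_F0) for a retinal origin ``u``.

    ``u`` runs naso-temporal, 0 = nasal, 1 = temporal.  The receptor
    baseline increases with ``u`` (temporal high) and the ligand baseline
    decreases, as exp(+/- gamma (u - 1/2)).
    """
    u = float(u)
    if not (0.0 <= u <= 1.0):
        raise ValueError(f"retinal origin u={u} outside [0, 1]")
    gamma = retinal_spec.steepness
    amp = retinal_spec.level
    R_F0 = amp * np.exp(gamma * (u - 0.5))
    L_F0 = amp * np.exp(-gamma * (u - 0.5))
    return float(R_F0), float(L_F0)
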