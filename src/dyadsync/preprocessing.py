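"""Transforms, smoothing and noise injection applied before detection.

The pipeline order is fixed: transform -> smooth -> add noise.  All
transforms are monotone non-decreasing, so a window with zero variance
stays zero-variance through them — which is exactly why a small Gaussian
noise floor (M = 0, SD = 0.1) is injected last: it makes every local
correlation/regression well defined even over motionless stretches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.interpolate import make_smoothing_spline

from .motion_energy import MotionEnergySeries, roi_ratio

__all__ = [
    "TransformSpec",
    "SmoothingSpec",
    "NoiseSpec",
    "anscombe",
    "log1p_transform",
    "size_standardize",
    "smooth",
    "add_noise",
    "apply_transform",
]

TRANSFORM_KINDS = ("raw", "size_standardization", "log1p", "anscombe")
SMOOTHING_KINDS = ("none", "slight", "high")

#: roughness-tradeoff parameter p per smoothing level: the spline minimizes
#: p * misfit + (1 - p) * roughness, so p -> 1 interpolates and p -> 0
#: approaches a straight line.  "slight" = .900 is mild, "high" = .005 heavy.
SPLINE_P = {"slight": 0.900, "high": 0.005}

_MIN_SPLINE_LEN = 5


@dataclass(frozen=True)
class TransformSpec:
    kind: str = "raw"

    def __post_init__(self) -> None:
        if self.kind not in TRANSFORM_KINDS:
            raise ValueError(f"unknown transform {self.kind!r}; one of {TRANSFORM_KINDS}")


@dataclass(frozen=True)
class SmoothingSpec:
    kind: str = "none"
    spline_p: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in SMOOTHING_KINDS:
            raise ValueError(f"unknown smoothing {self.kind!r}; one of {SMOOTHING_KINDS}")
        if self.spline_p is None and self.kind in SPLINE_P:
            object.__setattr__(self, "spline_p", SPLINE_P[self.kind])
        if self.spline_p is not None and not (0 < self.spline_p <= 1):
            raise ValueError("spline_p must lie in (0, 1]")


@dataclass(frozen=True)
class NoiseSpec:
    mean: float = 0.0
    sd: float = 0.1
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("noise sd must be >= 0")


def anscombe(values: np.ndarray) -> np.ndarray:
    """Anscombe transform 2*sqrt(x + 3/8); variance-stabilizing for counts."""
    x = np.asarray(values, dtype=float)
    if (x < 0).any():
        raise ValueError("anscombe requires non-negative input")
    return 2.0 * np.sqrt(x + 0.375)


def log1p_transform(values: np.ndarray) -> np.ndarray:
    """Box-Cox with lambda = 0 on x + 1, i.e. natural log(x + 1)."""
    x = np.asarray(values, dtype=float)
    if (x < -1).any():
        raise ValueError("log1p_transform requires values >= -1")
    return np.log1p(x)


def size_standardize(
    a: MotionEnergySeries, b: MotionEnergySeries
) -> tuple[MotionEnergySeries, MotionEnergySeries]:
    """Rescale the series of the person with the smaller ROI.

    The ratio larger/smaller ROI area multiplies every element of the
    smaller-ROI person's series; the other series is returned unchanged.
    Equal areas leave both unchanged.
    """
    if a.roi_area is None or b.roi_area is None:
        raise ValueError("size standardization needs roi_area on both series")
    ratio, smaller = roi_ratio(a.roi_area, b.roi_area)
    if smaller == "a":
        return a.with_values(a.values * ratio), b
    if smaller == "b":
        return a, b.with_values(b.values * ratio)
    return a, b


def smooth(values: np.ndarray, spec: SmoothingSpec) -> np.ndarray:
    """Cubic smoothing spline over the frame index, or identity for 'none'.

    Fits the natural cubic smoothing spline minimizing
    ``p * sum (y - f)^2 + (1 - p) * integral f''^2`` and returns the fitted
    values at every frame.  Because only curvature is penalized, exactly
    linear series are reproduced at any p.  Smoothed values may be negative;
    they are passed through unaltered (transforms run before smoothing).
    """
    x = np.asarray(values, dtype=float)
    if spec.kind == "none":
        return x.copy()
    if x.size < _MIN_SPLINE_LEN:
        raise ValueError(
            f"series of length {x.size} too short for spline smoothing "
            f"(minimum {_MIN_SPLINE_LEN})"
        )
    p = spec.spline_p
    lam = (1.0 - p) / p  # Reinsch penalty equivalent of the p convention
    t = np.arange(x.size, dtype=float)
    return make_smoothing_spline(t, x, lam=lam)(t)


def add_noise(values: np.ndarray, spec: NoiseSpec) -> np.ndarray:
    """Add i.i.d. Gaussian(mean, sd) noise from a generator seeded by spec.seed."""
    x = np.asarray(values, dtype=float)
    if spec.sd == 0 and spec.mean == 0:
        return x.copy()
    rng = np.random.default_rng(spec.seed)
    return x + rng.normal(spec.mean, spec.sd, size=x.shape)


def apply_transform(
    a: MotionEnergySeries, b: MotionEnergySeries, spec: TransformSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one grid transform to a dyad, returning plain value arrays."""
    if spec.kind == "raw":
        return a.values.copy(), b.values.copy()
    if spec.kind == "size_standardization":
        a2, b2 = size_standardize(a, b)
        return a2.values, b2.values
    if spec.kind == "log1p":
        return log1p_transform(a.values), log1p_transform(b.values)
    if spec.kind == "anscombe":
        return anscombe(a.values), anscombe(b.values)
    raise ValueError(f"unknown transform {spec.kind!r}")
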