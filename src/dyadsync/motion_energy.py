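"""Motion-energy extraction from grayscale frame stacks.

Motion energy analysis (MEA) reduces a video to one number per frame and
person: the count of pixels inside that person's region of interest (ROI)
whose intensity changed more than a threshold between consecutive frames.
The resulting motion energy time series (METS) is the raw material for all
downstream synchrony detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import numpy as np

__all__ = [
    "FrameStack",
    "RegionOfInterest",
    "MotionEnergySeries",
    "compute_motion_energy",
    "roi_ratio",
]

DEFAULT_DIFF_THRESHOLD = 10.0  # on a 0-255 intensity scale


@dataclass(frozen=True)
class RegionOfInterest:
    """Axis-aligned rectangle, 0-based half-open index ranges.

    Parameters
    ----------
    rows, cols : (int, int)
        Half-open ``[lo, hi)`` index ranges into the frame grid.
    """

    rows: tuple[int, int]
    cols: tuple[int, int]

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("rows", self.rows), ("cols", self.cols)):
            if not (0 <= lo < hi):
                raise ValueError(
                    f"ROI {name} range {(lo, hi)} must satisfy 0 <= lo < hi"
                )

    @property
    def area(self) -> int:
        """Pixel count of the rectangle."""
        return (self.rows[1] - self.rows[0]) * (self.cols[1] - self.cols[0])

    def check_within(self, frame_shape: tuple[int, int]) -> None:
        if self.rows[1] > frame_shape[0]:
            raise ValueError(
                f"ROI row range {self.rows} exceeds frame height {frame_shape[0]}"
            )
        if self.cols[1] > frame_shape[1]:
            raise ValueError(
                f"ROI column range {self.cols} exceeds frame width {frame_shape[1]}"
            )


@dataclass
class FrameStack:
    """An ordered stack of equal-shape grayscale frames."""

    frames: np.ndarray  # (n_frames, height, width)
    fps: float = 25.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3-D (n_frames, h, w) array")
        if self.frames.shape[0] < 2:
            raise ValueError("a frame stack needs at least 2 frames")
        if not np.isfinite(self.frames).all():
            raise ValueError("frame intensities must be finite")
        if (self.frames < 0).any():
            raise ValueError("frame intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @classmethod
    def from_tiff(cls, path: str | Path, fps: float = 25.0) -> "FrameStack":
        """Read a multi-page TIFF as a frame stack."""
        import tifffile

        return cls(frames=tifffile.imread(str(path)), fps=fps)

    @classmethod
    def from_directory(
        cls, directory: str | Path, pattern: str = "*", fps: float = 25.0
    ) -> "FrameStack":
        """Read per-frame image files (sorted by name) as a stack."""
        import tifffile

        paths = sorted(Path(directory).glob(pattern))
        if len(paths) < 2:
            raise ValueError(f"need at least 2 frame files in {directory}")
        frames = np.stack([tifffile.imread(str(p)) for p in paths])
        return cls(frames=frames, fps=fps)


@dataclass
class MotionEnergySeries:
    """Per-frame movement magnitude of one person.

    ``values[t]`` is derived from frames t-1 and t; frame 0 has no
    predecessor and is defined as 0.
    """

    values: np.ndarray
    fps: float = 25.0
    roi_area: Optional[int] = None
    person_role: Optional[str] = None  # "patient" | "therapist"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be 1-D")
        if not np.isfinite(self.values).all():
            raise ValueError("motion energy values must be finite")
        if (self.values < 0).any():
            raise ValueError("motion energy values must be non-negative")

    def __len__(self) -> int:
        return self.values.size

    def with_values(self, values: Iterable[float]) -> "MotionEnergySeries":
        """Copy of this series with new values, keeping metadata."""
        return replace(self, values=np.asarray(values, dtype=float))


def compute_motion_energy(
    stack: FrameStack,
    roi: RegionOfInterest,
    diff_threshold: float = DEFAULT_DIFF_THRESHOLD,
    person_role: Optional[str] = None,
) -> MotionEnergySeries:
    """Count ROI pixels whose intensity change exceeds ``diff_threshold``.

    value[t] = #{(i, j) in ROI : |frame_t(i, j) - frame_{t-1}(i, j)| > thr},
    with value[0] = 0.  The count is invariant to a constant intensity
    offset applied to every frame.
    """
    if diff_threshold < 0:
        raise ValueError("diff_threshold must be >= 0")
    roi.check_within(stack.frame_shape)
    sub = stack.frames[:, roi.rows[0] : roi.rows[1], roi.cols[0] : roi.cols[1]]
    changed = np.abs(np.diff(sub, axis=0)) > diff_threshold
    values = np.concatenate([[0.0], changed.sum(axis=(1, 2)).astype(float)])
    return MotionEnergySeries(
        values=values, fps=stack.fps, roi_area=roi.area, person_role=person_role
    )


def roi_ratio(
    roi_a: RegionOfInterest | int, roi_b: RegionOfInterest | int
) -> tuple[float, Optional[str]]:
    """Ratio of the larger ROI area to the smaller, and who is smaller.

    Accepts ROIs or raw pixel areas.  Returns ``(ratio, smaller)`` with
    ``smaller`` in ``{"a", "b", None}`` (None on a tie).  Always >= 1 and
    symmetric in its arguments up to the side label.
    """
    area_a = roi_a.area if isinstance(roi_a, RegionOfInterest) else int(roi_a)
    area_b = roi_b.area if isinstance(roi_b, RegionOfInterest) else int(roi_b)
    if area_a <= 0 or area_b <= 0:
        raise ValueError("ROI areas must be >= 1")
    if area_a == area_b:
        return 1.0, None
    if area_a < area_b:
        return area_b / area_a, "a"
    return area_a / area_b, "b"
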