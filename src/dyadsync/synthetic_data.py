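"""Synthetic dyadic motion-energy sequences with known synchrony ground truth.

The generator emulates motion-energy time series from dyadic interaction
video: zero-inflated, bursty pulse trains at 25 fps.  Each base sequence is
~118 s long and contains one designated interval (mean 145 frames, SD 57.93,
clipped to [26, 282]) in which, for sync pairs, person B's activity is a
noisy, amplitude-rescaled, small-lag copy of person A's movement.  From each
base (naturally *embedded*) pair two further complexity conditions are
derived: *isolated* (everything outside the interval zeroed) and
*artificial* (B replaced by an exact 50-frame-lagged echo of A, or by zeros
for no-sync pairs).

Pulses are raised-cosine envelopes carrying i.i.d. multiplicative gamma
jitter — frame-differencing pixel counts fluctuate strongly frame to frame
in real recordings, and that within-movement innovation is what lets an
autoregressive control (WCLR) still see the echoed signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional

import numpy as np

from .motion_energy import MotionEnergySeries
from ._seeds import derive_seed, rng_for

__all__ = [
    "IntervalSpec",
    "DyadSequence",
    "GeneratorParams",
    "generate_base_pair",
    "make_isolated",
    "make_artificial",
    "make_dataset",
]

CONDITIONS = ("embedded", "isolated", "artificial")
SYNC_LABELS = ("sync", "nosync")


@dataclass(frozen=True)
class IntervalSpec:
    """Half-open frame interval [start, end); the reference MSI."""

    start: int
    end: int
    construction_lag: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("interval requires 0 <= start < end")

    @property
    def duration(self) -> int:
        return self.end - self.start


@dataclass
class DyadSequence:
    """An aligned pair of motion-energy series with ground-truth metadata."""

    id: str
    condition: str
    sync_label: str
    a: MotionEnergySeries  # patient
    b: MotionEnergySeries  # therapist
    reference: Optional[IntervalSpec] = None

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.sync_label not in SYNC_LABELS:
            raise ValueError(f"sync_label must be one of {SYNC_LABELS}")
        if len(self.a) != len(self.b):
            raise ValueError("dyad series must have equal length")
        if self.a.fps != self.b.fps:
            raise ValueError("dyad series must share one frame rate")

    @property
    def n_frames(self) -> int:
        return len(self.a)


@dataclass(frozen=True)
class GeneratorParams:
    """Study conditions of the synthetic validation material.

    Durations and interval statistics follow the source material the
    generator emulates; pulse shape and background rate are the generator's
    own realism choices (see docs/methods.md).
    """

    fps: float = 25.0
    duration_mean_s: float = 118.0
    duration_sd_s: float = 12.94
    duration_min_s: float = 60.0
    msi_mean_frames: float = 145.0
    msi_sd_frames: float = 57.93
    msi_min_frames: int = 26
    msi_max_frames: int = 282
    pulse_width_frames: tuple[int, int] = (10, 60)
    pulse_amp: tuple[float, float] = (5.0, 80.0)
    #: expected background pulses per 1000 frames and person
    background_rate_per_1000: float = 2.0
    #: gamma shape of the multiplicative within-pulse jitter (mean 1)
    jitter_shape: float = 4.0
    roi_base_area: int = 40000
    roi_ratio_range: tuple[float, float] = (1.03, 1.99)
    echo_lag: int = 50
    #: embedded sync: B's copy lag is drawn uniformly from +/- this bound
    embedded_lag_max: int = 37
    embedded_scale: tuple[float, float] = (0.3, 1.5)
    #: reference intervals stay this many frames away from both sequence ends
    edge_margin_frames: int = 150


def _raised_cosine(length: int) -> np.ndarray:
    t = np.arange(length, dtype=float)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * (t + 0.5) / length))


def _jitter(rng: np.random.Generator, length: int, shape: float) -> np.ndarray:
    return rng.gamma(shape, 1.0 / shape, size=length)


def _add_pulse(values: np.ndarray, start: int, width: int, amp: float,
               rng: np.random.Generator, shape: float) -> None:
    end = min(start + width, values.size)
    start = max(start, 0)
    if end <= start:
        return
    env = _raised_cosine(width)[: end - start]
    values[start:end] += amp * env * _jitter(rng, end - start, shape)


def _event_signal(rng: np.random.Generator, duration: int,
                  params: GeneratorParams) -> np.ndarray:
    """Movement burst spanning the whole interval, zero exactly at its ends."""
    env = _raised_cosine(duration)
    modulation = np.full(duration, 0.4)
    n_bumps = max(1, duration // 50)
    for _ in range(n_bumps):
        width = int(rng.integers(params.pulse_width_frames[0],
                                 params.pulse_width_frames[1] + 1))
        center = int(rng.integers(0, duration))
        lo = max(0, center - width // 2)
        hi = min(duration, lo + width)
        if hi > lo:
            modulation[lo:hi] += rng.uniform(0.5, 1.5) * _raised_cosine(hi - lo)
    amp = rng.uniform(*params.pulse_amp)
    sig = env * modulation
    sig *= amp / max(sig.max(), 1e-12)
    return sig * _jitter(rng, duration, params.jitter_shape)


def _background(rng: np.random.Generator, n: int, params: GeneratorParams,
                avoid: Optional[tuple[int, int]] = None) -> np.ndarray:
    values = np.zeros(n)
    n_pulses = rng.poisson(params.background_rate_per_1000 * n / 1000.0)
    for _ in range(n_pulses):
        width = int(rng.integers(params.pulse_width_frames[0],
                                 params.pulse_width_frames[1] + 1))
        start = int(rng.integers(0, max(1, n - width)))
        if avoid is not None and start < avoid[1] and start + width > avoid[0]:
            continue  # keep the designated interval free of background
        amp = rng.uniform(*params.pulse_amp)
        _add_pulse(values, start, width, amp, rng, params.jitter_shape)
    return values


def _shift_forward(values: np.ndarray, lag: int) -> np.ndarray:
    """b[t] = values[t - lag] with zero fill (negative lag shifts backward)."""
    out = np.zeros_like(values)
    n = values.size
    if lag >= 0:
        out[lag:] = values[: n - lag]
    else:
        out[: n + lag] = values[-lag:]
    return out


def generate_base_pair(
    params: GeneratorParams, sync: bool, seed: int
) -> tuple[DyadSequence, IntervalSpec]:
    """One naturally-embedded dyad with its designated (no-)MSI interval.

    Both persons carry sparse background pulse trains; within the reference
    interval person A always moves, and person B either echoes A (sync;
    rescaled, small random lag) or moves independently (nosync).  Output is
    deterministic in (params, sync, seed).
    """
    rng = np.random.default_rng(seed)
    fps = params.fps
    n = int(round(fps * max(params.duration_min_s,
                            rng.normal(params.duration_mean_s, params.duration_sd_s))))
    duration = int(round(np.clip(rng.normal(params.msi_mean_frames, params.msi_sd_frames),
                                 params.msi_min_frames, params.msi_max_frames)))
    margin = params.edge_margin_frames
    hi = n - duration - margin
    if hi <= margin:
        raise ValueError(
            f"interval of {duration} frames does not fit a {n}-frame sequence "
            f"with {margin}-frame margins"
        )
    start = int(rng.integers(margin, hi + 1))
    interval = IntervalSpec(start=start, end=start + duration)

    a_vals = _background(rng, n, params)
    b_vals = _background(rng, n, params, avoid=(start, start + duration))

    event_a = _event_signal(rng, duration, params)
    a_vals[start : start + duration] += event_a

    if sync:
        lag = int(rng.integers(-params.embedded_lag_max, params.embedded_lag_max + 1))
        scale = rng.uniform(*params.embedded_scale)
        echoed = np.zeros(n)
        echoed[start : start + duration] = event_a
        echoed = _shift_forward(echoed, lag) * scale
        # a "noisy copy": B repeats A's movement with its own frame jitter
        echoed *= _jitter(rng, n, params.jitter_shape) ** 0.5
        b_vals += echoed
    else:
        b_vals[start : start + duration] += _event_signal(rng, duration, params)

    ratio = rng.uniform(*params.roi_ratio_range)
    small_first = bool(rng.integers(0, 2))
    area_small = params.roi_base_area
    area_large = int(round(params.roi_base_area * ratio))
    area_a, area_b = (area_small, area_large) if small_first else (area_large, area_small)

    label = "sync" if sync else "nosync"
    dyad = DyadSequence(
        id=f"embedded-{label}-{seed}",
        condition="embedded",
        sync_label=label,
        a=MotionEnergySeries(a_vals, fps=fps, roi_area=area_a, person_role="patient"),
        b=MotionEnergySeries(b_vals, fps=fps, roi_area=area_b, person_role="therapist"),
        reference=interval,
    )
    return dyad, interval


def make_isolated(embedded: DyadSequence) -> DyadSequence:
    """Zero both series outside the reference interval."""
    if embedded.reference is None:
        raise ValueError("make_isolated needs a reference interval")
    ref = embedded.reference
    mask = np.zeros(embedded.n_frames)
    mask[ref.start : ref.end] = 1.0
    return replace(
        embedded,
        id=embedded.id.replace(embedded.condition, "isolated", 1),
        condition="isolated",
        a=embedded.a.with_values(embedded.a.values * mask),
        b=embedded.b.with_values(embedded.b.values * mask),
    )


def make_artificial(isolated: DyadSequence, lag: int = 50) -> DyadSequence:
    """Replace B by an exact lagged echo of A (sync) or by zeros (nosync)."""
    if isolated.condition != "isolated":
        raise ValueError("make_artificial expects an isolated-condition dyad")
    if abs(lag) >= isolated.n_frames:
        raise ValueError("echo lag must be smaller than the sequence length")
    if isolated.sync_label == "sync":
        b_vals = _shift_forward(isolated.a.values, lag)
        reference = replace(isolated.reference, construction_lag=lag)
    else:
        b_vals = np.zeros(isolated.n_frames)
        reference = isolated.reference
    return replace(
        isolated,
        id=isolated.id.replace("isolated", "artificial", 1),
        condition="artificial",
        b=isolated.b.with_values(b_vals),
        reference=reference,
    )


def make_dataset(
    params: GeneratorParams = GeneratorParams(),
    n_sync: int = 10,
    n_nosync: int = 10,
    seed: int = 0,
) -> List[DyadSequence]:
    """The full validation dataset: all three conditions per base pair.

    Defaults give 3 conditions x (10 sync + 10 nosync) = 60 dyads with
    stable ids ``{condition}-{label}-seq{k:02d}``.
    """
    if n_sync < 0 or n_nosync < 0 or n_sync + n_nosync < 1:
        raise ValueError("need at least one base pair")
    dyads: List[DyadSequence] = []
    labels = ["sync"] * n_sync + ["nosync"] * n_nosync
    for k, label in enumerate(labels):
        child_seed = derive_seed(seed, "base-pair", k, label)
        embedded, _ = generate_base_pair(params, sync=(label == "sync"), seed=child_seed)
        isolated = make_isolated(embedded)
        artificial = make_artificial(isolated, lag=params.echo_lag)
        for dyad in (embedded, isolated, artificial):
            dyad.id = f"{dyad.condition}-{label}-seq{k:02d}"
            dyads.append(dyad)
    return dyads
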