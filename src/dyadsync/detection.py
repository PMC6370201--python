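"""Windowed cross-lagged correlation/regression and peak-picking.

The detector slides a window of length W (the bandwidth) along person A's
series and, for every time lag on a symmetric grid, measures the local
association with person B's equally long window.  WCLC uses the squared
Pearson correlation; WCLR regresses B's window on its own one-frame lag
(an autoregressive control against spurious correlation in cyclic series)
and scores the R-squared gained by adding A's window.  Each cell of the
resulting (time x lag) landscape carries a significance flag; contiguous
significant ridges are then chained into movement synchronization
intervals (MSIs) and filtered by an interval-level R-squared cutoff.

Lag sign convention: a positive lag means person B's behavior follows
person A's (B's window starts later).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy import stats

from .motion_energy import MotionEnergySeries
from .preprocessing import NoiseSpec, SmoothingSpec, TransformSpec, add_noise, apply_transform, smooth
from ._seeds import derive_seed

__all__ = [
    "AnalysisConfig",
    "R2Landscape",
    "SyncIntervalRecord",
    "ZeroVarianceError",
    "window_association_wclc",
    "window_association_wclr",
    "compute_landscape",
    "peak_pick",
    "filter_by_cutoff",
    "identify_msi",
]

METHODS = ("WCLC", "WCLR")

#: minimum duration (frames, ~0.5 s at 25 fps) of a reported interval
MIN_MSI_FRAMES = 13

#: chaining tolerance: the per-column best lag may move by at most this many
#: lag-grid steps between consecutive time columns without closing the chain
LAG_CHAIN_TOL_STEPS = 2

_VAR_EPS = 1e-12


class ZeroVarianceError(ValueError):
    """A window had (numerically) zero variance — noise injection missing."""


@dataclass(frozen=True)
class AnalysisConfig:
    """One cell of the factorial configuration grid.

    method, transform, smoothing, bandwidth and r2_cutoff are the varied
    families; max_lag, step, alpha and the noise floor are held fixed.
    """

    method: str = "WCLC"
    transform: TransformSpec = field(default_factory=TransformSpec)
    smoothing: SmoothingSpec = field(default_factory=SmoothingSpec)
    bandwidth: int = 125
    r2_cutoff: float = 0.25
    max_lag: int = 75
    step: int = 2
    alpha: float = 0.05
    noise: NoiseSpec = field(default_factory=NoiseSpec)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.bandwidth < 4:
            raise ValueError("bandwidth must be >= 4")
        if self.max_lag < 0 or self.step < 1:
            raise ValueError("max_lag must be >= 0 and step >= 1")
        if not (0 <= self.r2_cutoff < 1):
            raise ValueError("r2_cutoff must lie in [0, 1)")

    @property
    def config_id(self) -> str:
        return (
            f"{self.method}_{self.bandwidth}_{self.transform.kind}_"
            f"{self.smoothing.kind}_{self.r2_cutoff:g}"
        )


@dataclass
class R2Landscape:
    """m x n grid of squared local associations over (time, lag).

    Cells whose window would overrun either series are NaN with sig False.
    """

    r2: np.ndarray  # (m, n)
    sig: np.ndarray  # (m, n) bool
    time_grid: np.ndarray  # window start frames, every `step` frames
    lag_grid: np.ndarray  # lags in frames, symmetric about 0


@dataclass(frozen=True)
class SyncIntervalRecord:
    """One detected MSI: half-open frame span on A's timeline, plus lag."""

    start: int
    end: int
    lag: float
    mean_r2: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("interval requires start < end")

    @property
    def duration(self) -> int:
        return self.end - self.start


def _pearson_r2_p(a_win: np.ndarray, b_win: np.ndarray) -> tuple[float, float]:
    a = np.asarray(a_win, dtype=float)
    b = np.asarray(b_win, dtype=float)
    if a.size != b.size or a.size < 4:
        raise ValueError("windows must have equal length >= 4")
    for name, x in (("a", a), ("b", b)):
        if np.var(x) <= _VAR_EPS:
            raise ZeroVarianceError(
                f"window of series {name} has zero variance; add noise first"
            )
    w = a.size
    r = float(np.corrcoef(a, b)[0, 1])
    r2 = r * r
    denom = max(1.0 - r2, np.finfo(float).tiny)
    t = abs(r) * np.sqrt((w - 2) / denom)
    p = 2.0 * stats.t.sf(t, df=w - 2)
    return r2, float(p)


def window_association_wclc(a_win: np.ndarray, b_win: np.ndarray) -> tuple[float, float]:
    """Squared Pearson correlation of two windows and its two-sided p-value.

    Squaring makes the measure sign-blind: a perfectly anti-correlated
    window scores r2 = 1 just like a perfect copy.
    """
    return _pearson_r2_p(a_win, b_win)


def window_association_wclr(a_win: np.ndarray, b_win: np.ndarray) -> tuple[float, float]:
    """R-squared gained by adding A's window to an AR(1) model of B's.

    Baseline: b[i] ~ 1 + b[i-1] within the window (autoregressive control);
    full model adds a[i].  Returns (delta_r2, p) with the F test for the
    added predictor on (1, W - 4) degrees of freedom (W - 1 usable
    observations, 3 fitted parameters).
    """
    a = np.asarray(a_win, dtype=float)
    b = np.asarray(b_win, dtype=float)
    if a.size != b.size or a.size < 6:
        raise ValueError("WCLR windows must have equal length >= 6")
    y = b[1:]
    x1 = b[:-1]
    x2 = a[1:]
    return _wclr_from_parts(y, x1, x2)


def _wclr_from_parts(y: np.ndarray, x1: np.ndarray, x2: np.ndarray) -> tuple[float, float]:
    n = y.size
    for name, x in (("response", y), ("lagged response", x1), ("predictor", x2)):
        if np.var(x) <= _VAR_EPS:
            raise ZeroVarianceError(f"{name} is constant within the window; add noise first")
    ryx1 = float(np.corrcoef(y, x1)[0, 1])
    ryx2 = float(np.corrcoef(y, x2)[0, 1])
    r12 = float(np.corrcoef(x1, x2)[0, 1])
    denom = 1.0 - r12 * r12
    if denom <= _VAR_EPS:
        raise ZeroVarianceError("singular design: predictors are collinear")
    r2_base = ryx1 * ryx1
    r2_full = (ryx1 * ryx1 + ryx2 * ryx2 - 2 * ryx1 * ryx2 * r12) / denom
    r2_full = min(max(r2_full, r2_base), 1.0)
    delta = r2_full - r2_base
    df2 = n - 3
    resid = max(1.0 - r2_full, np.finfo(float).tiny)
    with np.errstate(over="ignore"):
        f = delta * df2 / resid
    p = float(stats.f.sf(f, 1, df2))
    return float(delta), p


def _grids(n: int, config: AnalysisConfig) -> tuple[np.ndarray, np.ndarray]:
    time_grid = np.arange(0, n, config.step)
    # zero-centered lag grid: +/- k*step up to max_lag; when max_lag is not a
    # multiple of the step, one extra positive endpoint pads the grid so both
    # leading directions stay representable at full count (76 lags for
    # max_lag 75, step 2).
    k = config.max_lag // config.step
    lags = list(range(-k * config.step, k * config.step + 1, config.step))
    if config.max_lag % config.step != 0:
        lags.append((k + 1) * config.step)
    return time_grid, np.asarray(lags)


def _series_values(x) -> np.ndarray:
    if isinstance(x, MotionEnergySeries):
        return np.asarray(x.values, dtype=float)
    return np.asarray(x, dtype=float)


def _rolling_sums(x: np.ndarray, w: int) -> np.ndarray:
    c = np.concatenate([[0.0], np.cumsum(x)])
    return c[w:] - c[:-w]


def _check_variances(var: np.ndarray, starts: np.ndarray, side: str) -> None:
    bad = var <= _VAR_EPS
    if bad.any():
        t0 = int(starts[np.argmax(bad)])
        raise ZeroVarianceError(
            f"zero-variance window in series {side} at frame {t0}; "
            "noise injection appears to be missing"
        )


def compute_landscape(a, b, config: AnalysisConfig) -> R2Landscape:
    """Evaluate the windowed association on the full (time, lag) grid.

    For window start t and lag l, associates ``a[t:t+W]`` with
    ``b[t+l : t+l+W]``; windows overrunning either series are skipped
    (NaN cells).  Accepts MotionEnergySeries or plain arrays (assumed to be
    already preprocessed).
    """
    av = _series_values(a)
    bv = _series_values(b)
    if av.size != bv.size:
        raise ValueError("series must have equal length")
    n = av.size
    w = config.bandwidth
    if n < w + config.max_lag:
        raise ValueError(
            f"series of length {n} too short: need at least bandwidth + max_lag "
            f"= {w + config.max_lag} frames"
        )
    time_grid, lag_grid = _grids(n, config)
    m, k = time_grid.size, lag_grid.size
    r2 = np.full((m, k), np.nan)
    stat = np.full((m, k), np.nan)  # t (WCLC) or F (WCLR) statistic

    # global centering: Pearson/OLS within a window are shift-invariant,
    # and centered cumulative sums are numerically far better behaved
    ac = av - av.mean()
    bc = bv - bv.mean()

    if config.method == "WCLC":
        _fill_wclc(ac, bc, config, time_grid, lag_grid, r2, stat)
        with np.errstate(invalid="ignore"):
            p = 2.0 * stats.t.sf(np.abs(stat), df=w - 2)
    else:
        _fill_wclr(ac, bc, config, time_grid, lag_grid, r2, stat)
        with np.errstate(invalid="ignore"):
            p = stats.f.sf(stat, 1, (w - 1) - 3)
    sig = np.zeros((m, k), dtype=bool)
    defined = np.isfinite(p)
    sig[defined] = p[defined] < config.alpha
    return R2Landscape(r2=r2, sig=sig, time_grid=time_grid, lag_grid=lag_grid)


def _fill_wclc(ac, bc, config, time_grid, lag_grid, r2, stat) -> None:
    n = ac.size
    w = config.bandwidth
    for j, lag in enumerate(lag_grid):
        lo = max(0, -int(lag))
        hi = n - max(0, int(lag))
        if hi - lo < w:
            continue
        x = ac[lo:hi]
        y = bc[lo + lag : hi + lag]
        sx = _rolling_sums(x, w)
        sy = _rolling_sums(y, w)
        sxx = _rolling_sums(x * x, w)
        syy = _rolling_sums(y * y, w)
        sxy = _rolling_sums(x * y, w)
        starts = lo + np.arange(sx.size)
        on_grid = starts % config.step == 0
        starts = starts[on_grid]
        vx = w * sxx[on_grid] - sx[on_grid] ** 2
        vy = w * syy[on_grid] - sy[on_grid] ** 2
        _check_variances(vx, starts, "a")
        _check_variances(vy, starts, "b")
        cov = w * sxy[on_grid] - sx[on_grid] * sy[on_grid]
        r = cov / np.sqrt(vx * vy)
        r = np.clip(r, -1.0, 1.0)
        rr = r * r
        denom = np.maximum(1.0 - rr, np.finfo(float).tiny)
        with np.errstate(over="ignore"):
            tval = np.abs(r) * np.sqrt((w - 2) / denom)
        rows = starts // config.step
        r2[rows, j] = rr
        stat[rows, j] = tval


def _fill_wclr(ac, bc, config, time_grid, lag_grid, r2, stat) -> None:
    # response y = b[t+l+i], AR control x1 = b[t+l+i-1], predictor x2 = a[t+i]
    # for i = 1..W-1; rolling correlation algebra gives the nested-model
    # delta R^2 without per-window least squares.
    n = ac.size
    w = config.bandwidth
    m_eff = w - 1  # usable observations per window
    df2 = m_eff - 3
    if df2 < 1:
        raise ValueError("bandwidth too small for WCLR (need W >= 5)")
    for j, lag in enumerate(lag_grid):
        lo = max(0, -int(lag))
        hi = n - max(0, int(lag))
        if hi - lo < w:
            continue
        seg_a = ac[lo:hi]
        seg_b = bc[lo + lag : hi + lag]
        y = seg_b[1:]
        x1 = seg_b[:-1]
        x2 = seg_a[1:]
        sums = {}
        for name, arr in (
            ("y", y), ("x1", x1), ("x2", x2),
            ("yy", y * y), ("x1x1", x1 * x1), ("x2x2", x2 * x2),
            ("yx1", y * x1), ("yx2", y * x2), ("x1x2", x1 * x2),
        ):
            sums[name] = _rolling_sums(arr, m_eff)
        starts = lo + np.arange(sums["y"].size)
        on_grid = starts % config.step == 0
        starts = starts[on_grid]
        s = {k: v[on_grid] for k, v in sums.items()}
        vy = m_eff * s["yy"] - s["y"] ** 2
        v1 = m_eff * s["x1x1"] - s["x1"] ** 2
        v2 = m_eff * s["x2x2"] - s["x2"] ** 2
        _check_variances(vy, starts, "b (response)")
        _check_variances(v1, starts, "b (lagged)")
        _check_variances(v2, starts, "a (predictor)")
        cy1 = m_eff * s["yx1"] - s["y"] * s["x1"]
        cy2 = m_eff * s["yx2"] - s["y"] * s["x2"]
        c12 = m_eff * s["x1x2"] - s["x1"] * s["x2"]
        ry1 = np.clip(cy1 / np.sqrt(vy * v1), -1.0, 1.0)
        ry2 = np.clip(cy2 / np.sqrt(vy * v2), -1.0, 1.0)
        r12 = np.clip(c12 / np.sqrt(v1 * v2), -1.0, 1.0)
        denom = np.maximum(1.0 - r12 * r12, _VAR_EPS)
        r2_base = ry1 * ry1
        r2_full = (ry1 * ry1 + ry2 * ry2 - 2 * ry1 * ry2 * r12) / denom
        r2_full = np.minimum(np.maximum(r2_full, r2_base), 1.0)
        delta = r2_full - r2_base
        resid = np.maximum(1.0 - r2_full, np.finfo(float).tiny)
        fval = delta * df2 / resid
        rows = starts // config.step
        r2[rows, j] = delta
        stat[rows, j] = fval


def peak_pick(
    landscape: R2Landscape,
    config: AnalysisConfig,
    min_duration: int = MIN_MSI_FRAMES,
) -> List[SyncIntervalRecord]:
    """Chain per-column ridge maxima into synchronization intervals.

    For each time column the lag maximizing r2 among significant cells is
    taken; consecutive columns chain while that lag moves by at most
    ``LAG_CHAIN_TOL_STEPS`` grid steps and stays significant.  A closed
    chain over window starts [t_first, t_last] is mapped to the frame span

        [t_first + W - step, t_last + step)

    on A's timeline: the window before t_first did not track the ridge, so
    the synchronous event cannot have begun before ``t_first + W - step``,
    and the window after t_last did not, so it ends by ``t_last + step``.
    The chain's lag is the argmax of the r2 profile *averaged over its
    columns* — averaging centers the estimate on the ridge peak, where a
    single column's maximum can wander on a broad ridge.  mean_r2 averages
    the picked cells.  Intervals shorter than ``min_duration`` frames are
    dropped; because neighbouring windows share all but ``step`` frames,
    chance ridges persist for a while, but their frame span rarely exceeds
    the bandwidth, and their low mean r2 is what the interval-level cutoff
    is there to remove.
    """
    r2 = landscape.r2
    sig = landscape.sig
    m = r2.shape[0]
    step = int(np.diff(landscape.time_grid)[0]) if m > 1 else config.step
    w = config.bandwidth
    n_frames = int(landscape.time_grid[-1]) + step if m else 0

    masked = np.where(sig & np.isfinite(r2), r2, -np.inf)
    best_j = np.argmax(masked, axis=1)
    has_sig = masked[np.arange(m), best_j] > -np.inf

    intervals: List[SyncIntervalRecord] = []
    chain_cols: List[int] = []

    def close_chain() -> None:
        if not chain_cols:
            return
        start = int(landscape.time_grid[chain_cols[0]]) + w - step
        end = min(int(landscape.time_grid[chain_cols[-1]]) + step, n_frames)
        if end - start >= max(min_duration, 1):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
                profile = np.nanmean(r2[chain_cols, :], axis=0)
            j_star = int(np.argmax(np.where(np.isfinite(profile), profile, -np.inf)))
            vals = r2[chain_cols, best_j[chain_cols]]
            intervals.append(
                SyncIntervalRecord(
                    start=start,
                    end=end,
                    lag=float(landscape.lag_grid[j_star]),
                    mean_r2=float(np.mean(vals)),
                )
            )
        chain_cols.clear()

    for col in range(m):
        if not has_sig[col]:
            close_chain()
            continue
        if chain_cols:
            contiguous = col == chain_cols[-1] + 1
            lag_ok = abs(int(best_j[col]) - int(best_j[chain_cols[-1]])) <= LAG_CHAIN_TOL_STEPS
            if not (contiguous and lag_ok):
                close_chain()
        chain_cols.append(col)
    close_chain()
    return intervals


def filter_by_cutoff(
    intervals: Sequence[SyncIntervalRecord], r2_cutoff: float
) -> List[SyncIntervalRecord]:
    """Keep intervals whose mean_r2 strictly exceeds the cutoff."""
    return [iv for iv in intervals if iv.mean_r2 > r2_cutoff]


def identify_msi(dyad, config: AnalysisConfig, master_seed: int = 0) -> List[SyncIntervalRecord]:
    """Full pipeline on one dyad: transform -> smooth -> noise -> landscape
    -> peak-pick -> cutoff filter.

    Noise seeds are derived deterministically from (master_seed, dyad id,
    person, config id), so a grid run is reproducible and independent of
    task ordering.
    """
    a, b = dyad.a, dyad.b
    xa, xb = apply_transform(a, b, config.transform)
    xa = smooth(xa, config.smoothing)
    xb = smooth(xb, config.smoothing)
    dyad_id = getattr(dyad, "id", "dyad")
    xa = add_noise(
        xa,
        NoiseSpec(
            mean=config.noise.mean,
            sd=config.noise.sd,
            seed=derive_seed(master_seed, dyad_id, "a", config.config_id),
        ),
    )
    xb = add_noise(
        xb,
        NoiseSpec(
            mean=config.noise.mean,
            sd=config.noise.sd,
            seed=derive_seed(master_seed, dyad_id, "b", config.config_id),
        ),
    )
    landscape = compute_landscape(xa, xb, config)
    intervals = peak_pick(landscape, config)
    return filter_by_cutoff(intervals, config.r2_cutoff)
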