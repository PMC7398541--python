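"""Stimulus-level calibration: I/O functions, T/C levels, target-rate search.

The electrical dynamic range of a channel is derived from an input/output
(I/O) function: the fiber's onset response rate (spikes/s inside the
0–12 ms onset window, which spans several 4 ms refractory periods) to a
900 pps pulse train, as a function of train current level.  Threshold (T)
and comfortable (C) levels are read off at 10% and 90% of the I/O
function — the model analogue of clinical loudness scaling (level 1 and
level 9 of 10).  A separate bisection search finds the level that evokes
a prescribed onset rate (e.g. 360 spikes/s for the spread-of-excitation
maps).  All calibrations are seeded and therefore reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from cisrd.fiber import FiberModel, pulse_train, rep_seed, simulate_fiber
from cisrd.geometry import ArrayLayout, CurrentSpreadModel


class CalibrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class IOFunction:
    """Measured onset-rate curve and the derived T/C levels (mA)."""

    levels: np.ndarray
    onset_rates: np.ndarray          # raw Monte-Carlo rates, spikes/s
    smoothed_rates: np.ndarray       # isotonic-regression fit (non-decreasing)
    t_level: float
    c_level: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.smoothed_rates) < 0):
            raise ValueError("smoothed rates must be non-decreasing")
        if not self.t_level < self.c_level:
            raise ValueError("t_level must be below c_level")

    def write(self, path: str | Path) -> None:
        path = Path(path)
        pd.DataFrame({"level_ma": self.levels, "onset_rate": self.onset_rates,
                      "smoothed_rate": self.smoothed_rates}).to_csv(path, index=False)
        path.with_suffix(".json").write_text(json.dumps(
            {"t_level_ma": self.t_level, "c_level_ma": self.c_level}, indent=2))


def onset_rate(model: FiberModel, layout: ArrayLayout, level_ma: float,
               electrode: int, *, rate_pps: float = 900.0,
               window_ms: float = 12.0, n_reps: int = 30, seed: int = 0,
               dt_us: float | None = None,
               spread: CurrentSpreadModel = CurrentSpreadModel()) -> float:
    """Mean onset-window response rate (spikes/s) of the fiber at its electrode."""
    pulses = pulse_train(level_ma, electrode, rate_pps,
                         duration_ms=window_ms + 1.0)
    trains = simulate_fiber(model, pulses, layout, fiber_i=electrode,
                            n_reps=n_reps, seed=seed, dt_us=dt_us, spread=spread)
    counts = [np.sum(tr.times_ms < window_ms) for tr in trains]
    return float(np.mean(counts) / (window_ms * 1e-3))


def compute_io_function(model: FiberModel, layout: ArrayLayout, *,
                        electrode: int = 11, rate_pps: float = 900.0,
                        level_sweep: np.ndarray | None = None,
                        n_reps: int = 30, seed: int = 0,
                        window_ms: float = 12.0, dt_us: float | None = None,
                        mode: str = "fraction_of_range") -> IOFunction:
    """Measure the I/O function and set T/C at its 10%/90% points.

    ``mode='fraction_of_range'`` (default) places 10%/90% on the
    min-to-max span of the isotonic-smoothed curve;
    ``mode='fraction_of_max'`` on the 0-to-max span.  Levels are
    interpolated on the smoothed curve.  A sweep that never leaves the
    floor (or never rises) raises :class:`CalibrationError`.

    When no sweep is given, a coarse geometric sweep (0.5–60 mA) first
    brackets the dynamic range with few repetitions, then a linear sweep
    across the bracket resolves the sigmoid.
    """
    if level_sweep is None:
        coarse = np.geomspace(0.5, 60.0, 14)
        c_rates = np.array([
            onset_rate(model, layout, lev, electrode, rate_pps=rate_pps,
                       window_ms=window_ms, n_reps=max(4, n_reps // 4),
                       seed=rep_seed(seed, 100 + i), dt_us=dt_us)
            for i, lev in enumerate(coarse)])
        if c_rates.max() < 1e-9:
            raise CalibrationError("coarse sweep entirely sub-threshold")
        if c_rates[0] > 0.5 * c_rates.max():
            raise CalibrationError("coarse sweep entirely supra-threshold")
        i_hi = int(np.argmax(c_rates >= 0.95 * c_rates.max()))
        below = np.where(c_rates[:i_hi] < 1e-9)[0]
        i_lo = int(below[-1]) if len(below) else 0
        level_sweep = np.linspace(0.9 * coarse[i_lo], 1.1 * coarse[i_hi], 12)
    levels = np.asarray(level_sweep, dtype=float)
    rates = np.array([
        onset_rate(model, layout, lev, electrode, rate_pps=rate_pps,
                   window_ms=window_ms, n_reps=n_reps,
                   seed=rep_seed(seed, i), dt_us=dt_us)
        for i, lev in enumerate(levels)])
    iso = IsotonicRegression(increasing=True)
    smoothed = iso.fit_transform(levels, rates)
    lo, hi = smoothed.min(), smoothed.max()
    if hi - lo < 1e-9 or smoothed[0] == hi:
        raise CalibrationError(
            "level sweep entirely sub- or supra-threshold; widen the sweep "
            f"(rates spanned [{lo:.1f}, {hi:.1f}] spikes/s)")
    base = 0.0 if mode == "fraction_of_max" else lo
    r10 = base + 0.1 * (hi - base)
    r90 = base + 0.9 * (hi - base)
    if r10 < smoothed[0]:
        raise CalibrationError("10% point below the lowest measured rate; "
                               "extend the sweep downward")
    # interpolate on the strictly increasing part of the smoothed curve
    keep = np.concatenate(([True], np.diff(smoothed) > 0))
    t_level = float(np.interp(r10, smoothed[keep], levels[keep]))
    c_level = float(np.interp(r90, smoothed[keep], levels[keep]))
    if not t_level < c_level:
        raise CalibrationError("degenerate T/C levels; sweep too coarse")
    return IOFunction(levels=levels, onset_rates=rates, smoothed_rates=smoothed,
                      t_level=t_level, c_level=c_level)


def find_level_for_rate(model: FiberModel, layout: ArrayLayout,
                        target_rate: float, *, electrode: int = 11,
                        rate_pps: float = 900.0, window_ms: float = 12.0,
                        n_reps: int = 30, seed: int = 0,
                        dt_us: float | None = None, rate_tol: float = 0.05,
                        lo_ma: float = 0.3, hi_ma: float = 80.0,
                        max_iters: int = 14) -> float:
    """Bisection for the train level evoking ``target_rate`` in the onset window.

    The search assumes the rate-vs-level curve is monotone (it is after
    isotonic smoothing; Monte-Carlo noise is handled by the ``rate_tol``
    stopping rule, default ±5%).  Raises :class:`CalibrationError` with
    the maximum achievable rate if the target is out of reach.
    """
    if target_rate <= 0:
        return lo_ma

    def measure(level, k):
        return onset_rate(model, layout, level, electrode, rate_pps=rate_pps,
                          window_ms=window_ms, n_reps=n_reps,
                          seed=rep_seed(seed, k), dt_us=dt_us)

    hi_rate = measure(hi_ma, 0)
    if hi_rate < target_rate:
        raise CalibrationError(
            f"target {target_rate} spikes/s unreachable; max achievable "
            f"~{hi_rate:.0f} spikes/s at {hi_ma} mA")
    lo, hi = lo_ma, hi_ma
    best = hi
    for it in range(1, max_iters + 1):
        mid = float(np.sqrt(lo * hi))
        r = measure(mid, it)
        if abs(r - target_rate) <= rate_tol * target_rate:
            return mid
        if r < target_rate:
            lo = mid
        else:
            hi = mid
            best = mid
    return best
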