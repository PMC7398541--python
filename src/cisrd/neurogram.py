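"""Neurogram construction from repeated-trial spike trains.

A neurogram is a fibers x time-bins matrix of firing rates (spikes/s)
built from per-fiber peri-stimulus time histograms (PSTHs): spike counts
pooled over repetitions in fixed bins (default 4 ms) divided by
``n_reps * bin width``.  Fiber rows are ordered 1 (basal) to 22 (apical),
matching the electrode numbering of the array.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Neurogram:
    """Fibers x time-bins matrix of firing rates.

    ``rates[f, b]`` is in spikes/s; ``bin_ms`` the bin width; ``n_reps``
    the number of stochastic repetitions pooled per fiber.  Values above
    the conventional 360 spikes/s display ceiling are retained (only the
    rendering saturates).
    """

    rates: np.ndarray
    bin_ms: float = 4.0
    n_reps: int = 30

    def __post_init__(self) -> None:
        if np.any(self.rates < 0):
            raise ValueError("negative rates")

    @property
    def n_fibers(self) -> int:
        return self.rates.shape[0]

    @property
    def n_bins(self) -> int:
        return self.rates.shape[1]

    @property
    def bin_times_ms(self) -> np.ndarray:
        return np.arange(self.n_bins) * self.bin_ms


def build_neurogram(spike_trains: Sequence[Sequence[np.ndarray]],
                    bin_ms: float = 4.0,
                    duration_ms: float | None = None) -> Neurogram:
    """Bin per-fiber, per-repetition spike times (ms) into a neurogram.

    ``spike_trains[f][r]`` holds the spike times of fiber ``f`` in
    repetition ``r``.  Bins are half-open ``[t, t + bin_ms)`` anchored at
    t = 0; ``rate(f, b) = count(f, b) / (n_reps * bin_ms / 1000)``.
    Spike times at or beyond ``duration_ms`` raise, signalling upstream
    misalignment.
    """
    n_fibers = len(spike_trains)
    if n_fibers == 0:
        raise ValueError("no fibers")
    n_reps = len(spike_trains[0])
    if duration_ms is None:
        duration_ms = max((float(np.max(t)) if len(t) else 0.0
                           for trains in spike_trains for t in trains), default=0.0)
        duration_ms = bin_ms * max(1, int(np.ceil(duration_ms / bin_ms + 1e-9)))
    n_bins = int(round(duration_ms / bin_ms))
    edges = np.arange(n_bins + 1) * bin_ms
    rates = np.zeros((n_fibers, n_bins))
    for f, trains in enumerate(spike_trains):
        if len(trains) != n_reps:
            raise ValueError("unequal repetition counts across fibers")
        for times in trains:
            times = np.asarray(times, dtype=float)
            if times.size and (times.min() < 0 or times.max() >= duration_ms):
                raise ValueError(
                    f"spike time outside [0, {duration_ms}) ms for fiber {f}")
            rates[f] += np.histogram(times, bins=edges)[0]
    rates /= n_reps * bin_ms / 1000.0
    return Neurogram(rates=rates, bin_ms=bin_ms, n_reps=n_reps)


def to_frame(ng: Neurogram) -> pd.DataFrame:
    """Neurogram as a DataFrame: one row per fiber, columns = bin start times."""
    return pd.DataFrame(ng.rates, columns=[f"{t:g}" for t in ng.bin_times_ms],
                        index=pd.RangeIndex(1, ng.n_fibers + 1, name="fiber"))


def write_csv(ng: Neurogram, path: str | Path) -> None:
    to_frame(ng).to_csv(path)


def read_csv(path: str | Path, bin_ms: float = 4.0, n_reps: int = 30) -> Neurogram:
    df = pd.read_csv(path, index_col=0)
    cols = df.columns.astype(float).to_numpy()
    if len(cols) > 1:
        bin_ms = float(cols[1] - cols[0])
    return Neurogram(rates=df.to_numpy(dtype=float), bin_ms=bin_ms, n_reps=n_reps)


def render_png(ng: Neurogram, path: str | Path, vmax: float = 360.0) -> None:
    """Render with the conventional 0 (blue) – 360 (red) spikes/s color scale."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3))
    extent = (0.0, ng.n_bins * ng.bin_ms, ng.n_fibers + 0.5, 0.5)
    im = ax.imshow(ng.rates, aspect="auto", cmap="jet", vmin=0.0, vmax=vmax,
                   extent=extent, interpolation="nearest")
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("fiber (1 basal – 22 apical)")
    fig.colorbar(im, ax=ax, label="rate (spikes/s)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
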