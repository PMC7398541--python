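"""End-to-end experiment drivers.

Four experiments probe how the electrode-to-fiber distance shapes
cochlear-implant spectral resolution:

* :func:`run_spread_of_excitation` — single-channel 900 pps trains at the
  360 spikes/s-calibrated level; onset response of all 22 fibers.
* :func:`run_two_pulse` — channel interaction between two neighboring
  electrodes with a 138 us inter-pulse delay (inhibition vs facilitation).
* :func:`run_current_spread_factor` — per-fiber relative spike-count
  change caused by neighboring-channel current during rippled-noise
  stimulation.
* :func:`run_srd` — full pipeline: standard/inverted rippled noise →
  ACE → fiber population → neurograms → NSIM → percent-correct score.

All randomness derives from a single master seed through explicit
seed-splitting, so full runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from cisrd import ace, calibrate, metrics, neurogram, stimulus
from cisrd.fiber import (FiberModel, FiberParams, pulse_train, rep_seed,
                         simulate_fiber, two_pulse_experiment)
from cisrd.geometry import ArrayLayout, CurrentSpreadModel

#: Human CI percent-correct reference statistics (mean, SD) per ripple
#: density, for plotting/report context only — no statistical test is run
#: against them.
HUMAN_CI_SCORES = {1.0: (77.59, 21.42), 2.0: (71.46, 16.72), 4.0: (48.34, 20.64)}

PAPER_DISTANCES_MM = (0.23, 0.68, 1.18, 1.88, 2.08)
PAPER_DENSITIES_RO = (1.0, 2.0, 4.0)
PROBE_CHANNELS = (3, 6, 9, 12, 15, 18, 21)


@dataclass(frozen=True)
class ExperimentConfig:
    """Shared configuration for the experiment drivers.

    ``scale='full'`` uses the reference repetition counts (30 neurogram
    repetitions, 6 score repetitions); ``scale='reduced'`` shrinks them
    (5 and 2) for quick runs that preserve the qualitative orderings.
    """

    distances_mm: tuple[float, ...] = PAPER_DISTANCES_MM
    densities_ro: tuple[float, ...] = PAPER_DENSITIES_RO
    n_reps_neurogram: int = 30
    n_score_repetitions: int = 6
    n_reps_spread: int = 10
    n_reps_two_pulse: int = 100
    probe_channels: tuple[int, ...] = PROBE_CHANNELS
    master_seed: int = 0
    scale: str = "full"
    dt_us: float = 2.5
    calib_reps: int = 20
    fiber_params: FiberParams = field(default_factory=FiberParams)
    spread: CurrentSpreadModel = field(default_factory=CurrentSpreadModel)
    bin_ms: float = 4.0
    stim_duration_ms: float = 200.0
    ripple_depth_db: float = 30.0
    respond_fraction: float = 0.1   # "responding fiber" = >=10% of driven rate

    def __post_init__(self) -> None:
        if min(self.n_reps_neurogram, self.n_score_repetitions,
               self.n_reps_spread, self.n_reps_two_pulse) < 1:
            raise ValueError("repetition counts must be >= 1")
        if any(d <= 0 for d in self.distances_mm):
            raise ValueError("distances must be positive")

    @classmethod
    def reduced(cls, **kwargs) -> "ExperimentConfig":
        kwargs.setdefault("n_reps_neurogram", 5)
        kwargs.setdefault("n_score_repetitions", 2)
        kwargs.setdefault("n_reps_spread", 5)
        kwargs.setdefault("scale", "reduced")
        return cls(**kwargs)


def _model(cfg: ExperimentConfig) -> FiberModel:
    return FiberModel(cfg.fiber_params)


# ---------------------------------------------------------------------------
# spread of excitation
# ---------------------------------------------------------------------------


def run_spread_of_excitation(cfg: ExperimentConfig) -> pd.DataFrame:
    """Onset response of all 22 fibers to single-channel stimulation.

    For each distance the 900 pps train level is calibrated to evoke
    360 spikes/s at the driven fiber (so the on-channel response is
    distance-invariant by construction, and any off-channel response is
    attributable to current spread).  Returns tidy rows
    (distance_mm, channel, fiber, onset_rate).
    """
    model = _model(cfg)
    rows = []
    for d_i, dist in enumerate(cfg.distances_mm):
        layout = ArrayLayout(electrode_anf_distance_mm=dist)
        level = calibrate.find_level_for_rate(
            model, layout, 360.0, n_reps=cfg.calib_reps,
            seed=rep_seed(cfg.master_seed, 1, d_i), dt_us=cfg.dt_us)
        for ch in cfg.probe_channels:
            pulses = pulse_train(level, ch, 900.0, duration_ms=13.0)
            for fiber_i in range(1, layout.n_electrodes + 1):
                trains = simulate_fiber(
                    model, pulses, layout, fiber_i,
                    n_reps=cfg.n_reps_spread,
                    seed=rep_seed(cfg.master_seed, 2, d_i, ch),
                    spread=cfg.spread, dt_us=cfg.dt_us)
                counts = [np.sum(tr.times_ms < 12.0) for tr in trains]
                rows.append({"distance_mm": dist, "channel": ch,
                             "fiber": fiber_i, "level_ma": level,
                             "onset_rate": float(np.mean(counts) / 0.012)})
    return pd.DataFrame(rows)


def responding_fiber_counts(spread_df: pd.DataFrame,
                            respond_fraction: float = 0.1) -> pd.DataFrame:
    """Count fibers responding per (distance, probe channel).

    A fiber responds when its onset rate reaches ``respond_fraction`` of
    the driven (on-channel) fiber's rate.
    """
    out = []
    for (dist, ch), grp in spread_df.groupby(["distance_mm", "channel"]):
        driven = grp.loc[grp["fiber"] == ch, "onset_rate"].iloc[0]
        thr = respond_fraction * driven
        n = int((grp["onset_rate"] >= thr).sum()) if driven > 0 else 0
        out.append({"distance_mm": dist, "channel": ch,
                    "driven_rate": driven, "n_responding": n})
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# two-pulse channel interaction
# ---------------------------------------------------------------------------


def run_two_pulse(cfg: ExperimentConfig, delay_us: float = 138.0) -> pd.DataFrame:
    """Fig-5-style two-pulse interaction at every configured distance."""
    return two_pulse_experiment(cfg.distances_mm, params=cfg.fiber_params,
                                n_reps=cfg.n_reps_two_pulse,
                                seed=rep_seed(cfg.master_seed, 3),
                                delay_us=delay_us, dt_us=cfg.dt_us)


# ---------------------------------------------------------------------------
# shared pipeline pieces
# ---------------------------------------------------------------------------


def _tc_levels(cfg: ExperimentConfig, model: FiberModel, layout: ArrayLayout,
               d_i: int) -> tuple[float, float]:
    io = calibrate.compute_io_function(
        model, layout, n_reps=cfg.calib_reps,
        seed=rep_seed(cfg.master_seed, 4, d_i), dt_us=cfg.dt_us)
    return io.t_level, io.c_level


def _encode_stimulus(cfg: ExperimentConfig, density: float, variant, stim_seed: int,
                     t_level: float, c_level: float) -> ace.PulseSequence:
    params = stimulus.RippleParams(density=density, phase_variant=variant,
                                   duration_ms=cfg.stim_duration_ms,
                                   peak_to_valley_db=cfg.ripple_depth_db,
                                   seed=stim_seed)
    stim = stimulus.generate_rippled_noise(params)
    acfg = ace.AceConfig(t_levels=np.full(22, t_level),
                         c_levels=np.full(22, c_level))
    return ace.encode(stim.samples, params.sample_rate, acfg)


def _population_spikes(cfg: ExperimentConfig, model: FiberModel,
                       layout: ArrayLayout, pulses: ace.PulseSequence,
                       n_reps: int, seed: int,
                       with_spread: bool = True) -> list[list[np.ndarray]]:
    trains = []
    for fiber_i in range(1, layout.n_electrodes + 1):
        reps = simulate_fiber(model, pulses, layout, fiber_i, n_reps=n_reps,
                              seed=rep_seed(seed, fiber_i),
                              spread=cfg.spread, with_spread=with_spread,
                              duration_ms=cfg.stim_duration_ms,
                              dt_us=cfg.dt_us)
        trains.append([tr.times_ms for tr in reps])
    return trains


# ---------------------------------------------------------------------------
# current-spread factor
# ---------------------------------------------------------------------------


def run_current_spread_factor(cfg: ExperimentConfig) -> pd.DataFrame:
    """Per-fiber spike-count change caused by neighboring-channel current.

    For each (distance, density, variant) the rippled-noise pulse
    sequence is presented twice per fiber: with full current spread, and
    with only the fiber's own channel active.  The factor
    (with - without)/without is NaN (excluded from summaries) when the
    baseline has no spikes.
    """
    model = _model(cfg)
    rows = []
    for d_i, dist in enumerate(cfg.distances_mm):
        layout = ArrayLayout(electrode_anf_distance_mm=dist)
        t_level, c_level = _tc_levels(cfg, model, layout, d_i)
        for den_i, density in enumerate(cfg.densities_ro):
            for variant in (stimulus.PhaseVariant.STANDARD,
                            stimulus.PhaseVariant.INVERTED):
                stim_seed = rep_seed(cfg.master_seed, 5, d_i, den_i)
                pulses = _encode_stimulus(cfg, density, variant, stim_seed,
                                          t_level, c_level)
                pop_seed = rep_seed(cfg.master_seed, 6, d_i, den_i,
                                    0 if variant == stimulus.PhaseVariant.STANDARD else 1)
                with_sp = _population_spikes(cfg, model, layout, pulses,
                                             cfg.n_reps_neurogram, pop_seed,
                                             with_spread=True)
                without_sp = _population_spikes(cfg, model, layout, pulses,
                                                cfg.n_reps_neurogram, pop_seed,
                                                with_spread=False)
                for f in range(layout.n_electrodes):
                    n_with = sum(len(t) for t in with_sp[f])
                    n_without = sum(len(t) for t in without_sp[f])
                    factor = (np.nan if n_without == 0 else
                              metrics.current_spread_factor(n_with, n_without))
                    rows.append({"distance_mm": dist, "density_ro": density,
                                 "variant": variant.value, "fiber": f + 1,
                                 "spikes_with": n_with,
                                 "spikes_without": n_without,
                                 "factor": factor})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# SRD performance
# ---------------------------------------------------------------------------


def run_srd(cfg: ExperimentConfig,
            score_fn: metrics.ScoreFunction = metrics.ScoreFunction(),
            nsim_cfg: metrics.NsimConfig = metrics.NsimConfig()) -> pd.DataFrame:
    """NSIM and percent-correct score per (distance, density, repetition).

    Each score repetition draws fresh stimulus phases (shared between the
    standard and inverted variants) and fresh fiber noise, builds the two
    neurograms, and converts their NSIM into a percent-correct score.
    """
    model = _model(cfg)
    rows = []
    for d_i, dist in enumerate(cfg.distances_mm):
        layout = ArrayLayout(electrode_anf_distance_mm=dist)
        t_level, c_level = _tc_levels(cfg, model, layout, d_i)
        for den_i, density in enumerate(cfg.densities_ro):
            for rep in range(cfg.n_score_repetitions):
                stim_seed = rep_seed(cfg.master_seed, 7, d_i, den_i, rep)
                ngs = {}
                for v_i, variant in enumerate((stimulus.PhaseVariant.STANDARD,
                                               stimulus.PhaseVariant.INVERTED)):
                    pulses = _encode_stimulus(cfg, density, variant, stim_seed,
                                              t_level, c_level)
                    pop_seed = rep_seed(cfg.master_seed, 8, d_i, den_i, rep, v_i)
                    spikes = _population_spikes(cfg, model, layout, pulses,
                                                cfg.n_reps_neurogram, pop_seed)
                    ngs[variant] = neurogram.build_neurogram(
                        spikes, bin_ms=cfg.bin_ms,
                        duration_ms=cfg.stim_duration_ms)
                value = metrics.nsim(ngs[stimulus.PhaseVariant.STANDARD].rates,
                                     ngs[stimulus.PhaseVariant.INVERTED].rates,
                                     nsim_cfg)
                rows.append({"distance_mm": dist, "density_ro": density,
                             "repetition": rep, "nsim": value,
                             "percent_correct": metrics.correct_score(value, score_fn),
                             "t_level_ma": t_level, "c_level_ma": c_level,
                             "stim_seed": stim_seed})
    return pd.DataFrame(rows)


def summarize_srd(srd_df: pd.DataFrame) -> pd.DataFrame:
    """Mean NSIM / percent correct per (distance, density), plus human stats."""
    g = (srd_df.groupby(["distance_mm", "density_ro"], as_index=False)
         .agg(nsim=("nsim", "mean"), percent_correct=("percent_correct", "mean")))
    g["human_mean"] = g["density_ro"].map({k: v[0] for k, v in HUMAN_CI_SCORES.items()})
    g["human_sd"] = g["density_ro"].map({k: v[1] for k, v in HUMAN_CI_SCORES.items()})
    return g


def run_all(cfg: ExperimentConfig) -> dict[str, pd.DataFrame]:
    """Run the four experiments; returns a dict of result tables."""
    spread = run_spread_of_excitation(cfg)
    return {
        "spread_of_excitation": spread,
        "responding_fibers": responding_fiber_counts(spread, cfg.respond_fraction),
        "two_pulse": run_two_pulse(cfg),
        "current_spread_factor": run_current_spread_factor(cfg),
        "srd": run_srd(cfg),
    }
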