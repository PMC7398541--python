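"""Stochastic multicompartment auditory-nerve-fiber model.

The fiber is a cable of 47 compartments: a peripheral axon (terminal
node + 3 myelinated internodes with Ranvier nodes between), the cell
body, and a central axon of 20 internodes with a Ranvier node after each
— 23 active nodes in total.  Each node carries voltage-gated Na and K
channels (Hodgkin–Huxley style m^3 h and n^4 kinetics with cat-node rate
constants); internodes and soma are passive.  Channel stochasticity uses
the Fox diffusion approximation: Gaussian perturbations of the gating
variables with variance set by the per-node channel counts, so spike
threshold fluctuates from trial to trial as in real fibers.

Extracellular stimulation follows the activating-function formalism: the
current reaching each compartment (electrode current attenuated by
exponential spread, see :mod:`cisrd.geometry`) times the extracellular
resistivity gives the local extracellular potential, whose discrete
second difference along the cable drives the membrane.  The stimulating
electrode faces the 9th active node; propagated spikes are detected at
the 20th active node by upward threshold crossing with a refractory
lockout.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from cisrd._cable import run_cable
from cisrd.ace import PulseSequence
from cisrd.geometry import ArrayLayout, CurrentSpreadModel

# ---------------------------------------------------------------------------
# rate functions (V = depolarization from rest, mV; rates in 1/ms)
# Na kinetics: Schwarz–Eikhof-style cat node constants as used in the
# stochastic ANF modelling literature; K: temperature-scaled HH kinetics.
# ---------------------------------------------------------------------------


def _lin_exp(v, a, b, cden):
    """a*(v-b)/(1-exp((b-v)/c)) with the removable singularity at v=b filled."""
    v = np.asarray(v, dtype=float)
    x = (b - v) / cden
    out = np.where(np.abs(x) < 1e-9, a * cden,
                   a * (v - b) / (1.0 - np.exp(np.where(np.abs(x) < 1e-9, 1.0, x))))
    return out


def alpha_m(v):
    return _lin_exp(v, 1.872, 25.41, 6.06)


def beta_m(v):
    return _lin_exp(v, 3.973, 21.001, -9.41) * -1.0


def alpha_h(v):
    return -1.0 * _lin_exp(v, 0.549, -27.74, -9.06)


def beta_h(v):
    v = np.asarray(v, dtype=float)
    return 22.57 / (1.0 + np.exp((56.0 - v) / 12.5))


def alpha_n(v):
    return _lin_exp(v, 0.29, 10.0, 10.0)


def beta_n(v):
    v = np.asarray(v, dtype=float)
    return 3.625 * np.exp(-v / 80.0)


RATES = {"m": (alpha_m, beta_m), "h": (alpha_h, beta_h), "n": (alpha_n, beta_n)}


def gate_inf(gate: str, v):
    a, b = RATES[gate]
    return a(v) / (a(v) + b(v))


# ---------------------------------------------------------------------------
# parameters and morphology
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FiberParams:
    """Membrane, morphology and simulation constants (all configurable).

    The Na/K channel counts and single-channel conductances set both the
    maximal nodal conductances (count x unitary conductance) and the Fox
    noise variance.  ``rho_e_ohm`` converts nodal stimulus current (mA)
    to extracellular potential (mV).  ``v_rest_mv`` documents the absolute
    resting potential; the model integrates depolarization re rest.
    """

    # node (Ranvier) geometry and membrane
    node_diameter_um: float = 2.0
    node_length_um: float = 1.5
    c_node_uf_cm2: float = 2.0
    g_leak_node_ms_cm2: float = 25.0
    # internodes (myelinated) and soma
    peripheral_internode_um: float = 250.0
    central_internode_um: float = 300.0
    c_myelin_uf_cm2: float = 0.02
    g_myelin_ms_cm2: float = 0.001
    soma_diameter_um: float = 20.0
    c_soma_pf: float = 2.5
    g_soma_ns: float = 0.6
    # axial
    rho_axoplasm_ohm_cm: float = 70.0
    # channels
    # Channel counts set the Fox noise variance; the unitary conductances
    # are lumped so that count x unitary gives the canonical maximal nodal
    # conductances (g_Na ~ 231 nS, g_K ~ 50 nS per node) while the
    # stochastic gating pool stays small enough to produce the few-percent
    # relative spread of threshold seen in cat fibers.
    n_na: int = 1000
    gamma_na_ps: float = 231.2
    n_k: int = 300
    gamma_k_ps: float = 166.7
    e_na_mv: float = 144.0
    e_k_mv: float = -12.0
    v_rest_mv: float = -78.0
    # extracellular coupling
    rho_e_ohm: float = 300.0
    # spike detection: -20 mV absolute = +58 mV depolarization re rest
    spike_threshold_mv: float = 58.0
    spike_lockout_ms: float = 0.5
    # integration
    dt_us: float = 1.0
    noise_scale: float = 1.0
    # Fox noise is injected at this interval (variance scaled by the
    # stride) — cheaper than per-step injection, spectrally equivalent
    # well below the gating time constants
    noise_interval_us: float = 5.0


def save_fiber_params(params: FiberParams, path: str | Path) -> None:
    """Write the membrane/morphology constants as a JSON config file."""
    Path(path).write_text(json.dumps(asdict(params), indent=2))


def load_fiber_params(path: str | Path) -> FiberParams:
    """Read a JSON fiber-parameter file (unknown keys rejected)."""
    return FiberParams(**json.loads(Path(path).read_text()))


def default_chain() -> list[str]:
    """Compartment kinds, peripheral terminal to central terminal.

    Peripheral axon: terminal node, then 3 internodes separated by nodes,
    then the soma; central axon: 20 internodes, each followed by a node.
    47 compartments, 23 active nodes.
    """
    chain = ["node", "internode", "node", "internode", "node", "internode", "soma"]
    for _ in range(20):
        chain += ["internode", "node"]
    return chain


class FiberModel:
    """Compiled per-compartment arrays plus the node bookkeeping.

    ``drive_active_node`` (default 9) is the node aligned with the
    stimulating electrode (z = 0); ``record_active_node`` (default 20)
    the spike-detection site.
    """

    def __init__(self, params: FiberParams = FiberParams(),
                 chain: Sequence[str] | None = None,
                 drive_active_node: int = 9,
                 record_active_node: int = 20) -> None:
        self.params = params
        self.chain = list(chain) if chain is not None else default_chain()
        kinds = self.chain
        ncomp = len(kinds)
        p = params

        area_node = np.pi * p.node_diameter_um * p.node_length_um * 1e-8  # cm^2
        c = np.empty(ncomp)
        gl = np.empty(ncomp)
        length_um = np.empty(ncomp)
        axial_half_ohm = np.empty(ncomp)
        a_cross = np.pi * (p.node_diameter_um / 2.0) ** 2 * 1e-8  # cm^2
        node_comp = []
        for k, kind in enumerate(kinds):
            if kind == "node":
                c[k] = p.c_node_uf_cm2 * area_node * 1e6           # pF
                gl[k] = p.g_leak_node_ms_cm2 * area_node * 1e6     # nS
                length_um[k] = p.node_length_um
                node_comp.append(k)
            elif kind == "soma":
                c[k] = p.c_soma_pf
                gl[k] = p.g_soma_ns
                length_um[k] = p.soma_diameter_um
            elif kind == "internode":
                peripheral = k < kinds.index("soma") if "soma" in kinds else True
                L = p.peripheral_internode_um if peripheral else p.central_internode_um
                area = np.pi * p.node_diameter_um * L * 1e-8
                c[k] = p.c_myelin_uf_cm2 * area * 1e6
                gl[k] = p.g_myelin_ms_cm2 * area * 1e6
                length_um[k] = L
            else:
                raise ValueError(f"unknown compartment kind {kind!r}")
            axial_half_ohm[k] = (p.rho_axoplasm_ohm_cm * (length_um[k] / 2.0) * 1e-4
                                 / a_cross)

        # axial conductance between k-1 and k, in nS; ga_lo[0] = 0
        ga_lo = np.zeros(ncomp + 1)
        for k in range(1, ncomp):
            ga_lo[k] = 1e9 / (axial_half_ohm[k - 1] + axial_half_ohm[k])

        self.c_pf = c
        self.g_leak_ns = gl
        self.ga_lo_ns = ga_lo
        self.node_comp = np.asarray(node_comp, dtype=np.int64)
        self.n_nodes = len(node_comp)
        nn = self.n_nodes
        self.gna_max_ns = np.full(nn, p.n_na * p.gamma_na_ps * 1e-3)  # nS
        self.gk_max_ns = np.full(nn, p.n_k * p.gamma_k_ps * 1e-3)

        # leak reversal per compartment chosen so V = 0 is the exact rest
        el = np.zeros(ncomp)
        m0, h0, n0 = gate_inf("m", 0.0), gate_inf("h", 0.0), gate_inf("n", 0.0)
        gna0 = self.gna_max_ns[0] * m0 ** 3 * h0
        gk0 = self.gk_max_ns[0] * n0 ** 4
        for j, k in enumerate(self.node_comp):
            el[k] = (gna0 * (0.0 - p.e_na_mv) + gk0 * (0.0 - p.e_k_mv)) / gl[k]
        self.e_leak_mv = el

        # compartment center positions along the fiber (z axis, mm)
        edges = np.concatenate(([0.0], np.cumsum(length_um))) * 1e-3
        centers = 0.5 * (edges[:-1] + edges[1:])
        if drive_active_node > self.n_nodes or record_active_node > self.n_nodes:
            drive_active_node = min(drive_active_node, self.n_nodes)
            record_active_node = min(record_active_node, self.n_nodes)
        self.drive_comp = int(self.node_comp[drive_active_node - 1])
        self.record_comp = int(self.node_comp[record_active_node - 1])
        self.z_mm = centers - centers[self.drive_comp]

        self._tables: dict[float, tuple] = {}

    # -- rate tables -------------------------------------------------------

    _V0, _V1, _DV = -150.0, 350.0, 0.1

    def _rate_tables(self, dt_ms: float):
        key = round(dt_ms, 9)
        if key not in self._tables:
            v = np.arange(self._V0, self._V1 + self._DV / 2, self._DV)
            tabs = []
            for gate in ("m", "h", "n"):
                a, b = RATES[gate][0](v), RATES[gate][1](v)
                tot = a + b
                tabs += [a / tot, np.exp(-dt_ms * tot), a, b]
            self._tables[key] = tuple(np.ascontiguousarray(t) for t in tabs)
        return self._tables[key]

    # -- drive construction ------------------------------------------------

    def drive_from_pulses(self, pulses: PulseSequence, dt_ms: float,
                          duration_ms: float | None = None,
                          with_spread: bool = True,
                          own_electrode: int | None = None):
        """Sparse pulse list -> per-step (source, signed mA) drive arrays."""
        if duration_ms is None:
            duration_ms = pulses.duration_us * 1e-3
        n_steps = int(np.ceil(duration_ms / dt_ms))
        src = np.full(n_steps, -1, dtype=np.int64)
        amp = np.zeros(n_steps)
        dt_us = dt_ms * 1e3
        for onset_us, electrode, amplitude, phase_us, _pol in pulses.iter_pulses():
            if not with_spread and electrode != own_electrode:
                continue
            i0 = int(round(onset_us / dt_us))
            i1 = int(round((onset_us + phase_us) / dt_us))
            i2 = int(round((onset_us + 2 * phase_us) / dt_us))
            i2 = min(i2, n_steps)
            src[i0:i1] = electrode - 1
            amp[i0:i1] = -amplitude          # cathodic first
            src[i1:i2] = electrode - 1
            amp[i1:i2] = amplitude
        return src, amp

    def activation_matrix(self, att: np.ndarray) -> np.ndarray:
        """Per-source axial drive (pA per mA) from an attenuation matrix.

        ``att[src, comp]`` is exp(-d/lambda) for each compartment; the
        extracellular potential profile is ``rho_e * att`` (mV/mA) and the
        drive of compartment k is its discrete Laplacian weighted by the
        axial conductances.
        """
        ve = self.params.rho_e_ohm * att  # mV per mA
        ncomp = ve.shape[1]
        act = np.zeros_like(ve)
        ga = self.ga_lo_ns
        for k in range(ncomp):
            if k > 0:
                act[:, k] += ga[k] * (ve[:, k - 1] - ve[:, k])
            if k + 1 < ncomp:
                act[:, k] += ga[k + 1] * (ve[:, k + 1] - ve[:, k])
        return act

    # -- integration -------------------------------------------------------

    def run(self, drive_src: np.ndarray, drive_amp: np.ndarray,
            act: np.ndarray, *, dt_ms: float | None = None,
            seed: int = 0, noise_scale: float | None = None,
            store_stride: int = 0):
        """One stochastic repetition; returns spike times (ms) [and V trace].

        ``act`` is the activation matrix (see :meth:`activation_matrix`).
        Raises ``FloatingPointError`` if the state becomes non-finite.
        """
        p = self.params
        dt = dt_ms if dt_ms is not None else p.dt_us * 1e-3
        n_steps = len(drive_src)
        tabs = self._rate_tables(dt)
        ns = p.noise_scale if noise_scale is None else noise_scale
        noise_stride = max(1, int(round(p.noise_interval_us * 1e-3 / dt)))
        if ns > 0:
            rng = np.random.default_rng(seed)
            noise = rng.standard_normal(
                ((n_steps + noise_stride - 1) // noise_stride, 3 * self.n_nodes),
                dtype=np.float32)
        else:
            noise = np.zeros((0, 0), dtype=np.float32)
        if store_stride > 0:
            v_out = np.zeros((n_steps // store_stride + 1, len(self.c_pf)))
        else:
            v_out = np.zeros((1, len(self.c_pf)))
        spikes = run_cable(
            n_steps, dt,
            self.c_pf, self.g_leak_ns, self.e_leak_mv, self.ga_lo_ns,
            self.node_comp, self.gna_max_ns, self.gk_max_ns,
            p.e_na_mv, p.e_k_mv,
            *tabs,
            self._V0, self._DV,
            float(p.n_na), float(p.n_k), float(ns),
            drive_src, drive_amp, act,
            self.record_comp, p.spike_threshold_mv, p.spike_lockout_ms,
            noise, noise_stride,
            v_out, store_stride)
        if len(spikes) and not np.isfinite(spikes[0]):
            raise FloatingPointError(
                f"non-finite membrane state at record compartment {self.record_comp}")
        if store_stride > 0:
            return spikes, v_out
        return spikes


# ---------------------------------------------------------------------------
# spike trains and high-level simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpikeTrain:
    """Propagated-spike times (ms) of one fiber in one repetition."""

    times_ms: np.ndarray
    fiber: int = 1
    repetition: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.times_ms, dtype=float)
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("spike times must be strictly increasing")


def write_spike_trains(trains: Sequence[SpikeTrain], path: str | Path) -> None:
    rows = [(tr.fiber, tr.repetition, t) for tr in trains for t in tr.times_ms]
    pd.DataFrame(rows, columns=["fiber", "repetition", "time_ms"]).to_csv(
        path, index=False)


def read_spike_trains(path: str | Path) -> list[SpikeTrain]:
    df = pd.read_csv(path)
    out = []
    for (fiber, rep), grp in df.groupby(["fiber", "repetition"], sort=True):
        out.append(SpikeTrain(times_ms=np.sort(grp["time_ms"].to_numpy(float)),
                              fiber=int(fiber), repetition=int(rep)))
    return out


def rep_seed(master_seed: int, *stream: int) -> int:
    """Derive an independent 31-bit seed from a master seed and stream ids."""
    ss = np.random.SeedSequence([int(master_seed), *map(int, stream)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def simulate_fiber(model: FiberModel, pulses: PulseSequence,
                   layout: ArrayLayout, fiber_i: int,
                   n_reps: int = 30, seed: int = 0, *,
                   spread: CurrentSpreadModel = CurrentSpreadModel(),
                   with_spread: bool = True,
                   duration_ms: float | None = None,
                   dt_us: float | None = None) -> list[SpikeTrain]:
    """Run ``n_reps`` independent stochastic repetitions of one fiber.

    Each repetition is seeded from ``(seed, fiber_i, rep)`` so results are
    reproducible and independent across fibers and repetitions.
    """
    dt_ms = (dt_us if dt_us is not None else model.params.dt_us) * 1e-3
    att = layout.attenuation_matrix(fiber_i, model.z_mm, spread)
    act = model.activation_matrix(att)
    src, amp = model.drive_from_pulses(pulses, dt_ms, duration_ms,
                                       with_spread=with_spread,
                                       own_electrode=fiber_i)
    out = []
    for rep in range(n_reps):
        spikes = model.run(src, amp, act, dt_ms=dt_ms,
                           seed=rep_seed(seed, fiber_i, rep))
        out.append(SpikeTrain(times_ms=spikes, fiber=fiber_i, repetition=rep))
    return out


# ---------------------------------------------------------------------------
# single-pulse utilities and the two-pulse channel-interaction experiment
# ---------------------------------------------------------------------------


def pulse_train(level_ma: float, electrode: int, rate_pps: float = 900.0,
                duration_ms: float = 13.0, phase_us: float = 25.0) -> PulseSequence:
    """Constant-rate, constant-level biphasic pulse train on one electrode."""
    period_us = 1e6 / rate_pps
    onsets = np.arange(0.0, duration_ms * 1e3 - 2 * phase_us, period_us)
    return PulseSequence(onset_us=onsets,
                         electrode=np.full(len(onsets), electrode, dtype=int),
                         amplitude=np.full(len(onsets), level_ma),
                         phase_us=phase_us, polarity="cathodic-first",
                         duration_us=duration_ms * 1e3)


def single_pulse_sequence(level_ma: float, electrode: int = 2,
                          onset_ms: float = 0.3, phase_us: float = 25.0,
                          duration_ms: float = 3.0) -> PulseSequence:
    """One cathodic-first biphasic pulse on one electrode."""
    return PulseSequence(onset_us=np.array([onset_ms * 1e3]),
                         electrode=np.array([electrode]),
                         amplitude=np.array([level_ma]),
                         phase_us=phase_us, polarity="cathodic-first",
                         duration_us=duration_ms * 1e3)


def firing_efficiency(model: FiberModel, layout: ArrayLayout, level_ma: float,
                      n_reps: int = 100, seed: int = 0, *,
                      electrode: int = 2, fiber_i: int = 2,
                      dt_us: float | None = None) -> float:
    """Fraction of repetitions in which a single pulse evokes a spike."""
    pulses = single_pulse_sequence(level_ma, electrode=electrode)
    trains = simulate_fiber(model, pulses, layout, fiber_i, n_reps=n_reps,
                            seed=seed, dt_us=dt_us)
    return float(np.mean([len(tr.times_ms) > 0 for tr in trains]))


def find_single_pulse_level(model: FiberModel, layout: ArrayLayout,
                            target_fe: float = 0.9, n_reps: int = 100,
                            seed: int = 0, *, electrode: int = 2,
                            fiber_i: int = 2, dt_us: float | None = None,
                            lo_ma: float = 1e-4, hi_ma: float = 50.0,
                            iters: int = 12) -> float:
    """Bisection for the pulse level with the given firing efficiency."""
    fe_hi = firing_efficiency(model, layout, hi_ma, n_reps, seed,
                              electrode=electrode, fiber_i=fiber_i, dt_us=dt_us)
    if fe_hi < target_fe:
        raise RuntimeError(f"upper sweep level {hi_ma} mA below target "
                           f"firing efficiency (reached {fe_hi})")
    lo, hi = lo_ma, hi_ma
    for _ in range(iters):
        mid = np.sqrt(lo * hi)
        fe = firing_efficiency(model, layout, mid, n_reps, seed,
                               electrode=electrode, fiber_i=fiber_i, dt_us=dt_us)
        if fe < target_fe:
            lo = mid
        else:
            hi = mid
    return float(hi)


def two_pulse_experiment(distances_mm: Sequence[float],
                         params: FiberParams = FiberParams(),
                         n_reps: int = 100, seed: int = 0,
                         delay_us: float = 138.0,
                         target_fe: float = 0.9,
                         dt_us: float | None = None,
                         alpha: float = 0.05,
                         e1_scale: float = 1.0) -> pd.DataFrame:
    """Channel interaction between two neighboring basal electrodes.

    For each electrode-to-fiber distance: the pulse level is calibrated so
    that a single pulse from electrode 2 fires fiber 2 in ``target_fe`` of
    repetitions.  Two conditions are then run on fiber 2 — the E2 pulse
    alone, and an identical E1 pulse preceding it by ``delay_us`` — and
    spikes after the E2 onset are counted over ``n_reps`` repetitions.
    A Fisher exact test (threshold ``alpha``) classifies each distance as
    ``inhibited`` (E1+E2 < E2), ``facilitated`` (>) or ``neutral``.
    ``e1_scale`` scales the preceding pulse only (0 = null control).
    """
    from scipy.stats import fisher_exact

    e2_onset_ms = 0.3 + delay_us * 1e-3
    rows = []
    for d_i, dist in enumerate(distances_mm):
        layout = ArrayLayout(electrode_anf_distance_mm=dist)
        model = FiberModel(params)
        level = find_single_pulse_level(model, layout, target_fe=target_fe,
                                        n_reps=n_reps,
                                        seed=rep_seed(seed, d_i, 0),
                                        dt_us=dt_us)
        counts = {}
        first_pulse_spikes = 0
        for cond in ("e2_only", "e1_e2"):
            if cond == "e2_only":
                pulses = single_pulse_sequence(level, electrode=2,
                                               onset_ms=e2_onset_ms)
            else:
                pulses = PulseSequence(
                    onset_us=np.array([0.3e3, e2_onset_ms * 1e3]),
                    electrode=np.array([1, 2]),
                    amplitude=np.array([e1_scale * level, level]),
                    phase_us=25.0, polarity="cathodic-first",
                    duration_us=3e3)
            trains = simulate_fiber(model, pulses, layout, fiber_i=2,
                                    n_reps=n_reps,
                                    seed=rep_seed(seed, d_i, 1),
                                    dt_us=dt_us)
            n_resp = sum(np.any(tr.times_ms >= e2_onset_ms) for tr in trains)
            counts[cond] = int(n_resp)
            if cond == "e1_e2":
                first_pulse_spikes = int(sum(
                    np.any(tr.times_ms < e2_onset_ms) for tr in trains))
        table = [[counts["e1_e2"], n_reps - counts["e1_e2"]],
                 [counts["e2_only"], n_reps - counts["e2_only"]]]
        if counts["e1_e2"] < counts["e2_only"]:
            p = fisher_exact(table, alternative="less").pvalue
            label = "inhibited" if p < alpha else "neutral"
        elif counts["e1_e2"] > counts["e2_only"]:
            p = fisher_exact(table, alternative="greater").pvalue
            label = "facilitated" if p < alpha else "neutral"
        else:
            p, label = 1.0, "neutral"
        rows.append({"distance_mm": dist, "level_ma": level,
                     "e2_only": counts["e2_only"], "e1_e2": counts["e1_e2"],
                     "first_pulse_spikes": first_pulse_spikes,
                     "p_value": float(p), "classification": label,
                     "n_reps": n_reps})
    return pd.DataFrame(rows)
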