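"""Rippled-noise stimulus synthesis.

Spectral-ripple discrimination (SRD) stimuli are broadband noises built by
summing pure tones (default 200 components, 100–5,000 Hz) with independent
random phases.  The power spectrum follows a full-wave-rectified sinusoidal
envelope on a log2 frequency axis with a fixed peak-to-valley depth
(default 30 dB).  Two variants exist per ripple density: *standard*
(envelope phase 0) and *inverted* (phase shifted by pi/2, which for the
period-pi rectified envelope interchanges peaks and valleys).  Listeners —
or, here, the model — discriminate the two variants; higher ripple
densities (peaks per octave) make the task harder.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from enum import Enum
from pathlib import Path

import numpy as np
from scipy.io import wavfile


class PhaseVariant(str, Enum):
    """Envelope phase of the rippled noise: standard (0) or inverted (pi/2)."""

    STANDARD = "standard"
    INVERTED = "inverted"


@dataclass(frozen=True)
class RippleParams:
    """Parameters of one rippled-noise stimulus.

    Parameters
    ----------
    density:
        Ripple density in ripples per octave (r/o).  The reference
        conditions are 1.0, 2.0 and 4.0 r/o; any positive value is valid.
    phase_variant:
        ``standard`` or ``inverted``.
    n_components:
        Number of pure-tone components summed (log-spaced in frequency).
    f_lo, f_hi:
        Frequency span of the components in Hz.
    peak_to_valley_db:
        Depth of the spectral ripple, in dB of *power*.
    duration_ms, ramp_ms:
        Total duration and raised-cosine rise/fall time, in ms.
    sample_rate:
        Output sample rate in Hz (>= 4 x f_hi by default).
    seed:
        Seed for the component phases.  The same seed produces the same
        phases for the standard and inverted variants, so the two stimuli
        differ only in their spectral envelope.
    rms:
        Target root-mean-square amplitude of the plateau (arbitrary
        pressure units); the waveform is normalized to this value.
    """

    density: float = 1.0
    phase_variant: PhaseVariant = PhaseVariant.STANDARD
    n_components: int = 200
    f_lo: float = 100.0
    f_hi: float = 5000.0
    peak_to_valley_db: float = 30.0
    duration_ms: float = 200.0
    ramp_ms: float = 50.0
    sample_rate: float = 20000.0
    seed: int = 0
    rms: float = 0.1

    def __post_init__(self) -> None:
        if not self.f_lo < self.f_hi:
            raise ValueError(f"f_lo ({self.f_lo}) must be < f_hi ({self.f_hi})")
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.peak_to_valley_db < 0:
            raise ValueError("peak_to_valley_db must be >= 0")
        if 2 * self.ramp_ms > self.duration_ms:
            raise ValueError("2*ramp_ms must not exceed duration_ms")
        if self.n_components < 2:
            raise ValueError("need at least 2 tone components")
        if self.sample_rate < 2 * self.f_hi:
            raise ValueError("sample_rate below Nyquist for f_hi")
        if isinstance(self.phase_variant, str) and not isinstance(self.phase_variant, PhaseVariant):
            object.__setattr__(self, "phase_variant", PhaseVariant(self.phase_variant))

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_ms * self.sample_rate / 1000.0))

    def inverted(self) -> "RippleParams":
        """The complementary variant with identical seed and spectrum shape."""
        other = (PhaseVariant.INVERTED if self.phase_variant == PhaseVariant.STANDARD
                 else PhaseVariant.STANDARD)
        return replace(self, phase_variant=other)


@dataclass(frozen=True)
class RippleStimulus:
    """A synthesized rippled-noise waveform plus its generating parameters."""

    samples: np.ndarray
    params: RippleParams

    def __post_init__(self) -> None:
        if len(self.samples) != self.params.n_samples:
            raise ValueError("sample count inconsistent with params")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("non-finite samples")


def envelope_db(frequency_hz, params: RippleParams):
    """Spectral power envelope in dB above the ripple valley.

    The envelope is a full-wave-rectified sinusoid on a log2 frequency
    axis with ``params.density`` peaks per octave::

        env_dB(f) = depth * |sin(pi * density * log2(f / f_lo) + phi)|

    with ``phi = 0`` for the standard variant and ``pi/2`` for the
    inverted one, so the two variants interchange peaks and valleys.
    Accepts scalars or arrays; returns values in ``[0, depth]``.
    """
    f = np.asarray(frequency_hz, dtype=float)
    if np.any(f < params.f_lo) or np.any(f > params.f_hi):
        raise ValueError(f"frequency outside [{params.f_lo}, {params.f_hi}] Hz")
    phi = 0.0 if params.phase_variant == PhaseVariant.STANDARD else np.pi / 2
    env = params.peak_to_valley_db * np.abs(
        np.sin(np.pi * params.density * np.log2(f / params.f_lo) + phi)
    )
    return env if env.ndim else float(env)


def component_frequencies(params: RippleParams) -> np.ndarray:
    """Log-spaced tone frequencies spanning [f_lo, f_hi]."""
    return np.geomspace(params.f_lo, params.f_hi, params.n_components)


def _ramp_window(n: int, ramp_samples: int) -> np.ndarray:
    """Raised-cosine rise/fall window; endpoints are exactly zero."""
    w = np.ones(n)
    if ramp_samples > 0:
        t = np.arange(ramp_samples) / ramp_samples
        rise = 0.5 * (1.0 - np.cos(np.pi * t))
        w[:ramp_samples] = rise
        w[n - ramp_samples:] = rise[::-1]
    return w


def generate_rippled_noise(params: RippleParams) -> RippleStimulus:
    """Synthesize a rippled-noise stimulus.

    Sums ``n_components`` log-spaced pure tones with seeded uniform random
    phases; component *power* is set by :func:`envelope_db`, i.e. the
    amplitude of the tone at frequency f is ``10**(env_dB(f)/20)`` (up to
    overall RMS normalization).  A raised-cosine ramp of ``ramp_ms`` is
    applied at onset and offset.  Identical seeds give identical component
    phases across the standard/inverted variants.
    """
    n = params.n_samples
    t = np.arange(n) / params.sample_rate
    freqs = component_frequencies(params)
    amps = 10.0 ** (envelope_db(freqs, params) / 20.0)
    rng = np.random.default_rng(params.seed)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=params.n_components)
    x = (amps[:, None] * np.sin(2.0 * np.pi * freqs[:, None] * t[None, :]
                                + phases[:, None])).sum(axis=0)
    # normalize the un-ramped waveform to the documented plateau RMS
    x *= params.rms / np.sqrt(np.mean(x ** 2))
    ramp_samples = int(round(params.ramp_ms * params.sample_rate / 1000.0))
    x *= _ramp_window(n, ramp_samples)
    return RippleStimulus(samples=x, params=params)


def write_wav(stimulus: RippleStimulus, path: str | Path, *, sidecar: bool = True) -> None:
    """Write a mono PCM16 WAV plus a JSON sidecar with the parameters."""
    path = Path(path)
    x = stimulus.samples
    peak = np.max(np.abs(x))
    scale = 0.0 if peak == 0 else 0.9 / peak
    pcm = np.round(x * scale * 32767).astype(np.int16)
    wavfile.write(path, int(stimulus.params.sample_rate), pcm)
    if sidecar:
        rec = asdict(stimulus.params)
        rec["phase_variant"] = stimulus.params.phase_variant.value
        path.with_suffix(".json").write_text(json.dumps(rec, indent=2))


def read_wav(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a mono WAV back as float samples in [-1, 1] and its sample rate."""
    rate, data = wavfile.read(Path(path))
    if data.dtype == np.int16:
        data = data.astype(float) / 32767.0
    return data, float(rate)
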