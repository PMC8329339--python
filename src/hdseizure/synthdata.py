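"""Seeded synthetic multichannel iEEG-like recordings with labeled seizures.

The generator emulates the statistical structure the detector consumes,
not biophysics.  Background activity on every channel is AR(2) colored
noise (coefficients 1.5, −0.55: a stable low-pass pair of poles at ~0.86
and ~0.64) — colored rather than white so that the order-relation symbol
distribution is non-uniform even interictally, as in real field
potentials.  During each labeled seizure interval, a subset of channels
(the "onset zone", by default the first quarter) additionally carries a
frequency-modulated oscillation inside a 4–12 Hz band whose RMS is a fixed
multiple (default 3.0) of that channel's background RMS, with a linear
amplitude ramp-in at onset.  Everything is a pure function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .symbolize import Recording

#: AR(2) background coefficients: x_t = a1 x_{t-1} + a2 x_{t-2} + eps_t.
AR_COEFFS = (1.5, -0.55)


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic recording."""

    duration_s: float
    n_channels: int = 60
    fs: float = 512.0
    seizures: tuple = ()  # ((onset_s, offset_s), ...)
    ictal_channels: tuple | None = None  # default: first quarter of channels
    f_band: tuple = (4.0, 12.0)  # Hz, ictal rhythm band
    amp_ratio: float = 3.0  # ictal rhythm RMS / background RMS
    ramp_s: float = 2.0  # linear amplitude ramp-in at seizure onset
    seed: int = 0

    def __post_init__(self):
        if self.duration_s <= 0 or self.fs <= 0 or self.n_channels < 1:
            raise ValueError("duration, fs and n_channels must be positive")
        if self.amp_ratio <= 0 or self.ramp_s < 0:
            raise ValueError("amp_ratio must be positive and ramp_s non-negative")
        if not 0 < self.f_band[0] < self.f_band[1] < self.fs / 2:
            raise ValueError(f"ictal band {self.f_band} must lie inside (0, fs/2)")
        for on, off in self.seizures:
            if not 0 <= on < off <= self.duration_s:
                raise ValueError(f"seizure interval ({on}, {off}) outside recording")
        if self.ictal_channels is None:
            object.__setattr__(self, "ictal_channels",
                               tuple(range(max(1, self.n_channels // 4))))
        if not set(self.ictal_channels) <= set(range(self.n_channels)):
            raise ValueError("ictal_channels must be a subset of the channels")


def generate(cfg: SynthConfig) -> tuple[Recording, list[tuple[float, float]]]:
    """Generate one labeled recording; bit-reproducible for a fixed config."""
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    a1, a2 = AR_COEFFS
    x = lfilter([1.0], [1.0, -a1, -a2],
                rng.standard_normal((cfg.n_channels, n)), axis=1)
    bg_rms = np.sqrt(np.mean(x ** 2, axis=1, keepdims=True))

    t = np.arange(n) / cfg.fs
    lo, hi = cfg.f_band
    ict = np.asarray(cfg.ictal_channels, dtype=int)
    for on, off in cfg.seizures:
        # rhythm frequency wanders sinusoidally around the band center,
        # staying strictly inside [lo, hi]; independent phase per channel
        f0, bw = (lo + hi) / 2.0, (hi - lo) / 2.0
        f_mod = rng.uniform(0.05, 0.2)
        f_inst = f0 + 0.9 * bw * np.sin(2 * np.pi * f_mod * t + rng.uniform(0, 2 * np.pi))
        phase = 2 * np.pi * np.cumsum(f_inst) / cfg.fs
        i0, i1 = int(round(on * cfg.fs)), int(round(off * cfg.fs))
        gate = np.zeros(n)
        gate[i0:i1] = 1.0
        if cfg.ramp_s > 0:
            nr = min(int(round(cfg.ramp_s * cfg.fs)), i1 - i0)
            gate[i0:i0 + nr] = np.linspace(0.0, 1.0, nr, endpoint=False)
        amp = cfg.amp_ratio * bg_rms[ict] * np.sqrt(2.0)  # sine RMS = amp/sqrt(2)
        phases0 = rng.uniform(0, 2 * np.pi, size=len(ict))[:, None]
        x[ict] += amp * gate[None, :] * np.sin(phase[None, :] + phases0)

    rec = Recording(x, fs=cfg.fs)
    labels = [(float(on), float(off)) for on, off in cfg.seizures]
    return rec, labels
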