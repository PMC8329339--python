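"""Order-relation symbolization of multichannel recordings.

Each window of ``L`` consecutive samples is reduced to the pattern of
``L-1`` order relations between neighbors: bit ``b_j = 1`` iff
``x[j+1] >= x[j]`` (equality counts as >=, so flat digitized segments map
to the all-ones pattern).  The bits, read most-significant-first, form a
symbol index in ``[0, 2**(L-1))``.  Symbolization slides this window with
stride 1 (maximal overlap), so ``T`` samples yield ``T - L + 1`` symbols
per channel.

Order relations discard all amplitude information: any positive affine
rescaling of a channel leaves its symbol sequence unchanged.  With the
default ``L = 9`` the alphabet has 2**8 = 256 symbols.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DEFAULT_L = 9
DEFAULT_FS = 512.0


@dataclass(frozen=True)
class Recording:
    """A channels x samples matrix of amplitudes (microvolts) at rate ``fs``."""

    samples: np.ndarray
    fs: float = DEFAULT_FS
    channel_labels: list[str] | None = None

    def __post_init__(self):
        s = np.asarray(self.samples, dtype=np.float64)
        if s.ndim != 2:
            raise ValueError(f"samples must be channels x time (2-D), got shape {s.shape}")
        if not np.isfinite(s).all():
            raise ValueError("recording contains NaN or infinite samples")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        object.__setattr__(self, "samples", s)
        if self.channel_labels is None:
            object.__setattr__(
                self, "channel_labels",
                [f"ch{i+1:02d}" for i in range(s.shape[0])])
        elif len(self.channel_labels) != s.shape[0]:
            raise ValueError("channel_labels length does not match channel count")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class SymbolFrame:
    """Per-channel, per-timestep symbol indices; column ``t`` is aligned with
    the *first* sample of its length-``L`` pattern."""

    symbols: np.ndarray  # channels x (T - L + 1), integer
    L: int
    t0_alignment: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        sym = np.asarray(self.symbols)
        if sym.ndim != 2:
            raise ValueError("symbols must be 2-D (channels x steps)")
        if sym.size and (sym.min() < 0 or sym.max() >= 2 ** (self.L - 1)):
            raise ValueError(f"symbol index out of range for L={self.L}")
        object.__setattr__(self, "symbols", sym)
        if self.t0_alignment is None:
            object.__setattr__(self, "t0_alignment", np.arange(sym.shape[1]))

    @property
    def n_channels(self) -> int:
        return self.symbols.shape[0]

    @property
    def n_steps(self) -> int:
        return self.symbols.shape[1]


def order_pattern(window: np.ndarray) -> int:
    """Symbol index of one length-``L`` amplitude window.

    ``[1., 2., 3.]`` -> bits (1,1) -> 3; ``[3., 2., 1.]`` -> bits (0,0) -> 0.
    """
    w = np.asarray(window, dtype=np.float64)
    if w.ndim != 1 or w.size < 2:
        raise ValueError(f"window must be 1-D with length L >= 2, got shape {w.shape}")
    bits = (w[1:] >= w[:-1]).astype(np.int64)
    weights = 1 << np.arange(bits.size - 1, -1, -1)
    return int(bits @ weights)


def symbolize(rec: Recording, L: int = DEFAULT_L) -> SymbolFrame:
    """Stride-1 symbolization of every channel of ``rec``.

    Raises if the recording is shorter than one pattern (``T < L``).
    """
    if L < 2:
        raise ValueError(f"pattern length L must be >= 2, got {L}")
    x = rec.samples
    T = x.shape[1]
    if T < L:
        raise ValueError(f"recording has {T} samples, need at least L={L}")
    ge = (x[:, 1:] >= x[:, :-1]).astype(np.int64)  # channels x (T-1)
    windows = sliding_window_view(ge, L - 1, axis=1)  # channels x (T-L+1) x (L-1)
    weights = 1 << np.arange(L - 2, -1, -1)
    symbols = windows @ weights
    return SymbolFrame(symbols=symbols, L=L)
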