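"""Spatial and spatiotemporal encoding, and one-shot prototype learning.

At one timestep the per-channel symbols are fused into a single *spatial
composite* ``S = [C_s1 ⊕ E_1 + C_s2 ⊕ E_2 + ...]``: each channel's symbol
vector is bound (XOR) to that channel's electrode vector, and the bound
pairs are bundled (majority).  Because XOR is self-inverse, binding ``E_i``
back onto ``S`` yields a noisy copy of channel *i*'s symbol vector, which
nearest-neighbor cleanup recovers — the composite is queryable.

Sliding the spatial encoding over every timestep of a window and bundling
the resulting ``S_t`` gives one *spatiotemporal composite* ``ST`` per
window.  A brain-state prototype is simply the bundle of the ``ST`` vectors
from a reference period: ``P = [ST_1 + ... + ST_k]``.  Learning is a single
pass — no iteration, no gradients — and classification encodes query
windows through exactly the same code path
(:func:`spatiotemporal_encode`) used for learning.

Performance: the hot loop (gather symbol vector, XOR electrode vector,
accumulate per-bit counts) runs through a numba JIT kernel when numba is
importable, with a bit-identical pure-numpy fallback
(:func:`_spatial_counts_numpy`) kept both as a safety net and as the
reference implementation in tests.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .hdcore import Hypervector, majority_from_counts
from .itemmemory import ItemMemory, cleanup
from .symbolize import Recording, SymbolFrame, symbolize

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    @njit(cache=True)
    def _spatial_counts_kernel(C, E, sym, out):  # (n_sym,D),(n_el,D),(n_el,n_t),(n_t,D)
        n_elec, n_t = sym.shape
        D = C.shape[1]
        for t in range(n_t):
            o = out[t]
            for i in range(n_elec):
                c = C[sym[i, t]]
                e = E[i]
                for d in range(D):
                    o[d] += c[d] ^ e[d]

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _spatial_counts_numpy(C: np.ndarray, E: np.ndarray, sym: np.ndarray) -> np.ndarray:
    """Per-timestep, per-bit counts of 1s among the bound vectors C[sym] ^ E.

    Reference implementation; returns an (n_t, D) uint16 array.
    """
    n_elec, n_t = sym.shape
    out = np.zeros((n_t, D := C.shape[1]), dtype=np.uint16)
    for i in range(n_elec):
        out += np.bitwise_xor(C[sym[i]], E[i])
    return out


def _spatial_counts(im: ItemMemory, sym: np.ndarray) -> np.ndarray:
    sym = np.ascontiguousarray(sym, dtype=np.int64)
    if _HAVE_NUMBA:
        out = np.zeros((sym.shape[1], im.D), dtype=np.uint16)
        _spatial_counts_kernel(im.symbol_vectors, im.electrode_vectors, sym, out)
        return out
    return _spatial_counts_numpy(im.symbol_vectors, im.electrode_vectors, sym)


def _check_column(col: np.ndarray, im: ItemMemory) -> np.ndarray:
    col = np.asarray(col)
    if col.shape != (im.n_electrodes,):
        raise ValueError(
            f"expected one symbol per electrode ({im.n_electrodes}), got shape {col.shape}"
        )
    if col.size and (col.min() < 0 or col.max() >= im.n_symbols):
        raise ValueError(f"symbol index out of range [0, {im.n_symbols})")
    return col.astype(np.int64)


def spatial_encode(frame_column: np.ndarray, im: ItemMemory,
                   rng: np.random.Generator | None = None) -> Hypervector:
    """Encode one timestep: bundle over channels i of bind(C_sym[i], E_i)."""
    col = _check_column(frame_column, im)
    counts = _spatial_counts(im, col[:, None])[0].astype(np.int64)
    return majority_from_counts(counts, im.n_electrodes, rng)


def unbind_query(S: Hypervector, electrode_index: int,
                 im: ItemMemory) -> tuple[int, float]:
    """Which symbol did electrode ``electrode_index`` contribute to ``S``?

    Binds ``E_i`` onto the composite (XOR is self-inverse) and cleans the
    noisy result up against the symbol store.  Returns (symbol index,
    residual distance).
    """
    if not 0 <= electrode_index < im.n_electrodes:
        raise ValueError(f"electrode index {electrode_index} not in item memory")
    noisy = np.bitwise_xor(np.asarray(S, dtype=np.uint8),
                           im.electrode_vectors[electrode_index])
    return cleanup(noisy, im.symbol_vectors)


def spatiotemporal_encode(frame: SymbolFrame | np.ndarray, im: ItemMemory,
                          rng: np.random.Generator | None = None) -> Hypervector:
    """Encode a window: ST = bundle over t of the spatial composites S_t."""
    sym = frame.symbols if isinstance(frame, SymbolFrame) else np.asarray(frame)
    if sym.ndim != 2 or sym.shape[1] < 1:
        raise ValueError("window must contain at least one symbol column")
    if sym.shape[0] != im.n_electrodes:
        raise ValueError(
            f"window has {sym.shape[0]} channels but item memory has "
            f"{im.n_electrodes} electrode vectors")
    n_elec, n_t = sym.shape
    counts = _spatial_counts(im, sym)
    S = _majority_matrix(counts, n_elec, rng)  # one S_t per row
    return majority_from_counts(S.sum(axis=0, dtype=np.int64), n_t, rng)


def _majority_matrix(counts: np.ndarray, n: int,
                     rng: np.random.Generator | None) -> np.ndarray:
    """Row-wise majority of per-bit 1-counts from ``n`` vectors.

    Same semantics as :func:`hdseizure.hdcore.majority_from_counts`, with
    tie coins drawn in one call in row-major (timestep, then bit) order.
    """
    c2 = counts.astype(np.uint16) << 1  # n <= 2**15 vectors
    if n % 2 == 0 and bool((c2 == n).any()):
        if rng is None:
            raise ValueError("even-count bundle ties require a seeded rng")
        coins = rng.integers(0, 2, size=c2.shape, dtype=np.uint16)
        return (c2 + coins > n).astype(np.uint8)
    return (c2 > n).astype(np.uint8)


@dataclass(frozen=True)
class Prototype:
    """A brain-state prototype: the bundle of a reference period's ST vectors."""

    vector: Hypervector = field(repr=False)
    state_label: str  # "interictal" | "ictal"
    n_windows_bundled: int
    fingerprint: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_windows_bundled < 1:
            raise ValueError("a prototype bundles at least one window")

    @property
    def D(self) -> int:
        return self.vector.shape[0]


def learn_prototype(windows: list, state_label: str, im: ItemMemory,
                    rng: np.random.Generator | None = None,
                    fingerprint: dict | None = None) -> Prototype:
    """One-shot learning: bundle the ST vectors of ``windows`` into a prototype.

    ``windows`` is a list of symbol windows (SymbolFrame or channels x steps
    arrays); a single pass over them, nothing iterative.
    """
    if len(windows) < 1:
        raise ValueError("cannot learn a prototype from zero windows")
    sts = np.stack([spatiotemporal_encode(w, im, rng) for w in windows])
    k = len(windows)
    vec = majority_from_counts(sts.sum(axis=0, dtype=np.int64), k, rng)
    return Prototype(vector=vec, state_label=state_label, n_windows_bundled=k,
                     fingerprint=dict(fingerprint or {}))


def window_starts(n_samples: int, fs: float, window_s: float,
                  stride_s: float) -> np.ndarray:
    """Start samples of every full window of ``window_s`` at stride ``stride_s``."""
    wlen = int(round(window_s * fs))
    step = int(round(stride_s * fs))
    if wlen < 2 or step < 1:
        raise ValueError("window and stride must span at least 2 and 1 samples")
    return np.arange(0, n_samples - wlen + 1, step)


def encode_recording(rec: Recording, im: ItemMemory, *, window_s: float = 1.0,
                     stride_s: float = 1.0, tie_seed: int = 0,
                     t_offset_s: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Window ``rec`` and encode each window to one ST vector.

    Windows are symbolized independently (patterns never straddle window
    boundaries).  The tie-break RNG of window ``w`` is seeded from
    ``(tie_seed, w)`` so a re-run over the same recording is
    bit-reproducible regardless of which windows were encoded before.

    Returns ``(times, sts)``: window start times in seconds (shifted by
    ``t_offset_s``) and an ``(n_windows, D)`` array of ST vectors.
    """
    starts = window_starts(rec.n_samples, rec.fs, window_s, stride_s)
    wlen = int(round(window_s * rec.fs))
    sts = np.empty((len(starts), im.D), dtype=np.uint8)
    for w, s0 in enumerate(starts):
        sub = Recording(rec.samples[:, s0:s0 + wlen], fs=rec.fs,
                        channel_labels=rec.channel_labels)
        frame = symbolize(sub, im.L)
        rng = np.random.default_rng([tie_seed, w])
        sts[w] = spatiotemporal_encode(frame, im, rng)
    times = starts / rec.fs + t_offset_s
    return times, sts


def learn_prototypes_from_intervals(
        rec: Recording, im: ItemMemory, *, interictal_ref: tuple[float, float],
        ictal_ref: tuple[float, float], window_s: float = 1.0,
        tie_seed: int = 0) -> tuple[Prototype, Prototype]:
    """Learn (P_int, P_ict) from two reference intervals of one recording.

    Each reference period is split into non-overlapping ``window_s`` windows
    (30 s at 1 s -> k = 30 bundled ST vectors per prototype).
    """
    protos = []
    for label, (a, b) in (("interictal", interictal_ref), ("ictal", ictal_ref)):
        i0, i1 = int(round(a * rec.fs)), int(round(b * rec.fs))
        if not 0 <= i0 < i1 <= rec.n_samples:
            raise ValueError(f"{label} reference {a, b} outside the recording")
        sub = Recording(rec.samples[:, i0:i1], fs=rec.fs)
        _, sts = encode_recording(sub, im, window_s=window_s, stride_s=window_s,
                                  tie_seed=tie_seed)
        k = len(sts)
        rng = np.random.default_rng([tie_seed, 10_000_019 + len(protos)])
        vec = majority_from_counts(sts.sum(axis=0, dtype=np.int64), k, rng)
        fp = {"D": im.D, "L": im.L, "im_seed": im.seed, "window_s": window_s,
              "tie_seed": tie_seed}
        protos.append(Prototype(vector=vec, state_label=label,
                                n_windows_bundled=k, fingerprint=fp))
    return protos[0], protos[1]


# ---------------------------------------------------------------------------
# Prototype serialization: 16-byte magic, little-endian uint32 header length,
# JSON header, then the bit payload packed 8 bits/byte (big-endian within
# each byte, numpy packbits default).

_MAGIC = b"HDSEIZPROTO\x00v01\x00"
assert len(_MAGIC) == 16


def save_prototype(proto: Prototype, path: str | Path) -> None:
    header = json.dumps({
        "state_label": proto.state_label,
        "D": proto.D,
        "n_windows_bundled": proto.n_windows_bundled,
        "fingerprint": proto.fingerprint,
    }).encode()
    payload = np.packbits(proto.vector).tobytes()
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<I", len(header)))
        fh.write(header)
        fh.write(payload)


def load_prototype(path: str | Path) -> Prototype:
    raw = Path(path).read_bytes()
    if raw[:16] != _MAGIC:
        raise ValueError(f"{path}: not a prototype file (bad magic)")
    (hlen,) = struct.unpack("<I", raw[16:20])
    meta = json.loads(raw[20:20 + hlen].decode())
    bits = np.unpackbits(np.frombuffer(raw[20 + hlen:], dtype=np.uint8))[:meta["D"]]
    return Prototype(vector=bits.astype(np.uint8), state_label=meta["state_label"],
                     n_windows_bundled=meta["n_windows_bundled"],
                     fingerprint=meta["fingerprint"])
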