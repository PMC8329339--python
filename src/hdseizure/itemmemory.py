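"""Item memory: the fixed store of atomic symbol and electrode hypervectors.

The item memory holds one random hypervector per order-relation symbol
(``2**(L-1)`` of them for pattern length ``L``) and one per electrode.  In
the clinical-scale configuration (L=9, 60 electrodes) that is 256 + 60 = 316
vectors.  All vectors are drawn i.i.d. from a single seeded stream —
symbols first, then electrodes — so the whole memory is reproducible from
``(L, n_electrodes, D, seed)`` alone, which is also exactly what gets
serialized.  The memory is immutable: it stays unchanged during both
learning and classification.

Querying is nearest-neighbor *cleanup*: a noisy hypervector is compared
against every stored vector and the closest one (by normalized Hamming
distance) wins.  Because stored vectors are mutually quasi-orthogonal
(pairwise distance ~0.5 at D=10,000), cleanup tolerates large fractions of
flipped bits — recovery is still essentially perfect at 30% flips and
beyond — before it collapses to chance at 50%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .hdcore import DEFAULT_D, Hypervector, random_hvs


@dataclass(frozen=True)
class ItemMemory:
    """Immutable store of symbol vectors ``C_i`` and electrode vectors ``E_j``."""

    L: int
    n_electrodes: int
    D: int
    seed: int
    symbol_vectors: np.ndarray = field(repr=False)
    electrode_vectors: np.ndarray = field(repr=False)

    @property
    def n_symbols(self) -> int:
        return self.symbol_vectors.shape[0]

    @property
    def size(self) -> int:
        """Total number of stored vectors, ``2**(L-1) + n_electrodes``."""
        return self.n_symbols + self.n_electrodes


def build_item_memory(L: int, n_electrodes: int, D: int = DEFAULT_D,
                      seed: int = 0) -> ItemMemory:
    """Construct an item memory of ``2**(L-1)`` symbol and ``n_electrodes``
    electrode vectors, deterministically from ``seed``.

    ``L`` is the order-pattern length in samples; ``L >= 2`` because a
    single sample defines no order relation.
    """
    if L < 2:
        raise ValueError(f"pattern length L must be >= 2 (got {L}): "
                         "no order relation is definable from one sample")
    if n_electrodes < 1:
        raise ValueError(f"need at least one electrode, got {n_electrodes}")
    n_symbols = 2 ** (L - 1)
    rng = np.random.default_rng(seed)
    # One stream, symbols first then electrodes: the memory is a pure
    # function of (L, n_electrodes, D, seed).
    symbols = random_hvs(n_symbols, D, rng)
    electrodes = random_hvs(n_electrodes, D, rng)
    return ItemMemory(L=L, n_electrodes=n_electrodes, D=D, seed=seed,
                      symbol_vectors=symbols, electrode_vectors=electrodes)


def cleanup(query: Hypervector, store: np.ndarray) -> tuple[int, float]:
    """Return ``(index, distance)`` of the stored vector nearest to ``query``.

    Distance ties are broken toward the smallest index, so cleanup — and
    everything classified through it — is deterministic given the memory.
    """
    query = np.asarray(query, dtype=np.uint8)
    labels, dists = cleanup_batch(query[None, :], store)
    return int(labels[0]), float(dists[0])


def cleanup_batch(queries: np.ndarray, store: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized cleanup of ``(n, D)`` queries against an ``(m, D)`` store.

    Hamming distances are computed through a float32 matmul
    (``|q - s|_H = sum(q) + sum(s) - 2 q.s``), which turns the all-pairs
    comparison into one BLAS call; argmin per row returns the first (i.e.
    smallest-index) minimizer.
    """
    queries = np.atleast_2d(np.asarray(queries, dtype=np.uint8))
    store = np.asarray(store, dtype=np.uint8)
    if store.ndim != 2 or store.shape[0] < 1:
        raise ValueError("store must be a non-empty (m, D) array")
    if queries.shape[1] != store.shape[1]:
        raise ValueError(
            f"dimension mismatch: query D={queries.shape[1]} vs store D={store.shape[1]}"
        )
    q = queries.astype(np.float32)
    s = store.astype(np.float32)
    ham = q.sum(axis=1, keepdims=True) + s.sum(axis=1)[None, :] - 2.0 * (q @ s.T)
    labels = ham.argmin(axis=1)
    dists = ham[np.arange(len(labels)), labels] / store.shape[1]
    # matmul in float32 is exact here (counts are small integers), but
    # guard against negative rounding residue all the same
    return labels, np.maximum(dists, 0.0)


def flip_bits(vectors: np.ndarray, flip_fraction: float,
              rng: np.random.Generator) -> np.ndarray:
    """Flip exactly ``round(flip_fraction * D)`` bits of each row, uniformly
    at random and independently per row."""
    vectors = np.atleast_2d(np.asarray(vectors, dtype=np.uint8)).copy()
    n, D = vectors.shape
    k = int(round(flip_fraction * D))
    if k == 0:
        return vectors
    # first k columns of a random permutation per row
    positions = rng.random((n, D)).argsort(axis=1)[:, :k]
    vectors[np.arange(n)[:, None], positions] ^= 1
    return vectors


def recovery_rate(store: np.ndarray, flip_fraction: float, n_trials: int,
                  rng: np.random.Generator) -> float:
    """Fraction of trials in which cleanup still returns the true item after
    ``flip_fraction`` of its bits are flipped uniformly at random."""
    store = np.asarray(store, dtype=np.uint8)
    truth = rng.integers(0, store.shape[0], size=n_trials)
    queries = flip_bits(store[truth], flip_fraction, rng)
    labels, _ = cleanup_batch(queries, store)
    return float((labels == truth).mean())


def save_item_memory(im: ItemMemory, path: str | Path) -> None:
    """Persist an item memory as its four defining parameters (JSON).

    Vectors are never stored — they are regenerated bit-identically by
    :func:`build_item_memory` on load.
    """
    spec = {"L": im.L, "n_electrodes": im.n_electrodes, "D": im.D, "seed": im.seed}
    Path(path).write_text(json.dumps(spec) + "\n")


def load_item_memory(path: str | Path) -> ItemMemory:
    spec = json.loads(Path(path).read_text())
    return build_item_memory(spec["L"], spec["n_electrodes"], spec["D"], spec["seed"])
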