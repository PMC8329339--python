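"""Dense binary hypervector algebra.

A *hypervector* is a 1-D :class:`numpy.ndarray` of dtype ``uint8`` whose
components are all 0 or 1.  The dimension ``D`` (default 10,000) is high
enough that independently drawn vectors are quasi-orthogonal: their
normalized Hamming distance concentrates tightly around 0.5, which is what
makes the symbolic manipulations downstream robust to noise.

Three operations manipulate hypervectors:

``bind``
    componentwise XOR.  The result is quasi-orthogonal to both inputs,
    commutative, associative, self-inverse (``bind(A, A)`` is the zero
    vector) — so binding also *unbinds*.
``bundle``
    componentwise majority vote.  The result is *similar* to every input
    (for three random inputs the expected distance to each is 0.25), which
    is what turns a set of vectors into a prototype.  Exact ties (even
    input counts) are broken by independent fair coins drawn from an
    explicit RNG so that every run is reproducible.
``permute``
    circular shift of the components; a distance-preserving bijection used
    to encode sequence position (provided as a core operation; the default
    seizure encoder does not use it).

Distances are measured with :func:`nhd`, the normalized Hamming distance.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np

#: Default hypervector dimension.
DEFAULT_D = 10_000

#: A hypervector is a 1-D uint8 array of 0/1 components.
Hypervector = np.ndarray


def _check_hv(a: np.ndarray, name: str = "vector") -> np.ndarray:
    a = np.asarray(a)
    if a.ndim != 1:
        raise ValueError(f"{name} must be 1-D, got shape {a.shape}")
    if a.size < 1:
        raise ValueError(f"{name} must have positive length")
    return a


def _check_same_d(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape[0] != b.shape[0]:
        raise ValueError(
            f"dimension mismatch: D={a.shape[0]} vs D={b.shape[0]}"
        )


def _freeze(a: np.ndarray) -> np.ndarray:
    a.flags.writeable = False
    return a


def random_hv(D: int = DEFAULT_D, rng: np.random.Generator | None = None) -> Hypervector:
    """Draw one dense binary hypervector with i.i.d. fair-coin components.

    Parameters
    ----------
    D
        Dimension, must be >= 1.
    rng
        A seeded :class:`numpy.random.Generator`.  Required: unseeded
        hypervectors are not reproducible and every consumer in this
        package is.
    """
    return random_hvs(1, D, rng)[0]


def random_hvs(n: int, D: int = DEFAULT_D, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw ``n`` i.i.d. random hypervectors as an ``(n, D)`` uint8 array."""
    if D < 1:
        raise ValueError(f"invalid dimension D={D}; must be >= 1")
    if n < 1:
        raise ValueError(f"need n >= 1, got {n}")
    if rng is None:
        raise ValueError("an explicitly seeded numpy Generator is required")
    return _freeze(rng.integers(0, 2, size=(n, D), dtype=np.uint8))


def bind(a: Hypervector, b: Hypervector) -> Hypervector:
    """Componentwise XOR of two hypervectors of equal dimension.

    Self-inverse: ``bind(x, x)`` is the all-zero vector, so binding with a
    known factor recovers the other one (unbinding).
    """
    a = _check_hv(a, "A")
    b = _check_hv(b, "B")
    _check_same_d(a, b)
    return _freeze(np.bitwise_xor(a, b))


def bundle(vs: Sequence[Hypervector] | np.ndarray,
           rng: np.random.Generator | None = None) -> Hypervector:
    """Componentwise majority vote over a non-empty set of hypervectors.

    A component of the result is 1 iff strictly more than half of the
    inputs carry a 1 there.  With an even number of inputs exact ties can
    occur; each tied component is resolved by an independent fair coin
    drawn from ``rng``.  ``rng`` is a *separate* stream from whatever seeded
    the vectors themselves, so tie-breaking never perturbs item-memory
    reproducibility.

    Raises
    ------
    ValueError
        on an empty input list, mismatched dimensions, or a missing RNG
        when the input count is even (the tie path must be seeded).
    """
    stack = np.asarray(vs, dtype=np.uint8)
    if stack.ndim != 2:
        raise ValueError("bundle expects a non-empty list of equal-length 1-D vectors")
    n, _ = stack.shape
    if n < 1:
        raise ValueError("cannot bundle an empty list")
    counts = stack.sum(axis=0, dtype=np.int64)
    return majority_from_counts(counts, n, rng)


def majority_from_counts(counts: np.ndarray, n: int,
                         rng: np.random.Generator | None = None) -> Hypervector:
    """Threshold per-component 1-counts from ``n`` vectors into a majority vector.

    Split out of :func:`bundle` so that encoders which accumulate counts
    incrementally (to avoid materializing every input vector) share the
    exact same majority/tie semantics.
    """
    if n < 1:
        raise ValueError("majority needs n >= 1")
    c2 = 2 * np.asarray(counts)
    if n % 2 == 0 and bool((c2 == n).any()):
        if rng is None:
            raise ValueError(
                "bundling an even number of vectors produced ties; "
                "a seeded rng is required to break them"
            )
        # adding an independent fair coin per component and raising the
        # threshold to n+1 gives every tied component its own coin and
        # leaves decided components untouched (coins at those positions
        # are drawn and discarded)
        coins = rng.integers(0, 2, size=c2.shape, dtype=c2.dtype)
        out = (c2 + coins > n).astype(np.uint8)
    else:
        out = (c2 > n).astype(np.uint8)
    return _freeze(out)


def permute(a: Hypervector, k: int) -> Hypervector:
    """Circular shift by ``k`` positions: ``result[i] = a[(i - k) mod D]``.

    Bijective and distance-preserving; ``permute(permute(a, k), D - k)``
    restores ``a``.
    """
    a = _check_hv(a, "A")
    return _freeze(np.roll(a, k))


def nhd(a: Hypervector, b: Hypervector) -> float:
    """Normalized Hamming distance: differing components divided by D."""
    a = _check_hv(a, "A")
    b = _check_hv(b, "B")
    _check_same_d(a, b)
    return float(np.count_nonzero(a != b)) / a.shape[0]
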