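"""Quasi-random draw engine for the simulated likelihood.

Standard-normal deviates are produced deterministically from prime-base
Halton (radical-inverse) sequences pushed through the inverse normal
CDF.  There is no random state anywhere: the same settings always yield
the bit-identical draw matrix, which keeps the simulated objective
smooth across optimizer iterations (common draws) and runs exactly
reproducible.

Conventions (the sequence itself does not fix them):

* random slot ``q`` uses the ``q``-th prime base (2, 3, 5, ...);
* the first ``burn`` points of each sequence are discarded (default 10),
  dropping the degenerate early run of small fractions;
* the stream for a slot is partitioned consecutively across crashes —
  crash ``k`` receives points ``burn + k*R + 1 .. burn + (k+1)*R``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtri

_PRIMES = [
    2, 3, 5, 7, 11, 13, 17, 19, 23, 29, 31, 37, 41, 43, 47, 53, 59, 61, 67,
    71, 73, 79, 83, 89, 97, 101, 103, 107, 109, 113,
]


def _is_prime(m: int) -> bool:
    if m < 2:
        return False
    f = 2
    while f * f <= m:
        if m % f == 0:
            return False
        f += 1
    return True


def n_primes(count: int) -> list[int]:
    """First ``count`` primes, extending the cached list as needed."""
    candidate = _PRIMES[-1]
    while len(_PRIMES) < count:
        candidate += 2
        if _is_prime(candidate):
            _PRIMES.append(candidate)
    return _PRIMES[:count]


def halton_sequence(base: int, count: int, burn: int = 0) -> np.ndarray:
    """Radical-inverse (Halton) sequence in ``base``.

    Returns points ``burn+1 .. burn+count`` of the sequence, each in
    (0, 1).  For base 2 with no burn-in: 1/2, 1/4, 3/4, 1/8, ...
    """
    if not _is_prime(base):
        raise ValueError(f"base must be prime, got {base}")
    if count <= 0:
        raise ValueError(f"count must be positive, got {count}")
    if burn < 0:
        raise ValueError(f"burn must be non-negative, got {burn}")
    idx = np.arange(burn + 1, burn + count + 1, dtype=np.int64)
    out = np.zeros(count, dtype=np.float64)
    denom = 1.0
    while idx.max() > 0:
        denom *= base
        out += (idx % base) / denom
        idx //= base
    return out


@dataclass(frozen=True)
class DrawsMatrix:
    """Standard-normal quasi-random draws, shape (n crashes, R, n slots)."""

    values: np.ndarray
    n_draws: int
    primes: tuple[int, ...]
    burn: int

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_random(self) -> int:
        return self.values.shape[2]


def build_draws(n: int, n_draws: int, n_random: int, burn: int = 10) -> DrawsMatrix:
    """Build the draw matrix for ``n`` crashes, ``n_draws`` replications
    and ``n_random`` random coefficients.

    Slot ``q`` uses the ``q``-th prime base; its Halton stream of
    ``n * n_draws`` points (after ``burn`` discarded) is inverse-normal
    transformed and split consecutively across crashes.
    """
    if n < 1 or n_draws < 1 or n_random < 1:
        raise ValueError("n, n_draws and n_random must all be >= 1")
    primes = tuple(n_primes(n_random))
    values = np.empty((n, n_draws, n_random), dtype=np.float64)
    for q, base in enumerate(primes):
        u = halton_sequence(base, n * n_draws, burn)
        values[:, :, q] = ndtri(u).reshape(n, n_draws)
    if not np.isfinite(values).all():
        raise ValueError("non-finite draw encountered; increase burn")
    return DrawsMatrix(values=values, n_draws=n_draws, primes=primes, burn=burn)
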