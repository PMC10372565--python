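"""Explicit-state pseudo-random number generator (xoshiro256**).

The simulation needs bit-reproducible trajectories from a single integer
seed, with the *same* stream visible both to the compiled Monte Carlo
kernel and to the slow pure-Python reference engine used in tests. A
global RNG (numpy's or numba's) cannot be shared safely between the two,
so the state lives in a plain ``uint64[4]`` array that is passed around
explicitly. All functions are numba-compiled but remain callable from
ordinary Python.

Stream discipline: every draw consumes exactly one 64-bit output; the
order of draws inside one Monte Carlo step is documented in
``docs/methods.md`` and is part of the reproducibility contract.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["seed_state", "next_uint64", "uniform", "rand_below", "shuffle"]

_U64 = np.uint64


_M64 = (1 << 64) - 1


def _splitmix64(z: int) -> int:
    # plain-int arithmetic: runs once per seeding, no numba needed
    z = (z + 0x9E3779B97F4A7C15) & _M64
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _M64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _M64
    return z ^ (z >> 31)


def seed_state(seed: int) -> np.ndarray:
    """Return a fresh xoshiro256** state array for an integer seed."""
    state = np.empty(4, dtype=np.uint64)
    z = int(seed) & _M64
    for i in range(4):
        z = _splitmix64(z)
        state[i] = _U64(z)
    return state


@njit(cache=True)
def _rotl(x, k):
    return ((x << k) | (x >> (_U64(64) - k))) & _U64(0xFFFFFFFFFFFFFFFF)


@njit(cache=True)
def next_uint64(state):
    """Advance the state and return the next 64-bit output."""
    s0, s1, s2, s3 = state[0], state[1], state[2], state[3]
    result = (_rotl((s1 * _U64(5)) & _U64(0xFFFFFFFFFFFFFFFF), _U64(7)) * _U64(9)) & _U64(
        0xFFFFFFFFFFFFFFFF
    )
    t = (s1 << _U64(17)) & _U64(0xFFFFFFFFFFFFFFFF)
    s2 ^= s0
    s3 ^= s1
    s1 ^= s2
    s0 ^= s3
    s2 ^= t
    s3 = _rotl(s3, _U64(45))
    state[0], state[1], state[2], state[3] = s0, s1, s2, s3
    return result


@njit(cache=True)
def uniform(state):
    """Uniform double in [0, 1) with 53 random bits."""
    return (next_uint64(state) >> _U64(11)) * 1.1102230246251565e-16  # 2**-53


@njit(cache=True)
def rand_below(state, n):
    """Uniform integer in [0, n) via the floor of a uniform double."""
    return int(uniform(state) * n)


@njit(cache=True)
def shuffle(state, arr, n):
    """Fisher–Yates shuffle of ``arr[:n]`` in place (descending index)."""
    for i in range(n - 1, 0, -1):
        j = rand_below(state, i + 1)
        tmp = arr[i]
        arr[i] = arr[j]
        arr[j] = tmp
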