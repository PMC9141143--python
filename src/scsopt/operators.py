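"""The four reaction operators on encoded candidate strings.

On-wall ineffective collision perturbs one position (local search);
decomposition splits one molecule into two circular shifts (global
search); the inter-molecular ineffective collision exchanges material
between two molecules via a two-step crossover; synthesis splices two
molecules into one at proportional cut points. All operators return raw
structures — the caller repairs them before they re-enter the
population.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "on_wall",
    "circular_shift",
    "decompose",
    "two_step_crossover",
    "synthesize",
]


def on_wall(x, rng, nsym: int) -> np.ndarray:
    """Replace one uniformly chosen position with a uniformly chosen
    *different* code in [0, nsym-1]."""
    x = np.asarray(x, dtype=np.int64)
    if x.size < 1:
        raise ValueError("on_wall needs a non-empty molecule")
    pos = int(rng.integers(x.size))
    c = int(rng.integers(nsym - 1))
    if c >= x[pos]:
        c += 1
    out = x.copy()
    out[pos] = c
    return out


def circular_shift(x, r: int, direction: str = "left") -> np.ndarray:
    """Rotate by r positions; the code multiset is preserved."""
    x = np.asarray(x, dtype=np.int64)
    if x.size < 1:
        raise ValueError("cannot shift an empty molecule")
    if not (0 <= r < x.size):
        raise ValueError("shift must satisfy 0 <= r < len(x)")
    if direction == "left":
        return np.roll(x, -r)
    if direction == "right":
        return np.roll(x, r)
    raise ValueError(f"unknown direction {direction!r}")


def decompose(x, rng) -> tuple[np.ndarray, np.ndarray]:
    """Split into two children: a left rotation by r1 and a right
    rotation by r2, with r1, r2 uniform in [1, len(x)-1]."""
    x = np.asarray(x, dtype=np.int64)
    if x.size < 2:
        raise ValueError("decompose needs at least two elements")
    r1 = int(rng.integers(1, x.size))
    r2 = int(rng.integers(1, x.size))
    return circular_shift(x, r1, "left"), circular_shift(x, r2, "right")


def _cut_swap(x, y, rng):
    p = int(rng.integers(1, x.size))
    q = int(rng.integers(1, y.size))
    return (
        np.concatenate([x[:p], y[q:]]),
        np.concatenate([y[:q], x[p:]]),
    )


def two_step_crossover(x, y, rng) -> tuple[np.ndarray, np.ndarray]:
    """Two rounds of one-point cut-and-swap with fresh cuts each round.

    Character multisets are conserved: the union of the offspring equals
    the union of the parents.
    """
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    if x.size < 2 or y.size < 2:
        raise ValueError("two_step_crossover needs molecules of length >= 2")
    i1, i2 = _cut_swap(x, y, rng)
    if i1.size < 2 or i2.size < 2:
        return i1, i2
    return _cut_swap(i1, i2, rng)


def synthesize(x, y, rng) -> np.ndarray:
    """Splice a prefix of x onto the proportionally aligned suffix of y."""
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    if x.size < 1 or y.size < 1:
        raise ValueError("synthesize needs non-empty molecules")
    if x.size == 1:
        return np.concatenate([x, y[1:]]) if y.size > 1 else x.copy()
    p = int(rng.integers(1, x.size))
    pp = int(round(p * y.size / x.size))
    pp = min(max(pp, 0), y.size)
    return np.concatenate([x[:p], y[pp:]])
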