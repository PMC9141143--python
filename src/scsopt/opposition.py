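"""Opposition-based learning (OBL) transforms.

For a code x in the feasible region [a, b] the opposite is o(x) = a + b - x;
the opposite of a molecule is the elementwise opposite. The feasible
region is always the alphabet's code range, so for DNA in (a, c, g, t)
order the transform is base complementation. Opposites of valid
supersequences are generally not valid; feasibility is restored by the
repair step downstream.
"""

from __future__ import annotations

import numpy as np

from .seqmodel import Alphabet

__all__ = ["opposite_code", "opposite_molecule"]


def opposite_code(x: int, a: int, b: int) -> int:
    """o(x) = a + b - x, the reflection of x about the midpoint of [a, b]."""
    if not (a <= x <= b):
        raise ValueError(f"code {x} outside feasible region [{a}, {b}]")
    return a + b - x


def opposite_molecule(x, alphabet: Alphabet) -> np.ndarray:
    """Elementwise opposite over the alphabet's code range; an involution."""
    x = np.asarray(x, dtype=np.int64)
    if x.size and (x.min() < alphabet.a or x.max() > alphabet.b):
        raise ValueError("code outside the alphabet range")
    return (alphabet.a + alphabet.b) - x
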