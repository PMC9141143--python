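"""Exact shortest-common-supersequence solver for small instances.

The solver runs a layered breadth-first search over pointer tuples
(p_1, ..., p_n), p_i = number of characters of string i already covered.
Emitting code sigma advances every string whose next character is sigma.
All moves cost one character, so the first layer containing the goal
state (all strings exhausted) gives the optimum; within each layer
states are expanded in lexicographic path order with codes ascending,
so the returned witness is the lexicographically smallest optimum.

State count is prod(k_i + 1); the solver refuses instances above a cap
rather than thrash.
"""

from __future__ import annotations

import math

import numpy as np

from .seqmodel import Instance

__all__ = ["exact_scs", "exact_scs_length", "scs2_length", "StateSpaceTooLarge"]


class StateSpaceTooLarge(ValueError):
    """The pointer-tuple state space exceeds the configured cap."""


def exact_scs(inst: Instance, cap: int = 2_000_000) -> np.ndarray:
    """Return an optimal common supersequence (lowest-code tie-break)."""
    lens = [int(l) for l in inst.lengths]
    space = math.prod(l + 1 for l in lens)
    if space > cap:
        raise StateSpaceTooLarge(
            f"state space {space} exceeds cap {cap}; exact search refused"
        )
    strs = [s.tolist() for s in inst.strings]
    n = len(strs)
    nsym = len(inst.alphabet)
    start = (0,) * n
    goal = tuple(lens)
    came_from: dict = {start: None}
    frontier = [start]
    while frontier:
        nxt = []
        for state in frontier:
            if state == goal:
                # reconstruct the witness
                codes = []
                cur = state
                while came_from[cur] is not None:
                    prev, sigma = came_from[cur]
                    codes.append(sigma)
                    cur = prev
                return np.array(codes[::-1], dtype=np.int64)
            for sigma in range(nsym):
                advanced = False
                new = list(state)
                for j in range(n):
                    if state[j] < lens[j] and strs[j][state[j]] == sigma:
                        new[j] = state[j] + 1
                        advanced = True
                if not advanced:
                    continue
                key = tuple(new)
                if key not in came_from:
                    came_from[key] = (state, sigma)
                    nxt.append(key)
        frontier = nxt
    raise RuntimeError("search exhausted without reaching the goal state")  # pragma: no cover


def exact_scs_length(inst: Instance, cap: int = 2_000_000) -> int:
    return int(exact_scs(inst, cap=cap).size)


def scs2_length(s1, s2) -> int:
    """|s1| + |s2| - LCS(s1, s2) via dynamic programming; equals the
    exact SCS length for two strings."""
    s1 = np.asarray(s1, dtype=np.int64)
    s2 = np.asarray(s2, dtype=np.int64)
    prev = np.zeros(s2.size + 1, dtype=np.int64)
    for i in range(s1.size):
        cur = np.empty_like(prev)
        cur[0] = 0
        match = prev[:-1] + (s2 == s1[i])
        for j in range(s2.size):
            cur[j + 1] = max(match[j], cur[j], prev[j + 1])
        prev = cur
    return int(s1.size + s2.size - prev[-1])
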