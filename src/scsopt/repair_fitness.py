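"""Check-and-repair and the potential-energy (fitness) function.

A candidate is *checked* by greedily matching every input string against
it; the unmatched tail lengths are the violations. If the total exceeds
``gamma`` times the instance's total character count the candidate is
discarded (repair returns ``None``). Otherwise the candidate is made
valid by majority-merge appending — repeatedly emitting the code that
advances the most pending strings, ties to the lowest code — and then
trimmed by a single deterministic left-to-right deletion pass.

Potential energy (PE) of a valid candidate is its length; molecules are
only ever stored post-repair, so PE always refers to a valid
supersequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import greedy_match_counts, majority_merge_append, trim_pass
from .seqmodel import Instance, is_common_supersequence

__all__ = ["ViolationReport", "count_violations", "repair", "trim", "potential_energy"]


@dataclass(frozen=True)
class ViolationReport:
    """Unmatched character counts of each input string under a greedy scan."""

    per_string_unmatched: tuple
    total: int

    @property
    def valid(self) -> bool:
        return self.total == 0


def count_violations(cand, inst: Instance) -> ViolationReport:
    cand = np.asarray(cand, dtype=np.int64)
    matched = greedy_match_counts(cand, inst.padded, inst.lengths)
    unmatched = inst.lengths - matched
    return ViolationReport(tuple(int(u) for u in unmatched), int(unmatched.sum()))


def repair(cand, inst: Instance, gamma: float = 0.5):
    """Check-and-repair; returns the repaired candidate or ``None`` when
    the violation count exceeds ``gamma * total_chars`` (the discard
    signal, not an error)."""
    if not (0 < gamma <= 1):
        raise ValueError("gamma must be in (0, 1]")
    cand = np.asarray(cand, dtype=np.int64)
    report = count_violations(cand, inst)
    if report.total > gamma * inst.total_chars:
        return None
    full = majority_merge_append(cand, inst.padded, inst.lengths, len(inst.alphabet))
    return trim_pass(full, inst.padded, inst.lengths)


def trim(cand, inst: Instance) -> np.ndarray:
    """Single left-to-right pass deleting every position whose removal
    keeps the candidate a valid common supersequence. Idempotent."""
    cand = np.asarray(cand, dtype=np.int64)
    if not is_common_supersequence(cand, inst):
        raise ValueError("trim requires a valid common supersequence")
    return trim_pass(cand, inst.padded, inst.lengths)


def potential_energy(cand, inst: Instance) -> int:
    """PE = candidate length; defined only for valid supersequences."""
    cand = np.asarray(cand, dtype=np.int64)
    if not is_common_supersequence(cand, inst):
        raise ValueError("potential energy is defined for valid supersequences only")
    return int(cand.size)
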