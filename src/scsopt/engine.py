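"""The CRO search engine: population setup, the collision loop, energy
accounting, and the opposition-based update.

Each candidate supersequence is a *molecule* carrying potential energy
(PE = its length, minimized), kinetic energy (KE, a budget for accepting
uphill moves), and hit counters. A central energy *buffer* collects KE
shed by on-wall collisions and subsidizes decompositions. The total
energy sum(PE) + sum(KE) + buffer is conserved by every accepted
reaction; when the opposition update swaps a structure for a
lower-energy opposite, the PE released is credited to that molecule's
KE, so conservation holds per step as well.

The population is seeded with opposition-based learning: PopSize random
molecules plus their repaired opposites are pooled and the PopSize with
lowest PE survive. During the search every accepted new structure is
compared with its repaired opposite and the shorter of the two is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .opposition import opposite_molecule
from .operators import decompose, on_wall, synthesize, two_step_crossover
from .repair_fitness import repair, trim
from .seqmodel import Instance

__all__ = [
    "Params",
    "Molecule",
    "Population",
    "StepTrace",
    "RunResult",
    "random_molecule",
    "init_population",
    "dispatch",
    "energy_accept",
    "obl_update",
    "step",
    "run",
    "params_for_algo",
]

ONWALL = "onwall"
DECOMPOSITION = "decomposition"
INTERMOLECULAR = "intermolecular"
SYNTHESIS = "synthesis"


@dataclass
class Params:
    """Engine parameters. PopSize/MoleColl/KELossRate and the iteration
    cap default to the standard benchmark configuration (20 / 0.2 / 0.6 /
    500); the energy constants are conventional CRO choices."""

    pop_size: int = 20
    mole_coll: float = 0.2
    ke_loss_rate: float = 0.6
    initial_ke: float = 1000.0
    alpha: int = 10
    beta: float = 10.0
    buffer0: float = 0.0
    max_iter: int = 500
    pe_threshold: float | None = None
    gamma: float = 0.5
    seed: int | None = None
    obl_enabled: bool = True
    intermolecular: str = "crossover"  # "crossover" (two-step) or "simple"

    def __post_init__(self):
        if self.pop_size < 2:
            raise ValueError("pop_size must be at least 2")
        if not (0 <= self.mole_coll <= 1):
            raise ValueError("mole_coll must lie in [0, 1]")
        if not (0 <= self.ke_loss_rate <= 1):
            raise ValueError("ke_loss_rate must lie in [0, 1]")
        if self.initial_ke < 0 or self.buffer0 < 0 or self.beta < 0:
            raise ValueError("energies must be non-negative")
        if self.alpha < 1 or self.max_iter < 1:
            raise ValueError("alpha and max_iter must be positive")
        if not (0 < self.gamma <= 1):
            raise ValueError("gamma must be in (0, 1]")
        if self.intermolecular not in ("crossover", "simple"):
            raise ValueError("intermolecular must be 'crossover' or 'simple'")


def params_for_algo(algo: str, **overrides) -> Params:
    """Presets: ``oblimcro`` (OBL on, two-step crossover), ``imcro``
    (OBL off, two-step crossover), ``cro_scs`` (OBL off, simple
    inter-molecular collision)."""
    algo = algo.lower()
    if algo == "oblimcro":
        base = dict(obl_enabled=True, intermolecular="crossover")
    elif algo == "imcro":
        base = dict(obl_enabled=False, intermolecular="crossover")
    elif algo == "cro_scs":
        base = dict(obl_enabled=False, intermolecular="simple")
    else:
        raise ValueError(f"unknown algorithm {algo!r}")
    base.update(overrides)
    return Params(**base)


@dataclass
class Molecule:
    structure: np.ndarray
    pe: float
    ke: float
    num_hit: int = 0
    min_hit: int = 0
    min_pe: float = None  # type: ignore[assignment]
    min_structure: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.min_pe is None:
            self.min_pe = self.pe
        if self.min_structure is None:
            self.min_structure = self.structure

    def record_hit(self, improved: bool = False):
        self.num_hit += 1
        if improved:
            self.min_pe = self.pe
            self.min_structure = self.structure
            self.min_hit = self.num_hit

    def update_structure(self, structure: np.ndarray, pe: float, ke: float):
        self.structure = structure
        self.pe = pe
        self.ke = ke
        self.num_hit += 1
        if pe < self.min_pe:
            self.min_pe = pe
            self.min_structure = structure
            self.min_hit = self.num_hit


@dataclass
class Population:
    molecules: list
    buffer: float
    best_pe: float
    best_structure: np.ndarray
    iteration: int = 0

    def note(self, structure: np.ndarray, pe: float):
        if pe < self.best_pe:
            self.best_pe = pe
            self.best_structure = structure

    @property
    def total_energy(self) -> float:
        return sum(m.pe + m.ke for m in self.molecules) + self.buffer


@dataclass
class StepTrace:
    iteration: int
    t: float
    reaction: str
    accepted: bool
    obl_chosen: bool
    best_pe: float
    pop_size: int
    buffer: float


@dataclass
class RunResult:
    best: np.ndarray
    pe: float
    iterations: int
    trace: list
    params: Params

    @property
    def length(self) -> int:
        return int(self.pe)


def random_molecule(inst: Instance, rng, initial_ke: float = 1000.0) -> Molecule:
    """Random-insertion construction: start from a uniform random string
    of length max_i |s_i|, then thread every input string through it at
    uniformly chosen increasing positions; trim the (always valid)
    result."""
    nsym = len(inst.alphabet)
    cur = rng.integers(0, nsym, size=inst.max_length).astype(np.int64)
    for s in inst.strings:
        new_len = cur.size + s.size
        pos = np.sort(rng.choice(new_len, size=s.size, replace=False))
        out = np.empty(new_len, dtype=np.int64)
        mask = np.zeros(new_len, dtype=bool)
        mask[pos] = True
        out[mask] = s
        out[~mask] = cur
        cur = out
    structure = trim(cur, inst)
    return Molecule(structure=structure, pe=float(structure.size), ke=initial_ke)


def init_population(inst: Instance, params: Params, rng) -> Population:
    """Opposition-seeded start: pool PopSize random molecules with their
    repaired opposites and keep the PopSize of lowest PE (stable sort, so
    ties resolve by insertion order). With OBL disabled the random
    molecules are used as-is."""
    rx = [random_molecule(inst, rng, params.initial_ke) for _ in range(params.pop_size)]
    if params.obl_enabled:
        ox = []
        for m in rx:
            opp = opposite_molecule(m.structure, inst.alphabet)
            fixed = repair(opp, inst, gamma=1.0)  # always repair at init
            ox.append(Molecule(structure=fixed, pe=float(fixed.size), ke=params.initial_ke))
        mx = rx + ox
        mx.sort(key=lambda m: m.pe)  # stable
        ix = mx[: params.pop_size]
    else:
        ix = rx
    best = min(ix, key=lambda m: m.pe)
    return Population(
        molecules=ix,
        buffer=params.buffer0,
        best_pe=best.pe,
        best_structure=best.structure,
    )


def dispatch(pop: Population, params: Params, rng) -> tuple:
    """Draw t and choose the reaction: t > MoleColl selects a
    uni-molecular reaction (decomposition once a molecule's hits since
    its last improvement exceed alpha, else on-wall); otherwise an
    inter-molecular one (synthesis when both kinetic energies are at or
    below beta, else collision/crossover). Returns (t, reaction, indices)."""
    mols = pop.molecules
    t = float(rng.random())
    if t > params.mole_coll:
        i = int(rng.integers(len(mols)))
        m = mols[i]
        if (m.num_hit - m.min_hit) > params.alpha and m.structure.size >= 2:
            return t, DECOMPOSITION, (i,)
        return t, ONWALL, (i,)
    i = int(rng.integers(len(mols)))
    j = int(rng.integers(len(mols) - 1))
    if j >= i:
        j += 1
    if mols[i].ke <= params.beta and mols[j].ke <= params.beta:
        return t, SYNTHESIS, (i, j)
    return t, INTERMOLECULAR, (i, j)


def energy_accept(reaction: str, parents: list, child_pes: list, buffer: float, params: Params, rng):
    """Canonical CRO acceptance and energy bookkeeping.

    Returns (accepted, child_kes, new_buffer). Rejected reactions leave
    every energy untouched. Accepted reactions conserve
    sum(PE) + sum(KE) + buffer exactly.
    """
    if reaction == ONWALL:
        (m,) = parents
        (pe_new,) = child_pes
        surplus = m.pe + m.ke - pe_new
        if surplus < 0:
            return False, [], buffer
        q = float(rng.uniform(params.ke_loss_rate, 1.0))
        return True, [surplus * q], buffer + surplus * (1.0 - q)
    if reaction == DECOMPOSITION:
        (m,) = parents
        total = m.pe + m.ke + buffer
        surplus = total - sum(child_pes)
        if surplus < 0:
            return False, [], buffer
        u1, u2 = rng.random(2)
        ke1 = surplus * float(u1)
        ke2 = (surplus - ke1) * float(u2)
        return True, [ke1, ke2], surplus - ke1 - ke2
    if reaction == INTERMOLECULAR:
        m1, m2 = parents
        surplus = m1.pe + m1.ke + m2.pe + m2.ke - sum(child_pes)
        if surplus < 0:
            return False, [], buffer
        u = float(rng.random())
        return True, [surplus * u, surplus * (1.0 - u)], buffer
    if reaction == SYNTHESIS:
        m1, m2 = parents
        total = m1.pe + m1.ke + m2.pe + m2.ke
        (pe_new,) = child_pes
        if total < pe_new:
            return False, [], buffer
        return True, [total - pe_new], buffer
    raise ValueError(f"unknown reaction {reaction!r}")


def obl_update(x_new: np.ndarray, inst: Instance, params: Params):
    """Compare an accepted structure with its repaired opposite and keep
    the shorter (ties, or an unrepairable opposite, keep the original).
    Returns (structure, opposite_won)."""
    if not params.obl_enabled:
        return x_new, False
    opp = opposite_molecule(x_new, inst.alphabet)
    fixed = repair(opp, inst, params.gamma)
    if fixed is not None and fixed.size < x_new.size:
        return fixed, True
    return x_new, False


def _fresh(structure: np.ndarray, ke: float) -> Molecule:
    return Molecule(structure=structure, pe=float(structure.size), ke=ke)


def step(pop: Population, inst: Instance, params: Params, rng) -> StepTrace:
    """One collision: dispatch, apply the operator, repair, settle the
    energy, apply the opposition update to each accepted structure, and
    update the population. A repair-discarded child voids the reaction
    (an unsuccessful collision; hit counters still advance)."""
    pop.iteration += 1
    nsym = len(inst.alphabet)
    mols = pop.molecules
    t, reaction, idxs = dispatch(pop, params, rng)
    parents = [mols[i] for i in idxs]
    accepted = False
    obl_chosen = False

    def fail():
        for m in parents:
            m.record_hit()

    if reaction == ONWALL:
        (m,) = parents
        raw = on_wall(m.structure, rng, nsym)
        rep = repair(raw, inst, params.gamma)
        if rep is None:
            fail()
        else:
            ok, kes, buf = energy_accept(reaction, parents, [float(rep.size)], pop.buffer, params, rng)
            if ok:
                accepted = True
                struct, obl_chosen = obl_update(rep, inst, params)
                ke = kes[0] + (rep.size - struct.size)  # OBL gain feeds KE
                m.update_structure(struct, float(struct.size), ke)
                pop.buffer = buf
                pop.note(m.structure, m.pe)
            else:
                fail()

    elif reaction == DECOMPOSITION:
        (m,) = parents
        raw1, raw2 = decompose(m.structure, rng)
        rep1 = repair(raw1, inst, params.gamma)
        rep2 = repair(raw2, inst, params.gamma)
        if rep1 is None or rep2 is None:
            fail()
        else:
            ok, kes, buf = energy_accept(
                reaction, parents, [float(rep1.size), float(rep2.size)], pop.buffer, params, rng
            )
            if ok:
                accepted = True
                children = []
                for rep, ke in zip((rep1, rep2), kes):
                    struct, won = obl_update(rep, inst, params)
                    obl_chosen = obl_chosen or won
                    children.append(_fresh(struct, ke + (rep.size - struct.size)))
                mols[idxs[0]] = children[0]
                mols.append(children[1])
                pop.buffer = buf
                for c in children:
                    pop.note(c.structure, c.pe)
            else:
                fail()

    elif reaction == INTERMOLECULAR:
        m1, m2 = parents
        if params.intermolecular == "simple" or m1.structure.size < 2 or m2.structure.size < 2:
            raw1 = on_wall(m1.structure, rng, nsym)
            raw2 = on_wall(m2.structure, rng, nsym)
        else:
            raw1, raw2 = two_step_crossover(m1.structure, m2.structure, rng)
        rep1 = repair(raw1, inst, params.gamma)
        rep2 = repair(raw2, inst, params.gamma)
        if rep1 is None or rep2 is None:
            fail()
        else:
            ok, kes, buf = energy_accept(
                reaction, parents, [float(rep1.size), float(rep2.size)], pop.buffer, params, rng
            )
            if ok:
                accepted = True
                for m, rep, ke in zip(parents, (rep1, rep2), kes):
                    struct, won = obl_update(rep, inst, params)
                    obl_chosen = obl_chosen or won
                    m.update_structure(struct, float(struct.size), ke + (rep.size - struct.size))
                    pop.note(m.structure, m.pe)
                pop.buffer = buf
            else:
                fail()

    elif reaction == SYNTHESIS:
        if len(mols) <= 2:
            fail()  # would drop the population below its floor
        else:
            m1, m2 = parents
            raw = synthesize(m1.structure, m2.structure, rng)
            rep = repair(raw, inst, params.gamma)
            if rep is None:
                fail()
            else:
                ok, kes, buf = energy_accept(reaction, parents, [float(rep.size)], pop.buffer, params, rng)
                if ok:
                    accepted = True
                    struct, obl_chosen = obl_update(rep, inst, params)
                    child = _fresh(struct, kes[0] + (rep.size - struct.size))
                    for i in sorted(idxs, reverse=True):
                        del mols[i]
                    mols.append(child)
                    pop.buffer = buf
                    pop.note(child.structure, child.pe)
                else:
                    fail()

    return StepTrace(
        iteration=pop.iteration,
        t=t,
        reaction=reaction,
        accepted=accepted,
        obl_chosen=obl_chosen,
        best_pe=pop.best_pe,
        pop_size=len(mols),
        buffer=pop.buffer,
    )


def run(inst: Instance, params: Params | None = None, collect_trace: bool = True) -> RunResult:
    """Run the search until the best PE reaches ``pe_threshold`` (when
    set) or ``max_iter`` collisions have occurred. Deterministic for a
    fixed ``params.seed``."""
    if params is None:
        params = Params()
    rng = np.random.default_rng(params.seed)
    pop = init_population(inst, params, rng)
    trace: list = []
    it = 0
    threshold = params.pe_threshold
    while it < params.max_iter and (threshold is None or pop.best_pe > threshold):
        tr = step(pop, inst, params, rng)
        if collect_trace:
            trace.append(tr)
        it += 1
    return RunResult(best=pop.best_structure, pe=pop.best_pe, iterations=it, trace=trace, params=params)
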