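"""Random-instance generation, the multi-run benchmark driver, and the
comparison statistics (mean length reduction, relative time reduction,
t-tests).

Benchmark instances follow the random-dataset recipe: n i.i.d. uniform
strings of length k over the alphabet. The instances themselves are not
fixed artifacts — each (cell, run) draws a fresh instance and a fresh
engine seed from one base seed, so a whole benchmark is bit-reproducible
from (grid, base_seed) alone.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import engine
from .seqmodel import Alphabet, DNA, PROTEIN, Instance

__all__ = [
    "gen_random_instance",
    "BenchResult",
    "Comparison",
    "run_cell",
    "run_benchmark",
    "compare",
]

_ALPHABETS = {"dna": DNA, "protein": PROTEIN}


def resolve_alphabet(spec) -> Alphabet:
    if isinstance(spec, Alphabet):
        return spec
    if isinstance(spec, str):
        key = spec.lower()
        if key in _ALPHABETS:
            return _ALPHABETS[key]
        return Alphabet.from_string(spec)
    raise ValueError(f"cannot interpret alphabet spec {spec!r}")


def gen_random_instance(n: int, k: int, alphabet: Alphabet = DNA, rng=None, name: str = "") -> Instance:
    """n strings of k i.i.d. uniform draws from the alphabet."""
    if n < 1 or k < 1:
        raise ValueError("n and k must be positive")
    if rng is None:
        rng = np.random.default_rng()
    strings = rng.integers(0, len(alphabet), size=(n, k)).astype(np.int64)
    return Instance(list(strings), alphabet, name=name or f"random-n{n}-k{k}")


@dataclass
class BenchResult:
    """Aggregates for one (instance family, algorithm) benchmark cell."""

    name: str
    n: int
    k: int
    algo: str
    seeds: list
    lengths: list
    iterations: list
    times: list = field(default_factory=list)

    @property
    def runs(self) -> int:
        return len(self.lengths)

    @property
    def L(self) -> float:
        """Mean best supersequence length over runs."""
        return float(np.mean(self.lengths))

    @property
    def sd_L(self) -> float:
        return float(np.std(self.lengths, ddof=1)) if self.runs > 1 else 0.0

    @property
    def mean_iterations(self) -> float:
        return float(np.mean(self.iterations))

    @property
    def mean_time(self) -> float:
        return float(np.mean(self.times)) if self.times else float("nan")


def _child_seed(base_seed: int, *path: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(base_seed), *map(int, path)])


def run_cell(
    n: int,
    k: int,
    alphabet=DNA,
    algo: str = "oblimcro",
    runs: int = 20,
    base_seed: int = 0,
    cell_id: int = 0,
    **param_overrides,
) -> BenchResult:
    """``runs`` independent runs, each on a freshly drawn instance with
    its own derived seed; the cell mean of best lengths is the L
    statistic."""
    alphabet = resolve_alphabet(alphabet)
    lengths, iterations, times, seeds = [], [], [], []
    for r in range(runs):
        ss = _child_seed(base_seed, cell_id, r)
        inst_rng = np.random.default_rng(ss)
        inst = gen_random_instance(n, k, alphabet, inst_rng)
        seed = int(ss.generate_state(2)[1] & 0x7FFFFFFF)
        params = engine.params_for_algo(algo, seed=seed, **param_overrides)
        t0 = time.perf_counter()
        res = engine.run(inst, params, collect_trace=False)
        times.append(time.perf_counter() - t0)
        lengths.append(res.length)
        iterations.append(res.iterations)
        seeds.append(seed)
    return BenchResult(
        name=f"n{n}-k{k}", n=n, k=k, algo=algo, seeds=seeds,
        lengths=lengths, iterations=iterations, times=times,
    )


def run_benchmark(config: dict, out_dir=None):
    """Run a grid of benchmark cells.

    ``config`` keys: ``cells`` (list of {n, k}), ``alphabet``, ``algos``,
    ``runs``, ``base_seed``, optional ``params`` overrides. Returns
    (results, runs_df, summary_df); writes results.tsv / summary.tsv /
    summary.json under ``out_dir`` when given.
    """
    alphabet = resolve_alphabet(config.get("alphabet", "dna"))
    algos = config.get("algos", ["oblimcro"])
    runs = int(config.get("runs", 20))
    base_seed = int(config.get("base_seed", 0))
    overrides = dict(config.get("params", {}))
    results = []
    rows = []
    for ci, cell in enumerate(config["cells"]):
        n, k = int(cell["n"]), int(cell["k"])
        for ai, algo in enumerate(algos):
            # same per-run instance/seed stream for every algorithm in a cell
            br = run_cell(n, k, alphabet, algo, runs, base_seed, cell_id=ci, **overrides)
            results.append(br)
            for r in range(br.runs):
                rows.append(
                    dict(instance=br.name, n=n, k=k, algo=algo, run=r, seed=br.seeds[r],
                         length=br.lengths[r], iterations=br.iterations[r], time_s=br.times[r])
                )
    runs_df = pd.DataFrame(rows)
    summary_df = pd.DataFrame(
        [dict(instance=b.name, n=b.n, k=b.k, algo=b.algo, runs=b.runs, L=b.L,
              sd_L=b.sd_L, mean_iterations=b.mean_iterations, mean_time_s=b.mean_time)
         for b in results]
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        runs_df.to_csv(out / "results.tsv", sep="\t", index=False)
        summary_df.to_csv(out / "summary.tsv", sep="\t", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary_df.to_dict(orient="records"), fh, indent=2)
            fh.write("\n")
    return results, runs_df, summary_df


@dataclass
class Comparison:
    """Baseline-vs-test statistics over matched benchmark cells.

    ``rc`` is the mean length reduction mean_i(L_base(i) - L_test(i));
    ``dt`` is the mean relative time reduction
    (T_base - T_test) / T_base — recorded wall time, hence not
    reproducible across machines.
    """

    rc: float
    p_value: float
    per_instance_p: list
    dt: float | None
    baseline: str
    test: str


def _ttest(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    res = stats.ttest_ind(a, b)
    p = float(res.pvalue)
    if np.isnan(p):  # zero variance in both samples
        return 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    return p


def compare(baseline, test) -> Comparison:
    """Compare two matched benchmark result lists (same cells, same run
    counts)."""
    if isinstance(baseline, BenchResult):
        baseline = [baseline]
    if isinstance(test, BenchResult):
        test = [test]
    if len(baseline) != len(test):
        raise ValueError("mismatched instance sets")
    for a, b in zip(baseline, test):
        if (a.n, a.k, a.runs) != (b.n, b.k, b.runs):
            raise ValueError(f"mismatched cells: {a.name}/{a.runs} vs {b.name}/{b.runs}")
    rc = float(np.mean([a.L - b.L for a, b in zip(baseline, test)]))
    per_p = [_ttest(a.lengths, b.lengths) for a, b in zip(baseline, test)]
    pooled = _ttest(
        np.concatenate([a.lengths for a in baseline]),
        np.concatenate([b.lengths for b in test]),
    )
    dt = None
    if all(a.times for a in baseline) and all(b.times for b in test):
        dt = float(np.mean([(a.mean_time - b.mean_time) / a.mean_time for a, b in zip(baseline, test)]))
    return Comparison(
        rc=rc, p_value=pooled, per_instance_p=per_p, dt=dt,
        baseline=baseline[0].algo, test=test[0].algo,
    )
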