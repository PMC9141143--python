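# scsopt

Chemical-reaction-optimization (CRO) metaheuristics for the **shortest
common supersequence (SCS) problem** on DNA and protein strings, with
**opposition-based learning (OBL)** in both the population seeding and
the per-move update, plus an exact small-instance solver, a random
instance generator, and a benchmark harness.

Given a set S = {s₁, …, sₙ} of strings over an alphabet Σ, the SCS
problem asks for a shortest string that contains every sᵢ as a
subsequence. It is NP-hard for |Σ| ≥ 2 and shows up in sequence
assembly, multiple alignment, and AI planning. This package is for
people who want a reasonable heuristic SCS solver for string sets at
bioinformatics scale, an exact oracle to validate it at small scale, and
a reproducible harness to benchmark search variants against each other.

## The algorithm

Candidate supersequences are encoded as integer code vectors over
Σ → {0, …, |Σ|−1} and treated as *molecules* with

- **PE** (potential energy) = candidate length, the minimized objective;
- **KE** (kinetic energy), a budget that lets a molecule accept uphill
  moves, decaying into a shared **buffer** at rate governed by
  `KELossRate`;

and four reaction operators: on-wall ineffective collision (one-position
substitution), decomposition (two circular shifts), inter-molecular
collision (two-step crossover), and synthesis (proportional-cut splice).
A draw t ~ U[0,1] each iteration picks uni-molecular (t > `MoleColl`)
vs inter-molecular reactions; decomposition triggers when a molecule has
gone more than α collisions without improving, synthesis when both
collision partners have KE ≤ β. Every raw offspring is passed through a
*check-and-repair* step: count the characters of each sᵢ a greedy scan
fails to match; discard if the total exceeds γ·Σ|sᵢ|, otherwise append
the missing characters by majority-merge and trim redundant positions.

Opposition-based learning evaluates, alongside each candidate x over
[a, b], its opposite o(x) = a + b − x (for DNA this is base
complementation). The initial population keeps the best PopSize of
{PopSize random molecules} ∪ {their repaired opposites}, and every
accepted new structure is replaced by its repaired opposite whenever
that is shorter.

Defaults follow the standard benchmark configuration: PopSize 20,
MoleColl 0.2, KELossRate 0.6, at most 500 iterations. See
`docs/methods.md` for the full parameter table and design notes.

## Worked example

```python
import numpy as np
import scsopt as S

inst = S.Instance.from_texts(["acgtacgtac", "gtacatcgta", "tacgtagcat"], S.DNA)
res = S.run(inst, S.Params(seed=5))
print(res.length, S.decode(res.best, S.DNA))
print("exact optimum:", S.exact_scs_length(inst))
```

prints

```
15 gtacagtacgtacat
exact optimum: 15
```

i.e. the search found a common supersequence of the three 10-mers of
length 15 — here provably optimal (the product-state solver confirms no
shorter one exists). The same from the shell:

```bash
printf 'acgtacgtac\ngtacatcgta\ntacgtagcat\n' > toy.txt
scs run --input toy.txt --alphabet dna --seed 5 --out report.tsv
scs exact --input toy.txt --alphabet dna
```

Benchmark grids (YAML listing cells, algorithms, run counts, base seed)
run via `scs bench --grid grid.yaml --out results/`, which writes
per-run and summary tables plus pairwise comparison statistics (mean
length reduction RC, t-test p-values, relative wall-time reduction).

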