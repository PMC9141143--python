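# Methods

## Problem and representation

A candidate solution is an integer code vector over the alphabet's
positional encoding Σ → {0, …, |Σ|−1}. Molecules are stored
*post-repair only*: every structure in the population is a valid common
supersequence at all times, and its potential energy (PE) is its length.
This keeps the objective exactly the quantity reported by the benchmark
tables and makes the oracle lower bound assertable at every iteration.

## Check-and-repair

`count_violations` greedily matches each input string left-to-right
against the candidate and reports the unmatched tail lengths. `repair`
discards a candidate when total violations exceed γ · Σᵢ|sᵢ|
(γ defaults to 0.5; a discarded offspring voids its reaction, which
counts as an unsuccessful collision). Otherwise it appends the missing
characters by **majority merge** — repeatedly emit the code that
advances the most pending string pointers, ties to the lowest code —
and trims. Both choices make repair fully deterministic given its
input, which is what makes whole runs bit-reproducible from one seed.

`trim` is a single deterministic left-to-right pass deleting each
position whose removal leaves a valid common supersequence. The naive
formulation revalidates the remainder after each tentative deletion
(O(n·L) per position); we precompute, once, the backward greedy match
of every string against every suffix of the candidate, which reduces
the identical pass to O(n·L) total via the standard split identity
(s ⊑ u+v iff forward-match(s, u) + backward-match(s, v) ≥ |s|). The
suffix used by each test is the untouched original suffix in both
formulations, so the outputs are identical; the pass is idempotent
(kept positions only lose matching slack as later deletions happen, so
a second pass deletes nothing). Trimming to a globally minimal
sub-supersequence is NP-hard, so no attempt is made to go beyond the
one-pass rule.

## Opposition-based learning

The opposite of code x over the feasible region [a, b] is
o(x) = a + b − x, applied elementwise (an involution; for DNA in
(a, c, g, t) order it is base complementation). The feasible region is
always the alphabet's full code range — the transform is defined on
codes, not positions, and nothing in the model calls for per-position
regions. Opposites of valid supersequences are generally invalid and go
through repair:

- **Seeding.** PopSize random molecules (RX) plus their repaired
  opposites (OX) are pooled and the PopSize lowest-PE members survive.
  At this point opposites are repaired unconditionally (γ = 1): the
  pool must contain 2·PopSize members for the selection to be
  meaningful, and a discard signal has no sensible consumer here.
- **Update.** Each accepted new structure is compared with its repaired
  opposite (using the configured γ; a discarded opposite simply loses)
  and the shorter of the two is kept. Ties keep the original.

With `obl_enabled=False` both mechanisms switch off and the engine is
the plain CRO baseline, which is what the ablation test compares
against.

## Reaction operators

The on-wall collision substitutes one uniformly chosen position with a
uniformly chosen *different* code. Decomposition returns a left rotation
by r₁ and a right rotation by r₂ (r₁, r₂ uniform in [1, L−1]) — rotation
preserves the code multiset while globally rearranging the interleaving
order. The inter-molecular collision is a two-step crossover: one-point
cut-and-swap applied twice with fresh cuts, conserving the parents'
combined character multiset. Synthesis splices x[0:p] onto y[p′:] with
p′ = round(p·|y|/|x|), so the cut lands at the same relative depth in
both parents. A `simple` inter-molecular mode (independent one-position
changes on both partners) is available for the older baseline behavior;
the crossover is the default.

## Energy accounting

Canonical CRO rules: on-wall accepts iff PE + KE ≥ PE′, retains fraction
q ~ U[KELossRate, 1] of the surplus as KE′ and sheds the rest into the
buffer; decomposition accepts iff PE + KE + buffer covers both children,
splitting the surplus by two uniform draws between child KEs and the
buffer; the inter-molecular collision accepts iff the partners' combined
energy covers both offspring, splitting the surplus uniformly; synthesis
gives the child everything beyond its PE. The invariant
ΣPE + ΣKE + buffer = const holds exactly over accepted reactions and is
asserted to 1e-9 in the tests.

One wrinkle is of our making: the opposition update runs *after*
acceptance, and swapping in a shorter opposite changes PE outside the
acceptance arithmetic. The PE released by the swap is credited to the
molecule's KE, so conservation holds per step and the gained energy
remains in the system as move budget rather than silently vanishing.

## Engine loop and termination

Each iteration performs one collision: draw t, dispatch (t > MoleColl →
uni-molecular; decomposition when NumHit − MinHit > α, else on-wall;
otherwise synthesis when both partners' KE ≤ β, else collision),
repair offspring, settle energy, apply the opposition update, update
the population. Decomposition replaces one molecule with two children
(fresh hit counters); synthesis replaces two with one and is skipped
(as a failed collision) when the population is at its floor of two.
The best-so-far snapshot is updated from every new structure, so it is
monotone non-increasing; the run stops at `max_iter` iterations or as
soon as the best PE reaches `pe_threshold` (unset by default).

## Parameters

| name | default | units | meaning |
|---|---|---|---|
| pop_size | 20 | molecules | population size (benchmark standard) |
| mole_coll | 0.2 | probability | inter-molecular reaction rate |
| ke_loss_rate | 0.6 | fraction | minimum surplus fraction retained as KE after on-wall |
| initial_ke | 1000 | energy | starting KE per molecule (conventional CRO value) |
| alpha | 10 | collisions | stagnation threshold triggering decomposition |
| beta | 10 | energy | KE depletion threshold triggering synthesis |
| buffer0 | 0 | energy | initial central buffer |
| max_iter | 500 | collisions | iteration cap (benchmark standard) |
| gamma | 0.5 | fraction | repair discard threshold (of total input characters) |
| pe_threshold | none | characters | optional early-stop objective value |

PopSize, MoleColl, KELossRate and the 500-iteration cap are the
standard benchmark configuration; InitialKE, α, β, buffer0 and γ are
not pinned by that configuration and take conventional CRO values.

## Exact oracle

`exact_scs` runs a layered breadth-first search over pointer tuples
(p₁, …, pₙ); emitting code σ advances every string whose next character
is σ. All moves cost one character, so the first layer containing the
all-exhausted state gives the optimum, and expanding codes in ascending
order within insertion-ordered layers makes the returned witness the
lexicographically smallest optimum — deterministic and directly
testable. The state space is Π(kᵢ+1); the solver refuses instances
beyond a cap (default 2·10⁶ states) rather than thrash. For two
strings, `scs2_length` gives |s₁| + |s₂| − LCS via dynamic programming
and is cross-checked against the product search.

## Synthetic instances and what the benchmarks show

`gen_random_instance` draws n strings of k i.i.d. uniform symbols —
the random-DNA benchmark recipe. Real DNA is not i.i.d. (composition
bias, repeats, shared ancestry all raise inter-string similarity and
shorten the SCS), so results on this generator say how the search
handles unstructured instances, not genomic ones; the FASTA reader is
the path for real data. Benchmark cells draw a *fresh* instance per run
(the benchmark statistic is a distribution mean, not a property of one
frozen instance), with every instance and engine seed derived from one
base seed, so entire benchmark tables are bit-reproducible.

One empirical anchor from this package's own oracle puts the small
benchmark cells in context (recomputed by the test suite, not quoted
from anywhere): on matched 5×10 uniform DNA instances the engine's mean
best length stays within half a character of the mean exact optimum —
the search averages at the floor of what any algorithm can achieve on
that distribution, so cell means there measure the instance
distribution more than the search. On long-string cells the binding
limitation is the move neighborhood itself: one-point substitution,
rotation and cut-and-swap followed by append-and-trim repair rearrange
interleavings only coarsely, and restructuring beyond that would need
alignment-style moves outside this operator set.

## Comparison statistics

`compare` reports RC (mean over matched cells of L_baseline − L_test),
per-cell and pooled two-sample t-tests on per-run lengths, and the mean
relative wall-time reduction ΔT = (T_base − T_test)/T_base. Wall times
are recorded for completeness but are hardware-dependent and excluded
from any reproducibility claim. Degenerate t-tests (zero variance in
both samples) are reported as p = 1 when means coincide and p = 0
otherwise.

## Numerical and degenerate-input notes

- All code vectors are int64; energies are float64. Conservation is
  exact up to float rounding (asserted at 1e-9 in the tests).
- Majority-merge ties, trim order, and the exact solver's witness are
  all deterministically tie-broken (lowest code / left-to-right), so
  every code path is reproducible bit-for-bit from a seed.
- Single-symbol alphabets make opposition the identity; single-string
  instances trim every molecule to the string itself.
- Empty candidates are legal inputs to repair (pure majority merge);
  empty strings are rejected at instance construction.
- Hot scans (greedy matching, trim, majority merge) are numba-compiled;
  first call in a fresh environment pays a few seconds of JIT.

## Known limitations

- PE is plain length; no secondary objectives (e.g. weighting strings).
- The trim pass is locally greedy; it does not attempt minimal
  hitting-set trimming.
- No parallel populations, adaptive parameter control, or quasi/elite
  opposition variants.
- The exact solver is for validation at desk scale, not production
  solving (state space is exponential in n).
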