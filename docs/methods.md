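# Methods

## The extraction model

A metabolic network is a stoichiometric matrix `S` (metabolites × reactions).
A *pathway* (flux mode) is any nonzero flux vector `v ≥ 0` with `S·v = 0` on
the split network; an *elementary flux mode* (EFM) is a pathway whose support
(set of active reactions) strictly contains no other pathway's support.
Because thermodynamic feasibility is encoded as plain nonnegativity, every
reversible reaction is first *de-doubled* into a forward column (unchanged)
and a backward column (negated). All extraction happens at split granularity;
`project_support` maps results back to signed original reactions, keeping
futile two-cycles (fwd+bwd of one reaction) visible.

Each extraction iteration solves the LP

    minimize    Σ w_i v_i
    subject to  S_split · v = 0,   v ≥ 0,   v_j ≥ c  for j in the seed

where the *seed* is a uniformly drawn set of `k` split reactions forced into
the solution (positive constraints only — forcing absence creates
infeasibility, forcing presence at worst makes a seed infeasible, in which
case it is discarded and redrawn without advancing the iteration counter).
Minimizing a positively weighted flux sum drives the solver toward
small-support vertices of the cone, which are expected — and on our fixtures
verified — to be predominantly EFMs.

The contribution being packaged is the *penalization* of the objective:
after each solution, per-reaction occurrence frequencies `F_i = O_i / N` are
updated and the weights reset to

    w_i = 1 + p · F_i ,

so reactions that already appeared often become more expensive (never
forbidden: `w_i ≤ 1 + p`). Higher penalization `p` steers later iterations
toward under-represented parts of the network, increasing the diversity and
representativeness of the sampled mode set.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `p` | 0 | penalization strength; `w ∈ [1, 1+p]`; 0 recovers the unweighted program |
| `k` | 4 | seed size; larger seeds constrain more and raise the infeasibility rate |
| `c` (`seed_lower_bound`) | 1.0 | flux floor on seed reactions; any positive value is equivalent up to cone rescaling |
| `support_threshold` | 1e-6 | relative cutoff `v_i > θ·max(v)` for support extraction; scale-invariant |
| `solver_feas_tol` | 1e-9 | HiGHS primal/dual feasibility tolerance |
| `weight_mode` | dynamic | `dynamic` recomputes `w` from running `F` each iteration; `static` fixes `w=1+p·F0` from a previous experiment; `off` is all-ones |
| `drought_cap` | 1000 | consecutive infeasible seeds before aborting with partial results |

Both weight protocols are exposed because either reading of "penalizing
previous results" is defensible; `dynamic` is the default. With `p = 0` the
dynamic path is exactly the unweighted program, and the two modes produce
identical solution sequences on the same RNG stream (asserted in tests on
all data rows of the output files; the metadata header records which mode
ran, so the files differ in their `#` comments by design).

## Elementarity test and oracle

Elementarity of a support `T` carried by some pathway is decided by the rank
test `rank(S_split[:,T]) = |T| − 1` (the restricted null space is then one
ray). Ranks use SVD with a relative singular-value cutoff of 1e-9; fixture
stoichiometries are small integers, so the cutoff is far from any true
singular value. The independent oracle, `brute_force_efms`, enumerates all
support subsets in increasing size on networks of ≤ 15 split columns and
keeps those for which a feasibility LP (`S v = 0`, `v ≥ 1` on, `v = 0` off)
succeeds and no smaller accepted support is contained — deliberately a
different algorithm (feasibility enumeration vs. rank), so agreement between
the two is a genuine cross-check.

## Comparing experiments

Two experiments are compared through their frequency vectors, paired by
reaction id:

- **Wilcoxon signed-rank**, two-sided, zero differences dropped; exact
  enumeration of sign assignments for ≤ 25 nonzero pairs (including tied
  magnitudes), normal approximation with tie correction above that.
- **chi-bar**: `Σ (F'_i − F_i)² / F_i` over reference frequencies `F_i > 0`;
  zero-reference terms are skipped and their count reported rather than
  pseudo-counted, so representativeness gaps stay visible. No p-value is
  attached: the frequencies are not independent, so no chi-square reference
  distribution is claimed — the statistic only orders experiment pairs by
  dissimilarity.

A caveat the test suite measures rather than hides: stoichiometric coupling
makes whole reaction clusters rise and fall together, so the signed-rank
test's independence assumption is violated and it is *anti-conservative* on
large models — on the de-doubled core E. coli model two unpenalized
replicate runs frequently differ "significantly" even though their frequency
profiles are exchangeable by construction, and this does not improve with
more iterations (rank tests ignore the shrinking noise scale). The
penalization *effect* (p = 0 vs p > 0, and the monotone growth of chi-bar in
p) is directionally robust on the same model; the p = 0 null comparison is
the fragile part, and the corresponding assertion is left failing rather
than weakened.

## Model reading

SBML and COBRA-JSON files are read through cobrapy; a reaction is reversible
iff its lower flux bound is negative, and bound magnitudes are otherwise
discarded (the extraction cone has no finite bounds). The `open_exchanges`
option additionally treats every boundary pseudo-reaction as reversible:
uptake limits encode a growth medium, not network structure, and with it the
bundled core E. coli model de-doubles to the expected 154 columns
(95 reactions + 39 internal reversibles + 20 exchanges); read literally from
the shipped medium bounds it gives 141. A package TSV dialect (header row of
reaction ids, a 0/1 reversible row, one row per metabolite) round-trips
networks bit-exactly for fixtures and toy models.

## Synthetic fixtures

`make_chain(L)` (unique EFM; degenerate frequency distribution F ≡ 1),
`make_parallel(b)` (exactly `b` EFMs; the diversity testbed; `b=2` is the
diamond), and `make_random(m, n, density, reversible_fraction, seed)`
(integer coefficients in {−2,−1,1,2}, rejection-sampled until a nontrivial
pathway exists). The 20-reaction fixture used in the directional tests
carries `reversible_fraction = 0.4`: real reconstructions are
majority-reversible, and reversibility is what gives the network the
alternative routes that penalization exploits — an all-irreversible random
network shows no penalization response at all. What fixtures do *not*
emulate: realistic degree distributions, compartments, biomass-style dense
columns, or the strong coupling structure of genome-scale models; passing on
fixtures therefore demonstrates correctness of the machinery, while the
core-model experiments carry the evidence about real-network behaviour.

## Experiment sizes

The packaged desk-scale experiment grid runs the core E. coli model at
N = 2000 collected solutions per run, 10 replicate trials of the
penalization grid p ∈ {0, 0, 2, 5, 20} with k = 4 seeds (~3 ms per LP with
HiGHS), and the parallel-5 representativeness check at N = 200, k = 1 over
20 RNG seeds. At these sizes the chi-bar medians (≈0.50 / 0.83 / 1.17 for
p = 2 / 5 / 20 vs unpenalized) already sit in the same range as grids run at
10–100× more iterations.

## Known limitations

- No enumeration completeness: LP sampling finds a diverse subset of EFMs,
  never provably all of them; the brute-force oracle is capped at 15 split
  reactions.
- Non-elementary solutions (supports that are unions of rays) occur and are
  flagged, not decomposed.
- The Wilcoxon caveat above: p-values on coupled frequency vectors should be
  read directionally, not literally.
- Determinism holds for a fixed (model, parameters, RNG seed) tuple on a
  fixed solver build; HiGHS is configured without randomized perturbation,
  but bit-identity across solver versions is not promised.
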