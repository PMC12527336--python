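# Methods

## The co-infection model

`cocktailnet` scores a candidate cocktail *C* (a subset of the virus rows
of a quantitative infection matrix) in two stages.

**Pairwise interference.** The quantitative phage–phage matrix is read as
*directed*: *w(p, q)* is the effect ON phage *p* OF phage *q* (a symmetric
input file therefore behaves symmetrically, and asymmetric measurements are
representable). Multiple partners compose multiplicatively,

    v_eff(p, h | C) = clamp( v(p, h) · Π_{q∈C, q≠p} w(p, q), 0, 1 ),

the simplest composition consistent with "multiplicative factor" semantics.
Alternatives (min over partners, mean) would be defensible; the product is
the only one that makes a completely lethal partner (w = 0) dominate
regardless of the rest of the formulation, which matches the intended
meaning of that anchor value. Synergy (w > 1) is applied at the per-phage
level and the result clamped to 1 *after* the product: inhibition is a
fraction by definition and can never exceed complete lysis.

**Independent action across phages.** Predicted growth inhibition of a host
is the noisy-OR of the members' effective virulences,

    I(h | C) = 1 − Π_{p∈C} (1 − v_eff(p, h | C)).

Independent action is the standard null model for co-infection: it reduces
correctly at the scale ends (any member with v_eff = 1 gives complete
lysis; an empty cocktail gives 0) and is monotone under cocktail growth
when interactions are neutral. No kinetic (time-course) behaviour is
modelled. Explicit higher-order (≥3-way) interactions are not representable
by a pairwise matrix; the multiplicative composition is this package's
policy for how pairwise values extrapolate.

**Cocktail criteria.** A cocktail evaluation records: coverage (hosts with
I above the infection threshold τ), total predicted inhibition Σ_h I(h|C),
antagonism burden Σ over *directed* pairs of max(0, 1 − w) (both directions
of a pair are real interference), per-host co-infection redundancy counts
(|{p ∈ C : v_eff(p, h) > τ}|), and per-virus marginal contributions
total(C) − total(C∖{p}). A contribution can be negative: removing a phage
that antagonises its partners raises the total. The default τ = 0 counts
any positive value as an infection, since 0 means "no lysis" on the input
scale.

## Ranking and redundancy policy

Two total orders are offered, applied lexicographically over the criteria:

* `coverage_first` (broadest host range, minimal antagonism): coverage
  desc, antagonism burden asc, total inhibition desc, size asc;
* `virulence_first`: total inhibition desc, coverage desc, antagonism
  burden asc, size asc.

Under the default redundancy policy `minimize_excess` the co-infection
excess Σ_h max(0, count_h − r*) (r* = 2 by default: at least two phages per
host has been proposed to enhance efficacy, but more is wasteful) is a late
ascending tie-break in both orders; `require_min` instead filters
candidates to those hitting every covered host at least r* times whenever
the full network makes that possible (d(h) ≥ r*); `ignore` does neither.
The final tie-break is always the sorted virus-name tuple, making every
designer run deterministic.

## Designers

**Exhaustive search** enumerates all subsets of size 1..K (K = 12 by
default — a hard cap, not a target; smaller winners are preferred by the
size tie-break) after pruning viruses with empty host range and flagging
hosts no phage can lyse. Enumeration is refused above a subset budget
(default 5×10⁶) with a pointer to the heuristic. Subset evaluation is
vectorised in chunks; the per-size winner is selected by a stable
lexicographic sort so the name tie-break costs nothing. Note that pruning
assumes a zero-host-range virus is useless; a hypothetical pure "helper"
phage that only boosts others synergistically would be pruned — a known
limitation of the pruning rule.

**Network-metrics greedy** iteratively adds the phage maximising the
resistance-weighted gain Σ_h (1/d(h)) · [I(h|S∪{p}) − I(h|S)], where d(h)
is the number of phages in the pruned network able to lyse h. Inverse-degree
weighting is the standard rare-element prioritisation of greedy set cover:
hosts killable by few phages dominate selection. The exact scoring rule is
this package's own reconstruction of a host-range/resistance-profile
heuristic; it is deterministic (lexicographic names on gain ties) and stops
at the cap or when no candidate has positive gain. Gains can be negative
for antagonised candidates, which is what steers the greedy away from them.

**Rotation series** designs n cocktails sequentially, each excluding every
virus already used (strict disjointness — the point of rotation therapy is
that later cocktails face bacteria that evolved against earlier, different
phages). The series truncates with a warning when no remaining virus covers
any host. Overlap-allowing variants are out of scope.

Reports always tabulate the best cocktail of every size under *both*
orderings, echo the configuration and the correction log, and break the
winner down into virus → host targets with expected lysis efficiency and
marginal contributions; when the interaction matrix is non-neutral an
antagonism-minimised alternative is reported alongside. Numbers are
rendered with 4 decimals and rendering is byte-deterministic.

## Input handling

The text dialect is whitespace-separated (spaces or tabs; the header's
corner token is optional and auto-detected by token count). Infection
values outside [0, 1] are clamped and logged rather than rejected — the
bounds are a scale convention, and raw assay scales (e.g. 0–3 cross-streak
virulence) can be divided down on read via an optional rescale factor,
logged. Interaction matrices are different: a negative factor has no
defined meaning and is a hard error, non-numeric cells fall back to 1
(neutral/unknown), the diagonal is forced to 1, and viruses absent from the
file get neutral rows/columns. A missing interaction file is equivalent to
an all-neutral matrix. Every silent mutation produces exactly one
correction-log entry, and reading already-corrected text logs nothing
(idempotence). Round trips preserve values to at least 6 significant
digits (9 are written).

## Synthetic networks

The generator draws occupied infection cells as Bernoulli(target_fill) with
virulence uniform on (0, 1], and assigns unordered virus pairs antagonistic
/ synergistic / neutral with the configured probabilities (symmetric
values; the model itself accepts directed inputs). Defaults: fill 0.3 —
mid-range of empirical infection networks and near the entropy maximum
where design is combinatorially hardest; p_antagonism 0.15 > p_synergy
0.05, since antagonism is the more commonly reported interaction in
cocktail studies; antagonistic factors U(0.1, 0.9), synergistic U(1.1, 2).
All-zero rows/columns are resampled away by default (they would be pruned;
an option keeps them for pruning tests). All randomness flows through
numpy's seeded PCG64 generator, so matrices are reproducible across runs
and platforms.

What the generator does *not* emulate: the nested or modular topology of
real phage–bacteria networks, correlated virulences, measurement noise, or
any relation between host range and virulence. Passing tests on synthetic
instances therefore demonstrate algorithmic correctness (optimality,
dominance, determinism, bounds), not predictive validity on laboratory
matrices.

## Test problem sizes and numerical choices

Oracle-equivalence and dominance tests run on 100 seeded instances of up to
10 viruses × 8 hosts with size cap 4 — small enough that an independent
pure-python brute-force enumerator is feasible as the comparison, while
covering mixed antagonism/synergy. Model-bound checks sample ~10⁴ random
cocktails with exponentially distributed interaction factors (so factors
above 1 are routinely exercised). Equality comparisons between the
designer and the oracle rely on both computing sums and products over the
same small index ranges; ties between distinct cocktails on continuous
criteria are measure-zero under the generators and are broken by names in
both implementations. Degenerate inputs (all-zero matrices, empty
cocktails, 1×1 matrices) are defined explicitly: empty cocktails score
zero everywhere, all-zero networks yield an empty winning cocktail.
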