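# Methods

This note records the scientific model, the numerical choices, and the
design decisions behind `agreenet`, in enough detail to re-derive every
quantity the package reports.

## 1. Response data model

A cohort's responses form a students × questions table of categorical
option labels with explicit missingness (`io.ResponseMatrix`). Option
sets are per-question (they may differ). Accuracy excludes missing
responses from both numerator and denominator; a student who answered
nothing has undefined accuracy and is excluded from cohort means.

## 2. Agreement network

Responses are encoded as a binary bipartite incidence matrix `M` over
students × (question, option) pairs; a missing response leaves the whole
option block of that question zero. The one-mode projection
`A = M Mᵀ` gives, for each student pair, the number of questions both
answered with the same option — for a 9-question test an integer in
[0, 9], equal to 9 exactly when the two response strings are identical.
Zero-agreement pairs are non-edges; students agreeing with nobody remain
in the graph as isolates.

## 3. Backbone (locally adaptive sparsification)

The projection is nearly complete (most student pairs agree on
something), so edges are filtered against a node-local null. For edge
(i, j) seen from endpoint i, the fractional weight is
`w_ij / strength(i)`; its p-value is the fraction of i's incident edges
with strictly greater fractional weight (one minus the empirical CDF
with a ≤ convention, so a node's maximal edges get p = 0 and ties share
a p-value). An edge is retained when p < α at **either** endpoint
(default α = 0.01; a stricter both-endpoints rule is available). This
keeps each student's strongest agreements regardless of their absolute
degree, and is parameter-free apart from α.

With small integer weights ties are common; the strictly-greater
convention means a node with many tied top edges retains them all
(each has p = 0), which is the desired behavior for clique-like groups.

## 4. Community detection (two-level map equation)

Communities minimize the two-level map equation

L(M) = q·H(Q) + Σᵢ pᵢ↻·H(Pⁱ)

with strength-proportional node visit rates `p_a = s_a / 2W` (the
stationary distribution of an unbiased walk on an undirected weighted
graph; no teleportation), community exit rates `q_c = cut_c / 2W`,
`q = Σ q_c`, and module codebooks over (exit, member-visit) vectors. For
a single module L reduces exactly to the entropy of the visit rates — a
tested identity.

The search is a greedy two-phase descent (local node moves that strictly
decrease L, then aggregation of communities into supernodes, repeated to
convergence) restarted `n_trials` times (default 100) from seeded
shuffled node orders; the best trial wins. Restart r uses an RNG child
of the root seed, so detection is deterministic given (graph, config).
Isolated nodes carry no walk flow; they are excluded from the objective
and appended as singleton communities. On graphs small enough to
enumerate every set partition (≤ 8 nodes), the search attains the global
minimum on all tested random graphs.

Weighted Newman–Girvan modularity
`Q = Σ_c [w_in(c)/W − (s(c)/2W)²]` is reported for the chosen partition
but never optimized.

## 5. Normative groups and motion screening

Communities with ≥ 10 members are *normative groups* (large enough for
group-level statistics). When per-run head motion (mean framewise
displacement, mm) is available, groups are screened for a motion
confound: a one-way fixed-effects ANOVA on per-run FD across groups
(observations are runs, not students); if the omnibus test is
significant at α = 0.05, Tukey HSD post hocs (Tukey–Kramer for unequal
sizes, p-values from the studentized-range distribution) identify groups
whose mean FD is significantly greater than *every* other group's; those
are excluded and the procedure repeats until the omnibus test is
non-significant or only two groups remain. The ANOVA decomposition and
the studentized-range statistic are computed in-package (tested against
scipy's `f_oneway` and `tukey_hsd` to 1e-8, with empirical type-I
calibration at α = 0.05 within [0.035, 0.065]); the distribution
functions come from scipy.

## 6. Conceptual modules and group profiles

A *module catalog* maps module IDs (e.g. `m1` "impetus force") to
disjoint sets of incorrect (question, option) pairs; a pair claimed by
two modules or matching the answer key is a hard validation error. For
each group, every incorrect response is attributed to the module owning
its pair (or to the unaffiliated pool), giving exact bookkeeping:
Σ_m raw[m] + unaffiliated = total incorrect. Two normalizations are
reported: `scaled_overlap` (module responses per group member, for
cross-group comparison) and `share` (fraction of the group's errors).
A module with share ≥ 0.5 is *dominant*; a group with no dominant module
is classified fragmented, with a fragmentation index equal to the share
entropy normalized by log2 of the number of active modules.

## 7. Synthetic generator (the test instrument)

The generator plants groups whose members share (i) a per-group
difficulty profile — *which* questions they miss — and (ii) a prototype
wrong answer per question — *what* they answer when they miss. These two
features are what makes real cohorts clusterable; both are needed:
with flat per-question difficulty, agreement is driven by accuracy
rather than group membership, and with independent per-student errors,
groups fragment into response-string cliques.

Per group:

- **Difficulty profile.** The error budget `(1 − p_correct) · n_questions`
  is spent as k = ⌊budget / 0.98⌋ "hard" questions at error probability
  0.98, chosen by weighted sampling without replacement with weights
  `(floor + module coverage) · Gamma(spread)` jitter (floor = 1.0,
  spread = 0.2), plus a flat low residual on the remaining questions.
  The flat residual is deliberate: lumpy sub-cap difficulty creates
  splinter sub-cliques (three or more students sharing a prototype
  error on a non-hard question out-weigh their edges to the group core
  and detach under the backbone rule). The profile sums exactly to the
  budget, so realized group accuracy is unbiased for `p_correct`.
- **Prototype.** One modal wrong answer per question, drawn from the
  group's module weights restricted to the modules present on that
  question (an arbitrary distractor, attributed to no conception, on
  uncovered questions). An erring student follows the prototype with
  probability `concentration` (default 0.95), otherwise errs
  idiosyncratically through the module weights.

The default configuration mirrors the modeled study: 107 students,
9 questions × 4 options, 9 modules; normative groups A (24, 0.77,
pure `m1`), B (17, 0.73, `m1`/`m9`), C (10, 0.53, five modules at equal
weight), a high-motion group D (13, 0.65, +0.2 mm mean FD), and nine
small background groups with distinct single dominant modules. Distinct
dominant modules matter: groups sharing a module share prototypes on its
questions and merge when their hard sets collide.

The module catalog itself is generated so that `m1` spans one distractor
on every question (the broad dominant conception) and every other module
spans ≥ 2 questions, partitioning all 27 incorrect pairs.

Calibration of these generator parameters was done at design time
against partition recovery and frozen before the acceptance surface was
evaluated; at the freeze, the median adjusted Rand index between the
inferred and planted partitions over 100 seeds was 0.956 (min 0.66), and
recovered normative-group accuracies sat within 1.4 binomial standard
errors of their planted values on every seed.

## 8. Numerical and engineering choices

- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; generators are pure functions of (config, seed); pipeline
  re-runs are byte-identical (sha256-checked in the run manifest).
- The map equation is evaluated in bits (log2); the search accepts moves
  improving L by more than 1e-10 bits to avoid tie-cycling.
- ARI/NMI come from scikit-learn; F, studentized-range and truncated
  normal distributions from scipy. The projection, map equation,
  modularity, backbone, ANOVA decomposition and Tukey statistic are
  implemented in-package and verified against independent literal
  oracles (nested loops, exhaustive partition enumeration, brute-force
  empirical CDFs, scipy references) in the test suite.
- Exit codes: 0 success (including degenerate-but-valid cases such as no
  community reaching the normative size), 1 validation error, 2 runtime
  error.

## 9. Limitations

- The generator is a test instrument, not a claim about real cohorts:
  real between-group separation is unknown, and the planted-recovery
  results certify the pipeline, not any dataset.
- The map-equation search is greedy with restarts; global optimality is
  only guaranteed where exhaustive enumeration is feasible.
- The motion screen assumes per-run FD values are exchangeable within
  groups and uses a classical fixed-effects ANOVA; it ignores
  within-student correlation across runs.
- Two-level (not hierarchical) map equation only; directed walks and
  teleportation are out of scope.
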