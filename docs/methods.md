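# Methods

## The evaluation problem

Orthologous-gene clustering tools applied to the same genome set produce
different partitions of (essentially) the same gene universe. Lacking a
ground truth, `paneval` scores each partition by how often it agrees with
two independent arbiters on co-clustered gene pairs: functional annotation
(COG) where available, and the consensus of the other tools elsewhere. The
unit of evidence is the unordered gene pair, as in Rand-index-style
partition comparison, but the arbiter is asymmetric: agreement is only
evaluated on the *pair universe* — pairs co-clustered by at least one
profile — never on the quadratically many never-co-clustered pairs, which
carry no information about tool disagreement and would swamp the score.

## Scoring model

For each universe pair and profile *s*, at most one point:

* both genes COG-annotated: `+1` if (same COG ∧ together in *s*) or
  (different COG ∧ apart in *s*). COG identity is string equality of single
  identifiers; the input format forbids multi-COG genes (a conflicting
  duplicate row is an error, not a merge).
* otherwise, with `c` = number of profiles placing the pair together and
  cutoff `x`: `+1` if (c > x ∧ together in *s*); under the default
  **majority** rule, `+1` if (c < x ∧ apart in *s*); at `c = x` neither
  direction is rewarded. An alternative **literal** rule rewards separation
  when the number of profiles placing the pair *apart* is `< x`
  (`ScoringConfig(consensus_rule="literal")`). The two readings coincide for
  N = 2 and diverge for N ≥ 3 (e.g. c = 2 of 3, x = 1.5: majority gives the
  lone separator nothing, literal rewards it). The majority rule is the
  default because it is the branch-symmetric counterpart of the COG branch
  and matches the definition of x as a count of profiles reporting the pair
  together; the literal rule is retained for auditability.

**Cutoff default x = N/2**, deliberately fractional for even N so the
`c = x` dead zone cannot occur. Any `0 ≤ x ≤ N` is accepted, fractional or
integer.

**Scope.** The scoring universe defaults to pairs from *all* clusters;
the shared-link comparison matrix defaults to pairs from *core* clusters
(each profile classified against its own genome set). Both operations take
an explicit `scope` argument, because the two conventions answer different
questions: "which profile is most concordant overall" vs "how much of the
conserved backbone do two tools share".

**Harmonization.** The pair evidence presumes every gene exists in every
profile, but tools drop or fail to assign genes. Before scoring, any gene
present in ≥ 1 profile but absent from profile *s* is added to *s* as a
singleton (co-clustered with nothing — the neutral completion). The number
of singletons added per profile is carried into the score report;
`strict=True` (CLI `--strict`) refuses mismatched universes instead.

**Ties and ranking.** Competition ranking on descending score; the reported
best profile is the lexicographically first of the top scorers, with the
full tie list attached — a tie is information, not an error.

## Cluster classification

Occurrence = number of distinct genomes contributing ≥ 1 gene (paralogs do
not inflate it). `unique` ⇔ occurrence = 1; `core` ⇔ occurrence ≥
⌈core_fraction · G⌉ (default core_fraction = 1.0, strict core); `accessory`
otherwise; `unique` wins in the degenerate G = 1 case. The threshold product
is rounded at the 9th decimal before the ceiling so float noise (e.g.
0.07 × 100 = 7.000000000000001) cannot shift it. Percentages are
**truncated** to two decimals using integer arithmetic
(`count·10⁴ // total / 100`), the convention under which a
419-of-11716 core fraction prints as 3.57%; the three percentages can
therefore undershoot 100 by ≤ 0.03.

## Synthetic data generator

`simulate_pangenome(G, K, core_frac, paralog_rate, seed)` emulates the
study conditions the evaluator targets: `round(core_frac·K)` families occur
in all G genomes; every other family draws its occurrence uniformly from
1..G−1 (the simplest model that populates all three occurrence classes);
each (family, present-genome) slot yields one gene plus one extra paralog
with probability `paralog_rate`. Defaults `core_frac = 0.2`,
`paralog_rate = 0.05` give the open-pan-genome shape typical of genus-level
sets. `annotate_cog_synthetic` assigns each gene its family's COG with
probability `coverage` (default 0.8, about the fraction of a bacterial
proteome COG typically covers), swapped to a uniformly different family's
COG with probability `error_rate` (default 0.02). `perturb_profile` applies,
in order: per-cluster **split** (uniform non-trivial bipartition of a
shuffled member list — over-splitting, the failure mode that depresses core
counts), per-cluster **merge** into a uniformly chosen surviving partner
(over-lumping), and per-gene **drop** (harmonization later reinstates
dropped genes as singletons). All randomness flows from integer seeds
through `numpy.random.default_rng`, with sets iterated in sorted order
before any draw, so every operation is bit-reproducible; independent
operations take independent seeds rather than sharing a stream.

What the generator does **not** emulate: sequence evolution, fragmented
assemblies, contamination, genome-size heterogeneity, or correlated errors
between tools (real tools sharing an algorithmic family fail similarly;
perturbations here are independent). Passing the recovery and degradation
tests therefore shows the score behaves correctly against these noise
models, not that it resolves every real-world tool disagreement.

## Numerical and design choices

* Gene pairs are canonically ordered by the rendered `genome|local_id`
  string, making pair-set intersections well-defined across profiles.
* Pair enumeration is per cluster (cost Σ k²), never over the full gene
  cross product; a `max_cluster_size` guard (off by default) errors loudly
  on pathological clusters.
* The optimized scorer uses each profile's gene→cluster index; the
  brute-force reference scorer (`score_profiles_bruteforce`) deliberately
  shares no code with it — it rebuilds the universe by nested loops and
  answers membership by scanning raw cluster lists — and the two are
  asserted equal on the worked example and on batches of random instances.
* Degenerate inputs: an empty profile summarizes to an error; an empty pair
  universe (all profiles all-singletons) scores everyone 0 with no best-er
  distinction beyond the tie rule; `x` outside [0, N] is a config error.

## Problem sizes

The randomized checks use instances of ≤ 6 genomes × ≤ 25 families
(≤ ~200 genes, ≤ 6 profiles) where the quadratic brute-force oracle is
instant; the recovery study uses G = 8, K = 60 over 20 seeds and the
degradation study G = 10, K = 200 over 20 seeds × 4 split rates, sizes at
which score differences dwarf seed noise while the whole suite stays in the
seconds range.

## Known limitations

* The score is comparative, not calibrated: it ranks profiles on one genome
  set but has no cross-dataset scale and no significance model for score
  gaps.
* COG-branch quality is bounded by annotation quality; systematically wrong
  annotations bias the score toward profiles repeating the same mistake.
* The consensus branch assumes tool errors are mostly independent; a
  majority of tools sharing a failure mode will be rewarded for it.
* Only three-way core/accessory/unique classification is provided (no
  soft-core/shell/cloud four-way split, no Heaps'-law openness estimate).
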