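# Methods

## Scope and model

`pedagg` quantifies familial aggregation (FA) of a binary trait on large,
irregular pedigrees: does a family, or a neighbourhood of relatives around an
affected person, contain more affected members — or more closely related
affected members — than the population prevalence explains?  The package
implements five tests, a Monte-Carlo empirical null, a Mendelian trait
simulator, a synthetic pedigree generator, and a benchmark harness that
measures how reliably each test singles out a simulated case family among
prevalence-matched decoys.

All relatedness is expressed through the kinship coefficient
φ(i, j) — the probability that one allele drawn at random from i and one
from j are identical by descent.  φ is computed per family by the classical
recursion in topological order: founders are treated as non-inbred and
mutually unrelated (φ(i,i) = 1/2, φ(i,j) = 0); for a non-founder c with
parents f, m:

    φ(c, c) = (1 + φ(f, m)) / 2
    φ(c, j) = (φ(f, j) + φ(m, j)) / 2          for j preceding c

Inbreeding therefore propagates through the self-kinship term.  A missing
parent behaves as an anonymous unrelated founder (contributes 0), which is
mathematically identical to materialising one.  Unphenotyped individuals
participate fully in φ — they connect relatives — but never in affected
counts or sampling pools.

## Pedigree handling

The on-disk format is the 6-column PED/FAM dialect (family, id, father,
mother, sex, phenotype; sex 1/2/0, phenotype 2/1/0 or −9, parent "0" =
missing).  Reader-level completion inserts an anonymous unphenotyped founder
for single-parent records.  Validation rejects dangling parent references,
explicit parent-sex contradictions (a father recorded as female, a mother as
male) and parentage cycles.  Unknown-sex parents are accepted at read time:
filtering removes unknown-sex individuals and singletons (no parent and no
child in the pedigree) iterated to a fixed point, severing links to removed
parents, so a filtered pedigree may contain single known parents — handled
by the missing-parent rule above.

Generation indices are 1-based from the family founders; a child sits one
level below its deepest parent and married-in founders inherit their
spouse's depth, made consistent by constraint propagation ("spouse" always
means "shares a child"; PED has no marriage records).

## The five tests

For a family with n phenotyped members, k of them affected, and a trait
prevalence R = (total affected)/(total phenotyped):

* **IF** (genealogical index of familiality), per family: the mean of
  φ(i, j) over all unordered pairs of affected members (needs k ≥ 2).
* **KS** (kinship sum), per affected individual i: Σ φ(i, j) over all other
  affected members of i's family (needs ≥ 1 other affected).
* **GR / GC** (kinship-group tests), per affected individual i: the group of
  i is every phenotyped family member at least as close to i as i's most
  distant affected relative with φ > 0 (ties in the reference relative are
  broken by lexicographic id).  GR counts the affected inside the group,
  including i; GC records φ of the closest affected group member.  Both are
  undefined when i has no affected relative sharing kinship.
* **PB** (binomial test), per family: the exact upper tail
  P(X ≥ k), X ~ Binomial(n, R), with R estimable from the data or supplied
  (e.g. a cohort prevalence excluding singletons).

## Empirical nulls

The null reference for the four kinship-based tests resamples, B times
(default 50 000), the observed number of affected individuals uniformly
without replacement from the pool of **all** phenotyped individuals across
families.  One-sided direction "greater" throughout: more kinship or more
affected means more aggregation.  The Monte-Carlo estimator is the add-one
rule P = (b + 1)/(B_eff + 1), never zero.

Two null constructions are used, chosen after explicit calibration analysis:

* **IF — per-family conditional null.**  The statistic is recomputed on the
  replicates in which at least two of the family's members were sampled;
  B_eff is that replicate count.  Matching the conditioning between unit
  selection (an IF family is testable iff it has ≥ 2 observed affected) and
  the null makes the permutation P exactly valid under exchangeability of
  affected labels.

* **KS/GR/GC — pooled conditional null.**  In every replicate the statistic
  is recomputed (kinship groups re-derived from the replicate's affected
  set) for *every* sampled individual that meets the test's own
  applicability condition, and these values are pooled across replicates and
  families into one reference distribution per test; B_eff is the pooled
  size.  Under the null an observed testable unit is a draw from the same
  mixture as the pooled values, so P values are uniform up to the atoms of
  the mixture.  A strictly per-unit conditional null is also exchangeable
  and was evaluated; it leaves each unit's P supported on the atoms of that
  unit's own (far more discrete) statistic and concentrates large mass at
  P = 1, so the pooled construction was preferred.  The two constructions
  agree in their rejection rates at the 0.05 level; neither claims numerical
  identity with any other software's resampling scheme.

Per run and test, Benjamini–Hochberg adjustment is applied across all
testable units (families for IF/PB, affected individuals for KS/GR/GC);
untestable units are reported with status `na` and excluded from the BH
family size and from ranking.  Individual-level tests are summarised to
family level by the minimum P_raw among the family's affected members.
Ranking is always on unadjusted P values, ascending, with tied values
replaced by the mean of the tied positions.

### Calibration properties and two structural caveats

With control-only Bernoulli phenotypes the affected labels are exchangeable
given their total, so the constructions above are valid permutation tests;
the bundled calibration check (200 synthetic families, R = 1/16, B = 2 000)
computes the rejection rate of each test at P_raw ≤ 0.05 and a
Kolmogorov–Smirnov uniformity statistic.  Two discreteness effects are
structural and worth stating plainly:

* **GC can be unable to reject at 0.05.**  In outbred pedigrees the GC
  statistic is capped at φ = 0.25 (closest possible relative), and the null
  mass at the cap — the probability that some first-degree relative of i is
  among the sampled affected — is of order 0.2–0.3 at prevalences like
  1/16.  No unit can then attain P ≤ 0.05, so GC's rejection rate at that
  level is 0: valid (conservative), but with no resolution in the far tail.
* **KS P values are uniform only up to atoms.**  The kinship-sum statistic
  is discrete; its largest atoms (units whose affected relatives all share
  zero kinship, giving a sum of 0, and units with a single first-degree
  affected relative, giving 0.25) carry ~0.1 mass each.  The empirical P
  CDF is a step function touching the diagonal from below, so a
  Kolmogorov–Smirnov test against the continuous uniform rejects once the
  unit count exceeds a few hundred, for any B.  Rejection rates at
  conventional levels are unaffected (the P values remain super-uniform).

## Trait simulation

Case families follow a Mendelian autosomal dominant model with a single
introduced allele and no phenocopies:

1. **Gene dropping.**  One founder with at least one descendant is chosen
   uniformly and seeded as a heterozygous carrier; in topological order a
   child of one carrier parent inherits with probability 1/2, of two carrier
   parents with probability 3/4 (carriers are tracked as a binary state).
   Affected ⇔ carrier.
2. **Penetrance Q ∈ {1.0, 0.6, 0.3}.**  Exactly round-half-up((1 − Q)·A) of
   the A affected are switched to unaffected, drawn uniformly without
   replacement (a deterministic count rather than per-individual Bernoulli,
   so the realised penetrance is exact per family).
3. **Affected generations G ∈ {2, 3, all}.**  The retained sub-branch is the
   seeded founder, its spouses, and all descendants (plus their spouses)
   whose generation lies within [g₀, g₀ + G − 1], g₀ the founder's
   generation.  Inside the window the Mendelian status is kept; every other
   phenotyped member is cleared and redrawn as Bernoulli(R).  G = all is the
   identity; an integer G larger than the family's depth is clamped to
   "all" inside the benchmark pipeline (a shallow family is simply fully
   affected) and is an error when calling the masking step directly.

Control families assign each phenotyped member affected status independently
with probability R ∈ {1/10, 1/16, 1/25, 1/50, 1/80}, so the expected overall
proportion of affected equals the prevalence used by the tests.  The
benchmark grid pairs each (Q, R) with the generation settings of the study
design (G = 3/all for R ≥ 1/16; G = 2/3/all for R ≤ 1/25; Q = 0.3 only with
R ∈ {1/25, 1/50}); off-grid scenarios run with a warning.

A *family set* F_a assigns family a the case pipeline and every other family
fresh controls; controls are regenerated independently per set.  A case
family ending with fewer than two affected is redrawn with a fresh substream
(IF and KS need two affected); families that are structurally unable to
reach two affected — e.g. a trio at Q = 0.6, where a pair of affected always
loses one to the exact-count mask — keep their last draw after the redraw
budget (200), so the set count stays intact and such sets carry weak cases.
RNG substreams derive from (seed, scenario key, set index, stage), making
results reproducible and independent of the order in which sets are
consumed.

## Synthetic pedigree backbone

The generator emulates the shape of large longitudinal family-study
pedigrees: independent families of 2–5 generations (drawn uniformly), built
top-down from a founder couple; sibship sizes are zero-truncated Poisson
with mean 3.6; each child below the family's target depth reproduces with
probability 0.8, acquiring a new unrelated founder spouse; one forced line
of descent guarantees the drawn depth; sexes are i.i.d. with ratio 0.5.
These defaults put the median family size near 36 (the size distribution is
right-skewed, roughly 5 to several hundred members).  Everything the
generator emits is phenotype-ready, acyclic, has both-or-none parents and
survives filtering unchanged.

What the backbone deliberately does not model: unphenotyped ancestors (real
cohorts often have the two oldest generations unphenotyped), consanguinity
loops (kinship ground truth stays analytic), non-random ascertainment, and
any particular study's exact size distribution.  Passing benchmarks on this
backbone therefore demonstrates correctness and qualitative behaviour of the
tests, not their quantitative operating characteristics on any specific real
cohort.

## Benchmark evaluation

For each scenario and test, every family set is reduced to family-level
P_raw values (min-P for the individual-level tests; untestable families are
conservatively assigned P = 1, tying them at the bottom of rankings), BH is
applied within the set, and two views are produced:

* per set — the tie-averaged rank of the case family on P_raw, and its
  significance at FDR 0.05 on the within-set P_adj; ranks are binned as
  significant top-3, insignificant top-3, ranks 4–10, above 10, plus counts
  of rank-1 cases (total and significant), and rank-1 overlaps across tests
  are tabulated as an exact partition by test subset;
* pooled — all sets form one imbalanced classification problem (one case
  per set, families − 1 controls per set) thresholded on P_adj; confusion
  counts obey TP + FN = #sets and FP + TN = #sets × (families − 1), and the
  precision/recall curve is a step function over every distinct observed P
  (no interpolation, which would be optimistic in PR space), with the
  operating point nearest P_adj = 0.05 marked.

Pooling P_adj across sets before thresholding is available as an alternative
reading but within-set adjustment is the default, since significance is
reported per analysis.

## Numerical choices

* Tie handling when counting null ≥ observed uses an absolute tolerance of
  1e-12, protecting float-identical statistics computed along different
  vectorised paths.
* Replicates are processed in chunks (default 512); because the underlying
  generator consumes random values row-by-row, results are independent of
  the chunk size and byte-reproducible given the seed.
* Sampling without replacement per replicate uses an argpartition of i.i.d.
  uniforms, vectorised per chunk.
* BH is the standard step-up procedure (via statsmodels), the binomial tail
  is an exact summation (scipy), and tie-averaged ranks come from
  scipy.stats.rankdata.

## Problem sizes of the bundled checks

The packaged test-suite and the `scripts/acceptance.py` summary use sizes
chosen to exercise every code path at full fidelity while remaining
single-CPU friendly: the family-set accounting runs the full 415-family
backbone (415 × 414 = 171 810 control instances) with the closed-form
binomial test; null calibration uses 200 families at B = 2 000; the
penetrance/prevalence response uses 50 families, three scenario cells,
B = 2 000 and five simulation seeds; kinship is cross-validated against a
200 000-drop gene-dropping IBD estimate on 20 families, and the empirical P
estimator against exhaustive label enumeration on small families.  Full
replication of a published benchmark at B = 50 000 with all five tests on a
real pedigree backbone is supported by the same interfaces (`pedagg assess`)
but is not part of the bundled checks.

## Known limitations

* GR and GC inherit the coarse group geometry of small neighbourhoods; they
  are best read as supporting evidence, never as stand-alone significance.
* The binomial test ignores kinship entirely; in one very large family it
  only asks whether the family-wide affected fraction exceeds prevalence.
* The simulator's binary carrier state ignores homozygous carriers'
  transmission advantage; with a single introduced allele per family this
  only matters for within-family remating patterns that the synthetic
  backbone excludes.
* X-linked inheritance, Jacquard's condensed identity coefficients,
  stratified or matched resampling, and ascertainment modelling are out of
  scope.
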