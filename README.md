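# pedagg

Familial aggregation testing and benchmarking on large, unstructured
pedigrees.

Familial aggregation (FA) analysis asks whether a binary trait clusters
among relatives beyond what chance and the population prevalence explain —
classically the first step of a genetic-epidemiology study, and a hard one
when pedigrees span hundreds of loosely connected members over several
generations.  `pedagg` provides, for people working with cohort pedigrees
(PED/FAM files):

* **Five FA tests.**  With φ(i, j) the kinship coefficient (probability of
  identity by descent for one allele drawn from each individual):
  * `IF` — genealogical index of familiality: per family, the mean φ over
    all pairs of affected members;
  * `KS` — kinship sum: per affected individual *i*, Σ<sub>j≠i</sub> φ(i, j)
    over the other affected family members;
  * `GR` / `GC` — kinship-group tests: inside the group of relatives at
    least as close to *i* as its most distant affected relative, the count
    of affected (GR) and the kinship of the closest affected (GC);
  * `PB` — exact binomial test: for a family of phenotyped size *n* with
    *k* affected and trait prevalence *R*, the upper tail
    P(X ≥ k), X ∼ B(n, R).

  The kinship-based tests are referenced to an empirical null built by
  resampling the observed number of affected individuals from the pool of
  all phenotyped members (default B = 50 000 replicates), with add-one
  Monte-Carlo P values, Benjamini–Hochberg adjustment, minimum-P family
  summarisation and tie-averaged ranking on unadjusted P values.
* **A Mendelian trait simulator**: autosomal dominant gene dropping from a
  seeded founder, penetrance masking (Q), restriction of the affected
  sub-branch to G generations, and Bernoulli(R) control phenotypes —
  assembled into *family sets* (one case family + prevalence-matched
  controls for every other family).
* **A synthetic pedigree generator** shaped like large family-study
  cohorts (2–5 generations, median family size ≈ 36, no consanguinity).
* **A benchmark harness** scoring each test's ability to detect the case
  family: rank summaries, rank-1 overlap tables, confusion counts and
  precision/recall curves on the pooled, heavily imbalanced case/control
  problem.

See `docs/methods.md` for the models, null constructions, and their known
structural caveats.

## Worked example

```python
import pedagg as pg
from pedagg.simulate import Scenario

# binomial FA test at a cohort prevalence R = 265/4373
for name, (n, k) in {"A": (20, 5), "XL": (3676, 236)}.items():
    print(f"group {name}: n={n}, k={k}, P_raw = {pg.pb_test(n, k, 265/4373):.3g}")

# mini benchmark: 30 synthetic families, kinship-sum vs binomial test
ped = pg.generate_pedigree(pg.PedigreeSpec(n_families=30, seed=7))
res = pg.run_assessment(ped, [Scenario(1.0, 1/25, 3)], ["KS", "PB"], B=2000, seed=7)
for t in ("KS", "PB"):
    r = res.per_test["Q1_R0.04_G3"][t]
    print(t, "top-rank cases:", r.rank_summary.top_rank_total,
          "significant top-3:", r.rank_summary.significant_top3,
          "| mean case rank:", round(sum(r.case_ranks) / 30, 2))
```

prints

```
group A: n=20, k=5, P_raw = 0.00588
group XL: n=3676, k=236, P_raw = 0.189
KS top-rank cases: 10 significant top-3: 4 | mean case rank: 3.93
PB top-rank cases: 15 significant top-3: 6 | mean case rank: 3.55
```

Group A — 20 phenotyped members, 5 affected — would be a chance finding
about 6 times in a thousand at this prevalence, while the very large group
XL's 236 affected are unremarkable (P ≈ 0.19): its affected fraction simply
tracks the cohort prevalence.  In the mini benchmark each of the 30 families
takes a turn as the simulated case (fully penetrant trait across three
generations, controls at 4 % prevalence): both tests place the case family
first in a third to a half of the sets, and the mean tie-averaged rank of
the case is below 4 of 30 for both.

The same functionality is scriptable via the CLI:

```sh
pedagg genped --n-families 50 --seed 1 --out backbone.ped
pedagg kinship backbone.ped --out-prefix backbone
pedagg test cohort.ped --tests PB,KS --b 50000 --seed 1 --out-prefix results
pedagg assess backbone.ped --q 0.6 --r 0.0625 --g 3 --tests PB,KS,IF --b 2000 \
    --seed 1 --out assessment/
```

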