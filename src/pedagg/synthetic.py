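"""Synthetic multi-family pedigree generator.

Produces backbones shaped like the large longitudinal family-study
pedigrees the benchmark targets: a few hundred independent families, two to
five generations each, median family size around 36, no consanguinity
(every spouse is a fresh unrelated founder), all members phenotype-ready.
Each family grows top-down from a founder couple; sibship sizes follow a
zero-truncated Poisson, and each child reproduces (acquiring a married-in
founder spouse) with a fixed probability while the family's drawn
generation count has not yet been reached.  One forced line of descent
guarantees the drawn depth is attained.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterator

import numpy as np
from scipy.optimize import brentq

from .pedigree import (
    Individual,
    Pedigree,
    Phenotype,
    Sex,
    assign_generations,
    split_families,
)

__all__ = ["PedigreeSpec", "generate_pedigree", "pedigree_summary"]


@dataclass(frozen=True)
class PedigreeSpec:
    """Shape parameters of a generated backbone.

    ``mean_sibship`` is the mean number of children per reproducing couple
    (zero-truncated Poisson); ``repro_prob`` the probability that a child
    below the family's target depth reproduces.  Defaults are tuned so the
    default spec yields a median family size near 36 with 2-5 generations.
    """

    n_families: int
    generations: tuple[int, int] = (2, 5)
    mean_sibship: float = 3.6
    repro_prob: float = 0.8
    sex_ratio: float = 0.5
    seed: int = 0
    fixed_sibship: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.generations
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if not (2 <= lo <= hi <= 10):
            raise ValueError("generations range must lie within [2, 10]")
        if self.mean_sibship <= (0 if self.fixed_sibship else 1):
            raise ValueError("mean_sibship too small")
        if not 0.0 <= self.repro_prob <= 1.0:
            raise ValueError("repro_prob must lie in [0, 1]")


def _ztp_lambda(mean: float) -> float:
    """Poisson rate whose zero-truncated mean equals ``mean``."""
    return brentq(lambda lam: lam / (1.0 - np.exp(-lam)) - mean, 1e-9, 60.0)


def _draw_sibship(spec: PedigreeSpec, lam: float, rng: np.random.Generator) -> int:
    if spec.fixed_sibship:
        return int(round(spec.mean_sibship))
    while True:
        k = int(rng.poisson(lam))
        if k > 0:
            return k


def _draw_sex(spec: PedigreeSpec, rng: np.random.Generator) -> Sex:
    return Sex.MALE if rng.random() < spec.sex_ratio else Sex.FEMALE


def _generate_family(
    fam: str, spec: PedigreeSpec, lam: float, rng: np.random.Generator
) -> Iterator[Individual]:
    lo, hi = spec.generations
    g_star = int(rng.integers(lo, hi + 1))
    n = 0

    def new_id() -> str:
        nonlocal n
        n += 1
        return f"{fam}_{n}"

    def founder(sex: Sex) -> Individual:
        return Individual(new_id(), fam, None, None, sex, Phenotype.UNAFFECTED)

    father, mother = founder(Sex.MALE), founder(Sex.FEMALE)
    yield father
    yield mother
    # (father_id, mother_id, generation of the couple, on the forced spine?)
    couples = [(father.id, mother.id, 1, True)]
    while couples:
        fid, mid, gen, spine = couples.pop()
        for ci in range(_draw_sibship(spec, lam, rng)):
            sex = _draw_sex(spec, rng)
            child = Individual(new_id(), fam, fid, mid, sex, Phenotype.UNAFFECTED)
            yield child
            child_gen = gen + 1
            if child_gen >= g_star:
                continue
            forced = spine and ci == 0
            if forced or rng.random() < spec.repro_prob:
                spouse = founder(Sex.FEMALE if sex is Sex.MALE else Sex.MALE)
                yield spouse
                f2, m2 = (
                    (child.id, spouse.id) if sex is Sex.MALE else (spouse.id, child.id)
                )
                couples.append((f2, m2, child_gen, forced))


def generate_pedigree(spec: PedigreeSpec) -> Pedigree:
    """Generate ``spec.n_families`` independent families; deterministic in
    (spec, seed)."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    lam = None if spec.fixed_sibship else _ztp_lambda(spec.mean_sibship)
    width = max(4, len(str(spec.n_families)))
    inds: list[Individual] = []
    for a in range(1, spec.n_families + 1):
        inds.extend(_generate_family(f"F{a:0{width}d}", spec, lam, rng))
    return Pedigree(inds)


def pedigree_summary(ped: Pedigree) -> dict:
    """Counts, family size quantiles and generation-count histogram."""
    sizes = sorted(Counter(i.family_id for i in ped).values())
    if not sizes:
        return {
            "n_individuals": 0,
            "n_families": 0,
            "family_sizes": {},
            "generation_counts": {},
        }
    quant = {
        "min": float(sizes[0]),
        "q25": float(np.quantile(sizes, 0.25)),
        "median": float(np.quantile(sizes, 0.5)),
        "q75": float(np.quantile(sizes, 0.75)),
        "max": float(sizes[-1]),
    }
    gen_hist: Counter = Counter()
    for fam in split_families(ped):
        gen_hist[max(assign_generations(fam).values())] += 1
    return {
        "n_individuals": len(ped),
        "n_families": len(sizes),
        "family_sizes": quant,
        "generation_counts": dict(sorted(gen_hist.items())),
    }
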