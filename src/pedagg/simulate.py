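"""Mendelian trait simulation on pedigree backbones.

Case families carry an autosomal dominant, fully penetrant trait introduced
by a single founder and transmitted by gene dropping; reduced penetrance is
then imposed by masking a fixed fraction of affected members, and the
affected region of the family can be restricted to a window of G
generations anchored at the seeded founder (individuals outside the window
have their status cleared and redrawn from the prevalence model).  Control
families receive independent Bernoulli(R) phenotypes.  One *family set*
pairs one case family with prevalence-matched controls for every other
family of the backbone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

from .pedigree import (
    Pedigree,
    Phenotype,
    assign_generations,
    split_families,
)

__all__ = [
    "TABLE_GRID",
    "Scenario",
    "PhenotypeAssignment",
    "FamilySet",
    "gene_drop_dominant",
    "apply_penetrance",
    "mask_generations",
    "generate_controls",
    "build_family_sets",
    "iter_family_sets",
]

ALL_GENERATIONS = "all"

# (Q, round(1/R)) -> admissible generation settings of the benchmark design.
TABLE_GRID: dict[tuple[float, int], tuple[object, ...]] = {
    (1.0, 10): (3, ALL_GENERATIONS),
    (0.6, 10): (3, ALL_GENERATIONS),
    (1.0, 16): (3, ALL_GENERATIONS),
    (0.6, 16): (3, ALL_GENERATIONS),
    (1.0, 25): (2, 3, ALL_GENERATIONS),
    (0.6, 25): (2, 3, ALL_GENERATIONS),
    (0.3, 25): (2, 3, ALL_GENERATIONS),
    (1.0, 50): (2, 3, ALL_GENERATIONS),
    (0.6, 50): (2, 3, ALL_GENERATIONS),
    (0.3, 50): (2, 3, ALL_GENERATIONS),
    (1.0, 80): (2, 3, ALL_GENERATIONS),
    (0.6, 80): (2, 3, ALL_GENERATIONS),
}


@dataclass(frozen=True)
class Scenario:
    """One (Q, R, G) cell: penetrance, prevalence, affected generations."""

    q: float
    r: float
    g: object  # 2, 3 or "all"

    def __post_init__(self) -> None:
        if not 0.0 < self.q <= 1.0:
            raise ValueError("penetrance Q must lie in (0, 1]")
        if not 0.0 < self.r < 1.0:
            raise ValueError("prevalence R must lie in (0, 1)")
        if self.g != ALL_GENERATIONS and (not isinstance(self.g, int) or self.g < 1):
            raise ValueError("G must be a positive integer or 'all'")

    @property
    def label(self) -> str:
        g = self.g if self.g == ALL_GENERATIONS else f"{self.g}"
        return f"Q{self.q:g}_R{self.r:g}_G{g}"

    def in_grid(self) -> bool:
        key = (round(self.q, 2), round(1.0 / self.r))
        return key in TABLE_GRID and self.g in TABLE_GRID[key]

    def seed_key(self) -> tuple[int, int, int]:
        """Integer encoding used to derive per-scenario RNG substreams."""
        g = 0 if self.g == ALL_GENERATIONS else int(self.g)
        return (int(round(self.q * 100)), int(round(1.0 / self.r * 100)), g)


@dataclass
class PhenotypeAssignment:
    """Affected/unaffected status plus provenance for one family's
    phenotyped members.  Provenance values: ``mendelian``,
    ``penetrance-masked``, ``generation-cleared``, ``bernoulli``."""

    status: dict[str, Phenotype]
    provenance: dict[str, str]

    def affected_ids(self) -> list[str]:
        return [i for i, s in self.status.items() if s is Phenotype.AFFECTED]


@dataclass
class FamilySet:
    """One case family plus independently drawn controls for all others."""

    case_family_id: str
    case: PhenotypeAssignment
    controls: dict[str, PhenotypeAssignment]
    scenario: Scenario
    n_redraws: int = 0
    carriers: frozenset[str] = field(default_factory=frozenset)

    def phenotype_map(self) -> dict[str, Phenotype]:
        out = dict(self.case.status)
        for assignment in self.controls.values():
            out.update(assignment.status)
        return out


# -- building blocks --------------------------------------------------------

def _phenotyped(family: Pedigree) -> list[str]:
    return family.phenotyped_ids()


def gene_drop_dominant(
    family: Pedigree,
    rng: np.random.Generator,
    seed_carrier: bool = True,
) -> tuple[PhenotypeAssignment, frozenset[str], str | None]:
    """Drop a dominant allele from one seeded founder through the family.

    The carrier founder is drawn uniformly among founders with at least one
    child (falling back to any founder).  A child of one carrier parent
    inherits the allele with probability 1/2, of two carrier parents with
    probability 3/4.  Full penetrance, no phenocopies: affected == carrier.
    ``seed_carrier=False`` is a diagnostic mode with no allele present.
    Returns (assignment over phenotyped members, carrier set, founder id).
    """
    if len(family) == 0:
        raise ValueError("empty family")
    founder_id: str | None = None
    carriers: set[str] = set()
    if seed_carrier:
        founders = sorted(family.founders())
        with_kids = [f for f in founders if family.children_of(f)]
        pool = with_kids or founders
        founder_id = pool[int(rng.integers(len(pool)))]
        carriers.add(founder_id)
    for iid in family.topological_ids():
        if iid in carriers:
            continue
        n_carrier_parents = sum(1 for p in family.parents_of(iid) if p in carriers)
        if n_carrier_parents and rng.random() < 1.0 - 0.5 ** n_carrier_parents:
            carriers.add(iid)
    status = {
        i: (Phenotype.AFFECTED if i in carriers else Phenotype.UNAFFECTED)
        for i in _phenotyped(family)
    }
    provenance = {i: "mendelian" for i in status}
    return PhenotypeAssignment(status, provenance), frozenset(carriers), founder_id


def apply_penetrance(
    assignment: PhenotypeAssignment, Q: float, rng: np.random.Generator
) -> PhenotypeAssignment:
    """Turn exactly round-half-up((1-Q) * A) of the A affected to unaffected."""
    if not 0.0 < Q <= 1.0:
        raise ValueError("penetrance Q must lie in (0, 1]")
    affected = sorted(assignment.affected_ids())
    n_mask = int(np.floor((1.0 - Q) * len(affected) + 0.5))
    status = dict(assignment.status)
    provenance = dict(assignment.provenance)
    if n_mask:
        masked = rng.choice(affected, size=n_mask, replace=False)
        for iid in masked:
            status[iid] = Phenotype.UNAFFECTED
            provenance[iid] = "penetrance-masked"
    return PhenotypeAssignment(status, provenance)


def _branch_members(
    family: Pedigree, founder_id: str, G: int, generations: Mapping[str, int]
) -> set[str]:
    """The retained sub-branch: the seeded founder, its spouses, and all
    descendants (plus their spouses) within G generations of the founder."""
    g0 = generations[founder_id]
    window = range(g0, g0 + G)
    desc: set[str] = set()
    stack = [founder_id]
    while stack:
        for c in family.children_of(stack.pop()):
            if c not in desc:
                desc.add(c)
                stack.append(c)
    keep = {founder_id} | family.spouses_of(founder_id)
    for d in desc:
        if generations[d] in window:
            keep.add(d)
            keep |= family.spouses_of(d)
    return keep


def mask_generations(
    family: Pedigree,
    assignment: PhenotypeAssignment,
    G: object,
    R: float,
    rng: np.random.Generator,
    founder_id: str,
    generations: Mapping[str, int] | None = None,
) -> PhenotypeAssignment:
    """Keep Mendelian status inside a G-generation sub-branch anchored at the
    seeded founder; clear and Bernoulli(R)-redraw everyone outside it."""
    if G == ALL_GENERATIONS:
        return assignment
    if generations is None:
        generations = assign_generations(family)
    depth = max(generations.values())
    if not isinstance(G, int) or not 1 <= G:
        raise ValueError("G must be a positive integer or 'all'")
    if G > depth:
        raise ValueError(f"G={G} exceeds the family's generation count {depth}")
    keep = _branch_members(family, founder_id, G, generations)
    status = dict(assignment.status)
    provenance = dict(assignment.provenance)
    outside = [i for i in sorted(status) if i not in keep]
    draws = rng.random(len(outside)) < R
    for iid, hit in zip(outside, draws):
        status[iid] = Phenotype.AFFECTED if hit else Phenotype.UNAFFECTED
        provenance[iid] = "generation-cleared"
    return PhenotypeAssignment(status, provenance)


def generate_controls(
    family: Pedigree, R: float, rng: np.random.Generator
) -> PhenotypeAssignment:
    """Independent Bernoulli(R) phenotypes for all phenotyped members."""
    if not 0.0 < R < 1.0:
        raise ValueError("prevalence R must lie in (0, 1)")
    members = _phenotyped(family)
    draws = rng.random(len(members)) < R
    status = {
        i: (Phenotype.AFFECTED if hit else Phenotype.UNAFFECTED)
        for i, hit in zip(members, draws)
    }
    return PhenotypeAssignment(status, {i: "bernoulli" for i in status})


# -- family sets ------------------------------------------------------------

def _case_assignment(
    family: Pedigree,
    scenario: Scenario,
    rng: np.random.Generator,
    generations: Mapping[str, int],
    max_redraws: int = 200,
) -> tuple[PhenotypeAssignment, frozenset[str], int]:
    """Case pipeline (drop -> penetrance -> G-mask), redrawn until >= 2
    affected so every case family is testable.  G is clamped to the family's
    own depth (a shallow family is fully affected, as with G='all').

    Very small families can be structurally unable to retain two affected
    (e.g. a trio at Q=0.6: two affected always lose one to the penetrance
    mask); after exhausting the redraw budget the last draw is kept, so the
    family-set count stays intact and such sets simply carry a weak case.
    """
    depth = max(generations.values())
    g_eff: object = scenario.g
    if isinstance(scenario.g, int) and scenario.g > depth:
        g_eff = ALL_GENERATIONS
    for redraw in range(max_redraws + 1):
        assignment, carriers, founder = gene_drop_dominant(family, rng)
        assignment = apply_penetrance(assignment, scenario.q, rng)
        assignment = mask_generations(
            family, assignment, g_eff, scenario.r, rng, founder, generations
        )
        if len(assignment.affected_ids()) >= 2 or redraw == max_redraws:
            return assignment, carriers, redraw
    raise AssertionError("unreachable")


def iter_family_sets(
    ped: Pedigree, scenario: Scenario, seed: int, max_redraws: int = 200
) -> Iterator[FamilySet]:
    """Lazily yield one :class:`FamilySet` per family of the backbone.

    RNG substreams derive from (seed, scenario key, family-set index), so
    results are reproducible and independent of consumption order.
    """
    families = split_families(ped)
    fam_ids = [f.family_ids[0] for f in families]
    generations = {fid: assign_generations(f) for fid, f in zip(fam_ids, families)}
    qk, rk, gk = scenario.seed_key()
    for a, (case_id, case_fam) in enumerate(zip(fam_ids, families)):
        rng_case = np.random.default_rng(
            np.random.SeedSequence([seed, qk, rk, gk, a, 0])
        )
        case, carriers, n_redraws = _case_assignment(
            case_fam, scenario, rng_case, generations[case_id], max_redraws
        )
        rng_ctrl = np.random.default_rng(
            np.random.SeedSequence([seed, qk, rk, gk, a, 1])
        )
        controls = {
            fid: generate_controls(fam, scenario.r, rng_ctrl)
            for fid, fam in zip(fam_ids, families)
            if fid != case_id
        }
        yield FamilySet(
            case_family_id=case_id,
            case=case,
            controls=controls,
            scenario=scenario,
            n_redraws=n_redraws,
            carriers=carriers,
        )


def build_family_sets(
    ped: Pedigree, scenario: Scenario, seed: int, max_redraws: int = 200
) -> list[FamilySet]:
    """Materialised list form of :func:`iter_family_sets`."""
    return list(iter_family_sets(ped, scenario, seed, max_redraws))
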