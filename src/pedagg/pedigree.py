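"""Pedigree data model, PED I/O, validation, filtering and family structure.

The pedigree container used throughout the package.  Individuals carry a
family label, optional parent links, sex and a three-state phenotype
(affected / unaffected / unphenotyped).  Unphenotyped members are first-class
citizens: they contribute to kinship but never to affected counts.

The on-disk dialect is the 6-column whitespace-delimited PED/FAM layout
(family, id, father, mother, sex, phenotype) with PLINK-style codes:
sex 1=male, 2=female, 0=unknown; phenotype 2=affected, 1=unaffected,
0 or -9=unphenotyped; parent id "0" means missing.
"""

from __future__ import annotations

import json
from collections import Counter, deque
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Iterator, Mapping

__all__ = [
    "Sex",
    "Phenotype",
    "Individual",
    "Pedigree",
    "PedigreeError",
    "ParseError",
    "ValidationError",
    "read_ped",
    "write_ped",
    "filter_pedigree",
    "split_families",
    "assign_generations",
]


class PedigreeError(ValueError):
    """Base class for pedigree parse/validation failures."""


class ParseError(PedigreeError):
    pass


class ValidationError(PedigreeError):
    pass


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Phenotype(str, Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNPHENOTYPED = "unphenotyped"


_SEX_READ = {"1": Sex.MALE, "2": Sex.FEMALE, "0": Sex.UNKNOWN}
_SEX_WRITE = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
_PHENO_READ = {
    "2": Phenotype.AFFECTED,
    "1": Phenotype.UNAFFECTED,
    "0": Phenotype.UNPHENOTYPED,
    "-9": Phenotype.UNPHENOTYPED,
}
_PHENO_WRITE = {
    Phenotype.AFFECTED: "2",
    Phenotype.UNAFFECTED: "1",
    Phenotype.UNPHENOTYPED: "0",
}

MISSING = None  # parent sentinel


@dataclass(frozen=True)
class Individual:
    """One pedigree member; ``father_id``/``mother_id`` are ``None`` when missing."""

    id: str
    family_id: str
    father_id: str | None
    mother_id: str | None
    sex: Sex
    phenotype: Phenotype

    def __post_init__(self) -> None:
        if self.id in (self.father_id, self.mother_id):
            raise ValidationError(f"individual {self.id!r} is its own parent")


class Pedigree:
    """An ordered collection of individuals partitioned into families.

    Validation enforces: unique ids, no dangling parent references, no
    explicit parent-sex contradictions (a recorded father must not be female,
    a recorded mother must not be male) and acyclic parentage.  Parents of a
    record are normally both present or both missing; :func:`read_ped`
    completes single-parent records with anonymous founders, while
    :func:`filter_pedigree` may legitimately leave single known parents
    behind (the absent parent then acts as an anonymous unrelated founder).
    """

    def __init__(self, individuals: Iterable[Individual], validate: bool = True):
        self._members: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in self._members:
                raise ValidationError(f"duplicate individual id {ind.id!r}")
            self._members[ind.id] = ind
        self._children: dict[str, list[str]] = {i: [] for i in self._members}
        for ind in self._members.values():
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None and pid in self._children:
                    self._children[pid].append(ind.id)
        if validate:
            self._validate()

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._members)

    def __iter__(self) -> Iterator[Individual]:
        return iter(self._members.values())

    def __contains__(self, iid: str) -> bool:
        return iid in self._members

    def __getitem__(self, iid: str) -> Individual:
        return self._members[iid]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Pedigree):
            return NotImplemented
        return dict(self._members) == dict(other._members)

    @property
    def ids(self) -> list[str]:
        return list(self._members)

    @property
    def family_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for ind in self:
            seen.setdefault(ind.family_id, None)
        return list(seen)

    def members_of(self, family_id: str) -> list[Individual]:
        return [i for i in self if i.family_id == family_id]

    def children_of(self, iid: str) -> list[str]:
        return list(self._children[iid])

    def parents_of(self, iid: str) -> list[str]:
        ind = self._members[iid]
        return [p for p in (ind.father_id, ind.mother_id) if p is not None and p in self]

    def spouses_of(self, iid: str) -> set[str]:
        """Co-parents of ``iid`` (spouse = shares a child; no marriage records)."""
        out: set[str] = set()
        for cid in self._children[iid]:
            for pid in self.parents_of(cid):
                if pid != iid:
                    out.add(pid)
        return out

    def founders(self, family_id: str | None = None) -> list[str]:
        pool = self.members_of(family_id) if family_id is not None else list(self)
        return [i.id for i in pool if not self.parents_of(i.id)]

    def phenotyped_ids(self) -> list[str]:
        return [i.id for i in self if i.phenotype is not Phenotype.UNPHENOTYPED]

    def affected_ids(self) -> list[str]:
        return [i.id for i in self if i.phenotype is Phenotype.AFFECTED]

    def with_phenotypes(self, phenotypes: Mapping[str, Phenotype]) -> "Pedigree":
        """A copy with phenotypes replaced for the ids present in the mapping."""
        return Pedigree(
            (replace(i, phenotype=phenotypes.get(i.id, i.phenotype)) for i in self),
            validate=False,
        )

    # -- validation ---------------------------------------------------------
    def _validate(self) -> None:
        dangling = []
        contradictions = []
        for ind in self:
            for pid, role, bad_sex in (
                (ind.father_id, "father", Sex.FEMALE),
                (ind.mother_id, "mother", Sex.MALE),
            ):
                if pid is None:
                    continue
                if pid not in self._members:
                    dangling.append((ind.id, role, pid))
                elif self._members[pid].sex is bad_sex:
                    contradictions.append((ind.id, role, pid))
        if dangling:
            refs = "; ".join(f"{i}: {role} {p!r} absent" for i, role, p in dangling)
            raise ValidationError(f"dangling parent reference(s): {refs}")
        if contradictions:
            refs = "; ".join(f"{i}: {role} {p!r} has wrong sex" for i, role, p in contradictions)
            raise ValidationError(f"parent sex contradiction(s): {refs}")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        indeg = {i: len(self.parents_of(i)) for i in self._members}
        ready = deque(i for i, d in indeg.items() if d == 0)
        seen = 0
        while ready:
            seen += 1
            for c in self._children[ready.popleft()]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    ready.append(c)
        if seen != len(self._members):
            cyc = sorted(i for i, d in indeg.items() if d > 0)
            raise ValidationError(f"parentage cycle involving: {', '.join(cyc)}")

    def topological_ids(self) -> list[str]:
        """Ids ordered so every parent precedes its children."""
        indeg = {i: len(self.parents_of(i)) for i in self._members}
        ready = deque(i for i in self._members if indeg[i] == 0)
        order: list[str] = []
        while ready:
            i = ready.popleft()
            order.append(i)
            for c in self._children[i]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    ready.append(c)
        return order


# -- I/O -------------------------------------------------------------------

def read_ped(path, complete_single_parents: bool = True) -> Pedigree:
    """Read a 6-column PED/FAM file into a validated :class:`Pedigree`.

    Single-parent records are completed by inserting an anonymous
    unphenotyped founder of the opposite role (both-or-none rule); the
    created ids are recorded on the returned pedigree as
    ``ped.creation_report``.
    """
    rows: list[tuple[str, str, str | None, str | None, Sex, Phenotype]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 6:
                raise ParseError(
                    f"{path}:{lineno}: expected 6 whitespace-delimited fields, got {len(fields)}"
                )
            fam, iid, fid, mid, sex, pheno = fields
            if sex not in _SEX_READ:
                raise ParseError(f"{path}:{lineno}: bad sex code {sex!r}")
            if pheno not in _PHENO_READ:
                raise ParseError(f"{path}:{lineno}: bad phenotype code {pheno!r}")
            rows.append(
                (
                    fam,
                    iid,
                    None if fid == "0" else fid,
                    None if mid == "0" else mid,
                    _SEX_READ[sex],
                    _PHENO_READ[pheno],
                )
            )

    created: list[str] = []
    inds: list[Individual] = []
    known = {r[1] for r in rows}
    anon = 0
    for fam, iid, fid, mid, sex, pheno in rows:
        if complete_single_parents and (fid is None) != (mid is None):
            anon += 1
            new_id = f"__anon{anon}"
            while new_id in known:
                anon += 1
                new_id = f"__anon{anon}"
            known.add(new_id)
            created.append(new_id)
            if fid is None:
                fid = new_id
                inds.append(Individual(new_id, fam, None, None, Sex.MALE, Phenotype.UNPHENOTYPED))
            else:
                mid = new_id
                inds.append(Individual(new_id, fam, None, None, Sex.FEMALE, Phenotype.UNPHENOTYPED))
        inds.append(Individual(iid, fam, fid, mid, sex, pheno))
    ped = Pedigree(inds)
    ped.creation_report = created  # type: ignore[attr-defined]
    return ped


def write_ped(ped: Pedigree, path) -> None:
    """Write the 6-column dialect with stable (family, then id) ordering."""
    rows = sorted(ped, key=lambda i: (i.family_id, i.id))
    with open(path, "w") as fh:
        for ind in rows:
            fh.write(
                "\t".join(
                    [
                        ind.family_id,
                        ind.id,
                        ind.father_id or "0",
                        ind.mother_id or "0",
                        _SEX_WRITE[ind.sex],
                        _PHENO_WRITE[ind.phenotype],
                    ]
                )
                + "\n"
            )


# -- filtering and family structure ----------------------------------------

def _sever(ind: Individual, removed: set[str]) -> Individual:
    fid = None if ind.father_id in removed else ind.father_id
    mid = None if ind.mother_id in removed else ind.mother_id
    if (fid, mid) != (ind.father_id, ind.mother_id):
        return replace(ind, father_id=fid, mother_id=mid)
    return ind


def filter_pedigree(ped: Pedigree) -> tuple[Pedigree, Counter]:
    """Remove unknown-sex individuals and singletons, iterated to a fixed point.

    A singleton has no parent in the pedigree and no child in the pedigree
    (and hence no shared-child spouse).  Removing an unknown-sex parent
    severs the link to its children, which may orphan further individuals;
    removal therefore iterates until stable.  Returns the filtered pedigree
    and a removal report ``Counter({reason: count})`` with reasons
    ``unknown_sex`` and ``singleton``.
    """
    members = {i.id: i for i in ped}
    report: Counter = Counter()

    unknown = {i for i, ind in members.items() if ind.sex is Sex.UNKNOWN}
    if unknown:
        report["unknown_sex"] = len(unknown)
        members = {i: _sever(ind, unknown) for i, ind in members.items() if i not in unknown}

    while True:
        has_child: set[str] = set()
        for ind in members.values():
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None and pid in members:
                    has_child.add(pid)
        singles = {
            i
            for i, ind in members.items()
            if i not in has_child
            and (ind.father_id is None or ind.father_id not in members)
            and (ind.mother_id is None or ind.mother_id not in members)
        }
        if not singles:
            break
        report["singleton"] += len(singles)
        members = {i: _sever(ind, singles) for i, ind in members.items() if i not in singles}

    return Pedigree(members.values(), validate=False), report


def split_families(ped: Pedigree) -> list[Pedigree]:
    """Connected components of the parent/child graph, as independent pedigrees.

    Components are relabelled with the majority family label of their members
    (suffixed ``.1``, ``.2``, ... if one label spans several components).
    """
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(ped.ids)
    for ind in ped:
        for pid in ped.parents_of(ind.id):
            g.add_edge(ind.id, pid)

    used: Counter = Counter()
    out: list[Pedigree] = []
    comps = sorted(nx.connected_components(g), key=lambda c: min(c))
    for comp in comps:
        label = Counter(ped[i].family_id for i in comp).most_common(1)[0][0]
        used[label] += 1
        if used[label] > 1:
            label = f"{label}.{used[label]}"
        inds = [replace(ped[i], family_id=label) for i in sorted(comp)]
        out.append(Pedigree(inds, validate=False))
    return out


def assign_generations(family: Pedigree, max_rounds: int | None = None) -> dict[str, int]:
    """1-based generation index per individual of one connected family.

    Children sit one level below their deepest parent; married-in founders
    inherit the depth of their spouse.  Depths are made consistent by
    constraint propagation to a fixed point; failure to converge (only
    possible for cyclic constraints) raises :class:`ValidationError`.
    """
    ids = family.ids
    depth = {i: 1 for i in ids}
    rounds = max_rounds if max_rounds is not None else 2 * len(ids) + 4
    for _ in range(rounds):
        changed = False
        for i in family.topological_ids():
            parents = family.parents_of(i)
            if parents:
                d = 1 + max(depth[p] for p in parents)
                if d > depth[i]:
                    depth[i] = d
                    changed = True
            else:
                for s in family.spouses_of(i):
                    if depth[s] > depth[i]:
                        depth[i] = depth[s]
                        changed = True
        if not changed:
            break
    else:
        raise ValidationError("generation assignment did not converge (cyclic constraints)")
    return depth


def generation_count(family: Pedigree) -> int:
    depths = assign_generations(family)
    return max(depths.values(), default=0)


def pedigree_json_summary(ped: Pedigree) -> str:
    """JSON summary: n_individuals, n_families, family size quantiles."""
    import numpy as np

    sizes = sorted(Counter(i.family_id for i in ped).values())
    summary = {
        "n_individuals": len(ped),
        "n_families": len(sizes),
        "family_size_quantiles": {
            q: (float(np.quantile(sizes, float(q))) if sizes else 0.0)
            for q in ("0.0", "0.25", "0.5", "0.75", "1.0")
        },
    }
    return json.dumps(summary, indent=2)
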