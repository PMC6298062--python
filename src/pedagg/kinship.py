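"""Kinship coefficients and kinship-neighbourhood queries.

The kinship coefficient phi(i, j) is the probability that two alleles drawn
at random, one from each individual, are identical by descent.  It is
computed per family by the classical recursion in topological order:
founders are non-inbred and mutually unrelated (phi(i,i) = 1/2,
phi(i,j) = 0), a non-founder's self-kinship is (1 + phi(father, mother))/2
and its kinship with any earlier individual averages the parental kinships.
A missing parent behaves as an anonymous unrelated founder.

Unphenotyped individuals are included: they connect relatives even though
they never enter affected counts.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np

from .pedigree import Pedigree, Phenotype, ValidationError

__all__ = ["KinshipMatrix", "kinship_matrix", "most_distant_affected", "kinship_group"]


class KinshipMatrix:
    """Block-diagonal (by family) symmetric matrix of kinship coefficients."""

    def __init__(self, blocks: Mapping[str, tuple[list[str], np.ndarray]]):
        self._blocks = dict(blocks)
        self._where: dict[str, tuple[str, int]] = {}
        for fam, (ids, _) in self._blocks.items():
            for k, i in enumerate(ids):
                self._where[i] = (fam, k)

    @property
    def family_ids(self) -> list[str]:
        return list(self._blocks)

    def family_of(self, iid: str) -> str:
        return self._where[iid][0]

    def family_block(self, family_id: str) -> tuple[list[str], np.ndarray]:
        ids, mat = self._blocks[family_id]
        return list(ids), mat

    def phi(self, i: str, j: str) -> float:
        """phi(i, j); zero between members of different families."""
        fam_i, ki = self._where[i]
        fam_j, kj = self._where[j]
        if fam_i != fam_j:
            return 0.0
        return float(self._blocks[fam_i][1][ki, kj])

    def to_tsv(self, path) -> None:
        """Long-format export of all within-family pairs (i, j, phi), i <= j."""
        with open(path, "w") as fh:
            fh.write("i\tj\tphi\n")
            for ids, mat in self._blocks.values():
                for a in range(len(ids)):
                    for b in range(a, len(ids)):
                        fh.write(f"{ids[a]}\t{ids[b]}\t{mat[a, b]:.10g}\n")

    def to_mtx(self, path) -> list[str]:
        """Symmetric MatrixMarket coordinate export; returns the row/col id order."""
        from scipy.io import mmwrite
        from scipy.sparse import block_diag

        order = [i for ids, _ in self._blocks.values() for i in ids]
        sparse = block_diag([mat for _, mat in self._blocks.values()], format="coo")
        mmwrite(path, sparse, symmetry="symmetric")
        return order


def _family_kinship(family: Pedigree) -> tuple[list[str], np.ndarray]:
    order = family.topological_ids()
    if len(order) != len(family):
        raise ValidationError("cannot compute kinship on a cyclic pedigree")
    pos = {i: k for k, i in enumerate(order)}
    n = len(order)
    mat = np.zeros((n, n))
    for k, iid in enumerate(order):
        parents = family.parents_of(iid)
        pidx = [pos[p] for p in parents]
        if pidx:
            rows = mat[pidx, :k]  # kinship of parents with all earlier individuals
            mat[k, :k] = rows.sum(axis=0) / 2.0
            mat[:k, k] = mat[k, :k]
            mat[k, k] = 0.5 * (1.0 + (mat[pidx[0], pidx[1]] if len(pidx) == 2 else 0.0))
        else:
            mat[k, k] = 0.5
    return order, mat


def kinship_matrix(ped: Pedigree) -> KinshipMatrix:
    """Kinship coefficients for every within-family pair of ``ped``."""
    blocks: dict[str, tuple[list[str], np.ndarray]] = {}
    fams = {i.family_id for i in ped}
    for fam in sorted(fams):
        sub = Pedigree(ped.members_of(fam), validate=False)
        blocks[fam] = _family_kinship(sub)
    return KinshipMatrix(blocks)


def most_distant_affected(
    K: KinshipMatrix, i: str, affected: Iterable[str]
) -> str | None:
    """Most distant affected relative of ``i``: the affected j != i in i's
    family with minimal positive phi(i, j); ties broken by lexicographic id;
    ``None`` if no affected relative shares kinship with ``i``."""
    affected = set(affected)
    if i not in affected:
        raise ValueError(f"index individual {i!r} must be affected")
    fam = K.family_of(i)
    best: tuple[float, str] | None = None
    for j in affected:
        if j == i or j not in K._where or K.family_of(j) != fam:
            continue
        phi = K.phi(i, j)
        if phi > 0 and (best is None or (phi, j) < best):
            best = (phi, j)
    return None if best is None else best[1]


def kinship_group(
    K: KinshipMatrix,
    i: str,
    affected: Iterable[str],
    phenotyped: Iterable[str] | None = None,
) -> set[str]:
    """Relatives of ``i`` at least as close as its most distant affected
    relative (including ``i``), restricted to phenotyped family members.

    ``phenotyped`` defaults to everyone in the family.  Raises ``ValueError``
    when no affected relative exists (test not applicable for ``i``).
    """
    affected = set(affected)
    ref = most_distant_affected(K, i, affected)
    if ref is None:
        raise ValueError(f"kinship group undefined for {i!r}: no affected relative")
    threshold = K.phi(i, ref)
    ids, mat = K.family_block(K.family_of(i))
    allowed = set(ids) if phenotyped is None else set(phenotyped)
    ki = ids.index(i)
    return {
        j
        for k, j in enumerate(ids)
        if j in allowed and mat[ki, k] >= threshold
    }
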