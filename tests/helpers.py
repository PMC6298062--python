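"""Independent oracles used by the test suite.

These deliberately avoid the package's own computational paths: kinship is
cross-checked by Monte-Carlo gene dropping of founder alleles, and the test
engine by a naive per-replicate recomputation with the scalar statistic
functions.
"""

from __future__ import annotations

import numpy as np

from pedagg.fa_tests import (
    gc_statistic,
    gr_statistic,
    if_statistic,
    ks_statistic,
    resample_null,
)
from pedagg.kinship import kinship_matrix
from pedagg.pedigree import Pedigree, Phenotype

_TOL = 1e-12


def gene_drop_phi(
    family: Pedigree, pairs: list[tuple[str, str]], n_drops: int, seed: int
) -> dict[tuple[str, str], tuple[float, float]]:
    """Monte-Carlo IBD estimate of kinship: drop two uniquely labelled
    alleles per founder down the pedigree and record, for each pair, the
    probability that one random allele from each matches by descent.
    Returns {pair: (phi_hat, standard_error)}."""
    rng = np.random.default_rng(seed)
    alleles: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    label = 0
    for iid in family.topological_ids():
        member = family[iid]
        inherited = []
        for pid in (member.father_id, member.mother_id):
            if pid is not None and pid in family:
                a1, a2 = alleles[pid]
                pick = rng.integers(0, 2, n_drops).astype(bool)
                inherited.append(np.where(pick, a1, a2))
            else:
                label += 1
                inherited.append(np.full(n_drops, label, dtype=np.int64))
        alleles[iid] = (inherited[0], inherited[1])
    out = {}
    for i, j in pairs:
        ai1, ai2 = alleles[i]
        aj1, aj2 = alleles[j]
        if i == j:
            # two draws *with replacement* from i's genotype
            x = 0.25 * (
                2.0 + (ai1 == ai2) + (ai2 == ai1)
            )  # match prob = (2 + 2*[a1==a2]) / 4
        else:
            x = 0.25 * (
                (ai1 == aj1).astype(float)
                + (ai1 == aj2)
                + (ai2 == aj1)
                + (ai2 == aj2)
            )
        out[(i, j)] = (float(x.mean()), float(x.std(ddof=1) / np.sqrt(n_drops)))
    return out


def naive_mc_pvalues(
    ped: Pedigree,
    pheno: dict[str, Phenotype],
    B: int,
    seed: int,
    chunk_size: int = 512,
) -> dict[str, dict[str, tuple[float, int]]]:
    """Slow reference implementation of the Monte-Carlo nulls.

    Recomputes every statistic per replicate with the scalar functions:
    per-family conditional null for IF, pooled conditional null for
    KS/GR/GC.  Returns {test: {unit_id: (P_raw, effective_B)}}.
    """
    K = kinship_matrix(ped)
    pool = [i for i in ped.ids if pheno[i] is not Phenotype.UNPHENOTYPED]
    affected = {i for i in pool if pheno[i] is Phenotype.AFFECTED}
    fam_of = {i: ped[i].family_id for i in pool}
    fam_pheno: dict[str, set[str]] = {}
    for i in pool:
        fam_pheno.setdefault(fam_of[i], set()).add(i)

    reps = [
        set(r)
        for r in resample_null(pool, len(affected), B, seed, chunk_size=chunk_size)
    ]

    def stats_for(assignment: set[str]):
        """(IF per family, KS/GR/GC value per testable affected individual)."""
        per_fam: dict[str, float] = {}
        per_ind: dict[str, dict[str, float]] = {"KS": {}, "GR": {}, "GC": {}}
        by_fam: dict[str, list[str]] = {}
        for i in assignment:
            by_fam.setdefault(fam_of[i], []).append(i)
        for fam, aff in by_fam.items():
            if len(aff) >= 2:
                per_fam[fam] = if_statistic(aff, K)
            for i in aff:
                try:
                    per_ind["KS"][i] = ks_statistic(i, aff, K)
                except ValueError:
                    pass
                try:
                    per_ind["GR"][i] = gr_statistic(i, aff, K, fam_pheno[fam])
                    per_ind["GC"][i] = gc_statistic(i, aff, K, fam_pheno[fam])
                except ValueError:
                    pass
        return per_fam, per_ind

    obs_fam, obs_ind = stats_for(affected)

    if_counts = {f: [0, 0] for f in obs_fam}  # family -> [count_ge, b_eff]
    pooled: dict[str, list[float]] = {"KS": [], "GR": [], "GC": []}
    for rep in reps:
        rep_fam, rep_ind = stats_for(rep)
        for f, v in rep_fam.items():
            if f in if_counts:
                if_counts[f][1] += 1
                if v >= obs_fam[f] - _TOL:
                    if_counts[f][0] += 1
        for t in pooled:
            pooled[t].extend(rep_ind[t].values())

    out: dict[str, dict[str, tuple[float, int]]] = {"IF": {}}
    for f, (c, b) in if_counts.items():
        out["IF"][f] = ((1 + c) / (b + 1), b)
    for t in ("KS", "GR", "GC"):
        null = np.asarray(pooled[t])
        out[t] = {}
        for i, v in obs_ind[t].items():
            c = int(np.sum(null >= v - _TOL))
            out[t][i] = ((1 + c) / (null.size + 1), null.size)
    return out
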