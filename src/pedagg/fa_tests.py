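"""The five familial aggregation tests with Monte-Carlo empirical nulls.

Tests
-----
IF  genealogical index of familiality: per family, the mean kinship
    coefficient over all unordered pairs of affected members.
KS  kinship sum: per affected individual i, the sum of phi(i, j) over all
    other affected members of i's family.
GR  group ratio: per affected individual i, the number of affected members
    of i's kinship group (relatives at least as close as i's most distant
    affected relative, including i).
GC  group closest relative: per affected individual i, the kinship
    coefficient of the closest affected relative inside i's group.
PB  binomial: per family of phenotyped size n with k affected, the exact
    upper tail P(X >= k) for X ~ Binomial(n, R), R the trait prevalence.

IF/KS/GR/GC are referenced to an empirical null obtained by resampling the
observed number of affected individuals, without replacement, from the pool
of all phenotyped individuals across all families (B replicates).  The IF
null for a family is conditional: the mean pairwise kinship recomputed on
the replicates in which at least two of that family's members were sampled
as affected.  The per-individual tests (KS, GR, GC) use a pooled
conditional null: in every replicate the statistic is recomputed, groups
included, for every *testable* sampled individual (one with at least one
other sampled affected in its family for KS, at least one sampled affected
relative sharing kinship for GR/GC), and these values are pooled across
replicates and families into one reference distribution per test.  Because
observed testable units are, under the null, draws from the same mixture as
the pooled values, the resulting P values are uniform up to the atoms of
the mixture.  The Monte-Carlo estimator is the add-one rule
(b + 1) / (B_effective + 1), never zero; B_effective is the conditional
replicate count for IF and the pooled reference size for KS/GR/GC.

Multiple testing uses Benjamini-Hochberg within one test run across all
testable units; ranking is tie-averaged and always performed on unadjusted
P values.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom, rankdata

from .kinship import KinshipMatrix, kinship_matrix, most_distant_affected, kinship_group
from .pedigree import Pedigree, Phenotype

__all__ = [
    "ALL_TESTS",
    "TestConfig",
    "if_statistic",
    "ks_statistic",
    "gr_statistic",
    "gc_statistic",
    "pb_test",
    "trait_prevalence",
    "resample_null",
    "empirical_p",
    "bh_adjust",
    "family_min_p",
    "rank_units",
    "run_test",
    "run_tests",
]

ALL_TESTS = ("IF", "KS", "GR", "GC", "PB")
MC_TESTS = ("IF", "KS", "GR", "GC")

_TIE_TOL = 1e-12  # tolerance when counting null >= observed, guards float ties


@dataclass
class TestConfig:
    """Configuration of one test run."""

    __test__ = False  # not a pytest class despite the name

    tests: tuple[str, ...] = ALL_TESTS
    B: int = 50_000
    seed: int = 0
    fdr_level: float = 0.05
    prevalence_override: float | None = None
    chunk_size: int = 512

    def __post_init__(self) -> None:
        bad = [t for t in self.tests if t not in ALL_TESTS]
        if bad:
            raise ValueError(f"unknown test id(s): {bad}")
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not 0.0 < self.fdr_level < 1.0:
            raise ValueError("fdr_level must lie in (0, 1)")


# -- observed statistics ----------------------------------------------------

def if_statistic(affected: Iterable[str], K: KinshipMatrix) -> float:
    """Mean kinship over all unordered pairs of a family's affected members."""
    ids = sorted(set(affected))
    if len(ids) < 2:
        raise ValueError("IF requires at least two affected members")
    pairs = list(itertools.combinations(ids, 2))
    return float(np.mean([K.phi(a, b) for a, b in pairs]))


def ks_statistic(i: str, affected: Iterable[str], K: KinshipMatrix) -> float:
    """Sum of kinship of ``i`` with every other affected family member."""
    others = [j for j in set(affected) if j != i and K.family_of(j) == K.family_of(i)]
    if i not in set(affected):
        raise ValueError("KS index individual must be affected")
    if not others:
        raise ValueError("KS requires at least one other affected in the family")
    return float(sum(K.phi(i, j) for j in others))


def gr_statistic(
    i: str, affected: Iterable[str], K: KinshipMatrix,
    phenotyped: Iterable[str] | None = None,
) -> int:
    """Number of affected members of i's kinship group (including i)."""
    affected = set(affected)
    group = kinship_group(K, i, affected, phenotyped=phenotyped)
    return len(group & affected)


def gc_statistic(
    i: str, affected: Iterable[str], K: KinshipMatrix,
    phenotyped: Iterable[str] | None = None,
) -> float:
    """Kinship coefficient of the closest affected relative in i's group."""
    affected = set(affected)
    group = kinship_group(K, i, affected, phenotyped=phenotyped)
    others = (group & affected) - {i}
    if not others:
        raise ValueError("GC requires an affected group member besides i")
    return float(max(K.phi(i, j) for j in others))


def pb_test(n: int, k: int, R: float) -> float:
    """Exact binomial upper tail P(X >= k), X ~ Binomial(n, R)."""
    if not 0.0 < R < 1.0:
        raise ValueError("prevalence R must lie in (0, 1)")
    if n < 1 or not 0 <= k <= n:
        raise ValueError("require n >= 1 and 0 <= k <= n")
    if k == 0:
        return 1.0
    return float(binom.sf(k - 1, n, R))


def trait_prevalence(n_affected: int, n_phenotyped: int) -> float:
    """Affected / phenotyped: the convenience prevalence used throughout."""
    if n_phenotyped <= 0 or not 0 <= n_affected <= n_phenotyped:
        raise ValueError("require 0 <= n_affected <= n_phenotyped, n_phenotyped > 0")
    return n_affected / n_phenotyped


# -- resampling and P value machinery ---------------------------------------

def _sample_chunks(
    rng: np.random.Generator, n_pool: int, n_affected: int, B: int, chunk: int
) -> Iterator[np.ndarray]:
    """Yield (c, n_affected) index arrays of uniform draws without replacement."""
    done = 0
    while done < B:
        c = min(chunk, B - done)
        u = rng.random((c, n_pool))
        yield np.argpartition(u, n_affected - 1, axis=1)[:, :n_affected]
        done += c


def resample_null(
    ped: Pedigree | Sequence[str], n_affected: int, B: int, seed: int,
    chunk_size: int = 512,
) -> Iterator[frozenset[str]]:
    """B uniform without-replacement samples of ``n_affected`` ids from the
    pool of all phenotyped individuals (or an explicit id pool)."""
    pool = list(ped.phenotyped_ids()) if isinstance(ped, Pedigree) else list(ped)
    if n_affected > len(pool):
        raise ValueError("n_affected exceeds the phenotyped pool")
    if n_affected < 0 or B < 1:
        raise ValueError("require n_affected >= 0 and B >= 1")
    arr = np.asarray(pool, dtype=object)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    for idx in _sample_chunks(rng, len(pool), n_affected, B, chunk_size):
        for row in idx:
            yield frozenset(arr[row])


def empirical_p(
    observed: float, null_values: Sequence[float], direction: str = "greater"
) -> float:
    """Add-one Monte-Carlo P value (1 + #{null >= observed}) / (B + 1)."""
    if direction != "greater":
        raise ValueError("only the one-sided 'greater' direction is supported")
    null = np.asarray(null_values, dtype=float)
    if null.size == 0:
        raise ValueError("empty null sample")
    b = int(np.sum(null >= observed - _TIE_TOL))
    return (1 + b) / (null.size + 1)


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P values, input order preserved."""
    from statsmodels.stats.multitest import multipletests

    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0) or np.any(arr > 1):
        raise ValueError("P values must lie in (0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def rank_units(p: Sequence[float]) -> np.ndarray:
    """Ascending tie-averaged ranks; NaN entries receive NaN ranks."""
    arr = np.asarray(p, dtype=float)
    out = np.full(arr.shape, np.nan)
    mask = np.isfinite(arr)
    if mask.any():
        out[mask] = rankdata(arr[mask], method="average")
    return out


def family_min_p(results: pd.DataFrame) -> pd.Series:
    """Per family, the minimum P_raw over its testable units (NA excluded)."""
    ok = results[results["status"] == "ok"]
    return ok.groupby("family_id")["P_raw"].min()


# -- the run engine ---------------------------------------------------------

@dataclass
class _Unit:
    unit_id: str
    family_id: str
    statistic: float = np.nan
    count_ge: int = 0
    b_eff: int = 0
    na: bool = False


def _family_layout(ped: Pedigree, pheno: Mapping[str, Phenotype]):
    """Pool of phenotyped ids and per-family column/affected index structures."""
    pool: list[str] = [i for i in ped.ids if pheno[i] is not Phenotype.UNPHENOTYPED]
    col = {iid: k for k, iid in enumerate(pool)}
    fam_cols: dict[str, list[str]] = {}
    for iid in pool:
        fam_cols.setdefault(ped[iid].family_id, []).append(iid)
    affected = [i for i in pool if pheno[i] is Phenotype.AFFECTED]
    return pool, col, fam_cols, affected


def run_tests(
    ped: Pedigree,
    phenotypes: Mapping[str, Phenotype] | None = None,
    config: TestConfig | None = None,
    K: KinshipMatrix | None = None,
) -> dict[str, pd.DataFrame]:
    """Run the configured tests on a (multi-family) pedigree.

    ``phenotypes`` overrides the pedigree's own phenotype column (ids absent
    from the mapping keep their pedigree value).  A precomputed kinship
    matrix may be passed to avoid recomputation across repeated runs on the
    same pedigree backbone.  Returns one result table per test with columns
    unit_id, unit_type, family_id, statistic, effective_B, P_raw, P_adj,
    rank, status.
    """
    config = config or TestConfig()
    pheno: dict[str, Phenotype] = {i.id: i.phenotype for i in ped}
    if phenotypes:
        for iid, ph in phenotypes.items():
            pheno[iid] = ph
    if K is None and any(t in MC_TESTS for t in config.tests):
        K = kinship_matrix(ped)

    pool, col, fam_cols, affected = _family_layout(ped, pheno)
    if not pool:
        raise ValueError("no phenotyped individuals")
    affected_set = set(affected)
    out: dict[str, pd.DataFrame] = {}

    if "PB" in config.tests:
        out["PB"] = _run_pb(ped, fam_cols, affected_set, config)

    mc = [t for t in config.tests if t in MC_TESTS]
    if mc:
        if not affected:
            raise ValueError("Monte-Carlo tests require at least one affected individual")
        out.update(
            _run_mc(mc, K, pool, col, fam_cols, affected_set, config)
        )
    return {t: out[t] for t in config.tests}


def run_test(
    test_id: str,
    ped: Pedigree,
    phenotypes: Mapping[str, Phenotype] | None = None,
    config: TestConfig | None = None,
    K: KinshipMatrix | None = None,
) -> pd.DataFrame:
    """Run a single test; see :func:`run_tests`."""
    config = config or TestConfig()
    cfg = TestConfig(
        tests=(test_id,), B=config.B, seed=config.seed,
        fdr_level=config.fdr_level, prevalence_override=config.prevalence_override,
        chunk_size=config.chunk_size,
    )
    return run_tests(ped, phenotypes, cfg, K)[test_id]


def _finish_table(units: list[_Unit], unit_type: str, p_raw: np.ndarray) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "unit_id": [u.unit_id for u in units],
            "unit_type": unit_type,
            "family_id": [u.family_id for u in units],
            "statistic": [u.statistic for u in units],
            "effective_B": [u.b_eff if not u.na else np.nan for u in units],
            "P_raw": p_raw,
        }
    )
    ok = np.isfinite(p_raw)
    p_adj = np.full(len(df), np.nan)
    if ok.any():
        p_adj[ok] = bh_adjust(p_raw[ok])
    df["P_adj"] = p_adj
    df["rank"] = rank_units(p_raw)
    df["status"] = np.where(ok, "ok", "na")
    return df


def _run_pb(
    ped: Pedigree, fam_cols: dict[str, list[str]], affected: set[str],
    config: TestConfig,
) -> pd.DataFrame:
    n_pheno = sum(len(v) for v in fam_cols.values())
    R = config.prevalence_override
    if R is None:
        R = trait_prevalence(len(affected), n_pheno)
    units: list[_Unit] = []
    p_raw: list[float] = []
    for fam, members in fam_cols.items():
        k = sum(1 for m in members if m in affected)
        units.append(_Unit(unit_id=fam, family_id=fam, statistic=float(k)))
        p_raw.append(pb_test(len(members), k, R))
    return _finish_table(units, "family", np.asarray(p_raw))


def _run_mc(
    tests: list[str],
    K: KinshipMatrix,
    pool: list[str],
    col: dict[str, int],
    fam_cols: dict[str, list[str]],
    affected: set[str],
    config: TestConfig,
) -> dict[str, pd.DataFrame]:
    n_pool, n_aff = len(pool), len(affected)

    # per-family phenotyped kinship submatrices and local indices
    fams: dict[str, dict] = {}
    for fam, members in fam_cols.items():
        ids, mat = K.family_block(fam)
        pos = {i: k for k, i in enumerate(ids)}
        sel = np.asarray([pos[m] for m in members])
        sub = mat[np.ix_(sel, sel)]
        fams[fam] = {
            "members": members,
            "cols": np.asarray([col[m] for m in members]),
            "K": sub,
            "diag": np.diag(sub).copy(),
            "aff_local": [k for k, m in enumerate(members) if m in affected],
        }

    # observed statistics and unit lists -----------------------------------
    units: dict[str, list[_Unit]] = {t: [] for t in tests}
    for fam, info in fams.items():
        members = info["members"]
        sub = info["K"]
        aff_local = info["aff_local"]
        aff_ids = [members[k] for k in aff_local]
        if "IF" in tests:
            u = _Unit(unit_id=fam, family_id=fam)
            if len(aff_local) >= 2:
                idx = np.asarray(aff_local)
                block = sub[np.ix_(idx, idx)]
                m = len(idx)
                u.statistic = float(
                    (block.sum() - np.trace(block)) / (m * (m - 1))
                )
            else:
                u.na = True
            units["IF"].append(u)
        for k_local, iid in zip(aff_local, aff_ids):
            krow = sub[k_local]
            others = [j for j in aff_local if j != k_local]
            if "KS" in tests:
                u = _Unit(unit_id=iid, family_id=fam)
                if others:
                    u.statistic = float(krow[others].sum())
                else:
                    u.na = True
                units["KS"].append(u)
            rel = [j for j in others if krow[j] > 0]
            for t in ("GR", "GC"):
                if t not in tests:
                    continue
                u = _Unit(unit_id=iid, family_id=fam)
                if rel:
                    thr = min(krow[j] for j in rel)
                    if t == "GC":
                        u.statistic = float(max(krow[j] for j in rel))
                    else:
                        in_group = krow >= thr
                        u.statistic = float(
                            sum(1 for j in aff_local if in_group[j])
                        )
                else:
                    u.na = True
                units[t].append(u)

    # nulls, chunked over replicates ----------------------------------------
    # IF: per-family conditional null (replicates with >= 2 sampled affected
    # in the family).  KS/GR/GC: pooled conditional null -- the statistic of
    # every testable sampled individual, pooled across all replicates and
    # families; each unit is scored against this common reference.
    if_units = {u.family_id: u for u in units.get("IF", ()) if not u.na}
    pooled_tests = [t for t in tests if t != "IF"]
    thresholds: dict[str, np.ndarray] = {}
    th_counts: dict[str, np.ndarray] = {}
    pooled_total: dict[str, int] = {}
    for t in pooled_tests:
        ok_stats = sorted(u.statistic - _TIE_TOL for u in units[t] if not u.na)
        thresholds[t] = np.asarray(ok_stats)
        th_counts[t] = np.zeros(len(ok_stats), dtype=np.int64)
        pooled_total[t] = 0

    active = [
        fam
        for fam, info in fams.items()
        if len(info["members"]) >= 2 or fam in if_units
    ]
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    for idx in _sample_chunks(rng, n_pool, n_aff, config.B, config.chunk_size):
        c = idx.shape[0]
        Z = np.zeros((c, n_pool), dtype=bool)
        Z[np.repeat(np.arange(c), n_aff), idx.ravel()] = True
        chunk_vals: dict[str, list[np.ndarray]] = {t: [] for t in pooled_tests}
        for fam in active:
            info = fams[fam]
            Zf = Z[:, info["cols"]]
            sub, diag = info["K"], info["diag"]
            kf = Zf.sum(axis=1)
            Zfl = None
            if fam in if_units:
                u = if_units[fam]
                valid = kf >= 2
                if valid.any():
                    Zfl = Zf.astype(float)
                    q = np.einsum("bi,ij,bj->b", Zfl, sub, Zfl)
                    d = Zfl @ diag
                    kv = kf[valid].astype(float)
                    stat = (q[valid] - d[valid]) / (kv * (kv - 1))
                    u.b_eff += int(valid.sum())
                    u.count_ge += int(np.sum(stat >= u.statistic - _TIE_TOL))
            if "KS" in pooled_tests:
                mask = Zf & (kf >= 2)[:, None]
                if mask.any():
                    Zfl = Zf.astype(float) if Zfl is None else Zfl
                    S = Zfl @ sub
                    chunk_vals["KS"].append((S - diag[None, :])[mask])
            if "GR" in pooled_tests or "GC" in pooled_tests:
                m = len(info["members"])
                for ci in range(m):
                    rows = Zf[:, ci]
                    if not rows.any():
                        continue
                    krow = sub[ci]
                    rel_mask = Zf[rows] & (krow > 0)[None, :]
                    rel_mask[:, ci] = False
                    has = rel_mask.any(axis=1)
                    if not has.any():
                        continue
                    rel_mask = rel_mask[has]
                    if "GC" in pooled_tests:
                        chunk_vals["GC"].append(
                            np.where(rel_mask, krow, -1.0).max(axis=1)
                        )
                    if "GR" in pooled_tests:
                        thr = np.where(rel_mask, krow, np.inf).min(axis=1)
                        grv = (
                            Zf[rows][has] & (krow[None, :] >= thr[:, None])
                        ).sum(axis=1)
                        chunk_vals["GR"].append(grv.astype(float))
        for t in pooled_tests:
            if not chunk_vals[t]:
                continue
            v = np.concatenate(chunk_vals[t])
            v.sort()
            pooled_total[t] += v.size
            th_counts[t] += v.size - np.searchsorted(v, thresholds[t], side="left")

    out: dict[str, pd.DataFrame] = {}
    for t, ulist in units.items():
        p_raw = np.full(len(ulist), np.nan)
        if t == "IF":
            for k, u in enumerate(ulist):
                if not u.na and u.b_eff > 0:
                    p_raw[k] = (1 + u.count_ge) / (u.b_eff + 1)
                else:
                    u.na = True
        else:
            order = np.argsort([u.statistic - _TIE_TOL for u in ulist if not u.na])
            ok_units = [u for u in ulist if not u.na]
            total = pooled_total[t]
            # thresholds[t] is sorted; map counts back through the sort order
            counts_by_unit = np.empty(len(ok_units), dtype=np.int64)
            counts_by_unit[order] = th_counts[t]
            for k_ok, u in enumerate(ok_units):
                u.count_ge = int(counts_by_unit[k_ok])
                u.b_eff = total
            for k, u in enumerate(ulist):
                if not u.na and total > 0:
                    p_raw[k] = (1 + u.count_ge) / (total + 1)
                else:
                    u.na = True
        out[t] = _finish_table(
            ulist, "family" if t == "IF" else "individual", p_raw
        )
    return out
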