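"""Benchmark evaluation: confusion counts, precision/recall, rank summaries
and top-rank overlap tables.

For a scenario (Q, R, G) the harness builds one family set per backbone
family, runs the configured aggregation tests on each set, reduces
individual-level tests to family level by the minimum P_raw within a
family, and evaluates two views:

* per family set — tie-averaged rank of the case family on P_raw, and its
  significance at FDR 0.05 after Benjamini-Hochberg adjustment of the
  family-level P values within the set;
* pooled — all sets combined into one imbalanced classification problem
  (one case per set, families-1 controls per set) thresholded on P_adj.

Untestable families are conservatively assigned P = 1, which ties them at
the bottom of every ranking.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .fa_tests import TestConfig, bh_adjust, family_min_p, rank_units, run_tests
from .kinship import kinship_matrix
from .pedigree import Pedigree
from .simulate import Scenario, iter_family_sets

__all__ = [
    "ConfusionCounts",
    "RankSummary",
    "classify_at_threshold",
    "precision_recall",
    "pr_curve",
    "rank_case",
    "bin_ranks",
    "overlap_sets",
    "run_assessment",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int
    threshold: float


@dataclass(frozen=True)
class RankSummary:
    """Case-family counts by rank bin across all family sets of a scenario."""

    significant_top3: int
    insignificant_top3: int
    rank4to10: int
    above10: int
    top_rank_total: int
    top_rank_significant: int
    n_sets: int


def classify_at_threshold(
    p: Sequence[float], labels: Sequence[bool], t: float
) -> ConfusionCounts:
    """Binary classification of pooled P values: positive iff P <= t."""
    p = np.asarray(p, dtype=float)
    lab = np.asarray(labels, dtype=bool)
    if p.shape != lab.shape:
        raise ValueError("P values and labels differ in length")
    pos = p <= t
    return ConfusionCounts(
        tp=int(np.sum(pos & lab)),
        fp=int(np.sum(pos & ~lab)),
        fn=int(np.sum(~pos & lab)),
        tn=int(np.sum(~pos & ~lab)),
        threshold=float(t),
    )


def precision_recall(cc: ConfusionCounts) -> tuple[float, float]:
    """(precision, recall); precision is NaN when nothing is called positive."""
    precision = cc.tp / (cc.tp + cc.fp) if cc.tp + cc.fp > 0 else float("nan")
    recall = cc.tp / (cc.tp + cc.fn) if cc.tp + cc.fn > 0 else float("nan")
    return precision, recall


def pr_curve(p: Sequence[float], labels: Sequence[bool]) -> pd.DataFrame:
    """Step precision/recall curve over every distinct observed P value.

    No interpolation.  The returned frame carries
    ``df.attrs['operating_index']``, the row whose threshold is nearest 0.05
    (the FDR operating point).
    """
    p = np.asarray(p, dtype=float)
    lab = np.asarray(labels, dtype=bool)
    order = np.argsort(p, kind="stable")
    p_sorted, lab_sorted = p[order], lab[order]
    n_cases = int(lab.sum())
    # last index of each distinct threshold in the sorted order
    distinct = np.nonzero(np.diff(p_sorted, append=np.inf))[0]
    cum_tp = np.cumsum(lab_sorted)[distinct]
    cum_pos = distinct + 1
    thresholds = p_sorted[distinct]
    precision = cum_tp / cum_pos
    recall = cum_tp / n_cases if n_cases else np.full(len(distinct), np.nan)
    df = pd.DataFrame(
        {"threshold": thresholds, "recall": recall, "precision": precision}
    )
    if len(df):
        df.attrs["operating_index"] = int(np.argmin(np.abs(thresholds - 0.05)))
    return df


def rank_case(family_p: Mapping[str, float], case_family_id: str) -> float:
    """Tie-averaged ascending rank of the case family on family-level P."""
    fams = list(family_p)
    ranks = rank_units([family_p[f] for f in fams])
    return float(ranks[fams.index(case_family_id)])


def bin_ranks(
    ranks: Sequence[float], significant: Sequence[bool]
) -> RankSummary:
    ranks = np.asarray(ranks, dtype=float)
    sig = np.asarray(significant, dtype=bool)
    top3 = ranks <= 3
    return RankSummary(
        significant_top3=int(np.sum(top3 & sig)),
        insignificant_top3=int(np.sum(top3 & ~sig)),
        rank4to10=int(np.sum((ranks > 3) & (ranks <= 10))),
        above10=int(np.sum(ranks > 10)),
        top_rank_total=int(np.sum(ranks == 1)),
        top_rank_significant=int(np.sum((ranks == 1) & sig)),
        n_sets=len(ranks),
    )


def overlap_sets(rank1: Mapping[str, Iterable]) -> dict[tuple[str, ...], int]:
    """Partition family sets by the exact subset of tests that ranked their
    case first.  Keys are sorted test-name tuples; ``()`` counts the sets
    top-ranked by no test."""
    tests = sorted(rank1)
    sets = {t: set(rank1[t]) for t in tests}
    universe = set().union(*sets.values()) if sets else set()
    out: dict[tuple[str, ...], int] = {}
    for r in range(len(tests), -1, -1):
        for combo in combinations(tests, r):
            inside = universe.copy()
            for t in combo:
                inside &= sets[t]
            for t in tests:
                if t not in combo:
                    inside -= sets[t]
            if combo == () or inside:
                out[combo] = len(inside)
    return out


@dataclass
class ScenarioTestResult:
    case_ranks: list[float]
    case_significant: list[bool]
    pooled_p_adj: np.ndarray
    pooled_is_case: np.ndarray
    rank_summary: RankSummary
    curve: pd.DataFrame
    confusion_05: ConfusionCounts


@dataclass
class AssessmentResult:
    """Per scenario label: per-test results plus the cross-test overlap."""

    per_test: dict[str, dict[str, ScenarioTestResult]]
    overlaps: dict[str, dict[tuple[str, ...], int]]
    n_cases: dict[str, int]
    n_controls: dict[str, int]


def _family_level_p(df: pd.DataFrame, family_ids: list[str], unit_type: str) -> dict[str, float]:
    if unit_type == "family":
        ok = df[df["status"] == "ok"]
        per_fam = dict(zip(ok["family_id"], ok["P_raw"]))
    else:
        per_fam = family_min_p(df).to_dict()
    return {f: float(per_fam.get(f, 1.0)) for f in family_ids}


def run_assessment(
    ped: Pedigree,
    scenarios: Sequence[Scenario],
    tests: Sequence[str],
    B: int,
    seed: int,
    fdr_level: float = 0.05,
) -> AssessmentResult:
    """Full benchmark: simulate family sets, run tests, summarise.

    Deterministic given (pedigree, scenarios, tests, B, seed).
    """
    kin = kinship_matrix(ped)
    family_ids = sorted({i.family_id for i in ped})
    per_test: dict[str, dict[str, ScenarioTestResult]] = {}
    overlaps: dict[str, dict[tuple[str, ...], int]] = {}
    n_cases: dict[str, int] = {}
    n_controls: dict[str, int] = {}

    for s_idx, scenario in enumerate(scenarios):
        acc = {
            t: {"ranks": [], "sig": [], "p": [], "lab": [], "rank1": set()}
            for t in tests
        }
        cases = controls = 0
        for a, fs in enumerate(iter_family_sets(ped, scenario, seed)):
            run_seed = int(
                np.random.SeedSequence([seed, s_idx, a, 7]).generate_state(1)[0]
                & 0x7FFFFFFF
            )
            cfg = TestConfig(tests=tuple(tests), B=B, seed=run_seed, fdr_level=fdr_level)
            results = run_tests(ped, fs.phenotype_map(), cfg, K=kin)
            cases += 1
            controls += len(family_ids) - 1
            for t in tests:
                df = results[t]
                famP = _family_level_p(df, family_ids, df["unit_type"].iloc[0])
                p_vec = np.asarray([famP[f] for f in family_ids])
                p_adj = bh_adjust(p_vec)
                r = rank_case(famP, fs.case_family_id)
                case_pos = family_ids.index(fs.case_family_id)
                acc[t]["ranks"].append(r)
                acc[t]["sig"].append(bool(p_adj[case_pos] <= fdr_level))
                acc[t]["p"].extend(p_adj.tolist())
                acc[t]["lab"].extend(
                    [f == fs.case_family_id for f in family_ids]
                )
                if r == 1:
                    acc[t]["rank1"].add(a)

        label = scenario.label
        per_test[label] = {}
        for t in tests:
            p = np.asarray(acc[t]["p"])
            lab = np.asarray(acc[t]["lab"], dtype=bool)
            per_test[label][t] = ScenarioTestResult(
                case_ranks=acc[t]["ranks"],
                case_significant=acc[t]["sig"],
                pooled_p_adj=p,
                pooled_is_case=lab,
                rank_summary=bin_ranks(acc[t]["ranks"], acc[t]["sig"]),
                curve=pr_curve(p, lab),
                confusion_05=classify_at_threshold(p, lab, fdr_level),
            )
        overlaps[label] = overlap_sets({t: acc[t]["rank1"] for t in tests})
        n_cases[label] = cases
        n_controls[label] = controls

    return AssessmentResult(per_test, overlaps, n_cases, n_controls)
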