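"""Building a minimal voting panel from candidate reversed pairs.

The search follows a three-stage design:

1. Every candidate pair in turn serves as a *pivot*.  Starting from the pivot,
   pairs are added greedily, each step choosing the candidate that most
   increases the fraction of case samples *covered* — a case sample counts as
   covered when at least one pair in the combination shows the reversed
   ordering in it (union semantics).  Growth stops when no remaining candidate
   strictly increases coverage.
2. Pairs are ranked by how often they occur across all per-pivot combinations;
   frequently recurring pairs are the ones that compensate for many pivots'
   coverage gaps.
3. For each odd panel size n up to ``max_top``, the top-n pairs are evaluated
   as a majority-reversed voting classifier on the training cohorts with the
   evaluation index sqrt(PPV x NPV); the smallest n attaining the maximal
   index becomes the final classifier.

All tie-breaks (greedy growth, frequency ranking) prefer smaller q-value, then
higher reversal rate, then lexicographic pair ids, so the whole search is a
deterministic pure function of its inputs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import classify_matrix
from .io import CASE, CONTROL, ExpressionMatrix, LabelMap, OrientedPair, SSClassifier
from .metrics import confusion, diagnostic_metrics
from .reversal import CandidateSet, PairStats

__all__ = [
    "Combination",
    "RankedPairList",
    "SelectionReport",
    "pair_coverage",
    "grow_combination",
    "rank_by_frequency",
    "evaluate_top_n",
    "select_classifier",
]


@dataclass(frozen=True)
class Combination:
    """A pivot pair plus the greedily added pairs, with the joint case coverage."""

    pivot: OrientedPair
    members: tuple[PairStats, ...]
    coverage: float

    def __post_init__(self):
        if not self.members or self.members[0].pair != self.pivot:
            raise ValueError("combination must start with its pivot")
        keys = [m.pair.key for m in self.members]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate pair in combination")


@dataclass(frozen=True)
class RankedPairList:
    """Candidate pairs with their occurrence counts, most frequent first."""

    entries: tuple[tuple[PairStats, int], ...]

    def __len__(self) -> int:
        return len(self.entries)

    def top(self, n: int) -> list[PairStats]:
        return [s for s, _ in self.entries[:n]]


@dataclass(frozen=True)
class SelectionReport:
    """Evaluation index per odd panel size, the chosen size, and the final panel."""

    indices: tuple[tuple[int, float], ...]
    chosen_n: int
    classifier: SSClassifier

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.indices, columns=["n", "eval_index"])


def pair_coverage(pair: OrientedPair, cases: ExpressionMatrix) -> frozenset[str]:
    """Case sample ids in which the pair shows the reversed ordering E_a < E_b."""
    mask = cases.row(pair.a) < cases.row(pair.b)
    sids = cases.sample_ids
    return frozenset(sid for sid, hit in zip(sids, mask) if hit)


def _tiebreak_key(s: PairStats):
    q = s.q_value if s.q_value is not None else 1.0
    rr = s.reversal_rate
    if math.isnan(rr):
        rr = -1.0
    return (q, -rr, s.pair.a, s.pair.b)


def _coverage_rows(candidates: Sequence[PairStats], cases: ExpressionMatrix) -> np.ndarray:
    X = cases.values
    ia = np.array([cases.row_index(s.pair.a) for s in candidates])
    ib = np.array([cases.row_index(s.pair.b) for s in candidates])
    return X[ia] < X[ib]


def grow_combination(
    pivot: PairStats,
    candidates: CandidateSet,
    cases: ExpressionMatrix,
    mode: str = "union",
) -> Combination:
    """Greedy coverage growth from one pivot over the candidate pool.

    ``mode="union"`` (default) counts a case sample as covered when any member
    pair is reversed in it.  ``mode="intersection"`` requires every member to
    be reversed — under that reading adding a pair can never increase
    coverage, so growth stops at the pivot; it is exposed only for sensitivity
    analysis of the coverage semantics.
    """
    if mode not in ("union", "intersection"):
        raise ValueError(f"mode must be 'union' or 'intersection', got {mode!r}")
    pool = list(candidates)
    try:
        pivot_idx = next(i for i, s in enumerate(pool) if s.pair.key == pivot.pair.key)
    except StopIteration:
        raise ValueError(f"pivot {pivot.pair.key} is not in the candidate set") from None
    n_cases = cases.n_samples
    if n_cases == 0:
        raise ValueError("case cohort is empty")
    rows = _coverage_rows(pool, cases)
    # fixed tie-break order: smaller q, higher reversal rate, lexicographic ids
    order = sorted(range(len(pool)), key=lambda i: _tiebreak_key(pool[i]))

    members = [pivot_idx]
    covered = rows[pivot_idx].copy()
    remaining = [i for i in order if i != pivot_idx]
    while remaining:
        best_i, best_gain = None, 0
        current = int(covered.sum())
        for i in remaining:
            joint = covered | rows[i] if mode == "union" else covered & rows[i]
            gain = int(joint.sum()) - current
            if gain > best_gain:
                best_i, best_gain = i, gain
        if best_i is None:
            break
        members.append(best_i)
        covered = covered | rows[best_i] if mode == "union" else covered & rows[best_i]
        remaining.remove(best_i)
    return Combination(
        pivot=pivot.pair,
        members=tuple(pool[i] for i in members),
        coverage=int(covered.sum()) / n_cases,
    )


def rank_by_frequency(combinations: Sequence[Combination]) -> RankedPairList:
    """Count each pair's occurrences across combinations; rank by count.

    Ties in frequency break by smaller q, then higher reversal rate, then
    lexicographic pair ids.
    """
    counts: dict[tuple[str, str], int] = {}
    stats: dict[tuple[str, str], PairStats] = {}
    for comb in combinations:
        for member in comb.members:
            key = member.pair.key
            counts[key] = counts.get(key, 0) + 1
            stats.setdefault(key, member)
    entries = sorted(
        ((stats[k], c) for k, c in counts.items()),
        key=lambda e: (-e[1], *_tiebreak_key(e[0])),
    )
    return RankedPairList(tuple(entries))


def _panel(ranked: RankedPairList, n: int, name: str) -> SSClassifier:
    return SSClassifier(name=name, pairs=tuple(s.pair for s in ranked.top(n)))


def _truth(cases: ExpressionMatrix, controls: ExpressionMatrix) -> LabelMap:
    labels = {sid: CASE for sid in cases.sample_ids}
    labels.update({sid: CONTROL for sid in controls.sample_ids})
    if len(labels) != cases.n_samples + controls.n_samples:
        raise ValueError("case and control cohorts share sample ids")
    return LabelMap(labels)


def evaluate_top_n(
    ranked: RankedPairList,
    n: int,
    cases: ExpressionMatrix,
    controls: ExpressionMatrix,
) -> float:
    """Evaluation index sqrt(PPV x NPV) of majority voting with the top n pairs."""
    if n % 2 == 0:
        raise ValueError(f"panel size must be odd, got {n}")
    if n > len(ranked):
        raise ValueError(f"panel size {n} exceeds ranked list length {len(ranked)}")
    panel = _panel(ranked, n, name=f"top-{n}")
    predicted = {
        r.sample_id: r.label
        for m in (cases, controls)
        for r in classify_matrix(m, panel)
    }
    m = diagnostic_metrics(confusion(predicted, _truth(cases, controls)))
    if "eval_index" in m.undefined:
        warnings.warn(
            f"PPV or NPV undefined for top-{n} panel (zero denominator); "
            "treating the evaluation index as 0",
            stacklevel=2,
        )
        return 0.0
    return m.eval_index


def select_classifier(
    ranked: RankedPairList,
    cases: ExpressionMatrix,
    controls: ExpressionMatrix,
    max_top: int = 31,
    name: str = "ssc",
) -> SelectionReport:
    """Evaluate every odd panel size and keep the smallest one with the best index."""
    if len(ranked) == 0:
        raise ValueError("ranked pair list is empty")
    sizes = range(1, min(max_top, len(ranked)) + 1, 2)
    indices = tuple((n, evaluate_top_n(ranked, n, cases, controls)) for n in sizes)
    chosen_n = max(indices, key=lambda e: (e[1], -e[0]))[0]
    return SelectionReport(
        indices=indices,
        chosen_n=chosen_n,
        classifier=_panel(ranked, chosen_n, name=name),
    )


def write_selection_report(report: SelectionReport, path: str | Path) -> None:
    report.as_frame().to_csv(path, sep="\t", index=False)
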