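"""Testing whether control-stable orderings are reversed in a case cohort.

For a stable pair stored in its control orientation E_a > E_b, the 2x2 table

                E_a > E_b   E_a < E_b
    controls       n1          n2
    cases          m1          m2

is tested with a one-sided Fisher's exact test for enrichment of the reversed
ordering E_a < E_b among cases.  The one-sided Fisher p-value is exactly the
hypergeometric tail P(X >= n1) for X the count in the (controls, E_a > E_b)
cell with all margins fixed, which is how the bulk path computes it.
p-values across pairs are corrected with the Benjamini-Hochberg step-up
procedure, and candidate diagnostic pairs must additionally be reversed in at
least a minimum fraction of (tie-free) case samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, FormatError, OrientedPair

__all__ = [
    "PairStats",
    "CandidateSet",
    "contingency_counts",
    "contingency_counts_bulk",
    "fisher_reversal_test",
    "fisher_reversal_pvalues",
    "bh_adjust",
    "attach_significance",
    "select_candidates",
    "read_pair_stats",
    "write_pair_stats",
]


@dataclass(frozen=True)
class PairStats:
    """Contingency counts and test results for one oriented pair.

    ``n1``/``n2`` count controls with E_a > E_b and E_a < E_b; ``m1``/``m2``
    the same among cases.  Ties are excluded from all four counts.
    """

    pair: OrientedPair
    n1: int
    n2: int
    m1: int
    m2: int
    p_value: float | None = field(default=None)
    q_value: float | None = field(default=None)

    def __post_init__(self):
        for name in ("n1", "n2", "m1", "m2"):
            if getattr(self, name) < 0:
                raise ValueError(f"count {name} must be non-negative")
        for name in ("p_value", "q_value"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    @property
    def reversal_rate(self) -> float:
        """Fraction of tie-free case samples showing the reversed ordering."""
        denom = self.m1 + self.m2
        return self.m2 / denom if denom else float("nan")

    @property
    def table(self) -> np.ndarray:
        return np.array([[self.n1, self.n2], [self.m1, self.m2]])


def contingency_counts(
    pair: OrientedPair, controls: ExpressionMatrix, cases: ExpressionMatrix
) -> PairStats:
    """Count orderings of one pair in both cohorts (ties fall out of all counts)."""
    ca, cb = controls.row(pair.a), controls.row(pair.b)
    ka, kb = cases.row(pair.a), cases.row(pair.b)
    return PairStats(
        pair=pair,
        n1=int(np.count_nonzero(ca > cb)),
        n2=int(np.count_nonzero(ca < cb)),
        m1=int(np.count_nonzero(ka > kb)),
        m2=int(np.count_nonzero(ka < kb)),
    )


def contingency_counts_bulk(
    pairs: Sequence[OrientedPair], controls: ExpressionMatrix, cases: ExpressionMatrix
) -> list[PairStats]:
    """Vectorised :func:`contingency_counts` over many pairs."""
    if not pairs:
        return []
    ia = np.array([controls.row_index(p.a) for p in pairs])
    ib = np.array([controls.row_index(p.b) for p in pairs])
    ja = np.array([cases.row_index(p.a) for p in pairs])
    jb = np.array([cases.row_index(p.b) for p in pairs])
    C, K = controls.values, cases.values
    n1 = (C[ia] > C[ib]).sum(axis=1)
    n2 = (C[ia] < C[ib]).sum(axis=1)
    m1 = (K[ja] > K[jb]).sum(axis=1)
    m2 = (K[ja] < K[jb]).sum(axis=1)
    return [
        PairStats(p, int(a), int(b), int(c), int(d))
        for p, a, b, c, d in zip(pairs, n1, n2, m1, m2)
    ]


def fisher_reversal_test(stats: PairStats, alternative: str = "reversal") -> float:
    """Fisher's exact test p-value for the pair's 2x2 ordering table.

    ``alternative="reversal"`` (default) is one-sided toward cases being
    enriched for the reversed ordering E_a < E_b — equivalently, controls
    enriched for E_a > E_b.  ``alternative="two-sided"`` is also available.
    """
    if stats.n1 + stats.n2 + stats.m1 + stats.m2 == 0:
        raise ValueError("Fisher test undefined: all four counts are zero")
    if alternative == "reversal":
        alt = "greater"
    elif alternative == "two-sided":
        alt = "two-sided"
    else:
        raise ValueError(f"alternative must be 'reversal' or 'two-sided', got {alternative!r}")
    return float(sps.fisher_exact(stats.table, alternative=alt).pvalue)


def fisher_reversal_pvalues(
    stats: Sequence[PairStats], alternative: str = "reversal"
) -> np.ndarray:
    """Vectorised one-sided p-values via the hypergeometric tail identity.

    With margins fixed, the one-sided Fisher p equals
    ``P(X >= n1)`` for ``X ~ Hypergeom(total, n1+m1, n1+n2)``.
    The two-sided alternative falls back to per-table ``fisher_exact``.
    """
    if not stats:
        return np.empty(0)
    if alternative == "two-sided":
        return np.array([fisher_reversal_test(s, "two-sided") for s in stats])
    if alternative != "reversal":
        raise ValueError(f"alternative must be 'reversal' or 'two-sided', got {alternative!r}")
    n1 = np.array([s.n1 for s in stats])
    n2 = np.array([s.n2 for s in stats])
    m1 = np.array([s.m1 for s in stats])
    m2 = np.array([s.m2 for s in stats])
    if np.any(n1 + n2 + m1 + m2 == 0):
        raise ValueError("Fisher test undefined: all four counts are zero")
    total = n1 + n2 + m1 + m2
    p = sps.hypergeom.sf(n1 - 1, total, n1 + m1, n1 + n2)
    return np.minimum(p, 1.0)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, clipped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def attach_significance(
    stats: Sequence[PairStats], alternative: str = "reversal"
) -> list[PairStats]:
    """Return stats with p-values and BH q-values filled in (one shared BH pass)."""
    p = fisher_reversal_pvalues(stats, alternative=alternative)
    q = bh_adjust(p)
    return [
        replace(s, p_value=float(pi), q_value=float(qi)) for s, pi, qi in zip(stats, p, q)
    ]


@dataclass(frozen=True)
class CandidateSet:
    """Significantly reversed pairs passing both the FDR and reversal-rate filters."""

    candidates: tuple[PairStats, ...]
    q_threshold: float
    reversal_threshold: float

    def __post_init__(self):
        object.__setattr__(self, "candidates", tuple(self.candidates))
        for s in self.candidates:
            if s.q_value is None or not (s.q_value < self.q_threshold):
                raise ValueError(f"candidate {s.pair.key} fails q < {self.q_threshold}")
            if not (s.reversal_rate >= self.reversal_threshold):
                raise ValueError(
                    f"candidate {s.pair.key} fails reversal >= {self.reversal_threshold}"
                )

    def __len__(self) -> int:
        return len(self.candidates)

    def __iter__(self):
        return iter(self.candidates)


def _candidate_sort_key(s: PairStats):
    return (-s.reversal_rate, s.q_value, s.pair.a, s.pair.b)


def select_candidates(
    stats: Iterable[PairStats],
    q_threshold: float = 0.05,
    reversal_threshold: float = 0.70,
) -> CandidateSet:
    """Filter to q < ``q_threshold`` and reversal rate >= ``reversal_threshold``.

    Output is sorted by reversal rate (descending), then q (ascending), then
    pair ids, so the candidate list is deterministic.
    """
    chosen = [
        s
        for s in stats
        if s.q_value is not None
        and s.q_value < q_threshold
        and (s.m1 + s.m2) > 0
        and s.reversal_rate >= reversal_threshold
    ]
    chosen.sort(key=_candidate_sort_key)
    return CandidateSet(tuple(chosen), q_threshold, reversal_threshold)


# ---------------------------------------------------------------------------
# TSV serialization: a, b, n1, n2, m1, m2, p, q, reversal_rate
# ---------------------------------------------------------------------------


def write_pair_stats(stats: Sequence[PairStats], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "a": [s.pair.a for s in stats],
            "b": [s.pair.b for s in stats],
            "n1": [s.n1 for s in stats],
            "n2": [s.n2 for s in stats],
            "m1": [s.m1 for s in stats],
            "m2": [s.m2 for s in stats],
            "p": [s.p_value for s in stats],
            "q": [s.q_value for s in stats],
            "reversal_rate": [s.reversal_rate for s in stats],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_pair_stats(path: str | Path) -> list[PairStats]:
    df = pd.read_csv(path, sep="\t")
    required = {"a", "b", "n1", "n2", "m1", "m2"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: pair-stats table must have columns {sorted(required)}")
    out = []
    for r in df.itertuples(index=False):
        p = float(r.p) if "p" in df.columns and pd.notna(r.p) else None
        q = float(r.q) if "q" in df.columns and pd.notna(r.q) else None
        out.append(
            PairStats(
                OrientedPair(str(r.a), str(r.b)),
                int(r.n1), int(r.n2), int(r.m1), int(r.m2),
                p_value=p, q_value=q,
            )
        )
    return out
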