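"""Applying a fixed pair panel to individual samples.

Each panel pair votes on one sample in isolation: *reversed* when E_a < E_b
strictly, *conforming* when E_a > E_b strictly, abstaining on exact ties.  The
sample is called *case* when strictly more than half of the usable pairs vote
reversed.  Nothing here looks at any other sample — the decision is a pure
function of one expression vector and the panel, which is what lets the
classifier run on a single profile with no cohort-level normalisation.

The module also provides the published 10-miRNA linear diagnostic index used
as a comparator model.  Unlike the vote, that index depends on absolute
expression values, so it is *not* invariant to monotonic rescaling — the
documented contrast between the two model families.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CASE, CONTROL, ExpressionMatrix, SSClassifier

__all__ = [
    "VoteResult",
    "vote",
    "classify_matrix",
    "predictions_frame",
    "yokoi_index",
    "yokoi_classify_matrix",
    "YOKOI_COEFFICIENTS",
    "YOKOI_INTERCEPT",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class VoteResult:
    """Outcome of majority-reversed voting on one sample."""

    sample_id: str
    votes_reversed: int
    votes_conforming: int
    n_usable: int
    label: str

    @property
    def score(self) -> float:
        """Fraction of usable pairs voting reversed — the ROC ranking statistic."""
        return self.votes_reversed / self.n_usable if self.n_usable else 0.0


def _panel_rows(
    matrix: ExpressionMatrix, classifier: SSClassifier, permissive: bool
) -> tuple[np.ndarray, np.ndarray, int]:
    """Row-index arrays for usable panel pairs, plus the usable-pair count."""
    ia, ib = [], []
    skipped = []
    for p in classifier.pairs:
        if p.a in matrix and p.b in matrix:
            ia.append(matrix.row_index(p.a))
            ib.append(matrix.row_index(p.b))
        else:
            skipped.append(p)
    if skipped and not permissive:
        missing = sorted({m for p in skipped for m in (p.a, p.b) if m not in matrix})
        raise KeyError(
            f"panel miRNAs absent from matrix: {missing}; "
            "pass permissive=True to skip the affected pairs"
        )
    if skipped:
        logger.warning(
            "permissive voting: skipped %d of %d pairs with absent miRNAs "
            "(effective panel size %d)",
            len(skipped), len(classifier.pairs), len(ia),
        )
    return np.asarray(ia, dtype=int), np.asarray(ib, dtype=int), len(ia)


def classify_matrix(
    matrix: ExpressionMatrix, classifier: SSClassifier, permissive: bool = False
) -> list[VoteResult]:
    """Vote every sample of ``matrix`` with the panel; one result per column.

    Each result depends only on its own column, so permuting sample columns
    permutes the output identically.  In strict mode (default) every panel
    miRNA must be present; in permissive mode pairs with absent miRNAs are
    skipped and the usable panel shrinks (with a logged warning).
    """
    ia, ib, n_usable = _panel_rows(matrix, classifier, permissive)
    X = matrix.values
    if n_usable:
        reversed_votes = (X[ia] < X[ib]).sum(axis=0)
        conforming_votes = (X[ia] > X[ib]).sum(axis=0)
    else:
        reversed_votes = np.zeros(matrix.n_samples, dtype=int)
        conforming_votes = np.zeros(matrix.n_samples, dtype=int)
    results = []
    for k, sid in enumerate(matrix.sample_ids):
        nr = int(reversed_votes[k])
        # exact half-votes (possible only via ties or a shrunken even panel)
        # resolve conservatively to control
        label = CASE if 2 * nr > n_usable else CONTROL
        results.append(
            VoteResult(
                sample_id=sid,
                votes_reversed=nr,
                votes_conforming=int(conforming_votes[k]),
                n_usable=n_usable,
                label=label,
            )
        )
    return results


def vote(
    sample: pd.Series | Mapping[str, float],
    classifier: SSClassifier,
    permissive: bool = False,
    sample_id: str = "sample",
) -> VoteResult:
    """Vote a single expression profile (miRNA id -> value) with the panel."""
    if isinstance(sample, pd.Series):
        series = sample.astype(float)
        sample_id = sample.name if sample.name is not None else sample_id
    else:
        series = pd.Series(dict(sample), dtype=float)
    matrix = ExpressionMatrix(series.to_frame(str(sample_id)))
    return classify_matrix(matrix, classifier, permissive=permissive)[0]


def predictions_frame(results: Sequence[VoteResult]) -> pd.DataFrame:
    """Tabulate vote results (sample_id, votes_reversed, n_usable, score, label)."""
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "votes_reversed": [r.votes_reversed for r in results],
            "votes_conforming": [r.votes_conforming for r in results],
            "n_usable": [r.n_usable for r in results],
            "score": [r.score for r in results],
            "label": [r.label for r in results],
        }
    )


def write_predictions(results: Sequence[VoteResult], path: str | Path) -> None:
    predictions_frame(results).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Published 10-miRNA linear comparator (expression-level model)
# ---------------------------------------------------------------------------

YOKOI_COEFFICIENTS: dict[str, float] = {
    "miR-320a": 0.581,
    "miR-665": 0.691,
    "miR-3184-5p": -0.704,
    "miR-6717-5p": -0.313,
    "miR-4459": -1.302,
    "miR-6076": 0.729,
    "miR-3195": 0.676,
    "miR-1275": 0.716,
    "miR-3185": 0.672,
    "miR-4640-5p": -0.384,
}
YOKOI_INTERCEPT: float = -9.375


def yokoi_index(sample: pd.Series | Mapping[str, float]) -> tuple[float, str]:
    """The published 10-miRNA linear diagnostic index and its label.

    index = sum(coefficient_i * expression_i) - 9.375; a sample is called
    ovarian cancer (case) when the index is >= 0, non-cancer otherwise.
    All ten miRNAs must be present.
    """
    getter = sample.get if hasattr(sample, "get") else None
    missing = [m for m in YOKOI_COEFFICIENTS if getter(m) is None] if getter else []
    if not hasattr(sample, "get"):
        raise TypeError("sample must be a mapping or pandas Series of expression values")
    if missing:
        raise KeyError(
            f"10-miRNA model requires {sorted(YOKOI_COEFFICIENTS)}; missing {missing}"
        )
    index = YOKOI_INTERCEPT + sum(
        coef * float(sample[mirna]) for mirna, coef in YOKOI_COEFFICIENTS.items()
    )
    return index, (CASE if index >= 0 else CONTROL)


def yokoi_classify_matrix(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Apply the 10-miRNA index to every sample; columns sample_id, index, label."""
    rows = [
        (sid, *yokoi_index(matrix.column(sid)))
        for sid in matrix.sample_ids
    ]
    return pd.DataFrame(rows, columns=["sample_id", "index", "label"])
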