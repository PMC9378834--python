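"""Mining miRNA pairs with stable within-sample relative expression orderings.

For an miRNA pair (a, b) and a cohort of N samples, let m be the number of
samples in which E_a > E_b holds strictly.  The ordering probability is
P(E_a > E_b) = m/N; a pair whose majority orientation satisfies m/N > threshold
(strict inequality, default threshold 0.95) is a *stable pair* and is stored in
that orientation.  Because only strict within-sample comparisons enter, every
result here is invariant to any strictly increasing transform applied per
sample — the property that makes the downstream classifier usable on single
samples without cross-sample normalisation.

Exact ties (E_a = E_b) count toward neither orientation; the denominator stays
the full cohort size N.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, FormatError, OrientedPair

__all__ = [
    "StablePairSet",
    "ordering_count",
    "pairwise_greater_counts",
    "mine_stable_pairs",
    "retain_in_cohort",
    "read_stable_pairs",
    "write_stable_pairs",
]

logger = logging.getLogger(__name__)

# cap on the boolean work array of the blocked count kernel (elements)
_BLOCK_ELEMENTS = 1 << 27


@dataclass(frozen=True)
class StablePairSet:
    """Pairs whose reference orientation held in > ``threshold`` of ``cohort_size`` samples."""

    pairs: tuple[OrientedPair, ...]
    threshold: float
    cohort_size: int
    #: pairs dropped during retention because an miRNA was absent from the cohort
    n_missing: int = field(default=0, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "pairs", tuple(self.pairs))
        keys = [p.key for p in self.pairs]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate unordered pair in stable set")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


def _check_threshold(threshold: float) -> None:
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"stability threshold must be in (0, 1), got {threshold}")


def ordering_count(matrix: ExpressionMatrix, a: str, b: str) -> int:
    """Number of samples in which miRNA ``a`` strictly exceeds ``b``."""
    if a == b:
        raise ValueError("pair members must differ")
    return int(np.count_nonzero(matrix.row(a) > matrix.row(b)))


def pairwise_greater_counts(matrix: ExpressionMatrix) -> np.ndarray:
    """M x M matrix C with C[i, j] = number of samples where row i > row j strictly.

    Computed in sample blocks so the boolean work array stays bounded
    regardless of cohort size; ties contribute to neither C[i, j] nor C[j, i].
    """
    X = matrix.values
    M, N = X.shape
    counts = np.zeros((M, M), dtype=np.int64)
    if N == 0 or M == 0:
        return counts
    block = max(1, min(N, _BLOCK_ELEMENTS // max(1, M * M)))
    for s0 in range(0, N, block):
        chunk = X[:, s0 : s0 + block]
        counts += (chunk[:, None, :] > chunk[None, :, :]).sum(axis=2)
    return counts


def mine_stable_pairs(matrix: ExpressionMatrix, threshold: float = 0.95) -> StablePairSet:
    """Enumerate all M(M-1)/2 pairs and keep those stable above ``threshold``.

    Each kept pair is stored in its majority orientation with its observed
    stability m/N.  Output is sorted lexicographically by (a, b) so repeated
    runs produce identical files; the set itself does not depend on the input
    row order.
    """
    _check_threshold(threshold)
    if matrix.n_samples < 1:
        raise ValueError("cohort must contain at least one sample")
    counts = pairwise_greater_counts(matrix)
    ids = matrix.mirna_ids
    N = matrix.n_samples
    iu, ju = np.triu_indices(matrix.n_mirnas, k=1)
    c_ij = counts[iu, ju]
    c_ji = counts[ju, iu]
    m = np.maximum(c_ij, c_ji)
    keep = m > threshold * N  # strict m/N > threshold without float division
    pairs = []
    for i, j, cij, cji, mm in zip(iu[keep], ju[keep], c_ij[keep], c_ji[keep], m[keep]):
        hi, lo = (ids[i], ids[j]) if cij >= cji else (ids[j], ids[i])
        if cij == cji:  # orientation tie: canonicalise lexicographically
            hi, lo = sorted((ids[i], ids[j]))
        pairs.append(OrientedPair(hi, lo, stability=float(mm) / N))
    pairs.sort(key=lambda p: (p.a, p.b))
    return StablePairSet(tuple(pairs), threshold=threshold, cohort_size=N)


def retain_in_cohort(
    stable: StablePairSet, matrix: ExpressionMatrix, threshold: float = 0.95
) -> StablePairSet:
    """Keep pairs whose stored orientation also holds in > ``threshold`` of a second cohort.

    The orientation fixed at mining time is never flipped.  Pairs referencing
    an miRNA absent from the cohort are dropped and counted in ``n_missing``
    on the returned set (and logged), not raised as errors.  Stabilities on
    the returned pairs are the proportions observed in the new cohort.
    """
    _check_threshold(threshold)
    N = matrix.n_samples
    if N < 1:
        raise ValueError("cohort must contain at least one sample")
    present = [p for p in stable.pairs if p.a in matrix and p.b in matrix]
    n_missing = len(stable.pairs) - len(present)
    if n_missing:
        logger.warning("retain_in_cohort: dropped %d pairs with absent miRNAs", n_missing)
    if present:
        ia = np.array([matrix.row_index(p.a) for p in present])
        ib = np.array([matrix.row_index(p.b) for p in present])
        X = matrix.values
        m = (X[ia] > X[ib]).sum(axis=1)
    else:
        m = np.empty(0, dtype=int)
    kept = tuple(
        OrientedPair(p.a, p.b, stability=float(mi) / N)
        for p, mi in zip(present, m)
        if mi > threshold * N
    )
    return StablePairSet(kept, threshold=threshold, cohort_size=N, n_missing=n_missing)


# ---------------------------------------------------------------------------
# TSV serialization: columns a, b, stability, cohort_size
# ---------------------------------------------------------------------------


def write_stable_pairs(stable: StablePairSet, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "a": [p.a for p in stable.pairs],
            "b": [p.b for p in stable.pairs],
            "stability": [p.stability for p in stable.pairs],
            "cohort_size": stable.cohort_size,
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# threshold={stable.threshold!r}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_stable_pairs(path: str | Path) -> StablePairSet:
    path = Path(path)
    threshold = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# threshold="):
            threshold = float(first.split("=", 1)[1])
            df = pd.read_csv(fh, sep="\t")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t")
    required = {"a", "b", "stability", "cohort_size"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: stable-pair table must have columns {sorted(required)}")
    if threshold is None:
        threshold = 0.95
    sizes = df["cohort_size"].unique()
    if len(sizes) > 1:
        raise FormatError(f"{path}: inconsistent cohort_size values {sizes[:3]}")
    pairs = tuple(
        OrientedPair(str(r.a), str(r.b), stability=float(r.stability))
        for r in df.itertuples(index=False)
    )
    size = int(sizes[0]) if len(sizes) else 0
    return StablePairSet(pairs, threshold=threshold, cohort_size=size)
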