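"""Reading and writing expression matrices, label maps, and pair-panel classifiers.

The on-disk formats are deliberately plain: tab-separated matrices (rows =
miRNAs, columns = samples, matching the orientation of GEO series-matrix
exports), two-column TSV label files, and a small JSON schema for classifier
panels.  Because the method downstream consumes only within-sample ranks, the
matrix values may be on any positive scale (raw intensities, log intensities,
quantile-normalised values); no transform is applied at read time.
"""

from __future__ import annotations

import io as _io
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ExpressionMatrix",
    "LabelMap",
    "OrientedPair",
    "SSClassifier",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_labels",
    "write_labels",
    "read_classifier",
    "write_classifier",
    "load_bundled_classifier",
    "BUNDLED_CLASSIFIERS",
]

CASE = "case"
CONTROL = "control"

#: tokens accepted in label files, normalised to case/control
CASE_TOKENS = frozenset({"case", "cancer", "tumor", "tumour", "ovc", "1"})
CONTROL_TOKENS = frozenset({"control", "non-cancer", "noncancer", "normal", "healthy", "0"})


class FormatError(ValueError):
    """An input file violates its documented format."""


# ---------------------------------------------------------------------------
# ExpressionMatrix
# ---------------------------------------------------------------------------


class ExpressionMatrix:
    """An M x N table of expression values (miRNAs by samples).

    Wraps a :class:`pandas.DataFrame` with validated unique identifiers and
    finite float values.  Row and column order are preserved as given.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate miRNA identifiers: {dups[:5]}")
        if data.columns.has_duplicates:
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample identifiers: {dups[:5]}")
        values = data.to_numpy(dtype=float, copy=True)
        if values.size and not np.isfinite(values).all():
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise FormatError(
                f"non-finite value at miRNA {data.index[i]!r}, sample {data.columns[j]!r}"
            )
        self._data = pd.DataFrame(
            values, index=data.index.astype(str), columns=data.columns.astype(str)
        )
        self._row_index = {m: i for i, m in enumerate(self._data.index)}

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_arrays(
        cls,
        mirna_ids: Sequence[str],
        sample_ids: Sequence[str],
        values: np.ndarray,
    ) -> "ExpressionMatrix":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(mirna_ids), len(sample_ids)):
            raise FormatError(
                f"value table shape {values.shape} does not match "
                f"{len(mirna_ids)} miRNAs x {len(sample_ids)} samples"
            )
        return cls(pd.DataFrame(values, index=list(mirna_ids), columns=list(sample_ids)))

    # -- accessors ------------------------------------------------------------

    @property
    def mirna_ids(self) -> list[str]:
        return list(self._data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._data.columns)

    @property
    def values(self) -> np.ndarray:
        """The M x N float array (no copy)."""
        return self._data.to_numpy(copy=False)

    @property
    def n_mirnas(self) -> int:
        return self._data.shape[0]

    @property
    def n_samples(self) -> int:
        return self._data.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self._data.shape

    def to_dataframe(self) -> pd.DataFrame:
        return self._data.copy()

    def row_index(self, mirna_id: str) -> int:
        try:
            return self._row_index[mirna_id]
        except KeyError:
            raise KeyError(f"unknown miRNA identifier: {mirna_id!r}") from None

    def row(self, mirna_id: str) -> np.ndarray:
        """Expression values of one miRNA across all samples."""
        return self.values[self.row_index(mirna_id)]

    def column(self, sample_id: str) -> pd.Series:
        """One sample's expression profile, indexed by miRNA id."""
        if sample_id not in self._data.columns:
            raise KeyError(f"unknown sample identifier: {sample_id!r}")
        return self._data[sample_id]

    def __contains__(self, mirna_id: str) -> bool:
        return mirna_id in self._row_index

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(sample_ids)
        missing = [s for s in ids if s not in self._data.columns]
        if missing:
            raise KeyError(f"unknown sample identifiers: {missing[:5]}")
        return ExpressionMatrix(self._data[ids])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self._data.equals(other._data)

    def __repr__(self) -> str:
        return f"ExpressionMatrix({self.n_mirnas} miRNAs x {self.n_samples} samples)"


# ---------------------------------------------------------------------------
# LabelMap
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LabelMap:
    """Sample id -> {case, control} assignment."""

    labels: Mapping[str, str]

    def __post_init__(self):
        bad = {l for l in self.labels.values() if l not in (CASE, CONTROL)}
        if bad:
            raise FormatError(f"labels must be 'case' or 'control', got {sorted(bad)}")
        object.__setattr__(self, "labels", dict(self.labels))

    def __getitem__(self, sample_id: str) -> str:
        return self.labels[sample_id]

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self) -> Iterator[str]:
        return iter(self.labels)

    def items(self):
        return self.labels.items()

    @property
    def case_ids(self) -> list[str]:
        return [s for s, l in self.labels.items() if l == CASE]

    @property
    def control_ids(self) -> list[str]:
        return [s for s, l in self.labels.items() if l == CONTROL]


# ---------------------------------------------------------------------------
# OrientedPair / SSClassifier
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class OrientedPair:
    """An miRNA pair stored in its reference (control) orientation E_a > E_b.

    ``stability`` is the proportion of reference-cohort samples in which the
    strict ordering E_a > E_b held; it is ``None`` for panels loaded from a
    definition file that does not record it.
    """

    a: str
    b: str
    stability: float | None = field(default=None, compare=False)

    def __post_init__(self):
        if not self.a or not self.b:
            raise ValueError("miRNA identifiers must be nonempty")
        if self.a == self.b:
            raise ValueError(f"pair members must differ, got {self.a!r} twice")
        if self.stability is not None and not (0.0 <= self.stability <= 1.0):
            raise ValueError(f"stability must be in [0, 1], got {self.stability}")

    @property
    def key(self) -> tuple[str, str]:
        """Unordered identity of the pair (sorted ids)."""
        return tuple(sorted((self.a, self.b)))  # type: ignore[return-value]


MAJORITY_REVERSED = "majority_reversed"


@dataclass(frozen=True)
class SSClassifier:
    """An ordered panel of oriented miRNA pairs with a majority-reversed vote rule.

    A sample is called *case* when strictly more than half of the usable pairs
    show the reversed ordering E_a < E_b.  Panels intended for voting carry an
    odd number of pairs; an even panel loads with a warning because exact vote
    ties then become possible.
    """

    name: str
    pairs: tuple[OrientedPair, ...]
    vote_rule: str = MAJORITY_REVERSED

    def __post_init__(self):
        object.__setattr__(self, "pairs", tuple(self.pairs))
        if not self.pairs:
            raise ValueError("classifier must contain at least one pair")
        if self.vote_rule != MAJORITY_REVERSED:
            raise ValueError(f"unsupported vote rule: {self.vote_rule!r}")
        keys = [p.key for p in self.pairs]
        if len(set(keys)) != len(keys):
            dup = next(k for k in keys if keys.count(k) > 1)
            raise ValueError(f"duplicate pair in classifier: {dup}")
        if len(self.pairs) % 2 == 0:
            warnings.warn(
                f"classifier {self.name!r} has an even number of pairs "
                f"({len(self.pairs)}); majority voting requires an odd panel",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def mirna_ids(self) -> list[str]:
        """Distinct miRNAs used by the panel, in first-appearance order."""
        seen: dict[str, None] = {}
        for p in self.pairs:
            seen.setdefault(p.a)
            seen.setdefault(p.b)
        return list(seen)


# ---------------------------------------------------------------------------
# Expression matrix readers/writers
# ---------------------------------------------------------------------------

GEO_TABLE_BEGIN = "!series_matrix_table_begin"
GEO_TABLE_END = "!series_matrix_table_end"


def _frame_from_text(text: str, path: object) -> pd.DataFrame:
    df = pd.read_csv(
        _io.StringIO(text),
        sep="\t",
        index_col=0,
        dtype=str,
        keep_default_na=False,
        skip_blank_lines=True,
    )
    if df.index.name is None and df.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns found")
    numeric = df.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = np.argwhere(numeric.isna().to_numpy())
    if bad.size:
        i, j = bad[0]
        raise FormatError(
            f"{path}: non-numeric value {df.iat[i, j]!r} at "
            f"miRNA {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    return numeric


def read_expression_matrix(path: str | Path, dialect: str = "plain_tsv") -> ExpressionMatrix:
    """Read an expression matrix from TSV or GEO series-matrix text.

    Parameters
    ----------
    path
        Input file.  For ``plain_tsv`` the first row holds sample ids (the
        first header cell is ignored) and each subsequent row is one miRNA.
        For ``geo_series_matrix`` only the block between the literal lines
        ``!series_matrix_table_begin`` and ``!series_matrix_table_end`` is
        consumed; everything else in the file is ignored.
    dialect
        ``"plain_tsv"`` or ``"geo_series_matrix"``.
    """
    path = Path(path)
    text = path.read_text()
    if dialect == "plain_tsv":
        return ExpressionMatrix(_frame_from_text(text, path))
    if dialect == "geo_series_matrix":
        lines = text.splitlines()
        try:
            begin = next(i for i, l in enumerate(lines) if l.strip() == GEO_TABLE_BEGIN)
            end = next(i for i, l in enumerate(lines) if l.strip() == GEO_TABLE_END)
        except StopIteration:
            raise FormatError(
                f"{path}: series-matrix table delimiters "
                f"({GEO_TABLE_BEGIN!r}/{GEO_TABLE_END!r}) not found"
            ) from None
        if end <= begin + 1:
            raise FormatError(f"{path}: empty series-matrix table block")
        block = "\n".join(lines[begin + 1 : end])
        # GEO quotes identifiers; pandas strips the quotes during parsing.
        return ExpressionMatrix(_frame_from_text(block, path))
    raise ValueError(f"unknown dialect: {dialect!r}")


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.to_dataframe().to_csv(Path(path), sep="\t", index_label="miRNA_ID")


# ---------------------------------------------------------------------------
# Label readers/writers
# ---------------------------------------------------------------------------


def read_labels(
    path: str | Path,
    case_tokens: frozenset[str] = CASE_TOKENS,
    control_tokens: frozenset[str] = CONTROL_TOKENS,
) -> LabelMap:
    """Read a two-column (sample_id, label) TSV into a LabelMap.

    Label tokens are matched case-insensitively against the accepted
    vocabularies and normalised to ``case`` / ``control``.  A header row
    reading ``sample_id<TAB>label`` is tolerated and skipped.
    """
    path = Path(path)
    labels: dict[str, str] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 tab-separated columns")
        sid, token = parts[0].strip(), parts[1].strip()
        if lineno == 1 and sid.lower() == "sample_id" and token.lower() == "label":
            continue
        if sid in labels:
            raise FormatError(f"{path}:{lineno}: duplicate sample id {sid!r}")
        low = token.lower()
        if low in case_tokens:
            labels[sid] = CASE
        elif low in control_tokens:
            labels[sid] = CONTROL
        else:
            accepted = sorted(case_tokens) + sorted(control_tokens)
            raise FormatError(
                f"{path}:{lineno}: unknown label {token!r}; accepted tokens: {accepted}"
            )
    return LabelMap(labels)


def write_labels(labels: LabelMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tlabel\n")
        for sid, lab in labels.items():
            fh.write(f"{sid}\t{lab}\n")


# ---------------------------------------------------------------------------
# Classifier serialization (JSON)
# ---------------------------------------------------------------------------


def classifier_to_dict(classifier: SSClassifier) -> dict:
    pairs = []
    for p in classifier.pairs:
        d: dict[str, object] = {"a": p.a, "b": p.b}
        if p.stability is not None:
            d["stability"] = p.stability
        pairs.append(d)
    return {"name": classifier.name, "vote_rule": classifier.vote_rule, "pairs": pairs}


def classifier_from_dict(doc: Mapping) -> SSClassifier:
    try:
        pairs = tuple(
            OrientedPair(p["a"], p["b"], p.get("stability")) for p in doc["pairs"]
        )
        return SSClassifier(
            name=doc["name"], pairs=pairs, vote_rule=doc.get("vote_rule", MAJORITY_REVERSED)
        )
    except (KeyError, TypeError) as exc:
        raise FormatError(f"malformed classifier document: {exc}") from exc


def read_classifier(path: str | Path) -> SSClassifier:
    with open(path) as fh:
        return classifier_from_dict(json.load(fh))


def write_classifier(classifier: SSClassifier, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(classifier_to_dict(classifier), fh, indent=1)
        fh.write("\n")


#: panels published for ovarian-cancer serum diagnosis, bundled with the package
BUNDLED_CLASSIFIERS = {
    "13-miRPairs": "thirteen_mirpairs.json",
    "17-miRPairs": "seventeen_mirpairs.json",
}


def load_bundled_classifier(name: str) -> SSClassifier:
    """Load a bundled published panel by name ('13-miRPairs' or '17-miRPairs')."""
    try:
        filename = BUNDLED_CLASSIFIERS[name]
    except KeyError:
        raise KeyError(
            f"unknown bundled classifier {name!r}; available: {sorted(BUNDLED_CLASSIFIERS)}"
        ) from None
    text = resources.files("mirpairs").joinpath("data", filename).read_text()
    return classifier_from_dict(json.loads(text))
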