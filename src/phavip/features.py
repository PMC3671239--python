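"""Amino-acid and dipeptide composition encoding.

A protein sequence is represented by the 420-vector

    F = [f_1, ..., f_20 | f_21, ..., f_420]

whose first 20 components are the normalized occurrence frequencies of the
amino acids (count / length) and whose remaining 400 components are the
normalized frequencies of the overlapping ordered dipeptides
(count / (length - 1)).  Each block sums to one; dipeptides are read in
N-to-C order, so KE and EK are distinct features.

The canonical feature order is alphabetical: A..Y for the residues, then
AA, AC, ..., YY row-major for the dipeptides.  Subsets of named features can
be projected out of a full matrix; the 38-feature subset selected on the
phage virion benchmark ships as :data:`PUBLISHED_38`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .seqio import (
    STANDARD_AA,
    DatasetManifest,
    PhavipError,
    ProteinRecord,
)

AA_NAMES: tuple[str, ...] = tuple(STANDARD_AA)
DIPEPTIDE_NAMES: tuple[str, ...] = tuple(a + b for a in STANDARD_AA for b in STANDARD_AA)
#: All 420 feature names in canonical order: 20 residues then 400 dipeptides.
CANONICAL_FEATURE_NAMES: tuple[str, ...] = AA_NAMES + DIPEPTIDE_NAMES

_AA_INDEX = {a: i for i, a in enumerate(STANDARD_AA)}
_CODE = np.full(128, -1, dtype=np.int64)
for _a, _i in _AA_INDEX.items():
    _CODE[ord(_a)] = _i


class EncodingError(PhavipError):
    """A sequence cannot be encoded (too short for the requested features)."""


class UnknownFeatureError(PhavipError):
    """A feature name is not part of the 420-feature composition space."""


@dataclass(frozen=True)
class FeatureSubset:
    """An ordered, duplicate-free set of named composition features."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        valid = set(CANONICAL_FEATURE_NAMES)
        for n in self.names:
            if n not in valid:
                raise UnknownFeatureError(f"unknown feature name {n!r}")
        if len(set(self.names)) != len(self.names):
            raise UnknownFeatureError("duplicate feature names in subset")

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text("".join(f"{n}\n" for n in self.names))

    @classmethod
    def from_file(cls, path: str | Path) -> "FeatureSubset":
        names = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
        return cls(tuple(names))


#: The 38 composition features selected on the 99-virion / 208-nonvirion
#: benchmark: 8 single residues and 30 dipeptides, dominated by K- and
#: E-containing pairs.
PUBLISHED_38 = FeatureSubset((
    "V", "T", "A", "H", "K", "E", "R", "S",
    "LE", "VT", "VG", "MK", "TA", "TS", "AT", "HI",
    "KL", "KI", "KH", "KN", "KK", "KD", "KE", "KW", "KR",
    "DK", "EF", "EL", "EV", "EK", "EE", "EW",
    "CE", "WK", "RE", "SG", "GV", "GG",
))


def _sequence_of(record: ProteinRecord | str) -> str:
    return record.sequence if isinstance(record, ProteinRecord) else record


def _codes(seq: str) -> np.ndarray:
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        bad = seq[int(np.argmax(codes < 0))]
        raise EncodingError(f"non-standard residue {bad!r} in sequence")
    return codes


def encode_aac(record: ProteinRecord | str) -> np.ndarray:
    """Amino-acid composition: 20 frequencies summing to 1."""
    seq = _sequence_of(record)
    if len(seq) < 1:
        raise EncodingError("cannot encode an empty sequence")
    codes = _codes(seq)
    return np.bincount(codes, minlength=20).astype(np.float64) / len(seq)


def encode_dpc(record: ProteinRecord | str) -> np.ndarray:
    """Dipeptide composition: 400 overlapping-pair frequencies summing to 1.

    The denominator is the number of overlapping windows, length - 1, which
    makes the block sum to exactly one; sequences of length < 2 have no
    windows and are rejected.
    """
    seq = _sequence_of(record)
    if len(seq) < 2:
        raise EncodingError("dipeptide composition undefined for length < 2")
    codes = _codes(seq)
    pair_idx = codes[:-1] * 20 + codes[1:]
    return np.bincount(pair_idx, minlength=400).astype(np.float64) / (len(seq) - 1)


@dataclass(frozen=True)
class FeatureVector:
    """A single encoded sequence: 420 values in canonical order."""

    values: np.ndarray
    source_id: str


def encode_full(record: ProteinRecord | str) -> FeatureVector:
    """Concatenated AAC + DPC encoding: exactly 420 components."""
    values = np.concatenate([encode_aac(record), encode_dpc(record)])
    source_id = record.id if isinstance(record, ProteinRecord) else ""
    return FeatureVector(values=values, source_id=source_id)


@dataclass
class FeatureMatrix:
    """Row-stacked feature vectors with ids, optional labels and column names."""

    values: np.ndarray                      # shape (n, p), float64
    ids: tuple[str, ...]
    feature_names: tuple[str, ...]
    labels: np.ndarray | None = None        # shape (n,), ints in {0,1}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise PhavipError("feature matrix must be 2-dimensional")
        n, p = self.values.shape
        if len(self.ids) != n:
            raise PhavipError("id count does not match row count")
        if len(self.feature_names) != p:
            raise PhavipError("feature-name count does not match column count")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape != (n,):
                raise PhavipError("label count does not match row count")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def require_labelled(self) -> None:
        if self.labels is None:
            raise PhavipError("operation requires a labelled feature matrix")
        if not ((self.labels == 0) | (self.labels == 1)).all():
            raise PhavipError("labels must be binary 0/1")

    def row(self, i: int) -> FeatureVector:
        return FeatureVector(values=self.values[i], source_id=self.ids[i])

    def take_rows(self, idx: Sequence[int] | np.ndarray) -> "FeatureMatrix":
        idx = np.asarray(idx, dtype=np.int64)
        return FeatureMatrix(
            values=self.values[idx],
            ids=tuple(self.ids[int(i)] for i in idx),
            feature_names=self.feature_names,
            labels=None if self.labels is None else self.labels[idx],
        )


def encode_matrix(dataset: DatasetManifest | Iterable[ProteinRecord]) -> FeatureMatrix:
    """Encode every record of a dataset into one 420-column matrix."""
    records = list(dataset.records if isinstance(dataset, DatasetManifest) else dataset)
    if not records:
        raise PhavipError("cannot encode an empty dataset")
    values = np.stack([encode_full(r).values for r in records])
    labels = None
    if all(r.label is not None for r in records):
        labels = np.array([r.label for r in records], dtype=np.int64)
    return FeatureMatrix(
        values=values,
        ids=tuple(r.id for r in records),
        feature_names=CANONICAL_FEATURE_NAMES,
        labels=labels,
    )


def project_subset(matrix: FeatureMatrix, subset: FeatureSubset) -> FeatureMatrix:
    """Reduce/reorder columns to the subset's order; rows and labels unchanged."""
    index = {n: i for i, n in enumerate(matrix.feature_names)}
    cols = []
    for name in subset.names:
        if name not in index:
            raise UnknownFeatureError(f"feature {name!r} not present in matrix")
        cols.append(index[name])
    return FeatureMatrix(
        values=matrix.values[:, cols],
        ids=matrix.ids,
        feature_names=tuple(subset.names),
        labels=matrix.labels,
    )


def write_matrix_tsv(matrix: FeatureMatrix, path: str | Path) -> None:
    """Serialize as TSV: ``id``, ``label`` then one column per feature.

    Floats are written with the shortest representation that parses back to
    the same double (up to 17 significant digits), so the round trip through
    :func:`read_matrix_tsv` is bit-exact.
    """
    df = pd.DataFrame(matrix.values, columns=list(matrix.feature_names))
    df.insert(0, "label", matrix.labels if matrix.labels is not None else "")
    df.insert(0, "id", list(matrix.ids))
    df.to_csv(path, sep="\t", index=False)


def read_matrix_tsv(path: str | Path) -> FeatureMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"id": str}, float_precision="round_trip")
    if df.columns[0] != "id" or df.columns[1] != "label":
        raise PhavipError(f"{path}: expected leading 'id' and 'label' columns")
    names = tuple(df.columns[2:])
    labels = None
    if not df["label"].isna().all():
        labels = df["label"].astype(np.int64).to_numpy()
    return FeatureMatrix(
        values=df[list(names)].to_numpy(dtype=np.float64),
        ids=tuple(df["id"].tolist()),
        feature_names=names,
        labels=labels,
    )
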