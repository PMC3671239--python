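"""Reading, validating and labelling protein sequence datasets.

Virion-protein prediction works on the 420-dimensional amino-acid plus
dipeptide composition space, which is defined only over the 20 standard
residues.  Every record is therefore screened against that alphabet on the
way in: ambiguous letters (B, X, Z) as well as any other non-standard
symbol (J, O, U, gaps, stops) make a sequence unusable and are rejected or
skipped according to an explicit policy.

Datasets are binary: label 1 marks a virion (structural) protein, label 0 a
nonvirion protein.  A :class:`DatasetManifest` bundles the validated,
labelled records together with provenance flags such as whether redundancy
pruning (e.g. CD-HIT clustering) was applied upstream -- pruning itself is a
curation step outside this package.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 standard amino-acid one-letter codes, alphabetical.
STANDARD_AA: str = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_SET = frozenset(STANDARD_AA)

Policy = Literal["strict", "skip", "mask-reject"]
_POLICIES = ("strict", "skip", "mask-reject")


class PhavipError(Exception):
    """Base class for all errors raised by this package."""


class FastaFormatError(PhavipError):
    """The input is not well-formed FASTA (empty file, header without sequence)."""


class SequenceValidationError(PhavipError):
    """A sequence contains a letter outside the 20-residue standard alphabet."""

    def __init__(self, record_id: str, offending: str):
        self.record_id = record_id
        self.offending = offending
        super().__init__(
            f"record {record_id!r}: non-standard residue {offending!r} "
            f"(allowed alphabet: {STANDARD_AA})"
        )


class DatasetError(PhavipError):
    """A dataset-level invariant is violated (duplicate ids, empty class, ...)."""


@dataclass(frozen=True)
class ProteinRecord:
    """One validated protein sequence.

    Parameters
    ----------
    id
        Unique identifier (first whitespace-delimited token of the FASTA
        header).
    sequence
        Uppercase string over the 20 standard amino-acid letters, length >= 1.
    description
        Free text following the id on the header line.
    label
        Optional binary class: 1 = virion protein, 0 = nonvirion protein.
    """

    id: str
    sequence: str
    description: str = ""
    label: int | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceValidationError("<missing>", "<empty id>")
        if not self.sequence:
            raise FastaFormatError(f"record {self.id!r} has an empty sequence")
        bad = first_invalid_residue(self.sequence)
        if bad is not None:
            raise SequenceValidationError(self.id, bad)
        if self.label not in (None, 0, 1):
            raise DatasetError(f"record {self.id!r}: label must be 0 or 1")

    def with_label(self, label: int) -> "ProteinRecord":
        return ProteinRecord(self.id, self.sequence, self.description, label)


def first_invalid_residue(sequence: str) -> str | None:
    """Return the first letter outside the standard alphabet, or ``None``.

    A sequence is valid iff every character is one of the 20 uppercase
    standard residues; in particular the ambiguity codes B, X and Z are
    invalid.
    """
    for ch in sequence:
        if ch not in _STANDARD_SET:
            return ch
    return None


@dataclass
class DatasetManifest:
    """An ordered, labelled protein dataset with provenance flags."""

    records: list[ProteinRecord] = field(default_factory=list)
    redundancy_pruned: bool = False

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise DatasetError(f"duplicate record id {i!r}")
                seen.add(i)

    @property
    def n_pos(self) -> int:
        return sum(1 for r in self.records if r.label == 1)

    @property
    def n_neg(self) -> int:
        return sum(1 for r in self.records if r.label == 0)

    def __len__(self) -> int:
        return len(self.records)

    def require_labelled(self) -> None:
        """Raise unless every record carries a label and both classes occur."""
        for r in self.records:
            if r.label is None:
                raise DatasetError(f"record {r.id!r} is unlabelled")
        if self.n_pos == 0 or self.n_neg == 0:
            raise DatasetError(
                f"both classes required: n_pos={self.n_pos}, n_neg={self.n_neg}"
            )


def read_fasta(path: str | Path, policy: Policy = "strict") -> list[ProteinRecord]:
    """Read and validate a FASTA file of protein sequences.

    ``policy`` controls what happens to sequences containing letters outside
    the 20-residue standard alphabet:

    ``strict``
        raise :class:`SequenceValidationError` on the first invalid record;
    ``skip``
        drop invalid records, logging each exclusion with its reason;
    ``mask-reject``
        like ``strict`` but soft-masked (lowercase) residues are also
        rejected instead of being uppercased.

    Under ``strict`` and ``skip`` lowercase input is uppercased before
    validation (a common FASTA dialect).
    """
    if policy not in _POLICIES:
        raise ValueError(f"unknown policy {policy!r}; expected one of {_POLICIES}")
    path = Path(path)
    raw = list(SeqIO.parse(str(path), "fasta"))
    if not raw:
        raise FastaFormatError(f"{path}: empty file or no FASTA records")
    records: list[ProteinRecord] = []
    for rec in raw:
        seq = str(rec.seq)
        if not seq:
            raise FastaFormatError(f"{path}: record {rec.id!r} has no sequence")
        if policy == "mask-reject":
            lower = next((c for c in seq if c.islower()), None)
            if lower is not None:
                raise SequenceValidationError(rec.id, lower)
        else:
            seq = seq.upper()
        bad = first_invalid_residue(seq)
        if bad is not None:
            if policy == "skip":
                logger.info(
                    "excluding record %r: non-standard residue %r", rec.id, bad
                )
                continue
            raise SequenceValidationError(rec.id, bad)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(ProteinRecord(id=rec.id, sequence=seq, description=desc))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as multi-line FASTA (60-column wrap).

    Round-trip guarantee: :func:`read_fasta` on the written file reproduces
    the (id, sequence) pairs, in order, exactly; descriptions survive too.
    """
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seq_records, fh, "fasta")


def load_labeled_dataset(
    pos_path: str | Path,
    neg_path: str | Path,
    policy: Policy = "strict",
    redundancy_pruned: bool = False,
) -> DatasetManifest:
    """Build a two-class manifest from one FASTA file per class.

    Records from ``pos_path`` get label 1 (virion), from ``neg_path`` label 0.
    Duplicate ids across the two files and empty classes are errors -- the
    classifier is undefined without both classes.
    """
    pos = [r.with_label(1) for r in read_fasta(pos_path, policy)]
    neg = [r.with_label(0) for r in read_fasta(neg_path, policy)]
    if not pos:
        raise DatasetError(f"{pos_path}: no valid positive sequences")
    if not neg:
        raise DatasetError(f"{neg_path}: no valid negative sequences")
    manifest = DatasetManifest(records=pos + neg, redundancy_pruned=redundancy_pruned)
    manifest.require_labelled()
    return manifest


def read_label_table(path: str | Path) -> dict[str, int]:
    """Read the two-column label TSV dialect: ``id<TAB>label``, labels in {0,1}."""
    labels: dict[str, int] = {}
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 2:
                raise DatasetError(f"{path}:{lineno}: expected 'id<TAB>label'")
            rid, lab = row[0].strip(), row[1].strip()
            if lab not in ("0", "1"):
                raise DatasetError(f"{path}:{lineno}: label must be 0 or 1, got {lab!r}")
            if rid in labels:
                raise DatasetError(f"{path}:{lineno}: duplicate id {rid!r}")
            labels[rid] = int(lab)
    return labels


def load_dataset_with_labels(
    fasta_path: str | Path,
    table_path: str | Path,
    policy: Policy = "strict",
    redundancy_pruned: bool = False,
) -> DatasetManifest:
    """Build a manifest from one FASTA plus a ``id<TAB>label`` table."""
    records = read_fasta(fasta_path, policy)
    table = read_label_table(table_path)
    labelled: list[ProteinRecord] = []
    for r in records:
        if r.id not in table:
            raise DatasetError(f"record {r.id!r} missing from label table")
        labelled.append(r.with_label(table[r.id]))
    manifest = DatasetManifest(records=labelled, redundancy_pruned=redundancy_pruned)
    manifest.require_labelled()
    return manifest
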