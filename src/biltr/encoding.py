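"""Sequence I/O and one-hot encoding of siRNA sense strands.

An siRNA is a fixed-length (default 19 nt) RNA sequence over {A, C, G, U},
read 5'->3' on the sense strand.  Each sequence is encoded as an n x 4
binary matrix whose row j is the one-hot vector of the base at position j,
with the global column order (A, C, G, U).  DNA-style input is accepted
and 'T' is silently normalised to 'U' (a logged conversion), since public
siRNA datasets use both conventions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Global nucleotide column order for encoding matrices and rows of
#: transformation matrices.  Fixed; every module indexes against it.
BASES = "ACGU"

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: Default sequence length (sense siRNA strands of 19 nt).
DEFAULT_N = 19


class EfficacyLabel(str, Enum):
    """Two-class efficacy label used for semi-supervision."""

    VERY_HIGH = "very_high"
    LOW = "low"


class AlphabetError(ValueError):
    """A sequence contains a character outside {A, C, G, U} (after T->U)."""


class LengthError(ValueError):
    """A sequence does not have the configured length n."""


@dataclass(frozen=True)
class SiRNASequence:
    """An siRNA sense-strand sequence.

    Parameters
    ----------
    id : str
        Record identifier (unique within a file).
    bases : str
        The sequence over {A, C, G, U}; 'T' input is normalised to 'U'
        and lowercase is upcased at construction.
    """

    id: str
    bases: str

    def __post_init__(self) -> None:
        raw = self.bases.upper()
        if "T" in raw:
            logger.debug("sequence %s: converting DNA T to RNA U", self.id)
            raw = raw.replace("T", "U")
        bad = set(raw) - set(BASES)
        if bad:
            raise AlphabetError(
                f"sequence {self.id!r} contains illegal characters "
                f"{sorted(bad)}; alphabet is A/C/G/U (T accepted as U)"
            )
        object.__setattr__(self, "bases", raw)

    def __len__(self) -> int:
        return len(self.bases)

    def validate_length(self, n: int) -> "SiRNASequence":
        if len(self.bases) != n:
            raise LengthError(
                f"sequence {self.id!r} has length {len(self.bases)}, expected {n}"
            )
        return self


@dataclass(frozen=True)
class ScoredRecord:
    """A sequence with a real-valued knockdown efficacy score."""

    sequence: SiRNASequence
    efficacy: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.efficacy):
            raise ValueError(
                f"record {self.sequence.id!r}: efficacy must be finite, "
                f"got {self.efficacy!r}"
            )


@dataclass(frozen=True)
class LabeledRecord:
    """A sequence with a two-class efficacy label ('very_high' or 'low')."""

    sequence: SiRNASequence
    label: EfficacyLabel


def encode_sequence(seq: SiRNASequence, n: int | None = None) -> np.ndarray:
    """One-hot encode a sequence as an n x 4 binary matrix.

    Row j is the one-hot vector of the base at position j+1; columns are
    ordered (A, C, G, U), i.e. A -> (1,0,0,0), C -> (0,1,0,0),
    G -> (0,0,1,0), U -> (0,0,0,1).

    Parameters
    ----------
    seq : SiRNASequence
    n : int, optional
        Expected length; if given, a mismatch raises :class:`LengthError`.

    Returns
    -------
    numpy.ndarray of shape (len(seq), 4), dtype float64
    """
    if n is not None:
        seq.validate_length(n)
    idx = np.fromiter((_BASE_INDEX[b] for b in seq.bases), dtype=np.intp)
    X = np.zeros((len(idx), 4))
    X[np.arange(len(idx)), idx] = 1.0
    return X


def decode_matrix(X: np.ndarray, id: str = "decoded") -> SiRNASequence:
    """Invert :func:`encode_sequence` (each row must be one-hot)."""
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[1] != 4:
        raise ValueError(f"expected an n x 4 matrix, got shape {X.shape}")
    if not (np.all(np.isin(X, (0.0, 1.0))) and np.all(X.sum(axis=1) == 1)):
        raise ValueError("matrix rows are not one-hot")
    bases = "".join(BASES[i] for i in np.argmax(X, axis=1))
    return SiRNASequence(id=id, bases=bases)


def base_indices(seq: SiRNASequence) -> np.ndarray:
    """Integer column indices (0..3 over A,C,G,U) of each position."""
    return np.fromiter((_BASE_INDEX[b] for b in seq.bases), dtype=np.intp)


def _check_unique_ids(seqs: Iterable[SiRNASequence]) -> list[SiRNASequence]:
    out: list[SiRNASequence] = []
    seen: set[str] = set()
    for s in seqs:
        if s.id in seen:
            raise ValueError(f"duplicate sequence id {s.id!r}")
        seen.add(s.id)
        out.append(s)
    return out


def read_sequences(
    path: str | Path, format: str = "fasta", n: int | None = None
) -> list[SiRNASequence]:
    """Read sequences from FASTA or a delimited table.

    Delimited files need a ``sequence`` column and may carry an ``id``
    column; '#' comment lines are skipped.  Order is preserved, DNA 'T' is
    normalised to 'U', and duplicate ids are rejected.

    Parameters
    ----------
    path : path-like
    format : {'fasta', 'delimited'}
    n : int, optional
        If given, every record is validated against this length and the
        error names the offending record.
    """
    path = Path(path)
    if format == "fasta":
        seqs = [
            SiRNASequence(id=rec.id, bases=str(rec.seq))
            for rec in SeqIO.parse(str(path), "fasta")
        ]
    elif format == "delimited":
        df = _read_table(path)
        if "sequence" not in df.columns:
            raise ValueError(f"{path}: delimited sequence file needs a 'sequence' column")
        ids = df["id"] if "id" in df.columns else [f"seq{i + 1}" for i in range(len(df))]
        seqs = [SiRNASequence(id=str(i), bases=str(b)) for i, b in zip(ids, df["sequence"])]
    else:
        raise ValueError(f"unknown sequence format {format!r}")
    seqs = _check_unique_ids(seqs)
    if n is not None:
        for s in seqs:
            s.validate_length(n)
    if not seqs:
        logger.warning("no sequences read from %s", path)
    return seqs


def _read_table(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    try:
        return pd.read_csv(path, sep=sep, comment="#", skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: cannot parse delimited file: {exc}") from exc


def read_scored(path: str | Path, n: int | None = None) -> list[ScoredRecord]:
    """Read a scored set from a delimited file with columns (sequence, score).

    An optional ``id`` column is honoured.  Non-numeric scores raise; an
    empty file returns an empty list with a warning.
    """
    path = Path(path)
    df = _read_table(path)
    if df.empty:
        logger.warning("empty scored file %s", path)
        return []
    for col in ("sequence", "score"):
        if col not in df.columns:
            raise ValueError(f"{path}: scored file needs a {col!r} column")
    records = []
    ids = df["id"] if "id" in df.columns else [f"seq{i + 1}" for i in range(len(df))]
    for row_id, bases, score in zip(ids, df["sequence"], df["score"]):
        try:
            y = float(score)
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"{path}: non-numeric score {score!r} for record {row_id!r}"
            ) from exc
        seq = SiRNASequence(id=str(row_id), bases=str(bases))
        if n is not None:
            seq.validate_length(n)
        records.append(ScoredRecord(sequence=seq, efficacy=y))
    _check_unique_ids(r.sequence for r in records)
    return records


def read_labeled(path: str | Path, n: int | None = None) -> list[LabeledRecord]:
    """Read a labelled set from a delimited file with columns (sequence, label).

    Labels must be 'very_high' or 'low'; anything else (e.g. 'medium') is
    rejected — merging intermediate classes is a preprocessing concern.
    """
    path = Path(path)
    df = _read_table(path)
    if df.empty:
        logger.warning("empty labeled file %s", path)
        return []
    for col in ("sequence", "label"):
        if col not in df.columns:
            raise ValueError(f"{path}: labeled file needs a {col!r} column")
    records = []
    ids = df["id"] if "id" in df.columns else [f"seq{i + 1}" for i in range(len(df))]
    for row_id, bases, label in zip(ids, df["sequence"], df["label"]):
        try:
            lab = EfficacyLabel(str(label))
        except ValueError as exc:
            raise ValueError(
                f"{path}: unknown label {label!r} for record {row_id!r}; "
                f"expected 'very_high' or 'low'"
            ) from exc
        seq = SiRNASequence(id=str(row_id), bases=str(bases))
        if n is not None:
            seq.validate_length(n)
        records.append(LabeledRecord(sequence=seq, label=lab))
    _check_unique_ids(r.sequence for r in records)
    return records
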