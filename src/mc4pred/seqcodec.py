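"""Fixed-length DNA window I/O, validation, and integer encoding.

The predictor operates on 41-nt windows with the candidate cytosine at the
central position (0-based index 20).  Sequences are mapped to integer rows
with the nucleotide code A->0, G->1, C->2, T->3; the encoded matrix is what
the embedding layer of the model consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Nucleotide-to-integer code used throughout the package.
BASE_TO_INT = {"A": 0, "G": 1, "C": 2, "T": 3}
INT_TO_BASE = np.array(["A", "G", "C", "T"])

DEFAULT_WINDOW_LENGTH = 41


class WindowValidationError(ValueError):
    """A DNA window violates a structural invariant (length/alphabet/center)."""


class CodecError(ValueError):
    """Encoded matrix contains symbols outside the {0,1,2,3} code."""


@dataclass
class DnaWindow:
    """A single fixed-length DNA window.

    Parameters
    ----------
    id : str
        Record identifier (FASTA header up to first whitespace).
    sequence : str
        Uppercase DNA string over {A, C, G, T}.
    label : int or None
        1 for a 4mC-positive window, 0 for negative, None if unknown.
    """

    id: str
    sequence: str
    label: int | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def center_index(self) -> int:
        return (len(self.sequence) - 1) // 2

    @property
    def center_base(self) -> str:
        return self.sequence[self.center_index]


@dataclass
class EncodedBatch:
    """Integer-encoded windows: one row per record, one column per position."""

    matrix: np.ndarray
    ids: list[str]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int64)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape[0] != self.matrix.shape[0]:
                raise ValueError("labels must align with matrix rows")

    @property
    def n_records(self) -> int:
        return self.matrix.shape[0]

    @property
    def seq_len(self) -> int:
        return self.matrix.shape[1]


def read_fasta(path: str | Path, label: int | None = None) -> list[DnaWindow]:
    """Read a FASTA file into DnaWindow records, preserving file order.

    Multi-line records are joined; lowercase is uppercased.  No validation
    is applied here — see :func:`validate_window`.  An empty file yields an
    empty list.
    """
    path = Path(path)
    windows = [
        DnaWindow(id=rec.id, sequence=str(rec.seq).upper(), label=label)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    return windows


def write_fasta(windows: Iterable[DnaWindow], path: str | Path) -> Path:
    """Write windows to FASTA, wrapping sequence lines at 60 columns."""
    path = Path(path)
    records = [
        SeqRecord(Seq(w.sequence), id=w.id, description="") for w in windows
    ]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")
    return path


def validate_window(
    w: DnaWindow,
    length: int = DEFAULT_WINDOW_LENGTH,
    strict_center: bool = True,
) -> DnaWindow:
    """Check the window invariants and return the window unchanged.

    Raises
    ------
    WindowValidationError
        If the length differs from ``length``, the sequence contains a
        character outside {A, C, G, T} (N, U, gaps and IUPAC ambiguity
        codes are all rejected), or — with ``strict_center`` — the central
        base is not 'C'.
    """
    if len(w.sequence) != length:
        raise WindowValidationError(
            f"record '{w.id}': length {len(w.sequence)} != required {length}"
        )
    bad = set(w.sequence) - set("ACGT")
    if bad:
        raise WindowValidationError(
            f"record '{w.id}': non-ACGT character(s) {sorted(bad)}"
        )
    if strict_center and w.center_base != "C":
        raise WindowValidationError(
            f"record '{w.id}': center base (index {w.center_index}) is "
            f"'{w.center_base}', expected 'C'"
        )
    return w


def validate_windows(
    windows: Sequence[DnaWindow],
    length: int = DEFAULT_WINDOW_LENGTH,
    strict_center: bool = True,
    skip_invalid: bool = False,
) -> list[DnaWindow]:
    """Validate a batch; with ``skip_invalid`` drop failures with a warning."""
    kept: list[DnaWindow] = []
    n_dropped = 0
    for w in windows:
        try:
            kept.append(validate_window(w, length=length, strict_center=strict_center))
        except WindowValidationError as exc:
            if not skip_invalid:
                raise
            n_dropped += 1
            logger.warning("dropping invalid record: %s", exc)
    if n_dropped:
        logger.warning("dropped %d invalid record(s), kept %d", n_dropped, len(kept))
    return kept


def encode(windows: Sequence[DnaWindow]) -> EncodedBatch:
    """Map windows to an integer matrix (A->0, G->1, C->2, T->3).

    Row order follows input order.  All windows must share one length.
    """
    if not windows:
        return EncodedBatch(matrix=np.empty((0, 0), dtype=np.int64), ids=[])
    lengths = {len(w) for w in windows}
    if len(lengths) != 1:
        raise ValueError(f"windows have unequal lengths: {sorted(lengths)}")
    lut = np.full(128, -1, dtype=np.int64)
    for base, code in BASE_TO_INT.items():
        lut[ord(base)] = code
    rows = []
    for w in windows:
        row = lut[np.frombuffer(w.sequence.encode("ascii"), dtype=np.uint8)]
        if (row < 0).any():
            raise WindowValidationError(
                f"record '{w.id}': contains characters outside ACGT"
            )
        rows.append(row)
    labels = None
    if all(w.label is not None for w in windows):
        labels = np.array([w.label for w in windows], dtype=np.int64)
    return EncodedBatch(matrix=np.stack(rows), ids=[w.id for w in windows], labels=labels)


def decode(batch: EncodedBatch | np.ndarray) -> list[str]:
    """Invert :func:`encode`: integer rows back to DNA strings."""
    matrix = batch.matrix if isinstance(batch, EncodedBatch) else np.asarray(batch)
    if matrix.size and ((matrix < 0) | (matrix > 3)).any():
        raise CodecError("matrix entries must lie in {0,1,2,3}")
    return ["".join(INT_TO_BASE[row]) for row in matrix]
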