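"""Barcode reference handling and the Hamming-distance primitive.

A barcode reference is an ordered set of fixed-length DNA tags (14 bp by
default), each with a unique ID and optionally a condition label. Every
downstream assignment step matches a fixed-length window against these
sequences under a maximum substitution count, so the reference must be
strictly ACGT and length-homogeneous; ambiguity codes are rejected rather
than wildcarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "BarcodeReference",
    "AmbiguityReport",
    "hamming",
    "load_reference",
    "write_reference",
    "validate_reference",
]

_VALID_BASES = frozenset("ACGT")


def hamming(a: str, b: str) -> int:
    """Number of mismatching positions between two equal-length strings.

    Raises ``ValueError`` on unequal lengths: a fixed-length window
    comparison has no meaningful distance between different lengths.
    """
    if len(a) != len(b):
        raise ValueError(f"hamming requires equal lengths, got {len(a)} and {len(b)}")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class BarcodeReference:
    """Ordered collection of equal-length ACGT barcode sequences.

    Order is preserved from the source file so count-table columns are
    reproducible run to run.
    """

    ids: tuple[str, ...]
    sequences: tuple[str, ...]
    labels: tuple[str | None, ...] = ()
    barcode_length: int = 14

    def __post_init__(self):
        if not self.labels:
            object.__setattr__(self, "labels", tuple(None for _ in self.ids))
        if not (len(self.ids) == len(self.sequences) == len(self.labels)):
            raise ValueError("ids, sequences and labels must have equal lengths")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise ValueError(f"duplicate barcode IDs: {dupes}")
        if len(set(self.sequences)) != len(self.sequences):
            dupes = sorted({s for s in self.sequences if self.sequences.count(s) > 1})
            raise ValueError(f"duplicate barcode sequences: {dupes}")
        for bc_id, seq in zip(self.ids, self.sequences):
            if len(seq) != self.barcode_length:
                raise ValueError(
                    f"barcode {bc_id!r} has length {len(seq)}, "
                    f"expected {self.barcode_length}"
                )
            bad = set(seq) - _VALID_BASES
            if bad:
                raise ValueError(
                    f"barcode {bc_id!r} contains non-ACGT characters: {sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(zip(self.ids, self.sequences, self.labels))

    def sequence_matrix(self) -> np.ndarray:
        """(n_barcodes, barcode_length) uint8 matrix of ASCII codes."""
        return np.frombuffer(
            "".join(self.sequences).encode("ascii"), dtype=np.uint8
        ).reshape(len(self.ids), self.barcode_length)

    def index_of(self, bc_id: str) -> int:
        return self.ids.index(bc_id)


def load_reference(path: str | Path, expected_length: int = 14) -> BarcodeReference:
    """Read a barcode reference from FASTA.

    Sequences are upper-cased; wrapped and single-line records are both
    accepted. Any record whose length differs from ``expected_length``, any
    non-ACGT character (including N), and any duplicate ID or sequence is an
    error naming the offending record.
    """
    ids: list[str] = []
    seqs: list[str] = []
    labels: list[str | None] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ValueError(f"{path}: FASTA record with empty ID")
        seq = str(rec.seq).upper()
        if len(seq) != expected_length:
            raise ValueError(
                f"{path}: record {rec.id!r} has length {len(seq)}, "
                f"expected {expected_length}"
            )
        ids.append(rec.id)
        seqs.append(seq)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        labels.append(desc or None)
    if not ids:
        raise ValueError(f"{path}: no FASTA records found")
    return BarcodeReference(
        ids=tuple(ids),
        sequences=tuple(seqs),
        labels=tuple(labels),
        barcode_length=expected_length,
    )


def write_reference(ref: BarcodeReference, path: str | Path) -> None:
    """Write a reference as unwrapped FASTA (one sequence line per record)."""
    with open(path, "w") as fh:
        for bc_id, seq, label in ref:
            header = f">{bc_id}" + (f" {label}" if label else "")
            fh.write(f"{header}\n{seq}\n")


@dataclass
class AmbiguityReport:
    """Pairs of reference barcodes close enough to admit ambiguous queries.

    A query window can sit within ``max_mismatch`` of two references only if
    those references are within ``2 * max_mismatch`` of each other (triangle
    inequality), so the report lists exactly the pairs at distance
    <= 2 * max_mismatch. Empty report <=> every possible query has at most
    one reference within max_mismatch.
    """

    max_mismatch: int
    pairs: list[tuple[str, str, int]] = field(default_factory=list)

    def __bool__(self) -> bool:
        return bool(self.pairs)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("id_a\tid_b\tdistance\n")
            for a, b, d in self.pairs:
                fh.write(f"{a}\t{b}\t{d}\n")


def validate_reference(ref: BarcodeReference, max_mismatch: int) -> AmbiguityReport:
    """Report all reference pairs at Hamming distance <= 2 * max_mismatch."""
    report = AmbiguityReport(max_mismatch=max_mismatch)
    mat = ref.sequence_matrix()
    # pairwise mismatch counts; n is small (tens), O(n^2 L) is fine
    for i in range(len(ref)):
        d = (mat[i + 1:] != mat[i]).sum(axis=1)
        for j_off in np.nonzero(d <= 2 * max_mismatch)[0]:
            j = i + 1 + int(j_off)
            report.pairs.append((ref.ids[i], ref.ids[j], int(d[j_off])))
    return report
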