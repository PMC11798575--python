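"""Amplicon demultiplexing: handle location, barcode assignment, counting.

The amplicon design places a fixed 20-bp PCR handle immediately upstream of
the barcode. Because the forward primer pool carries 0/2/4/6-base frameshift
spacers, the handle can start anywhere within the first few bases of read 1,
so the locator scans start offsets 0..max_search_offset for a window matching
the handle with at most ``max_handle_mismatch`` substitutions and trims
through the first (smallest-offset) hit. The 14 bp immediately after the
handle are then compared to every reference barcode; a read is assigned when
exactly one reference achieves the minimum distance and that distance is
<= ``max_barcode_mismatch`` (default 2).

All matching is substitution-only: the barcode is a fixed-length window, so
indels are excluded by construction. Quality scores are never used.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .reference import BarcodeReference, _VALID_BASES

__all__ = [
    "DEFAULT_HANDLE",
    "DemuxParams",
    "ReadAssignment",
    "CountTable",
    "AbundanceTable",
    "locate_and_trim",
    "assign_barcode",
    "assign_read",
    "assign_reads_batch",
    "count_reads",
    "count_sample",
    "count_samples",
    "normalize",
    "read_fastq",
]

DEFAULT_HANDLE = "CTTCCAACAACCGGAAGTGA"

# read outcome labels
ASSIGNED = "assigned"
NO_HANDLE = "no_handle"
TOO_SHORT = "too_short"
NO_MATCH = "no_match"
AMBIGUOUS = "ambiguous"

OUTCOMES = (ASSIGNED, NO_HANDLE, TOO_SHORT, NO_MATCH, AMBIGUOUS)
QC_COLUMNS = (
    "n_total",
    "n_no_handle",
    "n_too_short",
    "n_no_match",
    "n_ambiguous",
    "n_assigned",
)


@dataclass(frozen=True)
class DemuxParams:
    """Parameters of the trim-and-assign procedure.

    ``min_read_length_after_trim=None`` means "the reference barcode length":
    a trimmed read must at least contain a full barcode window.
    """

    handle: str = DEFAULT_HANDLE
    max_handle_mismatch: int = 1
    max_search_offset: int = 10
    max_barcode_mismatch: int = 2
    min_read_length_after_trim: int | None = None

    def __post_init__(self):
        bad = set(self.handle) - _VALID_BASES
        if bad:
            raise ValueError(f"handle contains non-ACGT characters: {sorted(bad)}")
        for name in ("max_handle_mismatch", "max_search_offset", "max_barcode_mismatch"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if (
            self.min_read_length_after_trim is not None
            and self.min_read_length_after_trim < 0
        ):
            raise ValueError("min_read_length_after_trim must be >= 0")

    def effective_min_length(self, barcode_length: int) -> int:
        base = (
            self.min_read_length_after_trim
            if self.min_read_length_after_trim is not None
            else barcode_length
        )
        # a read that cannot supply a full barcode window is too short to assign
        return max(base, barcode_length)


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    outcome: str
    barcode_id: str | None = None
    distance: int | None = None


def locate_and_trim(read_seq: str, params: DemuxParams) -> tuple[str | None, str]:
    """Find the handle near the read start and trim through it.

    Returns ``(suffix, "ok")`` on success, ``(None, "no_handle")`` if no
    offset in 0..max_search_offset matches the handle within tolerance, and
    ``(None, "too_short")`` if the suffix after the handle is shorter than
    the minimum post-trim length. Offsets are scanned in increasing order so
    the smallest-offset hit wins.
    """
    if not read_seq:
        raise ValueError("read_seq must be non-empty")
    handle = params.handle
    h = len(handle)
    min_len = (
        params.min_read_length_after_trim
        if params.min_read_length_after_trim is not None
        else 0
    )
    for off in range(params.max_search_offset + 1):
        window = read_seq[off:off + h]
        if len(window) < h:
            break
        mism = sum(a != b for a, b in zip(window, handle))
        if mism <= params.max_handle_mismatch:
            suffix = read_seq[off + h:]
            if len(suffix) < min_len:
                return None, TOO_SHORT
            return suffix, "ok"
    return None, NO_HANDLE


def assign_barcode(
    window: str, ref: BarcodeReference, max_mismatch: int
) -> tuple[str, str | None, int | None]:
    """Assign a barcode-length window to the closest reference barcode.

    Returns ``(outcome, barcode_id, distance)``; outcome is ``assigned`` when
    a unique reference achieves the minimum distance and it is within
    ``max_mismatch``, ``ambiguous`` when two or more references tie at a
    within-tolerance minimum, and ``no_match`` otherwise.
    """
    if len(window) != ref.barcode_length:
        raise ValueError(
            f"window length {len(window)} != barcode length {ref.barcode_length}"
        )
    best_d = ref.barcode_length + 1
    best_id: str | None = None
    n_best = 0
    for bc_id, seq in zip(ref.ids, ref.sequences):
        d = sum(a != b for a, b in zip(window, seq))
        if d < best_d:
            best_d, best_id, n_best = d, bc_id, 1
        elif d == best_d:
            n_best += 1
    if best_d > max_mismatch:
        return NO_MATCH, None, None
    if n_best > 1:
        return AMBIGUOUS, None, None
    return ASSIGNED, best_id, best_d


def assign_read(
    read_id: str, read_seq: str, ref: BarcodeReference, params: DemuxParams
) -> ReadAssignment:
    """Scalar trim-then-assign for a single read (reference path)."""
    min_len = params.effective_min_length(ref.barcode_length)
    eff = replace(params, min_read_length_after_trim=min_len)
    suffix, status = locate_and_trim(read_seq, eff)
    if status != "ok":
        return ReadAssignment(read_id, status)
    outcome, bc_id, dist = assign_barcode(
        suffix[: ref.barcode_length], ref, params.max_barcode_mismatch
    )
    return ReadAssignment(read_id, outcome, bc_id, dist)


def _encode_reads(seqs: Sequence[str], width: int) -> tuple[np.ndarray, np.ndarray]:
    """Pack reads into a zero-padded uint8 matrix plus a length vector."""
    n = len(seqs)
    arr = np.zeros((n, width), dtype=np.uint8)
    lens = np.empty(n, dtype=np.int64)
    for i, s in enumerate(seqs):
        b = s.encode("ascii")
        lens[i] = len(b)
        arr[i, : len(b)] = np.frombuffer(b, dtype=np.uint8)
    return arr, lens


def assign_reads_batch(
    seqs: Sequence[str], ref: BarcodeReference, params: DemuxParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized trim-and-assign over a batch of read sequences.

    Returns ``(outcome_codes, barcode_index, distance)`` arrays; outcome
    codes index into :data:`OUTCOMES`, barcode_index is -1 and distance -1
    wherever the read is not assigned. Semantically identical to mapping
    :func:`assign_read` over the batch.
    """
    h = len(params.handle)
    L = ref.barcode_length
    min_len = params.effective_min_length(L)
    width = max((max((len(s) for s in seqs), default=0)),
                params.max_search_offset + h + L)
    arr, lens = _encode_reads(seqs, width)
    n = len(seqs)

    handle_arr = np.frombuffer(params.handle.encode("ascii"), dtype=np.uint8)
    found = np.zeros(n, dtype=bool)
    offset = np.full(n, -1, dtype=np.int64)
    for off in range(params.max_search_offset + 1):
        cand = (~found) & (lens >= off + h)
        if not cand.any():
            continue
        mism = (arr[:, off:off + h] != handle_arr).sum(axis=1)
        hit = cand & (mism <= params.max_handle_mismatch)
        offset[hit] = off
        found |= hit

    outcome = np.full(n, OUTCOMES.index(NO_HANDLE), dtype=np.int8)
    bc_index = np.full(n, -1, dtype=np.int64)
    distance = np.full(n, -1, dtype=np.int64)

    start = offset + h
    too_short = found & (lens - start < min_len)
    outcome[too_short] = OUTCOMES.index(TOO_SHORT)

    ok = found & ~too_short
    idx = np.nonzero(ok)[0]
    if idx.size:
        cols = start[idx, None] + np.arange(L)
        windows = arr[idx[:, None], cols]  # (m, L)
        ref_mat = ref.sequence_matrix()  # (k, L)
        dists = (windows[:, None, :] != ref_mat[None, :, :]).sum(axis=2)  # (m, k)
        min_d = dists.min(axis=1)
        n_min = (dists == min_d[:, None]).sum(axis=1)
        within = min_d <= params.max_barcode_mismatch
        amb = within & (n_min > 1)
        hit = within & (n_min == 1)
        sub = np.full(idx.size, OUTCOMES.index(NO_MATCH), dtype=np.int8)
        sub[amb] = OUTCOMES.index(AMBIGUOUS)
        sub[hit] = OUTCOMES.index(ASSIGNED)
        outcome[idx] = sub
        bc_index[idx[hit]] = dists[hit].argmin(axis=1)
        distance[idx[hit]] = min_d[hit]
    return outcome, bc_index, distance


def read_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from a FASTQ file, gzipped or plain.

    Malformed records raise ``ValueError`` naming the 0-based record index.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        it = FastqGeneralIterator(fh)
        i = 0
        while True:
            try:
                item = next(it, None)
            except ValueError as exc:
                raise ValueError(f"{path}: malformed FASTQ record {i}: {exc}") from exc
            if item is None:
                return
            title, seq, qual = item
            if len(seq) != len(qual):
                raise ValueError(
                    f"{path}: malformed FASTQ record {i}: sequence and quality "
                    f"lengths differ ({len(seq)} vs {len(qual)})"
                )
            yield title.split()[0], seq.upper()
            i += 1


@dataclass
class CountTable:
    """Per-sample barcode read counts plus per-sample QC tallies.

    ``counts`` is samples x barcodes (integers); ``qc`` has the outcome
    tallies with the invariant n_total = n_assigned + n_no_handle +
    n_too_short + n_no_match + n_ambiguous and n_assigned = row sum.
    """

    counts: pd.DataFrame
    qc: pd.DataFrame

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if list(self.counts.index) != list(self.qc.index):
            raise ValueError("counts and qc must share the sample axis")
        row_sums = self.counts.sum(axis=1)
        if not (row_sums == self.qc["n_assigned"]).all():
            raise ValueError("n_assigned must equal the counts row sum")
        parts = self.qc[list(QC_COLUMNS[1:])].sum(axis=1)
        if not (parts == self.qc["n_total"]).all():
            raise ValueError("QC outcome tallies must sum to n_total")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def barcodes(self) -> list[str]:
        return list(self.counts.columns)

    def write(self, counts_path: str | Path, qc_path: str | Path | None = None) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="sample")
        if qc_path is not None:
            self.qc.to_csv(qc_path, sep="\t", index_label="sample")

    @classmethod
    def read(cls, counts_path: str | Path, qc_path: str | Path) -> "CountTable":
        counts = pd.read_csv(counts_path, sep="\t", index_col="sample")
        qc = pd.read_csv(qc_path, sep="\t", index_col="sample")
        return cls(counts=counts.astype(np.int64), qc=qc.astype(np.int64))


@dataclass
class AbundanceTable:
    """Per-sample barcode fractions; rows sum to 1 unless flagged empty."""

    fractions: pd.DataFrame
    empty_samples: list[str] = field(default_factory=list)

    @property
    def samples(self) -> list[str]:
        return list(self.fractions.index)

    @property
    def barcodes(self) -> list[str]:
        return list(self.fractions.columns)

    def write(self, path: str | Path) -> None:
        self.fractions.to_csv(path, sep="\t", index_label="sample")

    @classmethod
    def read(cls, path: str | Path) -> "AbundanceTable":
        frac = pd.read_csv(path, sep="\t", index_col="sample")
        empty = [s for s, row in frac.iterrows() if (row == 0).all()]
        return cls(fractions=frac, empty_samples=empty)


def count_reads(
    reads: Iterable[tuple[str, str]],
    ref: BarcodeReference,
    params: DemuxParams | None = None,
    keep_log: bool = False,
    chunk_size: int = 100_000,
) -> tuple[np.ndarray, dict[str, int], list[ReadAssignment] | None]:
    """Count barcode assignments over a stream of (read_id, sequence).

    Returns (per-barcode count vector, QC tally dict, optional per-read log).
    """
    params = params or DemuxParams()
    counts = np.zeros(len(ref), dtype=np.int64)
    qc = {c: 0 for c in QC_COLUMNS}
    log: list[ReadAssignment] | None = [] if keep_log else None

    ids_buf: list[str] = []
    seq_buf: list[str] = []

    def flush():
        if not seq_buf:
            return
        outcome, bc_idx, dist = assign_reads_batch(seq_buf, ref, params)
        qc["n_total"] += len(seq_buf)
        for code, name in enumerate(OUTCOMES):
            qc[f"n_{name}"] += int((outcome == code).sum())
        assigned = bc_idx >= 0
        if assigned.any():
            counts[:] += np.bincount(bc_idx[assigned], minlength=len(ref))
        if log is not None:
            for rid, code, bi, d in zip(ids_buf, outcome, bc_idx, dist):
                name = OUTCOMES[code]
                log.append(
                    ReadAssignment(
                        rid,
                        name,
                        ref.ids[bi] if bi >= 0 else None,
                        int(d) if bi >= 0 else None,
                    )
                )
        ids_buf.clear()
        seq_buf.clear()

    for rid, seq in reads:
        ids_buf.append(rid)
        seq_buf.append(seq)
        if len(seq_buf) >= chunk_size:
            flush()
    flush()
    return counts, qc, log


def count_sample(
    fastq: str | Path,
    ref: BarcodeReference,
    params: DemuxParams | None = None,
    sample_id: str | None = None,
    keep_log: bool = False,
) -> tuple[pd.Series, dict[str, int], list[ReadAssignment] | None]:
    """Demultiplex one FASTQ file into a per-barcode count row plus QC."""
    fastq = Path(fastq)
    if sample_id is None:
        sample_id = fastq.name.removesuffix(".gz").rsplit(".", 1)[0]
    counts, qc, log = count_reads(read_fastq(fastq), ref, params, keep_log=keep_log)
    return pd.Series(counts, index=list(ref.ids), name=sample_id), qc, log


def count_samples(
    fastqs: Sequence[tuple[str, str | Path]] | Sequence[str | Path],
    ref: BarcodeReference,
    params: DemuxParams | None = None,
) -> CountTable:
    """Demultiplex several FASTQ files into one CountTable.

    ``fastqs`` is either a list of paths (sample IDs from file stems) or a
    list of (sample_id, path) pairs.
    """
    rows, qcs, sample_ids = [], [], []
    for item in fastqs:
        if isinstance(item, (tuple, list)):
            sid, path = item
        else:
            sid, path = None, item
        row, qc, _ = count_sample(path, ref, params, sample_id=sid)
        rows.append(row)
        qcs.append(qc)
        sample_ids.append(row.name)
    counts = pd.DataFrame(rows, index=sample_ids)
    qc_df = pd.DataFrame(qcs, index=sample_ids)[list(QC_COLUMNS)]
    return CountTable(counts=counts, qc=qc_df)


def normalize(table: CountTable) -> AbundanceTable:
    """Convert counts to per-sample fractions of assigned reads.

    The denominator is assigned reads (unassigned reads carry no barcode
    information); samples with zero assigned reads get an all-zero row and
    are flagged in ``empty_samples``.
    """
    assigned = table.qc["n_assigned"].astype(float)
    denom = assigned.replace(0, np.nan)
    frac = table.counts.div(denom, axis=0).fillna(0.0)
    empty = list(assigned.index[assigned == 0])
    return AbundanceTable(fractions=frac, empty_samples=empty)
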