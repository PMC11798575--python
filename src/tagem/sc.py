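"""Barcode-to-cell assignment for multiplexed droplet scRNA-seq.

Each barcoded genotype expresses a deterministic tag transcript, so a cell's
genotype can be read from two evidence sources:

* the gene-expression (GE) matrix, where tags appear as added features; and
* an enriched amplicon library of (cell barcode, UMI, tag read) molecules.

Enriched records are deduplicated per (cell, UMI); UMIs whose records
disagree on the tag are resolved by majority (ties dropped) to suppress PCR
chimeras. Per-cell *purity* — the fraction of tag UMIs belonging to the most
abundant tag — gates enriched-based calls at a strict > 0.75 threshold.
Final calls give GE priority: a cell with a single tag detected directly in
GE keeps that call regardless of the enriched evidence; cells with two or
more GE tags are barcode-co-expression doublets.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread

from .demux import DemuxParams, assign_reads_batch, read_fastq
from .reference import BarcodeReference

__all__ = [
    "EnrichedRecord",
    "CellTagCounts",
    "OverlapStats",
    "MULTI",
    "read_enriched_tsv",
    "read_enriched_fastq",
    "count_enriched",
    "extract_ge_tag_counts",
    "load_mtx_dir",
    "purity",
    "call_cells",
    "detect_tag_doublets",
    "overlap_stats",
    "detection_fraction",
    "purity_concordance_curve",
]

MULTI = "multi"  # sentinel GE call for cells co-expressing >= 2 tags


class EnrichedRecord(NamedTuple):
    cell_barcode: str
    umi: str
    tag_read: str


@dataclass
class CellTagCounts:
    """Sparse per-cell, per-tag deduplicated UMI counts from one source."""

    source: str  # "GE" or "enriched"
    cells: list[str]
    tags: list[str]
    matrix: sparse.csr_matrix  # cells x tags, non-negative integers

    def __post_init__(self):
        if len(set(self.cells)) != len(self.cells):
            raise ValueError("cell IDs must be unique")
        self.matrix = sparse.csr_matrix(self.matrix)
        if self.matrix.shape != (len(self.cells), len(self.tags)):
            raise ValueError("matrix shape must be (n_cells, n_tags)")
        if (self.matrix.data < 0).any():
            raise ValueError("counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix.toarray(), index=self.cells, columns=self.tags
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="cell")

    @classmethod
    def read(cls, path: str | Path, source: str) -> "CellTagCounts":
        df = pd.read_csv(path, sep="\t", index_col="cell")
        return cls(
            source=source,
            cells=list(df.index),
            tags=list(df.columns),
            matrix=sparse.csr_matrix(df.to_numpy()),
        )


def read_enriched_tsv(path: str | Path) -> Iterator[EnrichedRecord]:
    """Stream (cell_barcode, umi, tag_read) records from a 3-column TSV."""
    with open(path) as fh:
        first = True
        for i, line in enumerate(fh):
            fields = line.rstrip("\n").split("\t")
            if first and fields[:2] == ["cell_barcode", "umi"]:
                first = False
                continue
            first = False
            if len(fields) != 3:
                raise ValueError(f"{path}: line {i} has {len(fields)} fields, expected 3")
            yield EnrichedRecord(*fields)


def read_enriched_fastq(
    read1: str | Path,
    read2: str | Path,
    cell_barcode_length: int = 16,
    umi_length: int = 12,
) -> Iterator[EnrichedRecord]:
    """Stream enriched records from a paired FASTQ in the droplet 3' layout.

    Read 1 carries cell barcode then UMI; read 2 is the tag read.
    """
    for (id1, seq1), (id2, seq2) in zip(read_fastq(read1), read_fastq(read2)):
        if len(seq1) < cell_barcode_length + umi_length:
            raise ValueError(
                f"read 1 record {id1!r} shorter than cell barcode + UMI "
                f"({cell_barcode_length}+{umi_length})"
            )
        yield EnrichedRecord(
            seq1[:cell_barcode_length],
            seq1[cell_barcode_length:cell_barcode_length + umi_length],
            seq2,
        )


def count_enriched(
    records: Iterable[EnrichedRecord],
    ref: BarcodeReference,
    whitelist: set[str] | None = None,
    max_mismatch: int = 2,
    params: DemuxParams | None = None,
) -> tuple[CellTagCounts, dict[str, int]]:
    """Deduplicate enriched records into per-cell unique-UMI tag counts.

    Tag reads go through the same handle-trim / <=max_mismatch assignment as
    amplicon reads. Records with N in the cell barcode or UMI, off-whitelist
    cells, and unassignable tag reads are dropped and tallied. Each
    (cell, UMI) pair contributes at most one count: if its records disagree
    on the tag, the majority tag wins and ties are dropped.
    """
    if params is None:
        params = DemuxParams(max_barcode_mismatch=max_mismatch)
    qc = {
        "n_records": 0,
        "n_cell_umi_with_N": 0,
        "n_off_whitelist": 0,
        "n_tag_unassigned": 0,
        "n_umi_tag_ties": 0,
        "n_umis_counted": 0,
    }
    cb_len: int | None = None
    umi_len: int | None = None

    kept_keys: list[tuple[str, str]] = []
    kept_reads: list[str] = []
    for rec in records:
        qc["n_records"] += 1
        if cb_len is None:
            cb_len, umi_len = len(rec.cell_barcode), len(rec.umi)
        elif len(rec.cell_barcode) != cb_len or len(rec.umi) != umi_len:
            raise ValueError(
                f"inconsistent field lengths at record {qc['n_records'] - 1}: "
                f"cell {len(rec.cell_barcode)} (expected {cb_len}), "
                f"umi {len(rec.umi)} (expected {umi_len})"
            )
        if "N" in rec.cell_barcode or "N" in rec.umi:
            qc["n_cell_umi_with_N"] += 1
            continue
        if whitelist is not None and rec.cell_barcode not in whitelist:
            qc["n_off_whitelist"] += 1
            continue
        kept_keys.append((rec.cell_barcode, rec.umi))
        kept_reads.append(rec.tag_read)

    outcome, bc_idx, _ = (
        assign_reads_batch(kept_reads, ref, params)
        if kept_reads
        else (np.empty(0, np.int8), np.empty(0, np.int64), np.empty(0, np.int64))
    )

    per_umi: dict[tuple[str, str], Counter] = {}
    for key, bi in zip(kept_keys, bc_idx):
        if bi < 0:
            qc["n_tag_unassigned"] += 1
            continue
        per_umi.setdefault(key, Counter())[int(bi)] += 1

    cell_order: dict[str, int] = {}
    triplets: dict[tuple[int, int], int] = {}
    for (cell, _umi), tag_votes in per_umi.items():
        top = tag_votes.most_common()
        if len(top) > 1 and top[0][1] == top[1][1]:
            qc["n_umi_tag_ties"] += 1
            continue
        tag_i = top[0][0]
        ci = cell_order.setdefault(cell, len(cell_order))
        triplets[(ci, tag_i)] = triplets.get((ci, tag_i), 0) + 1
        qc["n_umis_counted"] += 1

    cells = list(cell_order)
    if triplets:
        rows, cols = zip(*triplets)
        data = [triplets[k] for k in triplets]
        mat = sparse.coo_matrix(
            (data, (rows, cols)), shape=(len(cells), len(ref))
        ).tocsr()
    else:
        mat = sparse.csr_matrix((0, len(ref)), dtype=np.int64)
    return (
        CellTagCounts(source="enriched", cells=cells, tags=list(ref.ids), matrix=mat),
        qc,
    )


def extract_ge_tag_counts(
    matrix: sparse.spmatrix | np.ndarray,
    feature_ids: Sequence[str],
    cell_ids: Sequence[str],
    tag_feature_ids: Sequence[str],
) -> CellTagCounts:
    """Slice the tag-feature columns out of a cell x feature count matrix.

    Cells are retained even when all their tag counts are zero; a tag
    feature absent from the matrix is an error naming it.
    """
    index = {f: i for i, f in enumerate(feature_ids)}
    missing = [t for t in tag_feature_ids if t not in index]
    if missing:
        raise ValueError(f"tag features not present in matrix: {missing}")
    cols = [index[t] for t in tag_feature_ids]
    mat = sparse.csr_matrix(matrix)[:, cols]
    return CellTagCounts(
        source="GE", cells=list(cell_ids), tags=list(tag_feature_ids), matrix=mat
    )


def load_mtx_dir(path: str | Path) -> tuple[sparse.csr_matrix, list[str], list[str]]:
    """Load the MTX trio (matrix.mtx, features.tsv, barcodes.tsv).

    The matrix on disk is features x cells (the droplet-pipeline layout);
    the returned matrix is transposed to cells x features.
    """
    path = Path(path)
    mat = sparse.csr_matrix(mmread(path / "matrix.mtx")).T.tocsr()
    features = [
        line.split("\t")[0].strip()
        for line in (path / "features.tsv").read_text().splitlines()
        if line.strip()
    ]
    cells = [
        line.strip() for line in (path / "barcodes.tsv").read_text().splitlines()
        if line.strip()
    ]
    if mat.shape != (len(cells), len(features)):
        raise ValueError(
            f"{path}: matrix shape {mat.shape} does not match "
            f"{len(cells)} barcodes x {len(features)} features"
        )
    return mat, features, cells


def purity(cell_counts: Mapping[str, int] | pd.Series) -> tuple[float | None, str | None]:
    """Purity of tag detection for one cell: top-tag UMIs / total tag UMIs.

    Returns (purity, top_tag); purity is None for a cell with no tag UMIs,
    and the top tag is None on a tie for the maximum (the purity value is
    still reported).
    """
    items = list(cell_counts.items())
    total = sum(c for _, c in items)
    if total <= 0:
        return None, None
    top = max(c for _, c in items)
    winners = [t for t, c in items if c == top]
    return top / total, winners[0] if len(winners) == 1 else None


def call_cells(
    ge: CellTagCounts,
    enriched: CellTagCounts,
    purity_threshold: float = 0.75,
    ge_min_count: int = 1,
) -> pd.DataFrame:
    """Merge GE and enriched evidence into final per-cell barcode calls.

    Per cell: ``ge_call`` is the unique tag with GE count >= ge_min_count
    (None if no tag, "multi" if two or more — the cell is a barcode
    doublet); ``enriched_call`` is the enriched top tag iff purity is
    strictly above the threshold and the top tag is unambiguous. The final
    call is the GE call when it is a single tag (GE priority on conflicts),
    otherwise the enriched call, otherwise None.

    The cell axis is the outer union, GE cells first; ``in_ge`` marks cells
    present in the GE matrix (detection denominators are restricted to
    them, since cell QC happens on the expression side).
    """
    cells = list(ge.cells) + [c for c in enriched.cells if c not in set(ge.cells)]
    ge_df = ge.to_frame()
    enr_df = enriched.to_frame()
    ge_cells = set(ge.cells)

    rows = []
    for cell in cells:
        ge_call: str | None = None
        if cell in ge_cells:
            row = ge_df.loc[cell]
            hits = list(row.index[row >= ge_min_count])
            if len(hits) == 1:
                ge_call = hits[0]
            elif len(hits) >= 2:
                ge_call = MULTI
        pur: float | None = None
        top: str | None = None
        if cell in enr_df.index:
            pur, top = purity(enr_df.loc[cell])
        enr_call = top if (pur is not None and pur > purity_threshold) else None
        if ge_call is not None and ge_call != MULTI:
            final, source = ge_call, "GE"
        elif enr_call is not None:
            final, source = enr_call, "enriched"
        else:
            final, source = None, "none"
        rows.append(
            {
                "ge_call": ge_call,
                "enriched_top": top,
                "purity": np.nan if pur is None else pur,
                "enriched_call": enr_call,
                "final_call": final,
                "doublet_flag": ge_call == MULTI,
                "source_of_final": source,
                "in_ge": cell in ge_cells,
            }
        )
    out = pd.DataFrame(rows, index=pd.Index(cells, name="cell"))
    return out


def detect_tag_doublets(ge: CellTagCounts, min_count: int = 1) -> set[str]:
    """Cells co-expressing >= 2 tags at >= min_count in the GE matrix."""
    mat = ge.matrix
    n_tags = np.asarray((mat >= min_count).sum(axis=1)).ravel() if min_count > 0 else \
        np.full(mat.shape[0], mat.shape[1])
    return {c for c, k in zip(ge.cells, n_tags) if k >= 2}


@dataclass(frozen=True)
class OverlapStats:
    n_a: int
    n_b: int
    n_overlap: int
    pct_a_in_b: float | None  # 100 * |a ∩ b| / |a|, None when a is empty
    pct_b_in_a: float | None


def overlap_stats(set_a: Iterable[str], set_b: Iterable[str]) -> OverlapStats:
    """Overlap between two cell-ID sets, e.g. barcode doublets vs an
    external doublet caller's multiplets."""
    a, b = set(set_a), set(set_b)
    inter = len(a & b)
    return OverlapStats(
        n_a=len(a),
        n_b=len(b),
        n_overlap=inter,
        pct_a_in_b=100.0 * inter / len(a) if a else None,
        pct_b_in_a=100.0 * inter / len(b) if b else None,
    )


def detection_fraction(calls: pd.DataFrame, subset: str = "combined") -> float:
    """Fraction of (GE-matrix) cells with a barcode call.

    ``subset``: "GE_only" counts cells with a single-tag GE call,
    "enriched_only" cells with an enriched call (purity-gated top tag),
    "combined" cells with any final call.
    """
    denom_cells = calls[calls["in_ge"]] if "in_ge" in calls else calls
    if len(denom_cells) == 0:
        raise ValueError("no cells in the call table")
    if subset == "GE_only":
        hit = denom_cells["ge_call"].notna() & (denom_cells["ge_call"] != MULTI)
    elif subset == "enriched_only":
        hit = denom_cells["enriched_call"].notna()
    elif subset == "combined":
        hit = denom_cells["final_call"].notna()
    else:
        raise ValueError(f"unknown subset {subset!r}")
    return float(hit.sum() / len(denom_cells))


def purity_concordance_curve(
    ge: CellTagCounts,
    enriched: CellTagCounts,
    purity_bins: Sequence[float],
) -> pd.DataFrame:
    """GE/enriched tag concordance as a function of enriched purity.

    Eligible cells have a single-tag GE call and a defined enriched top tag;
    they are bucketed by purity into right-closed bins over ``purity_bins``
    edges (which must be increasing and cover (0, 1]). Concordance per
    bucket is the fraction whose GE and enriched top tags agree; empty
    buckets are flagged.
    """
    edges = list(purity_bins)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("purity bin edges must be strictly increasing")
    if edges[0] > 0 or edges[-1] < 1:
        raise ValueError("purity bins must cover (0, 1]")
    calls = call_cells(ge, enriched, purity_threshold=-1.0)  # no gating here
    elig = calls[
        calls["ge_call"].notna()
        & (calls["ge_call"] != MULTI)
        & calls["enriched_top"].notna()
        & calls["purity"].notna()
    ]
    agree = elig["ge_call"] == elig["enriched_top"]
    buckets = pd.cut(elig["purity"], bins=edges, right=True, include_lowest=False)
    out = []
    for interval in buckets.cat.categories:
        mask = buckets == interval
        n = int(mask.sum())
        out.append(
            {
                "bin_low": interval.left,
                "bin_high": interval.right,
                "n_cells": n,
                "concordance": float(agree[mask].mean()) if n else np.nan,
                "empty": n == 0,
            }
        )
    return pd.DataFrame(out)
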