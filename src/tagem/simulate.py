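"""Synthetic data generators with known ground truth.

Every downstream analysis in this package can be exercised end to end on
simulated data: amplicon pools (structured even or staggered pools, with
frameshift spacers, per-base substitution error and PCR chimerism),
phototaxis experiments (true preference indices realized as binomial tube
choices, then reads per tube), multiplexed single-cell tag evidence (GE tag
features plus an enriched UMI library with ambient and chimeric noise), and
gut-transit timepoint tables.

All generators are driven by ``numpy.random.default_rng(seed)`` and are
byte-reproducible for a fixed seed. The error model is substitution-only:
the assignment procedure compares fixed-length windows, so substitutions
(sequencing error, PCR error) and template-switching chimeras are the error
channels that matter; indels are not modeled.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmwrite

from .demux import DEFAULT_HANDLE, CountTable
from .reference import BarcodeReference, hamming

__all__ = [
    "SPACERS",
    "SV40_CONTEXT",
    "AmpliconSimConfig",
    "ScSimConfig",
    "AmpliconSim",
    "PhototaxisSim",
    "ScSim",
    "TransitSim",
    "random_reference",
    "sim_amplicon",
    "sim_phototaxis",
    "sim_sc",
    "sim_transit",
    "write_fastq",
    "write_mtx_dir",
]

# frameshifting bases of the forward primer pool, keyed by spacer length
SPACERS = {0: "", 2: "AG", 4: "TCGA", 6: "GAAGAG"}

# 30 bases of fixed downstream context on the SV40 side of the barcode
SV40_CONTEXT = "TGGTTACAAATAAAGCAATAGCATCACAAA"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return bytes(rng.choice(_BASES, size=length)).decode("ascii")


def random_reference(
    n: int,
    barcode_length: int = 14,
    min_distance: int = 5,
    seed: int = 0,
    ids: Sequence[str] | None = None,
) -> BarcodeReference:
    """Generate a random barcode reference with a minimum pairwise distance.

    ``min_distance=5`` guarantees unambiguous assignment under the default
    <=2-mismatch rule (no window can lie within 2 of two barcodes).
    """
    rng = np.random.default_rng(seed)
    seqs: list[str] = []
    attempts = 0
    while len(seqs) < n:
        cand = _random_seq(rng, barcode_length)
        if all(hamming(cand, s) >= min_distance for s in seqs):
            seqs.append(cand)
        attempts += 1
        if attempts > 1000 * n:
            raise RuntimeError(
                f"could not place {n} barcodes at pairwise distance "
                f">= {min_distance}"
            )
    if ids is None:
        ids = [f"BC{i + 1:02d}" for i in range(n)]
    return BarcodeReference(
        ids=tuple(ids), sequences=tuple(seqs), barcode_length=barcode_length
    )


@dataclass
class AmpliconSimConfig:
    """Configuration of one simulated amplicon pool."""

    reference: BarcodeReference
    pool: Mapping[str, float]          # barcode_id -> true fraction, sums to 1
    depth: int
    per_base_error: float = 0.0
    spacer_mix: Mapping[int, float] | None = None  # default uniform over 0/2/4/6
    chimera_rate: float = 0.0
    seed: int = 0
    exact_allocation: bool = False
    handle: str = DEFAULT_HANDLE

    def __post_init__(self):
        total = sum(self.pool.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"pool fractions must sum to 1, got {total}")
        unknown = set(self.pool) - set(self.reference.ids)
        if unknown:
            raise ValueError(f"pool barcodes not in reference: {sorted(unknown)}")
        for name in ("per_base_error", "chimera_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.spacer_mix is None:
            self.spacer_mix = {k: 0.25 for k in SPACERS}
        if set(self.spacer_mix) - set(SPACERS):
            raise ValueError(f"spacer lengths must be among {sorted(SPACERS)}")


@dataclass
class AmpliconSim:
    """Simulated amplicon reads plus per-read ground truth."""

    reads: list[tuple[str, str]]       # (read_id, sequence)
    truth: pd.DataFrame                # read_id, template_barcode, emitted_barcode, spacer
    pool: dict[str, float]

    def write_fastq(self, path: str | Path, gz: bool = False) -> None:
        write_fastq(self.reads, path, gz=gz)


def _largest_remainder(fracs: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation proportional to fractions, summing exactly to total."""
    raw = fracs * total
    base = np.floor(raw).astype(np.int64)
    short = total - base.sum()
    if short > 0:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:short]] += 1
    return base


def _apply_substitutions(
    seqs: np.ndarray, rng: np.random.Generator, rate: float
) -> np.ndarray:
    """I.i.d. per-base substitutions on a uint8 sequence matrix (in place)."""
    if rate <= 0:
        return seqs
    mask = rng.random(seqs.shape) < rate
    n = int(mask.sum())
    if n:
        # replace with a uniformly chosen *different* base
        shift = rng.integers(1, 4, size=n)
        orig = seqs[mask]
        idx = np.searchsorted(_BASES, orig)  # _BASES is sorted (A<C<G<T)
        seqs[mask] = _BASES[(idx + shift) % 4]
    return seqs


def sim_amplicon(config: AmpliconSimConfig) -> AmpliconSim:
    """Simulate one pool's amplicon reads.

    Each read is spacer + handle + 14-mer + 30 bases of SV40-side context,
    with i.i.d. substitution errors over the whole read. With probability
    ``chimera_rate`` the barcode window is resampled from the pool
    distribution independent of the read's template (template switching);
    the truth table records both the template and the emitted barcode.
    """
    rng = np.random.default_rng(config.seed)
    bc_ids = [b for b in config.reference.ids if b in config.pool]
    fracs = np.array([config.pool[b] for b in bc_ids], dtype=float)
    fracs = fracs / fracs.sum()

    if config.exact_allocation:
        alloc = _largest_remainder(fracs, config.depth)
    else:
        alloc = rng.multinomial(config.depth, fracs)
    template_idx = np.repeat(np.arange(len(bc_ids)), alloc)
    rng.shuffle(template_idx)

    n = config.depth
    emitted_idx = template_idx.copy()
    chim = rng.random(n) < config.chimera_rate
    if chim.any():
        emitted_idx[chim] = rng.choice(len(bc_ids), size=int(chim.sum()), p=fracs)

    spacer_lens = np.array(sorted(config.spacer_mix), dtype=np.int64)
    spacer_p = np.array([config.spacer_mix[k] for k in spacer_lens], dtype=float)
    spacer_p = spacer_p / spacer_p.sum()
    spacer_choice = rng.choice(len(spacer_lens), size=n, p=spacer_p)

    seq_by_idx = {i: config.reference.sequences[config.reference.index_of(b)]
                  for i, b in enumerate(bc_ids)}
    reads: list[tuple[str, str]] = []
    truth_rows = []
    # build per-spacer batches so each batch is a fixed-width uint8 matrix
    for si, slen in enumerate(spacer_lens):
        sel = np.nonzero(spacer_choice == si)[0]
        if sel.size == 0:
            continue
        prefix = SPACERS[int(slen)] + config.handle
        bodies = [
            prefix + seq_by_idx[int(emitted_idx[i])] + SV40_CONTEXT for i in sel
        ]
        mat = np.frombuffer(
            "".join(bodies).encode("ascii"), dtype=np.uint8
        ).reshape(len(bodies), -1).copy()
        _apply_substitutions(mat, rng, config.per_base_error)
        for row, i in zip(mat, sel):
            rid = f"read_{i}"
            reads.append((rid, row.tobytes().decode("ascii")))
            truth_rows.append(
                (
                    rid,
                    bc_ids[int(template_idx[i])],
                    bc_ids[int(emitted_idx[i])],
                    int(slen),
                )
            )
    # restore read order (read_0, read_1, ...) for reproducible files
    order = np.argsort([int(r[0].split("_")[1]) for r in reads], kind="stable")
    reads = [reads[i] for i in order]
    truth = pd.DataFrame(
        [truth_rows[i] for i in order],
        columns=["read_id", "template_barcode", "emitted_barcode", "spacer"],
    )
    return AmpliconSim(reads=reads, truth=truth, pool=dict(zip(bc_ids, fracs)))


def write_fastq(
    reads: Sequence[tuple[str, str]], path: str | Path, gz: bool = False
) -> None:
    """Write (read_id, sequence) pairs as FASTQ with constant quality."""
    opener = gzip.open if gz else open
    with opener(path, "wt") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


@dataclass
class PhototaxisSim:
    """One simulated phototaxis run: realized tubes, reads, and truth."""

    reference: BarcodeReference
    light_reads: list[tuple[str, str]]
    dark_reads: list[tuple[str, str]]
    n_light: dict[str, int]            # genotype -> flies in the light tube
    n_dark: dict[str, int]
    true_pi: dict[str, float]

    @property
    def tube_flies(self) -> dict[str, int]:
        return {
            "light": sum(self.n_light.values()),
            "dark": sum(self.n_dark.values()),
        }

    def realized_pi(self) -> dict[str, float]:
        return {
            g: (self.n_light[g] - self.n_dark[g])
            / (self.n_light[g] + self.n_dark[g])
            for g in self.true_pi
        }


def sim_phototaxis(
    true_pi: Mapping[str, float],
    n_flies_per_genotype: int,
    depth: int,
    per_base_error: float = 0.0,
    chimera_rate: float = 0.0,
    seed: int = 0,
    reference: BarcodeReference | None = None,
) -> PhototaxisSim:
    """Simulate a pooled phototaxis assay with one barcode per genotype.

    Each fly independently enters the light tube with probability
    (1 + pi) / 2; reads are then simulated per tube from the realized fly
    composition. Barcode IDs equal genotype names.
    """
    for g, pi in true_pi.items():
        if not -1 <= pi <= 1:
            raise ValueError(f"true P.I. for {g!r} must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    genotypes = list(true_pi)
    if reference is None:
        reference = random_reference(
            len(genotypes), seed=int(rng.integers(2**31)), ids=genotypes
        )
    n_light = {
        g: int(rng.binomial(n_flies_per_genotype, (1 + true_pi[g]) / 2))
        for g in genotypes
    }
    n_dark = {g: n_flies_per_genotype - n_light[g] for g in genotypes}

    def tube_reads(composition: dict[str, int]) -> list[tuple[str, str]]:
        total = sum(composition.values())
        if total == 0:
            return []
        pool = {g: c / total for g, c in composition.items() if c > 0}
        cfg = AmpliconSimConfig(
            reference=reference,
            pool=pool,
            depth=depth,
            per_base_error=per_base_error,
            chimera_rate=chimera_rate,
            seed=int(rng.integers(2**31)),
        )
        return sim_amplicon(cfg).reads

    return PhototaxisSim(
        reference=reference,
        light_reads=tube_reads(n_light),
        dark_reads=tube_reads(n_dark),
        n_light=n_light,
        n_dark=n_dark,
        true_pi=dict(true_pi),
    )


@dataclass
class ScSimConfig:
    """Configuration of a simulated multiplexed single-cell experiment."""

    reference: BarcodeReference
    n_cells: int
    genotype_tags: Mapping[str, str]          # genotype -> tag (barcode) id
    genotype_proportions: Mapping[str, float]
    doublet_rate: float = 0.0
    ge_capture: float = 0.3                   # Poisson mean GE tag counts per carried tag
    enriched_umis_per_cell: float = 20.0      # Poisson mean tag UMIs per cell
    ambient_rate: float = 0.0                 # P(UMI tag drawn from pool-wide distribution)
    chimera_rate: float = 0.0                 # P(record tag swapped post-UMI)
    mean_reads_per_umi: float = 1.5
    per_base_error: float = 0.0
    cell_barcode_length: int = 16
    umi_length: int = 12
    seed: int = 0

    def __post_init__(self):
        for name in ("doublet_rate", "ambient_rate", "chimera_rate", "per_base_error"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("ge_capture", "enriched_umis_per_cell"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.mean_reads_per_umi < 1:
            raise ValueError("mean_reads_per_umi must be >= 1")
        unknown = set(self.genotype_tags.values()) - set(self.reference.ids)
        if unknown:
            raise ValueError(f"tags not in reference: {sorted(unknown)}")
        if set(self.genotype_tags) != set(self.genotype_proportions):
            raise ValueError("genotype_tags and genotype_proportions must agree")
        total = sum(self.genotype_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"genotype proportions must sum to 1, got {total}")


@dataclass
class ScSim:
    """Simulated single-cell tag evidence with per-cell ground truth."""

    ge_matrix: sparse.csr_matrix            # cells x tags
    tag_ids: list[str]
    cell_ids: list[str]
    enriched_records: list[tuple[str, str, str]]  # (cell_barcode, umi, tag_read)
    truth: pd.DataFrame                     # cell, genotypes, tags, doublet

    def write_enriched_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("cell_barcode\tumi\ttag_read\n")
            for cb, umi, tr in self.enriched_records:
                fh.write(f"{cb}\t{umi}\t{tr}\n")


def _distinct_seqs(rng: np.random.Generator, n: int, length: int) -> list[str]:
    out: set[str] = set()
    while len(out) < n:
        need = n - len(out)
        block = rng.choice(_BASES, size=(need, length))
        for row in block:
            out.add(row.tobytes().decode("ascii"))
            if len(out) == n:
                break
    return sorted(out)  # sorted for seed-stable order independent of set iteration


def sim_sc(config: ScSimConfig) -> ScSim:
    """Simulate GE tag counts and an enriched UMI library for one run.

    Doublet cells carry two independently drawn genotypes' tags (a draw may
    repeat the same genotype, giving an undetectable homotypic doublet).
    GE counts per carried tag are Poisson(ge_capture); enriched UMIs per
    cell are Poisson(enriched_umis_per_cell), split uniformly across carried
    tags, with each UMI's tag flipped to a pool-wide draw at ambient_rate
    and each *record*'s tag swapped at chimera_rate.
    """
    rng = np.random.default_rng(config.seed)
    genotypes = list(config.genotype_tags)
    props = np.array([config.genotype_proportions[g] for g in genotypes])
    props = props / props.sum()
    tag_ids = list(config.reference.ids)
    tag_index = {t: i for i, t in enumerate(tag_ids)}
    tag_seq = dict(zip(config.reference.ids, config.reference.sequences))

    cell_ids = _distinct_seqs(rng, config.n_cells, config.cell_barcode_length)
    rng.shuffle(cell_ids)

    first = rng.choice(len(genotypes), size=config.n_cells, p=props)
    is_doublet = rng.random(config.n_cells) < config.doublet_rate
    second = rng.choice(len(genotypes), size=config.n_cells, p=props)

    pool_tag_probs = np.zeros(len(tag_ids))
    for g, p in zip(genotypes, props):
        pool_tag_probs[tag_index[config.genotype_tags[g]]] += p

    ge_rows, ge_cols, ge_data = [], [], []
    records: list[tuple[str, str, str]] = []
    truth_rows = []
    for ci in range(config.n_cells):
        cell_genos = [genotypes[first[ci]]]
        if is_doublet[ci]:
            cell_genos.append(genotypes[second[ci]])
        carried = sorted({tag_index[config.genotype_tags[g]] for g in cell_genos})

        for ti in carried:
            c = int(rng.poisson(config.ge_capture))
            if c > 0:
                ge_rows.append(ci)
                ge_cols.append(ti)
                ge_data.append(c)

        n_umis = int(rng.poisson(config.enriched_umis_per_cell))
        if n_umis > 0:
            umis = _distinct_seqs(rng, n_umis, config.umi_length)
            umi_tags = rng.choice(carried, size=n_umis)
            ambient = rng.random(n_umis) < config.ambient_rate
            if ambient.any():
                umi_tags[ambient] = rng.choice(
                    len(tag_ids), size=int(ambient.sum()), p=pool_tag_probs
                )
            for umi, ti in zip(umis, umi_tags):
                n_reads = 1 + int(rng.poisson(config.mean_reads_per_umi - 1))
                for _ in range(n_reads):
                    rec_tag = int(ti)
                    if rng.random() < config.chimera_rate:
                        rec_tag = int(rng.choice(len(tag_ids), p=pool_tag_probs))
                    body = DEFAULT_HANDLE + tag_seq[tag_ids[rec_tag]] + SV40_CONTEXT
                    if config.per_base_error > 0:
                        mat = np.frombuffer(body.encode(), dtype=np.uint8).copy()
                        _apply_substitutions(
                            mat[None, :], rng, config.per_base_error
                        )
                        body = mat.tobytes().decode("ascii")
                    records.append((cell_ids[ci], umi, body))
        truth_rows.append(
            (
                cell_ids[ci],
                ",".join(cell_genos),
                ",".join(tag_ids[t] for t in carried),
                bool(is_doublet[ci]),
            )
        )
    ge = sparse.coo_matrix(
        (ge_data, (ge_rows, ge_cols)), shape=(config.n_cells, len(tag_ids))
    ).tocsr()
    truth = pd.DataFrame(
        truth_rows, columns=["cell", "genotypes", "tags", "doublet"]
    )
    return ScSim(
        ge_matrix=ge,
        tag_ids=tag_ids,
        cell_ids=cell_ids,
        enriched_records=records,
        truth=truth,
    )


def write_mtx_dir(
    matrix: sparse.spmatrix, feature_ids: Sequence[str],
    cell_ids: Sequence[str], path: str | Path,
) -> None:
    """Write a cells x features matrix as the features x cells MTX trio."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    mmwrite(str(path / "matrix.mtx"), sparse.coo_matrix(matrix.T), field="integer")
    (path / "features.tsv").write_text("".join(f"{f}\n" for f in feature_ids))
    (path / "barcodes.tsv").write_text("".join(f"{c}\n" for c in cell_ids))


def write_reference_if_generated(cfg: Mapping, ref: BarcodeReference,
                                 outdir: str | Path) -> None:
    """Persist an auto-generated reference so downstream steps can reuse it."""
    if not cfg.get("reference"):
        from .reference import write_reference
        write_reference(ref, Path(outdir) / "reference.fasta")


@dataclass
class TransitSim:
    counts: CountTable
    truth: pd.DataFrame  # genotype, bin, n_larvae


def sim_transit(
    pass_time_dist: Mapping[str, Mapping[str, float]],
    n_larvae: int,
    bin_order: Sequence[str],
    seed: int = 0,
) -> TransitSim:
    """Multinomially allocate larvae of each genotype across time bins.

    ``pass_time_dist`` maps genotype -> {bin label -> probability}; bins may
    include terminal "never passed" / "died" labels. Returns a bin x
    genotype count table (QC rows are trivially complete: every larva is
    observed in exactly one bin).
    """
    genotypes = list(pass_time_dist)
    counts = pd.DataFrame(0, index=list(bin_order), columns=genotypes, dtype=np.int64)
    rng = np.random.default_rng(seed)
    truth_rows = []
    for g in genotypes:
        dist = pass_time_dist[g]
        unknown = set(dist) - set(bin_order)
        if unknown:
            raise ValueError(f"{g}: bins not in bin_order: {sorted(unknown)}")
        p = np.array([dist.get(b, 0.0) for b in bin_order], dtype=float)
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"{g}: bin probabilities must sum to 1")
        alloc = rng.multinomial(n_larvae, p)
        counts[g] = alloc
        for b, c in zip(bin_order, alloc):
            truth_rows.append((g, b, int(c)))
    qc = pd.DataFrame(
        {
            "n_total": counts.sum(axis=1),
            "n_no_handle": 0,
            "n_too_short": 0,
            "n_no_match": 0,
            "n_ambiguous": 0,
            "n_assigned": counts.sum(axis=1),
        },
        index=counts.index,
    )
    table = CountTable(counts=counts, qc=qc)
    return TransitSim(
        counts=table,
        truth=pd.DataFrame(truth_rows, columns=["genotype", "bin", "n_larvae"]),
    )
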