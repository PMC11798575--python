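"""Single-cell barcode assignment: dedup, purity, calling, doublets."""

import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from tagem.demux import DEFAULT_HANDLE
from tagem.sc import (
    MULTI,
    CellTagCounts,
    EnrichedRecord,
    call_cells,
    count_enriched,
    detect_tag_doublets,
    detection_fraction,
    extract_ge_tag_counts,
    load_mtx_dir,
    overlap_stats,
    purity,
    purity_concordance_curve,
    read_enriched_fastq,
    read_enriched_tsv,
)
from tagem.simulate import (
    SV40_CONTEXT,
    ScSimConfig,
    random_reference,
    sim_sc,
    write_fastq,
    write_mtx_dir,
)


@pytest.fixture(scope="module")
def ref():
    return random_reference(6, seed=3)


def _rec(cell, umi, ref, tag_idx):
    read = DEFAULT_HANDLE + ref.sequences[tag_idx] + SV40_CONTEXT
    return EnrichedRecord(cell, umi, read)


CELL1 = "A" * 16
CELL2 = "C" * 16
UMI1 = "A" * 12
UMI2 = "G" * 12


class TestCountEnriched:
    def test_duplicate_records_collapse_to_one_umi(self, ref):
        recs = [_rec(CELL1, UMI1, ref, 0)] * 3
        counts, qc = count_enriched(recs, ref)
        assert counts.to_frame().loc[CELL1, ref.ids[0]] == 1
        assert qc["n_umis_counted"] == 1

    def test_tag_tie_within_umi_is_dropped(self, ref):
        recs = [_rec(CELL1, UMI1, ref, 0), _rec(CELL1, UMI1, ref, 1)]
        counts, qc = count_enriched(recs, ref)
        assert counts.matrix.sum() == 0
        assert qc["n_umi_tag_ties"] == 1

    def test_majority_tag_wins_within_umi(self, ref):
        recs = [
            _rec(CELL1, UMI1, ref, 0),
            _rec(CELL1, UMI1, ref, 0),
            _rec(CELL1, UMI1, ref, 1),
        ]
        counts, _ = count_enriched(recs, ref)
        frame = counts.to_frame()
        assert frame.loc[CELL1, ref.ids[0]] == 1
        assert frame.loc[CELL1, ref.ids[1]] == 0

    def test_n_in_cell_or_umi_dropped(self, ref):
        recs = [
            _rec("N" + CELL1[1:], UMI1, ref, 0),
            _rec(CELL1, "N" + UMI1[1:], ref, 0),
            _rec(CELL1, UMI2, ref, 0),
        ]
        counts, qc = count_enriched(recs, ref)
        assert qc["n_cell_umi_with_N"] == 2
        assert counts.matrix.sum() == 1

    def test_whitelist_filters_cells(self, ref):
        recs = [_rec(CELL1, UMI1, ref, 0), _rec(CELL2, UMI1, ref, 0)]
        counts, qc = count_enriched(recs, ref, whitelist={CELL1})
        assert counts.cells == [CELL1]
        assert qc["n_off_whitelist"] == 1

    def test_unassignable_tag_reads_tallied(self, ref):
        bad = EnrichedRecord(CELL1, UMI1, "ACGT" * 12)  # no handle
        counts, qc = count_enriched([bad], ref)
        assert qc["n_tag_unassigned"] == 1
        assert counts.matrix.sum() == 0

    def test_inconsistent_lengths_rejected(self, ref):
        recs = [_rec(CELL1, UMI1, ref, 0), _rec(CELL1[:10], UMI1, ref, 0)]
        with pytest.raises(ValueError, match="inconsistent field lengths"):
            count_enriched(recs, ref)

    def test_matches_naive_dictionary_dedup(self, ref):
        """Random record stream vs an independent dict-of-Counters dedup."""
        rng = np.random.default_rng(31)
        cells = ["".join(rng.choice(list("ACGT"), 16)) for _ in range(40)]
        umis = ["".join(rng.choice(list("ACGT"), 12)) for _ in range(30)]
        recs = []
        for _ in range(600):
            recs.append(
                _rec(
                    cells[rng.integers(len(cells))],
                    umis[rng.integers(len(umis))],
                    ref,
                    int(rng.integers(len(ref))),
                )
            )
        counts, _ = count_enriched(recs, ref)

        votes: dict[tuple[str, str], Counter] = {}
        for cell, umi, read in recs:
            tag = None
            for i, s in enumerate(ref.sequences):
                w = read[len(DEFAULT_HANDLE):len(DEFAULT_HANDLE) + 14]
                if w == s:
                    tag = i
            votes.setdefault((cell, umi), Counter())[tag] += 1
        expected: dict[tuple[str, int], int] = {}
        for (cell, _umi), c in votes.items():
            top = c.most_common()
            if len(top) > 1 and top[0][1] == top[1][1]:
                continue
            key = (cell, top[0][0])
            expected[key] = expected.get(key, 0) + 1
        frame = counts.to_frame()
        for (cell, tag_i), n in expected.items():
            assert frame.loc[cell, ref.ids[tag_i]] == n
        assert counts.matrix.sum() == sum(expected.values())

    def test_dedup_idempotence(self, ref):
        """Re-streaming one record per counted UMI reproduces the matrix."""
        rng = np.random.default_rng(8)
        recs = [
            _rec(
                [CELL1, CELL2][rng.integers(2)],
                "".join(rng.choice(list("ACGT"), 12)),
                ref,
                int(rng.integers(len(ref))),
            )
            for _ in range(200)
        ]
        counts1, _ = count_enriched(recs, ref)
        # canonical stream: one record with a fresh UMI per counted UMI
        stream = []
        frame = counts1.to_frame()
        u = 0
        for cell in counts1.cells:
            for tag_i, tag in enumerate(counts1.tags):
                for _ in range(int(frame.loc[cell, tag])):
                    stream.append(_rec(cell, _int_to_umi(u), ref, tag_i))
                    u += 1
        counts2, _ = count_enriched(stream, ref)
        assert counts2.to_frame().loc[counts1.cells].equals(
            counts1.to_frame().loc[counts1.cells]
        )


def _int_to_umi(i: int, length: int = 12) -> str:
    digits = []
    for _ in range(length):
        digits.append("ACGT"[i % 4])
        i //= 4
    return "".join(digits)


class TestPurity:
    @pytest.mark.parametrize(
        "counts,expected_purity,expected_top",
        [
            ({"BC1": 9, "BC2": 1}, 0.9, "BC1"),
            ({"BC1": 5}, 1.0, "BC1"),
            ({"BC1": 3, "BC2": 3}, 0.5, None),
        ],
    )
    def test_examples(self, counts, expected_purity, expected_top):
        p, top = purity(counts)
        assert p == pytest.approx(expected_purity)
        assert top == expected_top

    def test_no_umis_undefined(self):
        assert purity({"BC1": 0, "BC2": 0}) == (None, None)

    def test_monotonicity(self):
        """Adding top-tag UMIs never decreases purity; adding another tag's
        UMIs never increases the top tag's share (and never increases
        purity while the top tag stays on top)."""
        rng = np.random.default_rng(12)
        for _ in range(50):
            counts = {f"t{i}": int(rng.integers(0, 20)) for i in range(5)}
            if sum(counts.values()) == 0:
                counts["t0"] = 1
            p0, top = purity(counts)
            if top is None:
                continue
            more_top = dict(counts)
            more_top[top] += int(rng.integers(1, 5))
            assert purity(more_top)[0] >= p0 - 1e-12
            other = rng.choice([t for t in counts if t != top])
            more_other = dict(counts)
            more_other[other] += int(rng.integers(1, 5))
            # the original top tag's share strictly shrinks
            assert more_other[top] / sum(more_other.values()) <= p0 + 1e-12
            p1, top1 = purity(more_other)
            if top1 == top:
                assert p1 <= p0 + 1e-12


def _tag_counts(frame: pd.DataFrame, source: str) -> CellTagCounts:
    return CellTagCounts(
        source=source,
        cells=list(frame.index),
        tags=list(frame.columns),
        matrix=sparse.csr_matrix(frame.to_numpy()),
    )


class TestCallCells:
    def _pair(self, ge_rows, enr_rows, cells, tags):
        ge = _tag_counts(pd.DataFrame(ge_rows, index=cells, columns=tags), "GE")
        enr = _tag_counts(pd.DataFrame(enr_rows, index=cells, columns=tags),
                          "enriched")
        return ge, enr

    def test_ge_priority_on_conflict(self):
        ge, enr = self._pair([[1, 0]], [[0, 99]], ["c1"], ["BC3", "BC5"])
        calls = call_cells(ge, enr)
        row = calls.loc["c1"]
        assert row["ge_call"] == "BC3"
        assert row["enriched_call"] == "BC5"
        assert row["final_call"] == "BC3"
        assert row["source_of_final"] == "GE"

    def test_high_purity_enriched_rescues_ge_negative(self):
        ge, enr = self._pair([[0, 0]], [[96, 4]], ["c1"], ["BC2", "BC7"])
        row = call_cells(ge, enr).loc["c1"]
        assert row["purity"] == pytest.approx(0.96)
        assert row["final_call"] == "BC2"
        assert row["source_of_final"] == "enriched"

    def test_low_purity_enriched_gives_no_call(self):
        ge, enr = self._pair([[0, 0]], [[6, 4]], ["c1"], ["BC2", "BC7"])
        row = call_cells(ge, enr).loc["c1"]
        assert row["purity"] == pytest.approx(0.6)
        assert row["final_call"] is None
        assert row["source_of_final"] == "none"

    def test_purity_threshold_is_strict(self):
        ge, enr = self._pair([[0, 0]], [[3, 1]], ["c1"], ["a", "b"])
        row = call_cells(ge, enr, purity_threshold=0.75).loc["c1"]
        assert row["purity"] == pytest.approx(0.75)
        assert row["enriched_call"] is None  # 0.75 is not > 0.75

    def test_multi_tag_ge_cell_is_doublet_without_final_ge_call(self):
        ge, enr = self._pair([[2, 1]], [[10, 0]], ["c1"], ["a", "b"])
        row = call_cells(ge, enr).loc["c1"]
        assert row["ge_call"] == MULTI
        assert bool(row["doublet_flag"])
        assert row["final_call"] == "a"  # falls through to enriched
        assert row["source_of_final"] == "enriched"

    def test_ge_priority_property_exhaustive(self):
        """For every cell with a single-tag GE call the final call equals
        it, whatever the enriched evidence says."""
        rng = np.random.default_rng(44)
        tags = ["a", "b", "c"]
        cells = [f"c{i}" for i in range(60)]
        ge_rows = rng.integers(0, 3, size=(60, 3))
        enr_rows = rng.integers(0, 30, size=(60, 3))
        ge, enr = self._pair(ge_rows, enr_rows, cells, tags)
        calls = call_cells(ge, enr)
        for cell in cells:
            row = ge.to_frame().loc[cell]
            hits = list(row.index[row >= 1])
            if len(hits) == 1:
                assert calls.loc[cell, "final_call"] == hits[0]
                assert calls.loc[cell, "source_of_final"] == "GE"

    def test_enriched_only_cells_marked_not_in_ge(self):
        ge = _tag_counts(pd.DataFrame([[1]], index=["c1"], columns=["a"]), "GE")
        enr = _tag_counts(
            pd.DataFrame([[9], [9]], index=["c1", "c2"], columns=["a"]),
            "enriched",
        )
        calls = call_cells(ge, enr)
        assert not bool(calls.loc["c2", "in_ge"])
        # detection denominators exclude enriched-only cells
        assert detection_fraction(calls, "combined") == pytest.approx(1.0)


class TestDoubletsAndOverlap:
    def test_co_expressing_cell_detected(self):
        ge = _tag_counts(
            pd.DataFrame([[2, 1], [5, 0]], index=["c1", "c2"], columns=["a", "b"]),
            "GE",
        )
        assert detect_tag_doublets(ge) == {"c1"}

    def test_matches_naive_nonzero_column_loop(self):
        rng = np.random.default_rng(3)
        mat = (rng.random((80, 6)) < 0.15) * rng.integers(1, 5, size=(80, 6))
        cells = [f"c{i}" for i in range(80)]
        ge = _tag_counts(
            pd.DataFrame(mat, index=cells, columns=[f"t{j}" for j in range(6)]),
            "GE",
        )
        expected = {
            c for c, row in zip(cells, mat) if sum(1 for v in row if v >= 1) >= 2
        }
        assert detect_tag_doublets(ge) == expected

    def test_min_count_threshold(self):
        ge = _tag_counts(
            pd.DataFrame([[2, 1]], index=["c1"], columns=["a", "b"]), "GE"
        )
        assert detect_tag_doublets(ge, min_count=2) == set()

    def test_overlap_reported_example(self):
        """298 barcode doublets, 198 shared with the external caller's
        2019 -> 66.4% of the barcode set overlaps."""
        a = {f"x{i}" for i in range(298)}
        b = {f"x{i}" for i in range(198)} | {f"y{i}" for i in range(2019 - 198)}
        ov = overlap_stats(a, b)
        assert (ov.n_a, ov.n_b, ov.n_overlap) == (298, 2019, 198)
        assert round(ov.pct_a_in_b, 1) == 66.4

    def test_disjoint_and_subset(self):
        assert overlap_stats({"a"}, {"b"}).pct_a_in_b == 0.0
        ov = overlap_stats({"a", "b"}, {"a", "b", "c"})
        assert ov.pct_a_in_b == 100.0
        assert overlap_stats(set(), {"a"}).pct_a_in_b is None


class TestDetectionFraction:
    def test_ge_only_fraction(self):
        ge = _tag_counts(
            pd.DataFrame(
                [[1, 0]] * 4 + [[0, 0]] * 6,
                index=[f"c{i}" for i in range(10)],
                columns=["a", "b"],
            ),
            "GE",
        )
        enr = _tag_counts(
            pd.DataFrame(np.zeros((0, 2), dtype=int), index=[], columns=["a", "b"]),
            "enriched",
        )
        calls = call_cells(ge, enr)
        assert detection_fraction(calls, "GE_only") == pytest.approx(0.4)
        assert detection_fraction(calls, "combined") == pytest.approx(0.4)

    def test_all_and_none_called(self):
        ge = _tag_counts(
            pd.DataFrame([[1], [2]], index=["c1", "c2"], columns=["a"]), "GE"
        )
        enr = _tag_counts(
            pd.DataFrame(np.zeros((0, 1), dtype=int), index=[], columns=["a"]),
            "enriched",
        )
        assert detection_fraction(call_cells(ge, enr)) == 1.0
        ge0 = _tag_counts(
            pd.DataFrame([[0], [0]], index=["c1", "c2"], columns=["a"]), "GE"
        )
        assert detection_fraction(call_cells(ge0, enr)) == 0.0

    def test_empty_table_is_error(self):
        with pytest.raises(ValueError):
            detection_fraction(
                pd.DataFrame(columns=["ge_call", "final_call", "in_ge"])
            )


class TestPurityConcordance:
    def test_all_concordant(self):
        cells = [f"c{i}" for i in range(6)]
        ge = _tag_counts(
            pd.DataFrame([[1, 0]] * 6, index=cells, columns=["a", "b"]), "GE"
        )
        enr = _tag_counts(
            pd.DataFrame([[9, 1]] * 6, index=cells, columns=["a", "b"]),
            "enriched",
        )
        curve = purity_concordance_curve(ge, enr, [0, 0.5, 0.75, 1.0])
        nonempty = curve[~curve["empty"]]
        assert (nonempty["concordance"] == 1.0).all()

    def test_empty_bin_flagged(self):
        ge = _tag_counts(pd.DataFrame([[1]], index=["c1"], columns=["a"]), "GE")
        enr = _tag_counts(pd.DataFrame([[5]], index=["c1"], columns=["a"]),
                          "enriched")
        curve = purity_concordance_curve(ge, enr, [0, 0.5, 1.0])
        assert bool(curve.loc[curve["bin_high"] == 0.5, "empty"].iloc[0])

    def test_unordered_bins_error(self):
        ge = _tag_counts(pd.DataFrame([[1]], index=["c1"], columns=["a"]), "GE")
        with pytest.raises(ValueError, match="increasing"):
            purity_concordance_curve(ge, ge, [0, 0.8, 0.5, 1.0])

    def test_chimeric_simulation_degrades_low_purity_bins(self):
        """With heavy chimerism, low-purity cells show lower GE/enriched
        concordance than (0.99, 1] cells."""
        ref6 = random_reference(6, seed=5)
        genos = {f"G{i + 1}": bc for i, bc in enumerate(ref6.ids)}
        # a dominant genotype concentrates chimeric tag swaps on one tag,
        # so heavily chimeric (low-purity) cells can carry a wrong top tag
        props = {"G1": 0.5, "G2": 0.1, "G3": 0.1, "G4": 0.1, "G5": 0.1,
                 "G6": 0.1}
        cfg = ScSimConfig(
            reference=ref6,
            n_cells=1500,
            genotype_tags=genos,
            genotype_proportions=props,
            ge_capture=2.0,
            enriched_umis_per_cell=10,
            chimera_rate=0.45,
            mean_reads_per_umi=1.0,
            seed=6,
        )
        sim = sim_sc(cfg)
        enr, _ = count_enriched(
            (EnrichedRecord(*r) for r in sim.enriched_records), ref6
        )
        ge = extract_ge_tag_counts(sim.ge_matrix, sim.tag_ids, sim.cell_ids,
                                   sim.tag_ids)
        curve = purity_concordance_curve(ge, enr, [0, 0.6, 0.8, 0.99, 1.0])
        lo = curve[(curve["bin_high"] <= 0.6) & ~curve["empty"]]
        hi = curve[(curve["bin_low"] >= 0.99) & ~curve["empty"]]
        assert len(lo) and len(hi)
        assert lo["concordance"].mean() < hi["concordance"].iloc[0]


class TestIO:
    def test_enriched_tsv_roundtrip(self, ref, tmp_path):
        p = tmp_path / "enr.tsv"
        p.write_text(
            "cell_barcode\tumi\ttag_read\n"
            f"{CELL1}\t{UMI1}\t{DEFAULT_HANDLE + ref.sequences[0]}\n"
        )
        recs = list(read_enriched_tsv(p))
        assert recs == [
            EnrichedRecord(CELL1, UMI1, DEFAULT_HANDLE + ref.sequences[0])
        ]

    def test_enriched_fastq_layout(self, ref, tmp_path):
        r1 = tmp_path / "r1.fastq"
        r2 = tmp_path / "r2.fastq"
        write_fastq([("m1", CELL1 + UMI1)], r1)
        write_fastq([("m1", DEFAULT_HANDLE + ref.sequences[2])], r2)
        recs = list(read_enriched_fastq(r1, r2))
        assert recs[0].cell_barcode == CELL1
        assert recs[0].umi == UMI1
        assert recs[0].tag_read.startswith(DEFAULT_HANDLE)

    def test_mtx_trio_roundtrip(self, ref, tmp_path):
        rng = np.random.default_rng(2)
        mat = sparse.csr_matrix(rng.integers(0, 3, size=(10, len(ref))))
        cells = [f"cell{i}" for i in range(10)]
        write_mtx_dir(mat, list(ref.ids), cells, tmp_path / "mtx")
        loaded, features, cell_ids = load_mtx_dir(tmp_path / "mtx")
        assert features == list(ref.ids)
        assert cell_ids == cells
        assert (loaded.toarray() == mat.toarray()).all()

    def test_missing_tag_feature_is_error(self):
        mat = sparse.csr_matrix(np.ones((2, 2), dtype=int))
        with pytest.raises(ValueError, match="BC99"):
            extract_ge_tag_counts(mat, ["a", "b"], ["c1", "c2"], ["a", "BC99"])
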