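import numpy as np
import pytest

from tagem.reference import BarcodeReference
from tagem.simulate import random_reference


@pytest.fixture(scope="session")
def small_ref() -> BarcodeReference:
    """Two maximally separated barcodes plus one near neighbor of the first."""
    return BarcodeReference(
        ids=("BC_A", "BC_B", "BC_C"),
        sequences=(
            "AAAAAAAAAAAAAA",
            "TTTTTTTTTTTTTT",
            "AAAAAAAAAAAATT",  # distance 2 from BC_A
        ),
    )


@pytest.fixture(scope="session")
def sep_ref() -> BarcodeReference:
    """20 random barcodes at pairwise distance >= 5 (no ambiguity under <=2 mm)."""
    return random_reference(20, seed=11)


def naive_assign(read_seq, ref, params):
    """Independent brute-force read assignment: scans every offset and every
    reference with naive per-character loops. Oracle for the pipeline."""
    handle = params.handle
    h = len(handle)
    min_len = max(
        params.min_read_length_after_trim
        if params.min_read_length_after_trim is not None
        else ref.barcode_length,
        ref.barcode_length,
    )
    for off in range(params.max_search_offset + 1):
        window = read_seq[off:off + h]
        if len(window) < h:
            break
        mm = sum(a != b for a, b in zip(window, handle))
        if mm <= params.max_handle_mismatch:
            suffix = read_seq[off + h:]
            if len(suffix) < min_len:
                return ("too_short", None, None)
            w = suffix[: ref.barcode_length]
            dists = {
                bid: sum(a != b for a, b in zip(w, s))
                for bid, s in zip(ref.ids, ref.sequences)
            }
            md = min(dists.values())
            winners = [b for b, d in dists.items() if d == md]
            if md > params.max_barcode_mismatch:
                return ("no_match", None, None)
            if len(winners) > 1:
                return ("ambiguous", None, None)
            return ("assigned", winners[0], md)
    return ("no_handle", None, None)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
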