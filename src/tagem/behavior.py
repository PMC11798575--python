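"""Population-phenotyping statistics computed from barcode abundance tables.

Pooled, barcoded animals are assayed together; the readout per experimental
tube (light vs dark side of a phototaxis chamber, a gut-transit timepoint
bin, an egg-lay plate) is a barcode abundance profile. Abundances are scaled
to the number of animals counted in each tube, turning fractions into
fly-equivalents, and per-genotype statistics follow:

* preference index  P.I. = (N_toward - N_away) / (N_toward + N_away)
* replicate summaries (mean, SEM with the n-1 standard deviation, CV)
* observed-vs-expected fits for structured pools (squared Pearson r, OLS)
* cumulative passage curves and median transit times for timepoint bins
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .demux import AbundanceTable, CountTable

__all__ = [
    "TubeDesign",
    "ReplicateSummary",
    "FitResult",
    "TransitResult",
    "scale_to_flies",
    "preference_index",
    "replicate_summary",
    "expected_observed_fit",
    "paired_measure_correlation",
    "timecourse_summary",
]


@dataclass
class TubeDesign:
    """Tube metadata: condition label and the number of flies counted."""

    tubes: pd.DataFrame  # index tube_id, columns: condition, n_flies

    def __post_init__(self):
        if self.tubes.index.has_duplicates:
            raise ValueError("tube IDs must be unique")
        if (self.tubes["n_flies"] < 0).any():
            raise ValueError("n_flies must be >= 0")

    @classmethod
    def from_records(cls, records: Sequence[tuple[str, str, int]]) -> "TubeDesign":
        df = pd.DataFrame(records, columns=["tube_id", "condition", "n_flies"])
        return cls(df.set_index("tube_id"))

    @classmethod
    def read(cls, path: str | Path) -> "TubeDesign":
        df = pd.read_csv(path, sep="\t")
        required = {"tube_id", "condition", "n_flies"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        return cls(df.set_index("tube_id"))

    def n_flies(self, tube_id: str) -> int:
        return int(self.tubes.loc[tube_id, "n_flies"])


def scale_to_flies(abund: AbundanceTable, design: TubeDesign) -> pd.DataFrame:
    """Scale abundance fractions to fly-equivalents per tube.

    Each row of the result sums to that tube's fly count (or 0 for flagged
    empty samples). Raises if any abundance sample is absent from the design.
    """
    missing = [s for s in abund.samples if s not in design.tubes.index]
    if missing:
        raise ValueError(f"tubes missing from design: {missing}")
    n = design.tubes.loc[abund.samples, "n_flies"].astype(float)
    return abund.fractions.mul(n, axis=0)


def preference_index(
    scaled: pd.DataFrame, positive_tube: str, negative_tube: str
) -> pd.DataFrame:
    """Per-barcode preference index from fly-scaled counts of two tubes.

    P.I. = (positive - negative) / (positive + negative), in [-1, 1];
    barcodes contributing zero flies to both tubes are flagged undefined
    (``defined`` False, P.I. NaN).
    """
    for tube in (positive_tube, negative_tube):
        if tube not in scaled.index:
            raise ValueError(f"tube {tube!r} not present in scaled counts")
    pos = scaled.loc[positive_tube].astype(float)
    neg = scaled.loc[negative_tube].astype(float)
    total = pos + neg
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = (pos - neg) / total
    defined = total > 0
    pi[~defined] = np.nan
    return pd.DataFrame({"pi": pi, "defined": defined})


@dataclass(frozen=True)
class ReplicateSummary:
    mean: float
    sem: float
    cv: float
    n: int
    sem_defined: bool  # False for n = 1 (SEM reported as 0 but uninformative)
    cv_defined: bool   # False when the mean is 0


def replicate_summary(values: Sequence[float]) -> ReplicateSummary:
    """Mean, SEM and CV across replicates.

    SEM uses the n-1 (sample) standard deviation; with a single replicate
    SEM is reported as 0 and flagged. CV = sd/mean, flagged undefined when
    the mean is 0.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("replicate_summary requires at least one value")
    mean = float(vals.mean())
    if vals.size == 1:
        return ReplicateSummary(mean, 0.0, math.nan, 1, False, False)
    sd = float(vals.std(ddof=1))
    sem = sd / math.sqrt(vals.size)
    if mean == 0:
        return ReplicateSummary(mean, sem, math.nan, int(vals.size), True, False)
    return ReplicateSummary(mean, sem, sd / mean, int(vals.size), True, True)


@dataclass(frozen=True)
class FitResult:
    r_squared: float
    slope: float
    intercept: float
    n_points: int
    per_level_means: dict[str, float] | None = None


def expected_observed_fit(
    observed: Mapping[str, float],
    expected: Mapping[str, float],
    group: Mapping[str, str] | None = None,
) -> FitResult:
    """Fit observed against expected abundances, optionally per input level.

    With ``group`` given (barcode -> level), observed values are averaged
    within each level and expected values must agree within a level; the fit
    is then over one point per level. R^2 is the squared Pearson correlation
    of the (expected, observed) pairs, equivalently the OLS R^2 with
    intercept; slope and intercept come from ordinary least squares of
    observed on expected.
    """
    keys = [k for k in expected if k in observed]
    if group is not None:
        levels: dict[str, list[float]] = {}
        exp_lvl: dict[str, float] = {}
        for k in keys:
            lvl = group[k]
            levels.setdefault(lvl, []).append(observed[k])
            if lvl in exp_lvl and not math.isclose(exp_lvl[lvl], expected[k]):
                raise ValueError(
                    f"level {lvl!r} has inconsistent expected values"
                )
            exp_lvl[lvl] = expected[k]
        per_level = {lvl: float(np.mean(v)) for lvl, v in levels.items()}
        x = np.array([exp_lvl[lvl] for lvl in per_level])
        y = np.array([per_level[lvl] for lvl in per_level])
    else:
        per_level = None
        x = np.array([expected[k] for k in keys], dtype=float)
        y = np.array([observed[k] for k in keys], dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("need at least 2 distinct expected values to fit")
    res = stats.linregress(x, y)
    return FitResult(
        r_squared=float(res.rvalue**2),
        slope=float(res.slope),
        intercept=float(res.intercept),
        n_points=len(x),
        per_level_means=per_level,
    )


def paired_measure_correlation(
    manual: Mapping[str, float],
    seq: Mapping[str, float],
    group: Mapping[str, str] | None = None,
) -> FitResult:
    """Correlate sequencing-based readouts with manual measurements.

    Alias of :func:`expected_observed_fit` with the manual measurement on
    the x-axis (R^2 is symmetric in the two axes in any case).
    """
    return expected_observed_fit(observed=seq, expected=manual, group=group)


@dataclass
class TransitResult:
    """Cumulative passage curves and median transit times per barcode."""

    cumulative: pd.DataFrame      # time (minutes) x barcode, non-decreasing in t
    median_minutes: pd.Series    # NaN where censored
    censored: pd.Series          # True where the curve never reaches 0.5
    n_died: pd.Series
    n_never: pd.Series


def timecourse_summary(
    counts: CountTable | pd.DataFrame,
    timepoints: Mapping[str, float],
    never_bin: str | None = None,
    died_bin: str | None = None,
) -> TransitResult:
    """Summarize gut-transit timepoint bins into passage curves.

    ``counts`` has one sample row per timepoint bin (larvae or
    abundance-weighted larvae per barcode); ``timepoints`` maps bin sample
    IDs to minutes and must be in increasing time order. Animals in the
    "never passed" bin stay in the denominator (they genuinely did not
    pass); animals in the "died" bin are excluded from it. The median
    transit time is the first timepoint at which the cumulative passed
    fraction reaches 0.5, censored if it never does.
    """
    mat = counts.counts if isinstance(counts, CountTable) else counts
    order = list(timepoints)
    times = [timepoints[s] for s in order]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("timepoint bins must be in strictly increasing time order")
    missing = [s for s in order if s not in mat.index]
    if missing:
        raise ValueError(f"bins missing from counts: {missing}")

    timed = mat.loc[order].astype(float)
    died = (
        mat.loc[died_bin].astype(float)
        if died_bin is not None and died_bin in mat.index
        else pd.Series(0.0, index=mat.columns)
    )
    never = (
        mat.loc[never_bin].astype(float)
        if never_bin is not None and never_bin in mat.index
        else pd.Series(0.0, index=mat.columns)
    )
    denom = timed.sum(axis=0) + never  # died excluded
    if (denom + died <= 0).any():
        bad = list(mat.columns[(denom + died) <= 0])
        raise ValueError(f"barcodes with no larvae in any bin: {bad}")

    with np.errstate(invalid="ignore", divide="ignore"):
        cum = timed.cumsum(axis=0).div(denom, axis=1)
    cum.index = pd.Index(times, name="minutes")

    median = pd.Series(np.nan, index=mat.columns, dtype=float)
    censored = pd.Series(True, index=mat.columns)
    for bc in mat.columns:
        reached = cum[bc] >= 0.5
        if reached.any():
            median[bc] = float(cum.index[reached.argmax()])
            censored[bc] = False
    return TransitResult(
        cumulative=cum,
        median_minutes=median,
        censored=censored,
        n_died=died,
        n_never=never,
    )
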