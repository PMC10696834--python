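"""Depth-based copy-number and aneuploidy analysis.

Window depths are normalized against the median depth of single-copy core
baseline windows (optionally re-normalized against a control isolate), then
region states are called on a half-copy grid {0, 0.5, 1, 1.5, 2, ...} —
half states arise because a monospore culture can be a mixture of cells
with different karyotypes, so a chromosome present in half the cells shows
a 1.5x whole-culture depth atop a 1x baseline, and a chromosome at two
copies in 80% of cells shows 1.8x.  Ratios that sit off the grid are
explained as a two-state karyotype mixture whose high-state cell fraction
is solved exactly from the depth ratio.

Whole-chromosome gains/losses are called when nearly all windows agree with
the off-expectation state; loss-of-heterozygosity runs on an extra
chromosome are read from bin origin calls in regions expected heterozygous.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bin_genotyping import BinOriginCall

__all__ = [
    "CopyCall",
    "call_region_state",
    "call_whole_chromosome_aneuploidy",
    "detect_loh",
    "infer_mixture_fraction",
    "normalize_depth",
]


@dataclass(frozen=True)
class CopyCall:
    """Copy state of one region: a half-grid state or a two-state mixture."""

    chrom: str
    start: int
    end: int
    ratio: float  # normalized depth, 1.0 = single-copy baseline
    state: Optional[float]  # half-grid value, or None when a mixture fits better
    mixture: Optional[tuple[int, int, float]] = None  # (low, high, fraction at high)

    def __post_init__(self) -> None:
        if self.ratio < 0:
            raise ValueError("ratio must be >= 0")
        if self.mixture is not None:
            f = self.mixture[2]
            if not 0.0 < f < 1.0:
                raise ValueError("mixture fraction must be in (0, 1)")

    @property
    def is_mixture(self) -> bool:
        return self.mixture is not None


def normalize_depth(
    windows: pd.DataFrame,
    baseline_regions: Optional[Sequence[tuple[str, int, int]]] = None,
    control_ratios: Optional[pd.DataFrame] = None,
    min_baseline_windows: int = 50,
) -> pd.DataFrame:
    """Normalize window depths to copy-number ratios.

    ``windows`` columns: ``chrom, start, end, depth``.  The baseline is the
    median depth over windows inside ``baseline_regions`` (single-copy core
    regions; accessory and known-CNV regions should be excluded so they do
    not contaminate the median).  With no regions given, all windows form
    the baseline.  ``control_ratios`` (same window grid, column ``ratio``)
    applies a second normalization against a control isolate.
    """
    df = windows.copy()
    if baseline_regions is None:
        mask = pd.Series(True, index=df.index)
    else:
        mask = pd.Series(False, index=df.index)
        for chrom, start, end in baseline_regions:
            mask |= (df["chrom"] == chrom) & (df["start"] >= start) & (df["end"] <= end)
    if int(mask.sum()) < min_baseline_windows:
        raise ValueError(
            f"baseline has {int(mask.sum())} windows; need >= {min_baseline_windows}"
        )
    baseline = float(df.loc[mask, "depth"].median())
    if baseline <= 0:
        raise ValueError("baseline median depth is zero")
    df["ratio"] = df["depth"] / baseline
    if control_ratios is not None:
        ctrl = control_ratios.set_index(["chrom", "start"])["ratio"]
        idx = pd.MultiIndex.from_frame(df[["chrom", "start"]])
        denom = ctrl.reindex(idx).to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            df["ratio"] = np.where(denom > 0, df["ratio"].to_numpy() / denom, np.nan)
    return df


def _trimmed_mean(values: np.ndarray, trim: float = 0.1) -> float:
    v = np.sort(np.asarray(values, dtype=float))
    k = int(len(v) * trim)
    if k > 0:
        v = v[k : len(v) - k]
    return float(v.mean())


def infer_mixture_fraction(ratio: float, low_state: int, high_state: int) -> float:
    """Cell fraction at ``high_state`` explaining an off-grid depth ratio.

    Inverts the forward mixture model ``ratio = low*(1-f) + high*f``
    exactly: ``f = (ratio - low) / (high - low)``.
    """
    if low_state >= high_state:
        raise ValueError("low_state must be < high_state")
    if not low_state <= ratio <= high_state:
        raise ValueError(
            f"ratio {ratio} outside [{low_state}, {high_state}]; "
            "no two-state mixture of these states explains it"
        )
    return (ratio - low_state) / (high_state - low_state)


def call_region_state(
    ratios: Sequence[float],
    chrom: str = "",
    start: int = 1,
    end: int = 1,
    grid_tolerance: float = 0.1,
    trim: float = 0.1,
) -> CopyCall:
    """Call the copy state of one region from its window ratios.

    The trimmed-mean ratio snaps to the nearest half-grid value when within
    ``grid_tolerance``; otherwise the region is explained as a two-state
    mixture between the flanking integer copy numbers (the minimal model
    for "two or more karyotypes in the culture").
    """
    r = np.asarray(ratios, dtype=float)
    if len(r) < 3:
        raise ValueError("need >= 3 windows to call a region state")
    mean = _trimmed_mean(r, trim)
    if end <= 1:
        end = max(1, len(r))
    grid = round(mean * 2) / 2
    if abs(mean - grid) <= grid_tolerance:
        return CopyCall(chrom=chrom, start=start, end=end, ratio=mean, state=grid)
    low = int(np.floor(mean))
    high = low + 1
    f = infer_mixture_fraction(mean, low, high)
    return CopyCall(chrom=chrom, start=start, end=end, ratio=mean, state=None, mixture=(low, high, f))


def call_whole_chromosome_aneuploidy(
    window_ratios: pd.DataFrame,
    expected: float | dict[str, float] = 1.0,
    grid_tolerance: float = 0.1,
    min_consistent: float = 0.9,
) -> pd.DataFrame:
    """Whole-chromosome gains and losses from per-window ratios.

    ``window_ratios`` columns: ``chrom, start, end, ratio``.  Each
    chromosome's state is called with :func:`call_region_state`; a gain or
    loss is reported only when the state differs from the expected copy
    number *and* at least ``min_consistent`` of windows individually agree
    with the called state (within ``grid_tolerance``) — a whole-chromosome
    event, not a segmental one.  Returns columns
    ``chrom, ratio, state, expected, change, consistent_fraction``.
    """
    rows = []
    for chrom, grp in window_ratios.groupby("chrom", sort=True):
        exp = expected[chrom] if isinstance(expected, dict) else float(expected)
        r = grp.sort_values("start")["ratio"].to_numpy()
        call = call_region_state(r, chrom=str(chrom), grid_tolerance=grid_tolerance)
        if call.state is None or call.state == exp:
            continue
        consistent = float(np.mean(np.abs(r - call.state) <= 2 * grid_tolerance))
        if consistent < min_consistent:
            continue
        rows.append(
            {
                "chrom": chrom,
                "ratio": call.ratio,
                "state": call.state,
                "expected": exp,
                "change": "gain" if call.state > exp else "loss",
                "consistent_fraction": consistent,
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "ratio", "state", "expected", "change", "consistent_fraction"])


def detect_loh(
    calls: Sequence[BinOriginCall],
    min_run: int = 2,
) -> list[tuple[str, int, int]]:
    """Loss-of-heterozygosity runs inside a region expected heterozygous.

    ``calls`` are the bin origin calls of a region carried atop a homologous
    counterpart (e.g. the Chr05 right arm in an isolate with an extra
    Chr12B), where every informative bin should be HET.  Maximal runs of at
    least ``min_run`` consecutive homozygous (A or B) bins are reported as
    1-based inclusive intervals; NA bins are transparent and break nothing.
    """
    ordered = [c for c in sorted(calls, key=lambda c: c.start) if c.state != "NA"]
    runs: list[list[BinOriginCall]] = []
    for c in ordered:
        if c.state in ("A", "B"):
            if runs and runs[-1]:
                runs[-1].append(c)
            else:
                runs.append([c])
        else:  # HET terminates a run
            runs.append([])
    intervals = []
    for run in runs:
        if len(run) >= min_run:
            intervals.append((run[0].chrom, run[0].start, run[-1].end))
    return intervals
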