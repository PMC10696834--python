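"""Haplotype-origin genotyping of monospore isolates in 10-kb bins.

Each bin of the haplotype-A reference frame with enough diagnostic SNP
density is classified from diagnostic-allele read counts as A, B,
heterozygous (both parental alleles present — e.g. a region carried on both
an A chromosome and an extra B-derived chromosome) or NA (uninformative or
under-covered).  Origin switches along a chromosome are recombination
events; events from many isolates are merged into recombination sites, and
sites hit by four or more isolates are hotspots.

All coordinates are on the haplotype-A reference frame; B-specific regions
(orphan segments, the extra Chr12B) are handled by the junction/karyotype
stage, not here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .coords import gap_between

__all__ = [
    "BinOriginCall",
    "RecombinationEvent",
    "RecombinationSite",
    "aggregate_sites",
    "calls_to_frame",
    "classify_bins",
    "call_events",
    "origin_fraction",
]

HOTSPOT_MIN_ISOLATES = 4


@dataclass(frozen=True)
class BinOriginCall:
    chrom: str
    start: int
    end: int
    n_a: int
    n_b: int
    informative: bool
    state: str  # A | B | HET | NA

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class RecombinationEvent:
    """One origin switch in one isolate; the breakpoint lies between the last
    bin of the left-state run and the first bin of the right-state run."""

    isolate: str
    chrom: str
    left_state: str
    right_state: str
    start: int  # end coordinate of the last left-state bin
    end: int  # start coordinate of the first right-state bin


@dataclass(frozen=True)
class RecombinationSite:
    chrom: str
    start: int
    end: int
    n_isolates: int
    n_events: int

    @property
    def hotspot(self) -> bool:
        return self.n_isolates >= HOTSPOT_MIN_ISOLATES


def classify_bins(
    counts: pd.DataFrame,
    min_reads: int = 5,
    purity: float = 0.9,
) -> list[BinOriginCall]:
    """Classify bins from diagnostic-allele counts.

    ``counts`` columns: ``chrom, start, end, n_a, n_b`` and optionally
    ``informative`` (bins below the SNP-density threshold carry no origin
    signal and are forced NA).  A bin is called A when the A-allele share is
    at least ``purity``; B symmetrically; HET when *both* alleles reach the
    ``1 - purity`` share; NA otherwise or when total reads < ``min_reads``.
    """
    if not 0.5 < purity <= 1.0:
        raise ValueError("purity must be in (0.5, 1]")
    out = []
    for row in counts.itertuples(index=False):
        n_a, n_b = int(row.n_a), int(row.n_b)
        if n_a < 0 or n_b < 0:
            raise ValueError("negative allele counts")
        informative = bool(getattr(row, "informative", True))
        total = n_a + n_b
        if not informative or total < min_reads:
            state = "NA"
        else:
            share_a = n_a / total
            if share_a >= purity:
                state = "A"
            elif share_a <= 1.0 - purity:
                state = "B"
            else:  # both alleles above the 1 - purity share
                state = "HET"
        out.append(
            BinOriginCall(
                chrom=str(row.chrom),
                start=int(row.start),
                end=int(row.end),
                n_a=n_a,
                n_b=n_b,
                informative=informative,
                state=state,
            )
        )
    return out


def calls_to_frame(calls: Sequence[BinOriginCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [c.chrom for c in calls],
            "start": [c.start for c in calls],
            "end": [c.end for c in calls],
            "n_a": [c.n_a for c in calls],
            "n_b": [c.n_b for c in calls],
            "informative": [c.informative for c in calls],
            "state": [c.state for c in calls],
        }
    )


def call_events(
    calls: Sequence[BinOriginCall],
    isolate: str = "",
    min_run: int = 2,
) -> list[RecombinationEvent]:
    """Recombination events from ordered bin calls of one chromosome.

    NA/HET bins are transparent: a switch across such a gap yields a single
    event whose breakpoint interval spans the gap (conservative counting).
    Homozygous runs shorter than ``min_run`` bins are treated as flicker and
    suppressed before transitions are read off.
    """
    chroms = {c.chrom for c in calls}
    if len(chroms) > 1:
        raise ValueError("call_events expects bins of a single chromosome")
    ordered = sorted(calls, key=lambda c: c.start)
    homozygous = [c for c in ordered if c.state in ("A", "B")]
    # group into runs of equal state
    runs: list[list[BinOriginCall]] = []
    for c in homozygous:
        if runs and runs[-1][-1].state == c.state:
            runs[-1].append(c)
        else:
            runs.append([c])
    runs = [r for r in runs if len(r) >= min_run]
    # merge adjacent same-state runs re-exposed by suppression
    merged: list[list[BinOriginCall]] = []
    for r in runs:
        if merged and merged[-1][-1].state == r[0].state:
            merged[-1].extend(r)
        else:
            merged.append(r)
    events = []
    for left, right in zip(merged, merged[1:]):
        events.append(
            RecombinationEvent(
                isolate=isolate,
                chrom=left[-1].chrom,
                left_state=left[-1].state,
                right_state=right[0].state,
                start=left[-1].end,
                end=right[0].start,
            )
        )
    return events


def aggregate_sites(
    events: Sequence[RecombinationEvent],
    merge_distance: int = 10,
) -> list[RecombinationSite]:
    """Merge events across isolates into recombination sites.

    Events on one chromosome whose breakpoint intervals overlap or lie
    within ``merge_distance`` bp of each other share a site.  The default
    keeps sites separated by 15 bp (as observed between the two closest
    sites in the study) distinct.  A site is a hotspot when at least four
    distinct isolates recombined there.
    """
    by_chrom: dict[str, list[RecombinationEvent]] = {}
    for e in events:
        by_chrom.setdefault(e.chrom, []).append(e)
    sites = []
    for chrom in sorted(by_chrom):
        evs = sorted(by_chrom[chrom], key=lambda e: (e.start, e.end))
        cluster: list[RecombinationEvent] = []
        cluster_end = None
        for e in evs:
            if cluster and gap_between(cluster_end, e.start) > merge_distance:
                sites.append(_site_from(cluster))
                cluster = []
                cluster_end = None
            cluster.append(e)
            cluster_end = max(cluster_end or e.end, e.end)
        if cluster:
            sites.append(_site_from(cluster))
    return sites


def _site_from(cluster: Sequence[RecombinationEvent]) -> RecombinationSite:
    return RecombinationSite(
        chrom=cluster[0].chrom,
        start=min(e.start for e in cluster),
        end=max(e.end for e in cluster),
        n_isolates=len({e.isolate for e in cluster}),
        n_events=len(cluster),
    )


def origin_fraction(calls: Sequence[BinOriginCall]) -> tuple[float, float, float]:
    """Length-weighted origin percentages (A, B, HET) over informative bins.

    Only informative non-NA bins contribute; percentages sum to 100 within
    rounding.  Raises when no bin is informative.
    """
    usable = [c for c in calls if c.informative and c.state != "NA"]
    total = sum(c.length for c in usable)
    if total == 0:
        raise ValueError("no informative bins with a non-NA call")
    pct = {}
    for state in ("A", "B", "HET"):
        pct[state] = 100.0 * sum(c.length for c in usable if c.state == state) / total
    return pct["A"], pct["B"], pct["HET"]
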