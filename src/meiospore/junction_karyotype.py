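"""Novel-junction detection, new-chromosome reconstruction, and karyotyping.

A new chromosome in a monospore isolate announces itself three ways: a step
in normalized read depth at each component boundary, reads spanning the
novel join, and *zero* reads crossing the broken reference adjacency at
either break site.  This module finds depth inflection points, validates
candidate junctions against spanning-read evidence, reconstructs the joined
chromosome model (with reverse-complement joins, inherited telomere caps and
centromere state), assigns the isolate's genome architecture from
breakpoint-spanning evidence, and types aneuploidy:

* Type I   — one extra acentric Chr12B;
* Type II  — one extra ChrN1 (Chr01B prefix + Chr12B prefix, reverse
  complement join);
* Type III — one extra ChrN2 (Chr05B prefix + Chr12B prefix RC);
* Type IV  — two extras, Chr12B and ChrN1;
atop the 11-chromosome A-architecture base.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .coords import overlap_length
from .genome_model import (
    Chromosome,
    HaplotypeGenome,
    OrientedSegment,
    reverse_complement,
)

__all__ = [
    "ArchitectureCall",
    "JunctionEvidence",
    "KaryotypeCall",
    "NewChromosomeModel",
    "assign_architecture",
    "find_depth_inflections",
    "reconstruct_new_chromosome",
    "type_aneuploidy",
    "validate_junction",
]


@dataclass(frozen=True)
class JunctionEvidence:
    """Read evidence for one candidate junction between two break sites."""

    chrom_x: str
    pos_x: int
    side_x: Literal["start", "end"]
    chrom_y: str
    pos_y: int
    side_y: Literal["start", "end"]
    support_reads: int
    reference_span_x: int  # reads crossing the unbroken reference at site X
    reference_span_y: int

    def __post_init__(self) -> None:
        if min(self.support_reads, self.reference_span_x, self.reference_span_y) < 0:
            raise ValueError("read counts must be >= 0")


@dataclass
class NewChromosomeModel:
    """A reconstructed chromosome: ordered oriented segments plus annotations."""

    name: str
    segments: tuple[OrientedSegment, ...]
    telomere_5p: bool
    telomere_3p: bool
    has_centromere: bool
    gene_count: Optional[int] = None
    essential_count: Optional[int] = None
    sequence: Optional[str] = None

    @property
    def length(self) -> int:
        return sum(s.length for s in self.segments)

    @property
    def stable(self) -> bool:
        return self.telomere_5p and self.telomere_3p


@dataclass
class KaryotypeCall:
    """Chromosome complement call for one isolate."""

    isolate: str
    n_chromosomes: int
    architecture: str
    extras: tuple[str, ...]
    aneuploidy_type: str  # euploid | I | II | III | IV | other


@dataclass
class ArchitectureCall:
    architecture: str  # A | B | unresolved
    per_breakpoint: pd.DataFrame  # breakpoint, reads_a, reads_b, state


# ---------------------------------------------------------------------------


def _trimmed_mean(values: np.ndarray, trim: float = 0.1) -> float:
    v = np.sort(np.asarray(values, dtype=float))
    k = int(len(v) * trim)
    if k > 0:
        v = v[k : len(v) - k]
    return float(v.mean())


def find_depth_inflections(
    ratios: Sequence[float],
    min_step: float = 0.4,
    flank: int = 5,
    trim: float = 0.1,
) -> list[tuple[int, float]]:
    """Depth-step breakpoint candidates along one chromosome.

    ``ratios`` are normalized depths of consecutive windows.  At every
    interior window boundary ``k`` (between windows ``k-1`` and ``k``) the
    trimmed means of the ``flank`` windows on each side are compared; a
    candidate is reported where the step magnitude exceeds ``min_step`` and
    is a local maximum within ``flank`` boundaries.  Returns
    ``[(boundary_index, step), ...]``; the bp position is the shared edge of
    windows ``k-1`` and ``k`` in the caller's window table.
    """
    r = np.asarray(ratios, dtype=float)
    n = len(r)
    if n < 2 * flank:
        raise ValueError(f"need at least {2 * flank} windows, got {n}")
    steps = np.zeros(n + 1)
    for k in range(flank, n - flank + 1):
        steps[k] = _trimmed_mean(r[k : k + flank], trim) - _trimmed_mean(r[k - flank : k], trim)
    out = []
    for k in range(flank, n - flank + 1):
        mag = abs(steps[k])
        if mag <= min_step:
            continue
        lo, hi = max(0, k - flank), min(n + 1, k + flank + 1)
        window = np.abs(steps[lo:hi])
        if mag >= window.max() and k - lo == int(np.argmax(window)):
            out.append((k, float(steps[k])))
    return out


def validate_junction(
    evidence: JunctionEvidence,
    min_support: int = 3,
    max_ref_span: int = 0,
) -> bool:
    """Accept a junction iff it is well supported *and* the reference is broken.

    The default ``max_ref_span=0`` encodes the observation that no reads
    cross a truly broken site; relax for noisy data.
    """
    return (
        evidence.support_reads >= min_support
        and evidence.reference_span_x <= max_ref_span
        and evidence.reference_span_y <= max_ref_span
    )


def _chromosome_registry(
    genomes: Sequence[HaplotypeGenome],
) -> dict[str, tuple[HaplotypeGenome, Chromosome]]:
    reg: dict[str, tuple[HaplotypeGenome, Chromosome]] = {}
    for g in genomes:
        for c in g.chromosomes:
            reg[c.id] = (g, c)
    return reg


def reconstruct_new_chromosome(
    name: str,
    segments: Sequence[OrientedSegment],
    genomes: Sequence[HaplotypeGenome],
    with_sequence: bool = False,
) -> NewChromosomeModel:
    """Build the model of a validated junction's product chromosome.

    Segments are listed in join order; a ``-`` segment contributes its
    reverse complement.  Telomere flags are looked up from the source
    chromosome ends the outer segments expose; centromere state and
    gene/essential counts come from track overlap.  Lengths follow 1-based
    inclusive arithmetic exactly.
    """
    if not segments:
        raise ValueError("at least one segment required")
    reg = _chromosome_registry(genomes)
    for seg in segments:
        if seg.chrom not in reg:
            raise ValueError(f"unknown chromosome {seg.chrom}")
        if seg.end > reg[seg.chrom][1].length:
            raise ValueError(f"segment {seg} exceeds {seg.chrom} length")

    def outer_telomere(seg: OrientedSegment, product_end: Literal["5p", "3p"]) -> bool:
        _, chrom = reg[seg.chrom]
        # which source end is exposed at this product end
        exposes_start = (product_end == "5p") == (seg.orient == "+")
        if exposes_start:
            return seg.start == 1 and chrom.telomere_5p
        return seg.end == chrom.length and chrom.telomere_3p

    has_cen = False
    gene_count = 0
    essential_count = 0
    have_tracks = False
    seq_parts: list[str] = []
    for seg in segments:
        genome, chrom = reg[seg.chrom]
        if chrom.centromere is not None:
            cs, ce = chrom.centromere
            if seg.start <= cs and ce <= seg.end:
                has_cen = True
        if genome.tracks:
            have_tracks = True
            gene_count += len(genome.features_in("genes", seg))
            essential_count += len(genome.features_in("essential_genes", seg))
        if with_sequence:
            if chrom.sequence is None:
                raise ValueError(f"{seg.chrom}: no sequence available for reconstruction")
            sub = chrom.sequence[seg.start - 1 : seg.end]
            seq_parts.append(reverse_complement(sub) if seg.orient == "-" else sub)

    return NewChromosomeModel(
        name=name,
        segments=tuple(segments),
        telomere_5p=outer_telomere(segments[0], "5p"),
        telomere_3p=outer_telomere(segments[-1], "3p"),
        has_centromere=has_cen,
        gene_count=gene_count if have_tracks else None,
        essential_count=essential_count if have_tracks else None,
        sequence="".join(seq_parts) if with_sequence else None,
    )


# ---------------------------------------------------------------------------


def assign_architecture(
    breakpoint_evidence: pd.DataFrame,
    min_reads: int = 3,
) -> ArchitectureCall:
    """Call genome architecture from spanning reads at the structural-variant
    breakpoints that distinguish the A and B chromosome arrangements.

    ``breakpoint_evidence`` has columns ``breakpoint``, ``reads_a``,
    ``reads_b`` (spanning-read counts supporting each arrangement).  A
    breakpoint is informative when its winning arrangement has at least
    ``min_reads`` support and strictly outvotes the other.  The call is
    ``A`` (resp. ``B``) when every informative breakpoint supports that
    arrangement and at least one is informative; anything mixed or
    under-covered is ``unresolved``.
    """
    df = breakpoint_evidence.copy()
    states = []
    for _, row in df.iterrows():
        a, b = int(row["reads_a"]), int(row["reads_b"])
        if a >= min_reads and a > b:
            states.append("A")
        elif b >= min_reads and b > a:
            states.append("B")
        else:
            states.append("uninformative")
    df["state"] = states
    informative = [s for s in states if s != "uninformative"]
    if informative and all(s == "A" for s in informative):
        call = "A"
    elif informative and all(s == "B" for s in informative):
        call = "B"
    else:
        call = "unresolved"
    return ArchitectureCall(architecture=call, per_breakpoint=df)


_TYPE_CATALOG: dict[frozenset[str], str] = {
    frozenset(): "euploid",
    frozenset({"Chr12B"}): "I",
    frozenset({"ChrN1"}): "II",
    frozenset({"ChrN2"}): "III",
    frozenset({"Chr12B", "ChrN1"}): "IV",
}

_BASE_CHROMOSOMES = {"A": 11, "B": 12, "unresolved": 11}


def type_aneuploidy(
    extras: Sequence[str],
    architecture: str,
    isolate: str = "",
    base_chromosomes: Optional[Mapping[str, int]] = None,
) -> KaryotypeCall:
    """Deterministic aneuploidy typing from the extra-chromosome set.

    A pure total function: every extras set maps to exactly one type; sets
    outside the catalog map to ``other``, never to I-IV.  The chromosome
    count is the architecture's base count plus the number of extras.
    """
    base = dict(_BASE_CHROMOSOMES)
    if base_chromosomes:
        base.update(base_chromosomes)
    extra_set = frozenset(extras)
    typ = _TYPE_CATALOG.get(extra_set, "other")
    return KaryotypeCall(
        isolate=isolate,
        n_chromosomes=base.get(architecture, base["unresolved"]) + len(extra_set),
        architecture=architecture,
        extras=tuple(sorted(extra_set)),
        aneuploidy_type=typ,
    )
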