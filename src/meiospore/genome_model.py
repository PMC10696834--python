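"""Core data model for phased dikaryotic genomes and sequence-feature rules.

A dikaryotic fungal cell carries two haploid nuclei; after phasing, each
nucleus is represented here as a :class:`HaplotypeGenome` (labelled ``A`` or
``B``) holding named chromosomes with sequence, telomere state, an optional
centromere interval, and feature tracks (genes, essential genes, repeats,
marker LTR families).

The module also implements the sequence-level classification rules used
throughout the analysis:

* telomere detection — tandem ``TTA(G)3-5`` repeats anchored at a chromosome
  end (reverse complement ``(C)3-5 TAA`` at the 5' end);
* the "two-speed genome" core/accessory classifier (gene density, repeat
  content, essential-gene absence);
* tandem-array copy number from a depth ratio (rDNA-style estimates);
* haplotype assignment of low-heterozygosity chromosomes from the copy
  numbers of two haplotype-biased LTR marker families.

Coordinates on all public types are 1-based inclusive (see
:mod:`meiospore.coords`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, NamedTuple, Optional

from .coords import interval_length, overlap_length

__all__ = [
    "Chromosome",
    "Feature",
    "HaplotypeGenome",
    "HomologyBlock",
    "OrientedSegment",
    "RegionFeatureSummary",
    "ClassificationThresholds",
    "assign_haplotype_by_ltr_bias",
    "classify_region",
    "detect_telomere",
    "estimate_tandem_copy_number",
    "reverse_complement",
    "summarize_region",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_VALID_NUCLEOTIDES = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


class Feature(NamedTuple):
    """One interval on a track: 1-based inclusive, with a free-form name."""

    chrom: str
    start: int
    end: int
    name: str = "."

    @property
    def length(self) -> int:
        return interval_length(self.start, self.end)


@dataclass
class Chromosome:
    """A named chromosome of one haplotype.

    ``sequence`` may be ``None`` for coordinate-only work; ``length`` is then
    authoritative.  ``centromere`` is a 1-based inclusive interval or ``None``
    for acentric chromosomes (e.g. the extra Chr12B of the study genome).
    """

    id: str
    length: int
    sequence: Optional[str] = None
    centromere: Optional[tuple[int, int]] = None
    telomere_5p: bool = False
    telomere_3p: bool = False
    telomere_5p_repeats: int = 0
    telomere_3p_repeats: int = 0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.id}: length must be positive")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(f"{self.id}: sequence length != declared length")
        if self.centromere is not None:
            s, e = self.centromere
            if not (1 <= s <= e <= self.length):
                raise ValueError(f"{self.id}: centromere {self.centromere} outside [1, {self.length}]")
        if self.telomere_5p_repeats < 0 or self.telomere_3p_repeats < 0:
            raise ValueError(f"{self.id}: telomere repeat counts must be >= 0")

    @property
    def has_centromere(self) -> bool:
        return self.centromere is not None


@dataclass(frozen=True)
class OrientedSegment:
    """A 1-based inclusive interval on a chromosome with an orientation.

    ``orient`` '-' means the segment contributes its reverse complement when
    placed into a derived chromosome (the "RC" of junction notation).
    """

    chrom: str
    start: int
    end: int
    orient: Literal["+", "-"] = "+"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid segment {self.chrom}:{self.start}-{self.end}")
        if self.orient not in ("+", "-"):
            raise ValueError(f"orient must be '+' or '-', got {self.orient!r}")

    @property
    def length(self) -> int:
        return interval_length(self.start, self.end)

    def __str__(self) -> str:  # Chr01B:1-58690(+)
        return f"{self.chrom}:{self.start}-{self.end}({self.orient})"


@dataclass(frozen=True)
class HomologyBlock:
    """A pair of homologous segments across two chromatids, with % identity.

    The pairing substrate of the meiosis model: chromosomes pair wherever a
    block links them.  Segment lengths must agree within ``length_ratio_tol``
    (homologous alignments, not arbitrary joins).
    """

    seg_a: OrientedSegment
    seg_b: OrientedSegment
    identity: float = 1.0
    length_ratio_tol: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"identity {self.identity} outside [0, 1]")
        la, lb = self.seg_a.length, self.seg_b.length
        if min(la, lb) < (1.0 - self.length_ratio_tol) * max(la, lb):
            raise ValueError(
                f"block segment lengths {la} and {lb} differ beyond tolerance {self.length_ratio_tol}"
            )

    @property
    def chromatids(self) -> tuple[str, str]:
        return self.seg_a.chrom, self.seg_b.chrom


@dataclass(frozen=True)
class RegionFeatureSummary:
    """Per-region feature statistics feeding the core/accessory classifier."""

    region: OrientedSegment
    gene_density: float  # genes per 10 kb
    repeat_pct: float  # % of bases repeat-masked
    essential_count: int
    gc_pct: float = 50.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.repeat_pct <= 100.0:
            raise ValueError(f"repeat_pct {self.repeat_pct} outside [0, 100]")
        if not 0.0 <= self.gc_pct <= 100.0:
            raise ValueError(f"gc_pct {self.gc_pct} outside [0, 100]")
        if self.essential_count < 0 or self.gene_density < 0:
            raise ValueError("counts and densities must be >= 0")


@dataclass
class HaplotypeGenome:
    """One nucleus of the dikaryon: ordered chromosomes plus feature tracks.

    Tracks are named lists of :class:`Feature`; the conventional names used by
    this package are ``genes``, ``essential_genes``, ``repeats``,
    ``ltr_famA`` and ``ltr_famB``.  ``essential_genes`` must be a subset (by
    name) of ``genes`` when both are present.
    """

    label: Literal["A", "B"]
    chromosomes: list[Chromosome] = field(default_factory=list)
    tracks: dict[str, list[Feature]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [c.id for c in self.chromosomes]
        if len(ids) != len(set(ids)):
            raise ValueError(f"haplotype {self.label}: duplicate chromosome ids")
        by_id = {c.id: c for c in self.chromosomes}
        for track_name, feats in self.tracks.items():
            for f in feats:
                chrom = by_id.get(f.chrom)
                if chrom is None:
                    raise ValueError(f"track {track_name}: unknown chromosome {f.chrom}")
                if not (1 <= f.start <= f.end <= chrom.length):
                    raise ValueError(
                        f"track {track_name}: {f.chrom}:{f.start}-{f.end} outside [1, {chrom.length}]"
                    )
        genes = self.tracks.get("genes")
        essentials = self.tracks.get("essential_genes")
        if genes is not None and essentials is not None:
            gene_keys = {(g.chrom, g.start, g.end) for g in genes}
            for e in essentials:
                if (e.chrom, e.start, e.end) not in gene_keys:
                    raise ValueError(f"essential gene {e} is not in the genes track")

    def chromosome(self, chrom_id: str) -> Chromosome:
        for c in self.chromosomes:
            if c.id == chrom_id:
                return c
        raise KeyError(f"no chromosome {chrom_id} in haplotype {self.label}")

    @property
    def chromosome_ids(self) -> list[str]:
        return [c.id for c in self.chromosomes]

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes)

    def track(self, name: str) -> list[Feature]:
        return self.tracks.get(name, [])

    def features_in(self, track_name: str, region: OrientedSegment) -> list[Feature]:
        """Track features overlapping ``region`` by at least 1 bp."""
        return [
            f
            for f in self.track(track_name)
            if f.chrom == region.chrom and overlap_length(f.start, f.end, region.start, region.end) > 0
        ]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

# Telomere motif family: TTA followed by 3-5 G at the 3' end; its reverse
# complement (3-5 C followed by TAA) anchors the 5' end.  Longer variants are
# tried first so a G-run is consumed by a single copy, never split.
_MOTIFS_3P = tuple("TTA" + "G" * g for g in (5, 4, 3))
_MOTIFS_5P = tuple("C" * g + "TAA" for g in (5, 4, 3))


def detect_telomere(
    end_sequence: str, which_end: Literal["5p", "3p"], min_repeats: int = 10
) -> tuple[bool, int]:
    """Count tandem telomere-motif copies anchored at a chromosome end.

    Returns ``(present, repeat_count)`` where ``repeat_count`` is the maximal
    run of tandem motif copies (G-run length free to vary 3-5 between copies)
    touching the given end, and ``present`` is ``repeat_count >= min_repeats``.

    ``N`` counts as non-matching; any character outside ``ACGTN`` is rejected.
    """
    if not end_sequence:
        raise ValueError("empty sequence")
    s = end_sequence.upper()
    bad = set(s) - _VALID_NUCLEOTIDES
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    count = 0
    if which_end == "3p":
        i = len(s)
        while True:
            for m in _MOTIFS_3P:
                if i >= len(m) and s[i - len(m) : i] == m:
                    i -= len(m)
                    count += 1
                    break
            else:
                break
    elif which_end == "5p":
        i = 0
        while True:
            for m in _MOTIFS_5P:
                if s.startswith(m, i):
                    i += len(m)
                    count += 1
                    break
            else:
                break
    else:
        raise ValueError(f"which_end must be '5p' or '3p', got {which_end!r}")
    return count >= min_repeats, count


@dataclass(frozen=True)
class ClassificationThresholds:
    """Cutoffs for the two-speed core/accessory classifier.

    Accessory regions in this genome have gene density below ~2.4 per 10 kb
    against >= 2.7 for core regions, and repeat content above 50% against
    <= 25.1% for core; the defaults sit between the two groups.  Absence of
    essential (single-copy ortholog) genes is mandatory — it is the most
    discriminative signal.
    """

    max_gene_density: float = 2.4  # genes per 10 kb, accessory strictly below
    min_repeat_pct: float = 40.0  # % repeat-masked, accessory strictly above


def classify_region(
    summary: RegionFeatureSummary,
    thresholds: ClassificationThresholds | None = None,
) -> Literal["core", "accessory"]:
    """Classify a region as ``core`` or ``accessory`` (two-speed genome rule).

    Accessory requires all three: gene density below the cutoff, repeat
    content above the cutoff, and zero essential genes.
    """
    t = thresholds or ClassificationThresholds()
    accessory = (
        summary.gene_density < t.max_gene_density
        and summary.repeat_pct > t.min_repeat_pct
        and summary.essential_count == 0
    )
    return "accessory" if accessory else "core"


def summarize_region(genome: HaplotypeGenome, region: OrientedSegment) -> RegionFeatureSummary:
    """Compute the classifier inputs for ``region`` from the genome's tracks."""
    genes = genome.features_in("genes", region)
    essentials = genome.features_in("essential_genes", region)
    repeats = genome.features_in("repeats", region)
    repeat_bases = sum(
        overlap_length(f.start, f.end, region.start, region.end) for f in repeats
    )
    gc_pct = 50.0
    chrom = genome.chromosome(region.chrom)
    if chrom.sequence is not None:
        sub = chrom.sequence[region.start - 1 : region.end].upper()
        if sub:
            gc_pct = 100.0 * (sub.count("G") + sub.count("C")) / len(sub)
    return RegionFeatureSummary(
        region=region,
        gene_density=len(genes) / (region.length / 10_000),
        repeat_pct=100.0 * repeat_bases / region.length,
        essential_count=len(essentials),
        gc_pct=gc_pct,
    )


def estimate_tandem_copy_number(
    probe_mean_depth: float, background_single_copy_depth: float
) -> float:
    """Copy number of a tandem array as a sequencing-depth ratio.

    The mean depth over a probe fragment drawn from the repeat unit, divided
    by the depth of single-copy background sequence, estimates the number of
    tandem copies (the rDNA-unit estimator).
    """
    if background_single_copy_depth <= 0:
        raise ValueError("background single-copy depth must be > 0")
    if probe_mean_depth < 0:
        raise ValueError("probe depth must be >= 0")
    return probe_mean_depth / background_single_copy_depth


def assign_haplotype_by_ltr_bias(
    count_marker_a: int,
    count_marker_b: int,
    min_fold: float = 3.0,
    min_count: int = 3,
) -> Literal["A", "B", "unresolved"]:
    """Assign a low-heterozygosity chromosome to a haplotype by LTR-family bias.

    Two species-specific LTR families are strongly biased to one nucleus each
    (in the study genome, 181 full-length copies of the A-biased family vs 4
    of the B-biased one in haplotype A, and 221 B-biased copies in haplotype
    B).  A chromosome is assigned ``A`` when the A-family count is at least
    ``min_count`` and at least ``min_fold`` times the B-family count;
    symmetrically for ``B``; otherwise ``unresolved``.
    """
    if count_marker_a < 0 or count_marker_b < 0:
        raise ValueError("marker counts must be >= 0")
    if count_marker_a >= min_count and count_marker_a >= min_fold * count_marker_b:
        return "A"
    if count_marker_b >= min_count and count_marker_b >= min_fold * count_marker_a:
        return "B"
    return "unresolved"
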