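"""Synthetic asymmetric dikaryon generator and sequencing-evidence simulator.

Generates a reduced-scale dikaryotic genome with the structural features of
the study system, together with full ground truth, so every downstream
stage is testable without any download:

* gradient heterozygosity — each 10-kb bin of the A reference frame is
  assigned a SNP-density class from a mosaic (about a fifth of bins
  near-identical, a fifth above 4% divergence, the rest spread between);
* three accessory chromosomes and two accessory compartments per haplotype
  (high repeat content, low gene density, no essential genes);
* a cyclic "architecture cassette" translocation among Chr01/Chr02/Chr05,
  so each cassette of essential content sits on one A chromosome and a
  *different* B chromosome — the source of architecture-dependent
  viability;
* one haplotype-B extra chromosome (Chr12B) that is centromere-free, mostly
  homologous to the right arm of Chr05A, and starts with a B-specific
  orphan terminal segment; Chr01B likewise begins with an orphan segment;
* telomere caps on every chromosome end and two haplotype-biased LTR
  marker families.

Evidence simulation mirrors the study's two read-mapping pipelines:
diagnostic-allele bin counts are mapped onto the haplotype-A frame, while
window depths are simulated on a combined reference (A chromosomes plus
B-specific contigs).  Depth is Poisson per window; allele counts are
Poisson totals with a binomial split at the configured allele error rate;
junction support appears only for joins the genotype actually carries, with
reference-spanning counts at broken sites reflecting intact copies only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .coords import overlap_length
from .genome_model import (
    Chromosome,
    Feature,
    HaplotypeGenome,
    HomologyBlock,
    OrientedSegment,
)
from .meiosis_sim import (
    AcentricSpec,
    ChromosomeModel,
    EssentialUnit,
    JunctionRule,
    MeiosisModel,
    SporeGenotype,
    whole_chromosome_model,
)

__all__ = [
    "DikaryonConfig",
    "DikaryonTruth",
    "EvidenceSet",
    "architecture_genotype",
    "eligible_switch_boundaries",
    "generate_dikaryon",
    "meiosis_model_from_truth",
    "recombinant_genotype",
    "simulate_evidence",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def _default_mosaic() -> list[tuple[float, float]]:
    # (fraction of bins, SNP density per bp); fractions follow the observed
    # bin-divergence spectrum: ~22% near-identical, ~15% in each 1%-wide
    # class from 0.1-1% to 3-4%, ~19% above 4%.
    return [
        (0.218, 0.0005),
        (0.150, 0.005),
        (0.150, 0.015),
        (0.147, 0.025),
        (0.150, 0.035),
        (0.185, 0.05),
    ]


@dataclass
class DikaryonConfig:
    """Reduced-scale study-like dikaryon.  Defaults are the test conditions.

    Chromosome lengths are scaled down (core 0.3-0.5 Mb) so a full generate/
    simulate/analyse cycle runs in seconds while keeping every structural
    feature; all lengths are multiples of ``bin_size``.
    """

    core_lengths: dict[str, int] = field(
        default_factory=lambda: {
            "Chr01": 500_000,
            "Chr02": 400_000,
            "Chr03": 300_000,
            "Chr04": 300_000,
            "Chr05": 450_000,
        }
    )
    accessory_lengths: dict[str, int] = field(
        default_factory=lambda: {"Chr09": 80_000, "Chr10": 70_000, "Chr11": 60_000}
    )
    accessory_compartments: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"Chr04": (1, 60_000), "Chr05": (1, 50_000)}
    )
    low_het_chromosomes: tuple[str, ...] = ("Chr04", "Chr09", "Chr10", "Chr11")
    heterozygosity_mosaic: list[tuple[float, float]] = field(default_factory=_default_mosaic)
    bin_size: int = 10_000
    informative_min_density: float = 0.01  # heterozygous-bin threshold (SNPs/bp)

    # architecture cassettes: same-length content blocks translocated in a
    # cycle Chr01 -> Chr02 -> Chr05 between the two haplotypes
    architecture_cassettes: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "Chr01": (200_001, 240_000),
            "Chr02": (150_001, 190_000),
            "Chr05": (100_001, 140_000),
        }
    )
    cassette_cycle: tuple[str, ...] = ("Chr01", "Chr02", "Chr05")

    acentric_extra: bool = True
    extra_chrom_id: str = "Chr12B"
    acentric_donor_arm: tuple[str, int, int] = ("Chr05", 330_001, 450_000)
    extra_orphan_length: int = 30_000
    orphan_prefixes: dict[str, int] = field(default_factory=lambda: {"Chr01": 20_000})

    junction_probability: float = 0.05
    chrn2_positions: tuple[int, int] = (200_000, 90_000)  # (Chr05B prefix, Chr12B prefix)

    ltr_counts: dict[str, dict[str, int]] = field(
        default_factory=lambda: {
            "A": {"ltr_famA": 60, "ltr_famB": 2},
            "B": {"ltr_famA": 2, "ltr_famB": 70},
        }
    )
    telomere_repeats: int = 25
    gene_length: int = 1_000
    gene_density_core: float = 3.0  # per 10 kb
    gene_density_accessory: float = 1.5
    repeat_unit: int = 500
    repeat_frac_core: float = 0.18
    repeat_frac_accessory: float = 0.60
    essential_shared_per_chrom: int = 4
    emit_sequence: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        frac = sum(f for f, _ in self.heterozygosity_mosaic)
        if abs(frac - 1.0) > 1e-9:
            raise ValueError(f"mosaic fractions sum to {frac}, expected 1")
        if any(d < 0 for _, d in self.heterozygosity_mosaic):
            raise ValueError("mosaic densities must be >= 0")
        for name, length in {**self.core_lengths, **self.accessory_lengths}.items():
            if length <= 0:
                raise ValueError(f"{name}: length must be positive")
        for chrom, olen in self.orphan_prefixes.items():
            if chrom not in self.core_lengths or olen >= self.core_lengths[chrom]:
                raise ValueError(f"orphan prefix on {chrom} exceeds chromosome length")
        donor, s, e = self.acentric_donor_arm
        if self.acentric_extra:
            if donor not in self.core_lengths or e != self.core_lengths[donor]:
                raise ValueError("acentric donor arm must be a terminal suffix of its donor")
            if self.extra_orphan_length <= 0:
                raise ValueError("extra orphan length must be positive")
        for chrom, (cs, ce) in self.architecture_cassettes.items():
            if chrom not in self.core_lengths or ce > self.core_lengths[chrom]:
                raise ValueError(f"cassette on {chrom} outside chromosome")
        lengths = {ce - cs + 1 for cs, ce in self.architecture_cassettes.values()}
        if len(lengths) > 1:
            raise ValueError("architecture cassettes must share one length")

    @property
    def aframe_lengths(self) -> dict[str, int]:
        return {**self.core_lengths, **self.accessory_lengths}

    @property
    def extra_length(self) -> int:
        _, s, e = self.acentric_donor_arm
        return self.extra_orphan_length + (e - s + 1)


# ---------------------------------------------------------------------------
# truth container
# ---------------------------------------------------------------------------


@dataclass
class DikaryonTruth:
    """Everything planted by the generator, for downstream verification."""

    config: DikaryonConfig
    bins: pd.DataFrame  # chrom(A id), start, end, density, n_snps, informative, has_homolog
    snps: pd.DataFrame  # chrom(A id), pos, ref, alt
    homology: list[HomologyBlock]
    accessory_regions: dict[str, list[OrientedSegment]]
    orphan_regions: list[OrientedSegment]
    junction_rules: list[JunctionRule]
    essential_units: list[EssentialUnit]
    chromosomes: dict[str, ChromosomeModel]  # parental registry, both haplotypes

    def aframe_bins(self, chrom: Optional[str] = None) -> pd.DataFrame:
        if chrom is None:
            return self.bins
        return self.bins[self.bins["chrom"] == chrom].reset_index(drop=True)

    def map_to_aframe(self, chrom: str, start: int, end: int) -> list[tuple[str, int, int]]:
        """Map a source interval onto the haplotype-A reference frame.

        A chromatids map identically; B intervals map through the homology
        blocks (identity within a block); B-specific content (orphans) maps
        nowhere and is dropped.
        """
        if chrom.endswith("A"):
            return [(chrom, start, end)]
        out = []
        for b in self.homology:
            if b.seg_b.chrom != chrom:
                continue
            ov = overlap_length(b.seg_b.start, b.seg_b.end, start, end)
            if ov <= 0:
                continue
            lo = max(start, b.seg_b.start)
            hi = min(end, b.seg_b.end)
            shift = b.seg_a.start - b.seg_b.start
            out.append((b.seg_a.chrom, lo + shift, hi + shift))
        return out

    def depth_references(self) -> dict[str, int]:
        """The combined depth reference: A chromosomes, B orphan contigs, and
        the extra acentric chromosome as its own contig."""
        refs = {f"{c}A": l for c, l in self.config.aframe_lengths.items()}
        for chrom, olen in self.config.orphan_prefixes.items():
            refs[f"{chrom}B"] = olen
        if self.config.acentric_extra:
            refs[self.config.extra_chrom_id] = self.config.extra_length
        return refs

    def map_to_depth_ref(self, chrom: str, start: int, end: int) -> list[tuple[str, int, int]]:
        """Map a source interval onto the combined depth reference."""
        if chrom.endswith("A"):
            return [(chrom, start, end)]
        if chrom == self.config.extra_chrom_id:
            return [(chrom, start, end)]
        base = chrom[:-1]
        pieces: list[tuple[str, int, int]] = []
        orphan = self.config.orphan_prefixes.get(base)
        if orphan is not None and start <= orphan:
            pieces.append((chrom, start, min(end, orphan)))
        lo = start if orphan is None else max(start, orphan + 1)
        if lo <= end:
            pieces.extend(self.map_to_aframe(chrom, lo, end))
        return pieces

    def crossing_copies(self, models: Sequence[tuple[ChromosomeModel, float]], chrom: str, pos: int) -> float:
        """Weighted copies whose segments span the reference adjacency
        (pos, pos+1) on a source chromosome."""
        total = 0.0
        for m, w in models:
            for seg in m.segments:
                if seg.chrom == chrom and seg.start <= pos and pos + 1 <= seg.end:
                    total += w
        return total


# ---------------------------------------------------------------------------
# generator internals
# ---------------------------------------------------------------------------


def _random_sequence(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, n)]


def _cap_telomeres(seq: np.ndarray, repeats: int) -> np.ndarray:
    cap5 = np.frombuffer(b"CCCTAA" * repeats, dtype=np.uint8)
    cap3 = np.frombuffer(b"TTAGGG" * repeats, dtype=np.uint8)
    if len(seq) < len(cap5) + len(cap3):
        raise ValueError("chromosome too short for telomere caps")
    seq = seq.copy()
    seq[: len(cap5)] = cap5
    seq[-len(cap3) :] = cap3
    return seq


def _regions_of(cfg: DikaryonConfig, chrom: str, length: int) -> list[tuple[int, int, str]]:
    """(start, end, kind) partition of an A-frame chromosome, kind in
    {core, accessory}."""
    if chrom in cfg.accessory_lengths:
        return [(1, length, "accessory")]
    comp = cfg.accessory_compartments.get(chrom)
    if comp is None:
        return [(1, length, "core")]
    cs, ce = comp
    regions = []
    if cs > 1:
        regions.append((1, cs - 1, "core"))
    regions.append((cs, ce, "accessory"))
    if ce < length:
        regions.append((ce + 1, length, "core"))
    return regions


def _place_genes(
    cfg: DikaryonConfig, chrom: str, length: int, density_map: dict[str, float]
) -> list[Feature]:
    feats = []
    for rs, re_, kind in _regions_of(cfg, chrom, length):
        density = density_map[kind]
        n = int(round((re_ - rs + 1) / 10_000 * density))
        if n <= 0:
            continue
        span = re_ - rs + 1 - cfg.gene_length
        if span <= 0:
            continue
        starts = np.unique((rs + np.linspace(0, span, n)).astype(int))
        for i, s in enumerate(starts):
            feats.append(Feature(chrom, int(s), int(s) + cfg.gene_length - 1, f"g_{chrom}_{i}"))
    return feats


def _place_repeats(cfg: DikaryonConfig, chrom: str, length: int) -> list[Feature]:
    feats = []
    for rs, re_, kind in _regions_of(cfg, chrom, length):
        frac = cfg.repeat_frac_accessory if kind == "accessory" else cfg.repeat_frac_core
        period = max(cfg.repeat_unit + 1, int(round(cfg.repeat_unit / frac)))
        for s in range(rs, re_ - cfg.repeat_unit + 1, period):
            feats.append(Feature(chrom, s, s + cfg.repeat_unit - 1, "rep"))
    return feats


def _excluded_zones(cfg: DikaryonConfig, chrom: str) -> list[tuple[int, int]]:
    zones = []
    if chrom in cfg.orphan_prefixes:
        zones.append((1, cfg.orphan_prefixes[chrom]))
    if chrom in cfg.architecture_cassettes:
        zones.append(cfg.architecture_cassettes[chrom])
    donor, s, e = cfg.acentric_donor_arm
    if cfg.acentric_extra and chrom == donor:
        zones.append((s, e))
    comp = cfg.accessory_compartments.get(chrom)
    if comp:
        zones.append(comp)
    return sorted(zones)


def _largest_free_interval(length: int, zones: list[tuple[int, int]], margin: int) -> tuple[int, int]:
    cursor = margin + 1
    best = (cursor, cursor)
    for zs, ze in zones + [(length - margin, length)]:
        if zs - 1 >= cursor and (zs - 1 - cursor) > (best[1] - best[0]):
            best = (cursor, zs - 1)
        cursor = max(cursor, ze + 1)
    return best


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------


def generate_dikaryon(
    config: Optional[DikaryonConfig] = None,
) -> tuple[HaplotypeGenome, HaplotypeGenome, DikaryonTruth]:
    """Generate the two haplotype genomes and the planted ground truth."""
    cfg = config or DikaryonConfig()
    rng = np.random.default_rng(cfg.rng_seed)
    margin = 6 * cfg.telomere_repeats + 100  # keep SNPs/features off telomere caps
    aframe = cfg.aframe_lengths
    cas_len = None
    if cfg.architecture_cassettes:
        cs, ce = next(iter(cfg.architecture_cassettes.values()))
        cas_len = ce - cs + 1

    # --- bins, density classes, SNPs ------------------------------------
    mosaic = cfg.heterozygosity_mosaic
    fractions = np.array([f for f, _ in mosaic])
    densities = np.array([d for _, d in mosaic])
    bin_rows = []
    snp_rows = []
    b_content: dict[str, np.ndarray] = {}
    a_seqs: dict[str, np.ndarray] = {}
    for chrom, length in aframe.items():
        a_id = f"{chrom}A"
        seq = None
        if cfg.emit_sequence:
            seq = _cap_telomeres(_random_sequence(rng, length), cfg.telomere_repeats)
            a_seqs[chrom] = seq
            mut = seq.copy()
        orphan = cfg.orphan_prefixes.get(chrom, 0)
        low_het = chrom in cfg.low_het_chromosomes or chrom in cfg.accessory_lengths
        comp = cfg.accessory_compartments.get(chrom)
        for start in range(1, length + 1, cfg.bin_size):
            end = min(start + cfg.bin_size - 1, length)
            has_homolog = end > orphan
            if not has_homolog:
                density = 0.0
            elif low_het or (comp and overlap_length(start, end, *comp) > 0):
                density = densities[0]
            else:
                density = float(densities[rng.choice(len(mosaic), p=fractions)])
            lo = max(start, orphan + 1, margin + 1)
            hi = min(end, length - margin)
            donor_chrom, d_arm_s, _ = cfg.acentric_donor_arm
            if cfg.acentric_extra and chrom == donor_chrom and start < d_arm_s:
                # the B copy is truncated and re-capped at the arm start; keep
                # SNPs clear of the overwritten tail
                hi = min(hi, d_arm_s - 1 - margin)
            n_target = int(round(density * (end - start + 1)))
            n_snps = 0
            if has_homolog and n_target > 0 and hi > lo:
                pos = np.sort(rng.choice(np.arange(lo, hi + 1), size=min(n_target, hi - lo + 1), replace=False))
                n_snps = len(pos)
                if cfg.emit_sequence:
                    idx = pos - 1
                    shift = rng.integers(1, 4, n_snps)
                    base_idx = np.searchsorted(_BASES, mut[idx])
                    mut[idx] = _BASES[(base_idx + shift) % 4]
                    for p, r, a in zip(pos, seq[pos - 1], mut[pos - 1]):
                        snp_rows.append((a_id, int(p), chr(r), chr(a)))
                else:
                    for p in pos:
                        snp_rows.append((a_id, int(p), "N", "N"))
            bin_rows.append(
                {
                    "chrom": a_id,
                    "start": start,
                    "end": end,
                    "density": density,
                    "n_snps": n_snps,
                    "informative": bool(has_homolog and density >= cfg.informative_min_density),
                    "has_homolog": bool(has_homolog),
                }
            )
        if cfg.emit_sequence:
            b_content[chrom] = mut

    bins = pd.DataFrame(bin_rows)
    snps = pd.DataFrame(snp_rows, columns=["chrom", "pos", "ref", "alt"])

    # --- assemble B-chromosome layouts ----------------------------------
    donor, arm_s, arm_e = cfg.acentric_donor_arm
    cycle = list(cfg.cassette_cycle)

    def cassette_source(chrom: str) -> Optional[str]:
        # which A-frame cassette content the B copy of `chrom` carries
        if chrom not in cycle or chrom not in cfg.architecture_cassettes:
            return None
        return cycle[cycle.index(chrom) - 1]

    b_seqs: dict[str, np.ndarray] = {}
    b_lengths: dict[str, int] = {}
    orphan_seqs: dict[str, np.ndarray] = {}
    for chrom, length in aframe.items():
        b_len = length
        if cfg.acentric_extra and chrom == donor:
            b_len = arm_s - 1
        b_lengths[chrom] = b_len
        if not cfg.emit_sequence:
            continue
        seq = b_content[chrom][:b_len].copy()
        src = cassette_source(chrom)
        if src is not None and src != chrom:
            cs, ce = cfg.architecture_cassettes[chrom]
            ss, se = cfg.architecture_cassettes[src]
            seq[cs - 1 : ce] = b_content[src][ss - 1 : se]
        if chrom in cfg.orphan_prefixes:
            olen = cfg.orphan_prefixes[chrom]
            orphan = _random_sequence(rng, olen)
            orphan_seqs[chrom] = orphan
            seq[:olen] = orphan
        b_seqs[chrom] = _cap_telomeres(seq, cfg.telomere_repeats)

    extra_seq = None
    if cfg.acentric_extra and cfg.emit_sequence:
        orphan = _random_sequence(rng, cfg.extra_orphan_length)
        extra_seq = _cap_telomeres(
            np.concatenate([orphan, b_content[donor][arm_s - 1 : arm_e]]), cfg.telomere_repeats
        )

    # --- centromeres and Chromosome objects ------------------------------
    def centromere_for(chrom: str, length: int) -> tuple[int, int]:
        mid = min(length // 2, aframe[chrom] // 2)
        return (mid - 2_499, mid + 2_500)

    chroms_a = []
    chroms_b = []
    for chrom, length in aframe.items():
        cen = centromere_for(chrom, length)
        chroms_a.append(
            Chromosome(
                id=f"{chrom}A",
                length=length,
                sequence=a_seqs[chrom].tobytes().decode() if cfg.emit_sequence else None,
                centromere=cen,
                telomere_5p=True,
                telomere_3p=True,
                telomere_5p_repeats=cfg.telomere_repeats,
                telomere_3p_repeats=cfg.telomere_repeats,
            )
        )
        b_len = b_lengths[chrom]
        chroms_b.append(
            Chromosome(
                id=f"{chrom}B",
                length=b_len,
                sequence=b_seqs[chrom].tobytes().decode() if cfg.emit_sequence else None,
                centromere=centromere_for(chrom, b_len),
                telomere_5p=True,
                telomere_3p=True,
                telomere_5p_repeats=cfg.telomere_repeats,
                telomere_3p_repeats=cfg.telomere_repeats,
            )
        )
    if cfg.acentric_extra:
        chroms_b.append(
            Chromosome(
                id=cfg.extra_chrom_id,
                length=cfg.extra_length,
                sequence=extra_seq.tobytes().decode() if cfg.emit_sequence else None,
                centromere=None,
                telomere_5p=True,
                telomere_3p=True,
                telomere_5p_repeats=cfg.telomere_repeats,
                telomere_3p_repeats=cfg.telomere_repeats,
            )
        )

    # --- homology map -----------------------------------------------------
    def block(a_chrom: str, a_s: int, a_e: int, b_chrom: str, b_s: int, b_e: int) -> HomologyBlock:
        sub = bins[(bins["chrom"] == a_chrom) & (bins["end"] >= a_s) & (bins["start"] <= a_e)]
        identity = 1.0 - float(sub["density"].mean()) if len(sub) else 1.0
        return HomologyBlock(
            OrientedSegment(a_chrom, a_s, a_e, "+"),
            OrientedSegment(b_chrom, b_s, b_e, "+"),
            identity=identity,
        )

    homology = []
    for chrom, length in aframe.items():
        a_id, b_id = f"{chrom}A", f"{chrom}B"
        b_len = b_lengths[chrom]
        cut_points = []
        if chrom in cfg.orphan_prefixes:
            cut_points.append((1, cfg.orphan_prefixes[chrom]))
        if chrom in cfg.architecture_cassettes and cassette_source(chrom) != chrom:
            cut_points.append(cfg.architecture_cassettes[chrom])
        if cfg.acentric_extra and chrom == donor:
            # the truncated B copy is re-capped with telomere repeats, so the
            # last cap-length of shared content no longer matches base-for-base
            cap_len = 6 * cfg.telomere_repeats
            cut_points.append((arm_s - cap_len, arm_e))
        cut_points.sort()
        cursor = 1
        for zs, ze in cut_points + [(min(length, b_len) + 1, length)]:
            if zs > cursor:
                homology.append(block(a_id, cursor, zs - 1, b_id, cursor, zs - 1))
            cursor = max(cursor, ze + 1)
    for chrom in cycle:
        src = cassette_source(chrom)
        if src is None or src == chrom:
            continue
        # B copy of `chrom` carries the cassette content of `src`
        ss, se = cfg.architecture_cassettes[src]
        cs, ce = cfg.architecture_cassettes[chrom]
        homology.append(block(f"{src}A", ss, se, f"{chrom}B", cs, ce))
    if cfg.acentric_extra:
        homology.append(
            block(
                f"{donor}A", arm_s, arm_e,
                cfg.extra_chrom_id, cfg.extra_orphan_length + 1, cfg.extra_length,
            )
        )

    # --- tracks -----------------------------------------------------------
    density_map = {"core": cfg.gene_density_core, "accessory": cfg.gene_density_accessory}

    def tracks_for(hap: str) -> dict[str, list[Feature]]:
        chrom_list = chroms_a if hap == "A" else chroms_b
        genes: list[Feature] = []
        repeats: list[Feature] = []
        for c in chrom_list:
            base = c.id[:-1] if c.id.endswith(("A", "B")) and c.id != cfg.extra_chrom_id else None
            if c.id == cfg.extra_chrom_id:
                # extra chromosome: core-like donor-arm content plus orphan
                n = int(round(c.length / 10_000 * cfg.gene_density_core))
                span = c.length - 2 * margin - cfg.gene_length
                starts = (margin + 1 + np.linspace(0, max(span, 1), max(n, 1))).astype(int)
                genes.extend(
                    Feature(c.id, int(s), int(s) + cfg.gene_length - 1, f"g_{c.id}_{i}")
                    for i, s in enumerate(np.unique(starts))
                )
                period = max(cfg.repeat_unit + 1, int(round(cfg.repeat_unit / cfg.repeat_frac_core)))
                repeats.extend(
                    Feature(c.id, s, s + cfg.repeat_unit - 1, "rep")
                    for s in range(1, c.length - cfg.repeat_unit + 1, period)
                )
                continue
            genes.extend(_place_genes(cfg, base, c.length, density_map))
            repeats.extend(_place_repeats(cfg, base, c.length))
        # re-tag features onto haplotype chromosome ids
        suffix = "A" if hap == "A" else "B"
        genes = [
            f if f.chrom == cfg.extra_chrom_id else Feature(f"{f.chrom}{suffix}", f.start, f.end, f.name)
            for f in genes
        ]
        repeats = [
            f if f.chrom == cfg.extra_chrom_id else Feature(f"{f.chrom}{suffix}", f.start, f.end, f.name)
            for f in repeats
        ]
        return {"genes": genes, "repeats": repeats}

    tracks_a = tracks_for("A")
    tracks_b = tracks_for("B")

    # --- essential units --------------------------------------------------
    units: list[EssentialUnit] = []
    glen = cfg.gene_length
    for chrom in cfg.core_lengths:
        zones = _excluded_zones(cfg, chrom)
        lo, hi = _largest_free_interval(aframe[chrom], zones, margin)
        k = cfg.essential_shared_per_chrom
        if hi - lo < (k + 1) * glen * 2:
            continue
        starts = (lo + np.linspace(0, hi - lo - glen, k)).astype(int)
        for i, s in enumerate(starts):
            units.append(
                EssentialUnit(
                    f"{chrom}_e{i}",
                    ((f"{chrom}A", int(s), int(s) + glen - 1), (f"{chrom}B", int(s), int(s) + glen - 1)),
                )
            )
    if cfg.architecture_cassettes:
        for i, chrom in enumerate(cycle):
            nxt = cycle[(i + 1) % len(cycle)]
            cs_a, _ = cfg.architecture_cassettes[chrom]
            cs_b, _ = cfg.architecture_cassettes[nxt]
            for j, off in enumerate((5_000, 15_000)):
                units.append(
                    EssentialUnit(
                        f"t_{chrom}_{j}",
                        (
                            (f"{chrom}A", cs_a + off, cs_a + off + glen - 1),
                            (f"{nxt}B", cs_b + off, cs_b + off + glen - 1),
                        ),
                    )
                )
    if cfg.acentric_extra:
        for j, off in enumerate((10_000, 50_000, 100_000)):
            if arm_s + off + glen - 1 > arm_e - margin:
                continue
            units.append(
                EssentialUnit(
                    f"arm_{j}",
                    (
                        (f"{donor}A", arm_s + off, arm_s + off + glen - 1),
                        (cfg.extra_chrom_id, cfg.extra_orphan_length + off + 1, cfg.extra_orphan_length + off + glen),
                    ),
                )
            )

    # essential genes track: every unit location, also present in `genes`
    for hap, tracks in (("A", tracks_a), ("B", tracks_b)):
        ess = []
        chrom_ids = {c.id for c in (chroms_a if hap == "A" else chroms_b)}
        for u in units:
            for chrom, s, e in u.locations:
                if chrom in chrom_ids:
                    ess.append(Feature(chrom, s, e, u.id))
        tracks["essential_genes"] = ess
        tracks["genes"] = tracks["genes"] + ess

    # --- LTR marker families ---------------------------------------------
    for hap, tracks, chrom_list in (("A", tracks_a, chroms_a), ("B", tracks_b, chroms_b)):
        lengths = np.array([c.length for c in chrom_list], dtype=float)
        probs = lengths / lengths.sum()
        for fam, count in cfg.ltr_counts[hap].items():
            fam_len = 600 if fam.endswith("A") else 1_200
            feats = []
            for _ in range(count):
                ci = rng.choice(len(chrom_list), p=probs)
                c = chrom_list[ci]
                pos = int(rng.integers(margin, max(margin + 1, c.length - fam_len - margin)))
                feats.append(Feature(c.id, pos, pos + fam_len - 1, fam))
            tracks[fam] = feats

    genome_a = HaplotypeGenome(label="A", chromosomes=chroms_a, tracks=tracks_a)
    genome_b = HaplotypeGenome(label="B", chromosomes=chroms_b, tracks=tracks_b)

    # --- junction rules and truth ----------------------------------------
    rules = []
    if cfg.acentric_extra and cfg.orphan_prefixes:
        first_orphan = next(iter(cfg.orphan_prefixes))
        rules.append(
            JunctionRule(
                "ChrN1",
                f"{first_orphan}B", cfg.orphan_prefixes[first_orphan],
                cfg.extra_chrom_id, cfg.extra_orphan_length,
                side_x="start", side_y="start",
                mechanism="terminal-pairing",
                probability=cfg.junction_probability,
            )
        )
        rules.append(
            JunctionRule(
                "ChrN2",
                f"{donor}B", cfg.chrn2_positions[0],
                cfg.extra_chrom_id, cfg.chrn2_positions[1],
                side_x="start", side_y="start",
                mechanism="internal-homologous-recombination",
                probability=cfg.junction_probability,
            )
        )

    accessory_regions = {
        hap: (
            [OrientedSegment(f"{c}{hap}", 1, l, "+") for c, l in cfg.accessory_lengths.items()]
            + [
                OrientedSegment(f"{c}{hap}", s, e, "+")
                for c, (s, e) in cfg.accessory_compartments.items()
            ]
        )
        for hap in ("A", "B")
    }
    orphan_regions = [
        OrientedSegment(f"{c}B", 1, olen, "+") for c, olen in cfg.orphan_prefixes.items()
    ]
    if cfg.acentric_extra:
        orphan_regions.append(OrientedSegment(cfg.extra_chrom_id, 1, cfg.extra_orphan_length, "+"))

    registry = {}
    for g in (genome_a, genome_b):
        for c in g.chromosomes:
            registry[c.id] = whole_chromosome_model(
                c.id, c.length, c.centromere, c.telomere_5p, c.telomere_3p
            )

    truth = DikaryonTruth(
        config=cfg,
        bins=bins,
        snps=snps,
        homology=homology,
        accessory_regions=accessory_regions,
        orphan_regions=orphan_regions,
        junction_rules=rules,
        essential_units=units,
        chromosomes=registry,
    )
    return genome_a, genome_b, truth


# ---------------------------------------------------------------------------
# genotype builders
# ---------------------------------------------------------------------------


def architecture_genotype(
    truth: DikaryonTruth,
    architecture: str = "A",
    extras: Sequence[str] = (),
    isolate_id: str = "iso",
) -> SporeGenotype:
    """A whole-chromosome spore genotype of pure A or B architecture, plus
    optional extra chromosomes (parental acentrics or derived models built
    from the truth's junction rules, by rule name)."""
    cfg = truth.config
    complement: list[tuple[ChromosomeModel, int]] = []
    for chrom in cfg.aframe_lengths:
        complement.append((truth.chromosomes[f"{chrom}{architecture}"], 1))
    if architecture == "B" and cfg.acentric_extra:
        complement.append((truth.chromosomes[cfg.extra_chrom_id], 1))
    from .meiosis_sim import assemble_junction_product

    for extra in extras:
        rule = next((r for r in truth.junction_rules if r.name == extra), None)
        if rule is not None:
            complement.append((assemble_junction_product(rule, truth.chromosomes), 1))
        else:
            complement.append((truth.chromosomes[extra], 1))
    return SporeGenotype(isolate_id=isolate_id, complement=complement, architecture=architecture)


def eligible_switch_boundaries(truth: DikaryonTruth, chrom: str) -> list[int]:
    """Bin boundaries (bp, end coordinate of the left bin) where a planted
    origin switch is observable: both flanking bins informative, identity-
    mapped (outside cassettes, orphans, the donor arm) on both haplotypes."""
    cfg = truth.config
    base = chrom[:-1] if chrom.endswith(("A", "B")) else chrom
    sub = truth.aframe_bins(f"{base}A")
    blocked: list[tuple[int, int]] = []
    if base in cfg.architecture_cassettes:
        blocked.append(cfg.architecture_cassettes[base])
    if base in cfg.orphan_prefixes:
        blocked.append((1, cfg.orphan_prefixes[base]))
    donor, arm_low, arm_high = cfg.acentric_donor_arm
    if cfg.acentric_extra and base == donor:
        blocked.append((arm_low, arm_high))
    out = []
    rows = sub.to_dict("records")
    for left, right in zip(rows, rows[1:]):
        if not (left["informative"] and right["informative"]):
            continue
        if any(
            overlap_length(left["start"], right["end"], zs, ze) > 0 for zs, ze in blocked
        ):
            continue
        out.append(left["end"])
    return out


def sample_switches(
    truth: DikaryonTruth,
    chrom: str,
    n_switches: int,
    rng: np.random.Generator,
    min_gap_bins: int = 3,
    min_informative_bins: int = 2,
    max_tries: int = 500,
) -> list[int]:
    """Random observable switch boundaries on one chromosome, constrained so
    every resulting origin run is detectable: switches at least
    ``min_gap_bins`` bins apart with at least ``min_informative_bins``
    heterozygous bins in every run (including before the first and after the
    last switch)."""
    cfg = truth.config
    boundaries = np.array(eligible_switch_boundaries(truth, chrom))
    info = truth.aframe_bins(f"{chrom}A" if not chrom.endswith(("A", "B")) else chrom)
    info = info[info["informative"]]
    length = cfg.aframe_lengths[chrom if not chrom.endswith(("A", "B")) else chrom[:-1]]

    def n_informative(lo: int, hi: int) -> int:
        return int(((info["start"] > lo) & (info["end"] <= hi)).sum())

    for n in range(min(n_switches, len(boundaries)), 0, -1):
        for _ in range(max_tries):
            cuts = sorted(int(x) for x in rng.choice(boundaries, size=n, replace=False))
            edges = [0] + cuts + [length]
            if all(b - a >= min_gap_bins * cfg.bin_size for a, b in zip(cuts, cuts[1:])) and all(
                n_informative(lo, hi) >= min_informative_bins
                for lo, hi in zip(edges, edges[1:])
            ):
                return cuts
    raise RuntimeError(f"{chrom}: no switch placement satisfied the constraints")


def recombinant_genotype(
    truth: DikaryonTruth,
    switches: dict[str, Sequence[int]],
    isolate_id: str = "iso",
    start_origin: str = "A",
    extras: Sequence[str] = (),
) -> SporeGenotype:
    """A spore whose core chromosomes are A/B mosaics with switches at the
    given bp boundaries (A-frame coordinates; origin flips after each)."""
    cfg = truth.config
    complement: list[tuple[ChromosomeModel, int]] = []
    for chrom, length in cfg.aframe_lengths.items():
        cuts = sorted(switches.get(chrom, ()))
        if not cuts:
            complement.append((truth.chromosomes[f"{chrom}{start_origin}"], 1))
            continue
        segs = []
        origin = start_origin
        cursor = 1
        for cut in cuts:
            if not 1 <= cut < length:
                raise ValueError(f"switch {cut} outside {chrom}")
            segs.append(OrientedSegment(f"{chrom}{origin}", cursor, cut, "+"))
            origin = "B" if origin == "A" else "A"
            cursor = cut + 1
        segs.append(OrientedSegment(f"{chrom}{origin}", cursor, length, "+"))
        model = ChromosomeModel(
            id=f"{chrom}:rec",
            segments=tuple(segs),
            telomere_5p=True,
            telomere_3p=True,
            has_centromere=True,
            centromere=None,
        )
        complement.append((model, 1))
    base = SporeGenotype(isolate_id=isolate_id, complement=complement)
    if extras:
        extra_geno = architecture_genotype(truth, "A", extras=extras, isolate_id=isolate_id)
        base.complement.extend(extra_geno.complement[len(cfg.aframe_lengths) :])
    return base


def meiosis_model_from_truth(
    truth: DikaryonTruth,
    acentric_bias: float = 0.7,
    junction_probability: Optional[float] = None,
    crossover_probability: float = 0.25,
    required_fraction: float = 1.0,
) -> MeiosisModel:
    """Assemble the meiosis model of the generated dikaryon.

    Crossover hotspots are placed deterministically at two observable bin
    boundaries per core chromosome (where both flanking bins are
    heterozygous and identity-mapped), so recurrent exchange sites appear
    across isolates.
    """
    from .meiosis_sim import CrossoverHotspot

    cfg = truth.config
    pairs = [(f"{c}A", f"{c}B") for c in cfg.aframe_lengths]
    acentrics = []
    if cfg.acentric_extra:
        donor, _, _ = cfg.acentric_donor_arm
        acentrics.append(AcentricSpec(cfg.extra_chrom_id, partner=f"{donor}A", bias=acentric_bias))
    rules = truth.junction_rules
    if junction_probability is not None:
        from dataclasses import replace as _replace

        rules = [_replace(r, probability=junction_probability) for r in rules]
    hotspots = []
    if crossover_probability > 0:
        for chrom in cfg.core_lengths:
            boundaries = eligible_switch_boundaries(truth, chrom)
            limit = min(
                truth.chromosomes[f"{chrom}A"].length, truth.chromosomes[f"{chrom}B"].length
            )
            boundaries = [b for b in boundaries if b < limit]
            if not boundaries:
                continue
            for idx in {len(boundaries) // 3, (2 * len(boundaries)) // 3}:
                hotspots.append(
                    CrossoverHotspot(
                        f"{chrom}A", f"{chrom}B", boundaries[idx], crossover_probability
                    )
                )
    arch_pairs = [(f"{c}A", f"{c}B") for c in cfg.cassette_cycle] if cfg.architecture_cassettes else pairs
    markers = None
    if cfg.architecture_cassettes:
        markers = {}
        for c in cfg.cassette_cycle:
            cs, ce = cfg.architecture_cassettes[c]
            markers[(f"{c}A", f"{c}B")] = ((f"{c}A", cs, ce), (f"{c}B", cs, ce))
    return MeiosisModel(
        chromosomes=dict(truth.chromosomes),
        pairs=pairs,
        acentrics=acentrics,
        essential_units=list(truth.essential_units),
        junction_rules=list(rules),
        crossover_hotspots=hotspots,
        architecture_pairs=arch_pairs,
        architecture_markers=markers,
        required_fraction=required_fraction,
    )


# ---------------------------------------------------------------------------
# evidence simulation
# ---------------------------------------------------------------------------


@dataclass
class EvidenceSet:
    """Simulated sequencing observables for one monospore isolate."""

    isolate: str
    bin_allele_counts: pd.DataFrame  # chrom, start, end, informative, n_a, n_b
    depth_windows: pd.DataFrame  # chrom, start, end, depth
    junction_reads: pd.DataFrame  # junction descriptor + support/ref-span counts
    breakpoint_reads: pd.DataFrame  # breakpoint, reads_a, reads_b


def _normalize_mixture(
    genotype: SporeGenotype | Sequence[tuple[SporeGenotype, float]],
) -> list[tuple[SporeGenotype, float]]:
    if isinstance(genotype, SporeGenotype):
        return [(genotype, 1.0)]
    total = sum(w for _, w in genotype)
    if total <= 0:
        raise ValueError("mixture weights must sum to a positive value")
    return [(g, w / total) for g, w in genotype]


def _weighted_models(
    mixture: Sequence[tuple[SporeGenotype, float]],
) -> list[tuple[ChromosomeModel, float]]:
    out = []
    for g, w in mixture:
        for m, n in g.complement:
            if n > 0:
                out.append((m, w * n))
    return out


def simulate_evidence(
    genotype: SporeGenotype | Sequence[tuple[SporeGenotype, float]],
    truth: DikaryonTruth,
    coverage: float = 30.0,
    allele_error: float = 0.01,
    read_length: int = 150,
    window_size: int = 2_000,
    rng_seed: int | np.random.Generator = 0,
    isolate_id: Optional[str] = None,
) -> EvidenceSet:
    """Simulate the per-isolate observables of the genotyping pipeline.

    ``genotype`` may be a single :class:`SporeGenotype` or a karyotype
    mixture ``[(genotype, weight), ...]`` — a monospore culture whose cells
    disagree about copy numbers; expectations are weight-averaged.
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    mixture = _normalize_mixture(genotype)
    models = _weighted_models(mixture)
    name = isolate_id or mixture[0][0].isolate_id
    bin_size = truth.config.bin_size

    # --- per-bin weighted copy numbers on the A frame --------------------
    bins = truth.bins
    cn_a = np.zeros(len(bins))
    cn_b = np.zeros(len(bins))
    bin_index: dict[str, tuple[int, int]] = {}
    for chrom, grp in bins.groupby("chrom", sort=False):
        bin_index[chrom] = (grp.index[0], grp.index[-1])

    def add_aframe(chrom: str, s: int, e: int, weight: float, origin: str) -> None:
        if chrom not in bin_index:
            return
        lo, hi = bin_index[chrom]
        first = lo + (s - 1) // bin_size
        last = lo + (e - 1) // bin_size
        for i in range(max(first, lo), min(last, hi) + 1):
            b = bins.iloc[i]
            frac = overlap_length(b["start"], b["end"], s, e) / (b["end"] - b["start"] + 1)
            if origin == "A":
                cn_a[i] += weight * frac
            else:
                cn_b[i] += weight * frac

    for m, w in models:
        for seg in m.segments:
            if seg.chrom.endswith("A"):
                add_aframe(seg.chrom, seg.start, seg.end, w, "A")
            else:
                for chrom, s, e in truth.map_to_aframe(seg.chrom, seg.start, seg.end):
                    add_aframe(chrom, s, e, w, "B")

    total_cn = cn_a + cn_b
    lam = coverage * total_cn
    n_total = rng.poisson(lam)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_a = np.where(total_cn > 0, (cn_a * (1 - allele_error) + cn_b * allele_error) / total_cn, 0.0)
    n_a = rng.binomial(n_total, np.clip(p_a, 0.0, 1.0))
    bin_counts = pd.DataFrame(
        {
            "chrom": bins["chrom"],
            "start": bins["start"],
            "end": bins["end"],
            "informative": bins["informative"],
            "n_a": n_a,
            "n_b": n_total - n_a,
        }
    )

    # --- depth windows on the combined reference -------------------------
    refs = truth.depth_references()
    rows = []
    ref_cn: dict[str, np.ndarray] = {}
    ref_grid: dict[str, np.ndarray] = {}
    for ref, length in refs.items():
        starts = np.arange(1, length + 1, window_size)
        ref_grid[ref] = starts
        ref_cn[ref] = np.zeros(len(starts))
    for m, w in models:
        for seg in m.segments:
            for ref, s, e in truth.map_to_depth_ref(seg.chrom, seg.start, seg.end):
                if ref not in ref_cn:
                    continue
                starts = ref_grid[ref]
                length = refs[ref]
                first = (s - 1) // window_size
                last = (e - 1) // window_size
                for i in range(first, min(last, len(starts) - 1) + 1):
                    ws = starts[i]
                    we = min(ws + window_size - 1, length)
                    frac = overlap_length(ws, we, s, e) / (we - ws + 1)
                    ref_cn[ref][i] += w * frac
    for ref, length in refs.items():
        starts = ref_grid[ref]
        ends = np.minimum(starts + window_size - 1, length)
        wlen = ends - starts + 1
        lam_reads = coverage * ref_cn[ref] * wlen / read_length
        reads = rng.poisson(lam_reads)
        depth = reads * read_length / wlen
        for ws, we, d in zip(starts, ends, depth):
            rows.append({"chrom": ref, "start": int(ws), "end": int(we), "depth": float(d)})
    depth_windows = pd.DataFrame(rows)

    # --- junction-spanning reads -----------------------------------------
    joins: dict[tuple, float] = {}
    for m, w in models:
        for left, right in zip(m.segments, m.segments[1:]):
            if left.orient == "+":
                cx, px, sx = left.chrom, left.end, "start"
            else:
                cx, px, sx = left.chrom, left.start, "end"
            if right.orient == "+":
                cy, py, sy = right.chrom, right.start, "end"
            else:
                cy, py, sy = right.chrom, right.end, "start"
            key = (cx, px, sx, cy, py, sy)
            joins[key] = joins.get(key, 0.0) + w
    jrows = []
    for (cx, px, sx, cy, py, sy), w in sorted(joins.items()):
        support = int(rng.poisson(coverage * w))
        span_x = int(rng.poisson(coverage * truth.crossing_copies(models, cx, px if sx == "start" else px - 1)))
        span_y = int(rng.poisson(coverage * truth.crossing_copies(models, cy, py if sy == "start" else py - 1)))
        jrows.append(
            {
                "chrom_x": cx, "pos_x": px, "side_x": sx,
                "chrom_y": cy, "pos_y": py, "side_y": sy,
                "support": support, "ref_span_x": span_x, "ref_span_y": span_y,
            }
        )
    junction_reads = pd.DataFrame(
        jrows,
        columns=["chrom_x", "pos_x", "side_x", "chrom_y", "pos_y", "side_y", "support", "ref_span_x", "ref_span_y"],
    )

    # --- architecture breakpoint evidence --------------------------------
    brows = []
    for chrom in truth.config.cassette_cycle:
        cs, _ = truth.config.architecture_cassettes[chrom]
        reads_a = int(rng.poisson(coverage * truth.crossing_copies(models, f"{chrom}A", cs - 1)))
        reads_b = int(rng.poisson(coverage * truth.crossing_copies(models, f"{chrom}B", cs - 1)))
        brows.append({"breakpoint": f"bp_{chrom}", "reads_a": reads_a, "reads_b": reads_b})
    breakpoint_reads = pd.DataFrame(brows, columns=["breakpoint", "reads_a", "reads_b"])

    return EvidenceSet(
        isolate=name,
        bin_allele_counts=bin_counts,
        depth_windows=depth_windows,
        junction_reads=junction_reads,
        breakpoint_reads=breakpoint_reads,
    )
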