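"""Mechanistic meiosis model for an asymmetric dikaryotic genome.

The model captures how meiosis of two structurally different haploid nuclei
(A and B) produces new chromosomes and biased, mostly inviable spores:

1. Homologous regions of the chromatids pair into a *pairing complex* — a
   graph whose nodes are chromatids and whose edges are homology blocks.  In
   the study genome, partial homologies join seven chromatids (Chr01A/B,
   Chr02A/B, Chr05A/B and the acentric Chr12B) into one large complex, while
   two B-specific terminal segments (Chr01B-C1, Chr12B-C1) remain unpaired.
2. Breakage at homology intersections followed by rejoining is expressed as
   *junction rules*: each rule names two break sites and which side of each
   chromatid survives into the telomere-capped product.  A fired rule
   consumes one sister chromatid of each participant, emits the new
   chromosome, and leaves telomere-less remainder fragments.
3. Segregation follows meiosis I/II semantics for centromeric homolog pairs
   (each pair splits 2+2 across the four products).  Acentric chromosomes
   cannot attach to spindle microtubules: each sister copy migrates to the
   pole of its designated pairing partner with a configurable probability
   (0.5 = uniform migration).
4. Products are filtered for stability (chromosomes lacking a telomere at
   either end are dropped, with a count) and for viability: a spore survives
   only if its complement covers every required essential-gene unit.

Both a Monte-Carlo mode and an exhaustive enumeration mode (all segregation
outcomes with their probabilities, for small models) are provided; the two
must agree within sampling error, which the test suite checks.

Meiosis is modelled at segment granularity: the claims being tested concern
architecture-scale outcomes, not base-level crossover resolution.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .coords import overlap_length
from .genome_model import HaplotypeGenome, HomologyBlock, OrientedSegment

__all__ = [
    "AcentricSpec",
    "ChromosomeModel",
    "EssentialUnit",
    "JunctionRule",
    "MeiosisModel",
    "MeiosisOutcome",
    "PairingComplex",
    "SporeGenotype",
    "assemble_junction_product",
    "build_pairing_complex",
    "check_conservation",
    "enumerate_cohort",
    "form_new_chromosomes",
    "junction_remainders",
    "reduced_asymmetric_model",
    "run_meiosis",
    "segregate",
    "simulate_cohort",
    "summarize_products",
    "viability",
    "whole_chromosome_model",
]


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChromosomeModel:
    """A (possibly derived) chromosome as an ordered list of source segments.

    Parental chromosomes are single whole-length segments on themselves;
    derived chromosomes (junction products, fragments) list the parental
    segments they are built from, in join order.  ``centromere`` carries the
    source-coordinate centromere interval for parental models; for derived
    models centromere presence is pre-computed into ``has_centromere``.
    """

    id: str
    segments: tuple[OrientedSegment, ...]
    telomere_5p: bool = True
    telomere_3p: bool = True
    has_centromere: bool = True
    centromere: Optional[tuple[int, int]] = None

    @property
    def length(self) -> int:
        return sum(s.length for s in self.segments)

    @property
    def stable(self) -> bool:
        """Stably heritable: telomere-capped at both ends."""
        return self.telomere_5p and self.telomere_3p

    @property
    def source_chromatids(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(s.chrom for s in self.segments))


def whole_chromosome_model(
    chrom_id: str,
    length: int,
    centromere: Optional[tuple[int, int]] = None,
    telomere_5p: bool = True,
    telomere_3p: bool = True,
) -> ChromosomeModel:
    return ChromosomeModel(
        id=chrom_id,
        segments=(OrientedSegment(chrom_id, 1, length, "+"),),
        telomere_5p=telomere_5p,
        telomere_3p=telomere_3p,
        has_centromere=centromere is not None,
        centromere=centromere,
    )


@dataclass(frozen=True)
class JunctionRule:
    """A breakage/rejoining event between two chromatids.

    ``side_x``/``side_y`` name which piece of each chromatid survives into
    the product: ``start`` keeps the prefix ``[1, pos]``, ``end`` keeps the
    suffix ``[pos, length]``.  The product is assembled so each piece's
    broken end faces the junction, which fixes the relative strand: a kept
    prefix of Y enters reverse-complemented (the "RC" of junction notation),
    a kept suffix enters forward; symmetric for X.  All four dyadic join
    classes are therefore expressible even though the observed new
    chromosomes are both prefix + prefix-RC joins.
    """

    name: str
    chrom_x: str
    pos_x: int
    chrom_y: str
    pos_y: int
    side_x: Literal["start", "end"] = "start"
    side_y: Literal["start", "end"] = "start"
    mechanism: Literal["terminal-pairing", "internal-homologous-recombination"] = "terminal-pairing"
    probability: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"rule {self.name}: probability {self.probability} outside [0, 1]")
        if self.side_x not in ("start", "end") or self.side_y not in ("start", "end"):
            raise ValueError(f"rule {self.name}: sides must be 'start' or 'end'")
        if self.pos_x < 1 or self.pos_y < 1:
            raise ValueError(f"rule {self.name}: break positions must be >= 1")


@dataclass(frozen=True)
class AcentricSpec:
    """An acentric chromosome and its migration behaviour.

    ``partner`` is the chromatid whose pole each sister copy tracks;
    ``bias`` is the probability of co-locating with the partner's pole
    (0.5 = uniform/free migration, 1.0 = always with the partner).
    """

    chrom: str
    partner: Optional[str] = None
    bias: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.bias <= 1.0:
            raise ValueError(f"{self.chrom}: bias {self.bias} outside [0, 1]")


@dataclass(frozen=True)
class EssentialUnit:
    """A unit of essential-gene content with every genomic location carrying it."""

    id: str
    locations: tuple[tuple[str, int, int], ...]  # (chromatid, start, end) 1-based inclusive
    required: bool = True


@dataclass(frozen=True)
class CrossoverHotspot:
    """An optional exchange event between collinear homologs.

    When fired, one sister of each homolog swaps distal segments at
    ``position`` (coordinates shared by both homologs), producing two
    reciprocal recombinant chromatids.  A hotspot is skipped in a meiosis
    where a junction rule already consumed a sister of either homolog.
    """

    chrom_a: str
    chrom_b: str
    position: int
    probability: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"hotspot probability {self.probability} outside [0, 1]")
        if self.position < 1:
            raise ValueError("hotspot position must be >= 1")


@dataclass
class MeiosisModel:
    """Parental complement plus the behavioural annotations of one meiosis."""

    chromosomes: dict[str, ChromosomeModel]
    pairs: list[tuple[str, str]]
    unpartnered: list[str] = field(default_factory=list)
    acentrics: list[AcentricSpec] = field(default_factory=list)
    essential_units: list[EssentialUnit] = field(default_factory=list)
    junction_rules: list[JunctionRule] = field(default_factory=list)
    crossover_hotspots: list[CrossoverHotspot] = field(default_factory=list)
    architecture_pairs: Optional[list[tuple[str, str]]] = None
    # content markers per architecture pair: ((chrom, s, e) for the A
    # arrangement, same for B); lets recombinant chromosomes be typed by the
    # arrangement they carry rather than by intact parental identity
    architecture_markers: Optional[dict[tuple[str, str], tuple[tuple[str, int, int], tuple[str, int, int]]]] = None
    required_fraction: float = 1.0
    allow_rule_cooccurrence: bool = True

    def __post_init__(self) -> None:
        for a, b in self.pairs:
            for cid in (a, b):
                if cid not in self.chromosomes:
                    raise ValueError(f"pair member {cid} not in complement")
                if not self.chromosomes[cid].has_centromere:
                    raise ValueError(f"pair member {cid} is acentric; list it under acentrics")
        for spec in self.acentrics:
            if spec.chrom not in self.chromosomes:
                raise ValueError(f"acentric {spec.chrom} not in complement")
        for h in self.crossover_hotspots:
            for cid in (h.chrom_a, h.chrom_b):
                if cid not in self.chromosomes:
                    raise ValueError(f"hotspot references unknown chromatid {cid}")
            limit = min(self.chromosomes[h.chrom_a].length, self.chromosomes[h.chrom_b].length)
            if h.position >= limit:
                raise ValueError(f"hotspot position {h.position} beyond homolog length {limit}")
        if self.architecture_pairs is None:
            self.architecture_pairs = list(self.pairs)


@dataclass
class SporeGenotype:
    """One meiotic product: chromosome complement with copy counts and calls."""

    isolate_id: str
    complement: list[tuple[ChromosomeModel, int]]
    viable: Optional[bool] = None
    architecture: Optional[str] = None  # 'A' | 'B' | 'unresolved'
    extras: tuple[str, ...] = ()
    aneuploidy_type: Optional[str] = None

    def models(self) -> list[ChromosomeModel]:
        out: list[ChromosomeModel] = []
        for m, n in self.complement:
            out.extend([m] * n)
        return out

    def copies_of(self, model_id: str) -> int:
        return sum(n for m, n in self.complement if m.id == model_id)

    def origin_segments(self) -> list[tuple[str, int, int, str, int]]:
        """Per-segment source haplotype: (source chrom, start, end, origin, copies)."""
        counts: Counter = Counter()
        for m, n in self.complement:
            for s in m.segments:
                counts[(s.chrom, s.start, s.end)] += n
        return [
            (chrom, start, end, "A" if chrom.endswith("A") else "B", n)
            for (chrom, start, end), n in sorted(counts.items())
        ]


# ---------------------------------------------------------------------------
# pairing complex
# ---------------------------------------------------------------------------


@dataclass
class PairingComplex:
    """The homologous-pairing graph over all chromatids of both haplotypes."""

    nodes: list[str]
    edges: list[HomologyBlock]
    components: list[frozenset[str]]
    intersections: list[tuple[str, int, frozenset[str]]]  # (chromatid, coordinate, chromatids meeting)
    unpaired: list[OrientedSegment]
    chrom_info: dict[str, ChromosomeModel] = field(default_factory=dict)

    def component_of(self, chrom_id: str) -> frozenset[str]:
        for comp in self.components:
            if chrom_id in comp:
                return comp
        raise KeyError(chrom_id)


def _parental_models(genomes: Iterable[HaplotypeGenome]) -> dict[str, ChromosomeModel]:
    info: dict[str, ChromosomeModel] = {}
    for g in genomes:
        for c in g.chromosomes:
            info[c.id] = whole_chromosome_model(
                c.id, c.length, c.centromere, c.telomere_5p, c.telomere_3p
            )
    return info


def build_pairing_complex(
    genome_a: HaplotypeGenome,
    genome_b: HaplotypeGenome,
    homology_map: Sequence[HomologyBlock],
    min_block: int = 10_000,
    boundary_tol: int = 1,
) -> PairingComplex:
    """Assemble the pairing complex from a homology map.

    Blocks shorter than ``min_block`` (on either side) do not pair.
    Intersections are coordinates where homology blocks to at least two
    *different* partner chromatids meet on one chromatid (within
    ``boundary_tol`` bp), i.e. at least three chromatids' homologies touch —
    the physical-contact sites where breakage can occur.  ``unpaired`` lists
    maximal segments (>= ``min_block``) covered by no pairing block: the
    haplotype-specific regions with no partner in the other nucleus.

    Overlapping blocks on one chromatid are contradictory (one region cannot
    pair two ways at once) and reject the map.
    """
    chrom_info = _parental_models((genome_a, genome_b))
    blocks = [
        b for b in homology_map if min(b.seg_a.length, b.seg_b.length) >= min_block
    ]
    for b in blocks:
        for seg in (b.seg_a, b.seg_b):
            if seg.chrom not in chrom_info:
                raise ValueError(f"homology block references unknown chromatid {seg.chrom}")
            if seg.end > chrom_info[seg.chrom].length:
                raise ValueError(f"homology block segment {seg} exceeds chromosome length")

    # per-chromatid incidence: (start, end, partner, block)
    incidence: dict[str, list[tuple[int, int, str]]] = {cid: [] for cid in chrom_info}
    for b in blocks:
        incidence[b.seg_a.chrom].append((b.seg_a.start, b.seg_a.end, b.seg_b.chrom))
        incidence[b.seg_b.chrom].append((b.seg_b.start, b.seg_b.end, b.seg_a.chrom))

    for cid, ivs in incidence.items():
        ivs.sort()
        for (s1, e1, _), (s2, e2, _) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"contradictory homology map: overlapping blocks on {cid} "
                    f"([{s1},{e1}] and [{s2},{e2}])"
                )

    graph = nx.Graph()
    graph.add_nodes_from(chrom_info)
    for b in blocks:
        graph.add_edge(b.seg_a.chrom, b.seg_b.chrom)
    components = [frozenset(c) for c in nx.connected_components(graph)]

    # intersections: cluster block boundaries per chromatid; a cluster where
    # the incident blocks involve >= 2 distinct partners marks a meeting
    # point of >= 3 chromatids.
    intersections: list[tuple[str, int, frozenset[str]]] = []
    for cid, ivs in incidence.items():
        boundaries = sorted({x for s, e, _ in ivs for x in (s, e)})
        clusters: list[list[int]] = []
        for x in boundaries:
            if clusters and x - clusters[-1][-1] <= boundary_tol:
                clusters[-1].append(x)
            else:
                clusters.append([x])
        for cluster in clusters:
            lo, hi = cluster[0] - boundary_tol, cluster[-1] + boundary_tol
            partners = {
                p for s, e, p in ivs if overlap_length(s, e, lo, hi) > 0
            }
            if len(partners) >= 2:
                coord = cluster[len(cluster) // 2]
                intersections.append((cid, coord, frozenset(partners | {cid})))

    unpaired: list[OrientedSegment] = []
    for cid, ivs in incidence.items():
        length = chrom_info[cid].length
        cursor = 1
        gaps: list[tuple[int, int]] = []
        for s, e, _ in ivs:
            if s > cursor:
                gaps.append((cursor, s - 1))
            cursor = max(cursor, e + 1)
        if cursor <= length:
            gaps.append((cursor, length))
        for s, e in gaps:
            if e - s + 1 >= min_block:
                unpaired.append(OrientedSegment(cid, s, e, "+"))

    return PairingComplex(
        nodes=sorted(chrom_info),
        edges=list(blocks),
        components=components,
        intersections=sorted(intersections),
        unpaired=sorted(unpaired, key=lambda s: (s.chrom, s.start)),
        chrom_info=chrom_info,
    )


# ---------------------------------------------------------------------------
# junction products
# ---------------------------------------------------------------------------


def _piece(
    chrom: ChromosomeModel, pos: int, side: str, at_junction: Literal["right", "left"]
) -> tuple[OrientedSegment, bool]:
    """One kept piece of a broken chromatid, oriented so its broken end faces
    the junction; returns (segment, telomere flag of the outer end)."""
    if not 1 <= pos <= chrom.length:
        raise ValueError(f"break position {pos} outside {chrom.id} [1, {chrom.length}]")
    if side == "start":
        seg = OrientedSegment(chrom.id, 1, pos, "+")  # broken end on the right
        outer_tel = chrom.telomere_5p
        needs_flip = at_junction == "left"
    else:
        seg = OrientedSegment(chrom.id, pos, chrom.length, "+")  # broken end on the left
        outer_tel = chrom.telomere_3p
        needs_flip = at_junction == "right"
    if needs_flip:
        seg = replace(seg, orient="-")
    return seg, outer_tel


def _contains_centromere(seg: OrientedSegment, source: ChromosomeModel) -> bool:
    if source.centromere is None:
        return False
    cs, ce = source.centromere
    return seg.start <= cs and ce <= seg.end


def assemble_junction_product(
    rule: JunctionRule, chrom_info: dict[str, ChromosomeModel]
) -> ChromosomeModel:
    """The new chromosome a junction rule emits: X piece joined to Y piece."""
    cx, cy = chrom_info[rule.chrom_x], chrom_info[rule.chrom_y]
    seg_x, tel5 = _piece(cx, rule.pos_x, rule.side_x, at_junction="right")
    seg_y, tel3 = _piece(cy, rule.pos_y, rule.side_y, at_junction="left")
    return ChromosomeModel(
        id=rule.name,
        segments=(seg_x, seg_y),
        telomere_5p=tel5,
        telomere_3p=tel3,
        has_centromere=_contains_centromere(seg_x, cx) or _contains_centromere(seg_y, cy),
        centromere=None,
    )


def junction_remainders(
    rule: JunctionRule, chrom_info: dict[str, ChromosomeModel]
) -> list[ChromosomeModel]:
    """The reciprocal fragments left by a fired rule (telomere-less at the break)."""
    out = []
    for chrom_id, pos, side in (
        (rule.chrom_x, rule.pos_x, rule.side_x),
        (rule.chrom_y, rule.pos_y, rule.side_y),
    ):
        c = chrom_info[chrom_id]
        if side == "start":
            if pos >= c.length:
                continue
            seg = OrientedSegment(chrom_id, pos + 1, c.length, "+")
            tel5, tel3 = False, c.telomere_3p
        else:
            if pos <= 1:
                continue
            seg = OrientedSegment(chrom_id, 1, pos - 1, "+")
            tel5, tel3 = c.telomere_5p, False
        out.append(
            ChromosomeModel(
                id=f"{chrom_id}:frag",
                segments=(seg,),
                telomere_5p=tel5,
                telomere_3p=tel3,
                has_centromere=_contains_centromere(seg, c),
                centromere=None,
            )
        )
    return out


def form_new_chromosomes(
    complex_: PairingComplex,
    rules: Sequence[JunctionRule],
    rng: np.random.Generator,
) -> list[ChromosomeModel]:
    """Fire junction rules against a pairing complex; return emitted models.

    Each rule fires independently with its configured probability.  A rule
    naming a chromatid absent from the complex cannot fire and is skipped;
    a rule with break coordinates outside its chromatid rejects.
    """
    out = []
    for rule in rules:
        sites = ((rule.chrom_x, rule.pos_x), (rule.chrom_y, rule.pos_y))
        if any(chrom_id not in complex_.chrom_info for chrom_id, _ in sites):
            continue
        for chrom_id, pos in sites:
            if pos > complex_.chrom_info[chrom_id].length:
                raise ValueError(f"rule {rule.name}: position {pos} outside {chrom_id}")
        if rng.random() < rule.probability:
            out.append(assemble_junction_product(rule, complex_.chrom_info))
    return out


# ---------------------------------------------------------------------------
# segregation
# ---------------------------------------------------------------------------

Choice = tuple[str, tuple[tuple[object, float], ...]]  # (key, ((value, prob), ...))


def _choice_spec(model: MeiosisModel, fired: Sequence[JunctionRule]) -> list[Choice]:
    """The discrete random choices of one meiosis, with their probabilities.

    Shared by the Monte-Carlo sampler and the exhaustive enumerator so the
    two modes explore the same probability space.
    """
    choices: list[Choice] = []
    half = ((0, 0.5), (1, 0.5))
    for i, _pair in enumerate(model.pairs):
        choices.append((f"pole:{i}", half))
    for cid in model.unpartnered:
        choices.append((f"pole_u:{cid}", half))

    consumed = {r.chrom_x for r in fired} | {r.chrom_y for r in fired}
    acentric_ids = {a.chrom for a in model.acentrics}
    bias_of = {a.chrom: a for a in model.acentrics}

    for cid in sorted(consumed):
        if cid not in acentric_ids:
            # which product of the chromatid's pole receives the intact sister
            choices.append((f"intact:{cid}", half))

    def acentric_options(bias: float) -> tuple[tuple[object, float], ...]:
        return (
            (("partner", 0), bias / 2),
            (("partner", 1), bias / 2),
            (("other", 0), (1 - bias) / 2),
            (("other", 1), (1 - bias) / 2),
        )

    for spec in model.acentrics:
        n_copies = 1 if spec.chrom in consumed else 2
        for k in range(n_copies):
            choices.append((f"acentric:{spec.chrom}:{k}", acentric_options(spec.bias)))
    for rule in fired:
        # the new chromosome and any acentric remainder fragments migrate freely;
        # a choice for a non-existent or centromeric fragment is simply unused
        choices.append((f"new:{rule.name}", acentric_options(0.5)))
        for frag_source in (rule.chrom_x, rule.chrom_y):
            choices.append((f"frag:{rule.name}:{frag_source}", acentric_options(0.5)))
    for i, h in enumerate(model.crossover_hotspots):
        if h.chrom_a in consumed or h.chrom_b in consumed:
            continue  # a broken sister cannot recombine this meiosis
        p = h.probability
        choices.append((f"xo:{i}", ((False, 1.0 - p), (True, p))))
        choices.append((f"xo_a:{i}", half))
        choices.append((f"xo_b:{i}", half))
    return choices


def _realize(
    model: MeiosisModel,
    fired: Sequence[JunctionRule],
    picks: dict[str, object],
) -> list[list[ChromosomeModel]]:
    """Materialise the four meiotic products for one set of choices."""
    products: list[list[ChromosomeModel]] = [[], [], [], []]
    pole_products = {0: (0, 1), 1: (2, 3)}
    consumed = {r.chrom_x for r in fired} | {r.chrom_y for r in fired}
    acentric_ids = {a.chrom for a in model.acentrics}

    pole_of: dict[str, int] = {}
    for i, (a, b) in enumerate(model.pairs):
        p = picks[f"pole:{i}"]
        pole_of[a], pole_of[b] = p, 1 - p
    for cid in model.unpartnered:
        pole_of[cid] = picks[f"pole_u:{cid}"]

    def partner_pole(partner: Optional[str]) -> Optional[int]:
        if partner is None:
            return None
        return pole_of.get(partner)

    def place_acentric(item: ChromosomeModel, pick: tuple[str, int], p_pole: Optional[int]) -> None:
        rel, which = pick
        if p_pole is None:
            pole = 0 if rel == "partner" else 1  # no partner: the split is uniform either way
        else:
            pole = p_pole if rel == "partner" else 1 - p_pole
        products[pole_products[pole][which]].append(item)

    # replicated sisters of the centromeric chromosomes; a fired crossover
    # replaces one sister of each homolog with the reciprocal recombinant
    sisters: dict[str, list[ChromosomeModel]] = {
        cid: [model.chromosomes[cid], model.chromosomes[cid]] for cid in pole_of
    }
    placement_flip: dict[str, int] = {}
    for i, h in enumerate(model.crossover_hotspots):
        if not picks.get(f"xo:{i}", False):
            continue
        if h.chrom_a in consumed or h.chrom_b in consumed:
            continue
        if sisters[h.chrom_a][1].id != h.chrom_a or sisters[h.chrom_b][1].id != h.chrom_b:
            continue  # at most one crossover per homolog pair per meiosis
        rec_a, rec_b = _recombinant_pair(
            model.chromosomes[h.chrom_a], model.chromosomes[h.chrom_b], h.position
        )
        sisters[h.chrom_a][1] = rec_a
        sisters[h.chrom_b][1] = rec_b
        placement_flip[h.chrom_a] = picks[f"xo_a:{i}"]
        placement_flip[h.chrom_b] = picks[f"xo_b:{i}"]

    for cid in list(pole_of):
        prods = pole_products[pole_of[cid]]
        if cid in consumed:
            intact_to = picks[f"intact:{cid}"]
            products[prods[intact_to]].append(model.chromosomes[cid])
            # the broken sister's pieces are handled with the fired rules below
        else:
            s0, s1 = sisters[cid]
            flip = placement_flip.get(cid, 0)
            products[prods[flip]].append(s1)
            products[prods[1 - flip]].append(s0)

    # acentric parental chromosomes
    for spec in model.acentrics:
        src = model.chromosomes[spec.chrom]
        n_copies = 1 if spec.chrom in consumed else 2
        p_pole = partner_pole(spec.partner)
        for k in range(n_copies):
            place_acentric(src, picks[f"acentric:{spec.chrom}:{k}"], p_pole)

    # junction products and remainder fragments
    for rule in fired:
        new_chrom = assemble_junction_product(rule, model.chromosomes)
        if new_chrom.has_centromere:
            # segregates with the pole of the centromere donor's broken sister
            donor = next(
                seg.chrom
                for seg in new_chrom.segments
                if _contains_centromere(seg, model.chromosomes[seg.chrom])
            )
            prods = pole_products[pole_of[donor]]
            intact_to = picks.get(f"intact:{donor}", 0)
            products[prods[1 - intact_to]].append(new_chrom)
        else:
            place_acentric(new_chrom, picks[f"new:{rule.name}"], None)
        for frag in junction_remainders(rule, model.chromosomes):
            source_id = frag.segments[0].chrom
            if frag.has_centromere and source_id in pole_of:
                prods = pole_products[pole_of[source_id]]
                intact_to = picks.get(f"intact:{source_id}", 0)
                products[prods[1 - intact_to]].append(frag)
            else:
                place_acentric(frag, picks[f"frag:{rule.name}:{source_id}"], None)
    return products


def _recombinant_pair(
    ca: ChromosomeModel, cb: ChromosomeModel, pos: int
) -> tuple[ChromosomeModel, ChromosomeModel]:
    """Reciprocal recombinants of two collinear homologs exchanging at pos."""

    def rec(left: ChromosomeModel, right: ChromosomeModel) -> ChromosomeModel:
        seg_l = OrientedSegment(left.id, 1, pos, "+")
        seg_r = OrientedSegment(right.id, pos + 1, right.length, "+")
        return ChromosomeModel(
            id=f"{left.id}:xo{pos}",
            segments=(seg_l, seg_r),
            telomere_5p=left.telomere_5p,
            telomere_3p=right.telomere_3p,
            has_centromere=_contains_centromere(seg_l, left) or _contains_centromere(seg_r, right),
            centromere=None,
        )

    return rec(ca, cb), rec(cb, ca)


def segregate(
    model: MeiosisModel,
    rng: np.random.Generator,
    acentric_bias: Optional[float | dict[str, float]] = None,
) -> list[list[ChromosomeModel]]:
    """One round of segregation of the parental complement (no junction rules).

    ``acentric_bias`` overrides the per-chromosome migration bias (a single
    float for all acentrics, or a mapping by chromosome id).
    """
    m = model
    if acentric_bias is not None:
        if isinstance(acentric_bias, dict):
            new_acentrics = [replace(a, bias=acentric_bias.get(a.chrom, a.bias)) for a in m.acentrics]
        else:
            new_acentrics = [replace(a, bias=float(acentric_bias)) for a in m.acentrics]
        m = MeiosisModel(
            chromosomes=model.chromosomes,
            pairs=model.pairs,
            unpartnered=model.unpartnered,
            acentrics=new_acentrics,
            essential_units=model.essential_units,
            junction_rules=[],
            architecture_pairs=model.architecture_pairs,
            required_fraction=model.required_fraction,
        )
    picks = _sample_choices(_choice_spec(m, ()), rng)
    return _realize(m, (), picks)


def _sample_choices(choices: list[Choice], rng: np.random.Generator) -> dict[str, object]:
    picks: dict[str, object] = {}
    for key, options in choices:
        u = rng.random()
        acc = 0.0
        value = options[-1][0]
        for v, p in options:
            acc += p
            if u < acc:
                value = v
                break
        picks[key] = value
    return picks


def _fire_rules(model: MeiosisModel, rng: np.random.Generator) -> list[JunctionRule]:
    fired = [r for r in model.junction_rules if rng.random() < r.probability]
    if not model.allow_rule_cooccurrence and len(fired) > 1:
        fired = [fired[rng.integers(len(fired))]]
    return fired


@dataclass
class MeiosisOutcome:
    """Four products of one meiosis, before and after the stability filter."""

    products_prefilter: list[list[ChromosomeModel]]
    products: list[list[ChromosomeModel]]
    fired: tuple[str, ...]
    n_dropped_unstable: int


def run_meiosis(model: MeiosisModel, rng: np.random.Generator) -> MeiosisOutcome:
    fired = _fire_rules(model, rng)
    picks = _sample_choices(_choice_spec(model, fired), rng)
    prefilter = _realize(model, fired, picks)
    filtered = [[m for m in prod if m.stable] for prod in prefilter]
    dropped = sum(len(a) - len(b) for a, b in zip(prefilter, filtered))
    return MeiosisOutcome(prefilter, filtered, tuple(r.name for r in fired), dropped)


# ---------------------------------------------------------------------------
# viability / architecture / conservation
# ---------------------------------------------------------------------------


def viability(
    complement: Iterable[ChromosomeModel],
    essential_units: Sequence[EssentialUnit],
    required_fraction: float = 1.0,
) -> bool:
    """A spore is viable iff its complement covers enough required essential units.

    A unit is covered when any of its genomic locations lies entirely inside a
    carried segment (one intact copy suffices).  By default every required
    unit must be covered; ``required_fraction`` relaxes this when only a
    subset of the placed essentials is truly required for survival.
    """
    models = list(complement)
    required = [u for u in essential_units if u.required]
    if not required:
        return True

    def covered(unit: EssentialUnit) -> bool:
        for chrom, start, end in unit.locations:
            for m in models:
                for seg in m.segments:
                    if seg.chrom == chrom and seg.start <= start and end <= seg.end:
                        return True
        return False

    n_covered = sum(covered(u) for u in required)
    return n_covered >= required_fraction * len(required)


def architecture_of(
    complement: Iterable[ChromosomeModel],
    architecture_pairs: Sequence[tuple[str, str]],
    markers: Optional[dict] = None,
) -> str:
    """Genome architecture from the arrangement each defining pair carries.

    With ``markers`` (per pair, the content interval diagnostic for each
    arrangement), recombinant chromosomes are typed by the arrangement they
    actually carry; without markers, intact parental identity decides.
    """
    models = list(complement)

    def covers(loc: tuple[str, int, int]) -> bool:
        chrom, s, e = loc
        return any(
            seg.chrom == chrom and seg.start <= s and e <= seg.end
            for m in models
            for seg in m.segments
        )

    states = []
    ids = {m.id for m in models}
    for pair in architecture_pairs:
        if markers and tuple(pair) in markers:
            loc_a, loc_b = markers[tuple(pair)]
            has_a, has_b = covers(loc_a), covers(loc_b)
        else:
            has_a, has_b = pair[0] in ids, pair[1] in ids
        if has_a and not has_b:
            states.append("A")
        elif has_b and not has_a:
            states.append("B")
        else:
            states.append("unresolved")
    if states and all(s == "A" for s in states):
        return "A"
    if states and all(s == "B" for s in states):
        return "B"
    return "unresolved"


def extras_of(complement: Iterable[ChromosomeModel], model: MeiosisModel, architecture: str) -> tuple[str, ...]:
    """Stable chromosomes beyond the base complement of the called architecture.

    The base A complement has no acentric chromosome; the base B complement
    includes the B-haplotype acentrics (e.g. Chr12B).  Junction products are
    always extras; crossover recombinants (``:xo``) and fragments (``:frag``)
    are homolog replacements, never extras.
    """
    parental = set(model.chromosomes)
    base_b_acentrics = {a.chrom for a in model.acentrics if a.chrom.endswith("B")}
    out = []
    for m in complement:
        if not m.stable:
            continue
        if m.id not in parental:
            if ":" not in m.id:  # derived replacements keep a suffixed id
                out.append(m.id)
        elif m.id in {a.chrom for a in model.acentrics}:
            if not (architecture == "B" and m.id in base_b_acentrics):
                out.append(m.id)
    return tuple(sorted(set(out)))


def check_conservation(
    products_prefilter: Sequence[Sequence[ChromosomeModel]], model: MeiosisModel
) -> bool:
    """Every base of every parental chromosome totals exactly 2 copies across
    the four products (replicated sisters), counting segments relocated into
    new chromosomes and fragments."""
    per_chrom: dict[str, list[tuple[int, int]]] = {cid: [] for cid in model.chromosomes}
    for prod in products_prefilter:
        for m in prod:
            for seg in m.segments:
                if seg.chrom in per_chrom:
                    per_chrom[seg.chrom].append((seg.start, seg.end))
    for cid, ivs in per_chrom.items():
        length = model.chromosomes[cid].length
        deltas: dict[int, int] = {}
        for s, e in ivs:
            deltas[s] = deltas.get(s, 0) + 1
            deltas[e + 1] = deltas.get(e + 1, 0) - 1
        cover, prev = 0, 1
        for x in sorted(deltas):
            if x > prev and cover != 2:  # region [prev, x-1] not at 2 copies
                return False
            cover += deltas[x]
            prev = x
        if prev <= length and cover != 2:  # tail [prev, length]
            return False
    return True


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


def _evaluate_product(
    product: Sequence[ChromosomeModel], model: MeiosisModel
) -> dict:
    from .junction_karyotype import type_aneuploidy  # local import, no cycle

    arch = architecture_of(product, model.architecture_pairs or [], model.architecture_markers)
    viable = viability(product, model.essential_units, model.required_fraction)
    extras = extras_of(product, model, arch)
    call = type_aneuploidy(extras, arch)
    return {
        "viable": viable,
        "architecture": arch,
        "extras": ",".join(extras),
        "aneuploidy_type": call.aneuploidy_type,
        "n_chromosomes": len({m.id for m in product}),
    }


def simulate_cohort(
    model: MeiosisModel,
    n_meioses: int,
    rng_seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, dict]:
    """Monte-Carlo cohort: per-product records plus aggregate summary."""
    if n_meioses < 1:
        raise ValueError("n_meioses must be >= 1")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    records = []
    fired_counter: Counter = Counter()
    dropped = 0
    for i in range(n_meioses):
        outcome = run_meiosis(model, rng)
        dropped += outcome.n_dropped_unstable
        for name in outcome.fired:
            fired_counter[name] += 1
        for prod in outcome.products:
            rec = _evaluate_product(prod, model)
            rec.update(meiosis=i, weight=1.0)
            records.append(rec)
    df = pd.DataFrame(records)
    summary = summarize_products(df)
    summary["rule_incidence"] = {k: v / n_meioses for k, v in sorted(fired_counter.items())}
    summary["n_dropped_unstable"] = dropped
    return df, summary


def enumerate_cohort(model: MeiosisModel, max_outcomes: int = 2_000_000) -> tuple[pd.DataFrame, dict]:
    """Exhaustive enumeration of all meiosis outcomes with their probabilities.

    Tractable for small models only; the outcome space is the product of the
    rule-firing pattern and every discrete segregation choice.
    """
    rule_patterns: list[tuple[tuple[JunctionRule, ...], float]] = []
    rules = model.junction_rules
    for mask in itertools.product([False, True], repeat=len(rules)):
        fired = tuple(r for r, on in zip(rules, mask) if on)
        if not model.allow_rule_cooccurrence and len(fired) > 1:
            continue
        w = 1.0
        for r, on in zip(rules, mask):
            w *= r.probability if on else 1.0 - r.probability
        if w > 0:
            rule_patterns.append((fired, w))
    if not model.allow_rule_cooccurrence:
        total = sum(w for _, w in rule_patterns)
        rule_patterns = [(f, w / total) for f, w in rule_patterns]

    records = []
    for fired, w_rules in rule_patterns:
        choices = _choice_spec(model, fired)
        n_combo = 1
        for _, options in choices:
            n_combo *= len(options)
        if n_combo * 4 > max_outcomes:
            raise ValueError(f"enumeration space too large ({n_combo} outcomes)")
        keys = [k for k, _ in choices]
        for combo in itertools.product(*[opts for _, opts in choices]):
            w = w_rules
            picks = {}
            for k, (v, p) in zip(keys, combo):
                picks[k] = v
                w *= p
            if w == 0.0:
                continue
            prefilter = _realize(model, fired, picks)
            for prod in prefilter:
                stable = [m for m in prod if m.stable]
                rec = _evaluate_product(stable, model)
                rec.update(weight=w)
                records.append(rec)
    df = pd.DataFrame(records)
    summary = summarize_products(df)
    summary["rule_incidence"] = {
        r.name: sum(w for fired, w in rule_patterns if r in fired) for r in rules
    }
    return df, summary


def summarize_products(df: pd.DataFrame) -> dict:
    """Aggregate per-product records (weighted) into cohort summaries."""
    w = df["weight"].to_numpy(dtype=float)
    total = w.sum()
    viable = df["viable"].to_numpy(dtype=bool)
    w_viable = w[viable].sum()
    summary: dict = {
        "viability_fraction": float(w_viable / total) if total else float("nan"),
        "architecture_fractions": {},
        "aneuploidy_type_fractions": {},
        "extra_incidence": {},
    }
    if w_viable > 0:
        sub = df[viable]
        wv = sub["weight"]
        for arch, grp in sub.groupby("architecture"):
            summary["architecture_fractions"][arch] = float(grp["weight"].sum() / w_viable)
        for typ, grp in sub.groupby("aneuploidy_type"):
            summary["aneuploidy_type_fractions"][typ] = float(grp["weight"].sum() / w_viable)
        extra_w: Counter = Counter()
        for extras, weight in zip(sub["extras"], wv):
            for e in filter(None, str(extras).split(",")):
                extra_w[e] += weight
        summary["extra_incidence"] = {k: float(v / w_viable) for k, v in sorted(extra_w.items())}
    return summary


# ---------------------------------------------------------------------------
# reduced preset
# ---------------------------------------------------------------------------


def reduced_asymmetric_model(
    junction_probability: float = 0.0,
    acentric_bias: float = 0.7,
    required_fraction: float = 1.0,
) -> MeiosisModel:
    """A reduced asymmetric-dikaryon preset: three heteromorphic architecture
    pairs plus one acentric B-haplotype chromosome.

    Mirrors the study system's essential-content topology: each architecture
    cassette of content lives on one A chromosome and a *different* B
    chromosome (a cyclic translocation), so only all-A or all-B complements
    cover every cassette; the acentric Chr12B carries the content of the
    Chr05A right arm, so B-architecture spores are viable only when they also
    receive Chr12B.  With migration bias toward the Chr05A pole, viable
    spores are predominantly A-architecture.
    """
    L = {"Chr01": 500_000, "Chr02": 400_000, "Chr05": 450_000}
    cas = {"Chr01": (200_001, 240_000), "Chr02": (150_001, 190_000), "Chr05": (100_001, 140_000)}
    arm = (330_001, 450_000)
    cen = {c: (l // 2 - 2_499, l // 2 + 2_500) for c, l in L.items()}

    chroms: dict[str, ChromosomeModel] = {}
    for c, l in L.items():
        chroms[f"{c}A"] = whole_chromosome_model(f"{c}A", l, cen[c])
    chroms["Chr01B"] = whole_chromosome_model("Chr01B", L["Chr01"], cen["Chr01"])
    chroms["Chr02B"] = whole_chromosome_model("Chr02B", L["Chr02"], cen["Chr02"])
    chroms["Chr05B"] = whole_chromosome_model("Chr05B", arm[0] - 1, cen["Chr05"])
    chroms["Chr12B"] = whole_chromosome_model("Chr12B", 150_000, None)

    units = [
        # shared core content: both homologs carry it at the same coordinates
        EssentialUnit("core1", (("Chr01A", 300_001, 302_000), ("Chr01B", 300_001, 302_000))),
        EssentialUnit("core2", (("Chr02A", 250_001, 252_000), ("Chr02B", 250_001, 252_000))),
        # cyclic cassette translocation t1/t2/t3
        EssentialUnit("t1", (("Chr01A", 210_001, 212_000), ("Chr02B", 160_001, 162_000))),
        EssentialUnit("t2", (("Chr02A", 160_001, 162_000), ("Chr05B", 110_001, 112_000))),
        EssentialUnit("t3", (("Chr05A", 110_001, 112_000), ("Chr01B", 210_001, 212_000))),
        # Chr05A right-arm content, carried by Chr12B in the B haplotype
        EssentialUnit("arm1", (("Chr05A", 350_001, 352_000), ("Chr12B", 40_001, 42_000))),
        EssentialUnit("arm2", (("Chr05A", 400_001, 402_000), ("Chr12B", 90_001, 92_000))),
    ]
    rules = []
    if junction_probability > 0:
        rules = [
            JunctionRule(
                "ChrN1", "Chr01B", 20_000, "Chr12B", 30_000,
                side_x="start", side_y="start",
                mechanism="terminal-pairing", probability=junction_probability,
            )
        ]
    return MeiosisModel(
        chromosomes=chroms,
        pairs=[("Chr01A", "Chr01B"), ("Chr02A", "Chr02B"), ("Chr05A", "Chr05B")],
        acentrics=[AcentricSpec("Chr12B", partner="Chr05A", bias=acentric_bias)],
        essential_units=units,
        junction_rules=rules,
        architecture_pairs=[("Chr01A", "Chr01B"), ("Chr02A", "Chr02B"), ("Chr05A", "Chr05B")],
        required_fraction=required_fraction,
    )
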