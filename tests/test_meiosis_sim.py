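"""Pairing complex, junction firing, segregation, viability, cohort modes."""

from __future__ import annotations

import numpy as np
import pytest

from meiospore.genome_model import Chromosome, HaplotypeGenome, HomologyBlock, OrientedSegment
from meiospore.meiosis_sim import (
    AcentricSpec,
    EssentialUnit,
    JunctionRule,
    MeiosisModel,
    assemble_junction_product,
    build_pairing_complex,
    check_conservation,
    enumerate_cohort,
    form_new_chromosomes,
    reduced_asymmetric_model,
    run_meiosis,
    segregate,
    simulate_cohort,
    viability,
    whole_chromosome_model,
)
from meiospore.tr01 import CHRN1_SEGMENTS, CHRN2_SEGMENTS


def _coordinate_genome(label, chroms):
    return HaplotypeGenome(
        label=label,
        chromosomes=[
            Chromosome(id=cid, length=ln, centromere=cen, telomere_5p=True, telomere_3p=True)
            for cid, ln, cen in chroms
        ],
    )


class TestPairingComplex:
    def test_collinear_pair(self):
        ga = _coordinate_genome("A", [("Chr01A", 100_000, (50_001, 52_000))])
        gb = _coordinate_genome("B", [("Chr01B", 100_000, (50_001, 52_000))])
        blocks = [
            HomologyBlock(
                OrientedSegment("Chr01A", 1, 100_000), OrientedSegment("Chr01B", 1, 100_000)
            )
        ]
        cx = build_pairing_complex(ga, gb, blocks)
        assert cx.component_of("Chr01A") == frozenset({"Chr01A", "Chr01B"})
        assert cx.intersections == []
        assert cx.unpaired == []

    def test_study_like_complex_has_seven_chromatids(self, dikaryon):
        genome_a, genome_b, truth = dikaryon
        cx = build_pairing_complex(genome_a, genome_b, truth.homology, min_block=10_000)
        comp = cx.component_of("Chr12B")
        assert comp == frozenset(
            {"Chr01A", "Chr01B", "Chr02A", "Chr02B", "Chr05A", "Chr05B", "Chr12B"}
        )

    def test_study_like_unpaired_are_orphan_segments(self, dikaryon):
        genome_a, genome_b, truth = dikaryon
        cx = build_pairing_complex(genome_a, genome_b, truth.homology, min_block=10_000)
        # the B-specific terminal segments find no partner in the A genome
        unpaired_b = {
            (s.chrom, s.start, s.end) for s in cx.unpaired if not s.chrom.endswith("A")
        }
        assert unpaired_b == {("Chr01B", 1, 20_000), ("Chr12B", 1, 30_000)}
        # the replaced A-side prefix is orphaned symmetrically
        assert ("Chr01A", 1, 20_000) in {(s.chrom, s.start, s.end) for s in cx.unpaired}

    def test_intersections_at_homology_meeting_points(self, dikaryon):
        genome_a, genome_b, truth = dikaryon
        cx = build_pairing_complex(genome_a, genome_b, truth.homology, min_block=10_000)
        # cassette boundaries put >= 3 chromatids at one coordinate
        spots = [(c, pos) for c, pos, members in cx.intersections if len(members) >= 3]
        assert any(c == "Chr05A" and abs(pos - 100_000) <= 1 for c, pos in spots)

    def test_rejects_contradictory_overlapping_blocks(self):
        ga = _coordinate_genome("A", [("Chr01A", 100_000, None), ("Chr02A", 100_000, None)])
        gb = _coordinate_genome("B", [("Chr01B", 100_000, None)])
        blocks = [
            HomologyBlock(OrientedSegment("Chr01A", 1, 60_000), OrientedSegment("Chr01B", 1, 60_000)),
            HomologyBlock(OrientedSegment("Chr01A", 50_001, 100_000), OrientedSegment("Chr02A", 50_001, 100_000)),
        ]
        with pytest.raises(ValueError, match="contradictory"):
            build_pairing_complex(ga, gb, blocks)


class TestNewChromosomes:
    @pytest.fixture()
    def printed_registry(self):
        # chromosome lengths large enough for the printed junction coordinates
        return {
            "Chr01B": whole_chromosome_model("Chr01B", 6_590_000, (3_000_001, 3_040_000)),
            "Chr05B": whole_chromosome_model("Chr05B", 4_560_000, (2_000_001, 2_040_000)),
            "Chr12B": whole_chromosome_model("Chr12B", 1_510_000, None),
        }

    def test_chrn1_model_from_printed_coordinates(self, printed_registry):
        rule = JunctionRule("ChrN1", "Chr01B", 58_690, "Chr12B", 172_535, probability=1.0)
        model = assemble_junction_product(rule, printed_registry)
        assert model.segments == CHRN1_SEGMENTS
        assert model.length == 231_225  # 0.23 Mb
        assert model.telomere_5p and model.telomere_3p
        assert not model.has_centromere

    def test_chrn2_model_from_printed_coordinates(self, printed_registry):
        rule = JunctionRule("ChrN2", "Chr05B", 675_684, "Chr12B", 834_373, probability=1.0)
        model = assemble_junction_product(rule, printed_registry)
        assert model.segments == CHRN2_SEGMENTS
        assert model.length == 675_684 + 834_373 == 1_510_057
        assert model.stable and not model.has_centromere

    def test_rules_with_absent_chromatids_emit_nothing(self):
        ga = _coordinate_genome("A", [("Chr03A", 100_000, (50_001, 52_000))])
        gb = _coordinate_genome("B", [("Chr03B", 100_000, (50_001, 52_000))])
        blocks = [
            HomologyBlock(OrientedSegment("Chr03A", 1, 100_000), OrientedSegment("Chr03B", 1, 100_000))
        ]
        cx = build_pairing_complex(ga, gb, blocks)
        rules = [JunctionRule("ChrN1", "Chr01B", 10, "Chr12B", 10, probability=1.0)]
        assert form_new_chromosomes(cx, rules, np.random.default_rng(0)) == []

    def test_out_of_bounds_rule_rejected(self, printed_registry):
        rule = JunctionRule("bad", "Chr12B", 2_000_000, "Chr01B", 10, probability=1.0)
        with pytest.raises(ValueError):
            assemble_junction_product(rule, printed_registry)


class TestSegregation:
    def test_symmetric_dikaryon_every_product_euploid(self):
        model = reduced_asymmetric_model()
        model = MeiosisModel(
            chromosomes={k: v for k, v in model.chromosomes.items() if k != "Chr12B"},
            pairs=model.pairs,
            essential_units=[],
        )
        rng = np.random.default_rng(0)
        for _ in range(50):
            products = segregate(model, rng)
            for prod in products:
                ids = sorted(m.id for m in prod)
                assert len(ids) == len(model.pairs)
                bases = {i[:-1] for i in ids}
                assert len(bases) == len(model.pairs)

    def test_acentric_full_bias_always_colocates(self):
        model = reduced_asymmetric_model(acentric_bias=1.0)
        rng = np.random.default_rng(1)
        for _ in range(100):
            products = segregate(model, rng)
            partner_products = [i for i, p in enumerate(products) if any(m.id == "Chr05A" for m in p)]
            chr12_products = [i for i, p in enumerate(products) for m in p if m.id == "Chr12B"]
            assert set(chr12_products) <= set(partner_products)

    def test_acentric_uniform_bias_is_binomial(self):
        model = reduced_asymmetric_model(acentric_bias=0.5)
        rng = np.random.default_rng(2)
        n, with_partner = 0, 0
        for _ in range(10_000):
            products = segregate(model, rng)
            partner_pole = {i for i, p in enumerate(products) if any(m.id == "Chr05A" for m in p)}
            for i, p in enumerate(products):
                for m in p:
                    if m.id == "Chr12B":
                        n += 1
                        with_partner += i in partner_pole
        frac = with_partner / n
        se = np.sqrt(0.25 / n)
        assert abs(frac - 0.5) <= 3 * se


class TestViability:
    def test_architecture_complements(self):
        model = reduced_asymmetric_model()
        a_set = [model.chromosomes[c] for c in ("Chr01A", "Chr02A", "Chr05A")]
        b_set = [model.chromosomes[c] for c in ("Chr01B", "Chr02B", "Chr05B")]
        chr12 = model.chromosomes["Chr12B"]
        assert viability(a_set, model.essential_units)  # arm content via Chr05A
        assert not viability(b_set, model.essential_units)  # missing the arm
        assert viability(b_set + [chr12], model.essential_units)
        # mixed architecture misses a translocated cassette
        mixed = [model.chromosomes[c] for c in ("Chr01A", "Chr02B", "Chr05A")]
        assert not viability(mixed + [chr12], model.essential_units)

    def test_missing_essential_segment_is_inviable(self):
        unit = EssentialUnit("u", (("Chr01A", 10_001, 12_000),))
        carrier = whole_chromosome_model("Chr01A", 500_000, (250_001, 252_000))
        assert viability([carrier], [unit])
        truncated = carrier.__class__(
            id="Chr01A:frag",
            segments=(OrientedSegment("Chr01A", 20_000, 500_000),),
            telomere_5p=False,
            telomere_3p=True,
            has_centromere=True,
        )
        assert not viability([truncated], [unit])

    def test_required_fraction_relaxes_the_rule(self):
        units = [EssentialUnit(f"u{i}", ((f"Chr0{i}A", 1, 100),)) for i in range(1, 5)]
        carried = [whole_chromosome_model(f"Chr0{i}A", 1_000, None) for i in (1, 2, 3)]
        assert not viability(carried, units, required_fraction=1.0)
        assert viability(carried, units, required_fraction=0.75)


class TestCohort:
    def test_conservation_across_meioses(self):
        """Every parental base totals two copies across the four products,
        including bases relocated into new chromosomes and fragments."""
        model = reduced_asymmetric_model(junction_probability=0.5, acentric_bias=0.7)
        rng = np.random.default_rng(3)
        for _ in range(300):
            outcome = run_meiosis(model, rng)
            assert check_conservation(outcome.products_prefilter, model)

    def test_unstable_fragments_are_dropped_and_counted(self):
        model = reduced_asymmetric_model(junction_probability=1.0)
        rng = np.random.default_rng(4)
        outcome = run_meiosis(model, rng)
        assert outcome.n_dropped_unstable >= 1
        for prod in outcome.products:
            assert all(m.stable for m in prod)

    def test_zero_probability_reduces_to_mendelian(self):
        model = reduced_asymmetric_model(junction_probability=0.0)
        rng = np.random.default_rng(5)
        parental = set(model.chromosomes)
        for _ in range(200):
            outcome = run_meiosis(model, rng)
            assert outcome.fired == ()
            for prod in outcome.products:
                assert {m.id for m in prod} <= parental

    def test_enumeration_matches_monte_carlo(self):
        model = reduced_asymmetric_model(acentric_bias=0.7)
        _, enum = enumerate_cohort(model)
        _, mc = simulate_cohort(model, n_meioses=10_000, rng_seed=6)
        n_products = 40_000
        for key in ("viability_fraction",):
            p = enum[key]
            se = np.sqrt(p * (1 - p) / n_products)
            assert abs(mc[key] - p) <= 3 * se
        for arch in ("A", "B"):
            p = enum["architecture_fractions"].get(arch, 0.0)
            q = mc["architecture_fractions"].get(arch, 0.0)
            se = np.sqrt(p * (1 - p) / (n_products * enum["viability_fraction"]))
            assert abs(q - p) <= 3 * se

    def test_viable_spores_favor_a_architecture(self):
        """With biased acentric migration, viable spores are predominantly
        A-architecture (exhaustive enumeration, no sampling error)."""
        _, enum = enumerate_cohort(reduced_asymmetric_model(acentric_bias=0.7))
        arch = enum["architecture_fractions"]
        assert arch.get("A", 0.0) > arch.get("B", 0.0)

    def test_crossovers_conserve_and_type_by_content(self, truth):
        """With crossovers forced on, recombinant homologs appear, every base
        still totals two copies, and marker-based architecture typing still
        resolves pure-arrangement products."""
        from meiospore.synthetic_data import meiosis_model_from_truth

        model = meiosis_model_from_truth(
            truth, crossover_probability=1.0, junction_probability=0.0
        )
        rng = np.random.default_rng(8)
        saw_recombinant = False
        for _ in range(20):
            outcome = run_meiosis(model, rng)
            assert check_conservation(outcome.products_prefilter, model)
            for prod in outcome.products:
                if any(":xo" in m.id for m in prod):
                    saw_recombinant = True
        assert saw_recombinant

    def test_symmetric_cohort_fully_viable_euploid(self):
        base = reduced_asymmetric_model()
        sym = MeiosisModel(
            chromosomes={k: v for k, v in base.chromosomes.items() if k != "Chr12B"},
            pairs=base.pairs,
            essential_units=[
                u for u in base.essential_units if all(c != "Chr12B" for c, _, _ in u.locations)
            ],
            architecture_pairs=base.pairs,
        )
        # make the B complement self-sufficient: drop cassette/arm units that
        # encode the asymmetry
        sym.essential_units = [u for u in sym.essential_units if u.id.startswith("core")]
        _, summary = simulate_cohort(sym, n_meioses=500, rng_seed=7)
        assert summary["viability_fraction"] == 1.0
        assert summary["aneuploidy_type_fractions"] == {"euploid": 1.0}
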