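"""Generator and evidence-simulator properties: determinism, planted-truth
closure, mosaic calibration, depth/allele sampling models."""

from __future__ import annotations

import numpy as np
import pytest

from meiospore.coords import overlap_length
from meiospore.genome_model import detect_telomere
from meiospore.synthetic_data import (
    DikaryonConfig,
    architecture_genotype,
    eligible_switch_boundaries,
    generate_dikaryon,
    recombinant_genotype,
    simulate_evidence,
)


def _plain_config(**kw) -> DikaryonConfig:
    """A structurally featureless dikaryon: collinear homologs only."""
    base = dict(
        core_lengths={"Chr01": 200_000, "Chr02": 150_000},
        accessory_lengths={},
        accessory_compartments={},
        low_het_chromosomes=(),
        architecture_cassettes={},
        cassette_cycle=(),
        acentric_extra=False,
        orphan_prefixes={},
        rng_seed=1,
    )
    base.update(kw)
    return DikaryonConfig(**base)


class TestGenerator:
    def test_same_seed_is_byte_identical(self):
        cfg = DikaryonConfig(rng_seed=3)
        a1, b1, t1 = generate_dikaryon(cfg)
        a2, b2, t2 = generate_dikaryon(DikaryonConfig(rng_seed=3))
        for c1, c2 in zip(a1.chromosomes + b1.chromosomes, a2.chromosomes + b2.chromosomes):
            assert c1.sequence == c2.sequence
        assert t1.bins.equals(t2.bins)
        assert t1.snps.equals(t2.snps)

    def test_zero_divergence_yields_identical_haplotypes(self):
        cfg = _plain_config(heterozygosity_mosaic=[(1.0, 0.0)])
        a, b, _ = generate_dikaryon(cfg)
        for ca, cb in zip(a.chromosomes, b.chromosomes):
            assert ca.sequence == cb.sequence

    def test_extra_chromosome_structure(self, dikaryon):
        genome_a, genome_b, truth = dikaryon
        assert len(genome_b.chromosomes) == len(genome_a.chromosomes) + 1
        extra = genome_b.chromosome("Chr12B")
        assert extra.centromere is None
        # most of the extra chromosome aligns to the donor arm in the truth map
        aligned = sum(
            b.seg_b.length for b in truth.homology if b.seg_b.chrom == "Chr12B"
        )
        assert aligned / extra.length >= 0.8
        donor_blocks = [b for b in truth.homology if b.seg_b.chrom == "Chr12B"]
        assert all(b.seg_a.chrom == "Chr05A" for b in donor_blocks)

    def test_all_ends_telomere_capped(self, dikaryon):
        genome_a, genome_b, _ = dikaryon
        for g in (genome_a, genome_b):
            for c in g.chromosomes:
                present5, _ = detect_telomere(c.sequence[:200], "5p")
                present3, _ = detect_telomere(c.sequence[-200:], "3p")
                assert present5 and present3, c.id

    def test_mosaic_fractions_calibrated(self):
        """Realized per-bin density histogram matches the configured mosaic
        within 3 binomial standard errors (10 Mb, 1000 bins)."""
        mosaic = [(0.2, 0.0005), (0.8, 0.02)]
        cfg = _plain_config(
            core_lengths={"Chr01": 10_000_000},
            heterozygosity_mosaic=mosaic,
            emit_sequence=False,
            rng_seed=5,
        )
        _, _, truth = generate_dikaryon(cfg)
        n = len(truth.bins)
        assert n == 1000
        for frac, dens in mosaic:
            realized = float((truth.bins["density"] == dens).mean())
            se = np.sqrt(frac * (1 - frac) / n)
            assert abs(realized - frac) <= 3 * se

    def test_rejects_oversized_orphan(self):
        with pytest.raises(ValueError):
            _plain_config(orphan_prefixes={"Chr01": 300_000})

    def test_planted_truth_closure(self):
        """Independent re-scan: base-by-base mismatches inside homology blocks
        equal the planted diagnostic SNPs, exactly."""
        cfg = DikaryonConfig(
            core_lengths={"Chr01": 120_000, "Chr02": 100_000, "Chr05": 100_000},
            accessory_lengths={"Chr09": 40_000},
            accessory_compartments={},
            low_het_chromosomes=("Chr09",),
            architecture_cassettes={
                "Chr01": (40_001, 60_000),
                "Chr02": (30_001, 50_000),
                "Chr05": (20_001, 40_000),
            },
            acentric_donor_arm=("Chr05", 60_001, 100_000),
            extra_orphan_length=20_000,
            orphan_prefixes={"Chr01": 10_000},
            rng_seed=13,
        )
        genome_a, genome_b, truth = generate_dikaryon(cfg)
        seqs = {c.id: c.sequence for g in (genome_a, genome_b) for c in g.chromosomes}
        planted = {
            (row.chrom, int(row.pos)) for row in truth.snps.itertuples(index=False)
        }
        rescanned = set()
        for block in truth.homology:
            sa, sb = block.seg_a, block.seg_b
            a = seqs[sa.chrom][sa.start - 1 : sa.end]
            b = seqs[sb.chrom][sb.start - 1 : sb.end]
            assert len(a) == len(b)
            for i, (x, y) in enumerate(zip(a, b)):
                if x != y:
                    rescanned.add((sa.chrom, sa.start + i))
        assert rescanned == planted


class TestEvidence:
    def test_same_seed_evidence_identical(self, truth):
        g = architecture_genotype(truth, "A")
        e1 = simulate_evidence(g, truth, rng_seed=42)
        e2 = simulate_evidence(g, truth, rng_seed=42)
        assert e1.bin_allele_counts.equals(e2.bin_allele_counts)
        assert e1.depth_windows.equals(e2.depth_windows)
        assert e1.junction_reads.equals(e2.junction_reads)

    def test_pure_a_genotype_error_free_has_no_b_alleles(self, truth):
        g = architecture_genotype(truth, "A")
        ev = simulate_evidence(g, truth, allele_error=0.0, rng_seed=1)
        assert int(ev.bin_allele_counts["n_b"].sum()) == 0

    def test_two_copy_region_depth(self, truth):
        """A region carried at 2 copies at 30x coverage shows ~60x depth."""
        g = architecture_genotype(truth, "A")
        # duplicate Chr03A in the complement
        g.complement = [(m, 2 if m.id == "Chr03A" else n) for m, n in g.complement]
        ev = simulate_evidence(g, truth, coverage=30, rng_seed=2)
        win = ev.depth_windows
        sub = win[win["chrom"] == "Chr03A"]["depth"].to_numpy()
        # windows are Poisson-read sampled; SE of the mean over the windows
        reads_per_window = 60 * 2000 / 150
        se = 60 / np.sqrt(reads_per_window * len(sub))
        assert abs(sub.mean() - 60.0) <= 3 * se

    def test_depth_unbiased_over_windows(self, truth):
        g = architecture_genotype(truth, "A")
        ev = simulate_evidence(g, truth, coverage=30, rng_seed=3)
        win = ev.depth_windows
        a_chroms = {f"{c}A" for c in truth.config.aframe_lengths}
        sub = win[win["chrom"].isin(a_chroms)]["depth"].to_numpy()
        assert len(sub) >= 1000
        assert 0.97 <= sub.mean() / 30.0 <= 1.03

    def test_junction_support_and_broken_reference(self, truth):
        g = architecture_genotype(truth, "A", extras=("ChrN1",))
        ev = simulate_evidence(g, truth, coverage=30, rng_seed=4)
        j = ev.junction_reads
        novel = j[(j["chrom_x"] == "Chr01B") & (j["chrom_y"] == "Chr12B")]
        assert len(novel) == 1
        row = novel.iloc[0]
        assert row["support"] > 0
        assert row["ref_span_x"] == 0 and row["ref_span_y"] == 0

    def test_mixture_weight_averaged_depth(self, truth):
        base = architecture_genotype(truth, "A", isolate_id="mix")
        dup = architecture_genotype(truth, "A", isolate_id="mix")
        dup.complement = [(m, 2 if m.id == "Chr11A" else n) for m, n in dup.complement]
        ev = simulate_evidence([(base, 0.5), (dup, 0.5)], truth, coverage=30, rng_seed=5)
        sub = ev.depth_windows.query("chrom == 'Chr11A'")["depth"]
        assert abs(sub.mean() / 30.0 - 1.5) < 0.1

    def test_recombinant_genotype_switches_are_planted(self, truth):
        boundaries = eligible_switch_boundaries(truth, "Chr02")
        assert len(boundaries) >= 3
        cut = boundaries[len(boundaries) // 2]
        g = recombinant_genotype(truth, {"Chr02": [cut]}, isolate_id="rec")
        ev = simulate_evidence(g, truth, allele_error=0.0, rng_seed=6)
        counts = ev.bin_allele_counts
        sub = counts[(counts["chrom"] == "Chr02A") & counts["informative"]]
        left = sub[sub["end"] <= cut]
        right = sub[sub["start"] > cut]
        assert int(left["n_b"].sum()) == 0
        assert int(right["n_a"].sum()) == 0
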