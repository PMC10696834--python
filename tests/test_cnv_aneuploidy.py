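"""Depth normalization, half-grid copy states, mixture inversion, whole-
chromosome aneuploidy, LOH runs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meiospore.bin_genotyping import BinOriginCall, classify_bins
from meiospore.cnv_aneuploidy import (
    call_region_state,
    call_whole_chromosome_aneuploidy,
    detect_loh,
    infer_mixture_fraction,
    normalize_depth,
)
from meiospore.synthetic_data import architecture_genotype, simulate_evidence


def _windows(depths, chrom="Chr01A", size=10_000):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.arange(len(depths)) * size + 1,
            "end": (np.arange(len(depths)) + 1) * size,
            "depth": depths,
        }
    )


def _het_bins(states, chrom="Chr05A", size=10_000, offset=0):
    return [
        BinOriginCall(chrom, offset + i * size + 1, offset + (i + 1) * size, 0, 0, True, s)
        for i, s in enumerate(states)
    ]


class TestNormalizeDepth:
    def test_constant_depth_gives_unit_ratio(self):
        out = normalize_depth(_windows([30.0] * 60))
        assert np.allclose(out["ratio"], 1.0)

    def test_ratio_arithmetic(self):
        depths = [30.0] * 60 + [54.0]
        out = normalize_depth(_windows(depths))
        assert out["ratio"].iloc[-1] == pytest.approx(1.8)

    def test_rejects_small_baseline(self):
        with pytest.raises(ValueError):
            normalize_depth(_windows([30.0] * 10))

    def test_control_isolate_second_normalization(self):
        win = _windows([30.0] * 60)
        ctrl = normalize_depth(_windows([15.0] * 60))
        ctrl["ratio"] = 0.5
        out = normalize_depth(win, control_ratios=ctrl)
        assert np.allclose(out["ratio"], 2.0)

    def test_zero_copy_chromosome(self, truth):
        """A chromosome absent from the genotype shows near-zero ratio."""
        g = architecture_genotype(truth, "A")
        g.complement = [(m, n) for m, n in g.complement if m.id != "Chr09A"]
        ev = simulate_evidence(g, truth, coverage=30, rng_seed=12)
        core = [("Chr01A", 250_000, 450_000), ("Chr02A", 1, 150_000), ("Chr03A", 1, 300_000)]
        out = normalize_depth(ev.depth_windows, core)
        chr09 = out[out["chrom"] == "Chr09A"]["ratio"]
        assert chr09.mean() < 0.05


class TestRegionState:
    @pytest.mark.parametrize("mean,state", [(0.51, 0.5), (1.49, 1.5), (1.0, 1.0), (2.02, 2.0)])
    def test_half_grid_snapping(self, mean, state):
        call = call_region_state([mean] * 20)
        assert call.state == state and not call.is_mixture

    def test_off_grid_routes_to_mixture(self):
        call = call_region_state([1.8] * 20)
        assert call.state is None
        low, high, f = call.mixture
        assert (low, high) == (1, 2)
        assert f == pytest.approx(0.8)

    def test_needs_three_windows(self):
        with pytest.raises(ValueError):
            call_region_state([1.0, 1.0])


class TestMixtureFraction:
    @pytest.mark.parametrize("ratio,f", [(1.8, 0.8), (2.0, 1.0), (1.0, 0.0)])
    def test_examples(self, ratio, f):
        assert infer_mixture_fraction(ratio, 1, 2) == pytest.approx(f)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            infer_mixture_fraction(2.5, 1, 2)

    @given(f=st.floats(0.0, 1.0), low=st.integers(0, 3), span=st.integers(1, 3))
    @settings(max_examples=200, deadline=None)
    def test_inverts_forward_model_exactly(self, f, low, span):
        high = low + span
        ratio = low * (1 - f) + high * f
        assert infer_mixture_fraction(ratio, low, high) == pytest.approx(f, abs=1e-12)


class TestWholeChromosomeAneuploidy:
    def test_whole_loss(self):
        ratios = pd.concat(
            [
                _windows([1.0] * 30, "Chr01A").assign(ratio=lambda d: d["depth"]),
                _windows([0.0] * 30, "Chr09A").assign(ratio=0.0),
            ]
        )
        calls = call_whole_chromosome_aneuploidy(ratios[["chrom", "start", "end", "ratio"]])
        assert list(calls["chrom"]) == ["Chr09A"]
        assert calls.iloc[0]["change"] == "loss"

    def test_euploid_reports_nothing(self):
        ratios = _windows([1.0] * 30).assign(ratio=1.0)
        calls = call_whole_chromosome_aneuploidy(ratios[["chrom", "start", "end", "ratio"]])
        assert calls.empty

    def test_segmental_change_not_called_whole(self):
        r = np.concatenate([np.ones(25), np.full(5, 2.0)])
        ratios = _windows(r).assign(ratio=r)
        calls = call_whole_chromosome_aneuploidy(ratios[["chrom", "start", "end", "ratio"]])
        assert calls.empty

    def test_planted_gain_recovered_in_simulation(self, truth):
        g = architecture_genotype(truth, "A")
        g.complement = [(m, 2 if m.id == "Chr10A" else n) for m, n in g.complement]
        ev = simulate_evidence(g, truth, coverage=30, rng_seed=13)
        core = [("Chr01A", 250_000, 450_000), ("Chr02A", 1, 150_000), ("Chr03A", 1, 300_000)]
        ratios = normalize_depth(ev.depth_windows, core)
        a_chroms = {f"{c}A" for c in truth.config.aframe_lengths}
        calls = call_whole_chromosome_aneuploidy(
            ratios[ratios["chrom"].isin(a_chroms)], expected=1.0
        )
        assert list(calls["chrom"]) == ["Chr10A"]
        assert calls.iloc[0]["change"] == "gain"

    def test_euploid_false_positive_rate_zero(self, truth):
        """Across replicate euploid isolates, no whole-chromosome call."""
        core = [("Chr01A", 250_000, 450_000), ("Chr02A", 1, 150_000), ("Chr03A", 1, 300_000)]
        a_chroms = {f"{c}A" for c in truth.config.aframe_lengths}
        g = architecture_genotype(truth, "A")
        for seed in range(25):
            ev = simulate_evidence(g, truth, coverage=30, rng_seed=100 + seed)
            ratios = normalize_depth(ev.depth_windows, core)
            calls = call_whole_chromosome_aneuploidy(
                ratios[ratios["chrom"].isin(a_chroms)], expected=1.0
            )
            assert calls.empty


class TestDetectLoh:
    def test_all_het_reports_nothing(self):
        assert detect_loh(_het_bins(["HET"] * 40)) == []

    def test_planted_run_recovered(self):
        states = ["HET"] * 10 + ["A"] * 75 + ["HET"] * 10
        intervals = detect_loh(_het_bins(states))
        assert len(intervals) == 1
        chrom, s, e = intervals[0]
        assert s == 10 * 10_000 + 1 and e == 85 * 10_000

    def test_two_separated_runs(self):
        states = ["HET"] * 5 + ["A"] * 10 + ["HET"] * 5 + ["B"] * 8 + ["HET"] * 5
        assert len(detect_loh(_het_bins(states))) == 2

    def test_short_runs_ignored(self):
        states = ["HET"] * 10 + ["A"] + ["HET"] * 10
        assert detect_loh(_het_bins(states), min_run=2) == []

    def test_loh_on_extra_chromosome_in_simulation(self, truth):
        """An isolate carrying an extra Chr12B whose middle arm content was
        replaced by A-origin sequence shows one LOH run over those bins."""
        from meiospore.genome_model import OrientedSegment
        from meiospore.meiosis_sim import ChromosomeModel

        donor, arm_s, arm_e = truth.config.acentric_donor_arm
        olen = truth.config.extra_orphan_length
        # replace Chr12B content for A-frame interval [370k, 410k] of the arm
        lo_src = olen + (370_000 - arm_s) + 1
        hi_src = olen + (410_000 - arm_s) + 1
        loh_model = ChromosomeModel(
            id="Chr12B:loh",
            segments=(
                OrientedSegment("Chr12B", 1, lo_src - 1),
                OrientedSegment(f"{donor}A", 370_000, 410_000 - 1),
                OrientedSegment("Chr12B", hi_src, truth.config.extra_length),
            ),
            telomere_5p=True,
            telomere_3p=True,
            has_centromere=False,
        )
        g = architecture_genotype(truth, "A")
        g.complement.append((loh_model, 1))
        ev = simulate_evidence(g, truth, coverage=40, allele_error=0.0, rng_seed=14)
        calls = classify_bins(ev.bin_allele_counts)
        arm_calls = [
            c
            for c in calls
            if c.chrom == f"{donor}A" and c.start >= arm_s and c.end <= arm_e and c.informative
        ]
        assert any(c.state == "HET" for c in arm_calls)
        intervals = detect_loh(arm_calls)
        assert len(intervals) == 1
        chrom, s, e = intervals[0]
        assert s >= 360_001 and e <= 420_000
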