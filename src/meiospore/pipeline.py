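"""End-to-end pipeline: simulate -> genotype -> cnv -> junctions -> karyotype -> report.

A single config (YAML/JSON-compatible dict) drives every stage; one seed
fans out deterministically to per-stage child seeds (numpy ``SeedSequence``
spawning), so re-running an identical config reproduces identical outputs
byte for byte and any stage can be recomputed in isolation.

The junction stage only considers joins between *different* base
chromosomes: a join between the A and B copies of one chromosome is a
homologous-recombination switch, which belongs to the bin-genotyping stage,
not a new chromosome.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import bin_genotyping, cnv_aneuploidy, junction_karyotype
from .genome_model import OrientedSegment
from .io import write_bed, write_fasta, write_genome_metadata, write_tsv
from .meiosis_sim import run_meiosis, SporeGenotype
from .synthetic_data import (
    DikaryonConfig,
    generate_dikaryon,
    meiosis_model_from_truth,
    simulate_evidence,
)

logger = logging.getLogger("meiospore")

STAGES = ("simulate", "genotype", "cnv", "junctions", "karyotype", "report")

DEFAULT_CONFIG: dict = {
    "outdir": "meiospore_run",
    "seed": 0,
    "n_isolates": 12,
    "max_meioses": 2000,
    "coverage": 30.0,
    "allele_error": 0.01,
    "read_length": 150,
    "window_size": 2000,
    "acentric_bias": 0.8,
    "junction_probability": 0.08,
    "crossover_probability": 0.25,
    "accessory_loss_rate": 0.05,
    "mixture_rate": 0.1,
    "min_reads": 5,
    "purity": 0.9,
    "min_run": 2,
    "merge_distance": 10,
    "grid_tolerance": 0.1,
    "min_step": 0.4,
    "inflection_flank": 5,
    "min_support": 3,
    "max_ref_span": 0,
    "dikaryon": {},  # overrides for DikaryonConfig fields
}


def validate_config(config: dict) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    unknown = set(config) - set(cfg)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg.update(config)
    if not 0.5 < cfg["purity"] <= 1.0:
        raise ValueError("config key 'purity' must be in (0.5, 1]")
    if cfg["n_isolates"] < 1:
        raise ValueError("config key 'n_isolates' must be >= 1")
    for key in ("coverage", "window_size", "read_length"):
        if cfg[key] <= 0:
            raise ValueError(f"config key '{key}' must be positive")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# cohort construction
# ---------------------------------------------------------------------------


def _build_cohort(truth, cfg: dict, rng: np.random.Generator) -> list[dict]:
    """Viable monospore isolates sampled from simulated meioses.

    Returns per-isolate records with the genotype (or karyotype mixture) and
    the planted truth (architecture, extras, switches).
    """
    model = meiosis_model_from_truth(
        truth,
        acentric_bias=cfg["acentric_bias"],
        junction_probability=cfg["junction_probability"],
        crossover_probability=cfg["crossover_probability"],
    )
    dik = truth.config
    accessory_ids = [f"{c}A" for c in dik.accessory_lengths] + [
        f"{c}B" for c in dik.accessory_lengths
    ]
    isolates: list[dict] = []
    n_meioses = 0
    while len(isolates) < cfg["n_isolates"] and n_meioses < cfg["max_meioses"]:
        outcome = run_meiosis(model, rng)
        n_meioses += 1
        for prod in outcome.products:
            if len(isolates) >= cfg["n_isolates"]:
                break
            from .meiosis_sim import architecture_of, extras_of, viability

            if not viability(prod, model.essential_units, model.required_fraction):
                continue
            arch = architecture_of(prod, model.architecture_pairs or [], model.architecture_markers)
            if arch == "unresolved":
                continue
            models = list(prod)
            # occasional meiotic loss of an accessory chromosome
            lost = [
                m.id
                for m in models
                if m.id in accessory_ids and rng.random() < cfg["accessory_loss_rate"]
            ]
            models = [m for m in models if m.id not in lost]
            extras = extras_of(models, model, arch)
            name = f"DBZ{len(isolates) + 1:02d}"
            counts: dict[str, int] = {}
            by_id = {}
            for m in models:
                counts[m.id] = counts.get(m.id, 0) + 1
                by_id[m.id] = m
            genotype = SporeGenotype(
                isolate_id=name,
                complement=[(by_id[i], n) for i, n in counts.items()],
                viable=True,
                architecture=arch,
                extras=extras,
            )
            mixture = None
            if truth.config.accessory_lengths and rng.random() < cfg["mixture_rate"]:
                # a karyotype mixture: half the cells carry a second copy of
                # one accessory chromosome (1.5x whole-culture depth)
                candidates = [i for i in counts if i in accessory_ids]
                if candidates:
                    dup = candidates[int(rng.integers(len(candidates)))]
                    extra_geno = SporeGenotype(
                        isolate_id=name,
                        complement=[(m, n + (1 if i == dup else 0)) for (m, n), i in
                                    zip(genotype.complement, counts)],
                        architecture=arch,
                    )
                    mixture = [(genotype, 0.5), (extra_geno, 0.5)]
            isolates.append(
                {
                    "isolate": name,
                    "genotype": genotype,
                    "mixture": mixture,
                    "architecture": arch,
                    "extras": extras,
                    "lost": tuple(lost),
                }
            )
    return isolates


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def run_pipeline(
    config: Optional[dict] = None,
    stages: Sequence[str] = STAGES,
    seed: Optional[int] = None,
) -> dict:
    """Run the pipeline stages in dependency order; returns the manifest.

    Earlier stages a selected stage depends on are recomputed in memory
    (deterministic under the run seed); outputs are written only for the
    selected stages.  The manifest records config, seeds and sha256
    checksums of every written output.
    """
    cfg = validate_config(config or {})
    if seed is not None:
        cfg["seed"] = int(seed)
    for st in stages:
        if st not in STAGES:
            raise ValueError(f"unknown stage {st!r}")
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(cfg["seed"])
    seeds = {name: rng_seed for name, rng_seed in zip(STAGES, root.generate_state(len(STAGES)))}
    written: list[Path] = []

    def save_tsv(df: pd.DataFrame, name: str, stage: str) -> None:
        if stage in stages:
            path = outdir / name
            path.parent.mkdir(parents=True, exist_ok=True)
            write_tsv(df, path)
            written.append(path)

    # --- simulate ---------------------------------------------------------
    dik_cfg = DikaryonConfig(**{"rng_seed": int(seeds["simulate"]) % (2**31), **cfg["dikaryon"]})
    genome_a, genome_b, truth = generate_dikaryon(dik_cfg)
    rng_cohort = np.random.default_rng(int(seeds["simulate"]) % (2**31) + 1)
    cohort = _build_cohort(truth, cfg, rng_cohort)
    logger.info("simulate: %d isolates from dikaryon (seed %s)", len(cohort), cfg["seed"])

    evidence = {}
    rng_ev = np.random.default_rng(int(seeds["simulate"]) % (2**31) + 2)
    for rec in cohort:
        evidence[rec["isolate"]] = simulate_evidence(
            rec["mixture"] or rec["genotype"],
            truth,
            coverage=cfg["coverage"],
            allele_error=cfg["allele_error"],
            read_length=cfg["read_length"],
            window_size=cfg["window_size"],
            rng_seed=rng_ev,
            isolate_id=rec["isolate"],
        )

    if "simulate" in stages:
        if dik_cfg.emit_sequence:
            write_fasta(genome_a, outdir / "haplotypeA.fasta")
            write_fasta(genome_b, outdir / "haplotypeB.fasta")
            written += [outdir / "haplotypeA.fasta", outdir / "haplotypeB.fasta"]
        for g, name in ((genome_a, "A"), (genome_b, "B")):
            write_genome_metadata(g, outdir / f"haplotype{name}.meta.json")
            written.append(outdir / f"haplotype{name}.meta.json")
            for track, feats in g.tracks.items():
                p = outdir / f"haplotype{name}.{track}.bed"
                write_bed(feats, p)
                written.append(p)
        save_tsv(truth.bins, "truth_bins.tsv", "simulate")
        save_tsv(truth.snps, "truth_snps.tsv", "simulate")
        iso_truth = pd.DataFrame(
            {
                "isolate": [r["isolate"] for r in cohort],
                "architecture": [r["architecture"] for r in cohort],
                "extras": [",".join(r["extras"]) for r in cohort],
                "lost": [",".join(r["lost"]) for r in cohort],
                "mixture": [r["mixture"] is not None for r in cohort],
            }
        )
        save_tsv(iso_truth, "truth_isolates.tsv", "simulate")
        for name, ev in evidence.items():
            save_tsv(ev.bin_allele_counts, f"isolates/{name}.bins.tsv", "simulate")
            save_tsv(ev.depth_windows, f"isolates/{name}.depth.tsv", "simulate")
            save_tsv(ev.junction_reads, f"isolates/{name}.junctions.tsv", "simulate")
            save_tsv(ev.breakpoint_reads, f"isolates/{name}.breakpoints.tsv", "simulate")

    # --- genotype ---------------------------------------------------------
    all_calls: dict[str, list] = {}
    all_events = []
    origin_rows = []
    for name, ev in evidence.items():
        calls = bin_genotyping.classify_bins(
            ev.bin_allele_counts, min_reads=cfg["min_reads"], purity=cfg["purity"]
        )
        all_calls[name] = calls
        for chrom in sorted({c.chrom for c in calls}):
            chrom_calls = [c for c in calls if c.chrom == chrom]
            all_events.extend(
                bin_genotyping.call_events(chrom_calls, isolate=name, min_run=cfg["min_run"])
            )
        pct_a, pct_b, pct_het = bin_genotyping.origin_fraction(calls)
        origin_rows.append({"isolate": name, "pct_a": pct_a, "pct_b": pct_b, "pct_het": pct_het})
    sites = bin_genotyping.aggregate_sites(all_events, merge_distance=cfg["merge_distance"])
    events_df = pd.DataFrame(
        [
            {
                "isolate": e.isolate, "chrom": e.chrom, "start": e.start, "end": e.end,
                "left_state": e.left_state, "right_state": e.right_state,
            }
            for e in all_events
        ],
        columns=["isolate", "chrom", "start", "end", "left_state", "right_state"],
    )
    sites_df = pd.DataFrame(
        [
            {
                "chrom": s.chrom, "start": s.start, "end": s.end,
                "n_isolates": s.n_isolates, "n_events": s.n_events, "hotspot": s.hotspot,
            }
            for s in sites
        ],
        columns=["chrom", "start", "end", "n_isolates", "n_events", "hotspot"],
    )
    origins_df = pd.DataFrame(origin_rows, columns=["isolate", "pct_a", "pct_b", "pct_het"])
    if "genotype" in stages:
        save_tsv(events_df, "events.tsv", "genotype")
        save_tsv(sites_df, "sites.tsv", "genotype")
        save_tsv(origins_df, "origin_fractions.tsv", "genotype")
        for name, calls in all_calls.items():
            save_tsv(bin_genotyping.calls_to_frame(calls), f"genotype/{name}.calls.tsv", "genotype")

    # --- cnv --------------------------------------------------------------
    dik = truth.config
    baseline_regions = []
    for chrom, length in dik.core_lengths.items():
        comp = dik.accessory_compartments.get(chrom)
        donor, arm_s, _ = dik.acentric_donor_arm
        lo = comp[1] + 1 if comp else 1
        hi = arm_s - 1 if (dik.acentric_extra and chrom == donor) else length
        if lo < hi:
            baseline_regions.append((f"{chrom}A", lo, hi))
    expected = {f"{c}A": 1.0 for c in dik.aframe_lengths}
    for chrom in dik.orphan_prefixes:
        expected[f"{chrom}B"] = 0.0
    if dik.acentric_extra:
        expected[dik.extra_chrom_id] = 0.0

    ratio_frames = {}
    cnv_rows = []
    loh_rows = []
    for name, ev in evidence.items():
        ratios = cnv_aneuploidy.normalize_depth(ev.depth_windows, baseline_regions)
        ratio_frames[name] = ratios
        calls = cnv_aneuploidy.call_whole_chromosome_aneuploidy(
            ratios, expected=expected, grid_tolerance=cfg["grid_tolerance"]
        )
        for _, row in calls.iterrows():
            cnv_rows.append({"isolate": name, **row.to_dict()})
        # LOH scan over the donor-arm bins when an extra Chr12B is carried
        if dik.acentric_extra:
            donor, arm_s, arm_e = dik.acentric_donor_arm
            arm_calls = [
                c
                for c in all_calls[name]
                if c.chrom == f"{donor}A" and c.start >= arm_s and c.end <= arm_e
            ]
            extra_state = _region_state(ratios, dik.extra_chrom_id, cfg)
            if extra_state is not None and extra_state >= 0.75 and arm_calls:
                for chrom, s, e in cnv_aneuploidy.detect_loh(arm_calls, min_run=cfg["min_run"]):
                    loh_rows.append({"isolate": name, "chrom": chrom, "start": s, "end": e})
    cnv_df = pd.DataFrame(
        cnv_rows,
        columns=["isolate", "chrom", "ratio", "state", "expected", "change", "consistent_fraction"],
    )
    loh_df = pd.DataFrame(loh_rows, columns=["isolate", "chrom", "start", "end"])
    if "cnv" in stages:
        save_tsv(cnv_df, "cnv_calls.tsv", "cnv")
        save_tsv(loh_df, "loh.tsv", "cnv")
        for name, ratios in ratio_frames.items():
            save_tsv(ratios, f"cnv/{name}.ratios.tsv", "cnv")

    # --- junctions --------------------------------------------------------
    junction_rows = []
    new_models = {}
    for name, ev in evidence.items():
        for _, row in ev.junction_reads.iterrows():
            base_x = str(row["chrom_x"]).rstrip("AB")
            base_y = str(row["chrom_y"]).rstrip("AB")
            if base_x == base_y:
                continue  # homologous-recombination switch, not a novel junction
            jev = junction_karyotype.JunctionEvidence(
                chrom_x=row["chrom_x"], pos_x=int(row["pos_x"]), side_x=row["side_x"],
                chrom_y=row["chrom_y"], pos_y=int(row["pos_y"]), side_y=row["side_y"],
                support_reads=int(row["support"]),
                reference_span_x=int(row["ref_span_x"]),
                reference_span_y=int(row["ref_span_y"]),
            )
            accepted = junction_karyotype.validate_junction(
                jev, min_support=cfg["min_support"], max_ref_span=cfg["max_ref_span"]
            )
            model = None
            if accepted:
                segs = _junction_segments(jev, truth)
                rule_name = _match_rule(jev, truth)
                model_name = rule_name or f"{name}:junction"
                model = junction_karyotype.reconstruct_new_chromosome(
                    model_name, segs, (genome_a, genome_b)
                )
                new_models[(name, model_name)] = model
            junction_rows.append(
                {
                    "isolate": name,
                    "chrom_x": jev.chrom_x, "pos_x": jev.pos_x, "side_x": jev.side_x,
                    "chrom_y": jev.chrom_y, "pos_y": jev.pos_y, "side_y": jev.side_y,
                    "support": jev.support_reads,
                    "ref_span_x": jev.reference_span_x, "ref_span_y": jev.reference_span_y,
                    "accepted": accepted,
                    "model": model.name if model else "",
                    "length": model.length if model else 0,
                }
            )
    junctions_df = pd.DataFrame(
        junction_rows,
        columns=[
            "isolate", "chrom_x", "pos_x", "side_x", "chrom_y", "pos_y", "side_y",
            "support", "ref_span_x", "ref_span_y", "accepted", "model", "length",
        ],
    )
    if "junctions" in stages:
        save_tsv(junctions_df, "junctions.tsv", "junctions")
        payload = {
            f"{iso}:{nm}": {
                "segments": [str(s) for s in m.segments],
                "length": m.length,
                "telomere_5p": m.telomere_5p,
                "telomere_3p": m.telomere_3p,
                "has_centromere": m.has_centromere,
            }
            for (iso, nm), m in sorted(new_models.items())
        }
        p = outdir / "new_chromosomes.json"
        p.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        written.append(p)

    # --- karyotype --------------------------------------------------------
    n_base_a = len(dik.aframe_lengths)
    base_counts = {"A": n_base_a, "B": n_base_a + (1 if dik.acentric_extra else 0), "unresolved": n_base_a}
    karyo_rows = []
    max_prefix = max(
        [r.pos_y for r in truth.junction_rules] + [dik.extra_orphan_length]
    )
    for name, ev in evidence.items():
        arch_call = junction_karyotype.assign_architecture(
            ev.breakpoint_reads, min_reads=cfg["min_support"]
        )
        extras = set()
        for (iso, model_name), m in new_models.items():
            if iso == name and model_name in {r.name for r in truth.junction_rules}:
                extras.add(model_name)
        if dik.acentric_extra:
            distal = _region_state(
                ratio_frames[name], dik.extra_chrom_id, cfg, start=max_prefix + 1
            )
            if distal is not None and distal >= 0.75:
                extras.add(dik.extra_chrom_id)
        if arch_call.architecture == "B" and dik.acentric_extra:
            extras.discard(dik.extra_chrom_id)  # part of the B base complement
        call = junction_karyotype.type_aneuploidy(
            sorted(extras), arch_call.architecture, isolate=name, base_chromosomes=base_counts
        )
        karyo_rows.append(
            {
                "isolate": name,
                "architecture": call.architecture,
                "n_chromosomes": call.n_chromosomes,
                "extras": ",".join(call.extras),
                "aneuploidy_type": call.aneuploidy_type,
            }
        )
    karyo_df = pd.DataFrame(
        karyo_rows,
        columns=["isolate", "architecture", "n_chromosomes", "extras", "aneuploidy_type"],
    )
    if "karyotype" in stages:
        save_tsv(karyo_df, "karyotypes.tsv", "karyotype")

    # --- report -----------------------------------------------------------
    report = make_report(
        karyotypes=karyo_df,
        origins=origins_df,
        events=events_df,
        sites=sites_df,
        cnv_calls=cnv_df,
    )
    if "report" in stages:
        p = outdir / "report.json"
        p.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        written.append(p)
        save_tsv(karyo_df, "report_karyotypes.tsv", "report")

    manifest = {
        "config": {k: v for k, v in cfg.items()},
        "seed": cfg["seed"],
        "stage_seeds": {k: int(v) for k, v in seeds.items()},
        "n_isolates": len(cohort),
        "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in sorted(set(written))},
        "report": report,
    }
    mp = outdir / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _region_state(
    ratios: pd.DataFrame, chrom: str, cfg: dict, start: int = 1
) -> Optional[float]:
    sub = ratios[(ratios["chrom"] == chrom) & (ratios["start"] >= start)]
    if len(sub) < 3:
        return None
    call = cnv_aneuploidy.call_region_state(
        sub["ratio"].to_numpy(), chrom=chrom, grid_tolerance=cfg["grid_tolerance"]
    )
    if call.state is not None:
        return call.state
    low, high, f = call.mixture
    return low * (1 - f) + high * f


def _junction_segments(ev, truth) -> list[OrientedSegment]:
    cx = truth.chromosomes[ev.chrom_x]
    cy = truth.chromosomes[ev.chrom_y]
    if ev.side_x == "start":
        seg_x = OrientedSegment(ev.chrom_x, 1, ev.pos_x, "+")
    else:
        seg_x = OrientedSegment(ev.chrom_x, ev.pos_x, cx.length, "-")
    if ev.side_y == "start":
        seg_y = OrientedSegment(ev.chrom_y, 1, ev.pos_y, "-")
    else:
        seg_y = OrientedSegment(ev.chrom_y, ev.pos_y, cy.length, "+")
    return [seg_x, seg_y]


def _match_rule(ev, truth) -> Optional[str]:
    for r in truth.junction_rules:
        if (
            r.chrom_x == ev.chrom_x and r.pos_x == ev.pos_x and r.side_x == ev.side_x
            and r.chrom_y == ev.chrom_y and r.pos_y == ev.pos_y and r.side_y == ev.side_y
        ):
            return r.name
    return None


def make_report(
    karyotypes: pd.DataFrame,
    origins: pd.DataFrame,
    events: pd.DataFrame,
    sites: pd.DataFrame,
    cnv_calls: pd.DataFrame,
) -> dict:
    """Cohort summary tables; refuses internally inconsistent inputs."""
    isolates = set(karyotypes["isolate"])
    if set(origins["isolate"]) != isolates:
        raise ValueError(
            "inconsistent isolate lists: karyotypes vs origin fractions differ by "
            f"{sorted(set(origins['isolate']) ^ isolates)}"
        )
    if len(events) and not set(events["isolate"]) <= isolates:
        raise ValueError("events table names isolates absent from the karyotype table")
    aneuploid = karyotypes[karyotypes["aneuploidy_type"] != "euploid"]
    type_counts = aneuploid["aneuploidy_type"].value_counts().to_dict()
    if sum(type_counts.values()) != len(aneuploid):
        raise ValueError("aneuploidy type counts do not sum to the aneuploid isolate count")
    n = len(karyotypes)
    report = {
        "n_isolates": n,
        "n_aneuploid": int(len(aneuploid)),
        "aneuploid_pct": round(100.0 * len(aneuploid) / n, 1) if n else 0.0,
        "aneuploidy_type_counts": {k: int(v) for k, v in sorted(type_counts.items())},
        "architecture_counts": {
            k: int(v) for k, v in karyotypes["architecture"].value_counts().items()
        },
        "chromosome_number_counts": {
            str(k): int(v) for k, v in karyotypes["n_chromosomes"].value_counts().items()
        },
        "n_recombination_events": int(len(events)),
        "n_recombination_sites": int(len(sites)),
        "n_hotspots": int(sites["hotspot"].sum()) if len(sites) else 0,
        "mean_pct_a": float(origins["pct_a"].mean()) if len(origins) else float("nan"),
        "n_cnv_calls": int(len(cnv_calls)),
    }
    return report
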