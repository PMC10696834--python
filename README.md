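# meiospore

Meiosis simulation and monospore-isolate genotyping for **asymmetric
dikaryotic fungal genomes**.

Basidiomycete fungi spend most of their life cycle as a dikaryon: every cell
carries two distinct haploid nuclei that only fuse just before spore
formation.  In some strains — the model here is the *Tremella fuciformis*
cultivar Tr01 — the two nuclear genomes are *asymmetric*: they differ in
chromosome number (11 vs 12), in the large-scale arrangement of several
chromosomes (the A vs B "architecture" of Chr01/Chr02/Chr05), and one
haplotype carries an extra **centromere-free** chromosome (Chr12B) that is
mostly homologous to one arm of another chromosome.  Meiosis of such a
genome is eventful: homologous regions of seven chromatids pair into one
large complex, breakage at the pairing intersections rejoins haplotype-
specific terminal segments into **new telomere-capped acentric
chromosomes**, the acentric chromosomes migrate irregularly because they
cannot attach to the spindle, and most spores die because their chromosome
complement misses essential genes.  The surviving monospore isolates are
strongly biased toward one architecture and over a third of them are
aneuploid, carrying one or two extra chromosomes.

`meiospore` is for researchers who want to model that process and analyse
monospore sequencing evidence against it.  It provides:

* **`genome_model`** — phased-haplotype data model plus the sequence rules:
  telomere detection (tandem `TTA(G)3–5` repeats), the two-speed
  core/accessory classifier (gene density < 2.4 per 10 kb, repeat content
  > 40 %, no essential genes), tandem-array copy number from depth ratios,
  and haplotype assignment of low-heterozygosity chromosomes from two
  nucleus-biased LTR marker families.
* **`synthetic_data`** — a seeded generator for a reduced-scale dikaryon
  with every structural feature (gradient heterozygosity in 10-kb bins,
  accessory chromosomes/compartments, architecture translocations, the
  acentric extra chromosome, orphan terminal segments, telomere caps) and a
  simulator for the per-isolate observables: diagnostic-allele bin counts,
  window depths, junction-spanning reads.
* **`meiosis_sim`** — the mechanistic model: pairing complex over a
  homology map, junction rules (breakage + rejoining with reverse-
  complement joins), meiosis I/II segregation with biased acentric
  migration, optional crossovers at hotspot coordinates, viability
  filtering by essential-gene complement.  Monte-Carlo and exhaustive
  enumeration modes agree within sampling error.
* **`bin_genotyping`** — bin-wise haplotype origin (A/B/HET/NA),
  recombination events at origin switches, site aggregation, hotspot
  calling (≥ 4 isolates), per-isolate origin fractions.
* **`cnv_aneuploidy`** — depth normalization, half-grid copy states
  (0, 0.5, 1, 1.5, …), exact two-state karyotype-mixture inversion
  (`f = (ratio − low)/(high − low)`), whole-chromosome gain/loss calls,
  loss-of-heterozygosity runs.
* **`junction_karyotype`** — depth-inflection candidates, junction
  validation (supporting reads present *and* zero reads crossing the broken
  reference), new-chromosome reconstruction with exact 1-based arithmetic,
  architecture assignment from breakpoint-spanning evidence, aneuploidy
  typing (Types I–IV).
* **`pipeline` / CLI `meiospore`** — the stages wired end to end under one
  config and one seed, with a manifest of checksummed outputs.

## Worked example

Reconstructing the first observed new chromosome from its printed component
coordinates — the prefix of Chr01B joined to the reverse complement of the
Chr12B prefix:

```python
from meiospore.meiosis_sim import JunctionRule, assemble_junction_product, whole_chromosome_model

registry = {
    "Chr01B": whole_chromosome_model("Chr01B", 6_590_000, centromere=(3_000_001, 3_040_000)),
    "Chr12B": whole_chromosome_model("Chr12B", 1_510_000, centromere=None),
}
rule = JunctionRule("ChrN1", "Chr01B", 58_690, "Chr12B", 172_535,
                    side_x="start", side_y="start", probability=1.0)
model = assemble_junction_product(rule, registry)
print(model.segments)        # (Chr01B:1-58690(+), Chr12B:1-172535(-))
print(model.length)          # 231225  -> 0.23 Mb
print(model.telomere_5p, model.telomere_3p, model.has_centromere)  # True True False
```

Both component prefixes contribute their outer telomere and neither
contains a centromere, so the product is a stable, heritable acentric
chromosome of 231,225 bp (0.23 Mb).

Running the whole pipeline on a synthetic cohort:

```bash
meiospore all --config configs/demo.yaml --outdir demo_run
```

prints the cohort report (seed 3, 6 isolates):

```json
{
  "aneuploid_pct": 66.7,
  "aneuploidy_type_counts": {"I": 4},
  "architecture_counts": {"A": 6},
  "chromosome_number_counts": {"8": 2, "9": 4},
  "mean_pct_a": 91.98717948717949,
  "n_aneuploid": 4,
  "n_cnv_calls": 5,
  "n_hotspots": 0,
  "n_isolates": 6,
  "n_recombination_events": 2,
  "n_recombination_sites": 2
}
```

Every viable spore has the A architecture; four of six carry an extra
acentric Chr12B (Type I aneuploids, 9 chromosomes against the 8-chromosome
reduced-scale A base), most sequence originates from haplotype A, and two
recombination events were mapped.  `demo_run/` holds the genomes (FASTA +
BED tracks), the per-isolate evidence and calls (TSV), the validated
junctions, karyotype table and a `manifest.json` with checksums; re-running
the same config and seed reproduces identical checksums.

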