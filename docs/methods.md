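# Methods

## The system being modelled

A dikaryotic fungal mycelium carries two haploid nuclei, here labelled
haplotype A (11 chromosomes) and haplotype B (12).  The haplotypes differ
in three ways that matter for meiosis:

1. **Architecture.**  Chr01, Chr02 and Chr05 are rearranged between the
   haplotypes.  We represent the rearrangement as a cyclic translocation of
   equal-length "architecture cassettes" of essential content: cassette
   content t1 sits on Chr01A in haplotype A but on Chr02B in haplotype B,
   t2 on Chr02A/Chr05B, t3 on Chr05A/Chr01B.  The consequence — and the
   reason for the representation — is that only an all-A or all-B
   combination of the three chromosomes covers all three cassettes; every
   mixed combination misses at least one and dies.  This reproduces the
   observed architecture-dependence of spore viability without modelling
   breakpoint microstructure.
2. **The acentric extra chromosome.**  Haplotype B's Chr12B has no
   centromere; most of it is homologous to the right arm of Chr05A (which
   haplotype B's Chr05 lacks), preceded by a B-specific orphan terminal
   segment.  Essential content on that arm therefore reaches
   B-architecture spores only via Chr12B, while A-architecture spores carry
   it on Chr05A.
3. **Orphan terminal segments.**  Chr01B begins with a B-specific segment
   with no homolog in A.  The two orphan terminal segments (Chr01B-C1,
   Chr12B-C1) are the raw material of new-chromosome formation.

## Meiosis model

Meiosis is modelled at **segment granularity**: chromosomes are ordered
lists of oriented source segments, and no base-level crossover resolution
or repair biochemistry is attempted.  The claims the model supports are
architecture-scale (which chromosomes end up in which spore).

One simulated meiosis proceeds as:

* **Junction rules.**  Each configured rule (two break sites, the side of
  each chromatid that survives, a mechanism label, a probability) fires
  independently.  A fired rule consumes one sister chromatid of each
  participant and emits (a) the new chromosome — each surviving piece
  oriented so its broken end faces the junction, which makes a kept prefix
  of the second partner enter as its reverse complement — and (b) the
  reciprocal remainder fragments, which lack a telomere at the break.
  Default probability 0.05 per rule per meiosis: the source data constrain
  the *products* of these events, not their rates, so the default is
  deliberately conservative and prominently configurable.  Whether two
  rules may fire in the same meiosis is a config flag
  (`allow_rule_cooccurrence`, default on — isolates carrying both Chr12B
  and ChrN1 show the products can co-occur).
* **Crossovers.**  Optional exchange events between collinear homologs at
  configured hotspot coordinates (probability 0.2–0.25 per hotspot per
  meiosis in the defaults); one crossover per homolog pair per meiosis.
  The reciprocal recombinants replace one sister of each homolog.
* **Segregation.**  Meiosis I/II semantics: each centromeric homolog pair
  splits 2 + 2 across the four products (each product receives one sister
  of its pole's homolog).  Each sister copy of an **acentric** chromosome
  migrates to the pole of its designated pairing partner (Chr05A for
  Chr12B) with probability `bias`, then lands in a uniformly chosen product
  of that pole.  `bias` = 0.5 is free migration; the asymmetric-dikaryon
  preset uses 0.7 (pipeline default 0.8) to express the qualitative
  partner-following claim — no quantitative rate is available, so the value
  is a model parameter, not an estimate.
* **Stability filter.**  Chromosomes lacking a telomere at either end
  (remainder fragments) are dropped after the meiosis, with a count kept —
  fragmented chromosomes are unstably inherited.
* **Viability.**  Essential content is a set of units, each with every
  genomic location that carries it.  A spore is viable iff every *required*
  unit lies wholly inside some carried segment; `required_fraction` < 1
  relaxes this, since only a subset of the placed essentials may truly be
  required for survival.

Copy conservation is a hard invariant: before the stability filter, every
base of every parental chromosome totals exactly two copies across the four
products, including bases relocated into new chromosomes and fragments.
`check_conservation` verifies it by line sweep.

Two execution modes share one choice-probability space: Monte-Carlo
sampling, and exhaustive enumeration of every discrete outcome with its
probability (for small models).  The test suite requires their summaries to
agree within three standard errors.

## Synthetic data

The generator emulates the study genome at reduced scale so a full
generate/simulate/analyse cycle runs in seconds: core chromosomes
0.3–0.5 Mb (five), accessory chromosomes 60–80 kb (three per haplotype),
two accessory compartments, a 150-kb acentric extra chromosome with a
30-kb orphan prefix, a 20-kb orphan prefix on Chr01B, 40-kb architecture
cassettes, 10-kb bins.  Heterozygosity is a per-bin mosaic with fractions
following the observed bin-divergence spectrum (≈ 22 % of bins
near-identical, ≈ 15 % in each class up to 4 %, ≈ 19 % above 4 %; bins
with ≥ 1 %/bp diagnostic density count as informative).  Accessory regions
and four whole chromosomes are assigned the near-identical class, matching
the observed low-heterozygosity landscape.  Diagnostic SNPs are biallelic
and uniformly placed within each bin at the class density; no indels.
Telomere caps (25 motif copies) are written onto every chromosome end.

Evidence simulation mirrors the study's two mappings:

* **Diagnostic-allele bin counts** are on the haplotype-A frame: every
  segment a spore carries is mapped through the homology blocks (B-specific
  content maps nowhere), per-bin totals are Poisson with mean
  `coverage × copy number`, and the A-allele count is binomial with the
  allele error rate flipping origin.
* **Window depths** are on a combined reference (A chromosomes plus
  B-specific contigs: the orphan prefix of Chr01B and the whole Chr12B),
  with unique best-hit mapping assumed.  Window read counts are Poisson
  with mean `coverage × copy number × window/read length`; the default
  window is 2 kb, keeping the window count per chromosome at reduced scale
  comparable to 10-kb windows at full scale.
* **Junction reads** are emitted only for adjacencies the genotype actually
  carries (support ≈ Poisson(coverage × copies)); reference-spanning counts
  at each break site reflect intact copies crossing that adjacency — zero
  when no intact copy exists.
* A **karyotype mixture** (a culture whose cells disagree about copy
  number) is a weighted list of genotypes; all expectations are
  weight-averaged, which produces the 1.5× and 1.8× depth signatures the
  half-grid/mixture caller consumes.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: mapping ambiguity in repeats and near-identical
regions, GC and library bias, indels and structural-variant microhomology,
overdispersed coverage (the Poisson model is the default; real data are
wider), chimeric reads, and contamination from the fungal partner the
species grows with.

## Analysis choices

* **Coordinates** are 1-based inclusive in every public interface
  (`Chr12B:1-172,535` style); internal slicing is 0-based half-open;
  `coords.py` is the only converter.  BED output is 0-based half-open per
  the standard.
* **Bin classification**: A if the A share ≥ purity (default 0.9), B
  symmetrically, HET if both alleles exceed the 1 − purity share, NA below
  `min_reads` (default 5) or in uninformative bins.  Raising purity can
  only move calls toward NA/HET, never create homozygous calls
  (monotonicity, property-tested).
* **Event calling** collapses NA/HET gaps (one event per A↔B transition,
  breakpoint interval spanning the gap) and suppresses homozygous runs
  shorter than `min_run` = 2 bins (allele-error flicker).
* **Site merging** joins breakpoint intervals within `merge_distance`
  = 10 bp; the two closest observed sites are 15 bp apart and must stay
  distinct.  Hotspot ⇔ ≥ 4 distinct isolates.
* **Depth normalization** divides by the median over core single-copy
  baseline windows (accessory and known-CNV regions excluded so they do not
  contaminate the median); an optional second normalization divides by a
  control isolate's ratios.  Region states use a 10 %-trimmed mean and snap
  to the half grid within `grid_tolerance` = 0.1; off-grid ratios are
  explained as a two-state mixture between the flanking integers — the
  minimal model for "two or more karyotypes".  A ratio sitting exactly on a
  half-grid value is reported as that state; whether 1.5× reflects a
  50/50 mixture or a true 3:2 dosage is not decidable from depth alone, and
  the caller does not pretend otherwise.
* **Whole-chromosome calls** additionally require ≥ 90 % of windows
  individually consistent with the called state, separating whole-
  chromosome events from segmental ones.
* **Junction validation** needs `min_support` = 3 spanning reads and at
  most `max_ref_span` = 0 reads crossing either broken reference site; the
  zero default encodes that a truly broken site has no crossing reads, and
  is relaxable for noisy data.
* **Architecture** is called from spanning evidence at the arrangement-
  diagnostic breakpoints: A (or B) only when every informative breakpoint
  agrees; anything mixed or under-covered is unresolved.  Inside the
  simulator, recombinant chromosomes are typed by the cassette content they
  carry (content markers), not by intact parental identity.
* **Aneuploidy typing** is a pure total mapping from the extras set:
  {Chr12B} → I, {ChrN1} → II, {ChrN2} → III, {Chr12B, ChrN1} → IV, ∅ →
  euploid, anything else → other.  Chr12B is part of the B-architecture
  base complement and is never an extra there.  Chromosome counts are
  base-architecture counts plus the number of extras; exact bp lengths are
  reported by the reconstruction, Mb rounding is left to the report layer.
* The **pipeline** treats a junction whose two sides map to the same base
  chromosome as a homologous-recombination switch (bin-genotyping's
  domain), not a novel junction; only cross-chromosome joins are
  reconstructed.

## Numerical and degenerate-input choices

Telomere scanning is greedy, longest motif variant first, so a G-run is
consumed by one copy and never split; `N` counts as non-matching; non-
nucleotide characters reject.  `min_repeats` defaults to 10 (true ends
carry 20–40 copies; 10 leaves margin for truncated ends).  The accessory
classifier is conjunctive with the essential-gene veto mandatory — absence
of conserved single-copy orthologs is the most discriminative signal — and
its thresholds (2.4 genes/10 kb, 40 % repeats) sit between the observed
core and accessory group statistics, which is all the data constrain.
Mixture inversion is exact algebra and rejects ratios outside the state
interval.  Empty bins, zero-baseline depth, overlapping homology blocks on
one chromatid, break positions outside a chromatid, and orphan segments
exceeding chromosome length all reject with explicit errors rather than
propagating.

## Problem sizes

The shipped defaults run the full test suite in well under a minute and the
acceptance script in seconds: 50 isolates for breakpoint recovery, 50
random junctions for the round trip, 1,000 meioses for conservation,
10,000 for Monte-Carlo/enumeration agreement, 101 grid points for mixture
inversion.  These sizes were chosen so that each property's sampling error
is far below its acceptance margin.

## Known limitations

The meiosis model has no synaptonemal-complex or DNA-repair mechanics, at
most one crossover per homolog pair per meiosis, and skips crossovers on a
pair whose sister was consumed by a junction rule.  The generator's B-side
orphan prefixes replace the homologous A content (so the corresponding A
prefix is also unpaired), a simplification of true orphan insertions.
Read-level artefacts (mapping ambiguity, chimeras) are not simulated, so
the junction validator's false-positive behaviour on real libraries is
untested here.  The karyotype-mixture model is limited to two states.
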