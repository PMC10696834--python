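"""Published catalog of the *Tremella fuciformis* Tr01 study system.

Printed coordinates and karyotype tables from the Tr01 dikaryon genome
project, used as worked-example inputs: the components of the two new
chromosomes (ChrN1, ChrN2) observed in monospore isolates, the aneuploidy
typing table over the 33 sequenced isolates, and a pair of closely spaced
recombination sites.  These are *inputs* (a reference catalog), not results:
every derived number (lengths, fractions, gaps) is recomputed by the package.
"""

from __future__ import annotations

from .genome_model import OrientedSegment

# --- new-chromosome catalog -------------------------------------------------
# Both observed new chromosomes are a prefix of one donor joined to the
# reverse complement of a prefix of Chr12B; both are telomere-capped at each
# end and acentric (each component prefix carries one telomere, no centromere).

CHRN1_SEGMENTS = (
    OrientedSegment("Chr01B", 1, 58_690, "+"),
    OrientedSegment("Chr12B", 1, 172_535, "-"),
)

CHRN2_SEGMENTS = (
    OrientedSegment("Chr05B", 1, 675_684, "+"),
    OrientedSegment("Chr12B", 1, 834_373, "-"),
)

# The Chr12B terminal orphan segment (Chr12B-C1) is printed with two boundary
# values in different passages of the genome report; the junction coordinate
# 172,535 is the one tied to ChrN1 formation.  Both are carried as data.
CHR12B_C1_END_VARIANTS = (172_532, 172_535)
CHR01B_C1_END_VARIANTS = (58_690, 58_696)

CHR12B_LENGTH_BP = 1_510_000  # printed as 1.51 Mb in the karyotype table
CHR12B_SIZE_MB_TABLE = 1.52  # as printed in the aneuploidy table

# --- closely spaced recombination sites (same chromosome) -------------------
CLOSE_SITE_PAIR = (
    ("Chr02A", 142_183, 142_201),
    ("Chr02A", 142_217, 142_302),
)

# --- aneuploidy typing table over the 33 monospore isolates -----------------
# type -> (chromosome count, extra chromosomes, isolate ids)
ANEUPLOIDY_TABLE: dict[str, dict] = {
    "I": {
        "chromosomes": 12,
        "extras": ("Chr12B",),
        "isolates": ("DBZ18", "DBZ23", "DBZ25", "DBZ28", "DBZ29", "DBZ33", "DBZ46", "DBZ10"),
    },
    "II": {"chromosomes": 12, "extras": ("ChrN1",), "isolates": ("DBZ15",)},
    "III": {"chromosomes": 12, "extras": ("ChrN2",), "isolates": ("DBZ02", "DBZ08")},
    "IV": {"chromosomes": 13, "extras": ("Chr12B", "ChrN1"), "isolates": ("DBZ11", "DBZ14", "DBZ20")},
}

N_MONOSPORE_ISOLATES = 33
BASE_CHROMOSOMES = {"A": 11, "B": 12}

# extras catalog used by karyotype typing (sizes in Mb as printed)
EXTRA_CHROMOSOME_SIZES_MB = {"Chr12B": 1.52, "ChrN1": 0.23, "ChrN2": 1.52}
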