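"""Readers/writers for the package's on-disk formats.

FASTA (60-column, via Biopython), BED (0-based half-open per the BED
standard; package-internal coordinates are 1-based inclusive and converted
here), plain TSV tables (pandas), and JSON genome metadata (telomere and
centromere state).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome_model import Chromosome, Feature, HaplotypeGenome


def write_fasta(genome: HaplotypeGenome, path: str | Path) -> None:
    records = []
    for c in genome.chromosomes:
        if c.sequence is None:
            raise ValueError(f"{c.id}: cannot write FASTA without sequence")
        records.append(SeqRecord(Seq(c.sequence), id=c.id, description=""))
    SeqIO.write(records, str(path), "fasta")  # biopython wraps at 60 columns


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_bed(features: Iterable[Feature], path: str | Path) -> None:
    """Write features as BED4; converts 1-based inclusive to 0-based half-open."""
    with open(path, "w") as fh:
        for f in features:
            fh.write(f"{f.chrom}\t{f.start - 1}\t{f.end}\t{f.name}\n")


def read_bed(path: str | Path) -> list[Feature]:
    feats = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start0, end0 = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else "."
            feats.append(Feature(chrom, start0 + 1, end0, name))
    return feats


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def genome_metadata(genome: HaplotypeGenome) -> dict:
    """JSON-serialisable telomere/centromere metadata for one haplotype."""
    return {
        "label": genome.label,
        "chromosomes": [
            {
                "id": c.id,
                "length": c.length,
                "centromere": list(c.centromere) if c.centromere else None,
                "telomere_5p": c.telomere_5p,
                "telomere_3p": c.telomere_3p,
                "telomere_5p_repeats": c.telomere_5p_repeats,
                "telomere_3p_repeats": c.telomere_3p_repeats,
            }
            for c in genome.chromosomes
        ],
    }


def write_genome_metadata(genome: HaplotypeGenome, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(genome_metadata(genome), fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_genome_metadata(path: str | Path) -> HaplotypeGenome:
    """Rebuild a coordinate-only HaplotypeGenome (no sequence, no tracks)."""
    with open(path) as fh:
        meta = json.load(fh)
    chroms = [
        Chromosome(
            id=c["id"],
            length=c["length"],
            centromere=tuple(c["centromere"]) if c["centromere"] else None,
            telomere_5p=c["telomere_5p"],
            telomere_3p=c["telomere_3p"],
            telomere_5p_repeats=c["telomere_5p_repeats"],
            telomere_3p_repeats=c["telomere_3p_repeats"],
        )
        for c in meta["chromosomes"]
    ]
    return HaplotypeGenome(label=meta["label"], chromosomes=chroms)
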