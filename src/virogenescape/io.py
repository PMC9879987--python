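"""Readers and writers for the formats the pipeline consumes and emits.

GFF3 and BED6 are read into :class:`~virogenescape.genomescape.GeneAnnotation`
lists; BED's 0-based half-open coordinates are converted to the internal
1-based inclusive convention on read and back on write.  Malformed lines are
reported with their line number.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd
from gffutils.feature import feature_from_line

from .genomescape import DensityProfile, GeneAnnotation
from .essentiality import read_fitness_tsv, write_fitness_tsv  # re-exported

__all__ = [
    "read_gff3",
    "write_gff3",
    "read_bed6",
    "write_bed6",
    "read_annotation",
    "read_fitness_tsv",
    "write_fitness_tsv",
]


class FormatError(ValueError):
    """Malformed input file; message carries the file and line number."""


def _ordinals_by_position(genes: List[GeneAnnotation]) -> List[GeneAnnotation]:
    ordered = sorted(genes, key=lambda g: (g.start, g.end, g.gene_id))
    return [
        GeneAnnotation(
            gene_id=g.gene_id, start=g.start, end=g.end, strand=g.strand, ordinal=i + 1
        )
        for i, g in enumerate(ordered)
    ]


def read_gff3(path, feature_types: Sequence[str] = ("gene",)) -> List[GeneAnnotation]:
    """Gene features from a GFF3 file (1-based inclusive, ID attribute)."""
    genes: List[GeneAnnotation] = []
    with open(path, "r", encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:
                raise FormatError(f"{path}:{ln}: malformed GFF3 line: {exc}") from exc
            if feat.featuretype not in feature_types:
                continue
            gene_id = feat.attributes.get("ID", [None])[0] or feat.attributes.get(
                "Name", [None]
            )[0]
            if gene_id is None:
                raise FormatError(f"{path}:{ln}: gene feature without ID attribute")
            try:
                genes.append(
                    GeneAnnotation(
                        gene_id=gene_id,
                        start=feat.start,
                        end=feat.end,
                        strand=feat.strand or ".",
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: {exc}") from exc
    return _ordinals_by_position(genes)


def write_gff3(
    genes: Sequence[GeneAnnotation],
    path,
    seqid: str = "genome",
    genome_length: Optional[int] = None,
    source: str = "virogenescape",
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        if genome_length is not None:
            fh.write(f"##sequence-region {seqid} 1 {genome_length}\n")
        for g in sorted(genes, key=lambda g: g.start):
            fh.write(
                f"{seqid}\t{source}\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )


def read_bed6(path) -> List[GeneAnnotation]:
    """BED6 intervals (0-based half-open) converted to 1-based inclusive."""
    genes: List[GeneAnnotation] = []
    with open(path, "r", encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{ln}: BED line has {len(parts)} fields, need >= 4")
            try:
                chrom_start, chrom_end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: non-integer BED coordinates") from exc
            if chrom_end <= chrom_start:
                raise FormatError(f"{path}:{ln}: empty or inverted BED interval")
            strand = parts[5] if len(parts) >= 6 else "."
            genes.append(
                GeneAnnotation(
                    gene_id=parts[3],
                    start=chrom_start + 1,
                    end=chrom_end,
                    strand=strand,
                )
            )
    return _ordinals_by_position(genes)


def write_bed6(genes: Sequence[GeneAnnotation], path, seqid: str = "genome") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in sorted(genes, key=lambda g: g.start):
            fh.write(
                f"{seqid}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n"
            )


def read_annotation(path) -> List[GeneAnnotation]:
    """Dispatch on extension: .gff/.gff3 or .bed."""
    suffix = Path(path).suffix.lower()
    if suffix in (".gff", ".gff3"):
        return read_gff3(path)
    if suffix == ".bed":
        return read_bed6(path)
    raise FormatError(f"unrecognized annotation format: {path}")
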