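"""Genome annotation container and interval geometry.

Coordinates are 0-based half-open everywhere in memory.  GFF3 output converts
to the 1-based inclusive convention on the way out; BED stays 0-based.

The annotation carries the feature universe the comparative analysis needs:
gene models (transcript span + exon intervals, strand), transposable-element
intervals and small-RNA loci, plus chromosome lengths so bounds can be
checked and flanks clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

Interval = tuple[str, int, int]  # (chrom, start, end), 0-based half-open


class AnnotationError(ValueError):
    """Raised when an annotation violates its structural invariants."""


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    start: int  # transcript start, 0-based
    end: int    # transcript end, half-open
    exons: list[tuple[int, int]] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
            if self.exons[i][1] < self.exons[i + 1][0]
        ]

    def validate(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.gene_id}: bad strand {self.strand!r}")
        if not self.start < self.end:
            raise AnnotationError(f"{self.gene_id}: empty transcript span")
        prev_end = None
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise AnnotationError(f"{self.gene_id}: exon ({s},{e}) outside span")
            if prev_end is not None and s < prev_end:
                raise AnnotationError(f"{self.gene_id}: exons overlap or unsorted")
            prev_end = e


@dataclass
class GenomeAnnotation:
    """Chromosome sizes plus gene / TE / smRNA interval tracks."""

    chromosomes: dict[str, int]
    genes: list[Gene] = field(default_factory=list)
    te_intervals: list[Interval] = field(default_factory=list)
    smrna_intervals: list[Interval] = field(default_factory=list)

    def validate(self) -> None:
        for gene in self.genes:
            gene.validate()
            clen = self.chromosomes.get(gene.chrom)
            if clen is None or not (0 <= gene.start < gene.end <= clen):
                raise AnnotationError(f"{gene.gene_id}: outside chromosome bounds")
        for track_name, track in (("TE", self.te_intervals), ("smRNA", self.smrna_intervals)):
            for chrom, s, e in track:
                clen = self.chromosomes.get(chrom)
                if clen is None or not (0 <= s < e <= clen):
                    raise AnnotationError(f"{track_name} interval ({chrom},{s},{e}) out of bounds")

    # -- strand-aware flank geometry -----------------------------------------

    def upstream_flank(self, gene: Gene, flank: int) -> tuple[int, int]:
        """2-kb-style flank on the 5' side of the transcript, clipped to the chromosome."""
        clen = self.chromosomes[gene.chrom]
        if gene.strand == "+":
            return max(0, gene.start - flank), gene.start
        return gene.end, min(clen, gene.end + flank)

    def downstream_flank(self, gene: Gene, flank: int) -> tuple[int, int]:
        clen = self.chromosomes[gene.chrom]
        if gene.strand == "+":
            return gene.end, min(clen, gene.end + flank)
        return max(0, gene.start - flank), gene.start

    # -- serialization -------------------------------------------------------

    def to_gff3(self, path) -> None:
        """Write gene models as GFF3; ``path`` may be a path or file object."""
        fh = path if hasattr(path, "write") else open(path, "w")
        try:
            fh.write("##gff-version 3\n")
            for chrom, length in self.chromosomes.items():
                fh.write(f"##sequence-region {chrom} 1 {length}\n")
            for gene in self.genes:
                fh.write(
                    f"{gene.chrom}\tmethyldiff\tgene\t{gene.start + 1}\t{gene.end}\t.\t"
                    f"{gene.strand}\t.\tID={gene.gene_id}\n"
                )
                for i, (s, e) in enumerate(gene.exons, start=1):
                    fh.write(
                        f"{gene.chrom}\tmethyldiff\texon\t{s + 1}\t{e}\t.\t"
                        f"{gene.strand}\t.\tID={gene.gene_id}.exon{i};Parent={gene.gene_id}\n"
                    )
        finally:
            if fh is not path:
                fh.close()

    def write_te_bed(self, path) -> None:
        _write_bed(self.te_intervals, path, "TE")

    def write_smrna_bed(self, path) -> None:
        _write_bed(self.smrna_intervals, path, "smRNA")

    @classmethod
    def from_gff3(cls, gff_path, te_bed=None, smrna_bed=None) -> "GenomeAnnotation":
        """Load gene models from GFF3 (via gffutils) plus optional BED tracks."""
        import gffutils

        chromosomes: dict[str, int] = {}
        with open(gff_path) as fh:
            for line in fh:
                if line.startswith("##sequence-region"):
                    _, chrom, _start, end = line.split()[:4]
                    chromosomes[chrom] = int(end)
        db = gffutils.create_db(
            str(gff_path), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        genes = []
        for g in db.features_of_type("gene", order_by="start"):
            exons = sorted(
                (e.start - 1, e.end) for e in db.children(g, featuretype="exon")
            )
            genes.append(Gene(g.id, g.seqid, g.strand, g.start - 1, g.end, exons))
        if not chromosomes:  # fall back to observed extents
            for g in genes:
                chromosomes[g.chrom] = max(chromosomes.get(g.chrom, 0), g.end)
        ann = cls(
            chromosomes=chromosomes,
            genes=genes,
            te_intervals=read_bed(te_bed) if te_bed else [],
            smrna_intervals=read_bed(smrna_bed) if smrna_bed else [],
        )
        ann.validate()
        return ann


def _write_bed(intervals: Iterable[Interval], path, name: str) -> None:
    with open(path, "w") as fh:
        for i, (chrom, s, e) in enumerate(intervals, start=1):
            fh.write(f"{chrom}\t{s}\t{e}\t{name}{i}\t0\t.\n")


def read_bed(path) -> list[Interval]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"])
    return [(str(r.chrom), int(r.start), int(r.end)) for r in df.itertuples()]
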