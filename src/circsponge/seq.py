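"""Sequence and annotation utilities shared across the pipeline.

Coordinates are 1-based inclusive everywhere in this package; conversion to
0-based half-open happens only at BED export.  DNA alphabet (A/C/G/T, upper
case) is used end-to-end; mature miRNA sequences are stored with T instead
of U and converted only at I/O if needed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def rna_to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass
class Gene:
    """A stranded, multi-exon gene. ``exons`` are (start, end) 1-based inclusive,
    sorted by start regardless of strand."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Intervals between consecutive exons, genomic order."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return out

    def overlaps(self, start: int, end: int) -> bool:
        return start <= self.end and end >= self.start


@dataclass
class Annotation:
    genes: list[Gene]

    def __post_init__(self) -> None:
        self._by_chrom: dict[str, list[Gene]] = {}
        for g in self.genes:
            self._by_chrom.setdefault(g.chrom, []).append(g)
        for glist in self._by_chrom.values():
            glist.sort(key=lambda g: (g.start, g.end, g.gene_id))

    @property
    def chromosomes(self) -> set[str]:
        return set(self._by_chrom)

    def genes_on(self, chrom: str) -> list[Gene]:
        return self._by_chrom.get(chrom, [])

    def overlapping(self, chrom: str, start: int, end: int) -> list[Gene]:
        return [g for g in self.genes_on(chrom) if g.overlaps(start, end)]


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def read_fastq(path: str | os.PathLike) -> Iterator[tuple[str, str]]:
    """Yield (read name, sequence) pairs."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield rec.id, str(rec.seq).upper()


def write_fastq(reads: Iterable[tuple[str, str]], path: str | os.PathLike) -> None:
    """Write (name, sequence) pairs with uniform placeholder qualities."""
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_gff3(annotation: Annotation, path: str | os.PathLike, source: str = "circsponge") -> None:
    """1-based inclusive GFF3 with gene and exon features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(annotation.genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.chrom}\t{source}\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


def read_gff3(path: str | os.PathLike) -> Annotation:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="error"
    )
    genes = []
    for feat in db.features_of_type("gene"):
        exons = sorted(
            (child.start, child.end) for child in db.children(feat, featuretype="exon")
        )
        genes.append(
            Gene(
                gene_id=feat.id,
                chrom=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                exons=exons,
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return Annotation(genes)


def transcript_sequence(genome: dict[str, str], gene: Gene) -> str:
    """Spliced transcript (exons concatenated, strand-adjusted, 5'->3')."""
    chrom = genome[gene.chrom]
    spliced = "".join(chrom[s - 1 : e] for s, e in gene.exons)
    return revcomp(spliced) if gene.strand == "-" else spliced


def transcript_position(gene: Gene, chrom_pos: int) -> int:
    """Map a genomic position inside an exon to 1-based transcript coordinates."""
    offsets = []
    total = 0
    for s, e in gene.exons:
        offsets.append((s, e, total))
        total += e - s + 1
    for s, e, off in offsets:
        if s <= chrom_pos <= e:
            pos_fwd = off + (chrom_pos - s) + 1
            if gene.strand == "-":
                return total - pos_fwd + 1
            return pos_fwd
    raise ValueError(f"position {chrom_pos} not exonic in {gene.gene_id}")
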