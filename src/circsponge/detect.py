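"""Back-splice junction detection and circRNA classification.

The detector implements a two-anchor strategy: the first and last
``anchor_len`` bases of each read are mapped exactly against the genome.
A read supports a back-splice when both anchors land on the same chromosome
and orientation with the read-terminal (3') anchor mapping *upstream* of the
read-initial (5') anchor — the reversed genomic order diagnostic of a
circular junction.  Anchors are then extended inward against the genome to
locate the exact breakpoint, requiring the full read to be explained as a
tail|head concatenation of the circle, optionally flanked by canonical
GT..AG splice dinucleotides on the assigned strand.

Identified junctions are aggregated into :class:`CircRNACall` records with
the "chrom:start|end" id convention (1-based inclusive; start = acceptor,
end = donor).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .seq import Annotation, Gene, revcomp

EXONIC = "exonic"
INTRONIC = "intronic"
INTERGENIC = "intergenic"

NO_ASSOCIATION = "no_association"
CONTAINMENT = "containment"
SHARED_SPLICE_SITE = "shared_splice_site"


@dataclass(frozen=True)
class DetectorParams:
    anchor_len: int = 20
    min_junction_reads: int = 2
    require_splice_signal: bool = True
    max_span: int = 100_000
    unique_anchors_only: bool = True

    def __post_init__(self) -> None:
        if self.anchor_len < 10:
            raise ValueError("anchor_len must be >= 10")
        if self.min_junction_reads < 1:
            raise ValueError("min_junction_reads must be >= 1")


@dataclass
class CircRNACall:
    chrom: str
    start: int  # acceptor / left breakpoint, 1-based inclusive
    end: int  # donor / right breakpoint, 1-based inclusive
    strand: str
    junction_reads: int = 1
    circ_type: str | None = None
    host_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"start must be < end, got {self.start}..{self.end}")
        if self.junction_reads < 1:
            raise ValueError("junction_reads must be >= 1")

    @property
    def circ_id(self) -> str:
        return f"{self.chrom}:{self.start}|{self.end}"

    @property
    def length(self) -> int:
        """Genomic span in bp."""
        return self.end - self.start + 1


class KmerIndex:
    """Exact-match k-mer index over a genome.

    Queries return every occurrence as (chrom, pos, strand): '+' hits are
    forward occurrences of the query; '-' hits are forward occurrences of its
    reverse complement, reported at the same locus. k-mers containing N are
    never indexed and queries containing N return no hits.
    """

    def __init__(self, genome: dict[str, str], k: int):
        if not genome:
            raise ValueError("genome is empty")
        shortest = min(len(s) for s in genome.values())
        if k > shortest:
            raise ValueError(f"k={k} exceeds shortest chromosome length {shortest}")
        self.k = k
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for chrom, seq in genome.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                self._index[kmer].append((chrom, i + 1))

    def query(self, kmer: str) -> list[tuple[str, int, str]]:
        if len(kmer) != self.k:
            raise ValueError(f"query length {len(kmer)} != k={self.k}")
        if "N" in kmer:
            return []
        hits = [(c, p, "+") for c, p in self._index.get(kmer, ())]
        rc = revcomp(kmer)
        if rc != kmer:  # palindromic k-mers report each locus once
            hits += [(c, p, "-") for c, p in self._index.get(rc, ())]
        return hits


def build_index(genome: dict[str, str], k: int = 20) -> KmerIndex:
    return KmerIndex(genome, k)


def _splice_signal_ok(chrom_seq: str, start: int, end: int, strand: str) -> bool:
    """Canonical back-splice flanks: GT just downstream of the donor, AG just
    upstream of the acceptor, on the assigned strand.  In forward genome
    coordinates this reads AG[circle]GT for '+' and AC[circle]CT for '-'."""
    if start < 3 or end + 2 > len(chrom_seq):
        return False
    up = chrom_seq[start - 3 : start - 1]
    down = chrom_seq[end : end + 2]
    if strand == "+":
        return up == "AG" and down == "GT"
    return up == "AC" and down == "CT"


def _candidate_splits(
    seq: str, index: KmerIndex, genome: dict[str, str], params: DetectorParams
) -> tuple[list[tuple[str, int, int]], str | None]:
    """All breakpoint-consistent (chrom, start, end) splits of ``seq`` taken as
    a '+'-orientation tail|head read, ordered by increasing donor position."""
    k = params.anchor_len
    length = len(seq)
    a5, a3 = seq[:k], seq[-k:]
    h5 = index.query(a5)
    h3 = index.query(a3)
    if not h5 or not h3:
        return [], "anchor_unmapped"
    if params.unique_anchors_only and (len(h5) > 1 or len(h3) > 1):
        return [], "anchor_ambiguous"
    hit5 = next((h for h in h5 if h[2] == "+"), None)
    hit3 = next((h for h in h3 if h[2] == "+"), None)
    if hit5 is None or hit3 is None:
        return [], "anchor_wrong_orientation"
    chrom5, p5, _ = hit5
    chrom3, p3, _ = hit3
    if chrom5 != chrom3:
        return [], "anchors_different_chromosomes"
    if p3 >= p5:
        return [], "colinear"
    chrom_seq = genome[chrom5]
    e1 = k
    while (
        e1 < length
        and p5 - 1 + e1 < len(chrom_seq)
        and seq[e1] == chrom_seq[p5 - 1 + e1]
    ):
        e1 += 1
    pe = p3 + k - 1
    e2 = k
    while e2 < length and pe - e2 - 1 >= 0 and seq[length - e2 - 1] == chrom_seq[pe - e2 - 1]:
        e2 += 1
    out = []
    for s in range(max(length - e2, 1), min(e1, length - 1) + 1):
        start = pe - (length - s) + 1
        end = p5 + s - 1
        if start < 1 or start >= end:
            continue
        if end - start + 1 > params.max_span:
            continue
        out.append((chrom5, start, end))
    if not out:
        return [], "no_consistent_split"
    return out, None


def detect_backsplice(
    reads: Iterable[tuple[str, str]],
    index: KmerIndex,
    genome: dict[str, str],
    params: DetectorParams | None = None,
) -> tuple[list[CircRNACall], dict[str, int]]:
    """Detect back-splice junctions from (name, sequence) reads.

    Returns aggregated calls with ``junction_reads >= min_junction_reads`` and
    a discard log keyed by reason.
    """
    params = params or DetectorParams()
    counts: Counter[tuple[str, int, int, str]] = Counter()
    discards: Counter[str] = Counter()
    for _name, read in reads:
        if len(read) < 2 * params.anchor_len:
            discards["read_too_short"] += 1
            continue
        junction = None
        reason = "no_backsplice"
        for strand, seq in (("+", read), ("-", revcomp(read))):
            splits, why = _candidate_splits(seq, index, genome, params)
            if why is not None:
                reason = why
                continue
            for chrom, start, end in splits:
                if params.require_splice_signal and not _splice_signal_ok(
                    genome[chrom], start, end, strand
                ):
                    continue
                junction = (chrom, start, end, strand)
                break
            if junction is None and splits:
                reason = "no_splice_signal" if params.require_splice_signal else reason
            if junction is not None:
                break
        if junction is None:
            discards[reason] += 1
        else:
            counts[junction] += 1
    calls = [
        CircRNACall(chrom=c, start=s, end=e, strand=st, junction_reads=n)
        for (c, s, e, st), n in counts.items()
        if n >= params.min_junction_reads
    ]
    calls.sort(key=lambda c: (c.chrom, c.start, c.end, c.strand))
    return calls, dict(discards)


def classify(call: CircRNACall, annotation: Annotation) -> CircRNACall:
    """Assign circ_type and host genes in place (returns the call).

    exonic: both breakpoints fall in exons of strand-matching gene(s);
    intronic: the whole interval lies within a single intron of one gene;
    intergenic: no overlapping gene (antisense-only overlap counts as
    intergenic since there is no host on the call's strand).  Residual
    sense-overlap geometries are labelled exonic with overlapping genes as
    hosts — a deliberate catch-all keeping the three-type partition exhaustive.
    """
    if call.chrom not in annotation.chromosomes and annotation.genes:
        raise ValueError(f"chromosome {call.chrom!r} absent from annotation")
    overlapping = annotation.overlapping(call.chrom, call.start, call.end)
    if not overlapping:
        call.circ_type = INTERGENIC
        call.host_genes = []
        return call
    matching = [g for g in overlapping if call.strand in (".", g.strand)]
    if not matching:
        call.circ_type = INTERGENIC
        call.host_genes = []
        return call

    def in_exon(gene: Gene, pos: int) -> bool:
        return any(s <= pos <= e for s, e in gene.exons)

    start_hosts = [g for g in matching if in_exon(g, call.start)]
    end_hosts = [g for g in matching if in_exon(g, call.end)]
    if start_hosts and end_hosts:
        hosts = sorted({g.gene_id for g in start_hosts + end_hosts})
        call.circ_type = EXONIC
        call.host_genes = hosts
        return call
    intron_hosts = [
        g
        for g in matching
        if any(s <= call.start and call.end <= e for s, e in g.introns)
    ]
    if intron_hosts:
        call.circ_type = INTRONIC
        call.host_genes = sorted({g.gene_id for g in intron_hosts})
        return call
    call.circ_type = EXONIC
    call.host_genes = sorted({g.gene_id for g in matching})
    return call


def relate_pair(a: CircRNACall, b: CircRNACall) -> str:
    """Relation between two circRNA isoforms from one host gene."""
    if a.end < b.start or b.end < a.start:
        return NO_ASSOCIATION
    shared = int(a.start == b.start) + int(a.end == b.end)
    if shared == 1:
        return SHARED_SPLICE_SITE
    if (a.start <= b.start and b.end <= a.end) or (b.start <= a.start and a.end <= b.end):
        return CONTAINMENT
    return NO_ASSOCIATION


def relate_isoforms(calls: Sequence[CircRNACall]) -> list[tuple[str, str, str]]:
    """Pairwise relations among calls sharing a host gene."""
    if len(calls) < 2:
        raise ValueError("need at least two calls to relate")
    out = []
    for i, a in enumerate(calls):
        for b in calls[i + 1 :]:
            out.append((a.circ_id, b.circ_id, relate_pair(a, b)))
    return out


def length_histogram(
    calls: Sequence[CircRNACall], edges: Sequence[float]
) -> pd.DataFrame:
    """Counts of genomic spans per circ_type in half-open bins [lo, hi).

    ``edges`` must be strictly increasing and start the partition of [0, inf);
    the final bin is open-ended if the last edge is finite.
    """
    import numpy as np

    edges = list(edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    if not np.isinf(edges[-1]):
        edges = edges + [np.inf]
    labels = [
        f"[{lo:g},{hi:g})" if np.isfinite(hi) else f">={lo:g}"
        for lo, hi in zip(edges, edges[1:])
    ]
    types = [EXONIC, INTRONIC, INTERGENIC]
    table = pd.DataFrame(0, index=types, columns=labels)
    for call in calls:
        idx = int(np.digitize(call.length, edges[1:], right=False))
        ctype = call.circ_type if call.circ_type in types else EXONIC
        table.loc[ctype, labels[idx]] += 1
    return table


def circ_sequence(genome: dict[str, str], call: CircRNACall) -> str:
    """The circle's sequence in transcript orientation (genomic span,
    reverse-complemented for '-' calls)."""
    s = genome[call.chrom][call.start - 1 : call.end]
    return revcomp(s) if call.strand == "-" else s


CATALOG_COLUMNS = ["id", "chrom", "start", "end", "strand", "type", "host_genes", "junction_reads"]


def write_catalog(calls: Sequence[CircRNACall], path) -> None:
    rows = [
        {
            "id": c.circ_id,
            "chrom": c.chrom,
            "start": c.start,
            "end": c.end,
            "strand": c.strand,
            "type": c.circ_type or "",
            "host_genes": ",".join(c.host_genes),
            "junction_reads": c.junction_reads,
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=CATALOG_COLUMNS).to_csv(path, sep="\t", index=False)


def read_catalog(path) -> list[CircRNACall]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=False)
    calls = []
    for row in df.itertuples(index=False):
        calls.append(
            CircRNACall(
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                strand=row.strand,
                junction_reads=int(row.junction_reads),
                circ_type=row.type or None,
                host_genes=[g for g in str(row.host_genes).split(",") if g],
            )
        )
    return calls


def write_bed6(calls: Sequence[CircRNACall], path) -> None:
    """BED6 export (0-based half-open)."""
    with open(path, "w") as fh:
        for c in calls:
            fh.write(
                f"{c.chrom}\t{c.start - 1}\t{c.end}\t{c.circ_id}\t{c.junction_reads}\t{c.strand}\n"
            )
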