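"""Synthetic study generator: toy genome, reads, sequences and counts.

Emulates the structure of a 3-condition (KNO3 levels N0/N6/N18) by
3-replicate root RNA-seq experiment with planted ground truth at every
level the pipeline tests:

* a random multi-chromosome genome carrying non-overlapping, stranded,
  multi-exon genes;
* planted circRNAs of the three genomic classes (exonic, intronic,
  intergenic), each flanked by canonical GT..AG back-splice dinucleotides on
  its strand so the detector can validate it;
* back-splice junction reads (tail|head concatenations) at configurable
  depth plus linear background reads from gene bodies, with uniform
  per-base sequencing error;
* mature miRNAs with perfect-complement response elements planted into both
  a circRNA and a non-host mRNA to form sponge (ceRNA) triplets;
* replicated negative-binomial count matrices for circRNAs, miRNAs and
  mRNAs in which triplet members share a strong condition-level expression
  pattern (so circRNA-mRNA co-expression exceeds the |r| >= 0.9 screen) and
  a configurable fraction of background features carries a planted fold
  change.

Everything is driven by a single integer seed; identical configurations
produce byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .quant import ExpressionMatrix
from .seq import (
    Annotation,
    Gene,
    revcomp,
    transcript_position,
    transcript_sequence,
    write_fasta,
    write_fastq,
    write_gff3,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")

CONDITION_NAMES = ("N0", "N6", "N18")


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Study-design and generator parameters.

    Defaults describe the reference synthetic study: 2 chromosomes x 200 kb,
    40 genes, 8 planted circRNAs (5 exonic / 2 intronic / 1 intergenic),
    100-bp reads at junction depth 10, 3 conditions x 3 replicates, NB
    dispersion 0.05, and 5 planted sponge triplets.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 200_000
    n_genes: int = 40
    exons_per_gene: int = 4
    n_circ_exonic: int = 5
    n_circ_intronic: int = 2
    n_circ_intergenic: int = 1
    read_length: int = 100
    anchor_len: int = 20  # matches the detector's default anchor
    junction_depth: int = 10
    background_depth: int = 2000
    error_rate: float = 0.001
    n_conditions: int = 3
    n_replicates: int = 3
    nb_dispersion: float = 0.05
    effect_log2fc: float = 2.0
    de_fraction: float = 0.2
    n_triplets: int = 5
    n_mirnas: int = 12
    mirna_length: int = 21

    def validate(self) -> None:
        if self.read_length < 2 * self.anchor_len:
            raise SimulationError("read_length must be >= 2 x anchor_len")
        if min(
            self.n_chromosomes,
            self.chrom_length,
            self.read_length,
        ) <= 0:
            raise SimulationError("sizes must be positive")
        if min(
            self.n_genes,
            self.n_circ_exonic,
            self.n_circ_intronic,
            self.n_circ_intergenic,
            self.junction_depth,
            self.background_depth,
            self.n_triplets,
        ) < 0:
            raise SimulationError("counts must be >= 0")
        if not 0 <= self.error_rate < 1:
            raise SimulationError("error_rate must be in [0, 1)")
        if self.n_replicates < 2:
            raise SimulationError("need >= 2 replicates per condition")
        if self.nb_dispersion <= 0:
            raise SimulationError("nb_dispersion must be > 0")
        if self.n_triplets > min(self.n_mirnas, self.total_circ):
            raise SimulationError("n_triplets exceeds available circRNAs or miRNAs")

    @property
    def total_circ(self) -> int:
        return self.n_circ_exonic + self.n_circ_intronic + self.n_circ_intergenic

    @property
    def conditions(self) -> tuple[str, ...]:
        if self.n_conditions == 3:
            return CONDITION_NAMES
        return tuple(f"G{i}" for i in range(self.n_conditions))


@dataclass
class PlantedCirc:
    chrom: str
    start: int
    end: int
    strand: str
    circ_type: str
    host_gene: str | None

    @property
    def circ_id(self) -> str:
        return f"{self.chrom}:{self.start}|{self.end}"


@dataclass
class PlantedSite:
    mirna_id: str
    target_id: str
    target_kind: str  # circRNA | mRNA
    position: int  # 1-based on the target transcript
    penalty: float


@dataclass
class GroundTruth:
    """Everything that was planted, for scoring recall downstream."""

    circs: list[PlantedCirc] = field(default_factory=list)
    sites: list[PlantedSite] = field(default_factory=list)
    triplets: list[tuple[str, str, str]] = field(default_factory=list)  # (circ, mirna, gene)
    de: dict[str, dict[str, float]] = field(default_factory=dict)  # feature -> {comparison: log2FC}
    mirnas: dict[str, str] = field(default_factory=dict)

    def de_features(self, comparison: str, min_log2fc: float = math.log2(1.5)) -> set[str]:
        return {
            f
            for f, per_cmp in self.de.items()
            if abs(per_cmp.get(comparison, 0.0)) > min_log2fc
        }


def _random_genome(rng: np.random.Generator, cfg: SimConfig) -> dict[str, np.ndarray]:
    return {
        f"chr{i + 1}": rng.choice(_BASES, size=cfg.chrom_length)
        for i in range(cfg.n_chromosomes)
    }


def _place_genes(rng: np.random.Generator, cfg: SimConfig) -> list[Gene]:
    """Pack non-overlapping multi-exon genes chromosome by chromosome."""
    genes: list[Gene] = []
    per_chrom = [cfg.n_genes // cfg.n_chromosomes] * cfg.n_chromosomes
    for i in range(cfg.n_genes % cfg.n_chromosomes):
        per_chrom[i] += 1
    gid = 0
    min_gap = 600
    for ci in range(cfg.n_chromosomes):
        chrom = f"chr{ci + 1}"
        layouts = []
        for _ in range(per_chrom[ci]):
            exon_lens = rng.integers(150, 301, size=cfg.exons_per_gene)
            intron_lens = rng.integers(150, 400, size=max(cfg.exons_per_gene - 1, 0))
            layouts.append((exon_lens, intron_lens))
        spans = [int(e.sum() + i.sum()) for e, i in layouts]
        need = sum(spans) + (len(layouts) + 1) * min_gap
        if need > cfg.chrom_length:
            raise SimulationError(
                f"cannot pack {per_chrom[ci]} genes into {chrom}: "
                f"need {need} bp, have {cfg.chrom_length}"
            )
        slack = cfg.chrom_length - need
        extra = rng.multinomial(slack, np.ones(len(layouts) + 1) / (len(layouts) + 1))
        pos = 1
        for j, (exon_lens, intron_lens) in enumerate(layouts):
            pos += min_gap + int(extra[j])
            gid += 1
            strand = "+" if rng.random() < 0.5 else "-"
            exons = []
            p = pos
            for k, elen in enumerate(exon_lens):
                exons.append((p, p + int(elen) - 1))
                p += int(elen)
                if k < len(intron_lens):
                    p += int(intron_lens[k])
            genes.append(
                Gene(
                    gene_id=f"G{gid:04d}",
                    chrom=chrom,
                    start=exons[0][0],
                    end=exons[-1][1],
                    strand=strand,
                    exons=exons,
                )
            )
            pos += spans[j]
    return genes


def _plant_signal(chrom_arr: np.ndarray, start: int, end: int, strand: str) -> None:
    """Write the canonical back-splice flanks for a circle at [start, end]."""
    up = b"AG" if strand == "+" else b"AC"
    down = b"GT" if strand == "+" else b"CT"
    chrom_arr[start - 3 : start - 1] = np.frombuffer(up, dtype="S1")
    chrom_arr[end : end + 2] = np.frombuffer(down, dtype="S1")


def _plant_circs(
    rng: np.random.Generator,
    cfg: SimConfig,
    genome: dict[str, np.ndarray],
    genes: list[Gene],
) -> list[PlantedCirc]:
    circs: list[PlantedCirc] = []
    by_chrom: dict[str, list[Gene]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    multi_exon = [g for g in genes if len(g.exons) >= 2]
    with_introns = [g for g in genes if g.introns]
    if cfg.n_circ_exonic and not multi_exon:
        raise SimulationError("exonic circRNAs requested but no multi-exon genes")
    if cfg.n_circ_intronic and not with_introns:
        raise SimulationError("intronic circRNAs requested but no introns available")
    need = cfg.n_circ_exonic + cfg.n_circ_intronic
    if need > len(genes):
        raise SimulationError("not enough genes to host the requested circRNAs")

    order = list(rng.permutation(len(genes)))
    pool = [genes[i] for i in order]
    exonic_hosts: list[Gene] = []
    intronic_hosts: list[Gene] = []
    for g in pool:
        if len(exonic_hosts) < cfg.n_circ_exonic and len(g.exons) >= 2:
            exonic_hosts.append(g)
        elif len(intronic_hosts) < cfg.n_circ_intronic and g.introns:
            intronic_hosts.append(g)
    if len(exonic_hosts) < cfg.n_circ_exonic or len(intronic_hosts) < cfg.n_circ_intronic:
        raise SimulationError("could not assign distinct host genes for planted circRNAs")

    for g in exonic_hosts:
        i = int(rng.integers(0, len(g.exons) - 1))
        start = g.exons[i][0]
        end = g.exons[i + 1][1]
        _plant_signal(genome[g.chrom], start, end, g.strand)
        circs.append(PlantedCirc(g.chrom, start, end, g.strand, "exonic", g.gene_id))

    for g in intronic_hosts:
        introns = g.introns
        i = int(rng.integers(0, len(introns)))
        s, e = introns[i]
        start, end = s + 10, e - 10
        if end - start + 1 < cfg.read_length:
            # pad towards intron bounds while staying strictly inside
            start, end = s + 2, e - 2
        if end - start + 1 < cfg.read_length:
            raise SimulationError(
                f"intron of {g.gene_id} too short for read_length={cfg.read_length}"
            )
        _plant_signal(genome[g.chrom], start, end, g.strand)
        circs.append(PlantedCirc(g.chrom, start, end, g.strand, "intronic", g.gene_id))

    # intergenic: widest gaps between genes, one circRNA per gap
    gaps: list[tuple[int, str, int, int]] = []
    for chrom, arr in genome.items():
        glist = sorted(by_chrom.get(chrom, []), key=lambda g: g.start)
        bounds = [(0, g.start - 1) for g in glist[:1]]
        prev_end = glist[0].end if glist else 0
        for g in glist[1:]:
            bounds.append((prev_end + 1, g.start - 1))
            prev_end = g.end
        bounds.append((prev_end + 1, len(arr)))
        for lo, hi in bounds:
            if hi - lo > 0:
                gaps.append((hi - lo + 1, chrom, lo, hi))
    gaps.sort(reverse=True)
    margin = 50
    for _ in range(cfg.n_circ_intergenic):
        if not gaps:
            raise SimulationError("not enough intergenic space for requested circRNAs")
        width, chrom, lo, hi = gaps.pop(0)
        span = int(rng.integers(3100, 3501))
        if width < span + 2 * margin:
            span = max(cfg.read_length, width - 2 * margin)
            if span < cfg.read_length:
                raise SimulationError("intergenic gap too narrow for a planted circRNA")
        start = max(lo, 1) + margin
        end = start + span - 1
        strand = "+" if rng.random() < 0.5 else "-"
        _plant_signal(genome[chrom], start, end, strand)
        circs.append(PlantedCirc(chrom, start, end, strand, "intergenic", None))
        # the unused right part of the gap can host further intergenic circRNAs
        rest_lo = end + 2 * margin
        if hi - rest_lo > 0:
            gaps.append((hi - rest_lo + 1, chrom, rest_lo, hi))
            gaps.sort(reverse=True)

    circs.sort(key=lambda c: (c.chrom, c.start, c.end))
    return circs


def _random_mirnas(rng: np.random.Generator, cfg: SimConfig) -> dict[str, str]:
    out = {}
    for i in range(cfg.n_mirnas):
        seq = "".join(chr(b[0]) for b in rng.choice(_BASES, size=cfg.mirna_length))
        out[f"miR-{i + 1:03d}"] = seq
    return out


def _plant_window(
    genome: dict[str, np.ndarray], chrom: str, g_start: int, window: str
) -> None:
    arr = np.frombuffer(window.encode(), dtype="S1")
    genome[chrom][g_start - 1 : g_start - 1 + len(window)] = arr


def _plant_triplets(
    rng: np.random.Generator,
    cfg: SimConfig,
    genome: dict[str, np.ndarray],
    genes: list[Gene],
    circs: list[PlantedCirc],
    mirnas: dict[str, str],
    truth: GroundTruth,
) -> None:
    """Embed a perfect miRNA response element into one circRNA and one
    non-host mRNA per triplet."""
    host_ids = {c.host_gene for c in circs if c.host_gene}
    free_genes = [g for g in genes if g.gene_id not in host_ids]
    if cfg.n_triplets > len(free_genes):
        raise SimulationError("not enough non-host genes for planted triplets")
    mirna_ids = sorted(mirnas)
    circ_order = list(rng.permutation(len(circs)))
    gene_order = list(rng.permutation(len(free_genes)))
    L = cfg.mirna_length
    for t in range(cfg.n_triplets):
        mid = mirna_ids[t]
        site = revcomp(mirnas[mid])  # perfect antiparallel complement
        circ = circs[circ_order[t]]
        gene = free_genes[gene_order[t]]

        # circRNA: plant into the interior of the genomic span, respecting the
        # circle's transcript orientation.
        span = circ.end - circ.start + 1
        off = int(rng.integers(30, span - L - 30))
        g_start = circ.start + off
        genomic = site if circ.strand == "+" else revcomp(site)
        _plant_window(genome, circ.chrom, g_start, genomic)
        if circ.strand == "+":
            tpos = g_start - circ.start + 1
        else:
            tpos = circ.end - (g_start + L - 1) + 1
        truth.sites.append(PlantedSite(mid, circ.circ_id, "circRNA", tpos, 0.0))

        # mRNA: plant into a middle exon of a gene that hosts no circRNA.
        ei = len(gene.exons) // 2
        es, ee = gene.exons[ei]
        off = int(rng.integers(5, (ee - es + 1) - L - 5))
        g_start = es + off
        genomic = site if gene.strand == "+" else revcomp(site)
        _plant_window(genome, gene.chrom, g_start, genomic)
        tpos = transcript_position(gene, g_start if gene.strand == "+" else g_start + L - 1)
        truth.sites.append(PlantedSite(mid, gene.gene_id, "mRNA", tpos, 0.0))

        truth.triplets.append((circ.circ_id, mid, gene.gene_id))


def simulate_genome(
    cfg: SimConfig,
) -> tuple[dict[str, str], Annotation, GroundTruth]:
    """Generate genome, annotation and planted ground truth.

    Returns (genome, annotation, truth); the truth at this stage carries the
    planted circRNAs, miRNA sequences, binding sites and sponge triplets.
    Count-level truth (planted fold changes) is added by
    :func:`simulate_counts`.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genome_arr = _random_genome(rng, cfg)
    genes = _place_genes(rng, cfg) if cfg.n_genes > 0 else []
    if cfg.n_genes == 0 and (cfg.n_circ_exonic or cfg.n_circ_intronic):
        raise SimulationError("exonic/intronic circRNAs requested with n_genes=0")
    truth = GroundTruth()
    truth.circs = _plant_circs(rng, cfg, genome_arr, genes)
    truth.mirnas = _random_mirnas(rng, cfg)
    if cfg.n_triplets:
        _plant_triplets(rng, cfg, genome_arr, genes, truth.circs, truth.mirnas, truth)
    genome = {c: arr.tobytes().decode() for c, arr in genome_arr.items()}
    return genome, Annotation(genes), truth


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def simulate_reads(
    truth: GroundTruth,
    genome: dict[str, str],
    cfg: SimConfig,
    annotation: Annotation | None = None,
) -> list[tuple[str, str]]:
    """Junction-spanning reads for every planted circRNA plus linear
    background reads from gene bodies.

    Each junction read is a tail|head concatenation of the circle in
    transcript orientation, with the junction at least ``anchor_len`` bases
    from both read ends.  A fresh sub-seed keeps read simulation independent
    of genome simulation.
    """
    cfg.validate()
    if cfg.read_length < 2 * cfg.anchor_len:
        raise SimulationError("read_length too short for the detector anchors")
    rng = np.random.default_rng((cfg.seed, 1))
    reads: list[tuple[str, str]] = []
    L = cfg.read_length
    for circ in truth.circs:
        chrom_seq = genome[circ.chrom]
        span = chrom_seq[circ.start - 1 : circ.end]
        circle = revcomp(span) if circ.strand == "-" else span
        if len(circle) < L:
            raise SimulationError(f"circle {circ.circ_id} shorter than read_length")
        for i in range(cfg.junction_depth):
            tail_len = int(rng.integers(cfg.anchor_len, L - cfg.anchor_len + 1))
            read = circle[-tail_len:] + circle[: L - tail_len]
            read = _apply_errors(rng, read, cfg.error_rate)
            reads.append((f"junc|{circ.circ_id}|{i}", read))
    genes = annotation.genes if annotation is not None else []
    if genes and cfg.background_depth:
        gi = rng.integers(0, len(genes), size=cfg.background_depth)
        for n, idx in enumerate(gi):
            g = genes[int(idx)]
            glen = g.end - g.start + 1
            if glen < L:
                continue
            off = int(rng.integers(0, glen - L + 1))
            seq = genome[g.chrom][g.start - 1 + off : g.start - 1 + off + L]
            if g.strand == "-":
                seq = revcomp(seq)
            seq = _apply_errors(rng, seq, cfg.error_rate)
            reads.append((f"lin|{g.gene_id}|{n}", seq))
    return reads


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative binomial with variance m + dispersion * m^2 (gamma-Poisson)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        raise SimulationError("nb_dispersion must be > 0")
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def _condition_means(
    rng: np.random.Generator,
    cfg: SimConfig,
    features: list[str],
    triplet_members: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Per-feature, per-condition expected counts. Triplet members get their
    planted pattern; a de_fraction of the rest get a one-condition fold
    change of 2**effect_log2fc; the remainder are flat."""
    n_cond = cfg.n_conditions
    means = np.zeros((len(features), n_cond))
    base = np.exp(rng.normal(np.log(100.0), 1.0, size=len(features)))
    base = np.clip(base, 5.0, 5000.0)
    for i, f in enumerate(features):
        if f in triplet_members:
            means[i] = triplet_members[f]
            continue
        means[i] = base[i]
        if cfg.effect_log2fc != 0 and rng.random() < cfg.de_fraction:
            c = int(rng.integers(0, n_cond))
            means[i, c] *= 2.0 ** cfg.effect_log2fc
    return pd.DataFrame(means, index=features, columns=list(cfg.conditions))


def _record_true_de(truth: GroundTruth, means: pd.DataFrame, conditions) -> None:
    thr = math.log2(1.5)
    for a_i in range(len(conditions)):
        for b_i in range(a_i + 1, len(conditions)):
            a, b = conditions[a_i], conditions[b_i]
            cmp_name = f"{a} vs {b}"
            lfc = np.log2(means[b].to_numpy() + 1e-300) - np.log2(
                means[a].to_numpy() + 1e-300
            )
            for f, v in zip(means.index, lfc):
                if abs(v) > thr:
                    truth.de.setdefault(f, {})[cmp_name] = float(v)


def simulate_counts(
    truth: GroundTruth, cfg: SimConfig, annotation: Annotation
) -> tuple[ExpressionMatrix, ExpressionMatrix, ExpressionMatrix]:
    """Replicated NB count matrices for circRNAs, miRNAs and mRNAs.

    Triplet circRNA/mRNA pairs share a per-triplet permutation of the
    (10, 100, 1000) condition-mean pattern, which makes their log-scale
    Pearson correlation exceed 0.9 in expectation at the default dispersion
    and guarantees a planted fold change well above the DE threshold; the
    triplet's miRNA gets its own permuted pattern so it is differentially
    expressed too.  Planted log2 fold changes (condition-mean ratios) are
    recorded in ``truth.de``.
    """
    cfg.validate()
    rng = np.random.default_rng((cfg.seed, 2))
    conditions = list(cfg.conditions)
    pattern = np.array([10.0, 100.0, 1000.0])[: cfg.n_conditions]

    circ_pat: dict[str, np.ndarray] = {}
    mir_pat: dict[str, np.ndarray] = {}
    gene_pat: dict[str, np.ndarray] = {}
    for circ_id, mirna_id, gene_id in truth.triplets:
        p = rng.permutation(pattern)
        circ_pat[circ_id] = p
        gene_pat[gene_id] = p
        mir_pat[mirna_id] = rng.permutation(pattern)

    circ_features = [c.circ_id for c in truth.circs]
    mir_features = sorted(truth.mirnas)
    gene_features = [g.gene_id for g in annotation.genes]

    matrices = []
    for features, pats, kind in (
        (circ_features, circ_pat, "circRNA"),
        (mir_features, mir_pat, "miRNA"),
        (gene_features, gene_pat, "mRNA"),
    ):
        means = _condition_means(rng, cfg, features, pats)
        _record_true_de(truth, means, conditions)
        cols, data = [], []
        for cond in conditions:
            for r in range(1, cfg.n_replicates + 1):
                cols.append(f"{cond}_r{r}")
                data.append(_nb_draw(rng, means[cond].to_numpy(), cfg.nb_dispersion))
        counts = pd.DataFrame(
            np.column_stack(data), index=features, columns=cols, dtype=int
        )
        design = pd.DataFrame(
            {
                "sample": cols,
                "condition": [c.rsplit("_", 1)[0] for c in cols],
                "replicate": [int(c.rsplit("_r", 1)[1]) for c in cols],
            }
        ).set_index("sample")
        matrices.append(ExpressionMatrix(counts=counts, design=design, kind=kind))
    return tuple(matrices)


def write_truth(truth: GroundTruth, outdir: str | Path) -> None:
    outdir = Path(outdir)
    pd.DataFrame(
        [
            {
                "circ_id": c.circ_id,
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "strand": c.strand,
                "type": c.circ_type,
                "host_gene": c.host_gene or "",
            }
            for c in truth.circs
        ]
    ).to_csv(outdir / "truth_circs.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "mirna": s.mirna_id,
                "target": s.target_id,
                "kind": s.target_kind,
                "position": s.position,
                "penalty": s.penalty,
            }
            for s in truth.sites
        ]
    ).to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)
    pd.DataFrame(truth.triplets, columns=["circ_id", "mirna_id", "gene_id"]).to_csv(
        outdir / "truth_triplets.tsv", sep="\t", index=False
    )
    rows = [
        {"feature": f, "comparison": cmp_name, "log2fc": v}
        for f, per in sorted(truth.de.items())
        for cmp_name, v in sorted(per.items())
    ]
    pd.DataFrame(rows, columns=["feature", "comparison", "log2fc"]).to_csv(
        outdir / "truth_de.tsv", sep="\t", index=False
    )


def simulate_study(cfg: SimConfig, outdir: str | Path) -> GroundTruth:
    """Run the full generator and write every artifact to ``outdir``.

    Writes genome.fa, annotation.gff3, reads.fastq, mirnas.fa, mrnas.fa,
    counts_{circ,mirna,mrna}.tsv, design.tsv and truth tables.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, annotation, truth = simulate_genome(cfg)
    write_fasta(genome, outdir / "genome.fa")
    write_gff3(annotation, outdir / "annotation.gff3")
    reads = simulate_reads(truth, genome, cfg, annotation)
    write_fastq(reads, outdir / "reads.fastq")
    write_fasta(truth.mirnas, outdir / "mirnas.fa")
    write_fasta(
        {g.gene_id: transcript_sequence(genome, g) for g in annotation.genes},
        outdir / "mrnas.fa",
    )
    circ_m, mir_m, mrna_m = simulate_counts(truth, cfg, annotation)
    circ_m.to_tsv(outdir / "counts_circ.tsv")
    mir_m.to_tsv(outdir / "counts_mirna.tsv")
    mrna_m.to_tsv(outdir / "counts_mrna.tsv")
    circ_m.design.to_csv(outdir / "design.tsv", sep="\t")
    write_truth(truth, outdir)
    return truth
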