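# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `circsponge`.  Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## 1. Coordinate and sequence conventions

All coordinates are 1-based inclusive internally; BED export converts to
0-based half-open.  Sequences use the uppercase DNA alphabet end-to-end;
mature miRNAs are stored with T in place of U and converted only at I/O.
A circRNA id renders as `chrom:start|end` where `start` is the acceptor
(left breakpoint) and `end` the donor (right breakpoint).

## 2. Back-splice detection (`circsponge.detect`)

A read crossing a back-splice junction is a tail|head concatenation of the
circle: its 5′ part derives from the circle's 3′ end (upstream of the
donor) and its 3′ part from the circle's 5′ end (downstream of the
acceptor).  The detector:

1. builds an exact k-mer index of the genome (default k = anchor length
   20 nt; k-mers containing N are not indexed);
2. maps each read's terminal anchors; both must map uniquely (multi-mapping
   reads are discarded and logged) on one chromosome and orientation, with
   the 3′ anchor upstream of the 5′ anchor — colinear reads fail here;
3. extends both anchors inward against the genome and enumerates every
   split point consistent with the full read; each split implies a
   breakpoint pair (start, end);
4. optionally requires the canonical splice signal on the assigned strand:
   the genomic dinucleotides immediately downstream of the donor must be
   GT and immediately upstream of the acceptor AG (in forward-genome
   coordinates: `AG[circle]GT` for +, `AC[circle]CT` for −);
5. picks the leftmost donor among valid splits (deterministic tie-break),
   aggregates identical (chrom, start, end, strand) across reads, and
   keeps calls with at least `min_junction_reads` (default 2) supporting
   reads and genomic span ≤ `max_span` (default 100 kb).

Minus-strand junctions are handled by applying the same '+' logic to the
reverse-complemented read, which maps a minus-strand tail|head pattern
onto the forward genome exactly.

**Classification.**  A call is *exonic* when both breakpoints fall inside
exons of strand-matching gene(s) (all such genes are recorded as hosts —
including the case of two different genes), *intronic* when the whole
interval lies within a single intron of one gene, and *intergenic* when no
gene overlaps it.  Two residual geometries keep the three-type partition
exhaustive: an interval overlapping only antisense genes is classified
intergenic (there is no host on the call's strand), and any remaining
sense-overlap geometry (e.g. breakpoints in different introns) is
classified exonic with the overlapping same-strand genes as hosts.  The
generator only plants the three clean cases; the catch-alls are covered by
dedicated unit tests.

**Isoform relations.**  For two circRNAs of one host gene: disjoint
intervals → `no_association`; exactly one shared endpoint →
`shared_splice_site` (checked first, so a nested interval sharing one
boundary counts as a shared splice site); one interval containing the
other (including identity) → `containment`; partial overlap without a
shared endpoint → `no_association`.

## 3. Synthetic study generator (`circsponge.sim`)

The generator emulates a 3-condition × 3-replicate root RNA-seq study of
nitrate response with planted ground truth.  Defaults define the reference
study: 2 chromosomes × 200 kb, 40 non-overlapping stranded genes of
4 exons (exon lengths 150–300 bp, introns 150–399 bp), 8 planted circRNAs
(5 exonic spanning two adjacent exons, genomic span ≤ 999 bp; 2 intronic
strictly inside one intron; 1 intergenic of 3.1–3.5 kb — mirroring the
observation that exonic circRNAs mostly span 200–1000 bp while intergenic
ones exceed 3 kb), 100-bp reads, junction depth 10, 2000 linear background
reads drawn uniformly from gene bodies, per-base error rate 0.001,
NB dispersion 0.05, and 5 planted sponge triplets among 12 miRNAs of
21 nt.

Every planted circle gets canonical splice flanks written into the genome
on its strand, so the detector can validate it.  Gene packing that does
not fit the chromosome raises an error rather than silently truncating.

**MREs and triplets.**  Each triplet plants the exact reverse complement
of its miRNA (a perfect-duplex site, penalty 0) into the interior of one
circRNA's genomic span and into a middle exon of one gene that hosts no
circRNA, both orientation-corrected for the transcript strand.

**Counts.**  Counts are negative-binomial with Var = μ + αμ², sampled as
gamma-Poisson; dispersion ≤ 0 is an error.  Triplet circRNA/mRNA pairs
share a per-triplet random permutation of condition means (10, 100, 1000),
which makes their log-scale Pearson correlation exceed 0.9 in expectation
at α = 0.05 and plants fold changes far above the DE threshold; each
triplet's miRNA receives its own permuted pattern so it is differentially
expressed too.  Of the remaining features, a fraction `de_fraction`
(default 0.2) receives a 2^`effect_log2fc` (default 4-fold) change in one
random condition; all condition-mean ratios exceeding 1.5× are recorded as
planted truth.  Library sizes and read depth per junction are free
parameters of the generator (no external study pins them); defaults were
chosen once at realistic desk scale.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: spliced circRNA isoform sequences (circles are
genomic spans, so exonic circle sequences include their introns),
paired-end reads, quality-score structure, adapter/rRNA contamination,
GC or length biases, between-sample library-composition shifts, isoform
switching, and imperfect/offset MREs.  Detector recall of 100% on planted
junctions demonstrates correctness of the algorithm under its stated
contract, not the sensitivity of CIRI-class tools on real libraries.

## 4. Quantification and differential expression (`circsponge.quant`)

*RPM* is counts/library-size × 10⁶ with library sizes defaulting to column
sums.  The *circular-to-linear ratio* is 2j/(2j + l) — a back-splice joint
is covered once while two linear joints flank the same breakpoints — and
is undefined (NaN) at j = l = 0.  The *replicate filter* keeps features
detected (nonzero) in ≥ 2 replicates of at least one condition.
*Five-level categories* use half-open bins [0, 0.5), [0.5, 1), [1, 5),
[5, 10), [10, ∞) for circRNAs and [0, 50), [50, 100), [100, 500),
[500, 2000), [2000, ∞) for host genes.

**The DE test** between two conditions (≥ 2 replicates each):

1. median-of-ratios size factors over the features positive in every
   sample (library-size ratios as fallback);
2. per-feature method-of-moments dispersion α̂ = (s² − m)/m² pooled across
   the two groups, clipped at 0, then shrunk toward the across-feature
   median with prior weight 4 (equal to the residual df at 3v3) and
   floored at 0.01 — three replicates alone give unusable dispersion
   estimates, and the shrinkage is what makes the test calibrated;
3. Wald statistic: log₂((m_B + c)/(m_A + c)) with pseudocount c = 1
   (condition-specific circRNAs would otherwise divide by zero), over the
   delta-method standard error using φ(m) = m + α̂m²;
4. a Student-t reference with a Satterthwaite-type effective df: only the
   dispersion component of φ carries estimation noise (the Poisson part is
   structural), so df = ν_eff · (s_A + s_B)²/u² with
   u = α̂(m_A²/(n_A d_A) + m_B²/(n_B d_B)) and base df
   ν_eff = (n_A + n_B − 2) + prior/2 = 6 at 3v3.  The df rises toward a
   normal reference where the Poisson term dominates (low counts or low
   dispersion) and falls toward the residual df where α̂m ≫ 1.  Simulation
   at the generator's study conditions (10,000 null features, 3v3,
   α = 0.05) puts the raw-P type-I rate at 0.046–0.053 across seeds — the
   acceptance script re-measures it on every run;
5. Benjamini–Hochberg adjustment across features (delegated to
   statsmodels; an independent brute-force step-up oracle checks it in the
   tests).

A feature is DE when FC > 1.5 or FC < 1/1.5 **and** adjusted P < 0.05.
Raw P is also emitted so a raw-P gate is reproducible (the conventional
description "P < 0.05 with BH correction" is ambiguous; adjusted is the
default reading here).  Known limitation: with very few features (e.g. a
12-row miRNA matrix) median-of-ratios size factors are noisy and the DEM
call is liberal; downstream triplet evidence (sites + co-expression)
guards against this.  The floor makes the test conservative when the true
dispersion is far below 0.01, and counts ≲ 20 with a pseudocount of 1 bias
fold changes toward zero.

## 5. miRNA target scoring (`circsponge.targets`)

The penalty scheme is the conventional plant-miRNA scoring: Watson–Crick
pair 0; G:U wobble 0.5 (directional on the RNA sense — target G with
miRNA U and target U with miRNA G); mismatch 1; each gapped base 1; every
penalty arising at miRNA positions 2–13 doubled; at most 1 gapped base;
site cutoff 4.0.  All constants are configurable (`ScoringParams`); no
external study pins them, so they are declared, not inferred.

The optimal antiparallel gapped alignment of the full miRNA against a
target window (window length = miRNA length ± gaps) is computed by dynamic
programming over (miRNA position, window position, gaps used); a target
bulge between miRNA positions i and i+1 is charged at position i+1 (capped
at the miRNA length).  Ties prefer fewer gaps, then pair over bulge over
miRNA-gap in traceback.  Scanning slides every admissible window over the
target; circular targets are extended by their own first
miRNA-length + gaps − 1 bases so sites may straddle the back-splice
junction (reported with wrapped coordinates and `spans_junction=True`).
Candidate sites at penalty ≤ cutoff are resolved to a non-overlapping set
greedily by ascending (penalty, position).  The sliding scan is
numba-compiled with a pure-Python fallback; penalties are exact multiples
of 0.5, so the two paths agree exactly, and an exhaustive alignment
enumerator verifies optimality in the tests.

## 6. ceRNA network (`circsponge.network`)

Co-expression is Pearson correlation of log₂(value + 1) across shared
samples — correlation on raw NB counts would be dominated by the largest
means — with the two-sided P from t = r√((n−2)/(1−r²)) on n − 2 df.  Pairs
pass at |r| ≥ 0.9 and P < 0.01 (an optional positive-only mode implements
the directional form the ceRNA hypothesis predicts; the absolute-value
criterion is the default).  At n = 9 samples, r = 0.9 corresponds to
P ≈ 9 × 10⁻⁴, so both gates bind.

A triplet (c, m, g) is accepted when m has ≥ 1 predicted site on the DE
circRNA c **and** ≥ 1 site on the DE mRNA g (shared MRE is read as shared
miRNA identity, the standard ceRNA usage, not identical site sequence) and
(c, g) passed co-expression.  miRNA–mRNA anticorrelation is not required.
The typed graph (circRNA/miRNA/mRNA nodes; binding and coexpression edges)
exports to SIF and GraphML for Cytoscape.

Enrichment of a gene set against user-supplied term→gene maps uses the
exact hypergeometric upper tail P(X ≥ k) with BH across terms; both the
conventional raw-P < 0.05 gate and adjusted P are reported.

## 7. Pipeline (`circsponge.pipeline`, CLI `circsponge`)

`run` chains simulate → detect → quantify → DE (all pairwise comparisons
of N0/N6/N18 by default) → target scan → ceRNA → report under one YAML
config and one seed; every output is deterministically ordered and a
checksum manifest is written, so re-running a config is bit-identical.
The target scan is restricted to DE features (DEM miRNAs against DEC
circRNA and DEG mRNA sequences): the sponge search operates on
condition-responsive candidates, which is also where the ceRNA mechanism
is interpretable.  Linear-spanning read counts for the circular-to-linear
ratio are obtained by exact matching of breakpoint-centred probes (±10 bp)
against the read set — a deliberate simplification standing in for a
full linear aligner, adequate at the generator's error rates.  The report
(`report.txt`) recomputes every number it shows from the stage TSVs:
per-type and per-length-bin catalogue counts, host-gene multiplicity
shares, per-comparison DEC counts with union/intersection bookkeeping,
and network sizes.

## 8. Problem sizes used in verification

The reference study (2 × 200 kb, 8 circRNAs, ~2100 reads, 5 triplets) runs
a full pipeline pass in a few seconds; the test suite performs 20
end-to-end runs for triplet recovery, a 10,000-feature null calibration,
and 200-case exhaustive-oracle comparisons for the duplex scorer — sizes
chosen so that planted-truth recovery is measured on hundreds of events
while the whole suite stays interactive.  Larger genomes only dilate the
k-mer index and scan time linearly; the algorithms have no
genome-scale-specific logic.
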