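"""End-to-end orchestration: simulate -> detect -> quantify -> DE ->
target scan -> ceRNA network -> report.

A single :class:`PipelineConfig` (YAML-serialisable) drives every stage;
re-running with the same configuration is bit-identical because all
randomness flows from one seed and every output is deterministically
ordered.  Target scanning is restricted to differentially expressed
features (the sponge search operates on N-responsive candidates), which is
also where the biology lives: a sponge that is not itself regulated cannot
explain condition-dependent derepression.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import detect as cd
from . import network as net
from . import quant
from . import targets as tg
from .seq import read_fasta, read_fastq, read_gff3, transcript_sequence
from .sim import SimConfig, simulate_study

log = logging.getLogger("circsponge")


@dataclass
class PipelineConfig:
    outdir: str = "circsponge_run"
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    detector: cd.DetectorParams = field(default_factory=cd.DetectorParams)
    scoring: tg.ScoringParams = field(default_factory=tg.ScoringParams)
    fc_threshold: float = 1.5
    de_alpha: float = 0.05
    use_adjusted_p: bool = True
    min_replicates: int = 2
    r_min: float = 0.9
    corr_alpha: float = 0.01
    comparisons: list[tuple[str, str]] | None = None

    def __post_init__(self) -> None:
        self.sim = dataclasses.replace(self.sim, seed=self.seed)
        conds = self.sim.conditions
        if self.comparisons is None:
            self.comparisons = [
                (conds[i], conds[j])
                for i in range(len(conds))
                for j in range(i + 1, len(conds))
            ]
        for a, b in self.comparisons:
            for c in (a, b):
                if c not in conds:
                    raise ValueError(
                        f"comparison condition {c!r} not among conditions {conds}"
                    )
        if min(self.fc_threshold, self.de_alpha, self.r_min, self.corr_alpha) <= 0:
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "sim" in kwargs:
            kwargs["sim"] = SimConfig(**kwargs["sim"])
        if "detector" in kwargs:
            kwargs["detector"] = cd.DetectorParams(**kwargs["detector"])
        if "scoring" in kwargs:
            kwargs["scoring"] = tg.ScoringParams(**kwargs["scoring"])
        if "comparisons" in kwargs and kwargs["comparisons"] is not None:
            kwargs["comparisons"] = [tuple(c) for c in kwargs["comparisons"]]
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        # outdir is a runtime location, not part of the scientific config
        data = {
            "seed": self.seed,
            "sim": dataclasses.asdict(self.sim),
            "detector": dataclasses.asdict(self.detector),
            "scoring": dataclasses.asdict(self.scoring),
            "fc_threshold": self.fc_threshold,
            "de_alpha": self.de_alpha,
            "use_adjusted_p": self.use_adjusted_p,
            "min_replicates": self.min_replicates,
            "r_min": self.r_min,
            "corr_alpha": self.corr_alpha,
            "comparisons": [list(c) for c in self.comparisons],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _checksum_log(outdir: Path) -> None:
    entries = {
        str(p.relative_to(outdir)): _sha256(p)
        for p in sorted(outdir.rglob("*"))
        if p.is_file() and p.name != "checksums.json"
    }
    (outdir / "checksums.json").write_text(json.dumps(entries, indent=2) + "\n")


def _linear_spanning_counts(
    reads_path: Path, genome: dict[str, str], calls, flank: int = 10
) -> dict[str, int]:
    """Count reads containing the colinear genomic context of either
    breakpoint (exact match over a 2*flank window centred on the joint)."""
    probes: dict[str, list[str]] = {}
    for call in calls:
        seq = genome[call.chrom]
        windows = [
            seq[call.start - 1 - flank : call.start - 1 + flank],
            seq[call.end - flank : call.end + flank],
        ]
        probes[call.circ_id] = [w for w in windows if len(w) == 2 * flank]
    counts = {cid: 0 for cid in probes}
    from .seq import revcomp

    for _name, read in read_fastq(reads_path):
        rc = revcomp(read)
        for cid, ws in probes.items():
            for w in ws:
                if w in read or w in rc:
                    counts[cid] += 1
                    break
    return counts


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage into ``config.outdir`` and return that directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    simdir = outdir / "sim"
    log.info("stage simulate -> %s", simdir)
    truth = simulate_study(config.sim, simdir)
    config.to_yaml(outdir / "config.yaml")

    log.info("stage detect")
    genome = read_fasta(simdir / "genome.fa")
    annotation = read_gff3(simdir / "annotation.gff3")
    index = cd.build_index(genome, config.detector.anchor_len)
    reads = read_fastq(simdir / "reads.fastq")
    calls, discards = cd.detect_backsplice(reads, index, genome, config.detector)
    for call in calls:
        cd.classify(call, annotation)
    cd.write_catalog(calls, outdir / "catalog.tsv")
    (outdir / "detect_discards.json").write_text(
        json.dumps(discards, sort_keys=True, indent=2) + "\n"
    )

    log.info("stage quantify")
    circ_m = quant.ExpressionMatrix.from_tsv(
        simdir / "counts_circ.tsv", simdir / "design.tsv", kind="circRNA"
    )
    mir_m = quant.ExpressionMatrix.from_tsv(
        simdir / "counts_mirna.tsv", simdir / "design.tsv", kind="miRNA"
    )
    mrna_m = quant.ExpressionMatrix.from_tsv(
        simdir / "counts_mrna.tsv", simdir / "design.tsv", kind="mRNA"
    )
    circ_rpm = quant.rpm_normalize(circ_m)
    mrna_rpm = quant.rpm_normalize(mrna_m)
    circ_rpm.rename_axis("feature").to_csv(outdir / "circ_rpm.tsv", sep="\t")
    lin = _linear_spanning_counts(simdir / "reads.fastq", genome, calls)
    pd.DataFrame(
        {
            "circ_id": [c.circ_id for c in calls],
            "junction_reads": [c.junction_reads for c in calls],
            "linear_spanning_reads": [lin[c.circ_id] for c in calls],
            "circular_to_linear_ratio": [
                quant.circular_to_linear_ratio(c.junction_reads, lin[c.circ_id])
                for c in calls
            ],
            "level": [
                quant.categorize_expression(v, "circRNA")
                for v in circ_rpm.reindex([c.circ_id for c in calls])
                .mean(axis=1)
                .fillna(0.0)
            ],
        }
    ).to_csv(outdir / "circ_quant.tsv", sep="\t", index=False)

    log.info("stage differential expression")
    de_kwargs = dict(
        fc_threshold=config.fc_threshold,
        alpha=config.de_alpha,
        use_adjusted=config.use_adjusted_p,
    )
    circ_f = quant.replicate_filter(circ_m, config.min_replicates)
    de_frames = {}
    for name, m in (("circ", circ_f), ("mirna", mir_m), ("mrna", mrna_m)):
        de = quant.de_all_comparisons(m, config.comparisons, **de_kwargs)
        de.to_csv(outdir / f"de_{name}.tsv", sep="\t", index=False)
        de_frames[name] = de
    dec = sorted(de_frames["circ"].loc[de_frames["circ"]["is_DE"], "feature"].unique())
    dem = sorted(de_frames["mirna"].loc[de_frames["mirna"]["is_DE"], "feature"].unique())
    deg = sorted(de_frames["mrna"].loc[de_frames["mrna"]["is_DE"], "feature"].unique())

    log.info("stage target scan (%d DEMs x %d DECs + %d DEGs)", len(dem), len(dec), len(deg))
    detected = {c.circ_id: c for c in calls}
    mirnas = {m: truth.mirnas[m] for m in dem if m in truth.mirnas}
    circ_seqs = {
        cid: cd.circ_sequence(genome, detected[cid]) for cid in dec if cid in detected
    }
    gene_by_id = {g.gene_id: g for g in annotation.genes}
    mrna_seqs = {
        gid: transcript_sequence(genome, gene_by_id[gid])
        for gid in deg
        if gid in gene_by_id
    }
    sites = tg.scan_all(mirnas, circ_seqs, circular=True, params=config.scoring)
    sites += tg.scan_all(mirnas, mrna_seqs, circular=False, params=config.scoring)
    sites_df = tg.sites_to_frame(sites)
    sites_df.to_csv(outdir / "sites.tsv", sep="\t", index=False)
    tg.interaction_table(sites).to_csv(outdir / "interactions.tsv", sep="\t", index=False)

    log.info("stage ceRNA network")
    coexpr = net.coexpression_pairs(
        circ_rpm.loc[circ_rpm.index.isin(dec)],
        mrna_rpm.loc[mrna_rpm.index.isin(deg)],
        r_min=config.r_min,
        alpha=config.corr_alpha,
    )
    coexpr.to_csv(outdir / "coexpression.tsv", sep="\t", index=False)
    triplets, graph = net.build_cerna(dec, dem, deg, sites_df, coexpr)
    triplets.to_csv(outdir / "triplets.tsv", sep="\t", index=False)
    net.write_sif(graph, outdir / "network.sif")
    net.write_graphml(graph, outdir / "network.graphml")

    log.info("stage report")
    report = summarize(outdir)
    (outdir / "report.txt").write_text(report)
    _checksum_log(outdir)
    return outdir


def recovered_triplets(outdir: str | Path) -> set[tuple[str, str, str]]:
    df = pd.read_csv(Path(outdir) / "triplets.tsv", sep="\t")
    return {(r.circ, r.mirna, r.mrna) for r in df.itertuples(index=False)}


def true_triplets(outdir: str | Path) -> set[tuple[str, str, str]]:
    df = pd.read_csv(Path(outdir) / "sim" / "truth_triplets.tsv", sep="\t")
    return {(r.circ_id, r.mirna_id, r.gene_id) for r in df.itertuples(index=False)}


def summarize(outdir: str | Path) -> str:
    """Assemble the run report from the stage TSVs (every number in the
    report is recomputable from the files it cites)."""
    outdir = Path(outdir)
    lines = ["circsponge run summary", "======================", ""]

    catalog_path = outdir / "catalog.tsv"
    if catalog_path.exists():
        cat = pd.read_csv(catalog_path, sep="\t", keep_default_na=False)
        lines.append(f"circRNAs detected: {len(cat)}")
        for t, n in cat["type"].value_counts().sort_index().items():
            lines.append(f"  {t}: {n}")
        if len(cat):
            spans = cat["end"] - cat["start"] + 1
            edges = [0, 200, 1000, 3000]
            labels = ["[0,200)", "[200,1000)", "[1000,3000)", ">=3000"]
            import numpy as np

            binned = np.digitize(spans, edges[1:])
            lines.append("length distribution (genomic span):")
            for i, lab in enumerate(labels):
                lines.append(f"  {lab}: {(binned == i).sum()}")
            hosts = [h for hs in cat["host_genes"] for h in str(hs).split(",") if h]
            if hosts:
                mult = pd.Series(hosts).value_counts().value_counts().sort_index()
                total_hosts = int(mult.sum())
                lines.append("host-gene multiplicity (circRNAs per host gene):")
                for k, n in mult.items():
                    cls = f"{k}" if k < 4 else "4+"
                    lines.append(
                        f"  {cls}: {n} host genes ({100.0 * n / total_hosts:.2f}%)"
                    )
    else:
        lines.append("circRNA catalog: MISSING")

    de_path = outdir / "de_circ.tsv"
    if de_path.exists():
        de = pd.read_csv(de_path, sep="\t")
        per_cmp = {}
        lines.append("")
        lines.append("differentially expressed circRNAs (DECs):")
        for cmp_name, sub in de.groupby("comparison"):
            called = sub.loc[sub["is_DE"]]
            per_cmp[cmp_name] = set(called["feature"])
            up = int((called["direction"] == "up").sum())
            down = int((called["direction"] == "down").sum())
            lines.append(f"  {cmp_name}: {len(called)} (up {up}, down {down})")
        union = set().union(*per_cmp.values()) if per_cmp else set()
        inter = set.intersection(*per_cmp.values()) if per_cmp else set()
        lines.append(f"  union over comparisons: {len(union)}")
        lines.append(f"  shared by all comparisons: {len(inter)}")
    else:
        lines.append("DE tables: MISSING")

    trip_path = outdir / "triplets.tsv"
    if trip_path.exists():
        trip = pd.read_csv(trip_path, sep="\t")
        lines.append("")
        lines.append(
            "ceRNA network: "
            f"{trip['circ'].nunique()} circRNAs, {trip['mirna'].nunique()} miRNAs, "
            f"{trip['mrna'].nunique()} mRNAs, {len(trip)} triplets"
        )
    else:
        lines.append("ceRNA triplets: MISSING")
    return "\n".join(lines) + "\n"
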