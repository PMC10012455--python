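"""Quantification and differential expression for junction-count matrices.

Expression is summarised as reads-per-million (RPM), the circular-to-linear
ratio 2j/(2j+l), and a five-level abundance categorisation.  Differential
expression between two conditions uses a negative-binomial two-group Wald
test: median-of-ratios size factors, method-of-moments dispersion shrunk
toward the across-feature median with a small-sample floor, a Wald
statistic on the log2 difference of normalised group means
(pseudocount-stabilised), a Student-t reference with a Satterthwaite-type
effective df (only the dispersion part of the NB variance carries
estimation noise), and Benjamini-Hochberg adjustment across features.  A feature is called differentially expressed when its fold
change exceeds 1.5 in either direction and its adjusted P falls below 0.05
(both raw and adjusted P are reported, so either gate can be reproduced).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CIRC_LEVELS = (0.0, 0.5, 1.0, 5.0, 10.0)
HOST_GENE_LEVELS = (0.0, 50.0, 100.0, 500.0, 2000.0)


@dataclass
class ExpressionMatrix:
    """Features x samples counts with (condition, replicate) design metadata."""

    counts: pd.DataFrame
    design: pd.DataFrame  # index: sample, columns: condition, replicate
    kind: str = "circRNA"

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate feature ids")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.design.index)
        if missing:
            raise ValueError(f"samples missing from design: {sorted(missing)}")

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for s in self.counts.columns:
            c = self.design.loc[s, "condition"]
            if c not in seen:
                seen.append(c)
        return seen

    def samples_of(self, condition: str) -> list[str]:
        return [
            s
            for s in self.counts.columns
            if self.design.loc[s, "condition"] == condition
        ]

    def to_tsv(self, path: str | Path) -> None:
        self.counts.rename_axis("feature").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(
        cls, counts_path: str | Path, design_path: str | Path, kind: str = "circRNA"
    ) -> "ExpressionMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        design = pd.read_csv(design_path, sep="\t", index_col=0)
        return cls(counts=counts, design=design, kind=kind)


@dataclass
class DEResult:
    feature: str
    comparison: str
    log2fc: float
    fold_change: float
    p_raw: float
    p_adj: float
    is_de: bool
    direction: str  # up | down


def rpm_normalize(
    matrix: ExpressionMatrix | pd.DataFrame, library_sizes: pd.Series | dict | None = None
) -> pd.DataFrame:
    """Reads-per-million: counts / library size x 1e6.

    Library sizes default to column sums (total mapped reads stand-in).
    """
    counts = matrix.counts if isinstance(matrix, ExpressionMatrix) else matrix
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    sizes = pd.Series(library_sizes, dtype=float).reindex(counts.columns)
    if sizes.isna().any():
        raise ValueError("library size missing for some samples")
    if (sizes <= 0).any():
        raise ValueError("library sizes must be > 0")
    return counts / sizes * 1e6


def circular_to_linear_ratio(junction_reads, linear_spanning_reads):
    """Fraction of junction evidence that is circular: 2j / (2j + l).

    The factor 2 reflects that a back-splice junction is covered by one
    circular joint while two linear splice joints flank the same breakpoints.
    Returns NaN when both inputs are zero (undefined locus).
    """
    j = np.asarray(junction_reads, dtype=float)
    l = np.asarray(linear_spanning_reads, dtype=float)
    if (j < 0).any() or (l < 0).any():
        raise ValueError("read counts must be >= 0")
    with np.errstate(invalid="ignore"):
        out = np.where(2 * j + l > 0, 2 * j / (2 * j + l), np.nan)
    return float(out) if out.ndim == 0 else out


def replicate_filter(matrix: ExpressionMatrix, min_replicates: int = 2) -> ExpressionMatrix:
    """Keep features detected (nonzero) in >= min_replicates replicates of at
    least one condition."""
    reps = {c: len(matrix.samples_of(c)) for c in matrix.conditions}
    if min_replicates > max(reps.values()):
        raise ValueError(
            f"min_replicates={min_replicates} exceeds available replicates {reps}"
        )
    keep = pd.Series(False, index=matrix.counts.index)
    for cond in matrix.conditions:
        cols = matrix.samples_of(cond)
        keep |= (matrix.counts[cols] > 0).sum(axis=1) >= min_replicates
    return ExpressionMatrix(
        counts=matrix.counts.loc[keep], design=matrix.design, kind=matrix.kind
    )


def categorize_expression(value, kind: str = "circRNA"):
    """Five-level abundance category (1..5) over half-open bins [lo, hi).

    circRNA levels: 0-0.5, 0.5-1, 1-5, 5-10, >10 (RPM);
    host-gene levels: 0-50, 50-100, 100-500, 500-2000, >2000.
    """
    edges = {"circRNA": CIRC_LEVELS, "host_gene": HOST_GENE_LEVELS}.get(kind)
    if edges is None:
        raise ValueError(f"unknown kind {kind!r}")
    v = np.asarray(value, dtype=float)
    if (v < 0).any():
        raise ValueError("expression values must be >= 0")
    level = np.digitize(v, edges[1:], right=False) + 1
    return int(level) if level.ndim == 0 else level


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """DESeq-style median-of-ratios size factors; falls back to library-size
    ratios when no feature is expressed in every sample."""
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if positive.sum() >= 1:
        log_ref = np.log(arr[positive]).mean(axis=1, keepdims=True)
        sf = np.exp(np.median(np.log(arr[positive]) - log_ref, axis=0))
    else:
        lib = arr.sum(axis=0)
        if (lib <= 0).any():
            raise ValueError("sample with all-zero library")
        sf = lib / np.exp(np.mean(np.log(lib)))
    return pd.Series(sf, index=counts.columns)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_test(
    matrix: ExpressionMatrix,
    condition_a: str,
    condition_b: str,
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
    dispersion_floor: float = 0.01,
    use_adjusted: bool = True,
) -> pd.DataFrame:
    """NB two-group Wald test of condition_b vs condition_a.

    Fold change is (mean_B + c) / (mean_A + c) on size-factor-normalised
    means with pseudocount c; ``direction`` follows the sign of log2FC.
    Returns one row per feature with columns feature, comparison, log2FC,
    FC, p, padj, is_DE, direction.
    """
    cols_a = matrix.samples_of(condition_a)
    cols_b = matrix.samples_of(condition_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need >= 2 replicates in both conditions")
    sub = matrix.counts[cols_a + cols_b]
    if (sub[cols_a].sum().sum() == 0) or (sub[cols_b].sum().sum() == 0):
        raise ValueError("a condition has an all-zero library")
    sf = size_factors(sub)
    norm = sub / sf
    a = norm[cols_a].to_numpy(dtype=float)
    b = norm[cols_b].to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    # pooled method-of-moments dispersion: var = m + alpha m^2, shrunk
    # toward the across-feature median (equal prior weight), floored
    nu = float(na + nb - 2)
    prior_df = 4.0
    num = (na - 1) * (va - ma) + (nb - 1) * (vb - mb)
    den = (na - 1) * ma**2 + (nb - 1) * mb**2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_raw = np.where(den > 0, np.maximum(num / den, 0.0), 0.0)
    alpha_med = float(np.median(alpha_raw))
    alpha_hat = np.maximum(
        (nu * alpha_raw + prior_df * alpha_med) / (nu + prior_df), dispersion_floor
    )
    c = pseudocount
    log2fc = np.log2(mb + c) - np.log2(ma + c)
    phi_a = ma + alpha_hat * ma**2
    phi_b = mb + alpha_hat * mb**2
    ln2_sq = math.log(2.0) ** 2
    sa = phi_a / (na * (ma + c) ** 2)
    sb = phi_b / (nb * (mb + c) ** 2)
    se = np.sqrt(np.maximum((sa + sb) / ln2_sq, 1e-300))
    stat = log2fc / se
    # Satterthwaite-type effective df: only the dispersion component of the
    # variance carries estimation noise (the Poisson part is structural), so
    # the reference gets heavier tails exactly where alpha*m dominates.  The
    # shrunk estimator is charged nu + prior_df/2 base df.
    u = alpha_hat * (ma**2 / (na * (ma + c) ** 2) + mb**2 / (nb * (mb + c) ** 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        df = (nu + prior_df / 2.0) * (sa + sb) ** 2 / np.maximum(u, 1e-300) ** 2
    df = np.clip(df, nu, 1e6)
    p_raw = 2.0 * stats.t.sf(np.abs(stat), df)
    # identical groups (zero variance, zero difference) are exactly null
    p_raw = np.where((log2fc == 0), 1.0, p_raw)
    p_raw = np.clip(p_raw, 0.0, 1.0)
    p_adj = bh_adjust(p_raw)
    fc = 2.0 ** log2fc
    gate_p = p_adj if use_adjusted else p_raw
    is_de = ((fc > fc_threshold) | (fc < 1.0 / fc_threshold)) & (gate_p < alpha)
    out = pd.DataFrame(
        {
            "feature": sub.index,
            "comparison": f"{condition_a} vs {condition_b}",
            "log2FC": log2fc,
            "FC": fc,
            "p": p_raw,
            "padj": p_adj,
            "is_DE": is_de,
            "direction": np.where(log2fc >= 0, "up", "down"),
        }
    ).reset_index(drop=True)
    return out


def de_all_comparisons(
    matrix: ExpressionMatrix,
    comparisons: list[tuple[str, str]] | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Run de_test over a list of (A, B) condition pairs (default: all
    ordered pairs in condition order)."""
    conds = matrix.conditions
    if comparisons is None:
        comparisons = [
            (conds[i], conds[j])
            for i in range(len(conds))
            for j in range(i + 1, len(conds))
        ]
    frames = [de_test(matrix, a, b, **kwargs) for a, b in comparisons]
    return pd.concat(frames, ignore_index=True)
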