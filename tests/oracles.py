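"""Independent reference implementations used only to check the package.

Each oracle recomputes a quantity by direct enumeration or closed-form
arithmetic, sharing no code path with the implementation under test.
"""

from __future__ import annotations

import math

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def rc(seq: str) -> str:
    return "".join(COMP[b] for b in reversed(seq))


def find_all(hay: str, needle: str) -> list[int]:
    """1-based occurrence starts."""
    out, i = [], hay.find(needle)
    while i != -1:
        out.append(i + 1)
        i = hay.find(needle, i + 1)
    return out


def signal_ok(chrom_seq: str, start: int, end: int, strand: str) -> bool:
    if start < 3 or end + 2 > len(chrom_seq):
        return False
    up = chrom_seq[start - 3 : start - 1]
    down = chrom_seq[end : end + 2]
    return (up, down) == (("AG", "GT") if strand == "+" else ("AC", "CT"))


def brute_force_backsplice(
    read: str,
    genome: dict[str, str],
    require_signal: bool = True,
    max_span: int = 100_000,
    min_flank: int = 20,
) -> tuple[str, int, int, str] | None:
    """Try every split point of the read against every genomic occurrence.

    A split (prefix|suffix) supports a back-splice if the prefix (circle
    tail, ending at the donor) maps downstream of the suffix (circle head,
    starting at the acceptor).  Only splits leaving >= min_flank bases on
    each side are considered — the junction-read contract guarantees that
    much context, and shorter arms are unmappable in any aligner.  Frames
    are tried '+' first then '-', and the leftmost donor wins, mirroring
    the detector's documented tie-break.
    """
    L = len(read)
    for strand, seq in (("+", read), ("-", rc(read))):
        candidates = []
        for chrom, g in genome.items():
            for s in range(min_flank, L - min_flank + 1):
                prefix, suffix = seq[:s], seq[s:]
                for p_pre in find_all(g, prefix):
                    end = p_pre + s - 1
                    for p_suf in find_all(g, suffix):
                        start = p_suf
                        if start >= end:
                            continue
                        if end - start + 1 > max_span:
                            continue
                        if require_signal and not signal_ok(g, start, end, strand):
                            continue
                        candidates.append((end, start, chrom))
        if candidates:
            end, start, chrom = min(candidates)
            return (chrom, start, end, strand)
    return None


# --- duplex alignment -------------------------------------------------------

WC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
WOBBLE = {("T", "G"), ("G", "T")}  # (miRNA, target): U:G and G:U


def _pair_penalty(m: str, t: str, params) -> float:
    if (m, t) in WC:
        return 0.0
    if (m, t) in WOBBLE:
        return params.gu_wobble_penalty
    return params.mismatch_penalty


def _mult(pos: int, m_len: int, params) -> float:
    pos = min(pos, m_len)
    if params.seed_start <= pos <= params.seed_end:
        return params.seed_multiplier
    return 1.0


def enumerate_duplex(mirna: str, window: str, params) -> float:
    """Minimum penalty over *all* global alignments (recursion, no DP reuse)."""
    wrev = window[::-1]
    m_len = len(mirna)

    def go(i: int, j: int, gaps: int) -> float:
        if i == m_len and j == len(wrev):
            return 0.0
        best = math.inf
        if i < m_len and j < len(wrev):
            best = min(
                best,
                _pair_penalty(mirna[i], wrev[j], params) * _mult(i + 1, m_len, params)
                + go(i + 1, j + 1, gaps),
            )
        if gaps < params.max_gaps:
            if i < m_len:
                best = min(
                    best,
                    params.gap_penalty * _mult(i + 1, m_len, params)
                    + go(i + 1, j, gaps + 1),
                )
            if j < len(wrev):
                best = min(
                    best,
                    params.gap_penalty * _mult(i + 1, m_len, params)
                    + go(i, j + 1, gaps + 1),
                )
        return best

    return go(0, 0, 0)


def enumerate_best_site(mirna: str, target: str, circular: bool, params) -> float:
    """Best penalty over every window of every admissible length."""
    L, m = len(target), len(mirna)
    ext = target + target[: m + params.max_gaps - 1] if circular else target
    best = math.inf
    n_starts = L if circular else L
    for w in range(max(m - params.max_gaps, 1), m + params.max_gaps + 1):
        for s in range(n_starts):
            if s + w > len(ext):
                continue
            if not circular and s + w > L:
                continue
            best = min(best, enumerate_duplex(mirna, ext[s : s + w], params))
    return best


# --- statistics -------------------------------------------------------------


def bh_stepup(p: list[float]) -> list[float]:
    """Textbook BH step-up: p_adj(i) = min_{j >= i} min(1, m * p_(j) / j)."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        adj[i] = running
    return adj


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) by exact enumeration of the hypergeometric pmf."""
    total = math.comb(N, n)
    acc = 0
    for i in range(k, min(K, n) + 1):
        if n - i > N - K:
            continue
        acc += math.comb(K, i) * math.comb(N - K, n - i)
    return acc / total


def pearson_direct(x: list[float], y: list[float]) -> tuple[float, float]:
    """r by the direct product-moment formula; two-sided p via the
    regularised incomplete beta identity for the t distribution."""
    from scipy.special import betainc

    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    r = sxy / math.sqrt(sxx * syy)
    df = n - 2
    t2 = r * r * df / (1 - r * r) if abs(r) < 1 else math.inf
    p = betainc(df / 2.0, 0.5, df / (df + t2)) if math.isfinite(t2) else 0.0
    return r, p
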