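"""Plant-style miRNA binding-site prediction on linear and circular targets.

A site is scored by a position-weighted duplex penalty (lower is better)
over the antiparallel miRNA:target duplex:

* Watson-Crick pair: 0
* G:U wobble (target G with miRNA U, or target U with miRNA G): 0.5
* mismatch: 1
* each gapped (unpaired) base: 1
* any penalty incurred at miRNA positions 2-13 (5' seed-proximal region)
  is doubled

The optimal gapped alignment of the full miRNA against a candidate target
window is found by dynamic programming with a cap on total gapped bases;
windows scoring at or below the cutoff (default 4.0) become candidate
sites, resolved to a non-overlapping set greedily by ascending penalty.
Circular targets are scanned across the back-splice junction by extending
the sequence with its own head, and junction-spanning sites are reported
with wrapped coordinates.

Sequences are DNA-alphabet (T for U); wobble is defined on the RNA sense.
The sliding scan is JIT-compiled with numba when available and falls back
to the pure-Python scorer otherwise; both produce identical penalties
(all scores are exact multiples of 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_GAP_STATES = 8  # upper bound on max_gaps supported by the compiled kernel


@dataclass(frozen=True)
class ScoringParams:
    mismatch_penalty: float = 1.0
    gu_wobble_penalty: float = 0.5
    gap_penalty: float = 1.0
    seed_start: int = 2  # 1-based miRNA positions with doubled penalty
    seed_end: int = 13
    seed_multiplier: float = 2.0
    max_gaps: int = 1
    cutoff: float = 4.0

    def __post_init__(self) -> None:
        if min(self.mismatch_penalty, self.gu_wobble_penalty, self.gap_penalty) < 0:
            raise ValueError("penalties must be >= 0")
        if not 1 <= self.seed_start <= self.seed_end:
            raise ValueError("invalid seed range")
        if not 0 <= self.max_gaps < _GAP_STATES:
            raise ValueError(f"max_gaps must be in [0, {_GAP_STATES - 1}]")


@dataclass
class BindingSite:
    mirna: str
    target: str
    target_kind: str  # circRNA | mRNA
    start: int  # 1-based on the target
    end: int  # 1-based; < start only when the site wraps the junction
    penalty: float
    duplex: tuple[str, str, str]  # miRNA 5'->3', match line, target 3'->5'
    spans_junction: bool = False


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_CODE[b] for b in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"non-ACGT base {exc} in sequence") from exc


def _pair_cost_matrix(params: ScoringParams) -> np.ndarray:
    cost = np.full((4, 4), params.mismatch_penalty)
    for a, b in (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")):
        cost[_CODE[a], _CODE[b]] = 0.0
    # wobble: miRNA U(T) : target G and miRNA G : target U(T)
    cost[_CODE["T"], _CODE["G"]] = params.gu_wobble_penalty
    cost[_CODE["G"], _CODE["T"]] = params.gu_wobble_penalty
    return cost


def _multipliers(m: int, params: ScoringParams) -> np.ndarray:
    mult = np.ones(m + 1)
    lo = max(params.seed_start, 1)
    hi = min(params.seed_end, m)
    mult[lo : hi + 1] = params.seed_multiplier
    return mult  # index by 1-based miRNA position; mult[0] unused


def score_duplex(
    mirna: str, target_window: str, params: ScoringParams | None = None
) -> tuple[float, tuple[str, str, str]]:
    """Optimal penalty and alignment of a miRNA against one target window.

    The window is given 5'->3' on the target; the duplex pairs the miRNA
    5'->3' against the window read 3'->5' (antiparallel).  Ties resolve to
    the alignment with fewest gaps, then by a fixed traceback preference
    (pair over target bulge over miRNA gap).
    """
    params = params or ScoringParams()
    if not mirna or not target_window:
        raise ValueError("empty sequence")
    m_codes = _encode(mirna.upper())
    w_codes = _encode(target_window.upper())[::-1]  # 3'->5'
    m, w = len(m_codes), len(w_codes)
    if abs(m - w) > params.max_gaps:
        raise ValueError("window length outside miRNA length +/- max_gaps")
    cost = _pair_cost_matrix(params)
    mult = _multipliers(m, params)
    gmax = params.max_gaps
    inf = float("inf")
    dp = np.full((m + 1, w + 1, gmax + 1), inf)
    dp[0, 0, 0] = 0.0
    for i in range(m + 1):
        for j in range(w + 1):
            for g in range(gmax + 1):
                cur = dp[i, j, g]
                if cur == inf:
                    continue
                if i < m and j < w:
                    v = cur + cost[m_codes[i], w_codes[j]] * mult[i + 1]
                    if v < dp[i + 1, j + 1, g]:
                        dp[i + 1, j + 1, g] = v
                if g < gmax:
                    if i < m:  # miRNA base unpaired
                        v = cur + params.gap_penalty * mult[i + 1]
                        if v < dp[i + 1, j, g + 1]:
                            dp[i + 1, j, g + 1] = v
                    if j < w:  # target bulge, charged at the next miRNA position
                        v = cur + params.gap_penalty * mult[min(i + 1, m)]
                        if v < dp[i, j + 1, g + 1]:
                            dp[i, j + 1, g + 1] = v
    best_g = int(np.argmin(dp[m, w]))  # fewest gaps on ties (argmin is first)
    penalty = float(dp[m, w, best_g])
    duplex = _traceback(m_codes, w_codes, dp, best_g, cost, mult, params, mirna, target_window)
    return penalty, duplex


def _traceback(m_codes, w_codes, dp, g_final, cost, mult, params, mirna, window):
    m, w = len(m_codes), len(w_codes)
    i, j, g = m, w, g_final
    cols: list[tuple[str, str]] = []
    wrev = window[::-1]
    while i > 0 or j > 0:
        cur = dp[i, j, g]
        if i > 0 and j > 0 and dp[i - 1, j - 1, g] + cost[m_codes[i - 1], w_codes[j - 1]] * mult[i] == cur:
            cols.append((mirna[i - 1], wrev[j - 1]))
            i, j = i - 1, j - 1
        elif g > 0 and j > 0 and dp[i, j - 1, g - 1] + params.gap_penalty * mult[min(i + 1, m)] == cur:
            cols.append(("-", wrev[j - 1]))
            j, g = j - 1, g - 1
        elif g > 0 and i > 0 and dp[i - 1, j, g - 1] + params.gap_penalty * mult[i] == cur:
            cols.append((mirna[i - 1], "-"))
            i, g = i - 1, g - 1
        else:  # numerical safety; cannot occur with exact half-integer scores
            raise AssertionError("traceback failed")
    cols.reverse()
    top = "".join(a for a, _ in cols)
    bottom = "".join(b for _, b in cols)
    wc = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
    wobble = {("T", "G"), ("G", "T")}
    match = "".join(
        "|" if (a, b) in wc else "o" if (a, b) in wobble else " "
        for a, b in cols
    )
    return top, match, bottom


def _best_penalty_python(m_codes, w_codes, cost, mult, gap_penalty, gmax) -> float:
    m, w = len(m_codes), len(w_codes)
    inf = float("inf")
    dp = np.full((m + 1, w + 1, gmax + 1), inf)
    dp[0, 0, 0] = 0.0
    for i in range(m + 1):
        for j in range(w + 1):
            for g in range(gmax + 1):
                cur = dp[i, j, g]
                if cur == inf:
                    continue
                if i < m and j < w:
                    v = cur + cost[m_codes[i], w_codes[j]] * mult[i + 1]
                    if v < dp[i + 1, j + 1, g]:
                        dp[i + 1, j + 1, g] = v
                if g < gmax:
                    if i < m:
                        v = cur + gap_penalty * mult[i + 1]
                        if v < dp[i + 1, j, g + 1]:
                            dp[i + 1, j, g + 1] = v
                    if j < w:
                        v = cur + gap_penalty * mult[min(i + 1, m)]
                        if v < dp[i, j + 1, g + 1]:
                            dp[i, j + 1, g + 1] = v
    return float(dp[m, w].min())


def _make_scan_kernel():
    try:
        from numba import njit
    except ImportError:  # pragma: no cover - numba is a hard dependency
        return None

    @njit(cache=False)
    def kernel(t_codes, m_codes, cost, mult, gap_penalty, gmax, wlens, n_starts):
        m = m_codes.shape[0]
        w_max = m + gmax
        out = np.full((n_starts, wlens.shape[0]), np.inf)
        dp = np.empty((m + 1, w_max + 1, gmax + 1))
        L = t_codes.shape[0]
        for s in range(n_starts):
            for wi in range(wlens.shape[0]):
                w = wlens[wi]
                if s + w > L:
                    continue
                dp[: m + 1, : w + 1, : gmax + 1] = np.inf
                dp[0, 0, 0] = 0.0
                for i in range(m + 1):
                    for j in range(w + 1):
                        for g in range(gmax + 1):
                            cur = dp[i, j, g]
                            if cur == np.inf:
                                continue
                            if i < m and j < w:
                                # window read 3'->5': j-th duplex base is
                                # target position s + w - 1 - j
                                v = cur + cost[m_codes[i], t_codes[s + w - 1 - j]] * mult[i + 1]
                                if v < dp[i + 1, j + 1, g]:
                                    dp[i + 1, j + 1, g] = v
                            if g < gmax:
                                if i < m:
                                    v = cur + gap_penalty * mult[i + 1]
                                    if v < dp[i + 1, j, g + 1]:
                                        dp[i + 1, j, g + 1] = v
                                if j < w:
                                    ip = i + 1
                                    if ip > m:
                                        ip = m
                                    v = cur + gap_penalty * mult[ip]
                                    if v < dp[i, j + 1, g + 1]:
                                        dp[i, j + 1, g + 1] = v
                best = np.inf
                for g in range(gmax + 1):
                    if dp[m, w, g] < best:
                        best = dp[m, w, g]
                out[s, wi] = best
        return out

    return kernel


_SCAN_KERNEL = _make_scan_kernel()


def _scan_penalties(
    t_codes: np.ndarray,
    m_codes: np.ndarray,
    params: ScoringParams,
    wlens: np.ndarray,
    n_starts: int,
) -> np.ndarray:
    cost = _pair_cost_matrix(params)
    mult = _multipliers(len(m_codes), params)
    if _SCAN_KERNEL is not None:
        return _SCAN_KERNEL(
            t_codes.astype(np.int64),
            m_codes.astype(np.int64),
            cost,
            mult,
            params.gap_penalty,
            params.max_gaps,
            wlens.astype(np.int64),
            n_starts,
        )
    out = np.full((n_starts, len(wlens)), np.inf)
    for s in range(n_starts):
        for wi, w in enumerate(wlens):
            if s + w > len(t_codes):
                continue
            out[s, wi] = _best_penalty_python(
                m_codes,
                t_codes[s : s + w][::-1],
                cost,
                mult,
                params.gap_penalty,
                params.max_gaps,
            )
    return out


def scan_target(
    mirna_id: str,
    mirna_seq: str,
    target_id: str,
    target_seq: str,
    circular: bool = False,
    params: ScoringParams | None = None,
    target_kind: str | None = None,
) -> list[BindingSite]:
    """All non-overlapping binding sites of one miRNA on one target.

    For circular targets the sequence is extended by its own head so windows
    may straddle the back-splice junction; junction-spanning sites report
    wrapped coordinates and ``spans_junction=True``.  Candidate windows with
    penalty <= cutoff are resolved greedily by (penalty, position).
    """
    params = params or ScoringParams()
    mirna_seq = mirna_seq.upper().replace("U", "T")
    target_seq = target_seq.upper().replace("U", "T")
    L = len(target_seq)
    m = len(mirna_seq)
    if L < m:
        raise ValueError("target shorter than miRNA")
    if target_kind is None:
        target_kind = "circRNA" if circular else "mRNA"
    wlens = np.array(
        [w for w in range(m - params.max_gaps, m + params.max_gaps + 1) if w >= 1]
    )
    if circular:
        ext = target_seq + target_seq[: int(wlens.max()) - 1]
        n_starts = L
    else:
        ext = target_seq
        n_starts = L - int(wlens.min()) + 1
    t_codes = _encode(ext)
    pen = _scan_penalties(t_codes, _encode(mirna_seq), params, wlens, n_starts)
    cand = []
    for s, wi in zip(*np.nonzero(pen <= params.cutoff)):
        cand.append((float(pen[s, wi]), int(s), int(wlens[wi])))
    cand.sort()
    chosen: list[tuple[float, int, int]] = []
    occupied: set[int] = set()
    for penalty, s, w in cand:
        span = {(s + k) % L for k in range(w)} if circular else set(range(s, s + w))
        if span & occupied:
            continue
        occupied |= span
        chosen.append((penalty, s, w))
    sites = []
    for penalty, s, w in chosen:
        window = ext[s : s + w]
        p2, duplex = score_duplex(mirna_seq, window, params)
        wraps = circular and (s + w) > L
        site = BindingSite(
            mirna=mirna_id,
            target=target_id,
            target_kind=target_kind,
            start=s + 1,
            end=((s + w - 1) % L) + 1 if circular else s + w,
            penalty=penalty if penalty == p2 else p2,
            duplex=duplex,
            spans_junction=wraps,
        )
        sites.append(site)
    sites.sort(key=lambda x: (x.penalty, x.start))
    return sites


def scan_all(
    mirnas: dict[str, str],
    targets: dict[str, str],
    circular: bool = False,
    params: ScoringParams | None = None,
    target_kind: str | None = None,
) -> list[BindingSite]:
    """Scan every miRNA against every target; deterministic ordering."""
    sites: list[BindingSite] = []
    for mid in sorted(mirnas):
        for tid in sorted(targets):
            sites.extend(
                scan_target(
                    mid, mirnas[mid], tid, targets[tid], circular, params, target_kind
                )
            )
    return sites


def interaction_table(sites: Sequence[BindingSite]) -> pd.DataFrame:
    """One row per (miRNA, target) pair with >= 1 site."""
    if not sites:
        return pd.DataFrame(
            columns=["mirna", "target", "kind", "n_sites", "best_penalty"]
        )
    df = pd.DataFrame(
        {
            "mirna": [s.mirna for s in sites],
            "target": [s.target for s in sites],
            "kind": [s.target_kind for s in sites],
            "penalty": [s.penalty for s in sites],
        }
    )
    out = (
        df.groupby(["mirna", "target", "kind"], as_index=False)
        .agg(n_sites=("penalty", "size"), best_penalty=("penalty", "min"))
        .sort_values(["mirna", "target"], ignore_index=True)
    )
    return out


def sites_to_frame(sites: Sequence[BindingSite]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mirna": [s.mirna for s in sites],
            "target": [s.target for s in sites],
            "kind": [s.target_kind for s in sites],
            "start": [s.start for s in sites],
            "end": [s.end for s in sites],
            "penalty": [s.penalty for s in sites],
            "spans_junction": [s.spans_junction for s in sites],
            "duplex": ["/".join(s.duplex) for s in sites],
        },
        columns=["mirna", "target", "kind", "start", "end", "penalty", "spans_junction", "duplex"],
    )
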