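"""PWM motif scanning and Fisher-exact enrichment (motifs and gene sets).

A position frequency matrix is converted to a log2-odds weight matrix against
a background base composition; sequences are scanned on both strands and a
hit is called when the score reaches ``min + threshold_fraction *
(max - min)`` of the PWM's attainable score range.  Enrichment of motif hits
in foreground versus background windows, and of a query gene list in GMT
gene sets, uses one-sided Fisher's exact tests with Benjamini-Hochberg
correction at an adjusted-p threshold of 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSetCollection, MotifPFM
from .preprocess import one_hot

__all__ = [
    "PWMScanHit",
    "EnrichmentResult",
    "pwm_logodds",
    "scan",
    "motif_enrichment",
    "geneset_enrichment",
]

SIGNIFICANCE = 0.05


@dataclass(frozen=True)
class PWMScanHit:
    sequence_id: str
    offset: int  # 0-based offset of the match on the forward sequence
    strand: str
    score: float


@dataclass(frozen=True)
class EnrichmentResult:
    """One motif or gene set with its 2x2 table, odds ratio and (adjusted) p."""

    unit_id: str
    a: int  # foreground / query with the property
    b: int  # foreground / query without
    c: int  # background / rest with
    d: int  # background / rest without
    odds_ratio: float
    p_value: float
    p_adjusted: float = np.nan

    @property
    def significant(self) -> bool:
        return self.p_adjusted < SIGNIFICANCE


def pwm_logodds(pfm: MotifPFM, pseudocount: float = 0.5,
                background: np.ndarray | None = None) -> np.ndarray:
    """log2((count + pc) / (colsum + 4 pc) / background), a 4 x w matrix."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive (zero counts would give -inf)")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    if bg.shape != (4,) or np.any(bg <= 0):
        raise ValueError("background must be 4 positive frequencies")
    counts = pfm.counts
    freqs = (counts + pseudocount) / (counts.sum(axis=0) + 4 * pseudocount)
    return np.log2(freqs / bg[:, None])


def _revcomp_pwm(pwm: np.ndarray) -> np.ndarray:
    # reverse columns, swap A<->T and C<->G rows
    return pwm[::-1, ::-1]


def _scan_scores(onehot: np.ndarray, pwm: np.ndarray) -> np.ndarray:
    """Score of the PWM at every offset of a one-hot sequence (L-w+1 values)."""
    L, w = onehot.shape[0], pwm.shape[1]
    if L < w:
        return np.empty(0)
    # correlate each base row with the PWM row, then sum over offsets
    per_base = onehot @ pwm  # (L, w): contribution of base at position i to motif column j
    n = L - w + 1
    out = np.zeros(n)
    for j in range(w):
        out += per_base[j : j + n, j]
    return out


def scan(sequence: str, pfm: MotifPFM, threshold_fraction: float = 0.8,
         sequence_id: str = "", pseudocount: float = 0.5) -> list[PWMScanHit]:
    """Both-strand log-odds scan; hits score >= min + fraction * (max - min)."""
    if not 0.0 < threshold_fraction <= 1.0:
        raise ValueError("threshold_fraction must be in (0, 1]")
    pwm = pwm_logodds(pfm, pseudocount=pseudocount)
    lo = float(pwm.min(axis=0).sum())
    hi = float(pwm.max(axis=0).sum())
    threshold = lo + threshold_fraction * (hi - lo)
    onehot = one_hot(sequence)
    hits: list[PWMScanHit] = []
    for strand, mat in (("+", pwm), ("-", _revcomp_pwm(pwm))):
        scores = _scan_scores(onehot, mat)
        for off in np.flatnonzero(scores >= threshold - 1e-12):
            hits.append(PWMScanHit(sequence_id, int(off), strand, float(scores[off])))
    return sorted(hits, key=lambda h: (h.offset, h.strand))


def _fisher_greater(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    res = stats.fisher_exact(np.array([[a, b], [c, d]]), alternative="greater")
    num, den = a * d, b * c
    if den == 0:
        odds = np.inf if num > 0 else 1.0  # degenerate all-or-nothing margins
    else:
        odds = num / den
    return float(res.pvalue), float(odds)


def _bh_adjust(results: list[EnrichmentResult]) -> list[EnrichmentResult]:
    if not results:
        return results
    pvals = [r.p_value for r in results]
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    adjusted = [
        EnrichmentResult(r.unit_id, r.a, r.b, r.c, r.d, r.odds_ratio, r.p_value, float(q))
        for r, q in zip(results, p_adj)
    ]
    return sorted(adjusted, key=lambda r: (r.p_value, r.unit_id))


def motif_enrichment(
    foreground: list[str],
    background: list[str],
    motifs: list[MotifPFM],
    threshold_fraction: float = 0.8,
) -> list[EnrichmentResult]:
    """Per motif: has-hit vs no-hit in foreground vs background windows.

    One-sided (enrichment-only) Fisher test per motif, BH-adjusted across
    motifs.
    """
    if not foreground or not background:
        raise ValueError("foreground and background window sets must be non-empty")
    results = []
    for pfm in motifs:
        fg_hits = sum(bool(scan(s, pfm, threshold_fraction)) for s in foreground)
        bg_hits = sum(bool(scan(s, pfm, threshold_fraction)) for s in background)
        a, b = fg_hits, len(foreground) - fg_hits
        c, d = bg_hits, len(background) - bg_hits
        p, orat = _fisher_greater(a, b, c, d)
        results.append(EnrichmentResult(pfm.motif_id, a, b, c, d, orat, p))
    return _bh_adjust(results)


def geneset_enrichment(
    query: set[str],
    collection: GeneSetCollection,
    universe: set[str],
) -> list[EnrichmentResult]:
    """Over-representation of ``query`` in each gene set over ``universe``."""
    if not universe:
        raise ValueError("universe must be non-empty")
    query = {q.upper() for q in query}
    universe = {u.upper() for u in universe}
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    results = []
    for name, members in collection:
        members = members & universe
        a = len(query & members)
        b = len(query) - a
        c = len(members) - a
        d = len(universe) - len(query) - c
        p, orat = _fisher_greater(a, b, c, d)
        results.append(EnrichmentResult(name, a, b, c, d, orat, p))
    return _bh_adjust(results)
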