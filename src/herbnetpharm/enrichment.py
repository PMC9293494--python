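"""Over-representation analysis and the qPCR fold-change statistic.

Enrichment of a query gene set against an annotation collection uses the
hypergeometric upper tail (optionally the conservative EASE variant that
discounts one overlapping gene, as the DAVID service does), with
Benjamini-Hochberg adjustment available. Selection mirrors the usual
reporting convention: raw p < 0.05 (strict), then the top-k terms.

The qPCR arm quantifies relative expression with the 2^-ddCt method:
delta Ct = Ct(target) - Ct(reference), delta-delta Ct = treated minus
control, fold change = 2 ** (-ddCt).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from statistics import fmean
from typing import Sequence

from scipy.special import gammaln
from scipy.stats import false_discovery_control

from .errors import ValidationError
from .io import AnnotationCollection

__all__ = [
    "EnrichmentResult",
    "DdctMeasurement",
    "hypergeometric_tail",
    "enrich_gene_set",
    "adjust_pvalues",
    "select_top_terms",
    "ddct_fold_change",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's over-representation outcome.

    k: overlap size; n: effective query size; K: term size; M: universe
    size; enrichment_ratio = (k/n) / (K/M).
    """

    term_id: str
    description: str
    k: int
    n: int
    K: int
    M: int
    p_raw: float
    p_adj: float
    enrichment_ratio: float


def _log_binom(n: float, k: float) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeometric_tail(k: int, n: int, K: int, M: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(M, K, n), summed in log space.

    k successes observed in a sample of n, from a universe of M with K
    marked elements. ``k = 0`` returns exactly 1.
    """
    if not (0 <= k <= min(n, K)):
        raise ValidationError(f"need 0 <= k <= min(n, K); got k={k}, n={n}, K={K}")
    if not (0 <= n <= M and 0 <= K <= M):
        raise ValidationError(f"need n <= M and K <= M; got n={n}, K={K}, M={M}")
    if k == 0:
        return 1.0
    log_denom = _log_binom(M, n)
    log_terms = [
        _log_binom(K, i) + _log_binom(M - K, n - i) - log_denom
        for i in range(k, min(n, K) + 1)
    ]
    peak = max(log_terms)
    total = peak + math.log(sum(math.exp(t - peak) for t in log_terms))
    return min(1.0, math.exp(total))


def adjust_pvalues(p: Sequence[float], method: str = "bh") -> list[float]:
    """Multiple-testing adjustment; ``bh`` (Benjamini-Hochberg) or ``none``.

    BH returns step-up adjusted values clipped at 1, in input order.
    """
    p = list(p)
    if any(not 0 <= x <= 1 for x in p):
        raise ValidationError("p-values must lie in [0, 1]")
    if method == "none":
        return p
    if method == "bh":
        if not p:
            return []
        return [float(x) for x in false_discovery_control(p, method="bh")]
    raise ValidationError(f"unknown adjustment method {method!r}")


def enrich_gene_set(
    query: set[str],
    annotations: AnnotationCollection,
    universe_mode: str = "annotated-union",
    ease: bool = False,
    adjust: str = "bh",
) -> list[EnrichmentResult]:
    """Test each annotation term for over-representation in ``query``.

    The universe is either the union of all annotated genes
    (``annotated-union``, the default) or the collection's explicit
    background (``explicit``). Query genes outside the universe are
    dropped before testing. Terms with no overlap are omitted. With
    ``ease=True`` the tail is evaluated at ``max(k - 1, 0)`` — DAVID's
    EASE score, conservative by one gene. Results are sorted by raw
    p-value, ties by term id.
    """
    if universe_mode == "explicit":
        if annotations.universe is None:
            raise ValidationError("collection has no explicit universe")
        universe = set(annotations.universe)
    elif universe_mode == "annotated-union":
        universe = annotations.annotated_genes()
    else:
        raise ValidationError(f"unknown universe_mode {universe_mode!r}")

    effective = set(query) & universe
    if not effective:
        raise ValidationError("query has no genes in the universe")

    n, M = len(effective), len(universe)
    rows: list[tuple[str, str, int, int]] = []
    for tid in sorted(annotations.terms):
        desc, genes = annotations.terms[tid]
        term_genes = genes & universe
        k = len(effective & term_genes)
        if k >= 1:
            rows.append((tid, desc, k, len(term_genes)))

    raw = [
        hypergeometric_tail(max(k - 1, 0) if ease else k, n, K, M)
        for (_, _, k, K) in rows
    ]
    adj = adjust_pvalues(raw, method=adjust)
    results = [
        EnrichmentResult(
            term_id=tid,
            description=desc,
            k=k,
            n=n,
            K=K,
            M=M,
            p_raw=p,
            p_adj=pa,
            enrichment_ratio=(k / n) / (K / M),
        )
        for (tid, desc, k, K), p, pa in zip(rows, raw, adj)
    ]
    results.sort(key=lambda r: (r.p_raw, r.term_id))
    return results


def select_top_terms(
    results: list[EnrichmentResult], alpha: float = 0.05, top_k: int | None = None
) -> list[EnrichmentResult]:
    """Keep terms with raw p strictly below ``alpha``, then the best
    ``top_k`` by raw p-value (ties by term id)."""
    kept = sorted(
        (r for r in results if r.p_raw < alpha), key=lambda r: (r.p_raw, r.term_id)
    )
    return kept if top_k is None else kept[:top_k]


# ---------------------------------------------------------------------------
# qPCR relative quantification
# ---------------------------------------------------------------------------

_Ct = float | Sequence[float]


def _mean_ct(value: _Ct) -> float:
    if isinstance(value, (int, float)):
        return float(value)
    return fmean(value)


@dataclass(frozen=True)
class DdctMeasurement:
    """Cycle thresholds for one target/reference pair, treated vs control.

    Each field is a single Ct or a sequence of replicate Cts (averaged).
    """

    ct_target_treated: _Ct
    ct_ref_treated: _Ct
    ct_target_control: _Ct
    ct_ref_control: _Ct


def ddct_fold_change(m: DdctMeasurement) -> float:
    """Relative expression fold change, 2^-ddCt."""
    dct_treated = _mean_ct(m.ct_target_treated) - _mean_ct(m.ct_ref_treated)
    dct_control = _mean_ct(m.ct_target_control) - _mean_ct(m.ct_ref_control)
    return 2.0 ** -(dct_treated - dct_control)
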