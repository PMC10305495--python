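"""Term-for-term over-representation statistics.

Each annotation term is tested individually: given a study set of n genes
drawn from a background of N genes of which K carry the term, the p-value
is the upper tail P(X ≥ k) of the hypergeometric distribution — identical
to the one-sided (greater) Fisher exact test on the corresponding 2×2
table.  Multiple testing across all tested terms is corrected with the
Benjamini–Hochberg step-up rule; fold enrichment is the ratio of study and
background hit rates, (k/n)/(K/N).

Annotations are used as given: there is no ontology-graph propagation
(ancestor closure is an input-preparation concern, not a testing one).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .exceptions import DomainError, UsageError
from .io_core import AnnotationTable


@dataclass(frozen=True)
class EnrichmentResult:
    """One tested term: counts, fold enrichment, raw p, BH-adjusted q."""

    term: str
    label: str
    k: int
    n: int
    K: int
    N: int
    fold_enrichment: float
    p: float
    q: float
    displayed: bool  # q < alpha for the run's significance threshold


def _check_bounds(k: int, n: int, K: int, N: int) -> None:
    if N <= 0:
        raise DomainError(f"background size N must be positive, got {N}")
    if not (0 <= K <= N and 0 <= n <= N):
        raise DomainError(f"need 0 <= K, n <= N; got k={k}, n={n}, K={K}, N={N}")
    if not (max(0, n + K - N) <= k <= min(n, K)):
        raise DomainError(
            f"k out of hypergeometric support: k={k}, n={n}, K={K}, N={N}"
        )


def hypergeom_overrep(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P(X ≥ k) for X ~ Hypergeometric(N, K, n)."""
    _check_bounds(k, n, K, N)
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def fisher_exact_greater(k: int, n: int, K: int, N: int) -> float:
    """One-sided (greater) Fisher exact p for the 2×2 table
    [[k, n−k], [K−k, N−n−K+k]]; equals :func:`hypergeom_overrep` on the
    same margins."""
    _check_bounds(k, n, K, N)
    table = [[k, n - k], [K - k, N - n - K + k]]
    return float(stats.fisher_exact(table, alternative="greater").pvalue)


def bh_fdr(pvals: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted values, in the input order.

    q_(i) = min_{j >= i} (m * p_(j) / j), capped at 1.
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise DomainError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q.tolist()


def fold_enrichment(k: int, n: int, K: int, N: int) -> float:
    """(k/n) / (K/N): the study hit rate relative to the background rate."""
    if n <= 0 or K <= 0:
        raise DomainError(f"fold enrichment needs n > 0 and K > 0; got n={n}, K={K}")
    _check_bounds(k, n, K, N)
    return (k / n) / (K / N)


def format_fold(fold: float, decimals: int = 2) -> str:
    """Render a fold value for reports; values strictly above 100 print
    as ``>100``."""
    if fold > 100:
        return ">100"
    return f"{fold:.{decimals}f}"


def enrich(
    study: Iterable[str],
    annotation: AnnotationTable,
    background: Iterable[str],
    alpha: float = 0.05,
    restrict_to_annotated: bool = False,
) -> list[EnrichmentResult]:
    """Test every term with at least one background hit for
    over-representation in the study set.

    The background defaults to *all* supplied genes, annotated or not
    (unannotated genes still count toward N); set
    ``restrict_to_annotated`` to drop genes without any annotation first.
    Results are sorted by (p, term id); rows with q < ``alpha`` carry the
    ``displayed`` flag.  The BH family is the set of tested terms.
    """
    study_set = set(study)
    bg = set(background)
    if not study_set:
        raise UsageError("study set is empty")
    stray = study_set - bg
    if stray:
        raise UsageError(
            f"{len(stray)} study genes missing from the background, "
            f"e.g. {sorted(stray)[:3]}"
        )
    if restrict_to_annotated:
        annotated = {g for g in bg if annotation.rows.get(g)}
        bg = annotated
        study_set &= annotated
        if not study_set:
            raise UsageError("study set empty after restricting to annotated genes")

    N = len(bg)
    n = len(study_set)
    term_bg: dict[str, int] = {}
    term_study: dict[str, int] = {}
    for gene in bg:
        for term in annotation.rows.get(gene, ()):
            term_bg[term] = term_bg.get(term, 0) + 1
            if gene in study_set:
                term_study[term] = term_study.get(term, 0) + 1

    terms = sorted(term_bg)
    if not terms:
        return []
    ks = np.array([term_study.get(t, 0) for t in terms])
    Ks = np.array([term_bg[t] for t in terms])
    ps = stats.hypergeom.sf(ks - 1, N, Ks, n)
    qs = bh_fdr(ps.tolist())

    results = [
        EnrichmentResult(
            term=t,
            label=annotation.term_names.get(t, t),
            k=int(k),
            n=n,
            K=int(K),
            N=N,
            fold_enrichment=(k / n) / (K / N),
            p=float(p),
            q=float(q),
            displayed=bool(q < alpha),
        )
        for t, k, K, p, q in zip(terms, ks, Ks, ps, qs)
    ]
    results.sort(key=lambda r: (r.p, r.q, r.term))
    return results
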