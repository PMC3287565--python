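"""Hypergeometric gene-set enrichment and the p-score transform.

For a query set of size C drawn from a universe of G genes of which n carry
an annotation, the enrichment P-value is the upper hypergeometric tail
``P = Pr(X >= k)`` where k is the observed overlap.  The *p-score* is
``-log10(P)``, so larger means more significant.  Batch enrichment against a
GMT annotation collection applies a multiple-testing correction
(Benjamini-Hochberg by default) across all tested terms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: p-scores of underflowed P-values are clipped here by default.
DEFAULT_PSCORE_CAP = 300.0


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    term_size: int
    overlap: int
    p: float
    p_score: float
    corrected_p: float


def hypergeometric_tail(G: int, n: int, C: int, k: int) -> float:
    """Upper-tail ``Pr(X >= k)`` for X ~ Hypergeometric(G, n, C).

    G: universe size; n: annotated genes in the universe; C: query-set
    size; k: observed overlap.  Returns a value in (0, 1]; ``k = 0`` gives
    exactly 1.
    """
    if not (0 <= n <= G):
        raise ValueError(f"need 0 <= n <= G, got n={n}, G={G}")
    if not (0 <= C <= G):
        raise ValueError(f"need 0 <= C <= G, got C={C}, G={G}")
    if not (0 <= k <= min(C, n)):
        raise ValueError(f"need 0 <= k <= min(C, n), got k={k}, C={C}, n={n}")
    if k == 0:
        return 1.0
    # survival function at k-1; for tiny tails recompute from the log-pmf
    # so underflow cannot round the result to 0
    p = float(hypergeom.sf(k - 1, G, n, C))
    if p <= 0.0:
        logs = [hypergeom.logpmf(i, G, n, C) for i in range(k, min(C, n) + 1)]
        peak = max(logs)
        p = math.exp(peak) * sum(math.exp(x - peak) for x in logs)
        if p <= 0.0:
            p = 5e-324  # tail below the subnormal range; p_score caps anyway
    return min(p, 1.0)


def p_score(p: float, cap: float = DEFAULT_PSCORE_CAP) -> float:
    """-log10 of a P-value, clipped at ``cap`` for underflowed inputs."""
    if not (0.0 < p <= 1.0):
        raise ValueError(f"P must be in (0, 1], got {p}")
    return min(-math.log10(p), cap)


def enrich(
    gene_set: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
    universe: Iterable[str] | None = None,
    correction: str = "bh",
    pscore_cap: float = DEFAULT_PSCORE_CAP,
) -> list[EnrichmentResult]:
    """Test a gene set against every term of an annotation collection.

    The universe defaults to the union of all term gene sets; query genes
    outside the universe are dropped (count logged).  ``correction`` is one
    of ``bh`` (Benjamini-Hochberg), ``bonferroni``, ``none``.  Results are
    sorted by ascending P, ties by term id.
    """
    if not annotation:
        raise ValueError("empty annotation collection")
    if correction not in ("bh", "bonferroni", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    terms = {t: {g.strip().upper() for g in gs} for t, gs in annotation.items()}
    if universe is None:
        uni: set[str] = set()
        for gs in terms.values():
            uni |= gs
    else:
        uni = {g.strip().upper() for g in universe}
    if not uni:
        raise ValueError("empty universe")
    query = {g.strip().upper() for g in gene_set}
    outside = len(query - uni)
    if outside:
        logger.info("enrich: %d query genes outside the universe dropped", outside)
    query &= uni
    G, C = len(uni), len(query)

    rows: list[tuple[str, int, int, float]] = []
    for term in sorted(terms):
        tg = terms[term] & uni
        n = len(tg)
        if n == 0:
            continue
        k = len(query & tg)
        rows.append((term, n, k, hypergeometric_tail(G, n, C, k)))
    if not rows:
        raise ValueError("no annotation term overlaps the universe")

    pvals = [r[3] for r in rows]
    if correction == "none":
        corrected = list(pvals)
    else:
        method = {"bh": "fdr_bh", "bonferroni": "bonferroni"}[correction]
        corrected = list(multipletests(pvals, method=method)[1])

    results = [
        EnrichmentResult(
            term=term,
            term_size=n,
            overlap=k,
            p=p,
            p_score=p_score(p, cap=pscore_cap),
            corrected_p=float(cp),
        )
        for (term, n, k, p), cp in zip(rows, corrected)
    ]
    results.sort(key=lambda r: (r.p, r.term))
    return results


def write_enrichment(results: list[EnrichmentResult], path) -> None:
    from pathlib import Path

    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("term\tn\tk\tP\tp_score\tcorrected_P\n")
        for r in results:
            fh.write(
                f"{r.term}\t{r.term_size}\t{r.overlap}\t{r.p:.10g}"
                f"\t{r.p_score:.10g}\t{r.corrected_p:.10g}\n"
            )
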