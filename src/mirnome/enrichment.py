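"""Over-representation analysis of a gene list against flat term annotations.

For each annotation term with at least ``min_term_size`` genes in the
background universe, the upper hypergeometric tail P[X >= k] is computed
for the overlap k between the term and the query (hub) list, and the
resulting p-values are adjusted with the Benjamini–Hochberg step-up
procedure. Only over-representation (one-sided) is tested. Annotations are
taken as a pre-propagated flat term -> gene map; no ontology-graph logic.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .data_io import AnnotationSet

ENRICHMENT_COLUMNS = [
    "term_id", "term_name", "k_overlap", "K_term", "n_sample", "N_universe",
    "expected", "fold", "p_value", "q_value", "significant",
]


@dataclass
class EnrichmentRow:
    term_id: str
    term_name: str
    k_overlap: int
    K_term: int
    n_sample: int
    N_universe: int
    expected: float
    fold: float
    p_value: float
    q_value: float
    significant: bool


def hypergeometric_tail(k: int, K: int, n: int, N: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(population N, successes K, draws n).

    Computed via the survival function (log-space internally), stable for
    populations up to ~1e5.
    """
    if not (0 <= k <= min(K, n) <= N):
        raise ValueError(f"invalid hypergeometric arguments k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    hub_genes: set[str],
    annotations: AnnotationSet,
    universe: set[str] | None = None,
    alpha: float = 0.05,
    min_term_size: int = 2,
) -> list[EnrichmentRow]:
    """Hypergeometric over-representation of ``hub_genes`` in each term.

    ``universe`` defaults to the union of annotated genes. The sample size n
    counts only hub genes inside the universe. Rows are BH-adjusted across
    all tested terms and sorted by ascending p-value (ties by term id);
    rows with q <= alpha are flagged significant.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if universe is None:
        universe = set(annotations.genes())
    universe = set(universe)
    sample = set(hub_genes) & universe
    if not sample:
        raise ValueError("hub list disjoint from universe")
    N = len(universe)
    n = len(sample)

    rows: list[EnrichmentRow] = []
    for term_id in sorted(annotations.terms):
        term_genes = set(annotations.terms[term_id]) & universe
        K = len(term_genes)
        if K < max(min_term_size, 1):
            continue
        k = len(term_genes & sample)
        expected = n * K / N
        rows.append(
            EnrichmentRow(
                term_id=term_id,
                term_name=annotations.names.get(term_id, ""),
                k_overlap=k,
                K_term=K,
                n_sample=n,
                N_universe=N,
                expected=expected,
                fold=k / expected,
                p_value=hypergeometric_tail(k, K, n, N),
                q_value=1.0,
                significant=False,
            )
        )
    if not rows:
        return rows
    reject, q_values, _, _ = multipletests(
        [r.p_value for r in rows], alpha=alpha, method="fdr_bh"
    )
    for row, q, rej in zip(rows, q_values, reject):
        row.q_value = float(q)
        row.significant = bool(rej)
    rows.sort(key=lambda r: (r.p_value, r.term_id))
    return rows
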