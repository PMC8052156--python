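"""Over-representation analysis of a query gene set against an annotation
database.

For a term annotating K genes out of a background universe of N, and a
query of n universe genes overlapping the term in k, the enrichment
p-value is the hypergeometric upper tail

    p = P(X >= k),  X ~ Hypergeometric(N, K, n),

evaluated in log space for numerical stability.  The conservative EASE
variant replaces k with max(k - 1, 0).  Multiple testing is controlled
with the Benjamini-Hochberg step-up procedure, applied within one
annotation namespace at a time; terms with zero overlap are omitted from
the output (the universe restriction already accounts for them).  Both a
raw-p threshold and an FDR threshold are evaluated and reported side by
side, since practice varies on which one a study quotes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .datatypes import AnnotationDatabase, GeneSet

logger = logging.getLogger(__name__)

MODES = ("hypergeometric", "ease")
UNIVERSES = ("annotated_union", "user_list")


@dataclass(frozen=True)
class EnrichConfig:
    """Settings for the over-representation test.

    mode : ``"hypergeometric"`` (default) or ``"ease"`` (k decremented by 1).
    universe : background choice — ``"annotated_union"`` (default; every gene
        annotated to any term of the database) or ``"user_list"`` (the
        ``background`` collection supplied by the caller).
    p_cut : raw p-value threshold (default 0.01).
    fdr_cut : BH-adjusted threshold (default 0.05).
    """

    mode: str = "hypergeometric"
    universe: str = "annotated_union"
    background: frozenset[str] | None = None
    p_cut: float = 0.01
    fdr_cut: float = 0.05

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.universe not in UNIVERSES:
            raise ValueError(f"universe must be one of {UNIVERSES}, got {self.universe!r}")
        for name in ("p_cut", "fdr_cut"):
            val = getattr(self, name)
            if not 0 < val <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {val}")
        if self.universe == "user_list" and not self.background:
            raise ValueError("universe='user_list' requires a non-empty background")


@dataclass(frozen=True)
class EnrichmentRecord:
    """One term's overlap counts, raw p-value and BH-adjusted value."""

    term_id: str
    namespace: str
    k: int          # overlap size
    K: int          # term size within the universe
    n: int          # query size within the universe
    N: int          # universe size
    p_raw: float
    p_adj: float
    gene_hits: tuple[str, ...]
    pass_p: bool = False
    pass_fdr: bool = False


def _log_pmf(i: np.ndarray, K: int, n: int, N: int) -> np.ndarray:
    """log P(X = i) for X ~ Hypergeometric(N, K, n), via log-gamma."""

    def lc(a, b):  # log C(a, b), vectorized
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    return lc(K, i) + lc(N - K, n - i) - lc(N, n)


def hypergeom_pvalue(k: int, K: int, n: int, N: int, mode: str = "hypergeometric") -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    Parameters are the overlap ``k``, term size ``K``, query size ``n`` and
    universe size ``N``; the bounds 0 <= k <= min(K, n) <= N must hold.
    ``mode="ease"`` substitutes max(k - 1, 0) for k.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K, n <= N; got K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"need 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if mode == "ease":
        k = max(k - 1, 0)
    if k == 0:
        return 1.0
    i = np.arange(k, min(K, n) + 1)
    return float(min(1.0, np.exp(logsumexp(_log_pmf(i, K, n, N)))))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j over the ascending-sorted p-values,
    capped at 1.  Input values must lie in (0, 1].
    """
    arr = np.asarray(list(pvalues), dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr <= 0) | (arr > 1)) or np.any(np.isnan(arr)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def enrich(
    query: GeneSet | Iterable[str],
    db: AnnotationDatabase,
    cfg: EnrichConfig | None = None,
) -> list[EnrichmentRecord]:
    """Test every term of ``db`` for over-representation in ``query``.

    The query is restricted to the background universe (genes outside it
    are dropped with a logged count), each term with a non-empty overlap is
    tested, BH adjustment is applied across the tested terms of this
    namespace, and records are returned sorted by raw p-value with ties
    broken by term id.

    Raises
    ------
    ValueError
        If the database has no terms, or no query gene lies in the universe.
    """
    cfg = cfg or EnrichConfig()
    if len(db.terms) == 0:
        raise ValueError("enrich: empty annotation database")
    query_genes = query.genes if isinstance(query, GeneSet) else frozenset(
        g.upper() for g in query
    )
    if cfg.universe == "annotated_union":
        universe = db.gene_universe()
    else:
        universe = frozenset(g.upper() for g in cfg.background)  # type: ignore[union-attr]
    q = query_genes & universe
    dropped = len(query_genes) - len(q)
    if dropped:
        logger.info("enrich: dropped %d query gene(s) outside the universe", dropped)
    if not q:
        raise ValueError("enrich: no query gene lies in the background universe")

    N = len(universe)
    n = len(q)
    rows: list[tuple[str, int, int, tuple[str, ...]]] = []
    for term_id in sorted(db.terms):
        members = db.terms[term_id].genes & universe
        hits = members & q
        if not hits:
            continue
        rows.append((term_id, len(hits), len(members), tuple(sorted(hits))))
    if not rows:
        return []

    p_raw = np.array(
        [hypergeom_pvalue(k, K, n, N, mode=cfg.mode) for _, k, K, _ in rows]
    )
    p_adj = bh_adjust(p_raw)
    records = [
        EnrichmentRecord(
            term_id=term_id,
            namespace=db.namespace,
            k=k,
            K=K,
            n=n,
            N=N,
            p_raw=float(pr),
            p_adj=float(pa),
            gene_hits=hits,
            pass_p=bool(pr < cfg.p_cut),
            pass_fdr=bool(pa < cfg.fdr_cut),
        )
        for (term_id, k, K, hits), pr, pa in zip(rows, p_raw, p_adj)
    ]
    records.sort(key=lambda r: (r.p_raw, r.term_id))
    return records


def records_to_frame(records: Sequence[EnrichmentRecord]):
    """Tabulate enrichment records for TSV export."""
    import pandas as pd

    return pd.DataFrame(
        [
            (
                r.term_id, r.namespace, r.k, r.K, r.n, r.N,
                r.p_raw, r.p_adj, r.pass_p, r.pass_fdr, ",".join(r.gene_hits),
            )
            for r in records
        ],
        columns=[
            "term_id", "namespace", "k", "K", "n", "N",
            "p_raw", "p_adj", "pass_p", "pass_fdr", "gene_hits",
        ],
    )
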