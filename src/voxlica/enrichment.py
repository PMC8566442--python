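"""Over-representation analysis of gene groups against an annotation universe.

For a query of ``n`` genes drawn from a universe of ``N`` genes, of which
``K`` carry a given annotation term, the overlap ``k`` is tested with the
hypergeometric upper tail P[X >= k] (over-representation only). Raw
p-values get Benjamini-Hochberg FDR adjustment; a fixed p cutoff mode is
also supported, mirroring analyses that pre-derive a family-wide cutoff
(3.8e-5 in the mouse-brain study this package replicates in miniature).
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthetic import AnnotationMap

__all__ = [
    "hypergeom_upper_tail",
    "fdr_adjust",
    "enrich",
    "EnrichmentTable",
    "DEFAULT_CUTOFF",
]

#: fixed significance cutoff replicating an FDR-derived family-wide level
DEFAULT_CUTOFF = 3.8e-5


def hypergeom_upper_tail(k: int, K: int, n: int, N_univ: int) -> float:
    """Exact P[X >= k] for X ~ Hypergeometric(N_univ, K, n).

    ``k``: overlap, ``K``: annotated genes in the universe, ``n``: query
    size, ``N_univ``: universe size.
    """
    k, K, n, N_univ = int(k), int(K), int(n), int(N_univ)
    if not (0 <= K <= N_univ and 0 <= n <= N_univ):
        raise ValueError("need 0 <= K, n <= N_univ")
    if not 0 <= k <= min(K, n):
        raise ValueError("need 0 <= k <= min(K, n)")
    if k == 0:
        return 1.0
    # sf(k-1) = P[X >= k]; scipy evaluates this in log-stable form
    return float(stats.hypergeom.sf(k - 1, N_univ, K, n))


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class EnrichmentTable:
    """Per-term hypergeometric results with FDR decisions."""

    table: pd.DataFrame          # columns: term, name, k, K, n, N_univ, p, q, significant
    alpha: float
    mode: str                    # "fixed_p" or "fdr"

    def significant_terms(self) -> list[str]:
        return list(self.table.loc[self.table["significant"], "term"])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def enrich(
    query,
    annot: AnnotationMap,
    alpha: float = DEFAULT_CUTOFF,
    mode: str = "fixed_p",
    include_empty: bool = False,
) -> EnrichmentTable:
    """Test every annotation term for over-representation in ``query``.

    ``mode="fixed_p"`` flags terms with raw ``p < alpha`` (the pre-derived
    family-wide cutoff convention); ``mode="fdr"`` flags ``q <= alpha``
    after BH adjustment across the tested terms. Query genes outside the
    universe are dropped with a warning. Rows are sorted by p-value with
    the term id breaking ties, so output is invariant to gene ordering.
    """
    if mode not in ("fixed_p", "fdr"):
        raise ValueError("mode must be 'fixed_p' or 'fdr'")
    query = set(query)
    stray = query - annot.universe
    if stray:
        warnings.warn(
            f"{len(stray)} query gene(s) outside the universe were dropped",
            stacklevel=2,
        )
        query &= annot.universe

    N_univ = len(annot.universe)
    n = len(query)
    rows = []
    for term in sorted(annot.terms):
        genes = annot.terms[term]
        k = len(query & genes)
        if k == 0 and not include_empty:
            continue
        p = hypergeom_upper_tail(k, len(genes), n, N_univ) if n else 1.0
        rows.append((term, annot.term_names.get(term, term), k, len(genes), n, N_univ, p))

    df = pd.DataFrame(
        rows, columns=["term", "name", "k", "K", "n", "N_univ", "p"]
    )
    if len(df):
        df["q"] = fdr_adjust(df["p"].to_numpy())
        flag = df["p"] < alpha if mode == "fixed_p" else df["q"] <= alpha
        df["significant"] = flag
        df = df.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)
    else:
        df["q"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
    return EnrichmentTable(table=df, alpha=alpha, mode=mode)
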