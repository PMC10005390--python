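"""Hypergeometric over-representation of a study gene set in flat terms.

For a study set of size n drawn from a universe of N genes, a term with
K annotated genes and k study hits gets the one-sided tail
p = P(X >= k), X ~ Hypergeometric(N, K, n), adjusted across terms with
Benjamini-Hochberg.  Term annotations are taken as given flat sets — no
ontology-graph propagation or gene-length bias correction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust
from .io import AnnotationMap

logger = logging.getLogger(__name__)

ALPHA = 0.05


def hypergeometric_enrichment(
    study: set[str], annotation: AnnotationMap, alpha: float = ALPHA
) -> pd.DataFrame:
    """One term per row: k, n, K, N, p, fdr, fold enrichment, flag.

    Study genes outside the population universe are dropped with a
    warning; terms with no study overlap are still reported (k = 0,
    p = 1).  Fold enrichment is (k/n)/(K/N).
    """
    universe = annotation.universe
    if not study or not universe:
        raise ValueError("study set and universe must be non-empty")
    outside = set(study) - universe
    if outside:
        logger.warning("%d study genes outside the universe dropped", len(outside))
    study_in = set(study) & universe
    if not study_in:
        raise ValueError("no study genes remain inside the universe")

    N, n = len(universe), len(study_in)
    rows = []
    for term in sorted(annotation.terms):
        genes = annotation.terms[term] & universe
        K = len(genes)
        k = len(genes & study_in)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        fold = (k / n) / (K / N) if K else np.nan
        rows.append(
            {
                "term": term,
                "name": annotation.names.get(term, term),
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "p": min(p, 1.0),
                "fold_enrichment": fold,
            }
        )
    table = pd.DataFrame(rows).set_index("term")
    table["fdr"] = bh_adjust(table["p"].to_numpy())
    table["significant"] = table["fdr"] < alpha
    return table


def top_terms(table: pd.DataFrame, n: int = 10, rank_by: str = "fdr") -> pd.DataFrame:
    """Top-n bubble-plot rows, ties broken by term id for determinism.

    Each row carries the term, its study hit count k (bubble size), fold
    enrichment and adjusted p (bubble color).
    """
    if table.empty:
        raise ValueError("empty enrichment table")
    ranked = table.sort_values([rank_by, "term"], kind="mergesort")
    cols = [c for c in ("name", "k", "fold_enrichment", "p", "fdr", "significant") if c in table.columns]
    return ranked.head(n)[cols]
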