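"""Hypergeometric over-representation test of GO terms with BH FDR.

The annotation is a flat gene -> terms map; no GO-graph propagation is
performed (supply a pre-propagated map if parent counting is wanted). The
background is the set of annotated genes passed in; the term universe is
every term with at least one annotated background gene.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def test_go_enrichment(
    selected: Iterable[str],
    annotations: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """One-sided (upper tail) hypergeometric enrichment per term.

    For a term annotated to K of the N background genes, with n selected
    genes of which x carry the term: p = P(X >= x), X ~ Hypergeom(N, K, n),
    expected count = n*K/N. Results are BH-adjusted and sorted by p.
    """
    selected = set(selected)
    background = set(annotations)
    extra = selected - background
    if extra:
        raise ValueError(
            f"{len(extra)} selected genes are missing from the annotation map")
    if not selected:
        logger.warning("empty selection: no enrichment to test")
        return pd.DataFrame(columns=["term", "N", "n", "K", "observed",
                                     "expected", "p", "q"])

    term_genes: dict[str, set[str]] = {}
    for gene, terms in annotations.items():
        for term in terms:
            term_genes.setdefault(term, set()).add(gene)

    big_n = len(background)
    n = len(selected)
    rows = []
    for term, genes in sorted(term_genes.items()):
        k = len(genes)
        observed = len(genes & selected)
        p = float(stats.hypergeom.sf(observed - 1, big_n, k, n))
        rows.append({
            "term": term, "N": big_n, "n": n, "K": k,
            "observed": observed, "expected": n * k / big_n, "p": p,
        })
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    out = out.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)
    return out


def expected_count(n_selected: int, k_term: int, n_background: int) -> float:
    """Expected overlap n*K/N of a term with the selection under the null."""
    if n_background == 0:
        return float("nan")
    return n_selected * k_term / n_background
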