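"""Hypergeometric over-representation analysis with FDR control.

Candidate gene sets are tested term by term against a background gene
universe (by default the supplied expressed-gene list, e.g. genes with
FPKM > 1).  For a term annotating K of N background genes, with k of the
n candidate genes in the term, the enrichment p-value is the upper tail
P(X >= k) of the hypergeometric(N, K, n) distribution.  Multiple testing
is controlled per namespace by Benjamini-Hochberg (switchable to
Bonferroni); terms are significant below the FDR cutoff (default 0.1).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

NAMESPACES = ("biological_process", "cellular_component", "molecular_function", "pathway")


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ hypergeometric(N, K, n) (population N, K marked,
    n drawn), exact via the survival function in log space."""
    if not (0 <= k <= min(K, n) <= N):
        raise ValueError(f"invalid hypergeometric arguments k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    candidates: Iterable[str],
    annotation: pd.DataFrame,
    background: Iterable[str] | None = None,
    fdr_cutoff: float = 0.1,
    method: str = "fdr_bh",
    min_term_size: int = 2,
) -> pd.DataFrame:
    """Term over-representation among candidate genes.

    Parameters
    ----------
    annotation:
        Long-format table with columns ``gene``, ``term``, ``namespace``
        (optionally ``term_name``).
    background:
        Background gene universe; defaults to all annotated genes.
        Candidates outside the background are dropped with a warning.
    method:
        ``"fdr_bh"`` (Benjamini-Hochberg, default) or ``"bonferroni"``,
        applied within each namespace.
    min_term_size:
        Terms annotating fewer background genes are skipped (singleton
        terms give degenerate tests).

    Returns a table sorted by (fdr, p_raw) with one row per tested term.
    """
    for col in ("gene", "term", "namespace"):
        if col not in annotation.columns:
            raise ValueError(f"annotation table missing column {col!r}")
    if method not in ("fdr_bh", "bonferroni"):
        raise ValueError(f"unknown correction method {method!r}")

    bg = set(background) if background is not None else set(annotation["gene"])
    cand = set(candidates)
    outside = cand - bg
    if outside:
        warnings.warn(
            f"{len(outside)} candidate gene(s) outside the background were dropped",
            stacklevel=2,
        )
        cand &= bg
    columns = [
        "term", "term_name", "namespace", "k", "K", "n", "N", "p_raw", "fdr",
        "significant",
    ]
    if not cand:
        return pd.DataFrame(columns=columns)

    ann = annotation[annotation["gene"].isin(bg)]
    names = (
        ann.drop_duplicates("term").set_index("term")["term_name"]
        if "term_name" in ann.columns
        else pd.Series(dtype=object)
    )
    N = len(bg)
    n = len(cand)
    rows = []
    for (term, namespace), genes in ann.groupby(["term", "namespace"])["gene"]:
        term_genes = set(genes)
        K = len(term_genes)
        if K < min_term_size:
            continue
        k = len(term_genes & cand)
        if k < 1:
            continue
        rows.append(
            {
                "term": term,
                "term_name": names.get(term, ""),
                "namespace": namespace,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_raw": hypergeom_upper(k, K, n, N),
            }
        )
    if not rows:
        return pd.DataFrame(columns=columns)
    result = pd.DataFrame(rows)
    result["fdr"] = np.nan
    for namespace, idx in result.groupby("namespace").groups.items():
        pvals = result.loc[idx, "p_raw"].to_numpy()
        result.loc[idx, "fdr"] = multipletests(pvals, method=method)[1]
    result["significant"] = result["fdr"] < fdr_cutoff
    return (
        result[columns]
        .sort_values(["fdr", "p_raw", "term"])
        .reset_index(drop=True)
    )
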