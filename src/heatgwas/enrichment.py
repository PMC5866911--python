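"""Gene-ontology over/under-representation of genes in significant 1-Mb windows.

Genes whose coordinates overlap a reported window by at least one base pair
form the test list; for each ontology term the observed count k in the list
is compared with the expectation n*K/N under random sampling from the
annotated background (n list genes, K background genes carrying the term,
N background genes).  The p-value is the exact two-sided binomial tail
(minimum-likelihood method) with success probability K/N over n trials,
Bonferroni-corrected by the number of terms tested within the same ontology
aspect.  The background is an explicit input: by default it is every gene
with at least one annotation in the supplied term table.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import binomtest

logger = logging.getLogger(__name__)

_WINDOW = 1_000_000


def genes_in_windows(windows: pd.DataFrame, genes: pd.DataFrame) -> list[str]:
    """Genes overlapping any of the given 1-Mb windows by >= 1 bp.

    Parameters
    ----------
    windows : DataFrame
        Columns ``chromosome``, ``window_mb`` (window = [k Mb, (k+1) Mb)).
    genes : DataFrame
        Columns ``gene_id``, ``chromosome``, ``start_bp``, ``end_bp``
        (1-based, inclusive).

    Returns
    -------
    Sorted list of unique gene ids.
    """
    if len(windows) == 0:
        return []
    hits: set[str] = set()
    gene_chroms = set(genes["chromosome"].astype(str))
    for ch, grp in windows.groupby("chromosome", sort=False):
        ch = str(ch)
        if ch not in gene_chroms:
            logger.warning("chromosome %s absent from gene annotation", ch)
            continue
        g = genes.loc[genes["chromosome"].astype(str) == ch]
        for w in grp["window_mb"]:
            lo = int(w) * _WINDOW
            hi = (int(w) + 1) * _WINDOW - 1
            sel = (g["start_bp"] <= hi) & (g["end_bp"] >= lo)
            hits.update(g.loc[sel, "gene_id"])
    return sorted(hits)


def binomial_enrichment(
    gene_list: list[str],
    annotation: pd.DataFrame,
    background_ids: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Binomial over/under-representation test for every annotated term.

    Parameters
    ----------
    gene_list : list of str
        Genes of interest; must be a subset of the background.
    annotation : DataFrame
        Columns ``gene_id``, ``term_id`` and optionally ``aspect``
        (biological_process / molecular_function / cellular_component).
    background_ids : list of str, optional
        The annotated background; defaults to all genes appearing in
        ``annotation``.  Its size N is the denominator of the expectation.
    alpha : float
        Bonferroni-corrected significance level for the ``significant`` flag.

    Returns
    -------
    DataFrame with one row per (term, aspect) having K >= 1 background genes:
    columns ``term_id``, ``aspect``, ``K``, ``k``, ``n``, ``N``, ``expected``,
    ``direction`` (+/-), ``p_raw``, ``p_bonferroni``, ``significant``; sorted
    by aspect then raw p-value.
    """
    if len(gene_list) == 0:
        return pd.DataFrame(columns=[
            "term_id", "aspect", "K", "k", "n", "N",
            "expected", "direction", "p_raw", "p_bonferroni", "significant",
        ])
    ann = annotation.copy()
    if "aspect" not in ann.columns:
        ann["aspect"] = "unspecified"
    if background_ids is None:
        background_ids = sorted(set(ann["gene_id"]))
    background = set(background_ids)
    missing = set(gene_list) - background
    if missing:
        raise ValueError(f"{len(missing)} list gene(s) not in the background")
    listed = set(gene_list)
    N = len(background)
    n = len(listed)

    ann = ann.loc[ann["gene_id"].isin(background)]
    rows = []
    for (aspect, term), grp in ann.groupby(["aspect", "term_id"], sort=True):
        members = set(grp["gene_id"])
        K = len(members)
        if K < 1:
            continue
        k = len(members & listed)
        expected = n * K / N
        res = binomtest(k, n, K / N, alternative="two-sided")
        rows.append({
            "term_id": term, "aspect": aspect, "K": K, "k": k, "n": n, "N": N,
            "expected": expected,
            "direction": "+" if k > expected else "-",
            "p_raw": res.pvalue,
        })
    out = pd.DataFrame(rows)
    n_tested = out.groupby("aspect")["term_id"].transform("count")
    out["p_bonferroni"] = np.minimum(1.0, out["p_raw"] * n_tested)
    out["significant"] = out["p_bonferroni"] < alpha
    return out.sort_values(["aspect", "p_raw"]).reset_index(drop=True)
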