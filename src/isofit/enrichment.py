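"""Fisher-based functional enrichment of a gene list against a background."""

from __future__ import annotations

import pandas as pd
from scipy import stats as sps

from isofit.annotation_io import Annotation
from isofit.errors import ContractError
from isofit.stats import bh_adjust


def gene_term_map(annotation: Annotation, category: str) -> dict[str, set[str]]:
    """gene_id -> set of feature IDs of a category annotated on any isoform."""
    out: dict[str, set[str]] = {}
    for g in annotation.genes.values():
        terms = {
            f.feature_id
            for feats in g.features.values()
            for f in feats
            if f.category == category
        }
        if terms:
            out[g.gene_id] = terms
    return out


def fisher_enrichment(
    test_genes,
    background_genes,
    gene_terms: dict[str, set[str]],
) -> pd.DataFrame:
    """Two-sided Fisher enrichment of every term present in the test set.

    ``gene_terms`` maps genes to annotated term IDs (see
    :func:`gene_term_map`).  The test set must be a non-empty subset of the
    background.  BH correction across reported terms.
    """
    test = set(test_genes)
    bg = set(background_genes)
    if not test:
        raise ContractError("empty test gene list")
    if not test <= bg:
        raise ContractError("test genes must be a subset of the background")

    term_genes: dict[str, set[str]] = {}
    for gene in bg:
        for term in gene_terms.get(gene, ()):
            term_genes.setdefault(term, set()).add(gene)

    n_test, n_bg = len(test), len(bg)
    rows = []
    for term, genes in sorted(term_genes.items()):
        a = len(genes & test)
        if a == 0:
            continue
        b = n_test - a
        c = len(genes) - a
        d = (n_bg - n_test) - c
        odds, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append({
            "term_id": term,
            "n_test_with": a, "n_test_without": b,
            "n_bg_with": len(genes), "n_bg_without": n_bg - len(genes),
            "odds_ratio": odds, "p": p,
        })
    cols = ["term_id", "n_test_with", "n_test_without", "n_bg_with",
            "n_bg_without", "odds_ratio", "p"]
    if not rows:
        return pd.DataFrame(columns=cols + ["fdr"])
    out = pd.DataFrame(rows, columns=cols).set_index("term_id")
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    return out
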