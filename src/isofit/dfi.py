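"""Differential Feature Inclusion: per-gene feature inclusion rates, the
include/exclude interaction test, category-level enrichment and condition
bias, and co-inclusion analysis of feature pairs."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from isofit.annotation_io import Annotation
from isofit.errors import ContractError
from isofit.expression import ExpressionSet, normalize
from isofit.fda import (
    CALLED,
    projection_signature,
    signatures_equivalent,
    varying_status,
)
from isofit.models import GeneModel
from isofit.stats import (
    bh_adjust,
    estimate_dispersion,
    fit_interaction_test,
    moderate_dispersions,
)


@dataclass
class InclusionSplit:
    """Partition of a gene's isoforms into feature-including and -excluding."""

    gene_id: str
    category: str
    feature_id: str
    include: list[str]
    exclude: list[str]


def split_isoforms(
    g: GeneModel,
    category: str,
    feature_id: str,
    expr_rank: pd.Series | None = None,
    tol_bp: int = 9,
) -> InclusionSplit | None:
    """Include/exclude membership for one gene x feature.

    Presence-varying features split on carrying at least one annotation of
    the ID.  Features present on all isoforms but positionally varying split
    on positional equivalence to the reference isoform (the most expressed
    overall, per ``expr_rank``); any other placement counts as exclusion.
    Returns ``None`` when the feature is not varying (not testable).
    """
    pres = varying_status(g, category, "presence", feature_id=feature_id)
    tx_ids = [t.transcript_id for t in g.transcripts]
    carriers = {
        tx: [f for f in g.features_of(tx)
             if f.category == category and f.feature_id == feature_id]
        for tx in tx_ids
    }
    if pres.varying:
        inc = [tx for tx in tx_ids if carriers[tx]]
        exc = [tx for tx in tx_ids if not carriers[tx]]
        return InclusionSplit(g.gene_id, category, feature_id, inc, exc)

    posi = varying_status(g, category, "positional", tol_bp=tol_bp,
                          feature_id=feature_id)
    if posi.status != CALLED or not posi.varying:
        return None
    # positional-only variation: reference class defines inclusion
    if expr_rank is not None:
        ranked = sorted(tx_ids, key=lambda tx: (-expr_rank.get(tx, 0.0), tx))
    else:
        ranked = sorted(tx_ids)
    ref = ranked[0]
    ref_sigs = [projection_signature(f, g) for f in carriers[ref] if f.positional]
    inc, exc = [], []
    for tx in tx_ids:
        sigs = [projection_signature(f, g) for f in carriers[tx] if f.positional]
        same = (
            len(sigs) == len(ref_sigs)
            and all(any(signatures_equivalent(s, r, tol_bp) for r in ref_sigs)
                    for s in sigs)
        )
        (inc if same else exc).append(tx)
    return InclusionSplit(g.gene_id, category, feature_id, inc, exc)


def feature_inclusion(
    split: InclusionSplit, means: pd.DataFrame
) -> dict:
    """FI per condition from condition-mean expression, plus the derived
    delta-FI (percent), favored condition and 0.5-crossing switch flag."""
    fi = {}
    for cond in means.columns:
        e_inc = float(means.loc[[t for t in split.include if t in means.index], cond].sum())
        e_exc = float(means.loc[[t for t in split.exclude if t in means.index], cond].sum())
        tot = e_inc + e_exc
        fi[cond] = e_inc / tot if tot > 0 else np.nan
    conds = list(means.columns)
    a, b = (fi[conds[0]], fi[conds[1]]) if len(conds) == 2 else (np.nan, np.nan)
    delta = abs(a - b) * 100.0 if np.isfinite(a) and np.isfinite(b) else np.nan
    if np.isfinite(a) and np.isfinite(b) and a != b:
        favored = conds[0] if a > b else conds[1]
    else:
        favored = None
    switching = (
        bool((a - 0.5) * (b - 0.5) < 0)
        if np.isfinite(a) and np.isfinite(b)
        else None
    )
    return {"fi": fi, "delta_fi": delta, "favored": favored, "switching": switching}


def run_dfi(
    raw: ExpressionSet,
    annotation: Annotation,
    categories: list[str] | None = None,
    alpha: float = 0.05,
    tol_bp: int = 9,
    prior_df: float = 8.0,
) -> pd.DataFrame:
    """Differential feature inclusion over all varying gene x feature pairs.

    Raw counts are aggregated into include/exclude units and fed to the NB
    interaction engine (k = 2); BH correction is applied separately within
    each annotation category.  FI metrics come from normalized condition
    means; records with zero gene expression in a condition are flagged and
    excluded from testing.
    """
    raw.require_two_groups()
    norm = normalize(raw)
    means = norm.condition_means()
    expr_rank = norm.values.sum(axis=1)
    offsets = norm.effective_lib_size.to_numpy()
    groups = raw.design.to_numpy()
    conds = raw.conditions

    if categories is None:
        categories = annotation.categories()

    splits: list[InclusionSplit] = []
    for g in annotation.genes.values():
        if not g.is_multi_isoform:
            continue
        pairs = sorted({
            (f.category, f.feature_id)
            for feats in g.features.values()
            for f in feats
            if f.category in categories
        })
        for cat, fid in pairs:
            s = split_isoforms(g, cat, fid, expr_rank=expr_rank, tol_bp=tol_bp)
            if s is not None:
                splits.append(s)

    # moderated dispersions across all testable records
    counts_list, disp_raw = [], []
    for s in splits:
        inc = [t for t in s.include if t in raw.values.index]
        exc = [t for t in s.exclude if t in raw.values.index]
        c = np.vstack([
            raw.values.loc[inc].sum(axis=0).to_numpy(dtype=float),
            raw.values.loc[exc].sum(axis=0).to_numpy(dtype=float),
        ])
        counts_list.append(c)
        disp_raw.append(estimate_dispersion(c, groups, offsets))
    per_cond_df = sum(max(0, (groups == g).sum() - 1) for g in np.unique(groups))
    disp = moderate_dispersions(
        np.array(disp_raw), resid_df=2.0 * per_cond_df, prior_df=prior_df
    ) if splits else np.array([])

    rows = []
    for s, c, a in zip(splits, counts_list, disp):
        res = fit_interaction_test(c, groups, offsets,
                                   unit_group_id=f"{s.gene_id}:{s.feature_id}",
                                   dispersion=float(a))
        m = feature_inclusion(s, means)
        evaluable = all(np.isfinite(m["fi"][cond]) for cond in conds)
        rows.append({
            "gene_id": s.gene_id,
            "category": s.category,
            "feature_id": s.feature_id,
            "n_include": len(s.include),
            "n_exclude": len(s.exclude),
            "status": res.status if evaluable else "not_evaluable",
            "p": res.p if evaluable else np.nan,
            "fi_" + conds[0]: m["fi"][conds[0]],
            "fi_" + conds[1]: m["fi"][conds[1]],
            "delta_fi": m["delta_fi"],
            "favored": m["favored"],
            "feature_switching": m["switching"],
        })
    cols = ["gene_id", "category", "feature_id", "n_include", "n_exclude",
            "status", "p", "delta_fi", "favored", "feature_switching"]
    if not rows:
        out = pd.DataFrame(columns=cols + ["fdr", "dfi"])
        return out
    out = pd.DataFrame(rows)
    out["fdr"] = np.nan
    for cat in out["category"].unique():
        sel = (out["category"] == cat) & (out["status"] == "tested")
        if sel.any():
            out.loc[sel, "fdr"] = bh_adjust(out.loc[sel, "p"].to_numpy(dtype=float))
    out["dfi"] = (out["fdr"] < alpha).fillna(False)
    return out


def dfi_category_stats(dfi_table: pd.DataFrame) -> pd.DataFrame:
    """Per-category relative enrichment of DFI features (two-sided Fisher on
    category membership of DFI vs non-DFI features) and condition bias
    (two-sided exact binomial, p0 = 0.5, on favored-condition counts).
    Feature occurrences are counted once per gene.  BH across categories,
    separately for the two tests.
    """
    if dfi_table.empty or not dfi_table["dfi"].any():
        raise ContractError("no DFI features to summarize")
    uniq = dfi_table.drop_duplicates(subset=["gene_id", "category", "feature_id"])
    tested = uniq[uniq["status"] == "tested"]
    n_dfi_total = int(tested["dfi"].sum())
    n_tot = len(tested)
    conds = sorted({c for c in tested["favored"].dropna().unique()})

    rows = []
    for cat, sub in tested.groupby("category"):
        n_cat = len(sub)
        n_dfi_cat = int(sub["dfi"].sum())
        if n_dfi_cat == 0:
            continue
        table = [
            [n_dfi_cat, n_dfi_total - n_dfi_cat],
            [n_cat - n_dfi_cat, (n_tot - n_dfi_total) - (n_cat - n_dfi_cat)],
        ]
        odds, p_enr = sps.fisher_exact(table, alternative="two-sided")
        fav = sub.loc[sub["dfi"] & sub["favored"].notna(), "favored"]
        if len(fav) and len(conds) == 2:
            k = int((fav == conds[0]).sum())
            p_bias = sps.binomtest(k, len(fav), 0.5, alternative="two-sided").pvalue
            bias_n = len(fav)
        else:
            p_bias, bias_n, k = np.nan, 0, 0
        rows.append({"category": cat, "n_features_tested": n_cat,
                     "n_dfi": n_dfi_cat, "odds_ratio": odds, "p_enrichment": p_enr,
                     "n_favored_" + (conds[0] if conds else "a"): k,
                     "n_bias": bias_n, "p_bias": p_bias})
    out = pd.DataFrame(rows).set_index("category")
    out["fdr_enrichment"] = bh_adjust(out["p_enrichment"].to_numpy())
    sel = out["p_bias"].notna()
    out["fdr_bias"] = np.nan
    if sel.any():
        out.loc[sel, "fdr_bias"] = bh_adjust(out.loc[sel, "p_bias"].to_numpy())
    return out


def run_co_dfi(dfi_table: pd.DataFrame, min_genes: int = 5) -> pd.DataFrame:
    """Co-inclusion / mutual exclusion of feature-ID pairs.

    For every unordered pair of feature IDs significant (DFI, with a favored
    condition) in at least ``min_genes`` common genes: co-inclusion counts
    genes where the favored conditions agree, mutual exclusion where they
    differ.
    """
    sig = dfi_table[dfi_table["dfi"] & dfi_table["favored"].notna()]
    by_gene: dict[str, dict[str, str]] = {}
    for _, r in sig.iterrows():
        by_gene.setdefault(r["gene_id"], {})[r["feature_id"]] = r["favored"]

    pair_counts: dict[tuple[str, str], list[int]] = {}
    for favs in by_gene.values():
        fids = sorted(favs)
        for i, f1 in enumerate(fids):
            for f2 in fids[i + 1:]:
                co, ex = pair_counts.setdefault((f1, f2), [0, 0])
                if favs[f1] == favs[f2]:
                    pair_counts[(f1, f2)][0] = co + 1
                else:
                    pair_counts[(f1, f2)][1] = ex + 1

    rows = [
        {"feature_id_1": f1, "feature_id_2": f2,
         "n_genes_both_dfi": co + ex, "n_co_inclusion": co,
         "n_mutual_exclusion": ex}
        for (f1, f2), (co, ex) in sorted(pair_counts.items())
        if co + ex >= min_genes
    ]
    return pd.DataFrame(rows, columns=["feature_id_1", "feature_id_2",
                                       "n_genes_both_dfi", "n_co_inclusion",
                                       "n_mutual_exclusion"])
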