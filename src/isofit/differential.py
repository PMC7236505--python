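"""Differential analyses built on the NB interaction engine: gene expression
(DGE), isoform usage (DIU) and coding-region usage (DCU), with the usage
redistribution metric, per-condition major isoforms and switching calls."""

from __future__ import annotations

import numpy as np
import pandas as pd

from isofit.errors import ContractError
from isofit.expression import (
    ExpressionSet,
    UsageTable,
    aggregate_expression,
    compute_usage,
    filter_minor_isoforms,
    gene_map_from_models,
    normalize,
)
from isofit.stats import (
    bh_adjust,
    estimate_dispersion,
    fit_interaction_test,
    moderate_dispersions,
    nb_condition_test,
)


def total_usage_change(means_a, means_b) -> float:
    """Percent redistribution of gene expression across isoforms between two
    conditions: half the L1 distance between usage vectors, times 100.

    ``means_a`` / ``means_b`` are per-isoform condition-mean expression
    values; each condition must have positive total expression.
    """
    a = np.asarray(means_a, dtype=float)
    b = np.asarray(means_b, dtype=float)
    if a.shape != b.shape:
        raise ContractError("condition vectors differ in length")
    ta, tb = a.sum(), b.sum()
    if ta <= 0 or tb <= 0:
        raise ContractError("zero gene expression in a condition")
    return float(np.abs(a / ta - b / tb).sum() * 100.0 * 0.5)


def majors_and_switching(
    usage: UsageTable, gene_id: str
) -> tuple[dict[str, str | None], bool | None]:
    """Per-condition major isoform (ties -> lexicographically smallest id)
    and whether the major differs between conditions.  A condition with zero
    gene expression yields major ``None`` and switching ``None``."""
    gu = usage.gene_usage(gene_id)
    majors: dict[str, str | None] = {}
    for cond in gu.columns:
        col = gu[cond]
        if not usage.evaluable.loc[gene_id, cond] or col.isna().all():
            majors[cond] = None
            continue
        best = col.max()
        majors[cond] = sorted(col.index[col == best])[0]
    vals = list(majors.values())
    switching = None if any(v is None for v in vals) else len(set(vals)) > 1
    return majors, switching


def run_dge(
    raw: ExpressionSet,
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
    prior_df: float = 8.0,
) -> pd.DataFrame:
    """Two-group differential gene expression on gene-level raw counts.

    NB likelihood-ratio test of the condition effect per gene, BH across
    genes; fold change from normalized condition means with a pseudo-count
    of 1.  ``de`` flags genes with FDR < ``alpha`` and |FC| > ``fc_threshold``.
    """
    raw.require_two_groups()
    norm = normalize(raw)
    offsets = norm.effective_lib_size.to_numpy()
    groups = raw.design.to_numpy()
    counts = raw.values.to_numpy(dtype=float)

    disp = np.array([
        estimate_dispersion(row[None, :], groups, offsets) for row in counts
    ])
    resid_df = sum(max(0, (groups == g).sum() - 1) for g in np.unique(groups))
    disp = moderate_dispersions(disp, resid_df=resid_df, prior_df=prior_df)

    stats_p = [
        nb_condition_test(row, groups, offsets, dispersion=float(a))
        for row, a in zip(counts, disp)
    ]
    p = np.array([sp[1] for sp in stats_p])
    stat = np.array([sp[0] for sp in stats_p])
    fdr = bh_adjust(p)

    means = norm.condition_means()
    cond_a, cond_b = raw.conditions
    fc = (means[cond_b] + 1.0) / (means[cond_a] + 1.0)
    abs_fc = np.maximum(fc, 1.0 / fc)
    out = pd.DataFrame(
        {
            "gene_id": raw.values.index,
            "statistic": stat,
            "p": p,
            "fdr": fdr,
            "mean_" + cond_a: means[cond_a].to_numpy(),
            "mean_" + cond_b: means[cond_b].to_numpy(),
            "fold_change": fc.to_numpy(),
            "de": (fdr < alpha) & (abs_fc.to_numpy() > fc_threshold),
        }
    ).set_index("gene_id")
    return out


def run_diu(
    raw: ExpressionSet,
    models,
    level: str = "transcript",
    prefilter: str | None = None,
    prefilter_threshold: float | None = None,
    alpha: float = 0.05,
    prior_df: float = 8.0,
) -> pd.DataFrame:
    """Differential isoform (``transcript``) or coding-region (``cds``) usage.

    Per multi-unit gene: NB LRT of the unit x condition interaction on raw
    counts, BH across tested genes, plus total usage change, per-condition
    majors and switching from normalized condition means.  ``prefilter``
    (``proportion`` / ``foldchange``) removes minor units before testing.
    """
    if level not in ("transcript", "cds"):
        raise ContractError(f"unknown DIU level {level!r}")
    raw.require_two_groups()
    gene_map = gene_map_from_models(models) if not isinstance(models, pd.Series) else models

    work_raw = raw
    if level == "cds":
        if isinstance(models, pd.Series):
            raise ContractError("cds level requires gene models, not a gene map")
        work_raw = aggregate_expression(raw, models, level="cds")
        gene_map = pd.Series(
            {uid: uid.rsplit(":", 1)[0] for uid in work_raw.values.index}
        )

    norm = normalize(work_raw)
    if prefilter is not None:
        norm = filter_minor_isoforms(norm, gene_map, mode=prefilter,
                                     threshold=prefilter_threshold)
        work_raw = work_raw.subset(norm.values.index)

    gm = gene_map.reindex(work_raw.values.index)
    usage = compute_usage(norm, gm)
    means = norm.condition_means()
    offsets = norm.effective_lib_size.to_numpy()
    groups = work_raw.design.to_numpy()
    cond_a, cond_b = work_raw.conditions

    gene_units = {
        g: list(idx) for g, idx in work_raw.values.groupby(gm).groups.items()
    }
    multi = {g: u for g, u in gene_units.items() if len(u) >= 2}

    disp_raw = {
        g: estimate_dispersion(
            work_raw.values.loc[u].to_numpy(dtype=float), groups, offsets
        )
        for g, u in multi.items()
    }
    per_cond_df = sum(max(0, (groups == g).sum() - 1) for g in np.unique(groups))
    resid_df = np.array([len(u) * per_cond_df for u in multi.values()], dtype=float)
    mod = moderate_dispersions(
        np.array(list(disp_raw.values())), resid_df=resid_df, prior_df=prior_df
    )
    disp = dict(zip(disp_raw.keys(), mod))

    records = []
    for g, units in multi.items():
        res = fit_interaction_test(
            work_raw.values.loc[units].to_numpy(dtype=float),
            groups,
            offsets,
            unit_group_id=g,
            dispersion=float(disp[g]),
        )
        majors, switching = majors_and_switching(usage, g)
        ma = means.loc[units, cond_a].to_numpy()
        mb = means.loc[units, cond_b].to_numpy()
        change = total_usage_change(ma, mb) if ma.sum() > 0 and mb.sum() > 0 else np.nan
        records.append(
            {
                "gene_id": g,
                "level": level,
                "k_units": res.k_units,
                "status": res.status,
                "statistic": res.statistic,
                "p": res.p,
                "total_usage_change": change,
                "switching": switching,
                "major_" + cond_a: majors.get(cond_a),
                "major_" + cond_b: majors.get(cond_b),
            }
        )
    out = pd.DataFrame.from_records(records).set_index("gene_id") if records else pd.DataFrame(
        columns=["level", "k_units", "status", "statistic", "p",
                 "total_usage_change", "switching"]
    )
    if len(out):
        tested = out["status"] == "tested"
        fdr = pd.Series(np.nan, index=out.index)
        fdr[tested] = bh_adjust(out.loc[tested, "p"].to_numpy(dtype=float))
        out["fdr"] = fdr
        out["significant"] = (out["fdr"] < alpha).fillna(False)
    else:
        out["fdr"] = []
        out["significant"] = []
    return out
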