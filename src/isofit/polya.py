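"""PolyA-site library construction, differential polyadenylation (DPAU) and
usage-weighted UTR length analysis."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from isofit.errors import ContractError
from isofit.expression import ExpressionSet, UsageTable, normalize
from isofit.models import GeneModel
from isofit.stats import (
    bh_adjust,
    estimate_dispersion,
    fit_interaction_test,
    moderate_dispersions,
)


@dataclass
class PolyACluster:
    representative: int  # genomic position
    span: tuple[int, int]
    members: list[str]  # transcript ids
    label: str | None = None  # "proximal" | "distal" | None
    share_by_condition: dict[str, float] = field(default_factory=dict)


@dataclass
class GenePolyA:
    gene_id: str
    strand: str
    clusters: list[PolyACluster]
    eligible: bool
    proximal: PolyACluster | None = None
    distal: PolyACluster | None = None

    def transcripts_of(self, label: str) -> list[str]:
        return [
            tx
            for c in self.clusters
            if c.label == label
            for tx in c.members
        ]


@dataclass
class PolyALibrary:
    genes: dict[str, GenePolyA] = field(default_factory=dict)

    def eligible_genes(self) -> list[str]:
        return sorted(g for g, rec in self.genes.items() if rec.eligible)

    def to_bed(self) -> pd.DataFrame:
        rows = []
        for rec in self.genes.values():
            for c in rec.clusters:
                rows.append({
                    "start": c.span[0] - 1,  # BED half-open
                    "end": c.span[1],
                    "name": f"{rec.gene_id}|{c.label or 'merged'}",
                    "strand": rec.strand,
                })
        return pd.DataFrame(rows, columns=["start", "end", "name", "strand"])


def _single_linkage(positions: dict[str, int], window: int) -> list[list[str]]:
    """Cluster transcripts whose 3' ends chain within ``window`` bp."""
    items = sorted(positions.items(), key=lambda kv: (kv[1], kv[0]))
    clusters, current = [], [items[0]]
    for tx, pos in items[1:]:
        if pos - current[-1][1] <= window:
            current.append((tx, pos))
        else:
            clusters.append([t for t, _ in current])
            current = [(tx, pos)]
    clusters.append([t for t, _ in current])
    return clusters


def build_polya_library(
    models: dict[str, GeneModel],
    x: ExpressionSet,
    merge_window: int = 75,
    min_frac: float = 0.10,
    min_pair_dist: int = 60,
) -> PolyALibrary:
    """Cluster transcript 3' ends into per-gene polyA sites.

    Non-coding and NMD-flagged isoforms are discarded first.  Sites are
    merged by single linkage within ``merge_window`` bp; clusters holding
    less than ``min_frac`` of total gene expression in every condition are
    dropped (their transcripts leave the analysis); the surviving cluster
    nearest the gene 5' end in transcript orientation is proximal, the
    farthest distal, and intermediate clusters are assigned to the nearest
    labeled site.  A gene is eligible for DPA testing when both labels exist
    and their representatives lie at least ``min_pair_dist`` bp apart.
    The denominator of the expression floor is the total expression of all
    clustered (pre-filter) transcripts.
    """
    if not x.normalized:
        x = normalize(x)
    means = x.condition_means()
    totals = x.values.sum(axis=1)
    lib = PolyALibrary()

    for gene_id, g in models.items():
        usable = [
            t for t in g.transcripts
            if t.is_coding and not t.is_nmd and t.transcript_id in x.values.index
        ]
        if not usable:
            continue
        positions = {t.transcript_id: t.polya_pos for t in usable}
        strand = usable[0].strand
        member_groups = _single_linkage(positions, merge_window)

        gene_total = means.loc[list(positions)].sum(axis=0)  # per condition
        clusters = []
        for members in member_groups:
            expr = totals.loc[members]
            top = expr.max()
            candidates = [tx for tx in members if expr[tx] == top]
            # ties -> 3'-most end in transcript orientation
            rep_tx = max(
                candidates,
                key=lambda tx: positions[tx] if strand == "+" else -positions[tx],
            )
            pos = [positions[tx] for tx in members]
            share = {
                cond: (
                    float(means.loc[members, cond].sum() / gene_total[cond])
                    if gene_total[cond] > 0 else 0.0
                )
                for cond in means.columns
            }
            clusters.append(PolyACluster(
                representative=positions[rep_tx],
                span=(min(pos), max(pos)),
                members=sorted(members),
                share_by_condition=share,
            ))

        surviving = [c for c in clusters
                     if any(s >= min_frac for s in c.share_by_condition.values())]
        rec = GenePolyA(gene_id=gene_id, strand=strand, clusters=surviving,
                        eligible=False)
        if surviving:
            # transcript orientation: 5'-most = smallest on +, largest on -
            keyed = sorted(
                surviving,
                key=lambda c: c.representative if strand == "+" else -c.representative,
            )
            keyed[0].label = "proximal"
            keyed[-1].label = "distal"
            rec.proximal, rec.distal = keyed[0], keyed[-1]
            for c in keyed[1:-1]:
                d_prox = abs(c.representative - rec.proximal.representative)
                d_dist = abs(c.representative - rec.distal.representative)
                c.label = "proximal" if d_prox <= d_dist else "distal"
            if rec.proximal is not rec.distal:
                dist = abs(rec.distal.representative - rec.proximal.representative)
                rec.eligible = dist >= min_pair_dist
        lib.genes[gene_id] = rec
    return lib


def dpau(e_distal: float, e_proximal: float) -> float:
    """Relative distal polyA-site usage."""
    tot = e_distal + e_proximal
    if tot <= 0:
        return np.nan
    return e_distal / tot


def run_dpa(
    lib: PolyALibrary,
    raw: ExpressionSet,
    alpha: float = 0.05,
    prior_df: float = 8.0,
) -> pd.DataFrame:
    """Differential polyadenylation over eligible genes.

    Raw counts are collapsed to distal/proximal units and tested with the NB
    interaction engine; DPAU and its metrics come from normalized condition
    means; BH across genes."""
    raw.require_two_groups()
    norm = normalize(raw)
    means = norm.condition_means()
    offsets = norm.effective_lib_size.to_numpy()
    groups = raw.design.to_numpy()
    conds = raw.conditions

    genes = lib.eligible_genes()
    counts_list, disp_raw, keep = [], [], []
    for gid in genes:
        rec = lib.genes[gid]
        d_tx = [t for t in rec.transcripts_of("distal") if t in raw.values.index]
        p_tx = [t for t in rec.transcripts_of("proximal") if t in raw.values.index]
        if not d_tx or not p_tx:
            continue
        c = np.vstack([
            raw.values.loc[d_tx].sum(axis=0).to_numpy(dtype=float),
            raw.values.loc[p_tx].sum(axis=0).to_numpy(dtype=float),
        ])
        counts_list.append(c)
        disp_raw.append(estimate_dispersion(c, groups, offsets))
        keep.append((gid, d_tx, p_tx))
    per_cond_df = sum(max(0, (groups == g).sum() - 1) for g in np.unique(groups))
    disp = moderate_dispersions(
        np.array(disp_raw), resid_df=2.0 * per_cond_df, prior_df=prior_df
    ) if keep else np.array([])

    rows = []
    for (gid, d_tx, p_tx), c, a in zip(keep, counts_list, disp):
        res = fit_interaction_test(c, groups, offsets, unit_group_id=gid,
                                   dispersion=float(a))
        vals = {}
        for cond in conds:
            vals[cond] = dpau(
                float(means.loc[d_tx, cond].sum()),
                float(means.loc[p_tx, cond].sum()),
            )
        u, v = vals[conds[0]], vals[conds[1]]
        delta = abs(u - v) * 100.0 if np.isfinite(u) and np.isfinite(v) else np.nan
        switching = (
            bool((u - 0.5) * (v - 0.5) < 0)
            if np.isfinite(u) and np.isfinite(v) else None
        )
        favored = None
        if np.isfinite(u) and np.isfinite(v) and u != v:
            favored = conds[0] if u > v else conds[1]
        rows.append({
            "gene_id": gid, "status": res.status, "p": res.p,
            "dpau_" + conds[0]: u, "dpau_" + conds[1]: v,
            "delta_dpau": delta, "polya_switching": switching,
            "favored": favored,
        })
    cols = ["gene_id", "status", "p", "delta_dpau", "polya_switching", "favored"]
    if not rows:
        return pd.DataFrame(columns=cols + ["fdr", "significant"])
    out = pd.DataFrame(rows).set_index("gene_id")
    tested = out["status"] == "tested"
    out["fdr"] = np.nan
    if tested.any():
        out.loc[tested, "fdr"] = bh_adjust(out.loc[tested, "p"].to_numpy(dtype=float))
    out["significant"] = (out["fdr"] < alpha).fillna(False)
    return out


def utr_weighted_length(usages, lengths) -> float:
    """Usage-weighted UTR length: sum of usage x UTR length (a convex
    combination when usages sum to one)."""
    u = np.asarray(usages, dtype=float)
    l = np.asarray(lengths, dtype=float)
    return float(np.sum(u * l))


def run_utrl(
    models: dict[str, GeneModel],
    usage: UsageTable,
    end: str = "utr3",
    paired: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Per-gene usage-weighted UTR lengths and a global shift test.

    Usages are renormalized over the expressed coding isoforms of each gene.
    The global test is a Wilcoxon signed-rank on per-gene (condition A -
    condition B) weighted lengths (paired by gene); ``paired=False`` uses the
    rank-sum variant instead.
    """
    if end not in ("utr3", "utr5"):
        raise ContractError(f"unknown UTR end {end!r}")
    conds = list(usage.usage.columns)
    rows = []
    for gene_id, g in models.items():
        coding = [t for t in g.transcripts
                  if t.is_coding and t.transcript_id in usage.usage.index]
        if not coding:
            continue
        ids = [t.transcript_id for t in coding]
        lens = np.array([t.utr3_len if end == "utr3" else t.utr5_len for t in coding],
                        dtype=float)
        rec = {"gene_id": gene_id}
        ok = True
        for cond in conds:
            u = usage.usage.loc[ids, cond].to_numpy(dtype=float)
            u = np.nan_to_num(u, nan=0.0)
            tot = u.sum()
            if tot <= 0:
                ok = False
                break
            rec[f"utrw_{cond}"] = utr_weighted_length(u / tot, lens)
        if not ok:
            continue
        rec["delta"] = rec[f"utrw_{conds[0]}"] - rec[f"utrw_{conds[1]}"]
        rows.append(rec)
    table = pd.DataFrame(rows).set_index("gene_id") if rows else pd.DataFrame(
        columns=[f"utrw_{c}" for c in conds] + ["delta"]
    )
    deltas = table["delta"].to_numpy(dtype=float) if len(table) else np.array([])
    if len(deltas) == 0 or np.allclose(deltas, 0.0):
        global_test = {"statistic": np.nan, "p": 1.0, "n": int(len(deltas))}
    elif paired:
        stat, p = sps.wilcoxon(deltas)
        global_test = {"statistic": float(stat), "p": float(p), "n": int(len(deltas))}
    else:
        a = table[f"utrw_{conds[0]}"].to_numpy(dtype=float)
        b = table[f"utrw_{conds[1]}"].to_numpy(dtype=float)
        stat, p = sps.ranksums(a, b)
        global_test = {"statistic": float(stat), "p": float(p), "n": int(len(deltas))}
    return table, global_test
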