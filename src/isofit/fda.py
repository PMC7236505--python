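"""Functional Diversity Analysis: presence / positional varying calls per
gene and category, structural variation (APA, UTR lengths, CDS), and
category- or feature-ID-level summaries with Fisher enrichment."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from isofit.annotation_io import project_feature_to_genomic
from isofit.errors import ContractError
from isofit.models import FeatureAnnotation, GeneModel
from isofit.stats import bh_adjust

# statuses for a varying call
CALLED = "called"
NOT_ANNOTATED = "not_annotated"
NOT_EVALUABLE = "not_evaluable"

STRUCTURAL_KINDS = ("apa", "utr3", "utr5", "cds")


@dataclass
class VaryingCall:
    gene_id: str
    category: str
    mode: str  # "presence" | "positional"
    varying: bool
    witness: tuple[str, str] | None = None
    feature_id: str | None = None
    status: str = CALLED


def projection_signature(
    f: FeatureAnnotation, g: GeneModel
) -> tuple[tuple[int, int], ...]:
    """Genomic-interval fingerprint of one positional feature (sorted)."""
    t = g.transcript(f.transcript_id)
    return tuple(sorted(project_feature_to_genomic(f, t)))


def signatures_equivalent(
    sig_a: tuple[tuple[int, int], ...],
    sig_b: tuple[tuple[int, int], ...],
    tol_bp: int,
) -> bool:
    """Positional equivalence: same interval count and, interval-wise after
    sorting, both endpoints within ``tol_bp``."""
    if len(sig_a) != len(sig_b):
        return False
    return all(
        abs(a0 - b0) <= tol_bp and abs(a1 - b1) <= tol_bp
        for (a0, a1), (b0, b1) in zip(sig_a, sig_b)
    )


def _gene_features(g: GeneModel, category: str, feature_id: str | None):
    """Per-transcript features of a category (optionally one feature ID)."""
    out: dict[str, list[FeatureAnnotation]] = {t.transcript_id: [] for t in g.transcripts}
    for tx_id, feats in g.features.items():
        for f in feats:
            if f.category != category:
                continue
            if feature_id is not None and f.feature_id != feature_id:
                continue
            out[tx_id].append(f)
    return out


def varying_status(
    g: GeneModel,
    category: str,
    mode: str,
    tol_bp: int = 9,
    feature_id: str | None = None,
) -> VaryingCall:
    """Is a category (or one feature ID) varying across a gene's isoforms?

    Presence mode: varying iff some isoform pair differs in carrying at least
    one annotation.  Positional mode: annotations are projected to genomic
    intervals and the gene is varying iff some isoform pair has an annotation
    with no positionally equivalent counterpart on the other isoform
    (endpoints within ``tol_bp``); a presence difference therefore also
    counts as positional variation.
    """
    if mode not in ("presence", "positional"):
        raise ContractError(f"unknown FDA mode {mode!r}")
    if not g.is_multi_isoform:
        raise ContractError(f"{g.gene_id}: varying status needs >= 2 isoforms")
    per_tx = _gene_features(g, category, feature_id)
    if all(len(v) == 0 for v in per_tx.values()):
        return VaryingCall(g.gene_id, category, mode, False,
                           feature_id=feature_id, status=NOT_ANNOTATED)

    tx_ids = [t.transcript_id for t in g.transcripts]
    if mode == "presence":
        have = [tx for tx in tx_ids if per_tx[tx]]
        lack = [tx for tx in tx_ids if not per_tx[tx]]
        if have and lack:
            return VaryingCall(g.gene_id, category, mode, True,
                               witness=(have[0], lack[0]), feature_id=feature_id)
        return VaryingCall(g.gene_id, category, mode, False, feature_id=feature_id)

    # positional mode
    if all(not f.positional for feats in per_tx.values() for f in feats):
        return VaryingCall(g.gene_id, category, mode, False,
                           feature_id=feature_id, status=NOT_EVALUABLE)
    sigs = {
        tx: [projection_signature(f, g) for f in per_tx[tx] if f.positional]
        for tx in tx_ids
    }
    for i, t1 in enumerate(tx_ids):
        for t2 in tx_ids[i + 1:]:
            if _positional_pair_differs(sigs[t1], sigs[t2], tol_bp):
                return VaryingCall(g.gene_id, category, mode, True,
                                   witness=(t1, t2), feature_id=feature_id)
    return VaryingCall(g.gene_id, category, mode, False, feature_id=feature_id)


def _positional_pair_differs(sigs1, sigs2, tol_bp) -> bool:
    for s in sigs1:
        if not any(signatures_equivalent(s, o, tol_bp) for o in sigs2):
            return True
    for s in sigs2:
        if not any(signatures_equivalent(s, o, tol_bp) for o in sigs1):
            return True
    return False


def structural_varying(
    g: GeneModel,
    kind: str,
    apa_min_bp: int = 100,
    utr_min_bp: int = 75,
) -> VaryingCall:
    """Structural variation across isoforms.

    ``apa``: some isoform pair's polyA positions differ by at least
    ``apa_min_bp`` (absolute genomic distance).  ``utr3`` / ``utr5``: some
    coding pair's UTR lengths differ by more than ``utr_min_bp``.  ``cds``:
    some coding pair differs in CDS genomic intervals or CDS length.
    Non-coding isoforms are excluded from the UTR/CDS kinds.
    """
    if kind not in STRUCTURAL_KINDS:
        raise ContractError(f"unknown structural kind {kind!r}")
    if not g.is_multi_isoform:
        raise ContractError(f"{g.gene_id}: structural variation needs >= 2 isoforms")
    cat = {"apa": "APA", "utr3": "UTR3_length", "utr5": "UTR5_length", "cds": "CDS"}[kind]

    if kind == "apa":
        pos = [t.polya_pos for t in g.transcripts]
        ids = [t.transcript_id for t in g.transcripts]
        for i in range(len(pos)):
            for j in range(i + 1, len(pos)):
                if abs(pos[i] - pos[j]) >= apa_min_bp:
                    return VaryingCall(g.gene_id, cat, "positional", True,
                                       witness=(ids[i], ids[j]))
        return VaryingCall(g.gene_id, cat, "positional", False)

    coding = [t for t in g.transcripts if t.is_coding]
    if len(coding) < 2:
        return VaryingCall(g.gene_id, cat, "positional", False, status=NOT_EVALUABLE)
    if kind in ("utr3", "utr5"):
        lens = [t.utr3_len if kind == "utr3" else t.utr5_len for t in coding]
        for i in range(len(coding)):
            for j in range(i + 1, len(coding)):
                if abs(lens[i] - lens[j]) > utr_min_bp:
                    return VaryingCall(
                        g.gene_id, cat, "positional", True,
                        witness=(coding[i].transcript_id, coding[j].transcript_id))
        return VaryingCall(g.gene_id, cat, "positional", False)

    # cds: genomic-interval inequality or unequal CDS length
    for i in range(len(coding)):
        for j in range(i + 1, len(coding)):
            ti, tj = coding[i], coding[j]
            if (ti.cds_genomic_intervals() != tj.cds_genomic_intervals()
                    or ti.cds_len != tj.cds_len):
                return VaryingCall(g.gene_id, cat, "positional", True,
                                   witness=(ti.transcript_id, tj.transcript_id))
    return VaryingCall(g.gene_id, cat, "positional", False)


def fda_summary(
    genes: dict[str, GeneModel],
    mode: str,
    categories: list[str] | None = None,
    tol_bp: int = 9,
    include_structural: bool = False,
    apa_min_bp: int = 100,
    utr_min_bp: int = 75,
) -> pd.DataFrame:
    """Category-level FDA summary over multi-isoform genes.

    Returns one row per category: number of annotated multi-isoform genes,
    number varying, and the varying rate.  Categories annotated on no
    multi-isoform gene are excluded.  With ``include_structural`` (positional
    mode), the APA / UTR-length / CDS structural kinds are appended.
    """
    multi = [g for g in genes.values() if g.is_multi_isoform]
    if categories is None:
        categories = sorted({
            f.category for g in multi for feats in g.features.values() for f in feats
        })
    rows = []
    for cat in categories:
        n_annot = n_vary = 0
        for g in multi:
            call = varying_status(g, cat, mode, tol_bp=tol_bp)
            if call.status == NOT_ANNOTATED:
                continue
            n_annot += 1
            if call.status == CALLED and call.varying:
                n_vary += 1
        if n_annot == 0:
            continue
        rows.append({"category": cat, "mode": mode, "n_genes_annotated": n_annot,
                     "n_genes_varying": n_vary, "rate": n_vary / n_annot})
    if include_structural and mode == "positional":
        for kind in STRUCTURAL_KINDS:
            n_annot = n_vary = 0
            for g in multi:
                call = structural_varying(g, kind, apa_min_bp=apa_min_bp,
                                          utr_min_bp=utr_min_bp)
                if call.status == NOT_EVALUABLE:
                    continue
                n_annot += 1
                n_vary += int(call.varying)
            if n_annot:
                cat = {"apa": "APA", "utr3": "UTR3_length",
                       "utr5": "UTR5_length", "cds": "CDS"}[kind]
                rows.append({"category": cat, "mode": mode,
                             "n_genes_annotated": n_annot,
                             "n_genes_varying": n_vary, "rate": n_vary / n_annot})
    return pd.DataFrame(rows, columns=["category", "mode", "n_genes_annotated",
                                       "n_genes_varying", "rate"])


def fda_by_id(
    genes: dict[str, GeneModel],
    category: str,
    mode: str,
    tol_bp: int = 9,
) -> pd.DataFrame:
    """Feature-ID-level diversity within one category.

    Per feature ID: annotated / varying multi-isoform gene counts plus a
    two-sided Fisher exact test of varying status for this ID against all
    other IDs of the category, BH-corrected across IDs.
    """
    multi = [g for g in genes.values() if g.is_multi_isoform]
    ids = sorted({
        f.feature_id
        for g in multi
        for feats in g.features.values()
        for f in feats
        if f.category == category
    })
    if not ids:
        raise ContractError(f"category {category!r} has no feature IDs")

    counts = {}
    for fid in ids:
        n_annot = n_vary = 0
        for g in multi:
            call = varying_status(g, category, mode, tol_bp=tol_bp, feature_id=fid)
            if call.status == NOT_ANNOTATED:
                continue
            n_annot += 1
            if call.status == CALLED and call.varying:
                n_vary += 1
        counts[fid] = (n_annot, n_vary)

    tot_annot = sum(a for a, _ in counts.values())
    tot_vary = sum(v for _, v in counts.values())
    rows = []
    for fid, (n_annot, n_vary) in counts.items():
        other_annot = tot_annot - n_annot
        other_vary = tot_vary - n_vary
        table = [[n_vary, n_annot - n_vary],
                 [other_vary, other_annot - other_vary]]
        odds, p = sps.fisher_exact(table, alternative="two-sided")
        rows.append({"feature_id": fid, "category": category, "mode": mode,
                     "n_genes_annotated": n_annot, "n_genes_varying": n_vary,
                     "odds_ratio": odds, "p": p})
    out = pd.DataFrame(rows).set_index("feature_id")
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    return out
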