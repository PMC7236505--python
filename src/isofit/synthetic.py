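"""Synthetic fixture generator: annotation + counts + design + ground truth
with planted usage / inclusion / polyadenylation / UTR-length effects.

Gene structure: every gene sits on its own stretch of ``chr1`` (plus strand)
with a shared first exon and isoform-specific last exons whose lengths step
by ``utr_step``.  All isoforms share one CDS (start in exon 1, stop early in
exon 2), so last-exon length differences translate directly into distinct 3'
UTR lengths and polyA sites — one polyA cluster per isoform.  A tracked
motif on isoform 1 only makes every usage shift also a feature-inclusion
shift, and distinct polyA sites make it a distal-usage shift, so one planted
usage flip realizes DIU, DFI, DPA and UTR effects simultaneously (ground
truth flags all of them).

Counts are drawn per transcript as NB(gene_mean x usage x depth, dispersion),
so expression is NB-marginal by construction and fully reproducible from the
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from isofit.annotation_io import Annotation, write_annotation
from isofit.errors import SpecError
from isofit.expression import ExpressionSet
from isofit.models import FeatureAnnotation, GeneModel, TranscriptModel

TRACKED_CATEGORY = "MOTIF"
SHARED_CATEGORY = "PFAM-domain"


@dataclass
class SimulationSpec:
    n_genes: int = 100
    isoforms_per_gene: int = 2
    n_replicates: int = 3
    conditions: tuple[str, str] = ("A", "B")
    mean_range: tuple[float, float] = (50.0, 500.0)
    dispersion_range: tuple[float, float] = (0.05, 0.3)
    depth_range: tuple[float, float] = (1.0, 1.0)  # per-sample depth factors
    frac_diu: float = 0.0
    diu_flip: tuple[float, float] = (0.9, 0.1)
    frac_dfi: float = 0.0
    dfi_flip: tuple[float, float] = (0.9, 0.1)
    frac_dpa: float = 0.0
    dpa_flip: tuple[float, float] = (0.9, 0.1)
    frac_utr: float = 0.0
    utr_flip: tuple[float, float] = (0.9, 0.1)
    utr_step: int = 150  # last-exon length increment between isoforms (bp)
    distinct_cds: bool = False  # odd isoforms start their ORF 30 bp downstream
    seed: int = 0

    def __post_init__(self):
        for name in ("frac_diu", "frac_dfi", "frac_dpa", "frac_utr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SpecError(f"{name} must lie in [0, 1], got {v}")
        if self.dispersion_range[0] <= 0:
            raise SpecError("dispersion must be positive")
        if self.isoforms_per_gene < 1:
            raise SpecError("need at least 1 isoform per gene")
        total = self.frac_diu + self.frac_dfi + self.frac_dpa + self.frac_utr
        if total > 1.0 + 1e-9:
            raise SpecError("planted fractions sum to more than 1")
        if (total > 0 and self.isoforms_per_gene < 2):
            raise SpecError("planted effects require >= 2 isoforms per gene")


@dataclass
class SimulatedDataset:
    annotation: Annotation
    counts: pd.DataFrame
    design: pd.Series
    truth: pd.DataFrame
    usage: pd.DataFrame = None  # transcript x condition expected usage

    def expression_set(self) -> ExpressionSet:
        return ExpressionSet(values=self.counts, design=self.design)


def _gene_structure(gene_id: str, base: int, k: int, utr_step: int,
                    distinct_cds: bool = False):
    """Build k isoforms sharing exon 1 and the CDS; last exons step in length."""
    exon1 = (base, base + 199)
    transcripts, features = [], {}
    for j in range(k):
        tx_id = f"{gene_id}.{j + 1}"
        last_len = 400 + j * utr_step
        exon2 = (base + 300, base + 300 + last_len - 1)
        start = base + 50 + (30 if distinct_cds and j % 2 == 1 else 0)
        cds = (start, base + 300 + 149)
        transcripts.append(TranscriptModel(
            transcript_id=tx_id, gene_id=gene_id, chrom="chr1", strand="+",
            exons=[exon1, exon2], cds_genomic=cds,
        ))
        feats = [FeatureAnnotation(
            transcript_id=tx_id, category=SHARED_CATEGORY,
            feature_id=f"D{gene_id[1:]}", layer="protein", start=5, end=25,
            source="PFAM", description="shared domain",
        )]
        if j == 0:
            feats.append(FeatureAnnotation(
                transcript_id=tx_id, category=TRACKED_CATEGORY,
                feature_id=f"M{gene_id[1:]}", layer="transcript",
                start=10, end=30, source="sim", description="tracked motif",
            ))
        features[tx_id] = feats
    return GeneModel(gene_id=gene_id, transcripts=transcripts, features=features)


def _usage_vectors(k: int, flip: tuple[float, float] | None, rng) -> tuple[np.ndarray, np.ndarray]:
    """Expected usage per condition; identical for null genes."""
    if flip is None:
        u = rng.dirichlet(np.full(k, 2.0))
        return u, u.copy()
    hi, lo = flip
    if k == 2:
        return np.array([hi, lo]), np.array([lo, hi])
    eps = (1.0 - hi - lo) / (k - 2) if k > 2 else 0.0
    a = np.array([hi, lo] + [eps] * (k - 2))
    b = np.array([lo, hi] + [eps] * (k - 2))
    return a / a.sum(), b / b.sum()


def simulate_dataset(spec: SimulationSpec, out_dir: str | Path | None = None) -> SimulatedDataset:
    """Generate a complete fixture dataset from a :class:`SimulationSpec`.

    Returns in-memory objects; with ``out_dir``, also writes
    ``annotation.txt``, ``counts.tsv``, ``design.tsv`` and ``truth.tsv``.
    """
    rng = np.random.default_rng(spec.seed)
    k = spec.isoforms_per_gene
    conds = spec.conditions
    samples = [f"{c}_{r + 1}" for c in conds for r in range(spec.n_replicates)]
    design = pd.Series(
        {s: s.rsplit("_", 1)[0] for s in samples}, name="condition"
    )
    depth = rng.uniform(*spec.depth_range, size=len(samples))

    n = spec.n_genes
    n_diu = int(round(spec.frac_diu * n))
    n_dfi = int(round(spec.frac_dfi * n))
    n_dpa = int(round(spec.frac_dpa * n))
    n_utr = int(round(spec.frac_utr * n))
    planted = rng.permutation(n)[: n_diu + n_dfi + n_dpa + n_utr]
    flip_of: dict[int, tuple[str, tuple[float, float]]] = {}
    cursor = 0
    for label, count, flip in (
        ("diu", n_diu, spec.diu_flip),
        ("dfi", n_dfi, spec.dfi_flip),
        ("dpa", n_dpa, spec.dpa_flip),
        ("utr", n_utr, spec.utr_flip),
    ):
        for gi in planted[cursor:cursor + count]:
            flip_of[int(gi)] = (label, flip)
        cursor += count

    annotation = Annotation()
    count_rows, truth_rows, usage_rows = [], [], []
    for gi in range(n):
        gene_id = f"G{gi + 1:05d}"
        base = 100_000 * (gi + 1)
        gene = _gene_structure(gene_id, base, k, spec.utr_step,
                               distinct_cds=spec.distinct_cds)
        annotation.genes[gene_id] = gene

        mean = rng.uniform(*spec.mean_range)
        disp = rng.uniform(*spec.dispersion_range)
        label, flip = flip_of.get(gi, (None, None))
        u_a, u_b = _usage_vectors(k, flip, rng)
        usage_by_cond = {conds[0]: u_a, conds[1]: u_b}

        for j, t in enumerate(gene.transcripts):
            row = {"transcript_id": t.transcript_id}
            for si, s in enumerate(samples):
                mu = mean * usage_by_cond[design[s]][j] * depth[si]
                if mu <= 0:
                    row[s] = 0
                else:
                    r = 1.0 / disp
                    row[s] = int(rng.negative_binomial(r, r / (r + mu)))
            count_rows.append(row)
            usage_rows.append({
                "transcript_id": t.transcript_id,
                conds[0]: u_a[j], conds[1]: u_b[j],
            })

        is_planted = label is not None
        expected_change = 100.0 * 0.5 * float(np.abs(u_a - u_b).sum())
        truth_rows.append({
            "gene_id": gene_id,
            "planted_as": label or "null",
            "is_diu": is_planted,
            "is_dfi": is_planted,  # tracked motif follows isoform 1
            "is_dpa": is_planted,  # distinct polyA clusters per isoform
            "is_utr": is_planted,
            "expected_total_change": expected_change,
            "gene_mean": mean,
            "dispersion": disp,
            "tracked_feature": f"M{gi + 1:05d}",
        })

    counts = pd.DataFrame(count_rows).set_index("transcript_id")
    truth = pd.DataFrame(truth_rows).set_index("gene_id")
    usage = pd.DataFrame(usage_rows).set_index("transcript_id")
    ds = SimulatedDataset(annotation=annotation, counts=counts, design=design,
                          truth=truth, usage=usage)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_annotation(annotation, out / "annotation.txt")
        counts.to_csv(out / "counts.tsv", sep="\t")
        design.rename_axis("sample").reset_index().to_csv(
            out / "design.tsv", sep="\t", index=False
        )
        truth.to_csv(out / "truth.tsv", sep="\t")
    return ds


def spec_from_mapping(data: dict) -> SimulationSpec:
    """Build a spec from a flat mapping (e.g. parsed YAML), coercing tuples."""
    kwargs = {}
    for f in SimulationSpec.__dataclass_fields__.values():
        if f.name in data:
            v = data[f.name]
            if isinstance(v, list):
                v = tuple(v)
            kwargs[f.name] = v
    unknown = set(data) - set(SimulationSpec.__dataclass_fields__)
    if unknown:
        raise SpecError(f"unknown simulation keys: {sorted(unknown)}")
    return SimulationSpec(**kwargs)
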