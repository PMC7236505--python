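"""Read and write the isoform annotation dialect; genomic projection; NMD rule.

File dialect (9 tab-separated columns, ``#`` comment lines ignored)::

    <transcript_id> <source> <category> <start> <end> <score> <strand> <frame> <attributes>

Structural rows use ``source = "structural"`` and categories ``genomic``,
``exon``, ``CDS`` and ``polyA`` with genomic coordinates (start <= end) and
attributes ``Chr=...;Strand=...;Gene=...``.  Every other row is a functional
feature in its layer's coordinate space with attributes
``ID=...;Desc=...;Layer=transcript|protein|none``.  Presence-only labels
(layer ``none``) carry placeholder coordinates ``1 1``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import pandas as pd

from isofit.errors import AnnotationParseError, ContractError, CoordinateError, ModelError
from isofit.models import (
    LAYER_NONE,
    LAYER_PROTEIN,
    LAYER_TRANSCRIPT,
    FeatureAnnotation,
    GeneModel,
    TranscriptModel,
)

STRUCTURAL_SOURCE = "structural"
STRUCTURAL_CATEGORIES = frozenset({"genomic", "exon", "CDS", "polyA"})
NMD_CATEGORY = "NMD"


@dataclass
class Annotation:
    """Parsed annotation: gene models plus a flat feature table."""

    genes: dict[str, GeneModel] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def transcripts(self) -> dict[str, TranscriptModel]:
        return {
            t.transcript_id: t for g in self.genes.values() for t in g.transcripts
        }

    def gene_of(self) -> dict[str, str]:
        """transcript_id -> gene_id map."""
        return {
            t.transcript_id: g.gene_id
            for g in self.genes.values()
            for t in g.transcripts
        }

    def all_features(self) -> list[FeatureAnnotation]:
        return [
            f
            for g in self.genes.values()
            for feats in g.features.values()
            for f in feats
        ]

    def feature_table(self) -> pd.DataFrame:
        rows = [
            {
                "transcript_id": f.transcript_id,
                "category": f.category,
                "feature_id": f.feature_id,
                "layer": f.layer,
                "start": f.start,
                "end": f.end,
                "source": f.source,
                "description": f.description,
            }
            for f in self.all_features()
        ]
        cols = [
            "transcript_id", "category", "feature_id", "layer",
            "start", "end", "source", "description",
        ]
        return pd.DataFrame(rows, columns=cols)

    def categories(self) -> list[str]:
        return sorted({f.category for f in self.all_features()})


def _parse_attributes(text: str, lineno: int) -> dict[str, str]:
    out = {}
    for item in text.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            raise AnnotationParseError(f"malformed attribute {item!r}", lineno)
        k, v = item.split("=", 1)
        out[k.strip()] = v.strip()
    return out


@dataclass
class _PendingTranscript:
    transcript_id: str
    chrom: str | None = None
    strand: str | None = None
    gene_id: str | None = None
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: tuple[int, int] | None = None


def parse_annotation(path_or_buffer) -> Annotation:
    """Parse an annotation file into gene models and feature annotations.

    Features referencing unknown transcripts are dropped with a collected
    warning; malformed rows raise :class:`AnnotationParseError` carrying the
    line number; a CDS outside its transcript's exons raises
    :class:`ModelError`.
    """
    if hasattr(path_or_buffer, "read"):
        lines = path_or_buffer.read().splitlines()
    else:
        with open(path_or_buffer, "rt", encoding="utf-8") as fh:
            lines = fh.read().splitlines()

    pending: dict[str, _PendingTranscript] = {}
    raw_features: list[tuple[int, FeatureAnnotation]] = []

    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise AnnotationParseError(
                f"expected 9 tab-separated columns, got {len(cols)}", lineno
            )
        tx_id, source, category, start_s, end_s, _score, strand, _frame, attr_s = cols
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise AnnotationParseError(
                f"non-integer coordinates {start_s!r}/{end_s!r}", lineno
            ) from None
        attrs = _parse_attributes(attr_s, lineno)

        if source == STRUCTURAL_SOURCE:
            if category not in STRUCTURAL_CATEGORIES:
                raise AnnotationParseError(
                    f"unknown structural category {category!r}", lineno
                )
            rec = pending.setdefault(tx_id, _PendingTranscript(tx_id))
            if category == "genomic":
                rec.chrom = attrs.get("Chr", rec.chrom)
                rec.strand = attrs.get("Strand", strand if strand in "+-" else None)
                rec.gene_id = attrs.get("Gene", rec.gene_id)
            elif category == "exon":
                rec.exons.append((start, end))
            elif category == "CDS":
                rec.cds = (start, end)
            # polyA rows are redundant with the exon structure; validated below
        else:
            layer = attrs.get("Layer", LAYER_TRANSCRIPT)
            feat = FeatureAnnotation(
                transcript_id=tx_id,
                category=category,
                feature_id=attrs.get("ID", category),
                layer=layer,
                start=start,
                end=end,
                source=source,
                description=attrs.get("Desc", ""),
            )
            raw_features.append((lineno, feat))

    ann = Annotation()
    for tx_id, rec in pending.items():
        if rec.chrom is None or rec.strand is None or rec.gene_id is None:
            raise ModelError(f"{tx_id}: missing 'genomic' structural record")
        exons = sorted(rec.exons) if rec.strand == "+" else sorted(rec.exons, reverse=True)
        cds = None
        if rec.cds is not None:
            lo, hi = rec.cds
            cds = (lo, hi) if rec.strand == "+" else (hi, lo)
        model = TranscriptModel(
            transcript_id=tx_id,
            gene_id=rec.gene_id,
            chrom=rec.chrom,
            strand=rec.strand,
            exons=exons,
            cds_genomic=cds,
        )
        gene = ann.genes.setdefault(rec.gene_id, GeneModel(gene_id=rec.gene_id))
        gene.transcripts.append(model)

    transcripts = ann.transcripts
    for lineno, feat in raw_features:
        model = transcripts.get(feat.transcript_id)
        if model is None:
            ann.warnings.append(
                f"line {lineno}: feature {feat.feature_id!r} references unknown "
                f"transcript {feat.transcript_id!r}; dropped"
            )
            continue
        if feat.category == NMD_CATEGORY:
            model.is_nmd = True
        gene = ann.genes[model.gene_id]
        gene.features.setdefault(feat.transcript_id, []).append(feat)
    return ann


def write_annotation(ann: Annotation, path_or_buffer=None) -> str | None:
    """Serialize an :class:`Annotation` back to the dialect.

    Record order is normalized (genes, then transcripts, structural rows
    before features) so ``parse -> write -> parse`` is the identity.
    """
    buf = io.StringIO()
    for gene_id in sorted(ann.genes):
        gene = ann.genes[gene_id]
        for t in sorted(gene.transcripts, key=lambda t: t.transcript_id):
            lo = min(a for a, _ in t.exons)
            hi = max(b for _, b in t.exons)
            attrs = f"Chr={t.chrom};Strand={t.strand};Gene={t.gene_id}"
            _row(buf, t.transcript_id, STRUCTURAL_SOURCE, "genomic", lo, hi, t.strand, attrs)
            for a, b in sorted(t.exons):
                _row(buf, t.transcript_id, STRUCTURAL_SOURCE, "exon", a, b, t.strand,
                     f"Chr={t.chrom}")
            if t.cds_genomic is not None:
                c_lo, c_hi = sorted(t.cds_genomic)
                _row(buf, t.transcript_id, STRUCTURAL_SOURCE, "CDS", c_lo, c_hi, t.strand,
                     f"Chr={t.chrom}")
            p = t.polya_pos
            _row(buf, t.transcript_id, STRUCTURAL_SOURCE, "polyA", p, p, t.strand,
                 f"Chr={t.chrom}")
            feats = sorted(
                gene.features_of(t.transcript_id),
                key=lambda f: (f.category, f.feature_id, f.start, f.end),
            )
            for f in feats:
                attrs = f"ID={f.feature_id};Desc={f.description};Layer={f.layer}"
                _row(buf, f.transcript_id, f.source, f.category, f.start, f.end, ".", attrs)
    text = buf.getvalue()
    if path_or_buffer is None:
        return text
    if hasattr(path_or_buffer, "write"):
        path_or_buffer.write(text)
    else:
        with open(path_or_buffer, "wt", encoding="utf-8") as fh:
            fh.write(text)
    return None


def _row(buf, tx, source, category, start, end, strand, attrs):
    buf.write(f"{tx}\t{source}\t{category}\t{start}\t{end}\t.\t{strand}\t.\t{attrs}\n")


# ---------------------------------------------------------------------------
# genomic projection
# ---------------------------------------------------------------------------

def feature_transcript_interval(
    f: FeatureAnnotation, t: TranscriptModel
) -> tuple[int, int]:
    """Feature span in transcript nucleotide coordinates.

    Protein codon ``c`` maps to nucleotides ``[utr5 + 3c - 2, utr5 + 3c]``.
    """
    if f.layer == LAYER_TRANSCRIPT:
        lo, hi = f.start, f.end
    elif f.layer == LAYER_PROTEIN:
        if not t.is_coding:
            raise ContractError(
                f"protein feature {f.feature_id} on non-coding {t.transcript_id}"
            )
        u5 = t.utr5_len
        lo, hi = u5 + 3 * f.start - 2, u5 + 3 * f.end
    else:
        raise ContractError(f"feature {f.feature_id} has no positional layer")
    if lo < 1 or hi > t.length:
        raise CoordinateError(
            f"feature {f.feature_id} spans {lo}..{hi}, outside transcript "
            f"{t.transcript_id} (length {t.length})"
        )
    return lo, hi


def project_feature_to_genomic(
    f: FeatureAnnotation, t: TranscriptModel
) -> list[tuple[int, int]]:
    """Project a positional feature onto genomic coordinates.

    Returns intervals 5'->3' in transcript orientation, split across exon
    boundaries; total projected length equals the feature's layer length in
    nucleotides.
    """
    lo, hi = feature_transcript_interval(f, t)
    intervals: list[tuple[int, int]] = []
    pos = lo
    while pos <= hi:
        g = t.transcript_to_genomic(pos)
        # extent of the run within the current exon
        for (a, b), off in zip(t.exons, t._exon_offsets):
            n = b - a + 1
            if off < pos <= off + n:
                run = min(hi, off + n) - pos + 1
                if t.strand == "+":
                    intervals.append((g, g + run - 1))
                else:
                    intervals.append((g - run + 1, g))
                pos += run
                break
        else:  # pragma: no cover - guarded by feature_transcript_interval
            raise CoordinateError(f"position {pos} unmapped")
    return intervals


# ---------------------------------------------------------------------------
# NMD / PTC prediction (50-nt rule)
# ---------------------------------------------------------------------------

def predict_nmd(t: TranscriptModel, threshold_nt: int = 50) -> bool:
    """Apply the 50-nt rule: a stop codon strictly more than ``threshold_nt``
    nucleotides upstream of the last exon-exon junction marks a premature
    termination codon.  Single-exon transcripts are never flagged.
    """
    if not t.is_coding:
        raise ContractError(f"{t.transcript_id}: NMD prediction requires a CDS")
    junctions = t.junction_positions()
    if not junctions:
        return False
    stop = t.cds_transcript[1]
    return junctions[-1] - stop > threshold_nt
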