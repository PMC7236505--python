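import numpy as np
import pandas as pd
import pytest

from isofit.expression import ExpressionSet
from isofit.models import FeatureAnnotation, GeneModel, TranscriptModel


@pytest.fixture
def design_2x3():
    return pd.Series(
        {"A_1": "A", "A_2": "A", "A_3": "A", "B_1": "B", "B_2": "B", "B_3": "B"}
    )


@pytest.fixture
def single_exon_plus():
    """Single-exon plus-strand transcript on exon 101-200."""
    return TranscriptModel(
        transcript_id="T1", gene_id="G1", chrom="chr1", strand="+",
        exons=[(101, 200)],
    )


@pytest.fixture
def single_exon_minus():
    """Same exon on the minus strand."""
    return TranscriptModel(
        transcript_id="T1m", gene_id="G1", chrom="chr1", strand="-",
        exons=[(101, 200)],
    )


@pytest.fixture
def two_exon_plus():
    """Exons 1-50 and 101-150 (plus strand)."""
    return TranscriptModel(
        transcript_id="T2", gene_id="G2", chrom="chr1", strand="+",
        exons=[(1, 50), (101, 150)],
    )


def make_gene(gene_id, transcripts, features=None):
    feats = {}
    for f in features or []:
        feats.setdefault(f.transcript_id, []).append(f)
    return GeneModel(gene_id=gene_id, transcripts=transcripts, features=feats)


def tfeat(tx, start, end, feature_id="F1", category="MOTIF", layer="transcript"):
    return FeatureAnnotation(
        transcript_id=tx, category=category, feature_id=feature_id,
        layer=layer, start=start, end=end,
    )


def expr_from_means(means_by_condition, design, noise=None, index=None):
    """ExpressionSet whose replicate columns equal the given condition means."""
    cols = {}
    for s, cond in design.items():
        cols[s] = np.asarray(means_by_condition[cond], dtype=float)
    values = pd.DataFrame(cols, index=index)
    return ExpressionSet(values=values, design=design)


def random_transcript(rng, transcript_id="TX", gene_id="GX"):
    """Random multi-exon transcript for projection property tests."""
    strand = rng.choice(["+", "-"])
    n_exons = int(rng.integers(1, 5))
    pos = int(rng.integers(1, 1000))
    exons = []
    for _ in range(n_exons):
        length = int(rng.integers(3, 60))
        exons.append((pos, pos + length - 1))
        pos += length + int(rng.integers(10, 50))
    if strand == "-":
        exons = exons[::-1]
    return TranscriptModel(
        transcript_id=transcript_id, gene_id=gene_id, chrom="chr1",
        strand=strand, exons=exons,
    )
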