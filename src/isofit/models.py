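"""Domain types: transcript structure, positional features, gene models.

Coordinate conventions
----------------------
* Genomic and transcript coordinates are 1-based and inclusive.
* Protein coordinates are 1-based codons.
* Exons are stored 5'->3' in *transcript* orientation: ascending genomic
  position on the plus strand, descending on the minus strand.  Each exon is
  a ``(start, end)`` genomic pair with ``start <= end``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

from isofit.errors import ContractError, CoordinateError, ModelError

# Layer a feature's coordinates live in.
LAYER_TRANSCRIPT = "transcript"
LAYER_PROTEIN = "protein"
LAYER_NONE = "none"
VALID_LAYERS = frozenset({LAYER_TRANSCRIPT, LAYER_PROTEIN, LAYER_NONE})


@dataclass(frozen=True)
class FeatureAnnotation:
    """One positional functional label attached to one transcript."""

    transcript_id: str
    category: str
    feature_id: str
    layer: str
    start: int
    end: int
    source: str = "."
    description: str = ""

    def __post_init__(self):
        if self.layer not in VALID_LAYERS:
            raise ModelError(f"unknown layer {self.layer!r} on {self.transcript_id}")
        if self.layer != LAYER_NONE and self.start > self.end:
            raise ModelError(
                f"feature {self.feature_id} on {self.transcript_id}: start > end"
            )

    @property
    def positional(self) -> bool:
        return self.layer != LAYER_NONE

    def length_nt(self) -> int:
        """Feature length in nucleotides of its layer."""
        n = self.end - self.start + 1
        return 3 * n if self.layer == LAYER_PROTEIN else n


@dataclass
class TranscriptModel:
    """Structure of one isoform: exons, CDS, UTRs, polyA site, NMD flag."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_genomic: tuple[int, int] | None = None  # (start-codon 1st base, stop-codon last base)
    is_nmd: bool = False

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ModelError(f"{self.transcript_id}: strand must be '+' or '-'")
        if not self.exons:
            raise ModelError(f"{self.transcript_id}: no exons")
        for a, b in self.exons:
            if a > b:
                raise ModelError(f"{self.transcript_id}: exon start > end")
        key = [e[0] for e in self.exons]
        ordered = key == sorted(key) if self.strand == "+" else key == sorted(key, reverse=True)
        if not ordered:
            raise ModelError(f"{self.transcript_id}: exons not in transcript orientation")
        spans = sorted(self.exons)
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            if a2 <= b1:
                raise ModelError(f"{self.transcript_id}: overlapping exons")
        if self.cds_genomic is not None:
            c5, c3 = self.cds_genomic
            try:
                t5, t3 = self.genomic_to_transcript(c5), self.genomic_to_transcript(c3)
            except CoordinateError as exc:
                raise ModelError(f"{self.transcript_id}: CDS outside exons") from exc
            if t5 > t3:
                raise ModelError(f"{self.transcript_id}: CDS start downstream of CDS end")

    # -- basic geometry ----------------------------------------------------

    @property
    def length(self) -> int:
        return sum(b - a + 1 for a, b in self.exons)

    @property
    def is_coding(self) -> bool:
        return self.cds_genomic is not None

    @property
    def polya_pos(self) -> int:
        """Genomic coordinate of the transcript's 3'-most base."""
        a, b = self.exons[-1]
        return b if self.strand == "+" else a

    @cached_property
    def _exon_offsets(self) -> list[int]:
        # transcript coordinate of the first base of each exon, minus one
        offs, acc = [], 0
        for a, b in self.exons:
            offs.append(acc)
            acc += b - a + 1
        return offs

    def transcript_to_genomic(self, pos: int) -> int:
        """Map a 1-based transcript position to its genomic coordinate."""
        if pos < 1 or pos > self.length:
            raise CoordinateError(
                f"{self.transcript_id}: transcript position {pos} outside 1..{self.length}"
            )
        for (a, b), off in zip(self.exons, self._exon_offsets):
            n = b - a + 1
            if pos <= off + n:
                i = pos - off - 1
                return a + i if self.strand == "+" else b - i
        raise AssertionError("unreachable")

    def genomic_to_transcript(self, gpos: int) -> int:
        """Map a genomic coordinate on an exon to its transcript position."""
        for (a, b), off in zip(self.exons, self._exon_offsets):
            if a <= gpos <= b:
                i = gpos - a if self.strand == "+" else b - gpos
                return off + i + 1
        raise CoordinateError(
            f"{self.transcript_id}: genomic position {gpos} not exonic"
        )

    # -- CDS / UTR ---------------------------------------------------------

    @property
    def cds_transcript(self) -> tuple[int, int]:
        """CDS span in transcript coordinates (start-codon base, stop-codon base)."""
        if not self.is_coding:
            raise ContractError(f"{self.transcript_id}: non-coding transcript")
        c5, c3 = self.cds_genomic
        return self.genomic_to_transcript(c5), self.genomic_to_transcript(c3)

    @property
    def cds_len(self) -> int:
        t5, t3 = self.cds_transcript
        return t3 - t5 + 1

    @property
    def utr5_len(self) -> int:
        return self.cds_transcript[0] - 1 if self.is_coding else 0

    @property
    def utr3_len(self) -> int:
        return self.length - self.cds_transcript[1] if self.is_coding else 0

    def cds_genomic_intervals(self) -> list[tuple[int, int]]:
        """Exonic genomic intervals covered by the CDS, sorted ascending."""
        if not self.is_coding:
            raise ContractError(f"{self.transcript_id}: non-coding transcript")
        lo, hi = sorted(self.cds_genomic)
        out = [
            (max(a, lo), min(b, hi))
            for a, b in sorted(self.exons)
            if max(a, lo) <= min(b, hi)
        ]
        return out

    def junction_positions(self) -> list[int]:
        """Transcript coordinate of the last base before each exon-exon junction."""
        acc, out = 0, []
        for a, b in self.exons[:-1]:
            acc += b - a + 1
            out.append(acc)
        return out


@dataclass
class GeneModel:
    """All isoforms of one gene plus their positional feature annotations."""

    gene_id: str
    transcripts: list[TranscriptModel] = field(default_factory=list)
    features: dict[str, list[FeatureAnnotation]] = field(default_factory=dict)

    def __post_init__(self):
        for t in self.transcripts:
            if t.gene_id != self.gene_id:
                raise ModelError(
                    f"transcript {t.transcript_id} has gene {t.gene_id}, expected {self.gene_id}"
                )

    @property
    def transcript_ids(self) -> list[str]:
        return [t.transcript_id for t in self.transcripts]

    def transcript(self, transcript_id: str) -> TranscriptModel:
        for t in self.transcripts:
            if t.transcript_id == transcript_id:
                return t
        raise KeyError(transcript_id)

    def features_of(self, transcript_id: str) -> list[FeatureAnnotation]:
        return self.features.get(transcript_id, [])

    @property
    def is_multi_isoform(self) -> bool:
        return len(self.transcripts) >= 2
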