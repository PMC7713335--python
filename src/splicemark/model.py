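"""Reference genome and transcript-model handling.

All internal coordinates are 0-based, half-open, on the forward genomic
strand.  GTF input (1-based, inclusive) is converted at the I/O boundary.
Exon and intron ordinals are numbered in *transcription* order, so EXON1
is always the 5'-most exon of the transcript regardless of strand.

Exon phase follows the Ensembl convention: the codon position of the
exon's first transcribed base (0 = the exon starts a fresh codon), with
-1 for noncoding or unknown.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "ExonRegion",
    "IntronRegion",
    "TranscriptModel",
    "TranscriptIndex",
    "read_genome",
    "read_annotation",
    "derive_introns",
    "extract_sequence",
    "revcomp",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def intersection_width(self, other: "GenomicInterval") -> int:
        """Width of the overlap with ``other``; 0 on different chromosomes."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class ExonRegion:
    """One exon of a transcript; ``index`` is 1-based in transcription order."""

    interval: GenomicInterval
    index: int
    phase: int = -1

    kind = "exon"

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError("exon index is 1-based")
        if self.phase not in (-1, 0, 1, 2):
            raise ValueError(f"invalid exon phase {self.phase}")

    @property
    def label(self) -> str:
        return f"EXON{self.index}"


@dataclass(frozen=True)
class IntronRegion:
    """One intron; intron k lies between exons k and k+1 in transcription order."""

    interval: GenomicInterval
    index: int

    kind = "intron"

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError("intron index is 1-based")

    @property
    def label(self) -> str:
        return f"INTRON{self.index}"


def derive_introns(
    exons: list[ExonRegion], strand: str, chrom: str
) -> list[IntronRegion]:
    """Introns as the gaps between genomically adjacent exons.

    Returned in transcription order.  A zero-width gap between adjacent
    exons indicates a malformed model and raises ``ValueError``.
    """
    if len(exons) < 2:
        return []
    by_genome = sorted(exons, key=lambda e: e.interval.start)
    n = len(by_genome)
    introns: list[IntronRegion] = []
    for j in range(n - 1):
        left, right = by_genome[j], by_genome[j + 1]
        if left.interval.end >= right.interval.start:
            raise ValueError(
                f"exons {left.label} and {right.label} on {chrom} are adjacent "
                "with no intervening intron (zero gap or overlap)"
            )
        tx_index = j + 1 if strand == "+" else n - j - 1
        introns.append(
            IntronRegion(
                interval=GenomicInterval(
                    chrom, left.interval.end, right.interval.start, strand
                ),
                index=tx_index,
            )
        )
    introns.sort(key=lambda i: i.index)
    return introns


@dataclass
class TranscriptModel:
    """Ordered exon/intron structure of one transcript."""

    transcript_id: str
    gene_id: str
    strand: str
    exons: list[ExonRegion]
    gene_name: str = ""
    introns: list[IntronRegion] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        indices = [e.index for e in self.exons]
        if indices != list(range(1, len(self.exons) + 1)):
            raise ValueError(
                f"transcript {self.transcript_id}: exon indices not consecutive from 1"
            )
        if not self.introns:
            self.introns = derive_introns(self.exons, self.strand, self.chrom)

    @property
    def chrom(self) -> str:
        return self.exons[0].interval.chrom

    @property
    def spliced_length(self) -> int:
        return sum(e.interval.width for e in self.exons)

    @property
    def span(self) -> GenomicInterval:
        start = min(e.interval.start for e in self.exons)
        end = max(e.interval.end for e in self.exons)
        return GenomicInterval(self.chrom, start, end, self.strand)

    @property
    def regions(self) -> list[ExonRegion | IntronRegion]:
        """All exons and introns of the transcript."""
        return [*self.exons, *self.introns]

    def region_by_label(self, label: str) -> ExonRegion | IntronRegion:
        for r in self.regions:
            if r.label == label:
                return r
        raise KeyError(
            f"transcript {self.transcript_id} has no region {label!r}"
        )


class TranscriptIndex:
    """Per-chromosome interval index over transcript spans."""

    def __init__(self, transcripts: list[TranscriptModel]):
        self.transcripts = {t.transcript_id: t for t in transcripts}
        self._trees: dict[str, IntervalTree] = {}
        for t in transcripts:
            tree = self._trees.setdefault(t.chrom, IntervalTree())
            tree.addi(t.span.start, t.span.end, t.transcript_id)

    def candidates(self, chrom: str, start: int, end: int) -> list[TranscriptModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = sorted({iv.data for iv in tree.overlap(start, end)})
        return [self.transcripts[tid] for tid in hits]

    def __getitem__(self, transcript_id: str) -> TranscriptModel:
        return self.transcripts[transcript_id]

    def __iter__(self):
        return iter(self.transcripts.values())

    def __len__(self) -> int:
        return len(self.transcripts)


def read_genome(path) -> dict[str, str]:
    """Load a FASTA genome into an id -> uppercase sequence mapping.

    Record ids are kept verbatim up to the first whitespace.  Duplicate
    ids and empty files are errors.
    """
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise ValueError(f"duplicate FASTA record id {rec.id!r} in {path}")
        genome[rec.id] = str(rec.seq).upper()
    if not genome:
        raise ValueError(f"no FASTA records found in {path}")
    return genome


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def extract_sequence(genome: dict[str, str], interval: GenomicInterval) -> str:
    """Slice of the genome for ``interval``, reverse-complemented on '-'."""
    if interval.chrom not in genome:
        raise KeyError(f"chromosome {interval.chrom!r} not in genome")
    chrom_seq = genome[interval.chrom]
    if interval.end > len(chrom_seq):
        raise ValueError(
            f"interval {interval.chrom}:{interval.start}-{interval.end} exceeds "
            f"chromosome length {len(chrom_seq)}"
        )
    seq = chrom_seq[interval.start : interval.end]
    return revcomp(seq) if interval.strand == "-" else seq


def read_annotation(path, phase_attr: str = "exon_phase") -> list[TranscriptModel]:
    """Load transcript models from a GTF file.

    Exon features are grouped by ``transcript_id`` and sorted into
    transcription order (ascending genomic coordinates on '+', descending
    on '-').  GTF 1-based inclusive coordinates become 0-based half-open.
    Exon phase is read from the ``phase_attr`` attribute when present;
    absent phase is stored as -1.  Exons lacking a transcript_id are
    skipped with a warning; overlapping exons within one transcript are
    an error.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    raw: dict[str, dict] = {}
    for feat in db.features_of_type("exon"):
        tid = feat.attributes.get("transcript_id", [None])[0]
        if tid is None:
            log.warning(
                "skipping exon %s:%d-%d without transcript_id",
                feat.seqid, feat.start, feat.end,
            )
            continue
        entry = raw.setdefault(
            tid,
            {
                "gene_id": feat.attributes.get("gene_id", [""])[0],
                "gene_name": feat.attributes.get("gene_name", [""])[0],
                "strand": feat.strand,
                "chrom": feat.seqid,
                "exons": [],
            },
        )
        phase_val = feat.attributes.get(phase_attr, ["-1"])[0]
        try:
            phase = int(phase_val)
        except ValueError:
            phase = -1
        # GTF is 1-based inclusive.
        entry["exons"].append((feat.start - 1, feat.end, phase))

    transcripts: list[TranscriptModel] = []
    for tid, entry in raw.items():
        strand = entry["strand"] if entry["strand"] in ("+", "-") else "+"
        coords = sorted(entry["exons"])
        for (s1, e1, _), (s2, e2, _) in zip(coords, coords[1:]):
            if s2 < e1:
                raise ValueError(
                    f"transcript {tid}: overlapping exons "
                    f"[{s1},{e1}) and [{s2},{e2})"
                )
        ordered = coords if strand == "+" else coords[::-1]
        exons = [
            ExonRegion(
                interval=GenomicInterval(entry["chrom"], s, e, strand),
                index=i + 1,
                phase=p,
            )
            for i, (s, e, p) in enumerate(ordered)
        ]
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=entry["gene_id"],
                gene_name=entry["gene_name"],
                strand=strand,
                exons=exons,
            )
        )
    transcripts.sort(key=lambda t: t.transcript_id)
    return transcripts
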