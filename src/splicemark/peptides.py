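"""Junction-peptide database construction.

Each selected splicing event is turned into a short synthesized
transcript: for two-region (junction) events the last 120 nt of the
5' region are concatenated with the first 120 nt of the 3' region
(<= 240 nt total); single-region events contribute their first 120 nt.
The 120-nt flank reflects the length of peptides observable after
tryptic digestion in MS/MS.

Translation frame comes from the Ensembl exon phase when the event's
leading region is a phase-annotated exon; otherwise all three frames
are translated and the frame containing the longest stop-free peptide
is kept.  Decoy entries are per-record sequence reversals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio.Seq import Seq

from .junctions import AnnotatedEvent
from .model import TranscriptIndex, extract_sequence

log = logging.getLogger(__name__)

DECOY_PREFIX = "DECOY_"

__all__ = [
    "SplicingEventSequence",
    "AsPeptideRecord",
    "synthesize_event_sequence",
    "infer_frame_from_phase",
    "translate_longest",
    "build_peptide_records",
    "build_decoy",
    "write_fasta",
    "parse_accession",
    "junction_notation",
]


@dataclass
class SplicingEventSequence:
    """Synthesized nucleotide sequence around one splicing event."""

    event_id: str
    category: str
    nt_sequence: str
    junction_offset: int | None = None  # splice boundary; None for 1-region
    left_truncated: bool = False
    right_truncated: bool = False


@dataclass
class AsPeptideRecord:
    """A translated splicing-event peptide with a traceable FASTA header."""

    event_id: str
    category: str
    gene_id: str
    transcript_id: str
    frame: int
    frame_source: str  # "phase" or "3frame"
    peptide: str
    header: str
    nt_start: int = 0          # offset of the peptide's first base in nt_sequence
    junction_offset: int | None = None

    @property
    def spans_junction(self) -> bool | None:
        """Whether the peptide's codons cross the splice boundary."""
        if self.junction_offset is None:
            return None
        rel = self.junction_offset - self.nt_start
        return 0 < rel < 3 * len(self.peptide)


def synthesize_event_sequence(
    event: AnnotatedEvent,
    transcripts: TranscriptIndex,
    genome: dict[str, str],
    flank: int = 120,
) -> SplicingEventSequence:
    """Synthesize the flanking nucleotide sequence for one event.

    Two-region events: last min(flank, |left|) nt of the left region +
    first min(flank, |right|) nt of the right region, both in
    transcription orientation.  Single-region events: the region's first
    min(flank, |region|) nt.  Truncation flags mark regions shorter than
    the flank.
    """
    tx = transcripts[event.transcript_id]
    left = tx.region_by_label(event.left_label)
    left_seq = extract_sequence(genome, left.interval)
    if event.right_label is None:
        take = min(flank, len(left_seq))
        return SplicingEventSequence(
            event_id=event.event_id,
            category=event.category,
            nt_sequence=left_seq[:take],
            junction_offset=None,
            left_truncated=len(left_seq) < flank,
        )
    right = tx.region_by_label(event.right_label)
    right_seq = extract_sequence(genome, right.interval)
    left_part = left_seq[-min(flank, len(left_seq)):]
    right_part = right_seq[:min(flank, len(right_seq))]
    return SplicingEventSequence(
        event_id=event.event_id,
        category=event.category,
        nt_sequence=left_part + right_part,
        junction_offset=len(left_part),
        left_truncated=len(left_seq) < flank,
        right_truncated=len(right_seq) < flank,
    )


def infer_frame_from_phase(
    phase: int, flank_start_offset_in_exon: int
) -> int | None:
    """Translation frame of a flank starting inside a phase-annotated exon.

    Ensembl phase is the codon position of the exon's first base, so the
    flank's first base sits at codon position (phase + offset) mod 3 and
    translation must skip (3 - position) mod 3 bases.  Phase -1 (unknown/
    noncoding) yields None, signalling three-frame translation.
    """
    if phase == -1:
        return None
    if phase not in (0, 1, 2):
        raise ValueError(f"invalid phase {phase}")
    codon_position = (phase + flank_start_offset_in_exon) % 3
    return (3 - codon_position) % 3


def translate_longest(
    nt_sequence: str, frames: tuple[int, ...] = (0, 1, 2)
) -> tuple[str, int, int]:
    """Longest stop-free peptide over the requested reading frames.

    Each frame is translated with the standard genetic code and split at
    stop codons; the single longest fragment wins.  Ties go to the lowest
    frame index, then the earliest start.  Returns (peptide, frame,
    nt_start) where nt_start is the offset of the peptide's first base in
    ``nt_sequence``; the peptide may be empty.
    """
    if not frames or any(f not in (0, 1, 2) for f in frames):
        raise ValueError(f"frames must be a nonempty subset of {{0,1,2}}: {frames}")
    best = ("", min(frames), min(frames))
    for frame in sorted(frames):
        sub = nt_sequence[frame:]
        usable = sub[: len(sub) - len(sub) % 3]
        if not usable:
            continue
        aa = str(Seq(usable).translate())
        pos = 0
        for fragment in aa.split("*"):
            if len(fragment) > len(best[0]):
                best = (fragment, frame, frame + 3 * pos)
            pos += len(fragment) + 1
    return best


def _frame_plan(
    event: AnnotatedEvent,
    transcripts: TranscriptIndex,
    seq: SplicingEventSequence,
    flank: int,
) -> tuple[tuple[int, ...], str]:
    """Frames to translate and their provenance for one event."""
    tx = transcripts[event.transcript_id]
    left = tx.region_by_label(event.left_label)
    if left.kind != "exon" or left.phase == -1:
        return (0, 1, 2), "3frame"
    if seq.junction_offset is None:
        offset = 0  # single-region flank starts at the exon's first base
    else:
        offset = left.interval.width - seq.junction_offset
    frame = infer_frame_from_phase(left.phase, offset)
    return (frame,), "phase"


def build_peptide_records(
    events: list[AnnotatedEvent],
    transcripts: TranscriptIndex,
    genome: dict[str, str],
    flank: int = 120,
    min_peptide_len: int = 6,
) -> list[AsPeptideRecord]:
    """Synthesize, translate and package every event into a DB record.

    Records whose best peptide is shorter than ``min_peptide_len`` amino
    acids (below tryptic detectability) are dropped with a logged count.
    """
    records: list[AsPeptideRecord] = []
    dropped = 0
    for event in events:
        seq = synthesize_event_sequence(event, transcripts, genome, flank)
        frames, source = _frame_plan(event, transcripts, seq, flank)
        peptide, frame, nt_start = translate_longest(seq.nt_sequence, frames)
        if len(peptide) < min_peptide_len:
            dropped += 1
            continue
        header = (
            f"AS|{event.event_id}|{event.category}|{event.gene_id}|"
            f"{event.transcript_id}|frame={frame}|src={source}"
        )
        records.append(
            AsPeptideRecord(
                event_id=event.event_id,
                category=event.category,
                gene_id=event.gene_id,
                transcript_id=event.transcript_id,
                frame=frame,
                frame_source=source,
                peptide=peptide,
                header=header,
                nt_start=nt_start,
                junction_offset=seq.junction_offset,
            )
        )
    if dropped:
        log.info(
            "dropped %d event(s) translating below %d aa", dropped, min_peptide_len
        )
    return records


def build_decoy(records: list[AsPeptideRecord]) -> list[AsPeptideRecord]:
    """Per-record reversed-sequence decoys (headers prefixed DECOY_)."""
    decoys = []
    for rec in records:
        reversed_pep = rec.peptide[::-1]
        if reversed_pep == rec.peptide:
            log.warning(
                "palindromic peptide %s: decoy identical to target", rec.event_id
            )
        decoys.append(
            AsPeptideRecord(
                event_id=rec.event_id,
                category=rec.category,
                gene_id=rec.gene_id,
                transcript_id=rec.transcript_id,
                frame=rec.frame,
                frame_source=rec.frame_source,
                peptide=reversed_pep,
                header=DECOY_PREFIX + rec.header,
                nt_start=rec.nt_start,
                junction_offset=rec.junction_offset,
            )
        )
    return decoys


def write_fasta(records: list[AsPeptideRecord], path) -> None:
    """Write peptide records as FASTA; duplicate headers are an error."""
    seen = set()
    for rec in records:
        if rec.header in seen:
            raise ValueError(f"duplicate FASTA header {rec.header!r}")
        seen.add(rec.header)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.header}\n{rec.peptide}\n")


def parse_accession(accession: str) -> dict[str, str]:
    """Recover event provenance from a database header.

    Accepts target and DECOY_ headers.  The event_id itself contains the
    field separator, so it is reassembled from its four components.
    """
    acc = accession
    is_decoy = acc.startswith(DECOY_PREFIX)
    if is_decoy:
        acc = acc[len(DECOY_PREFIX):]
    parts = acc.split("|")
    if len(parts) != 10 or parts[0] != "AS":
        raise ValueError(f"unparseable accession {accession!r}")
    return {
        "event_id": "|".join(parts[1:5]),
        "category": parts[5],
        "gene_id": parts[6],
        "transcript_id": parts[7],
        "frame": parts[8].removeprefix("frame="),
        "frame_source": parts[9].removeprefix("src="),
        "is_decoy": is_decoy,
    }


def junction_notation(record: AsPeptideRecord) -> str:
    """Report notation marking the splice site within the peptide.

    '^' separates residues encoded entirely left/right of the junction;
    '(X)' marks a residue whose codon spans it.  Peptides not crossing
    the junction (or from single-region events) are returned unchanged.
    """
    pep = record.peptide
    if record.junction_offset is None:
        return pep
    rel = record.junction_offset - record.nt_start
    if not 0 < rel < 3 * len(pep):
        return pep
    idx, within = divmod(rel, 3)
    if within == 0:
        return pep[:idx] + "^" + pep[idx:]
    return pep[:idx] + "(" + pep[idx] + ")" + pep[idx + 1:]
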