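"""Splice-junction observation parsing, annotation and merging.

A junction-spanning read is represented by its two aligned blocks (BED12,
two blocks, score = supporting read count); exon/intron coverage evidence
("first category") comes in as one-block region records.  Each block is
assigned to the exon or intron of a candidate transcript that maximizes
the overlap rate

    overlap_rate(A, B) = |A intersect B| / |A|

(A = the block, so the rate is asymmetric), subject to a 90% minimum.
Observations whose blocks all pass on a transcript become one of six
event categories:

    EXON_NM    single exon                     (normal)
    INTRON_AS  single intron                   (intron retention)
    I_E_AS     intron then exon                (left intron retention)
    E_I_AS     exon then intron                (right intron retention)
    E_E_NM     neighboring exon-exon junction  (normal splicing)
    E_E_AS     non-neighboring exon-exon       (exon skipping)

left/right are in transcription order, so categories read 5' to 3' on
either strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .model import (
    ExonRegion,
    GenomicInterval,
    IntronRegion,
    TranscriptIndex,
    TranscriptModel,
)

log = logging.getLogger(__name__)

CATEGORIES = ("EXON_NM", "E_E_NM", "E_I_AS", "I_E_AS", "E_E_AS", "INTRON_AS")

__all__ = [
    "CATEGORIES",
    "JunctionObservation",
    "AnnotatedEvent",
    "parse_junction_bed",
    "parse_region_tsv",
    "overlap_rate",
    "classify_junction",
    "merge_observations",
    "filter_min_support",
    "counts_matrix",
    "summarize_categories",
    "events_to_frame",
    "events_from_frame",
]


@dataclass
class JunctionObservation:
    """One observed junction (two blocks) or covered region (one block)."""

    sample_id: str
    chrom: str
    blocks: tuple[GenomicInterval, ...]
    read_count: int

    def __post_init__(self) -> None:
        if len(self.blocks) not in (1, 2):
            raise ValueError("observation must have 1 or 2 blocks")
        if self.read_count < 0:
            raise ValueError("read_count must be non-negative")
        if len(self.blocks) == 2 and self.blocks[0].end > self.blocks[1].start:
            raise ValueError("junction blocks must be disjoint and ordered")


@dataclass
class AnnotatedEvent:
    """A junction assigned to regions of one transcript, with sample counts."""

    event_id: str
    category: str
    gene_id: str
    transcript_id: str
    left_label: str
    right_label: str | None = None
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())


def make_event_id(
    category: str, transcript_id: str, left_label: str, right_label: str | None
) -> str:
    return "|".join([category, transcript_id, left_label, right_label or "-"])


def parse_junction_bed(path, sample_id: str) -> list[JunctionObservation]:
    """Parse a BED12 junction track (two blocks, score = read count)."""
    out: list[JunctionObservation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 BED fields, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                chrom_start = int(fields[1])
                score = int(float(fields[4]))
                block_count = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED line: {exc}")
            if block_count != 2 or len(sizes) != 2 or len(starts) != 2:
                log.warning(
                    "%s:%d: skipping record with blockCount=%d (expected 2)",
                    path, lineno, block_count,
                )
                continue
            blocks = tuple(
                GenomicInterval(chrom, chrom_start + bs, chrom_start + bs + sz)
                for bs, sz in zip(starts, sizes)
            )
            out.append(
                JunctionObservation(
                    sample_id=sample_id,
                    chrom=chrom,
                    blocks=blocks,
                    read_count=score,
                )
            )
    return out


def parse_region_tsv(path, sample_id: str) -> list[JunctionObservation]:
    """Parse one-block coverage records (chrom, start, end, read_count)."""
    out: list[JunctionObservation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0] == "chrom":
                continue
            if len(fields) < 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 4 columns, got {len(fields)}"
                )
            chrom, start, end, count = fields[0], int(fields[1]), int(fields[2]), int(fields[3])
            if count < 0:
                raise ValueError(f"{path}:{lineno}: negative read count {count}")
            out.append(
                JunctionObservation(
                    sample_id=sample_id,
                    chrom=chrom,
                    blocks=(GenomicInterval(chrom, start, end),),
                    read_count=count,
                )
            )
    return out


def overlap_rate(block: GenomicInterval, region: GenomicInterval) -> float:
    """|block ∩ region| / |block|; 0 when on different chromosomes."""
    return block.intersection_width(region) / block.width


def _best_region(
    block: GenomicInterval, transcript: TranscriptModel, min_overlap: float
) -> ExonRegion | IntronRegion | None:
    """Region of ``transcript`` maximizing overlap_rate with ``block``.

    Ties are broken deterministically: exon before intron, then lower
    region index.  Returns None when no region reaches ``min_overlap``.
    """
    best = None
    best_key = None
    for region in transcript.regions:
        rate = overlap_rate(block, region.interval)
        key = (-rate, 0 if region.kind == "exon" else 1, region.index)
        if best_key is None or key < best_key:
            best, best_key = region, key
    if best is None or -best_key[0] < min_overlap:
        return None
    return best


def _categorize(
    left: ExonRegion | IntronRegion, right: ExonRegion | IntronRegion | None
) -> str | None:
    if right is None:
        return "EXON_NM" if left.kind == "exon" else "INTRON_AS"
    kinds = (left.kind, right.kind)
    if kinds == ("exon", "exon"):
        return "E_E_NM" if abs(left.index - right.index) == 1 else "E_E_AS"
    if kinds == ("intron", "exon"):
        return "I_E_AS"
    if kinds == ("exon", "intron"):
        return "E_I_AS"
    return None  # intron-intron has no category; treated as unannotated


def classify_junction(
    obs: JunctionObservation,
    transcripts: TranscriptIndex,
    min_overlap: float = 0.90,
) -> list[AnnotatedEvent]:
    """Annotate one observation against every candidate transcript.

    Every block must individually reach ``min_overlap`` on the same
    transcript; otherwise the observation is unannotated for that
    transcript.  One event is produced per transcript the observation
    annotates to (an empty list signals an unannotated junction).
    """
    span_start = min(b.start for b in obs.blocks)
    span_end = max(b.end for b in obs.blocks)
    events: list[AnnotatedEvent] = []
    for tx in transcripts.candidates(obs.chrom, span_start, span_end):
        assigned = []
        for block in obs.blocks:
            best = _best_region(block, tx, min_overlap)
            if best is None:
                break
            assigned.append(best)
        if len(assigned) != len(obs.blocks):
            continue
        if len(assigned) == 2 and tx.strand == "-":
            # blocks are genomic-left/right; flip into transcription order
            assigned = assigned[::-1]
        left = assigned[0]
        right = assigned[1] if len(assigned) == 2 else None
        category = _categorize(left, right)
        if category is None:
            continue
        events.append(
            AnnotatedEvent(
                event_id=make_event_id(
                    category, tx.transcript_id, left.label,
                    right.label if right else None,
                ),
                category=category,
                gene_id=tx.gene_id,
                transcript_id=tx.transcript_id,
                left_label=left.label,
                right_label=right.label if right else None,
                counts={obs.sample_id: obs.read_count},
            )
        )
    return events


def merge_observations(
    events: list[AnnotatedEvent], samples: list[str] | None = None
) -> list[AnnotatedEvent]:
    """Merge per-observation events by event_id, summing per-sample counts.

    When ``samples`` is given, every merged event carries a count for every
    sample (0 when absent).  A category conflict for one event_id indicates
    a key collision and is an error.
    """
    merged: dict[str, AnnotatedEvent] = {}
    for ev in events:
        if ev.event_id not in merged:
            merged[ev.event_id] = AnnotatedEvent(
                event_id=ev.event_id,
                category=ev.category,
                gene_id=ev.gene_id,
                transcript_id=ev.transcript_id,
                left_label=ev.left_label,
                right_label=ev.right_label,
                counts={},
            )
        tgt = merged[ev.event_id]
        if tgt.category != ev.category:
            raise ValueError(
                f"event_id collision: {ev.event_id} seen with categories "
                f"{tgt.category} and {ev.category}"
            )
        for sid, n in ev.counts.items():
            tgt.counts[sid] = tgt.counts.get(sid, 0) + n
    if samples is not None:
        for ev in merged.values():
            for sid in samples:
                ev.counts.setdefault(sid, 0)
    return [merged[k] for k in sorted(merged)]


def filter_min_support(
    events: list[AnnotatedEvent], min_reads: int = 6, scope: str = "pooled"
) -> list[AnnotatedEvent]:
    """Keep events with enough supporting reads.

    scope="pooled": total reads across all samples >= min_reads.
    scope="per-sample": at least one sample alone reaches min_reads.
    """
    if scope == "pooled":
        return [ev for ev in events if ev.total_reads >= min_reads]
    if scope == "per-sample":
        return [
            ev for ev in events
            if ev.counts and max(ev.counts.values()) >= min_reads
        ]
    raise ValueError(f"unknown support scope {scope!r}")


def counts_matrix(events: list[AnnotatedEvent], samples: list[str]) -> pd.DataFrame:
    """Event x sample read-count matrix (missing cells are 0)."""
    data = {
        ev.event_id: [ev.counts.get(s, 0) for s in samples] for ev in events
    }
    return pd.DataFrame.from_dict(
        data, orient="index", columns=list(samples)
    ).rename_axis("event_id")


def summarize_categories(events: list[AnnotatedEvent]) -> dict[str, int]:
    """Per-category event counts plus their total (the ledger row)."""
    summary = {cat: 0 for cat in CATEGORIES}
    for ev in events:
        summary[ev.category] += 1
    summary["Total"] = len(events)
    return summary


def events_to_frame(
    events: list[AnnotatedEvent], samples: list[str]
) -> pd.DataFrame:
    """Tabular event representation with per-sample count columns."""
    rows = []
    for ev in events:
        row = {
            "event_id": ev.event_id,
            "category": ev.category,
            "gene_id": ev.gene_id,
            "transcript_id": ev.transcript_id,
            "left_region": ev.left_label,
            "right_region": ev.right_label or "-",
        }
        for s in samples:
            row[s] = ev.counts.get(s, 0)
        rows.append(row)
    cols = [
        "event_id", "category", "gene_id", "transcript_id",
        "left_region", "right_region", *samples,
    ]
    return pd.DataFrame(rows, columns=cols)


def events_from_frame(frame: pd.DataFrame) -> list[AnnotatedEvent]:
    """Inverse of :func:`events_to_frame`."""
    meta = {"event_id", "category", "gene_id", "transcript_id",
            "left_region", "right_region"}
    samples = [c for c in frame.columns if c not in meta]
    events = []
    for _, row in frame.iterrows():
        right = row["right_region"]
        events.append(
            AnnotatedEvent(
                event_id=row["event_id"],
                category=row["category"],
                gene_id=row["gene_id"],
                transcript_id=row["transcript_id"],
                left_label=row["left_region"],
                right_label=None if right in ("-", "", None) else right,
                counts={s: int(row[s]) for s in samples},
            )
        )
    return events
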