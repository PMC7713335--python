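"""Seeded synthetic fixtures: toy genomes, junction tracks and PSM tables.

The generator emulates the cohort structure of a two-group splicing
study: multi-exon genes on both strands, per-sample junction-spanning
read evidence (BED12) plus exon/intron coverage records, planted
differential events with group-specific inclusion probabilities, and
downstream search-engine PSM tables with target/decoy hits whose decoy
E-values sit stochastically above true-hit E-values.

One integer seed governs everything; each stage draws from its own
deterministically derived substream, so stages can be re-run
independently and a given seed reproduces byte-identical files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .junctions import make_event_id
from .model import ExonRegion, GenomicInterval, IntronRegion, TranscriptModel
from .peptides import AsPeptideRecord, build_decoy

__all__ = [
    "SimulationConfig",
    "SimulatedReference",
    "simulate_reference",
    "simulate_junction_observations",
    "simulate_psm_table",
]

_BASES = np.array(list("ACGT"))

# substream tags
_REF, _JUNC, _PSM = 1, 2, 3


@dataclass
class SimulationConfig:
    """All knobs of the fixture generator.

    Defaults are the study conditions the test-suite properties assume:
    two groups of 20 samples, planted events included with probability
    0.8 in the cancer group vs 0.1 in the normal group, PSM emission
    0.7 vs 0.05 with a 5% per-sample decoy background.
    """

    seed: int = 0
    n_genes: int = 12
    exons_per_gene: tuple[int, int] = (3, 5)
    exon_length: tuple[int, int] = (150, 300)
    intron_length: tuple[int, int] = (90, 200)
    intergenic: int = 200
    chrom: str = "chr1"
    group_labels: tuple[str, str] = ("normal", "cancer")
    n_samples: tuple[int, int] = (20, 20)
    # (category, inclusion prob in group 1, inclusion prob in group 2);
    # planted event i is placed on gene i
    planted: tuple[tuple[str, float, float], ...] = (
        ("E_E_AS", 0.1, 0.8),
        ("INTRON_AS", 0.1, 0.8),
        ("I_E_AS", 0.1, 0.8),
        ("E_I_AS", 0.1, 0.8),
        ("EXON_NM", 0.1, 0.8),
    )
    junction_overhang: int = 40
    read_count_nb: tuple[int, float] = (4, 0.3)  # negative binomial (n, p), +1
    # PSM stage
    n_psm_samples: tuple[int, int] = (20, 20)
    psm_emission: tuple[float, float] = (0.05, 0.7)  # planted peptides, per group
    psm_background_emission: tuple[float, float] = (0.1, 0.1)
    psm_decoy_rate: float = 0.05  # per decoy entry per sample
    target_log10_evalue: tuple[float, float] = (-4.0, 0.7)  # mean, sd
    decoy_log10_evalue: tuple[float, float] = (0.7, 0.5)

    def __post_init__(self) -> None:
        for cat, p1, p2 in self.planted:
            if not (0 <= p1 <= 1 and 0 <= p2 <= 1):
                raise ValueError(f"inclusion probabilities outside [0,1]: {cat}")
        if self.exons_per_gene[0] < 3:
            raise ValueError("genes need >= 3 exons to host skipping events")
        if min(self.exon_length[0], self.intron_length[0]) < 3:
            raise ValueError("region lengths must be >= 3")
        if len(self.planted) > self.n_genes:
            raise ValueError("more planted events than genes")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in data:
                continue
            value = data[f.name]
            if isinstance(value, list):
                value = tuple(
                    tuple(v) if isinstance(v, list) else v for v in value
                )
            kwargs[f.name] = value
        return cls(**kwargs)


@dataclass
class SimulatedReference:
    """In-memory reference plus the planted ground truth."""

    genome: dict[str, str]
    transcripts: list[TranscriptModel]
    planted_event_ids: dict[str, tuple[float, float]]  # event_id -> group probs
    genome_path: Path | None = None
    gtf_path: Path | None = None


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def simulate_reference(config: SimulationConfig, outdir) -> SimulatedReference:
    """Generate a toy genome FASTA and GTF with phase-annotated exons.

    Genes are laid left to right on one chromosome with alternating
    strands; exon phases accumulate along each transcript as in a CDS
    (phase of exon k+1 = (phase_k + length_k) mod 3, first exon phase 0).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = _rng(config, _REF)
    pos = config.intergenic
    transcripts: list[TranscriptModel] = []
    for g in range(config.n_genes):
        n_exons = int(rng.integers(config.exons_per_gene[0],
                                   config.exons_per_gene[1] + 1))
        strand = "+" if g % 2 == 0 else "-"
        exon_lens = rng.integers(config.exon_length[0],
                                 config.exon_length[1] + 1, n_exons)
        intron_lens = rng.integers(config.intron_length[0],
                                   config.intron_length[1] + 1,
                                   max(n_exons - 1, 0))
        intervals = []
        p = pos
        for i in range(n_exons):
            intervals.append((p, p + int(exon_lens[i])))
            p += int(exon_lens[i])
            if i < n_exons - 1:
                p += int(intron_lens[i])
        pos = p + config.intergenic
        ordered = intervals if strand == "+" else intervals[::-1]
        phases = [0]
        for s, e in ordered[:-1]:
            phases.append((phases[-1] + (e - s)) % 3)
        exons = [
            ExonRegion(
                interval=GenomicInterval(config.chrom, s, e, strand),
                index=i + 1,
                phase=phases[i],
            )
            for i, (s, e) in enumerate(ordered)
        ]
        transcripts.append(
            TranscriptModel(
                transcript_id=f"TX{g:03d}",
                gene_id=f"GENE{g:03d}",
                gene_name=f"gene{g}",
                strand=strand,
                exons=exons,
            )
        )
    genome_len = pos + config.intergenic
    genome = {config.chrom: "".join(rng.choice(_BASES, genome_len))}

    genome_path = outdir / "genome.fa"
    with open(genome_path, "w") as fh:
        fh.write(f">{config.chrom}\n")
        seq = genome[config.chrom]
        for i in range(0, len(seq), 80):
            fh.write(seq[i : i + 80] + "\n")

    gtf_path = outdir / "annotation.gtf"
    with open(gtf_path, "w") as fh:
        for tx in transcripts:
            for exon in tx.exons:
                iv = exon.interval
                attrs = (
                    f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}"; '
                    f'gene_name "{tx.gene_name}"; exon_phase "{exon.phase}";'
                )
                fh.write(
                    "\t".join(
                        [
                            iv.chrom, "simulated", "exon",
                            str(iv.start + 1), str(iv.end), ".",
                            tx.strand, ".", attrs,
                        ]
                    )
                    + "\n"
                )

    planted = _planted_event_ids(config, transcripts)
    return SimulatedReference(
        genome=genome,
        transcripts=transcripts,
        planted_event_ids=planted,
        genome_path=genome_path,
        gtf_path=gtf_path,
    )


def _planted_regions(category: str, tx: TranscriptModel):
    """(left, right) regions of the planted event on ``tx``; right may be None."""
    if category == "E_E_AS":
        return tx.exons[0], tx.exons[2]
    if category == "E_E_NM":
        return tx.exons[0], tx.exons[1]
    if category == "I_E_AS":
        return tx.introns[0], tx.exons[1]
    if category == "E_I_AS":
        return tx.exons[0], tx.introns[0]
    if category == "INTRON_AS":
        return tx.introns[0], None
    if category == "EXON_NM":
        return tx.exons[1], None
    raise ValueError(f"unknown planted category {category!r}")


def _planted_event_ids(
    config: SimulationConfig, transcripts: list[TranscriptModel]
) -> dict[str, tuple[float, float]]:
    out = {}
    for i, (category, p1, p2) in enumerate(config.planted):
        tx = transcripts[i]
        left, right = _planted_regions(category, tx)
        eid = make_event_id(
            category, tx.transcript_id, left.label,
            right.label if right else None,
        )
        out[eid] = (p1, p2)
    return out


def _junction_blocks(left_region, right_region, overhang: int):
    """Genomic (left, right) block intervals flanking a junction boundary."""
    a, b = sorted(
        (left_region.interval, right_region.interval), key=lambda iv: iv.start
    )
    o1 = min(overhang, a.width)
    o2 = min(overhang, b.width)
    return (a.end - o1, a.end), (b.start, b.start + o2)


def _bed12_line(chrom, blocks, name, score) -> str:
    (s1, e1), (s2, e2) = blocks
    return "\t".join(
        [
            chrom, str(s1), str(e2), name, str(score), "+",
            str(s1), str(e2), "0", "2",
            f"{e1 - s1},{e2 - s2}", f"0,{s2 - s1}",
        ]
    )


def simulate_junction_observations(
    config: SimulationConfig, reference: SimulatedReference, outdir
) -> dict:
    """Write per-sample BED12 junction tracks, region TSVs and the design.

    Background evidence present in every sample: one normal junction per
    neighboring exon pair and coverage of the first exon of every
    transcript.  Planted events are drawn per sample with their group's
    inclusion probability; read counts follow a shifted negative
    binomial.
    """
    outdir = Path(outdir)
    bed_dir = outdir / "junctions"
    region_dir = outdir / "regions"
    bed_dir.mkdir(parents=True, exist_ok=True)
    region_dir.mkdir(parents=True, exist_ok=True)
    rng = _rng(config, _JUNC)
    nb_n, nb_p = config.read_count_nb

    def draw_count() -> int:
        return int(rng.negative_binomial(nb_n, nb_p)) + 1

    samples: list[tuple[str, str]] = []
    for label, n in zip(config.group_labels, config.n_samples):
        samples.extend((f"{label}{i:02d}", label) for i in range(n))

    design_path = outdir / "design.tsv"
    with open(design_path, "w") as fh:
        fh.write("sample_id\tgroup\n")
        for sid, grp in samples:
            fh.write(f"{sid}\t{grp}\n")

    planted_specs = []
    for i, (category, p1, p2) in enumerate(config.planted):
        tx = reference.transcripts[i]
        left, right = _planted_regions(category, tx)
        planted_specs.append((category, tx, left, right, (p1, p2)))

    for sid, group in samples:
        gi = config.group_labels.index(group)
        bed_lines: list[str] = []
        region_lines: list[str] = ["chrom\tstart\tend\tread_count"]
        jn = 0
        for tx in reference.transcripts:
            for k in range(len(tx.exons) - 1):
                blocks = _junction_blocks(
                    tx.exons[k], tx.exons[k + 1], config.junction_overhang
                )
                bed_lines.append(
                    _bed12_line(tx.chrom, blocks, f"JUNC{jn:05d}", draw_count())
                )
                jn += 1
            first = tx.exons[0].interval
            region_lines.append(
                f"{first.chrom}\t{first.start}\t{first.end}\t{draw_count()}"
            )
        for category, tx, left, right, probs in planted_specs:
            # draw unconditionally to keep the stream aligned across samples
            included = rng.random() < probs[gi]
            count = draw_count()
            if not included:
                continue
            if right is None:
                iv = left.interval
                region_lines.append(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{count}"
                )
            else:
                blocks = _junction_blocks(left, right, config.junction_overhang)
                bed_lines.append(
                    _bed12_line(tx.chrom, blocks, f"JUNC{jn:05d}", count)
                )
                jn += 1
        (bed_dir / f"{sid}.bed").write_text("\n".join(bed_lines) + "\n")
        (region_dir / f"{sid}.tsv").write_text("\n".join(region_lines) + "\n")

    return {
        "bed_dir": bed_dir,
        "region_dir": region_dir,
        "design": design_path,
        "samples": [sid for sid, _ in samples],
    }


def simulate_psm_table(
    config: SimulationConfig,
    target_records: list[AsPeptideRecord],
    planted_event_ids: dict[str, tuple[float, float]],
    outdir,
) -> dict:
    """Write OMSSA-style per-sample PSM CSVs for a built peptide database.

    Each target peptide emits one PSM per sample with its group's
    emission probability (the planted probabilities for planted events,
    a flat background otherwise); decoy entries emit at the configured
    background rate with log-normally larger E-values.
    """
    outdir = Path(outdir)
    psm_dir = outdir / "psms"
    psm_dir.mkdir(parents=True, exist_ok=True)
    rng = _rng(config, _PSM)
    decoys = build_decoy(target_records)

    samples: list[tuple[str, str]] = []
    for label, n in zip(config.group_labels, config.n_psm_samples):
        samples.extend((f"plasma_{label}{i:02d}", label) for i in range(n))
    design_path = outdir / "psm_design.tsv"
    with open(design_path, "w") as fh:
        fh.write("sample_id\tgroup\n")
        for sid, grp in samples:
            fh.write(f"{sid}\t{grp}\n")

    t_mu, t_sd = config.target_log10_evalue
    d_mu, d_sd = config.decoy_log10_evalue
    header = "Spectrum number,Filename/id,Peptide,E-value,Defline,Charge"
    for sid, group in samples:
        gi = config.group_labels.index(group)
        lines = [header]
        spec_no = 0
        for rec in target_records:
            if rec.event_id in planted_event_ids:
                prob = config.psm_emission[gi]
            else:
                prob = config.psm_background_emission[gi]
            if rng.random() >= prob:
                continue
            evalue = 10.0 ** rng.normal(t_mu, t_sd)
            lines.append(
                f"{spec_no},{sid}.{spec_no}.dta,{rec.peptide},"
                f"{evalue:.6g},{rec.header},2"
            )
            spec_no += 1
        for rec in decoys:
            if rng.random() >= config.psm_decoy_rate:
                continue
            evalue = 10.0 ** rng.normal(d_mu, d_sd)
            lines.append(
                f"{spec_no},{sid}.{spec_no}.dta,{rec.peptide},"
                f"{evalue:.6g},{rec.header},2"
            )
            spec_no += 1
        (psm_dir / f"{sid}.csv").write_text("\n".join(lines) + "\n")
    return {"psm_dir": psm_dir, "design": design_path,
            "samples": [sid for sid, _ in samples]}
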