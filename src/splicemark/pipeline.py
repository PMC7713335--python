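"""End-to-end orchestration: annotate -> test -> builddb -> msfilter.

Stages are plain functions over file paths so the CLI stays a thin
wrapper; ``run_all`` chains them and writes a run manifest recording the
tool version, the full parameter snapshot, input checksums and the
per-stage record counts (each filter chain is non-increasing).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .junctions import (
    AnnotatedEvent,
    classify_junction,
    counts_matrix,
    events_from_frame,
    events_to_frame,
    filter_min_support,
    merge_observations,
    parse_junction_bed,
    parse_region_tsv,
    summarize_categories,
)
from .model import TranscriptIndex, read_annotation, read_genome
from .peptides import (
    build_decoy,
    build_peptide_records,
    junction_notation,
    write_fasta,
)
from .psm import (
    compute_fdr_threshold,
    filter_psms,
    identify_peptide_biomarkers,
    peptide_sample_hits,
    read_psm_table,
)
from .simulate import (
    SimulationConfig,
    simulate_junction_observations,
    simulate_psm_table,
    simulate_reference,
)
from .stats import read_design, select_biomarkers, test_events

__all__ = [
    "RunManifest",
    "annotate_stage",
    "test_stage",
    "builddb_stage",
    "msfilter_stage",
    "run_all",
    "run_closed_loop",
]


@dataclass
class RunManifest:
    """Structured record of one pipeline run."""

    version: str = __version__
    config: dict = field(default_factory=dict)
    input_checksums: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    category_summary: dict = field(default_factory=dict)

    def add_input(self, path) -> None:
        p = Path(path)
        digest = hashlib.sha256(p.read_bytes()).hexdigest()
        self.input_checksums[str(p)] = digest

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "version": self.version,
                "config": self.config,
                "input_checksums": self.input_checksums,
                "counts": self.counts,
                "category_summary": self.category_summary,
            },
            sort_keys=False,
        )

    def write(self, path) -> None:
        Path(path).write_text(self.to_yaml())


def _collect_files(directory, suffix: str) -> dict[str, Path]:
    d = Path(directory)
    return {p.stem: p for p in sorted(d.glob(f"*{suffix}"))}


def annotate_stage(
    genome_path,
    gtf_path,
    bed_dir=None,
    region_dir=None,
    min_overlap: float = 0.90,
    min_reads: int = 6,
    support_scope: str = "pooled",
    phase_attr: str = "exon_phase",
    manifest: RunManifest | None = None,
) -> tuple[list[AnnotatedEvent], list[str]]:
    """Parse, annotate, merge and support-filter all observations.

    Returns the retained events (counts filled for every sample) and the
    sample list (union over input files, sorted).
    """
    genome = read_genome(genome_path)
    transcripts = TranscriptIndex(read_annotation(gtf_path, phase_attr=phase_attr))

    observations = []
    samples: set[str] = set()
    n_junc = n_region = 0
    if bed_dir is not None:
        for sid, path in _collect_files(bed_dir, ".bed").items():
            obs = parse_junction_bed(path, sid)
            n_junc += len(obs)
            observations.extend(obs)
            samples.add(sid)
    if region_dir is not None:
        for sid, path in _collect_files(region_dir, ".tsv").items():
            obs = parse_region_tsv(path, sid)
            n_region += len(obs)
            observations.extend(obs)
            samples.add(sid)

    annotated = []
    for obs in observations:
        annotated.extend(classify_junction(obs, transcripts, min_overlap))
    sample_list = sorted(samples)
    merged = merge_observations(annotated, samples=sample_list)
    retained = filter_min_support(merged, min_reads=min_reads, scope=support_scope)

    if manifest is not None:
        manifest.counts.update(
            {
                "junction_records": n_junc,
                "region_records": n_region,
                "observations_parsed": len(observations),
                "observation_annotations": len(annotated),
                "merged_events": len(merged),
                "retained_events": len(retained),
            }
        )
        manifest.category_summary = summarize_categories(retained)
    return retained, sample_list


def test_stage(
    events: list[AnnotatedEvent],
    design_path,
    q_max: float = 0.05,
    presence_min: int = 1,
    mode: str = "presence",
    yates: bool = False,
    manifest: RunManifest | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Differential testing and biomarker selection."""
    design = read_design(design_path)
    results = test_events(
        events, design, presence_min=presence_min, mode=mode, yates=yates
    )
    selected = select_biomarkers(results, q_max=q_max)
    if manifest is not None:
        manifest.counts["events_tested"] = len(results)
        manifest.counts["rna_biomarkers"] = len(selected)
    return results, selected


def builddb_stage(
    selected_events: list[AnnotatedEvent],
    genome_path,
    gtf_path,
    target_fasta,
    decoy_fasta=None,
    flank: int = 120,
    min_peptide_len: int = 6,
    phase_attr: str = "exon_phase",
    manifest: RunManifest | None = None,
):
    """Synthesize, translate and write the target (and decoy) database."""
    genome = read_genome(genome_path)
    transcripts = TranscriptIndex(read_annotation(gtf_path, phase_attr=phase_attr))
    records = build_peptide_records(
        selected_events, transcripts, genome,
        flank=flank, min_peptide_len=min_peptide_len,
    )
    write_fasta(records, target_fasta)
    if decoy_fasta is not None:
        write_fasta(build_decoy(records), decoy_fasta)
    if manifest is not None:
        manifest.counts["db_peptides"] = len(records)
    return records


def msfilter_stage(
    psm_dir,
    design_path,
    fdr_max: float = 0.01,
    evalue_max: float = 0.1,
    q_max: float = 0.05,
    min_hits: int = 2,
    per_sample_fdr: bool = False,
    records=None,
    manifest: RunManifest | None = None,
) -> pd.DataFrame:
    """Filter PSM tables and call peptide-level biomarkers."""
    design = read_design(design_path)
    psms = []
    for sid, path in _collect_files(psm_dir, ".csv").items():
        psms.extend(read_psm_table(path, sample_id=sid))
    accepted = filter_psms(
        psms, fdr_max=fdr_max, evalue_max=evalue_max, per_sample=per_sample_fdr
    )
    hits = peptide_sample_hits(accepted, design)
    biomarkers = identify_peptide_biomarkers(
        hits, design, q_max=q_max, min_hits=min_hits
    )
    if records is not None and not biomarkers.empty:
        by_pep = {r.peptide: r for r in records}
        biomarkers = biomarkers.copy()
        biomarkers["junction_peptide"] = biomarkers["peptide"].map(
            lambda p: junction_notation(by_pep[p]) if p in by_pep else p
        )
    if manifest is not None:
        manifest.counts.update(
            {
                "psms_total": len(psms),
                "psms_accepted": len(accepted),
                "peptides_tested": len(hits),
                "peptide_biomarkers": len(biomarkers),
            }
        )
    return biomarkers


def run_all(config: dict, outdir) -> RunManifest:
    """Run every stage from a flat config mapping and write all outputs.

    The config either names real inputs (genome, gtf, bed_dir,
    region_dir, design, psm_dir) or contains a ``simulate`` section, in
    which case fixtures are generated first and the PSM tables are
    simulated from the pipeline's own database (the closed loop).
    Missing inputs fail before any stage runs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=dict(config))

    sim_cfg = None
    if "simulate" in config:
        sim_cfg = SimulationConfig.from_dict(config["simulate"] or {})
        if "seed" in config:
            sim_cfg = SimulationConfig.from_dict(
                {**sim_cfg.to_dict(), "seed": config["seed"]}
            )
        ref = simulate_reference(sim_cfg, outdir / "fixtures")
        sim = simulate_junction_observations(sim_cfg, ref, outdir / "fixtures")
        paths = {
            "genome": ref.genome_path,
            "gtf": ref.gtf_path,
            "bed_dir": sim["bed_dir"],
            "region_dir": sim["region_dir"],
            "design": sim["design"],
        }
    else:
        paths = {k: config.get(k) for k in
                 ("genome", "gtf", "bed_dir", "region_dir", "design")}
        missing = [k for k in ("genome", "gtf", "design") if not paths[k]]
        missing += [
            k for k, v in paths.items() if v and not Path(v).exists()
        ]
        if missing:
            raise FileNotFoundError(f"missing inputs: {sorted(set(missing))}")

    for key in ("genome", "gtf", "design"):
        manifest.add_input(paths[key])

    events, samples = annotate_stage(
        paths["genome"], paths["gtf"],
        bed_dir=paths.get("bed_dir"), region_dir=paths.get("region_dir"),
        min_overlap=float(config.get("min_overlap", 0.90)),
        min_reads=int(config.get("min_reads", 6)),
        support_scope=config.get("support_scope", "pooled"),
        phase_attr=config.get("phase_attr", "exon_phase"),
        manifest=manifest,
    )
    events_to_frame(events, samples).to_csv(
        outdir / "events.tsv", sep="\t", index=False
    )

    results, selected = test_stage(
        events, paths["design"],
        q_max=float(config.get("q_max", 0.05)),
        presence_min=int(config.get("presence_min", 1)),
        mode=config.get("test_mode", "presence"),
        yates=bool(config.get("yates", False)),
        manifest=manifest,
    )
    results.to_csv(outdir / "event_tests.tsv", sep="\t", index=False)
    selected.to_csv(outdir / "rna_biomarkers.tsv", sep="\t", index=False)

    selected_ids = set(selected["event_id"]) if not selected.empty else set()
    selected_events = [ev for ev in events if ev.event_id in selected_ids]
    records = builddb_stage(
        selected_events, paths["genome"], paths["gtf"],
        target_fasta=outdir / "as_peptides.fasta",
        decoy_fasta=outdir / "as_peptides_decoy.fasta",
        flank=int(config.get("flank", 120)),
        min_peptide_len=int(config.get("min_peptide_len", 6)),
        phase_attr=config.get("phase_attr", "exon_phase"),
        manifest=manifest,
    )

    if sim_cfg is not None:
        psm_sim = simulate_psm_table(
            sim_cfg, records, _sim_planted(sim_cfg, paths), outdir / "fixtures"
        )
        psm_dir, psm_design = psm_sim["psm_dir"], psm_sim["design"]
    else:
        psm_dir = config.get("psm_dir")
        psm_design = config.get("psm_design", paths["design"])

    if psm_dir:
        biomarkers = msfilter_stage(
            psm_dir, psm_design,
            fdr_max=float(config.get("fdr_max", 0.01)),
            evalue_max=float(config.get("evalue_max", 0.1)),
            q_max=float(config.get("q_max", 0.05)),
            min_hits=int(config.get("min_hits", 2)),
            per_sample_fdr=bool(config.get("per_sample_fdr", False)),
            records=records,
            manifest=manifest,
        )
        biomarkers.to_csv(outdir / "peptide_biomarkers.tsv", sep="\t", index=False)

    manifest.write(outdir / "manifest.yaml")
    return manifest


def _sim_planted(sim_cfg: SimulationConfig, paths) -> dict:
    # re-derive planted event ids from the written reference (deterministic)
    ref = simulate_reference(sim_cfg, Path(paths["genome"]).parent)
    return ref.planted_event_ids


def run_closed_loop(config: SimulationConfig, workdir) -> dict:
    """Simulate -> annotate -> test -> builddb -> simulate PSMs -> msfilter.

    Returns everything needed to score recovery of the planted truth,
    including the realized decoy fraction among score-accepted PSMs.
    """
    workdir = Path(workdir)
    manifest = RunManifest(config={"simulate": config.to_dict()})
    ref = simulate_reference(config, workdir / "ref")
    sim = simulate_junction_observations(config, ref, workdir)

    events, samples = annotate_stage(
        ref.genome_path, ref.gtf_path,
        bed_dir=sim["bed_dir"], region_dir=sim["region_dir"],
        manifest=manifest,
    )
    results, selected = test_stage(events, sim["design"], manifest=manifest)
    selected_ids = set(selected["event_id"]) if not selected.empty else set()
    selected_events = [ev for ev in events if ev.event_id in selected_ids]

    genome = read_genome(ref.genome_path)
    transcripts = TranscriptIndex(read_annotation(ref.gtf_path))
    records = build_peptide_records(selected_events, transcripts, genome)
    manifest.counts["db_peptides"] = len(records)

    psm_sim = simulate_psm_table(
        config, records, ref.planted_event_ids, workdir
    )
    psms = []
    for sid, path in _collect_files(psm_sim["psm_dir"], ".csv").items():
        psms.extend(read_psm_table(path, sample_id=sid))
    design = read_design(psm_sim["design"])
    accepted = filter_psms(psms)
    hits = peptide_sample_hits(accepted, design)
    biomarkers = identify_peptide_biomarkers(hits, design)
    manifest.counts.update(
        {
            "psms_total": len(psms),
            "psms_accepted": len(accepted),
            "peptides_tested": len(hits),
            "peptide_biomarkers": len(biomarkers),
        }
    )

    # realized decoy fraction among PSMs passing the score thresholds
    decoy_fraction = 0.0
    if psms:
        try:
            cutoff = compute_fdr_threshold(psms)
        except ValueError:
            cutoff = float("-inf")
        thresh = min(cutoff, 0.1)
        passing = [p for p in psms if p.evalue <= thresh]
        if passing:
            decoy_fraction = sum(p.is_decoy for p in psms
                                 if p.is_decoy and p.evalue <= thresh) / len(passing)

    return {
        "reference": ref,
        "events": events,
        "samples": samples,
        "results": results,
        "selected": selected,
        "records": records,
        "hits": hits,
        "biomarkers": biomarkers,
        "planted_event_ids": ref.planted_event_ids,
        "decoy_fraction": decoy_fraction,
        "manifest": manifest,
    }
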