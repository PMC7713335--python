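"""Peptide-spectrum-match filtering and peptide-level biomarker calling.

PSM tables from an external search engine (OMSSA-style CSV or a generic
delimited dialect) are filtered in two stages: a target-decoy FDR cutoff
on the E-value (prefix FDR = #decoys/#targets along the E-value-sorted
list, largest cutoff with FDR <= 1%) combined with a hard 0.1 E-value
cap.  Accepted PSMs are collapsed to sample-level peptide hits, tested
for group-differential presence (chi-square + Storey q, reusing the
RNA-stage statistics), and reported as biomarkers when q < 0.05 and at
least one group shows >= 2 hits.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .peptides import DECOY_PREFIX, parse_accession
from .stats import GroupDesign, chi_square, storey_qvalues

log = logging.getLogger(__name__)

__all__ = [
    "PsmRecord",
    "read_psm_table",
    "compute_fdr_threshold",
    "filter_psms",
    "peptide_sample_hits",
    "identify_peptide_biomarkers",
]

# field -> column name per dialect
DIALECTS = {
    "omssa": {
        "sep": ",",
        "spectrum_id": "Spectrum number",
        "peptide": "Peptide",
        "evalue": "E-value",
        "accession": "Defline",
    },
    "tsv": {
        "sep": "\t",
        "spectrum_id": "spectrum_id",
        "peptide": "peptide",
        "evalue": "evalue",
        "accession": "accession",
    },
}


@dataclass
class PsmRecord:
    """One peptide-spectrum match from the search engine."""

    sample_id: str
    spectrum_id: str
    peptide: str
    evalue: float
    accession: str
    is_decoy: bool

    def __post_init__(self) -> None:
        if self.evalue <= 0:
            raise ValueError(f"E-value must be positive, got {self.evalue}")


def read_psm_table(
    path,
    sample_id: str | None = None,
    dialect: str = "omssa",
    mapping: dict[str, str] | None = None,
) -> list[PsmRecord]:
    """Read one sample's PSM table.

    ``mapping`` overrides the dialect's field -> column names.  The decoy
    flag is derived from the accession's DECOY_ prefix.  ``sample_id``
    defaults to the file's stem.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    spec = dict(DIALECTS[dialect])
    if mapping:
        spec.update(mapping)
    sid = sample_id if sample_id is not None else Path(path).stem
    frame = pd.read_csv(path, sep=spec["sep"])
    frame.columns = [c.strip() for c in frame.columns]
    missing = [
        spec[f] for f in ("spectrum_id", "peptide", "evalue", "accession")
        if spec[f] not in frame.columns
    ]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    records = []
    for _, row in frame.iterrows():
        accession = str(row[spec["accession"]]).strip()
        records.append(
            PsmRecord(
                sample_id=sid,
                spectrum_id=str(row[spec["spectrum_id"]]),
                peptide=str(row[spec["peptide"]]).strip(),
                evalue=float(row[spec["evalue"]]),
                accession=accession,
                is_decoy=accession.startswith(DECOY_PREFIX),
            )
        )
    return records


def compute_fdr_threshold(
    psms: list[PsmRecord], fdr_max: float = 0.01
) -> float:
    """Largest E-value cutoff with prefix target-decoy FDR <= ``fdr_max``.

    PSMs are sorted by ascending E-value; at each distinct E-value the
    prefix FDR is #decoys/#targets (ties share one prefix, so the cutoff
    is inclusive).  Returns +inf when the full list passes and -inf when
    no prefix does.  A list with zero target PSMs is an error.
    """
    if not any(not p.is_decoy for p in psms):
        raise ValueError("no target PSMs; cannot estimate FDR")
    ordered = sorted(psms, key=lambda p: p.evalue)
    best = -math.inf
    n_targets = n_decoys = 0
    for i, psm in enumerate(ordered):
        if psm.is_decoy:
            n_decoys += 1
        else:
            n_targets += 1
        is_group_end = i == len(ordered) - 1 or ordered[i + 1].evalue != psm.evalue
        if not is_group_end:
            continue
        fdr = n_decoys / n_targets if n_targets else math.inf
        if fdr <= fdr_max:
            best = psm.evalue
    if best == ordered[-1].evalue:
        return math.inf
    return best


def filter_psms(
    psms: list[PsmRecord],
    fdr_max: float = 0.01,
    evalue_max: float = 0.1,
    per_sample: bool = False,
) -> list[PsmRecord]:
    """Targets passing both the FDR-derived cutoff and the E-value cap.

    The FDR cutoff is computed over the pooled PSM list by default, or
    per sample with ``per_sample=True``.  Decoys never appear in the
    output.
    """
    if not psms:
        return []
    if per_sample:
        cutoffs = {}
        by_sample: dict[str, list[PsmRecord]] = {}
        for p in psms:
            by_sample.setdefault(p.sample_id, []).append(p)
        for sid, group in by_sample.items():
            cutoffs[sid] = compute_fdr_threshold(group, fdr_max)
        return [
            p for p in psms
            if not p.is_decoy
            and p.evalue <= cutoffs[p.sample_id]
            and p.evalue <= evalue_max
        ]
    cutoff = compute_fdr_threshold(psms, fdr_max)
    return [
        p for p in psms
        if not p.is_decoy and p.evalue <= cutoff and p.evalue <= evalue_max
    ]


def peptide_sample_hits(
    psms: list[PsmRecord], design: GroupDesign
) -> pd.DataFrame:
    """Per-peptide sample hit counts by group.

    A hit is a sample with >= 1 accepted PSM for the peptide, whatever
    the PSM multiplicity.  Columns: peptide, accession, hits_<group1>,
    hits_<group2>.
    """
    unknown = sorted({p.sample_id for p in psms} - set(design.samples))
    if unknown:
        raise ValueError(f"PSM sample(s) not in design: {unknown}")
    g1, g2 = design.groups
    hits: dict[str, dict] = {}
    for p in psms:
        entry = hits.setdefault(
            p.peptide, {"accessions": set(), g1: set(), g2: set()}
        )
        entry["accessions"].add(p.accession)
        entry[design.assignments[p.sample_id]].add(p.sample_id)
    rows = [
        {
            "peptide": pep,
            "accession": ";".join(sorted(entry["accessions"])),
            f"hits_{g1}": len(entry[g1]),
            f"hits_{g2}": len(entry[g2]),
        }
        for pep, entry in sorted(hits.items())
    ]
    return pd.DataFrame(
        rows, columns=["peptide", "accession", f"hits_{g1}", f"hits_{g2}"]
    )


def identify_peptide_biomarkers(
    hit_counts: pd.DataFrame,
    design: GroupDesign,
    q_max: float = 0.05,
    min_hits: int = 2,
    yates: bool = False,
) -> pd.DataFrame:
    """Final biomarker call: q < ``q_max`` and >= ``min_hits`` in a group.

    The chi-square presence table per peptide is (hits, group size -
    hits) per group; q-values are computed across all peptides with at
    least one accepted PSM.  Event identity and category are recovered
    from the database accession for the report.
    """
    if hit_counts.empty:
        return hit_counts.copy()
    g1, g2 = design.groups
    n1, n2 = design.group_sizes()
    frame = hit_counts.copy()
    stats = [
        chi_square(
            [[h1, n1 - h1], [h2, n2 - h2]], yates=yates
        )
        for h1, h2 in zip(frame[f"hits_{g1}"], frame[f"hits_{g2}"])
    ]
    frame["chi2"] = [s for s, _ in stats]
    frame["p"] = [p for _, p in stats]
    frame["q"] = storey_qvalues(frame["p"].to_numpy())

    def _meta(accession: str, key: str) -> str:
        first = accession.split(";")[0]
        try:
            return parse_accession(first)[key]
        except ValueError:
            return ""

    frame["event_id"] = frame["accession"].map(lambda a: _meta(a, "event_id"))
    frame["category"] = frame["accession"].map(lambda a: _meta(a, "category"))
    keep = (frame["q"] < q_max) & (
        frame[[f"hits_{g1}", f"hits_{g2}"]].max(axis=1) >= min_hits
    )
    return (
        frame[keep]
        .sort_values(["q", "peptide"], kind="stable")
        .reset_index(drop=True)
    )
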