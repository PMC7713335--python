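# splicemark

Proteogenomic discovery of alternative-splicing (AS) biomarkers. The
package implements a three-stage workflow for studies that pair bulk
RNA-seq from a two-group cohort (e.g. tumour vs. benign tissue) with
LC–MS/MS proteomics of plasma samples:

1. **RNA stage** — splice-junction observations (BED12 junction tracks
   and exon/intron coverage records) are annotated against a transcript
   model and tested for differential representation between groups.
2. **Database stage** — significant events are converted into a
   customized junction-peptide FASTA database (plus a reversed-sequence
   decoy database) for searching MS/MS spectra.
3. **Proteome stage** — peptide-spectrum matches (PSMs) from an external
   search engine are filtered by target-decoy FDR and E-value, and
   peptide-level biomarkers are called with the same statistics as the
   RNA stage.

It is aimed at bioinformaticians who have junction-level RNA-seq output
(e.g. a Tophat-style `junctions.bed`) and PSM tables in hand, and who
want a reproducible, testable path from junction evidence to a short
list of splice-isoform peptide biomarkers.

## Method

**Junction annotation.** Each observed block *T* (an aligned segment of
a junction-spanning read, or a covered exon/intron region) is compared
with every exon/intron region of the candidate transcripts via an
asymmetric overlap rate

```
overlap_rate(A, B) = |A ∩ B| / |A|          (A = the block)
```

and assigned to the region with the optimal index

```
C* = argmax_C overlap_rate(Region_C, T)  subject to  overlap_rate ≥ 0.90 .
```

Blocks that fail the 90% threshold leave the junction unannotated for
that transcript. Annotated observations fall into six categories:
single exon (`EXON_NM`), single intron (`INTRON_AS`, intron retention),
intron–exon (`I_E_AS`), exon–intron (`E_I_AS`), neighboring exon–exon
(`E_E_NM`, normal splicing) and non-neighboring exon–exon (`E_E_AS`,
exon skipping). Events are merged across samples by a deterministic
event key and kept when they pool ≥ 6 supporting reads.

**Differential testing.** Per event, a 2×2 group × present/absent table
(presence = ≥ 1 read in a sample) is tested with a Pearson chi-square
(df = 1, no continuity correction); multiplicity is handled with
Storey–Tibshirani q-values (π₀ from a natural cubic spline over the
λ-grid 0, 0.05, …, 0.90; π₀ = 1 for small problems, which reduces the
procedure to Benjamini–Hochberg). Events with q < 0.05 are biomarkers.

**Peptide database.** For a junction event, the last 120 nt of the 5'
region are concatenated with the first 120 nt of the 3' region (≤ 240 nt
total); single-region events contribute their first 120 nt. When the
leading exon carries an Ensembl phase, the reading frame follows from
the phase; otherwise all three frames are translated and the frame with
the longest stop-free peptide is kept. Decoys are per-entry reversals.

**PSM filtering.** Pooled PSMs are sorted by E-value; the accepted
cutoff is the largest E-value whose prefix FDR (#decoys/#targets) stays
≤ 1%, combined with a hard 0.1 E-value cap. Accepted PSMs collapse to
sample-level hits per peptide; biomarkers require q < 0.05 and ≥ 2 hits
in one of the groups.

## Worked example

The bundled generator plants differential events in a toy cohort so the
whole loop runs in seconds with no external data:

```bash
cat > demo.yaml <<'EOF'
seed: 7
simulate:
  n_genes: 12
  n_samples: [20, 20]
  n_psm_samples: [20, 20]
EOF
splicemark run-all --config demo.yaml --out demo_out
```

The manifest printed at the end records every stage (output for seed 7):

```
counts:
  junction_records: 1535
  region_records: 517
  merged_events: 54
  retained_events: 54
  rna_biomarkers: 5
  db_peptides: 5
  psms_total: 91
  psms_accepted: 82
  peptide_biomarkers: 5
category_summary:
  EXON_NM: 13
  E_E_NM: 37
  E_I_AS: 1
  I_E_AS: 1
  E_E_AS: 1
  INTRON_AS: 1
  Total: 54
```

2052 simulated observations annotate into 54 events; the 5 planted
differential events (and no background event) pass q < 0.05, are
translated into the peptide database, and all 5 survive the proteome
stage. The top RNA biomarker is the planted intron retention:

```
event_id                   category   present_normal present_cancer  chi2   q
INTRON_AS|TX001|INTRON1|-  INTRON_AS  2              20              32.73  5.7e-07
```

and the final peptide report ties each peptide back to its event, e.g.
an exon-skipping peptide hit in 19/20 cancer vs 1/20 normal samples
(`q = 6.3e-08`). Individual stages are also available as
`splicemark annotate | test | builddb | msfilter | simulate`.

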