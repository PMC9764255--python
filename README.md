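# proximap

Downstream analysis of APEX2 proximity-labeling proteomics experiments.
Given a MaxQuant-style protein-groups table from a four-group labeling design
(bait-APEX2 + substrate target, plus no-substrate, wild-type, and
cytoplasmic-bait negative controls), the package:

1. **reads and validates** the standard artifacts (protein-groups TSV, FASTA,
   annotation TSV, design file) — `proximap.quant_io`;
2. **filters** for bait-proximal proteins: a presence filter (detection in ≥ 2
   target replicates, total MS/MS count ≥ 2) followed by sequential
   target-vs-control comparisons (two-sample Student's t-test on log2
   intensities, p < 0.05 and two-fold change), with landmark validation and
   pairwise replicate-R² QC — `proximap.filters`;
3. **tests category enrichment** of the proximal set against the detected
   background with a one-sided Fisher exact test (enrichment factor > 2 and
   p < 0.05) — `proximap.enrichment`;
4. **classifies** hits into integral-membrane vs luminal proteins from
   TM-segment / signal-peptide annotations (imported, or from bundled
   Kyte–Doolittle heuristics) and **infers membrane orientation** from the
   side-exclusive distribution of peroxidase-labelable residues (Y/W/H/C)
   across the loops between TM segments — `proximap.topology`;
5. **simulates** complete experiments with known ground truth (planted TM
   segments, signal peptides, lumen-side labelable residues, three background
   channels, intensity-dependent missingness) so every stage is verifiable —
   `proximap.synthetic`;
6. **orchestrates** end-to-end runs from one YAML config with a deterministic
   JSON summary — `proximap.pipeline`.

## CLI

```bash
# synthetic experiment with ground truth
proximap simulate --seed 1 --out data/

# sequential multi-control filtering
proximap filter --table data/proteinGroups.tsv --design data/design.tsv \
    --landmarks data/landmarks.tsv --out filtered/

# category enrichment of the final set
proximap enrich --selected filtered/final_set.tsv --background bg.tsv \
    --categories data/categories.tsv --out enrichment.tsv

# IMP/luminal classification + orientation inference
proximap classify --fasta data/proteome.fasta \
    --annotations data/annotations.tsv --out classes.tsv
proximap topology --fasta data/proteome.fasta --labelable YWHC --out topo.tsv

# everything from one config
proximap run --config run.yaml --out out/
```

A `run.yaml` contains either a `simulate:` block (simulation parameters) or a
`paths:` block (table/design/fasta/annotations/landmarks/categories), plus
optional `thresholds:` overrides:

```yaml
simulate:
  seed: 1
  replicate_sd: 0.3
thresholds:
  fold_change: 2.0
  p_cutoff: 0.05
seed: 1
```

All thresholds are echoed into `out/summary.json`; reruns with the same
config and seed are byte-identical.

## Notes on method choices

- Missing-data policy defaults to *detected-only* (the t-test uses detected
  values, requiring ≥ 2 per side) with an absent-in-control escape (detected
  in all target replicates, zero control detections → pass with infinite
  ratio).  Perseus-style downshifted-normal imputation is available via
  `missing_policy: impute`.
- The t-test is the pooled-variance Student's test by default; Welch and
  Benjamini–Hochberg correction are available by flag.
- The final proximal set has intersection semantics: it is invariant to the
  order of the control comparisons.
- The TM/SP predictors are deliberately simple hydropathy heuristics meant
  for annotation-free inputs and synthetic data; imported predictor output is
  the fidelity path.
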