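# radvar

Analysis toolkit for intragenomic and intraspecies rDNA variation in
single-specimen long-read amplicon data (polycystine Radiolaria and
similar protist surveys).

Given an ASV × specimen occurrence chart (absolute read counts with
per-ASV sequence, ranked lineage, and assignment confidence) and a
specimen metadata table, the package provides:

- **Vetting** (`radvar.vetting`): family-consistency filtering against
  each specimen's morphological assignment (with a relaxed rule for
  naked/juvenile specimens that accepts any polycystine family), a
  ≥3-reads-per-cell presence rule, a ≥3-reads-somewhere per-ASV rule,
  and a ≥5-read specimen rule — with a fully auditable removal report.
- **V4 extraction and merging** (`radvar.primer_v4`): IUPAC-aware primer
  matching, extraction of the V4 sub-region delimited by the
  TAR-EukF1/TAR-EukR3 eukaryotic primer pair, and merging of ASVs with
  identical V4 sequences (read mass conserved, provenance tracked).
- **Richness metrics** (`radvar.richness_metrics`): per-specimen ASV
  richness at relative-abundance thresholds (0.1% / 1% / 10%,
  inclusive), top-10 rank-abundance profiles, per-order summaries.
- **Sharing classification** (`radvar.sharing_classify`): dominant-ASV
  sets (ties preserved), shared-ASV prevalence, and the three-way
  morphospecies classification (same dominant everywhere / shared ASV
  but different dominants / no universal ASV).
- **p-distances** (`radvar.pdistance`): pairwise p-distance with
  pairwise or complete deletion, within/between-group means at the
  intragenomic, intraspecies, and interspecies levels, built-in global
  pairwise alignment, and an external-MAFFT MSA helper.
- **Chimera flagging** (`radvar.phylo_flags`): dominant-ASV FASTA export
  for external tree building, and advisory flagging of long-branching,
  reference-free, low-read (<50) tips/clades on a supplied newick tree,
  with head/tail fragment export for external database checks.
- **Synthetic data** (`radvar.synthetic_data`): a seeded generator
  producing charts with known haplotype structure, forced sharing
  categories, target p-distance hierarchy, order-specific dominance
  decay, log-normal depths (~22.6k reads/specimen), noise singletons,
  and off-family contaminants — ground truth is recorded for recovery
  testing of every stage.
- **Pipeline** (`radvar.cli_pipeline`): one-config orchestration with a
  machine-readable run report.

## CLI

```bash
radvar simulate --preset paper-like --seed 1 --out sim/
radvar vet --chart sim/chart.tsv --meta sim/meta.tsv \
    --min-presence 3 --min-specimen-reads 5 \
    --out vetted.tsv --report report.json
radvar v4 --chart vetted.tsv --out v4.tsv
radvar richness --chart vetted.tsv --meta sim/meta.tsv --out richness.tsv
radvar classify --chart vetted.tsv --meta sim/meta.tsv --out categories.tsv
radvar run --config run.yaml          # full pipeline from YAML
```

`run.yaml` minimally needs `chart_path`, `meta_path`, and `out_dir`;
optional keys: `tree_path` (newick, enables chimera flagging),
`alignment_path` (MSA FASTA for distance calculations), `vetting`
(threshold overrides), `thresholds`.

## File formats

- Occurrence chart TSV: columns `asv_id, sequence, taxon, confidence`,
  then one integer column per specimen. An importer for the multi-sheet
  supplementary spreadsheet layout is provided
  (`read_occurrence_chart(path, dialect="s1data_xlsx")`).
- Specimen metadata TSV: `specimen_id, morphotaxon, morph_rank, order,
  family, relaxed_filter`.
- Sequences: FASTA. Trees: newick.
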