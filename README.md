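# pmap

Network-based phenotype mapping of drug response. From basal gene-expression
profiles, per-sample drug EC50 values and a protein–protein interaction (PPI)
graph, `pmap`:

1. fits EC50 from raw dose–response viability (4-parameter logistic) and ranks
   samples per (drug, group) condition, taking the k lowest-EC50 samples as the
   **sensitive** tail and the k highest as the **resistant** tail (default k = 15);
2. calls **PDEGs** (phenotypic differentially expressed genes) per phenotype
   class (drug class × response) by correlating expression with the binary
   sensitive/resistant template and requiring up-regulation in ≥ 2 cell lines;
3. mines the PPI graph for **N1** genes (non-PDEG nodes adjacent to ≥ 2 PDEGs)
   and **N2** genes (nodes adjacent to ≥ 1 N1 gene and ≥ 2 PDEGs, UBC excluded),
   builds the PDEG–N1 pair registry (M rows) and assembles the induced
   **drug response network** (DRN);
4. scores genes by **phenotypic frequency** (PF = occurrence count in the
   sensitive network − occurrence count in the resistant network, kept per
   N1/N2 role) and ranks candidates;
5. runs local enrichment: hypergeometric over-representation with Bonferroni
   correction, and pre-ranked GSEA with a gene-label permutation null;
6. classifies knockdown-screen outcomes against the PF-sign prediction into
   weak (|PF| < 10) / moderate (10 ≤ |PF| ≤ 100) / strong (|PF| > 100)
   consistency bands, with cell-line-restricted and inconsistent calls.

A synthetic-data module (`pmap.synth`) generates fully structured inputs —
expression with planted two-state genes, 4PL dose–response curves with known
EC50s, a scale-free PPI graph with planted N1 wiring, GMT gene sets and screen
tables — so the entire pipeline is testable offline with known ground truth.

## CLI

```sh
# generate a synthetic input directory with ground truth
pmap synth --seed 1 --out fixtures/

# stage by stage
pmap phenotype --ec50 fixtures/ec50.tsv --k 15 --out assign.tsv
pmap pdeg --expr fixtures/expression.tsv --assign assign.tsv --out pdegs.tsv
pmap drn --ppi fixtures/ppi.tsv --pdegs pdegs.tsv --drug-class anthracycline --out drn_out/
pmap enrich ora --query pdegs.tsv --gmt fixtures/gene_sets.gmt \
    --universe fixtures/expression.tsv --out ora.tsv
pmap enrich gsea --scores drn_out/pf_scores.tsv --gmt fixtures/gene_sets.gmt \
    --nperm 1000 --seed 7 --out gsea.tsv
pmap consistency --pf drn_out/pf_scores.tsv --screen screen.tsv --out calls.tsv

# or everything at once from a YAML config
pmap run --config pipeline.yaml
```

`pipeline.yaml` fields: `expression`, `ppi`, `ec50` (or `dose_response` for
raw viability), optional `gene_sets` (GMT) and `screen`, plus `outdir`, `k`,
`class_map`, `alpha`, `up_z`, `min_links`, `n_perm`, `seed`. Every stage
persists TSV/JSON artifacts and a manifest with content hashes; reruns under
the same seed are bit-identical.

Exit codes: 0 ok, 2 configuration error, 3 data error, 4 stage failure.

## Bundled data

`src/pmap/data/` ships machine-readable transcriptions of the two published
knockdown-screen summary tables (anthracycline and taxane PDEG-interacting
genes with per-cell-line observed sensitivity changes and summed PF scores),
used by the consistency-module regression tests and the acceptance report.

## Notes on conventions

- All joins use one case-sensitive gene-symbol namespace; PSI-MI TAB alias
  cells resolve gene symbol > locus tag > accession.
- Duplicate expression rows collapse by per-sample maximum (logged).
- N1/N2 are role ledgers, not a partition: a gene adjacent to ≥ 2 PDEGs and to
  an N1 gene carries both an N1-role and an N2-role frequency (the strict
  disjoint variant is available via `discover_n2(..., exclude_n1=True)`).
- PF-score sign convention: positive ⇒ sensitive-network occurrence dominates
  ⇒ knockdown predicted to increase drug sensitivity.
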