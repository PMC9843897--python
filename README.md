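# convexpr

Cross-species convergent gene-expression analysis, end to end: starting from
per-species gene-level count matrices and pairwise protein hit tables, the
pipeline infers 1:1 single-copy orthologues (reciprocal best hits with an
E-value cutoff, clique intersection across species), normalizes expression
with GeTMM (gene-length-corrected TMM), runs PCA and Spearman sample
clustering, calls per-species-pair differentially expressed genes with a
negative-binomial exact test (BH-adjusted, |log2FC| >= 1, FDR < 0.05 by
default), intersects direction-consistent DEGs into convergent-expression
calls for two focal species against a shared background, performs
hypergeometric over-representation analysis, and scores promoter methylation
from cytosine reports (1 kb upstream of the TSS, strand-aware, with coverage
filters and a Welch t-test between groups).

A first-class synthetic-data generator produces every input format with
planted ground truth (convergent genes, orthology, methylation levels), so
the whole pipeline is validated by planted-truth recovery.

## Quick start

Simulate a dataset (writes all input files, truth files and a ready
`pipeline.yaml`), then run every stage:

```sh
convexpr simulate --seed 1 --out demo
convexpr run-all --config demo/pipeline.yaml
```

Outputs land in `demo/results/`: the orthologue map, normalized matrix with
TMM factors, PCA scores, Spearman correlation matrix and dendrogram
(newick), per-comparison DE tables, convergent gene lists, a promoter
methylation table with differential tests, and `run_report.json` with
per-stage counts, parameters and sha256 checksums of every artifact. When
truth files are present the report also contains planted-truth sensitivity
and empirical FDR.

Individual stages are exposed as subcommands (`orthology`, `normalize`,
`describe`, `de`, `converge`, `enrich`, `methylation`); see
`convexpr <cmd> --help`.

Simulation parameters can be overridden with a YAML file:

```sh
convexpr simulate --config sim.yaml --seed 7 --out bigger
```

where `sim.yaml` holds `SimConfig` fields, e.g. `n_species: 8`,
`n_genes: 5000`, `n_convergent_up: 50`, `effect_log2fc: 2.0`.

## File formats

All plain TSV: count matrices (genes x samples, integer), BED-like gene
tables (`gene_id, isoform_id, chrom, start, end, strand, protein_length`,
0-based half-open), 12-column BLAST tabular hit tables, bismark-style
cytosine reports (`chrom, position, strand, count_methylated,
count_unmethylated`, 1-based), and GMT-like term maps.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (TMM/BH/RBH/ORA
oracle equivalences, NB-test calibration, GeTMM scale invariance, CV
reduction, planted convergence recovery with sensitivity >= 0.90 at
empirical FDR <= 0.10, methylation filter semantics and calibration,
descriptive-layer properties, and end-to-end bit-identical determinism).

The acceptance report script re-runs the full pipeline on a freshly
simulated dataset at the given seed and writes the (empty) numeric-target
report:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Notes on method choices

- DEG thresholds are |log2FC| >= 1 and BH FDR < 0.05; both configurable
  (`params.lfc_threshold`, `params.fdr_threshold`).
- The DE engine is a conditional NB exact test with a common
  method-of-moments dispersion, run on length-corrected (RPK) values with
  TMM-effective library sizes — chosen for exact enumerability and
  oracle-testability rather than GLM machinery.
- TMM precision weights are computed from library-relative proportions,
  which makes GeTMM output exactly invariant to rescaling any sample.
- "Shared" DEGs must be significant with the same direction against every
  background species (`params.min_support` relaxes this); the two focal
  species are not compared against each other by default
  (`params.include_other_focal`).
- Methylation coverage filter: a CpG needs depth strictly greater than 5
  reads, and a promoter at least 2 passing CpGs (both configurable).
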