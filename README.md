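# phylostrat-rt

Tools for asking whether **recently duplicated genes sit in copy-number
variable (CNV), late-replicating regions of a genome** — the question behind
gene-birth-by-duplication analyses in human and mouse.

The package links three per-gene annotations and the statistics that relate
them:

1. **Duplication age (phylostratification).** Each focal-species gene is
   dated from its annotated gene-family tree: walking from the gene's leaf
   toward the root, the first duplication node with a consistency score
   strictly above 0.3 gives the gene's phylostratum (the taxon of that
   node, mapped onto an ordered timeline of 14 human or 13 mouse age
   classes, oldest = Bilateria). Zero-score duplications are treated as
   reconstruction artifacts and skipped; scores in (0, 0.3] leave the gene
   unassigned; genes with no acceptable duplication node are singletons.
2. **CNV status.** A gene is copy-number variable when ≥ 4 or < 2 copies
   are observed in at least 2 individuals of a population panel; genes
   shorter than 1 kb and non-autosomal genes are excluded first.
3. **Replication timing (RT).** Probe log-ratios from several Repli-chip
   samples are ranked within each sample, each probe gets its median rank,
   each gene takes the nearest probe to its center (≤ 10 kb), and genes are
   re-ranked into a genome-wide *order of replication* (1 = earliest).

Genes are further stratified as pericentromeric / subtelomeric (within
5 Mb of the centromere or a telomere) / interstitial, and the report runs
the battery of chi-squared, two-proportion, Wilcoxon rank-sum, Spearman and
fold-enrichment tests over these annotations.

Because the original data sets (Ensembl Compara trees, population
copy-number panels, GEO RT profiles) are large external downloads, the
package ships a **synthetic-data generator with planted truth** — known
duplication ages, CNV labels, and a monotone age→RT effect — so every stage
is verifiable by planted-truth recovery. See `docs/methods.md` for the
generative model and its limitations.

## Worked example

```python
from phylostrat_rt import PipelineConfig, SimulationConfig, run_full_analysis

report = run_full_analysis(
    PipelineConfig(simulation=SimulationConfig(seed=1, n_genes=10_000))
)
print(report.tests_frame()[["test", "effect", "p_value"]].to_string(index=False))
```

prints (abridged):

```
                           test    effect       p_value
       cnv_fraction_by_age_chi2       NaN  0.000000e+00
           pdg_vs_singleton_cnv  0.192828 2.731686e-119
               rt_cnv_young_pdg  0.178383  9.776498e-15
                 rt_cnv_old_pdg -0.059847  2.046456e-01
                age_rt_spearman  0.966760  0.000000e+00
```

Reading the rows: duplicated genes are ~19 percentage points more often CNV
than singletons; among *young* duplicates, CNV genes replicate later than
non-CNV ones (positive rank-biserial effect, p ≈ 1e-14) while old
duplicates show no such difference; and the ordinal age class correlates
strongly with the order of replication (Spearman ρ ≈ 0.97 in this noiseless
-ish synthetic world — real data gives far smaller ρ). The accompanying
`report.cnv_by_age` table shows the CNV fraction rising from ~3% in the
oldest classes to ~69% in the youngest:

```
 age_class_index age_class_label  n_cnv  n_noncnv  fraction_cnv
               1       Bilateria     18       475      0.036511
             ...
              14    Homo sapiens    342       152      0.692308
            <NA>       SINGLETON     89      2761      0.031228
```

## Command line

```bash
phylostrat-rt simulate --seed 5 --outdir data/           # planted dataset
phylostrat-rt phylostrat --trees data/trees --out ages.tsv
phylostrat-rt cnv-call --matrix data/copy_number.tsv --genes data/genes.bed --out cnv.tsv
phylostrat-rt rt-rank --probes data/rt_probes.tsv --genes data/genes.bed --out rt.tsv
phylostrat-rt stratify --genes data/genes.bed --chrom-map data/chrom_map.tsv --out regions.tsv
phylostrat-rt run --config run.yaml --outdir results/    # full analysis
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the default synthetic dataset with the given seed, runs the
complete pipeline end to end, and writes the results JSON to `--out`.
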