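# scoliogen

Gene-discovery analyses for idiopathic scoliosis (IS): a reusable, tested
implementation of the pipeline that takes published GWAS loci to candidate
genes, tests those genes for ultra-rare variant burden in a case-control
cohort, and quantifies the zebrafish left-right coordination phenotypes
used to validate hits. It is aimed at statistical geneticists who want a
transparent, desk-scale re-implementation of each stage, exercisable end
to end on synthetic data with planted ground truth.

## What it computes

**SNP-to-gene mapping** (`scoliogen.snp2gene`). Genome-wide-significant
SNPs (p < 5×10⁻⁸) are greedily LD-clumped (independent at r² < 0.6),
re-expanded to their LD blocks (r² ≥ 0.6, one hop), and mapped to genes
three ways: positionally (within the gene span or 10 kb of it), by eQTL
(SNP-gene FDR ≤ 0.05 in any tissue), and by chromatin interaction
(contact FDR ≤ 10⁻⁶ with one end on the SNP and the other on the gene
promoter, −250/+500 bp around the TSS). The union is the candidate panel.

**Weighted rare-variant burden** (`scoliogen.weighting`,
`scoliogen.burden`). Ultra-rare variants (gnomAD popmax AF ≤ 0.01%,
cohort AC ≤ 3) get a weight w ∈ {0, 0.2, 0.4, 0.6, 0.8, 1.0} from their
consequence class and LOFTEE / SpliceAI / REVEL / CADD annotations
(e.g. high-confidence LoF → 1.0; missense REVEL > 0.8 → 0.8). The burden
of individual i at gene g is

&nbsp;&nbsp;&nbsp;&nbsp;B(i, g) = max { w(v) : v carried by i in g },

and each gene is tested case vs control with three engines: Fisher exact
on carrier collapse (OR with Haldane correction), a logistic score test
(with Firth fallback for separation), and an exact label-permutation test.

**Left-right coordination** (`scoliogen.coordination`). Bilateral GCaMP
traces are normalized to F_t/F_min per channel, events are detected by
threshold crossing with a refractory period, and asymmetry is summarized
as log(f_left / f_right). Swim tracks are summarized by distance,
velocity, and signed turning-angle statistics (leftward positive).

**Synthetic data** (`scoliogen.synthetic`). Generates every input above
with planted structure — LD blocks, sub/supra-threshold mapping records,
a causal gene with carrier enrichment at an exact target odds ratio, and
traces/tracks with known event times — so every stage is testable offline.

## Worked example

```python
from scoliogen.synthetic import SimConfig, gen_gene_models, gen_gwas_inputs, gen_cohort
from scoliogen import snp2gene as s2g, weighting as wt, burden as bd

cfg = SimConfig(seed=42, n_genes=20, n_snps=12, ld_block_size=3,
                n_cases=411, n_controls=3800, target_or=4.0,
                baseline_carrier_rate=0.002, causal_gene="G0001")
genes = gen_gene_models(cfg)
snps, ld, eqtls, interactions = gen_gwas_inputs(cfg, genes)

significant = [s for s in snps if s.pvalue < 5e-8]
independent = s2g.prune_independent(significant, ld)
block = s2g.expand_to_blocks(independent, snps, ld)
candidates = s2g.combine_candidates(
    s2g.map_positional(independent, genes),
    s2g.map_eqtl(block, eqtls),
    s2g.map_chromatin(block, interactions, genes),
)
print(f"{len(significant)} significant SNPs -> {len(independent)} independent -> "
      f"{len(block)} block SNPs -> {len(candidates)} candidate genes")

variants, geno, pheno = gen_cohort(cfg, genes)
qualifying = wt.filter_ultra_rare(variants, genotypes=geno)
bm = wt.compute_gene_burden(geno, wt.assign_weights(qualifying),
                            genes=[g.gene_id for g in genes])
results = bd.run_gene_scan(bm, pheno)
print(results.head(3)[["gene", "case_carriers", "control_carriers",
                       "odds_ratio", "p_fisher"]].to_string(index=False))
```

prints

```
4 significant SNPs -> 4 independent -> 12 block SNPs -> 4 candidate genes
 gene  case_carriers  control_carriers  odds_ratio  p_fisher
G0001              3                 6    4.649510  0.049624
G0002              3                 9    3.097222  0.104536
G0011              3                 9    3.097222  0.104536
```

The planted causal gene (G0001, carrier odds ratio 4 with a 0.2% control
carrier rate, 411 cases vs 3800 controls) tops the scan: 3 case carriers
against 6 control carriers gives an observed odds ratio of 4.65 at
nominal p ≈ 0.05, while the null genes sit above it. The same stages are
available from the shell: `scoliogen simulate`, `scoliogen map-genes`,
`scoliogen weight`, `scoliogen burden`, `scoliogen calcium`, and
`scoliogen kinematics` (see `--help` on each).

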