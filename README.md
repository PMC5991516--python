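# rhinopop

Genome-wide diversity, inbreeding and selection-scan analyses for a pair of
closely related populations — the setting of conservation-genomics studies
such as the comparison of the critically endangered northern white
rhinoceros (*Ceratotherium simum cottoni*, 9 sequenced individuals) with the
southern white rhinoceros (*C. s. simum*, 4 individuals).  The package takes
multi-sample variant calls (VCF), a sample-to-population panel, scaffold
lengths and gene annotations, and computes:

* **hard filtering** of bcftools-style calls with five rules (indel
  proximity ≤ 3 bp, indel clusters ≤ 10 bp, QUAL < 10, rank-sum bias
  p < 0.1 & QUAL < 15, alternate support < 2 & QUAL < 15), with exact
  per-rule removal accounting;
* **per-individual heterozygosity** (proportion of heterozygous sites over a
  callable genome length), **d<sub>xy</sub>** between populations, the
  **SNP partition** (polymorphic in both / fixed in both / unique to each),
  the **joint site-frequency spectrum** (∂a∂i-compatible output) and
  PLINK-style **LD thinning** (50-SNP window, 10-SNP step, r² > 0.1);
* **runs of homozygosity** from heterozygosity in overlapping 1-Mbp windows
  advanced by 200 kbp (a window is ROH when its rate falls below
  0.0004/bp = 400 het sites per 1 Mbp), merged into runs, with optional
  het-gap boundary refinement, and the genomic inbreeding coefficient
  **F<sub>ROH</sub>**;
* a **Tajima's D selection scan**: Watterson's θ, θ<sub>π</sub> and
  D = (θ<sub>π</sub> − θ<sub>W</sub>)/√(e₁S + e₂S(S−1)) in non-overlapping
  50-kbp windows, two-tailed 1%-quantile outlier regions, and classification
  of coding SNPs in outlier regions as fixed differences or polymorphisms;
* a **synthetic two-population generator** (Balding–Nichols divergence,
  tunable target heterozygosity, indel/annotation mixtures with labelled
  filter violations, insertable autozygous tracts) plus a neutral
  **coalescent window simulator**, so every stage is verifiable against
  ground truth without any sequencing data.

## Worked example

Simulate a 5-Mbp genome for 9 + 4 diploids and run the whole pipeline:

```bash
rhinopop simulate --outdir sim --scaffold-length 5000000 --seed 17
rhinopop run-all --vcf sim/synthetic.vcf --panel sim/panel.tsv \
    --genes sim/genes.bed --outdir results
# dxy=0.00111296 outlier_regions=2
```

`results/heterozygosity.tsv` then starts

```
sample  population  heterozygosity  denominator_bp
pop1_1  pop1        0.001002        5000000
pop1_2  pop1        0.0009962       5000000
```

— each individual's proportion of heterozygous sites, here recovering the
generator's target of 0.001/bp, the magnitude observed in white rhinoceros
genomes.  `results/snp_partition.tsv` holds the partition counts

```
category                     count
shared_polymorphic           10748
fixed_both                   450
unique_pop1                  1357
unique_pop2                  467
fixed_one_polymorphic_other  1806
invariant                    442
```

and `results/filter_report.tsv`, `results/roh_summary.tsv` (per-sample
F<sub>ROH</sub>, median and maximum run length), `results/window_stats.tsv`,
`results/outliers.bed` and `results/coding_snps.tsv` carry the remaining
stage outputs.  The printed d<sub>xy</sub> ≈ 0.0011 is the mean per-site
divergence between cross-population sample pairs given the simulated
differentiation (F = 0.1) — the same order as the 0.001 observed between
the two white rhinoceros subspecies.

Everything is also available as a library; see the docstrings in
`rhinopop.variants`, `rhinopop.diversity`, `rhinopop.roh`,
`rhinopop.selection`, `rhinopop.simulate` and `rhinopop.pipeline`, and
`docs/methods.md` for the underlying models and design choices.

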