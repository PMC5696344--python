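# cochip

Downstream ChIP-seq/RNA-seq quantification for factor co-occupancy
analysis, built around the Drosophila **Ash1–Mrg15** system: Ash1 is a
Trithorax-group H3K36me2 methyltransferase, Mrg15 a complex subunit that
stimulates it.  `cochip` answers, from peak sets, fragment reads and
expression tables, the questions such a study poses:

* How much do two factors' peak sets overlap, and how correlated are their
  intensities where they co-bind?
* How does the product mark (H3K36me2) at the factor's peaks respond to
  knocking down the factor or its cofactor — overall, and stratified by
  cofactor level at matched factor abundance?
* Is the factor's own occupancy more cofactor-dependent at weak peaks than
  at strong ones (retained fraction per wild-type quintile)?
* Which genes are *super targets* — the minimal prefix of the ranked
  first-exon density list holding ~45% of the top-200 signal — and is
  transcriptional repression after knockdown concentrated there?
* Do in-vitro kinetics show a V-type activation (Vmax up, Km unchanged)?

The core quantities are depth-normalized read densities: for a region of
length *L* kb in a library of *N* reads, with fragments extended to the
average fragment size (250 bp),

```
density = (sum of fragment-overlap fractions) × (S / N) / L      [S = 1e7 → "RP10M per kb"]
```

and the super-target rule is the minimal ranked prefix with cumulative
score share ≥ 0.45.  A synthetic-data generator plants all of this
structure (peak nesting, ρ = 0.58 log-intensity correlation, knockdown
retained fractions, the 26-gene/45% score geometry, 18 down / 8 up
expression responders) with a machine-readable truth set, so the whole
pipeline is validated closed-loop.  Michaelis–Menten fitting
(`v = Vmax·S/(Km+S)`, per-replicate fits, pooled t-comparison) covers the
enzymology side.  See `docs/methods.md` for the full model.

## Worked example

Simulate a study-scale landscape and run the analyses:

```python
from cochip import (SimConfig, generate_annotation, generate_landscape,
                    generate_reads, overlap_peaks, correlate_intensities,
                    dependency_analysis, quantify_regions,
                    assign_targets, score_and_rank, detect_super_targets)

cfg = SimConfig(seed=1)                      # 2x5 Mb genome, 3000 genes
genes = generate_annotation(cfg)
truth = generate_landscape(cfg, genes)
ash1, mrg15 = truth.ash1_peak_objects(), truth.mrg15_peak_objects()
regions = [p.interval for p in ash1]

ov = overlap_peaks(ash1, mrg15)
print(f"{ov.n_a} Ash1 peaks, {ov.n_b} Mrg15 peaks, "
      f"{100*ov.fraction_a:.0f}% of Ash1 peaks overlap Mrg15")

reads = generate_reads(truth, "WT", "Ash1")
d_ash1 = quantify_regions(reads, regions)
d_mrg  = quantify_regions(generate_reads(truth, "WT", "Mrg15"), regions)
r, n = correlate_intensities(d_ash1, d_mrg)      # Pearson on log2(1+d)
print(f"intensity correlation R = {r:.2f} (n = {n})")

d_kd = quantify_regions(generate_reads(truth, "Mrg15KD", "Ash1"), regions)
dep = dependency_analysis(d_ash1, d_kd, n_strata=5)
print("Ash1 retained after Mrg15 KD, weak->strong:",
      [round(x, 2) for x in dep["retained"]])

targets = assign_targets(genes, ash1)
hits = set(targets.loc[targets["has_peak"], "gene_id"])
ranked = score_and_rank([g for g in genes if g.gene_id in hits], reads,
                        top_n=200, chrom_sizes=cfg.chrom_sizes)
supers = detect_super_targets(ranked, 0.45)
print(f"{len(hits)} target genes; {supers.n_super} super targets hold "
      f"{100*supers.share_captured:.0f}% of the top-200 signal")
```

prints

```
562 Ash1 peaks, 3678 Mrg15 peaks, 41% of Ash1 peaks overlap Mrg15
intensity correlation R = 0.58 (n = 562)
Ash1 retained after Mrg15 KD, weak->strong: [0.58, 0.61, 0.72, 0.8, 0.9]
398 target genes; 26 super targets hold 46% of the top-200 signal
```

— the overlap fraction, correlation and peak counts are the planted study
conditions recovered by measurement; the retained-fraction profile rises
with peak strength exactly as planted (0.5 → 0.9; the weakest stratum
reads slightly high because background under a weak peak inflates the
ratio — see the methods note).

The same run as a one-shot reproducible pipeline with a results bundle
(config echo, per-stage logs with input hashes, TSV/JSON outputs):

```bash
cochip run --seed 1 --out run1/
cochip supertargets --gtf run1/annotation.gtf --ash1 run1/ash1_peaks.bed \
       --reads run1/reads_WT_Ash1.bed --top 200 --share 0.45
```

Other subcommands: `convert`, `coverage`, `overlap`, `matrix`, `stratify`,
`dependency`, `kinetics`, `simulate`.

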