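# dartpop

Population-genetic analysis of DArTseq SNP panels from **pooled crop
cultivar samples** — the kind of data a gene bank produces when it
genotypes each cultivar as a bulked DNA sample of a few seedlings.
The package was built around a survey of 83 Polish spring barley
cultivars spanning 120 years of breeding (11,655 SNPs after
filtering), and provides every stage of that analysis as a tested,
reusable library:

* reading/writing the **two-row DArTseq dialect** (one locus = a
  ref-allele row and an alt-allele row of 0/1 scores) and the standard
  quality filters (RepAvg ≥ 0.95, call rate ≥ 0.95, MAF ≥ 0.01);
* **diversity statistics**: PIC (diversity form `1 − p² − q²`),
  observed heterozygosity `Ho`, Nei's unbiased expected
  heterozygosity `uHe = 2n/(2n−1)·(1 − p² − q²)`, fixation index
  `F = (uHe − Ho)/uHe`, Hurlbert rarefaction allelic richness, and
  per-cultivar heterogeneity (in a selfing crop sampled as a seedling
  pool, a heterozygous call means the cultivar is internally mixed);
* **genome scans**: sliding windows (500 kb at 250 positions per
  chromosome), Wright's two-group `FST = (HT − H̄S)/HT` with the
  contrast-enhancing `FST^10` transform, and unique-allele
  gain/loss between consecutive breeding periods;
* **Jaccard distances** on the two-bit-per-locus expansion, group
  distance summaries, classical **PCoA**;
* **AMOVA** (distance-based, with Φ_ST and a permutation test);
* **admixture inference** by EM on the binomial admixture likelihood,
  replicate label alignment, **Evanno ΔK** model choice, and
  0.8-threshold membership assignment;
* **duplicate detection** via PLINK-style method-of-moments
  identity-by-descent (duplicates: P̂ > 0.95) with a four-evidence
  verdict table;
* **M-strategy core collection**: the smallest accession subset
  retaining every observed allele class, by admissible best-first
  set-cover search with a greedy fallback;
* a **synthetic-panel generator** that emulates the study design
  (83 pooled samples of 8 seedlings, 5 breeding periods, 11 ancestral
  gene pools, planted duplicates and sweeps) with a recorded ground
  truth, so the whole pipeline is testable end to end.

## Worked example

```sh
python examples/01_filter_and_diversity.py
```

prints (abridged):

```
filtering kept 1390/1450 loci (rep_avg 27, call_rate 32, MAF 1 removed)

panel means: PIC=0.369  Ho=0.070  uHe=0.372  F=0.812

observed heterozygosity by breeding period (oldest first):
  pre-1945    Ho=0.128  uHe=0.368  F=0.651
  1945-1969   Ho=0.094  uHe=0.353  F=0.735
  1970-1989   Ho=0.072  uHe=0.357  F=0.800
  1990-1999   Ho=0.048  uHe=0.351  F=0.862
  post-2000   Ho=0.023  uHe=0.323  F=0.930
```

`Ho` falls and `F` rises across breeding periods: modern cultivars are
internally uniform, old ones heterogeneous — the signature the method
is designed to quantify.  The other examples localise a planted
selective sweep on chromosome 5H (`02_selection_scan.py`), choose the
number of gene pools by ΔK and verify duplicates
(`03_structure_and_duplicates.py`), and partition variance and build a
core collection (`04_distance_amova_core.py`).

The same stages are available from the shell:

```sh
dartpop simulate --seed 1 --out panel
dartpop all --seed 1 --out results      # full pipeline + manifest.json
```

## Input format

A two-row DArTseq CSV has six metadata columns —
`locus_id, chromosome, position_bp, change, rep_avg, call_rate` —
followed by one 0/1 column per accession; each locus occupies two
consecutive rows (reference-allele presence, then alternative-allele
presence).  Pairs collapse to genotype calls: `(1,0)` → ref
homozygote, `(0,1)` → alt homozygote, `(1,1)` → heterozygous (mixed
pool), `(0,0)` → missing.  See `examples/data/mini_panel.csv` for a
3-accession, 2-locus example; `dartpop.read_dartseq_tworow` /
`write_dartseq_tworow` round-trip it losslessly.

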