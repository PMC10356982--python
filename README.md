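# rohmap

Homozygosity mapping for bull fertility: a tested, reusable pipeline for
detecting runs of homozygosity (ROH) in dense SNP genotypes and relating
them to sire conception rate (SCR).

Intensive dairy-cattle selection raises inbreeding, and fitness traits such
as male fertility are the first to suffer. A run of homozygosity — a
contiguous stretch of homozygous genotypes — marks a genomic segment that
is likely identical by descent, so ROH burden is a direct, genomic measure
of inbreeding. `rohmap` implements the full analysis chain for studying
inbreeding depression of bull fertility:

1. **ROH detection** (`rohmap.detect`) — a PLINK-style sliding-window scan:
   windows of 50 SNPs tolerating 1 heterozygous and 1 missing call, per-SNP
   homozygous-window proportions thresholded at 0.05, runs split at >500 kb
   marker gaps, and final segments filtered to ≥100 SNPs, ≥1,000 kb and
   ≤50 kb/SNP density. A brute-force reference caller
   (`detect_roh_oracle`) defines the semantics and backs differential tests.
2. **Characterization** (`rohmap.summary`) — per-animal and per-chromosome
   homozygosity, genomic inbreeding F_ROH = (total ROH bp)/(covered map bp),
   Wright's pedigree inbreeding F_PED by the tabular relationship method,
   their Pearson correlation, and simple linear regressions of SCR on total
   ROH length (Mb) or segment count.
3. **Extreme-group enrichment** (`rohmap.enrich`) — the population is split
   into the bottom-100 and top-100 bulls by SCR; the genome is partitioned
   into overlap regions with constant carrier sets, and each region is
   tested for carrier over-representation among low-fertility bulls with a
   one-tailed Fisher exact test (significance at p ≤ 0.001).
4. **Mixed-model validation** (`rohmap.mixed_model`) — each candidate
   region enters the animal model y = Xb + u + e with u ~ N(0, G σ²_g),
   where G is the VanRaden genomic relationship matrix; REML by profiling
   the variance ratio on the eigenbasis of G. Regions with |t| ≥ 2 on the
   carrier effect are declared validated.
5. **Synthetic studies** (`rohmap.simulate`) — a generator that emulates
   the data shape of such a study (dense autosomal chip, pedigree loops,
   planted autozygous tracts of roughly 1–90 Mb, an SCR phenotype with an
   inbreeding-depression slope, a polygenic term and designated risk
   regions) and exports complete ground truth, so every stage has a
   recoverable target.

## Worked example

```python
import numpy as np
from rohmap import *
from rohmap.simulate import SimulationConfig, simulate_study

study = simulate_study(SimulationConfig(seed=1))   # 800 bulls x 20,000 SNPs
roh = detect_roh(study.dataset)
stats = summarize_animals(roh)
print(f"segments: {len(roh.segments)}  mean length: "
      f"{np.mean([s.length_kb for s in roh.segments]):.0f} kb")
print(f"mean F_ROH: {np.mean([s.f_roh for s in stats]):.3f}")
print(f"r(F_ROH, F_PED): {correlate_roh_pedigree(stats, study.truth.f_ped):.3f}")
fit = regress_scr_on_roh(study.phenotypes, stats)
print(f"SCR on total ROH (Mb): beta = {fit.beta:.4f}, t = {fit.t_value:.2f}")

low, high = split_extremes(study.phenotypes, n=100)
regions = overlap_regions(roh)
enriched = test_enrichment(regions, low, high)
sig = significant_regions(enriched, alpha=0.001)
print(f"overlap regions: {len(regions)}  significant: {len(sig)}")
report = validate_regions([sig[0].region], study.dataset, roh, study.phenotypes)
r = report.results[0]
print(f"top region chr{r.region.chromosome}:{r.region.start_bp}-"
      f"{r.region.end_bp}  beta = {r.beta:.2f}  t = {r.t_value:.2f}  "
      f"validated = {r.validated}")
```

prints

```
segments: 7054  mean length: 9288 kb
mean F_ROH: 0.164
r(F_ROH, F_PED): 0.649
SCR on total ROH (Mb): beta = -0.0122, t = -4.37
overlap regions: 10776  significant: 226
top region chr2:39581929-39808086  beta = -2.22  t = -10.83  validated = True
```

Reading the output: the reference study plants autozygous tracts so that
about 16% of the covered genome is in ROH; genomic and pedigree inbreeding
correlate at r ≈ 0.65; each extra Mb of ROH costs about 0.012 SCR
percentage points (t = −4.4, so the inbreeding-depression slope is clearly
negative); and the top enriched region — which sits inside the planted
risk region on chromosome 2 — carries a −2.2 SCR% effect that survives
mixed-model validation on the full population (|t| ≥ 2) with the polygenic
background controlled by the GRM.

The same chain is available from the shell:

```sh
rohmap simulate --out study --seed 1
rohmap detect --ped study/study.ped --map study/study.map --out roh.tsv
rohmap summarize --ped study/study.ped --map study/study.map --roh roh.tsv \
    --phenotypes study/phenotypes.tsv --pedigree study/pedigree.tsv
rohmap enrich --roh roh.tsv --map study/study.map --ped study/study.ped \
    --phenotypes study/phenotypes.tsv --out regions.tsv --genes study/genes.bed
rohmap validate --regions regions.tsv --ped study/study.ped \
    --map study/study.map --roh roh.tsv \
    --phenotypes study/phenotypes.tsv --out validated.tsv
```

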