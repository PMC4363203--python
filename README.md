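# ectomap

Mapping where a centromeric histone variant goes when it leaves the
centromere.  The centromere-specific histone H3 variant CENP-A is
overexpressed in many cancers, and the excess protein deposits at
*ectopic* (non-centromeric) sites — promoters, DNase I hypersensitive
regions, transcription-factor clusters, and large subtelomeric domains.
`ectomap` is an analysis pipeline for locating these ectopic nucleosome
"hotspots" from strand-aware MNase-ChIP-seq tag positions, together with
the surrounding quantification arithmetic a study of this kind needs:
replicate concordance, genomic-feature classification, overlap
enrichment against reference cluster sets, repeat-element and CpG
annotation, ChIP-qPCR ΔCt fold enrichment, quantitative western-blot
ratios, and AFM nucleosome-height statistics.

It is written for epigenomics analysts who have aligned tag positions
(BED) in hand and want a transparent, fully tested hotspot caller that is
robust to the copy-number amplification that riddles cancer genomes —
plus a synthetic-data generator so every stage can be exercised without
any external download.

## The statistic at the core

Each chromosome is scanned with a small target window (*w* = 250 bp,
stride 50 bp) inside a large centered local-background window
(*W* = 50 kb).  With *n*<sub>bg</sub> tags in the background window and
*p* = *w*/*W*, the target-window count *n*<sub>obs</sub> is scored as

> z = (n_obs − n_bg·p) / sqrt(n_bg·p·(1 − p))

For ChIP with a matched input library, the input is normalized to the
ChIP library size and subtracted from the target-window count (floored
at 0) before scoring — this cancels shared copy-number signal, because
an amplified block inflates ChIP and input alike while true hotspots are
enriched only in the ChIP.  Significance is calibrated, not assumed:
random tag sets of the observed library size are scanned identically,
and the smallest z cutoff *t* with

> mean null #{z ≥ t} / observed #{z ≥ t} ≤ FDR  (default 0.1%)

is applied; surviving windows are merged into hotspots scored by their
maximum member z.

## Worked example

```python
import ectomap as em

# a scaled-down planted landscape: 500-kb genome, 25 true 500-bp hotspots
# (enrichment weight 40), shared CNV blocks, 100k tags per sample
truth = em.acceptance_landscape(seed=1, scale=0.05)
chip = em.simulate_tags(truth, "chip", replicate_seed=2)
ctrl = em.simulate_tags(truth, "input", replicate_seed=3)

hs = em.detect_hotspots(chip, ctrl, truth.genome, em.HotspotParams(seed=4))
print(f"{len(hs)} hotspots at z >= {hs.provenance['threshold']:.3f}")
print(hs.df.head(3).to_string(index=False))
```

prints

```
25 hotspots at z >= 0.130
chrom  start   end      max_z  adj_tags  n_windows
 chr1  13600 14500 117.489775    1558.0         14
 chr1  21300 22200 118.877116    1475.0         14
 chr1  52750 53650 131.558195    1523.0         14
```

All 25 planted hotspots are recovered and nothing else is called: each
call spans ~900 bp around a planted 500-bp region, carries ~1,500
input-adjusted tags, and scores z > 100 against its 50-kb local
background, while the calibrated threshold (z ≥ 0.13) sits just above
the best window a uniform random genome produces.  The same run pattern
on replicate pairs and qPCR plates:

```python
r1, r2 = em.simulate_replicates(truth, 2, [21, 22])
a = em.binned_density(r1, truth.genome, 10_000)
b = em.binned_density(r2, truth.genome, 10_000)
print("r2 =", round(em.concordance_r2(a, b), 4))      # r2 = 0.9984

w = em.simulate_qtpcr(true_fold=4.0, noise_sd=0.2, seed=5)
res = em.analyze_qtpcr(em.QtPcrSample("IP", w["IP"]),
                       em.QtPcrSample("mock", w["mock"]),
                       em.QtPcrSample("input", w["input"]))
print(f"fold = {res.fold_enrichment:.2f} ± {res.fold_enrichment_error:.2f}")
# fold = 3.58 ± 1.18  (one noisy triplicate plate; 200 plates average to 4.0)
```

An `r²` of 0.998 between independent replicate draws reflects the
reproducibility a concordant replicate pair should show (> 0.9), and the
qPCR pipeline inverts the simulator: a planted 4-fold enrichment is
recovered within well noise.

There is also a thin CLI for the shell-facing steps:

```bash
ectomap simulate --out-dir sim --seed 3 --scale 0.02
ectomap detect --chip sim/chip.bed --input sim/input.bed \
               --genome sim/genome.sizes --out sim/hotspots.bed
ectomap concordance --rep1 sim/chip.bed --rep2 sim/input.bed \
               --genome sim/genome.sizes
ectomap coverage --tags sim/chip.bed --genome sim/genome.sizes
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

simulates the full default landscape (one 10-Mb chromosome, 500 planted
500-bp hotspots at weight 40, two 500-kb copy-number blocks at
multiplier 3 shared by ChIP and input, 2×10⁶ tags per sample), runs
detection at FDR 0.1%, and writes the false-discovery proportion of the
calls measured against the planted truth (as a percentage, with the
number of calls).  Runs in a few seconds on one CPU.

## Layout

| module | contents |
| --- | --- |
| `ectomap.genome_tags` | genomes, tag sets, intervals, BED I/O, tag extension, coverage |
| `ectomap.hotspot_detection` | window z-scores, input adjustment, FDR calibration, merging |
| `ectomap.replicate_concordance` | binned densities, r², replicate pooling |
| `ectomap.annotation_enrichment` | feature classification, cluster overlap, repeat fractions, Fisher's exact test, CpG profiles |
| `ectomap.quantification` | qPCR ΔCt/fold-enrichment, western-blot ratios |
| `ectomap.particle_stats` | AFM particle filtering/summaries, fragment-length binning |
| `ectomap.synthetic_data` | landscape/replicate/qPCR/particle simulators |

See `docs/methods.md` for the model, its assumptions, and the reasoning
behind every default.
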