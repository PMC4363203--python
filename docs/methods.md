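# Methods

## Problem and model

MNase-ChIP-seq for an ectopically deposited histone variant yields a set
of strand-aware 5' tag positions for the ChIP sample, a matched input
(whole-chromatin) library, and optionally a mock IP.  The analytical
problem is to find regions where ChIP tags are locally enriched beyond
what chromatin abundance explains, in genomes where copy-number
amplification can inflate local tag density several-fold in *both*
libraries.

The caller scores sliding target windows of width *w* against a large
centered local background of width *W* under a binomial thinning model:
if the *n*<sub>bg</sub> background tags were scattered uniformly over
the background window, the target-window count would be
Binomial(*n*<sub>bg</sub>, *p*) with *p* = *w*/*W*, giving

    z = (n_obs − n_bg·p) / sqrt(n_bg·p·(1 − p)).

A binomial (not Poisson) variance is used; at *p* = 0.005 the difference
is the (1 − *p*) factor, but it keeps the statistic exact when
chromosome-end clipping makes *p* non-negligible.  Near chromosome ends
the background window is clipped and *p* becomes *w*/*W*<sub>eff</sub>
with the clipped width; a chromosome shorter than *W* is therefore legal.
Degenerate windows (no background tags, or *w* = *W*<sub>eff</sub> making
the variance 0) score z = 0; with raw-count backgrounds a zero background
implies a zero observation, so no information is lost.

## Input adjustment

The input library is scaled to the ChIP library size
(r = N<sub>ChIP</sub>/N<sub>input</sub>) and its target-window count is
subtracted from the ChIP target-window count before scoring, floored at
zero (negative pseudo-counts carry no meaning in a count model):

    obs = max(0, chip_w − r · input_w).

The expectation and variance are computed from the **raw** ChIP counts in
the background window.  This was a genuinely open design point, and the
alternative — applying the same subtraction to the background window —
fails a basic self-consistency check on strongly enriched samples: when a
large share of the ChIP library concentrates in hotspots (half of it in
the default simulated landscape), the genome-wide scale factor makes the
scaled input exceed the ChIP background *everywhere outside hotspots*, so
an adjusted background floors to zero across the genome and the z-score
degenerates (0/0) exactly where the signal is.  Subtracting in the target
window only keeps the statistic defined, is conservative (the expectation
still includes any local enrichment present in the background window),
and preserves the copy-number-robustness property: in a CNV-only world
the adjusted observations are ≈ 0 while the expectation stays positive,
so amplified blocks score strongly *negative* rather than positive.

## FDR calibration

No parametric null is assumed.  `n_null_sims` (default 5) random tag
sets with the observed ChIP library size, uniform over the genome, are
scanned identically — including input adjustment against the *real*
input, so the null experiences the same CNV-driven subtraction the
observations do.  The threshold is the smallest observed z value *t*
such that

    (mean null windows with z ≥ t) / (observed windows with z ≥ t) ≤ FDR,

with ties included (z ≥ *t*).  The default FDR is 0.1%, the stringent
window-level setting the analysis is designed around.  When no cutoff
satisfies the inequality — e.g. the observed data *are* a null draw — the
calibration returns +∞ with a warning, and merging an infinite threshold
yields an empty hotspot set; this is deliberate, so the composed pipeline
degrades to "no calls" rather than erroring on signal-free data.  The
threshold is non-increasing in FDR, and the whole procedure is
deterministic given the parameter seed.

Windows passing the threshold (and an optional minimum adjusted count,
`min_tags`, default 0) are unioned when they overlap or lie within
`merge_gap` bp (default 0; stepped windows of width 250 at stride 50
already overlap).  A hotspot's score is its maximum member z; its
adjusted tag count is recomputed over the merged interval (member
windows overlap, so summing them would double-count).

Window-level FDR is calibrated once and not recomputed per merged
hotspot; merging only coalesces adjacent significant windows, so the
hotspot-level false-call fraction is bounded by the window-level one in
practice (and measured directly against planted truth in the tests).

## Defaults that matter

| parameter | default | units | rationale |
| --- | --- | --- | --- |
| target window *w* | 250 | bp | nucleosome-scale signal; hotspot-method convention |
| background *W* | 50,000 | bp | local background absorbing broad chromatin trends |
| step | 50 | bp | 5× oversampling of the target window |
| FDR | 0.001 | fraction | the stringent setting this analysis is built around |
| `n_null_sims` | 5 | count | null tail stable to ~1/5 window at 2M tags |
| `merge_gap` | 0 | bp | only overlapping/adjacent windows merge |
| `min_tags` | 0 | tags | neutral; raise to suppress low-count calls in shallow data |
| tag extension | 150 | bp | strand-aware fragment length used for all overlap counting |
| concordance bin | 10,000 | bp | raw counts; empty bin pairs retained (dropping them inflates r²) |

All are configurable; none were chosen by looking at test outcomes.

## The synthetic world

`synthetic_data` states one landscape and draws from it exactly:

* uniform background tag placement, multiplied by a copy-number factor
  inside CNV blocks (both samples) and by an enrichment weight inside
  planted hotspots (ChIP only);
* exact library sizes via a multinomial over the piecewise-constant
  density; strands uniform, independent of position;
* the default landscape: one 10-Mb chromosome, 500 non-overlapping
  500-bp hotspots at weight 40 placed one per 20-kb slot, two 500-kb CNV
  blocks at multiplier 3, 2×10⁶ tags per sample — strong, comfortably
  powered signal at desk scale;
* qPCR plates: IP Ct mean = input Ct mean − log2(planted fold), mock at
  fold 1, Gaussian well noise on the Ct scale (sd 0.2 cycles, a typical
  well-to-well spread; triplicates by default);
* AFM particles: Gaussian height mixtures (e.g. tetramer-like 2.1 ±
  0.3 nm vs octamer-like 2.5 ± 0.25 nm), one Gaussian diameter model
  truncated at 1 nm.

What it does **not** emulate: mappability, MNase sequence bias,
duplicate reads, fragment-size distributions, GC effects, or any
chromatin-state structure in the background.  A green detection test
therefore establishes that the statistics and calibration are correct
for the stated model — not that real genomes satisfy the model.  In
particular, uniform-null FDR calibration will be anticonservative on
real data wherever unmodeled bias creates heavy-tailed background, which
is why the input adjustment (measuring real chromatin abundance) does
the heavy lifting there.

## qPCR, western blot, particles

* ΔCt = Ct<sub>input</sub> − Ct<sub>IP</sub>; spreads combine in
  quadrature.  Fold change FC = 2^ΔCt assumes amplification efficiency
  exactly 2 per cycle; its error uses first-order propagation
  E = FC·ln2·s<sub>ΔCt</sub> (kept in one function, trivially swappable
  for an exact log-normal form).  Fold enrichment divides FC of the IP by
  FC of the mock IP, relative errors in quadrature.  Ct dispersion uses
  the sample (n−1) estimator over wells.
* Western-blot abundance standardizes the target to co-loaded histone H4
  and then to the reference cell line; IP fold ratios are
  background-corrected and input-adjusted, flooring negative corrected
  signals at 0 with a warning.
* AFM particle filtering keeps diameters strictly below 20 nm (strictly
  DNA-associated particles) and optionally requires the round/elliptical
  shape flag.  Height comparisons use Welch's unequal-variance t-test —
  the test identity behind published particle-height P values is
  typically unstated, so the choice is guarded by a permutation-test
  oracle in the suite (same accept/reject at α = 0.01).  Fragment-length
  binning uses 4 equal-width bins on [0, 350) bp, strict upper cutoff,
  percentages of retained fluorescence.

## Numerical and tie-break choices

* Fisher's exact test (two-sided) is computed by exact integer
  hypergeometric enumeration: all tables with the observed margins whose
  probability numerator (over the common denominator) is ≤ the observed
  table's are summed.  Integer comparison makes tie handling exact; the
  suite cross-checks against an independent float enumeration and
  scipy.
* Percentages are carried unrounded and rounded half-up only at report
  time (2 decimals for overlap tables; tiny repeat fractions keep 3).
* Interval arithmetic is exact sorted-array sweeping; "overlap" always
  means ≥ 1 shared bp; touching intervals merge.
* Minus-strand tag extension anchors the 5' base as the *last* base of
  the fragment (mirror of plus strand); extensions clip at chromosome
  bounds.
* Classification precedence (promoter > exon > intron > gene >
  intergenic) resolves multi-feature overlaps; each hotspot gets exactly
  one label, so categories partition the set.

## Known limitations

* The uniform null and background model ignore mappability and sequence
  bias (see above).
* Per-hotspot FDR is not recomputed after merging.
* The concordance default (10-kb bins, raw counts) is one reasonable
  convention among several; `log1p` is provided but not default.
* `classify_hotspots` requires the precedence list to cover every label
  present in the feature set; it does not silently ignore unknown
  feature types.
* The qPCR error model is first-order; for large ΔCt spreads the
  log-normal asymmetry is not represented.
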