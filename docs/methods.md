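# Methods

## Scope

`pgscreen` models a three-arm embryo screening comparison: for each embryo,
a trophectoderm biopsy (TE), the pooled spent culture medium + blastocoel
fluid (ECB) and the remaining embryo (RE) are each sequenced at low pass and
scored for whole-chromosome and large segmental aneuploidy; TE and ECB are
then judged against RE as the reference standard. Because no raw data are
deposited for studies of this design, the package ships a first-class
synthetic-data generator that emulates the study conditions; everything
downstream (normalization, calling, concordance) operates identically on
simulated or user-supplied binned counts.

## Genome model

The genome is a list of chromosomes tiled into fixed-width, half-open,
0-based bins (default 2,000,000 bp, the upper end of the 1.5–2 Mb range
typical of low-pass embryo CNV screening; configurable via `--bin-size`).
The protocol this emulates quotes both "1.5~2 Mb" counting bins and
"1000 Kb" GC-correction bins; these cannot describe a single binning, so
the package uses one configurable bin size for both counting and GC
correction rather than guessing the original intent. Each bin carries a GC
fraction. For synthetic references GC is drawn from a Beta distribution
with mean 0.41 and sd 0.05 (human-like), clipped to [0.2, 0.8]; real bin
definitions with observed GC can be supplied as BED4. Sequence itself is
never parsed — GC is an annotation, not a computation.

The hg19 chromosome lengths (UCSC naming) are built in; at 2 Mb this gives
1560 bins, 1452 of them autosomal.

## Embryo and sample-type models

An embryo is a **clone mixture**: clonal cell populations, each with a
karyotype (whole-chromosome copy numbers plus optional segmental overrides),
with fractions summing to 1, and a constitutional sex (XX, XY or X0).
Aneuploid embryos carry 1–3 affected autosomes (uniform), gain/loss
equiprobable; with probability `p_segmental` an event is segmental with
length ≥ 50 Mb (uniform 50–100 Mb, megabase-aligned) on a chromosome long
enough to host it. Mosaic embryos are a two-clone euploid/abnormal mixture
with abnormal fraction drawn uniformly from `mosaic_fraction_range`.

The three arms see the mixture differently:

* **RE** — the deterministic mix-weighted mean copy number: a whole embryo
  averages over many cells.
* **TE** — 3–5 cells drawn multinomially from the clone fractions, then
  cell-averaged. A 50% mosaic biopsied at 4 cells yields chr copy in
  {2, 2.25, 2.5, 2.75, 3} with Binomial(4, ½) weights; a minority clone is
  regularly missed or over-represented, which is the mechanistic source of
  biopsy-vs-embryo discordance.
* **ECB** — cell-free DNA enriched for apoptotic and shed cells. Each
  abnormal clone's fraction is multiplied by `1 + w` and the mixture
  renormalized; `w = 0` reduces exactly to RE. How much ECB DNA derives
  from apoptosis versus shedding is not quantified anywhere; `w` is a free
  parameter with default 0.5, meant to be varied in experiments.

## Count model

Expected counts are proportional to `copy × bin-width × g(GC)`, where the
GC-bias curve defaults to `g(gc) = 1 − 4·(gc − 0.45)²` floored at 0.1 — a
unimodal multiplicative bias typical of WGA/low-pass libraries. With
dispersion `φ = 0` counts are multinomial over bins (totals are conserved
exactly); with `φ > 0` each bin is Gamma–Poisson (negative binomial) with
variance `μ + (φμ)²`, i.e. **φ is the extra-Poisson coefficient of
variation per bin**. The default `φ = 0.1` gives ~10–11% bin-to-bin noise
at 2 M reads, matching the MAPD ≈ 0.1 characteristic of MALBAC-amplified
low-pass data. Negative controls (blank medium) are simulated with ~1% of
a normal library and `φ = 5`, which produces the "splattering" profile of a
failed amplification (≈80% empty bins). Amplification failure of a real
sample (rate 3/120 per sample by default) replaces its table with such a
profile; QC must catch it from the data.

Default cohort conditions: ~2,000,000 reads/sample; sex frequencies
22:17:1 for XX:XY:X0; `p_aneuploid = 0.7` and `p_mosaic = 0.7` with
fractions uniform on (0.05, 0.95). These reflect a cohort in which roughly
three quarters of embryos harbor an abnormality in at least one arm and
mosaicism is common, with many fractions below the 30% reporting floor —
the regime in which the three arms genuinely disagree.

## Normalization

1. Read starts (BED) are assigned to the unique bin containing them;
   unknown chromosomes are counted as skipped.
2. The count-vs-GC trend is fitted on autosomal bins (sex bins may be
   legitimately empty) using LOWESS (span 0.3, 2 robustifying iterations,
   interpolated with boundary clamping), on width-normalized rates so the
   short terminal bin of each chromosome does not drag the curve. With
   fewer than 50 usable bins the method falls back to per-GC-decile
   medians with a warning; the decile method is also available directly
   and is deterministic. Corrected counts are `count / f̂(gc) · mean(f̂)`,
   preserving the count scale; the trend is floored at 1% of its mean to
   keep the correction bounded.
3. Corrected counts are rescaled to full-bin-width equivalents and divided
   by the autosomal **median** to give copy ratios with diploid baseline
   exactly 1.0. The median is robust while fewer than half the autosomal
   bins are aneuploid; near-haploid or near-triploid genomes would anchor
   the baseline on the wrong ploidy — a known limitation shared by all
   median-anchored low-pass CNV methods. Zero-count bins are retained.
   Sample noise is summarized as the (unscaled) MAD of autosomal ratios.

GC correction is per sample, independent of the rest of the cohort; no
mappability correction or reference-panel normalization is attempted.

## Calling

* **QC**: a sample fails if its autosomal-ratio MAD exceeds 0.35, its
  library is under 200,000 reads, or its diploid baseline is zero. Failed
  samples get `no_call` everywhere and are excluded downstream.
* **Whole chromosome**: mosaic fraction `f̂ = 2·|r − 1|` (clipped to 1).
  `f̂ < 0.30` → normal; `0.30 ≤ f̂ ≤ 0.80` → mosaic gain/loss with that
  fraction; `f̂ > 0.80` → full gain/loss. The 30%/80% band is a reporting
  rule — out-of-band dosages are still reported (as normal or full), never
  dropped — so every QC-pass sample remains classifiable. Band edges are
  inclusive with a 1e-9 tolerance against float rounding.
* **Segments**: recursive binary segmentation on bin ratios. At each step
  the split maximizing the pooled two-sample t statistic is accepted iff
  |t| ≥ 5 and both pieces span ≥ 50 Mb; each final segment is classified
  by the whole-chromosome rule. Chromosomes shorter than 100 Mb therefore
  never split, and events under 50 Mb are never isolated — matching a
  detection floor of ~50 Mb. Interior events weaken the *first* split's
  contrast (the flanking halves are pooled), so the detection guarantees
  are strongest for terminal events of ≥ 60 Mb.
* **Sex**: Y is present iff the mean Y-bin ratio exceeds 0.25; X copies are
  `round(2 · mean X ratio)` clipped to [0, 3]. (2X, −Y) → XX, (1X, +Y) →
  XY, (1X, −Y) → X0, anything else → `other`. The combined sex-chromosome
  entity is counted abnormal only when the dosage is inconsistent with the
  sample's own sex call (`other`); X0 is treated as a constitutional sex,
  consistent across the trio, not as an abnormality.
* A sample's 23 call entities are the 22 autosomes plus the combined sex
  entity; a chromosome is abnormal if its whole-chromosome call or any
  reported segment is non-normal.

Thresholds (t ≥ 5, Y presence 0.25, QC MAD 0.35) are configuration with
defaults justified by simulation: at the default noise level they give
whole-chromosome recall ≥ 99% with ≤ 1% false calls per euploid chromosome,
100% sex-call accuracy, and 100%/≥99% separation of failed vs normal
amplifications (asserted in the acceptance tests).

## Concordance

Two call sets agree iff their canonical abnormality signatures — sets of
(chromosome, direction) pairs, merging mosaic and full events of the same
direction — are equal. Mosaic calls in the 30–80% band count as abnormal by
default; a switch (`--exclude-mosaic`) drops them from signatures, since
published tables sometimes binarize differently. Agreement is an
equivalence relation, so each complete trio falls in exactly one of the
five groups and the "two agreements without the third" pattern is
impossible (property-tested).

Confusion tables take RE as truth: positives are RE-abnormal units (embryos,
or 23 entities per embryo at chromosome level), computed over QC-complete
pairs, with dropped pairs reported. Sensitivity = TP/(TP+FN), specificity =
TN/(TN+FP), each undefined on a zero denominator; percentages are exact
fractions rounded half-up to two decimals (the convention under which
19/32 prints as 59.38). Pairwise discordance fractions use the full cohort
size as denominator, mirroring how such studies report "11 of 40 (27.5%)"
even when some pairs are incomparable; incomparable pairs are tallied
separately. Group classification requires all three samples to pass QC;
embryos with any failed member are listed as excluded rather than forced
into a group.

## Problem sizes and determinism

All simulation-backed tests run at the full study scale — 2 M reads, 2 Mb
bins on the hg19-length genome — since the per-sample pipeline costs only
a few milliseconds; batches range from 40 replicates per condition
(mosaic-recovery grid, segmentation) to 500 samples (caller power). Every
stochastic path takes a seed or a `numpy.random.Generator`; cohort
simulation spawns per-embryo child seeds so runs are bit-reproducible, and
the end-to-end pipeline writes byte-identical reports under a fixed seed.

## What the simulator does not emulate

* Real ECB DNA carries degradation, fragment-length effects and possible
  maternal contamination; here ECB differs from RE only through the
  deterministic apoptosis weighting. Consequently simulated ECB-vs-RE
  discordance is milder than observed in real cohorts, and cohorts in
  which *all five* trio groups appear simultaneously are a minority of
  seeds (total three-way disagreement needs a borderline-fraction
  multi-chromosome mosaic plus an unlucky biopsy draw). Passing tests
  therefore demonstrate the arithmetic and the calling machinery, not that
  real ECB screening reaches any particular concordance level.
* No per-read simulation (no FASTQ/alignment), no mitochondrial reads, no
  mappability structure, no uniparental disomy (invisible to dosage), no
  genome-wide ploidy shifts (haploid/triploid genomes defeat a
  median-anchored baseline).
* Segmental events are simulated at ≥ 50 Mb so the default caller can see
  them; sub-50 Mb biology exists but is below this design's floor.

## Design choices where the design was open

* The dispersion parameter is defined as the Gamma-mixing CV (variance
  `μ + (φμ)²`) rather than the `μ + φμ²` convention: it makes `φ = 0.1`
  correspond to the ~10% bin noise seen in real WGA data, degrades
  gracefully to Poisson at `φ = 0`, and makes the negative-control setting
  `φ = 5` an unambiguous amplification failure.
* Copy ratios are computed from width-normalized counts; otherwise the
  remainder bin at each chromosome end (e.g. 130 kb on chr21) would
  masquerade as a loss.
* The diploid baseline is the autosomal median (robust, standard for
  low-pass CNV); the GC trend is fitted on autosomes only.
* Whole-chromosome status and segment calls share one dosage rule, so the
  caller has a single threshold vocabulary.
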