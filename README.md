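# pgscreen

Low-pass copy-number aneuploidy calling and three-way concordance analysis
for **less-invasive preimplantation genetic screening (PGS)**.

## The problem

Clinical PGS of IVF blastocysts relies on a trophectoderm (TE) biopsy of 3–5
cells. A less invasive alternative samples cell-free embryonic DNA from the
spent culture medium pooled with blastocoel fluid (**ECB**). Whether either
sample faithfully represents the embryo is an empirical question: embryos are
frequently **mosaic** — a mixture of karyotypically normal and abnormal cell
lineages — so a tiny biopsy or a pool of shed/apoptotic DNA can each tell a
different story than the **remaining embryo (RE)** taken as the reference
standard.

`pgscreen` implements the computational core of such a study end to end:

1. **Simulation** of mosaic embryo cohorts sampled three ways, with
   mechanistic sample-type models (multinomial cell sampling for TE,
   apoptosis-weighted clone mixing for ECB) and low-pass sequencing noise
   (~2 million reads/sample, 0.02–0.03×, 1.5–2 Mb bins, GC bias,
   Gamma–Poisson overdispersion, occasional amplification failure).
2. **Calling**: GC-corrected copy ratios with diploid baseline 1.0,
   whole-chromosome and ≥50 Mb segmental calls with mosaic-fraction
   estimates, sex calls (XX/XY/X0), and per-sample QC.
3. **Concordance**: sensitivity/specificity against the RE standard at the
   embryo and chromosome level, the five trio agreement groups, and pairwise
   discordance rates.

## The model

Reads are counted in fixed 2 Mb bins. For a bin `b` with GC fraction `gc_b`
and mean copy number `c_b`, expected counts are

```
E[n_b]  ∝  c_b · width_b · g(gc_b)
```

with `g` a multiplicative GC-bias curve. After local-regression GC
correction and width normalization, the copy ratio `r_b` is the corrected
count divided by the autosomal median, so two copies sit at `r = 1.0`: a
trisomy raises bin counts by 50% (`r = 1.5`) and a monosomy lowers them by
50% (`r = 0.5`).

With abnormal-cell fraction `f`, a mosaic trisomy gives `r = 1 + f/2` and a
mosaic monosomy `r = 1 − f/2`, so the caller estimates `f̂ = 2·|r − 1|`.
Mosaicism below 30% is reported as normal and above 80% as a full
gain/loss, giving ratio cut-points (0.85, 1.15) for normal and
[0.60, 0.85] / [1.15, 1.40] for mosaic calls. Sub-chromosomal events are
found by recursive binary segmentation (maximal two-sample t statistic,
accepted at |t| ≥ 5 with both pieces ≥ 50 Mb).

Two call sets **agree** when they report the same set of
(chromosome, gain/loss) findings — a full loss and a "half decrease" of the
same chromosome are one finding. Each complete trio lands in one of five
groups: (1) all agree, (2) ECB = TE ≠ RE, (3) TE = RE ≠ ECB,
(4) ECB = RE ≠ TE, (5) all differ.

## Worked example

```bash
pgs run --n 40 --seed 1 --out demo
pgs report --report demo/report.json
```

prints (output of this exact command):

```
embryos: 40  excluded: 2
groups: 1:28, 2:1, 3:1, 4:7, 5:1
embryo ECB vs RE: tp=25 fn=0 tn=12 fp=2 sens=100.0% spec=85.71%
embryo TE vs RE: tp=21 fn=3 tn=12 fp=3 sens=87.5% spec=80.0%
chromosome ECB vs RE: tp=51 fn=0 tn=843 fp=3 sens=100.0% spec=99.65%
chromosome TE vs RE: tp=41 fn=9 tn=839 fp=8 sens=82.0% spec=99.06%
discordance ECB_vs_RE: 3/40 (7.5%)
discordance TE_vs_ECB: 9/40 (22.5%)
discordance TE_vs_RE: 9/40 (22.5%)
```

Reading this: 40 embryos were simulated; 2 had an amplification-failure
sample and are excluded from grouping. 28 trios were fully concordant
(group 1); in 7 embryos the biopsy disagreed with both other samples
(group 4) — the signature of a minority clone over- or under-represented in
a 3–5 cell biopsy. Embryo-level sensitivity/specificity score each arm
against the RE standard over the QC-complete pairs (here 38 for TE, 39 for
ECB); chromosome-level tables count 23 entities (22 autosomes + the
combined sex chromosomes) per compared embryo. Discordance fractions use
the full cohort of 40 as denominator.

Every intermediate is a plain-text artifact under `demo/`: `bins.bed` (bin
tiling with GC), `counts/*.counts.tsv`, `truth.json` (the simulated clone
mixtures), `calls.tsv` (the cohort call matrix) and `report/` (TSV tables).
The stages are also available separately as `pgs simulate`, `pgs count`
(BED read positions → bin counts), `pgs call` and `pgs compare`, and as
library functions (`pgscreen.simulate`, `pgscreen.normalize`,
`pgscreen.caller`, `pgscreen.concordance`).

## Documentation

See `docs/methods.md` for the full model description, parameter defaults,
what the simulator does and does not emulate, and known limitations.
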