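# convexcnv

Somatic copy-number calling from tumour/matched-normal **whole-exome**
sequencing, for cancer genomics analysts working with capture data. Exome
coverage is sparse and noisy — GC content, mappability and bait-capture
bias all distort per-exon read depth — so naive per-exon ratio thresholds
produce floods of false positives. `convexcnv` addresses this by denoising
the tumour/normal depth-of-coverage (DOC) ratio track with a Haar discrete
wavelet transform before segmenting it with a copy-number hidden Markov
model, trading a little sensitivity on one-exon events for much higher
precision.

## Method

For each capture target (exon) *i*, with mean-normalized tumour and control
depths *N<sub>Ti</sub>* and *N<sub>Ci</sub>*:

1. **QC + ratios.** Targets with control DOC < 10× are dropped from both
   samples; each sample is divided by its mean DOC (library-size
   normalization); the per-exon ratio is *R<sub>i</sub> = N<sub>Ti</sub> /
   N<sub>Ci</sub>*, then divided by the genome-wide median so the most
   abundant tumour ploidy sits at ratio 1.
2. **Wavelet denoising.** The ratio is modelled as a piecewise-constant
   copy-number signal plus iid N(0, σ²) noise. Each chromosome is
   decomposed with the orthonormal Haar wavelet; every detail level is
   soft-thresholded at the level's own minimizer of Stein's unbiased risk
   estimate (SURE), with the noise scale estimated by the MAD rule on the
   finest level; the inverse transform gives the denoised track.
3. **Copy-number HMM.** Hidden states are integer copies 0–5 (homozygous
   deletion … three-copy amplification). State *k* emits
   N(μ<sub>k</sub>, σ²) with

   μ<sub>k</sub> = (α·2 + (1−α)·c<sub>k</sub>) / (α·2 + (1−α)·P<sub>T</sub>),

   where α is the normal-cell contamination fraction and *P<sub>T</sub>*
   the most abundant tumour ploidy — so with α = 0, P<sub>T</sub> = 2 the
   copies 0–4 map to ratios (0, 0.5, 1, 1.5, 2). The initial and transition
   distributions favour the neutral state and self-transitions; the one
   free parameter σ is fitted by bounded negative-log-likelihood
   minimization, and states are decoded per chromosome with the Viterbi
   algorithm, then run-length encoded into segments.

A paired-coverage simulator (shared exon capture efficiency, overdispersed
counting noise, CNV spike-ins, contamination mixing) and exon-level
direction-matched scoring support benchmarking.

## Worked example

Simulate a 3,000-exon pair with a 250 kb homozygous deletion (depth ×0.05)
and a 40 kb duplication (×2), call it, and score against the truth:

```bash
convex simulate --out sim --seed 7 --n-exons 3000 \
    --event 250000:0.05 --event 40000:2
convex call --tumour sim/tumour.tsv --control sim/control.tsv --out calls
# -> 5 segments (2 CNV); sigma=0.0100; results in calls
```

`calls/segments.tsv` contains the two spiked events and nothing else:

```text
chrom   start     end       copy_number  n_exons  mean_ratio  is_cnv
chr1    16096541  16121846  4            3        1.90737     1
chr1    34507321  34729842  0            17       0.0771441   1
```

The duplication is recovered as copy 4 (ratio ≈ 2) over its 3 exons and the
deletion as copy 0 (ratio ≈ 0.05) over its 17 exons; the remaining three
segments (not shown) are the flanking copy-2 runs. Exon-level scoring:

```bash
convex evaluate --truth sim/truth.tsv --calls calls/exons.tsv
# tp 20  fp 0  tn 2980  fn 0
# sensitivity 1  specificity 1  precision 1  accuracy 1
```

All 20 spiked exons are recovered in the right direction with no false
positive among the 2,980 neutral exons.

Real data enter through the same two depth tables — 4 columns
(`chrom`, `start`, `end`, `doc`) with the mean per-base coverage of every
capture target, e.g. produced from a BAM and a target BED with
`bedtools coverage -mean -a targets.bed -b sample.bam`.

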