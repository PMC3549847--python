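# Methods

## Signal model

The observable is the per-exon depth-of-coverage (DOC) ratio between a
tumour and its matched normal. After library-size normalization the ratio
at exon *i* is modelled as a piecewise-constant copy-number signal plus
additive noise, R_i = R̄_i + ε_i with ε_i ~ iid N(0, σ²). Both the wavelet
denoiser and the HMM emissions rest on this Gaussian-additive assumption;
real counting noise is only approximately Gaussian (ratios of counts are
right-skewed, and variance grows as coverage falls), which is why the QC
step removes the low-coverage targets where the approximation is worst.

## Preprocessing

* **QC filter** — a target is retained iff its *control* DOC ≥ `min_doc`
  (default 10×, inclusive). The control alone decides: low tumour depth is
  potential deletion signal, not a quality defect. The filter runs before
  library normalization, so removed targets do not bias the library-size
  estimate.
* **Library-size normalization** — each sample's DOC vector is divided by
  its own mean over the retained targets.
* **Median normalization** — the ratio track is divided by its genome-wide
  median (not per-chromosome: the most abundant tumour ploidy, the
  quantity the median estimates, is a property of the sample, not of a
  chromosome). After this step the expected ratio of a region with tumour
  copy number c is (α·2 + (1−α)·c) / (α·2 + (1−α)·P_T).

## Wavelet denoising

Each chromosome is denoised independently:

* **Padding** — the ratio vector is extended on the right by reflection to
  the next power of two and cropped after reconstruction. Reflection keeps
  the extension continuous for piecewise-constant signals; periodic
  padding would create a spurious jump between the two chromosome ends.
  A side effect is that exact reversal-equivariance of the smoother holds
  only at dyadic lengths.
* **Transform** — orthonormal Haar (periodized), so energy is preserved
  exactly and the iid noise has the same standard deviation at every
  level; the finest-level MAD estimate median(|d|)/0.6745 is therefore
  used unscaled at all levels.
* **Depth** — floor(log2 n) levels, capped at 6. The cap keeps the
  coarsest levels populated with enough coefficients for the SURE minimum
  to be stable on exome-sized chromosomes; it also bounds the widest
  block average at 64 exons.
* **Thresholding** — each detail level gets its own soft threshold, the
  minimizer of SURE(t) = nσ² − 2σ²·#{|d_i| ≤ t} + Σ min(d_i², t²) over the
  candidate set {0} ∪ {|d_i|}; ties go to the smallest threshold (least
  shrinkage). Approximation coefficients are never thresholded, following
  standard wavelet-denoising practice. Pure SURE is used rather than a
  hybrid rule; in very sparse regimes SURE is known to under-threshold,
  which we document rather than correct.
* **Degenerate inputs** — chromosomes with fewer than 4 targets pass
  through unsmoothed; output is clipped below at 0 (ratios are
  non-negative by construction).

## Copy-number HMM

States are integer copies 0..K−1 (default K = 6). Emissions are Gaussian
with state means from the contamination/ploidy model above (normal ploidy
fixed at 2) and one shared σ. The copy-0 mean is α·2/(α·2+(1−α)·P_T) — 0
without contamination — with no truncation of the emission density, since
the observations are clipped non-negative upstream.

The initial distribution puts 0.95 on the neutral (copy-2) state and
splits 0.05 equally over the rest. Transitions: 0.95 on the diagonal;
from a CNV state, 0.03 to neutral and the remaining 0.02 split equally
over the other CNV states; from neutral, 0.05 split equally over all CNV
states. These numbers realize the ordinal design constraints — stay >
return-to-neutral > CNV-to-CNV — and are deliberately simple; they are
exposed as module constants rather than fitted.

Only σ is estimated from data (bounded scalar minimization of the forward
negative log-likelihood on [0.01, 1.0], tolerance 1e-6, started from
MAD(track − 1)/0.6745 clipped to the bounds, never returning a worse model
than the start). π, A and μ stay fixed: with a single noisy track per
sample, re-estimating the full transition structure (Baum–Welch) mostly
absorbs noise and is out of scope. On clean tracks the fit pins σ at the
lower bound, which simply means "noise below the resolution floor".

Decoding is Viterbi in log space, run per chromosome with a fresh initial
distribution (chromosomes are independent calling units); exact ties break
toward the lower copy number, which makes output deterministic and
conservative at decision boundaries. For multi-chromosome inputs the one
shared σ is fitted on the concatenated smoothed track in a single forward
pass; the cross-boundary transition this implies is one factor in ~10⁴ and
numerically irrelevant. Decoded runs of equal copy number within a
chromosome become segments (neutral ones included, flagged `is_cnv=0`).

## Synthetic data generator

The simulator emulates paired capture data at the default study
conditions: 15,000 exons of 200–300 bp on one chromosome with inter-exon
gaps uniform on 1–30 kb (≈235 Mb span, matching the exon density of a
large human chromosome, under which a 10 kb event covers 1–2 exons and a
1 Mb event ≈60), mean coverage `base_rate` = 100×, a log-normal
exon-specific capture efficiency (sd 0.5 on the log scale) *shared* by the
two samples, and per-base counting noise: each base's coverage is
negative-binomial with size `dispersion` = 10 (Poisson in the
`dispersion → ∞` limit), and the exon DOC is the mean over its bases —
the same mean-of-per-base-coverage definition the caller consumes.

Spiked events multiply tumour depths over whole exons by a factor (0.05 ≈
homozygous deletion, 2 = duplication to copy 4; truth copy =
round(2·factor) clipped to [0, 5]), are anchored at uniformly chosen
exons, and stay disjoint. Contamination is mixed on the depth scale as
α·control + (1−α)·tumour.

What the generator does **not** emulate: GC-content and mappability trends
(bias that does not cancel between samples), coverage-dependent ratio
variance, germline CNVs in the control, and read-level artefacts. Because
the shared capture effect cancels in the ratio, the synthetic ratio track
is substantially cleaner (per-exon ratio noise ≈ 3% at these defaults)
than typical real tumour/normal exome data. Consequences to keep in mind
when reading the benchmark numbers:

* near-ceiling sensitivity and precision on the spike-in study demonstrate
  the pipeline's correctness and its behaviour under the stated
  conditions, not expected field performance on real exomes;
* with contamination **misspecified as 0**, sensitivity stays at ceiling
  until the shrunk event amplitude crosses the HMM's decision boundary
  (≈α = 0.75), so the degradation over α is weakly monotone — flat, then a
  cliff — rather than the gradual decline seen on noisier real data. The
  trend test in the acceptance suite therefore uses per-replicate runs,
  where the cliff still yields a significant negative Spearman rank
  correlation.

## Evaluation

Scoring is exon-level. A truth exon is positive iff its copy differs
from 2. A true positive requires the call to be non-neutral **in the same
direction** (any loss matches any loss, any gain any gain); exact-copy
matching is available via `strict_copy`. A call in the wrong direction is
counted as both a false positive and a false negative — one spurious call
plus one missed event — so the four counts can exceed the exon total when
direction mismatches occur. Exons removed by QC are excluded from all
metrics, and any metric with a zero denominator is reported as NA (and
dropped before medians/means in study summaries).

## Problem sizes of the shipped benchmark

The acceptance script and the heavy tests run the study at the documented
defaults: 100 overall replicates (50 deletions ×0.05, 50 duplications ×2,
sizes uniform on 1 kb–1 Mb) and a short-variant sweep of 10 sizes
(200 bp–10 kb) × 20 replicates × both types, all on 15,000-exon tracks;
the contamination analysis uses 15 replicates per (α, type) cell at
1–10 kb. All replicate seeds derive from one root seed.
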