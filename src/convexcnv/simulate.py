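"""Synthetic paired-exome coverage and the CNV spike-in protocol.

The generator stands in for real tumour/normal exome depth data.  It
emulates the two dominant features of capture data that matter for ratio
calling:

* an exon-specific capture efficiency g_i = exp(N(0, capture_effect_sd^2))
  shared between the two samples — the bait-capture bias that largely
  cancels in the tumour/normal ratio;
* overdispersed counting noise: the per-base coverage of each of the
  length_i bases of exon i is NB(mean = base_rate * g_i, size = dispersion)
  iid, independently per sample, and the exon DOC is their mean — the same
  mean-of-per-base-coverage definition the caller consumes.  Since the iid
  per-base draws share one success probability, the exon total is drawn
  exactly as a single NB with size length_i * dispersion.  ``dispersion``
  is the negative-binomial size parameter (variance m + m^2/dispersion per
  base); ``dispersion = inf`` gives the Poisson limit.

Spiked events multiply the tumour depths of the covered exons by a factor
(0.05 for a homozygous deletion, 2 for a duplication to copy 4, ...); the
implied truth copy number is round(2 * factor) clipped to [0, K-1].
Normal-cell contamination is emulated by mixing
alpha * control + (1 - alpha) * tumour on the depth scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .targets_io import DepthProfile, InputError, TargetRegion

__all__ = [
    "SimulationSpec",
    "generate_pair",
    "spike_cnv",
    "mix_contamination",
    "place_event",
    "run_simulation_study",
]

MAX_COPY = 5


@dataclass
class SimulationSpec:
    """Study conditions of the synthetic paired-exome generator."""

    n_exons: int = 15000
    exon_length_range: tuple[int, int] = (200, 300)
    gap_range: tuple[int, int] = (1_000, 30_000)
    chrom_layout: dict[str, int] | None = None  # default: all exons on chr1
    base_rate: float = 100.0
    capture_effect_sd: float = 0.5
    dispersion: float = 10.0
    alpha: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_exons < 1:
            raise InputError("n_exons must be >= 1")
        if self.base_rate <= 0 or self.dispersion <= 0:
            raise InputError("base_rate and dispersion must be > 0")
        if not 0.0 <= self.alpha <= 1.0:
            raise InputError("alpha must be in [0, 1]")
        if self.chrom_layout is None:
            self.chrom_layout = {"chr1": self.n_exons}
        if sum(self.chrom_layout.values()) != self.n_exons:
            raise InputError("chrom_layout exon counts must sum to n_exons")


def _draw_regions(spec: SimulationSpec, rng: np.random.Generator) -> list[TargetRegion]:
    regions: list[TargetRegion] = []
    lo_l, hi_l = spec.exon_length_range
    lo_g, hi_g = spec.gap_range
    for chrom, n in spec.chrom_layout.items():
        pos = int(rng.integers(lo_g, hi_g + 1))
        for i in range(n):
            length = int(rng.integers(lo_l, hi_l + 1))
            regions.append(TargetRegion(chrom, pos, pos + length, f"{chrom}_exon{i}"))
            pos += length + int(rng.integers(lo_g, hi_g + 1))
    return regions


def _draw_depths(
    per_base_mean: np.ndarray,
    lengths: np.ndarray,
    dispersion: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Exon DOC = mean of iid per-base NB counts, drawn as one NB per exon."""
    if np.isinf(dispersion):
        return rng.poisson(per_base_mean * lengths) / lengths
    p = dispersion / (dispersion + per_base_mean)
    return rng.negative_binomial(lengths * dispersion, p) / lengths


def generate_pair(
    spec: SimulationSpec,
) -> tuple[DepthProfile, DepthProfile, list[TargetRegion]]:
    """Generate a control and a copy-neutral tumour-baseline depth profile."""
    rng = np.random.default_rng(spec.seed)
    regions = _draw_regions(spec, rng)
    lengths = np.array([len(r) for r in regions], dtype=float)
    g = np.exp(rng.normal(0.0, spec.capture_effect_sd, size=len(regions)))
    per_base_mean = spec.base_rate * g
    control = _draw_depths(per_base_mean, lengths, spec.dispersion, rng)
    tumour = _draw_depths(per_base_mean, lengths, spec.dispersion, rng)
    return (
        DepthProfile(regions=regions, doc=control, sample_id="control"),
        DepthProfile(regions=list(regions), doc=tumour, sample_id="tumour"),
        regions,
    )


def _resolve_span(
    regions: Sequence[TargetRegion], span
) -> np.ndarray:
    """Span -> exon index array.  Accepts (chrom, start, end) or exon indices."""
    if (
        isinstance(span, tuple)
        and len(span) == 3
        and isinstance(span[0], str)
    ):
        chrom, start, end = span
        idx = np.array(
            [
                i
                for i, r in enumerate(regions)
                if r.chrom == chrom and r.start < end and r.end > start
            ],
            dtype=int,
        )
    else:
        idx = np.asarray(span, dtype=int)
    if idx.size == 0:
        raise InputError(f"event span {span!r} covers no exon")
    return idx


def spike_cnv(
    tumour: DepthProfile,
    regions: Sequence[TargetRegion],
    event: tuple,
) -> tuple[DepthProfile, np.ndarray]:
    """Multiply the tumour depth of the event's exons by the event factor.

    ``event`` is ``(span, factor)`` where span is a (chrom, start, end)
    genomic interval or an explicit exon-index sequence.  Returns the spiked
    profile and the per-exon truth copy numbers (neutral exons stay 2);
    the implied copy of a factor-f event is round(2*f) clipped to [0, 5].
    """
    span, factor = event
    if factor <= 0:
        raise InputError(f"event factor must be > 0, got {factor}")
    idx = _resolve_span(regions, span)
    doc = tumour.doc.copy()
    doc[idx] *= factor
    truth = np.full(len(regions), 2, dtype=int)
    truth[idx] = int(np.clip(round(2.0 * factor), 0, MAX_COPY))
    spiked = DepthProfile(
        regions=list(tumour.regions), doc=doc, sample_id=tumour.sample_id
    )
    return spiked, truth


def mix_contamination(
    control: DepthProfile, tumour: DepthProfile, alpha: float
) -> DepthProfile:
    """Normal-cell admixture on the depth scale: alpha*control + (1-alpha)*tumour."""
    if not 0.0 <= alpha <= 1.0:
        raise InputError(f"alpha must be in [0, 1], got {alpha}")
    if len(control) != len(tumour) or any(
        (a.chrom, a.start, a.end) != (b.chrom, b.start, b.end)
        for a, b in zip(control.regions, tumour.regions)
    ):
        raise InputError("control and tumour cover different region lists")
    return DepthProfile(
        regions=list(tumour.regions),
        doc=alpha * control.doc + (1.0 - alpha) * tumour.doc,
        sample_id=tumour.sample_id,
    )


def place_event(
    regions: Sequence[TargetRegion],
    size_bp: int,
    rng: np.random.Generator,
    chrom: str = "chr1",
    exclude: set[int] | None = None,
) -> tuple[str, int, int]:
    """Anchor an event of ``size_bp`` at a uniformly chosen exon of ``chrom``.

    The genomic interval starts at the anchor exon's start, so every event
    covers at least one whole exon.  ``exclude`` holds exon indices already
    used by other events (placement retries to keep events disjoint).
    """
    candidates = [i for i, r in enumerate(regions) if r.chrom == chrom]
    if not candidates:
        raise InputError(f"no exons on {chrom}")
    for _ in range(1000):
        anchor = int(rng.choice(candidates))
        span = (chrom, regions[anchor].start, regions[anchor].start + int(size_bp))
        idx = _resolve_span(regions, span)
        if exclude is None or not exclude.intersection(idx.tolist()):
            if exclude is not None:
                exclude.update(idx.tolist())
            return span
    raise InputError("could not place a non-overlapping event after 1000 tries")


def run_simulation_study(
    conditions: Sequence[dict],
    base_spec: SimulationSpec | None = None,
    seed: int = 0,
    min_doc: float = 10.0,
    K: int = 6,
    tumour_ploidy: float = 2.0,
    smoothing: bool = True,
) -> pd.DataFrame:
    """Run the spike-in study grid: generate, spike, mix, call, score.

    Each condition is a dict with keys:

    ``name``          condition label;
    ``factor``        depth multiplier of the spiked event (>0);
    ``size_bp``       event size — a scalar, or a (lo, hi) tuple sampled
                      uniformly per replicate;
    ``n_replicates``  number of seeded replicates;
    ``n_events``      events per replicate (default 1; 0 gives a pure-noise
                      replicate whose sensitivity is NA);
    ``alpha``         true contamination mixed into the tumour (default 0);
    ``alpha_given``   contamination passed to the caller (default = alpha).

    Returns one row per replicate with the exon-level confusion counts and
    the four headline metrics.
    """
    from .pipeline import CallParams, call_copy_number  # local import, no cycle

    base_spec = base_spec or SimulationSpec()
    rows: list[dict] = []
    ss = np.random.SeedSequence(seed)
    for cond in conditions:
        name = cond.get("name", f"factor={cond['factor']}")
        factor = float(cond["factor"])
        n_rep = int(cond.get("n_replicates", 1))
        n_events = int(cond.get("n_events", 1))
        alpha_true = float(cond.get("alpha", 0.0))
        alpha_given = float(cond.get("alpha_given", alpha_true))
        size_spec = cond.get("size_bp", (1_000, 1_000_000))
        for rep, child in enumerate(ss.spawn(n_rep)):
            rep_seed = int(child.generate_state(1)[0] % (2**31))
            rng = np.random.default_rng(rep_seed)
            spec = SimulationSpec(
                n_exons=base_spec.n_exons,
                exon_length_range=base_spec.exon_length_range,
                gap_range=base_spec.gap_range,
                chrom_layout=dict(base_spec.chrom_layout),
                base_rate=base_spec.base_rate,
                capture_effect_sd=base_spec.capture_effect_sd,
                dispersion=base_spec.dispersion,
                alpha=alpha_true,
                seed=rep_seed,
            )
            control, tumour, regions = generate_pair(spec)
            truth = np.full(len(regions), 2, dtype=int)
            used: set[int] = set()
            size = 0
            for _ in range(n_events):
                if isinstance(size_spec, (tuple, list)):
                    size = int(rng.integers(int(size_spec[0]), int(size_spec[1]) + 1))
                else:
                    size = int(size_spec)
                span = place_event(regions, size, rng, exclude=used)
                tumour, ev_truth = spike_cnv(tumour, regions, (span, factor))
                truth = np.where(ev_truth != 2, ev_truth, truth)
            if alpha_true > 0:
                tumour = mix_contamination(control, tumour, alpha_true)
            result = call_copy_number(
                control,
                tumour,
                CallParams(
                    min_doc=min_doc,
                    alpha=alpha_given,
                    tumour_ploidy=tumour_ploidy,
                    K=K,
                    smoothing=smoothing,
                ),
            )
            metrics = result.score(truth)
            rows.append(
                {
                    "condition": name,
                    "replicate": rep,
                    "seed": rep_seed,
                    "factor": factor,
                    "size_bp": size,
                    "alpha_true": alpha_true,
                    "alpha_given": alpha_given,
                    "n_exons_scored": int(result.retained.sum()),
                    "fitted_sigma": result.model.sigma,
                    **metrics.as_dict(),
                }
            )
    return pd.DataFrame(rows)
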