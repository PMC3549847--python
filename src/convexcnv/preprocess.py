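"""QC filtering, library-size normalization and tumour/normal ratio tracks.

Stages, in the order the pipeline applies them:

1. ``qc_filter`` — drop every target whose *control* mean depth is below a
   threshold (default 10x); low-coverage targets have wildly unstable
   ratios.  The same targets are dropped from both samples.
2. ``normalize_library`` — divide each sample's depths by its own mean,
   removing the difference in total sequencing yield between the two
   libraries.
3. ``compute_ratio`` — per-exon ratio R_i = N_Ti / N_Ci of the normalized
   tumour over normalized control depth.
4. ``median_normalize`` — divide the whole ratio track by its genome-wide
   median, so that the most abundant tumour ploidy maps to ratio 1 and the
   copy-number-to-ratio model depends on tumour ploidy only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .targets_io import DepthProfile, InputError, TargetRegion

__all__ = ["RatioTrack", "qc_filter", "normalize_library", "compute_ratio", "median_normalize"]

DEFAULT_MIN_DOC = 10.0


@dataclass
class RatioTrack:
    """Per-region tumour/normal DOC ratios grouped by chromosome.

    ``stage`` is one of ``raw``, ``median_normalized``, ``smoothed``;
    ``chrom_index`` maps each chromosome name to the slice of positions it
    occupies (regions must be contiguous per chromosome).
    """

    regions: list[TargetRegion]
    values: np.ndarray
    stage: str = "raw"
    chrom_index: dict[str, slice] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.regions):
            raise InputError("values length does not match regions")
        if self.values.size and np.min(self.values) < 0:
            raise InputError("ratio values must be non-negative")
        if self.chrom_index is None:
            self.chrom_index = _build_chrom_index(self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    def with_values(self, values: np.ndarray, stage: str) -> "RatioTrack":
        return replace(self, values=np.asarray(values, dtype=float), stage=stage)

    def chromosomes(self) -> list[str]:
        return list(self.chrom_index)


def _build_chrom_index(regions: list[TargetRegion]) -> dict[str, slice]:
    index: dict[str, slice] = {}
    if not regions:
        return index
    start = 0
    for i in range(1, len(regions) + 1):
        if i == len(regions) or regions[i].chrom != regions[start].chrom:
            chrom = regions[start].chrom
            if chrom in index:
                raise InputError(f"regions of chromosome {chrom} are not contiguous")
            index[chrom] = slice(start, i)
            start = i
    return index


def _check_same_regions(a: DepthProfile, b: DepthProfile) -> None:
    if len(a) != len(b) or any(
        (ra.chrom, ra.start, ra.end) != (rb.chrom, rb.start, rb.end)
        for ra, rb in zip(a.regions, b.regions)
    ):
        raise InputError("tumour and control profiles cover different region lists")


def qc_filter(
    control: DepthProfile,
    tumour: DepthProfile,
    min_doc: float = DEFAULT_MIN_DOC,
) -> tuple[DepthProfile, DepthProfile]:
    """Retain only targets whose control DOC is >= ``min_doc``, in both samples.

    The control sample alone decides retention: its depth is the reference
    and a well-covered control keeps the ratio denominator stable.
    """
    _check_same_regions(control, tumour)
    mask = control.doc >= min_doc
    return control.subset(mask), tumour.subset(mask)


def normalize_library(profile: DepthProfile) -> DepthProfile:
    """Divide every depth by the profile mean (library-size normalization)."""
    if len(profile) == 0:
        raise InputError("cannot normalize an empty profile (no regions survive QC?)")
    mean = float(profile.doc.mean())
    if mean <= 0:
        raise InputError(f"degenerate profile {profile.sample_id}: mean depth {mean}")
    return DepthProfile(
        regions=profile.regions,
        doc=profile.doc / mean,
        sample_id=profile.sample_id,
        normalized=True,
    )


def compute_ratio(tumour_norm: DepthProfile, control_norm: DepthProfile) -> RatioTrack:
    """Per-exon DOC ratio R_i = N_Ti / N_Ci of the two normalized profiles."""
    if not (tumour_norm.normalized and control_norm.normalized):
        raise InputError("compute_ratio expects mean-normalized profiles")
    _check_same_regions(tumour_norm, control_norm)
    zeros = np.flatnonzero(control_norm.doc == 0)
    if zeros.size:
        r = control_norm.regions[int(zeros[0])]
        raise InputError(
            f"control depth is zero at {r.chrom}:{r.start}-{r.end}; "
            "raise the QC threshold"
        )
    return RatioTrack(
        regions=list(tumour_norm.regions),
        values=tumour_norm.doc / control_norm.doc,
        stage="raw",
    )


def median_normalize(track: RatioTrack) -> RatioTrack:
    """Divide the whole track by its genome-wide median ratio.

    After this step the most abundant ploidy of the tumour sits at ratio 1,
    so the expected ratio of copy number c is (alpha*2+(1-alpha)*c) over
    (alpha*2+(1-alpha)*P_T) regardless of absolute ploidy.
    """
    if len(track) == 0:
        raise InputError("empty ratio track")
    med = float(np.median(track.values))
    if med <= 0:
        raise InputError(f"degenerate ratio track: median {med}")
    return track.with_values(track.values / med, stage="median_normalized")
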