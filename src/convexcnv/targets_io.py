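"""Target regions and per-exon depth-of-coverage tables.

The calling pipeline starts from capture-target coordinates (BED,
0-based half-open) and one 4-column depth table per sample
(chrom, start, end, doc) as produced by a ``bedtools coverage``-style
upstream step.  The atomic unit throughout is the exon / capture target;
depths are mean per-base coverage over the target.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TargetRegion",
    "DepthProfile",
    "read_targets",
    "write_targets",
    "read_depth_table",
    "write_depth_table",
    "exon_doc_from_per_base",
    "natural_chrom_key",
]


class InputError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass(frozen=True, order=False)
class TargetRegion:
    """One capture target (exon), 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    id: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise InputError(f"negative start in region {self.chrom}:{self.start}-{self.end}")
        if self.start >= self.end:
            raise InputError(
                f"region {self.chrom}:{self.start}-{self.end} has start >= end"
            )

    def __len__(self) -> int:
        return self.end - self.start


_CHROM_CHUNKS = re.compile(r"(\d+)")


def natural_chrom_key(chrom: str) -> tuple:
    """Sort key giving the natural chromosome order chr1 < chr2 < chr10 < chrX."""
    return tuple(
        int(part) if part.isdigit() else part
        for part in _CHROM_CHUNKS.split(chrom)
    )


def sort_regions_with_index(regions: Sequence[TargetRegion]) -> tuple[list[TargetRegion], np.ndarray]:
    """Natural (chrom, start) sort; returns regions and the permutation applied."""
    order = sorted(
        range(len(regions)),
        key=lambda i: (natural_chrom_key(regions[i].chrom), regions[i].start, regions[i].end),
    )
    idx = np.asarray(order, dtype=int)
    return [regions[i] for i in order], idx


@dataclass
class DepthProfile:
    """Per-region mean depth of coverage for one sample.

    ``doc[i]`` is the mean per-base coverage of ``regions[i]``.  After
    library-size normalization (``normalized=True``) the values are unitless
    with mean 1 over all regions.
    """

    regions: list[TargetRegion]
    doc: np.ndarray
    sample_id: str = "sample"
    normalized: bool = False

    def __post_init__(self) -> None:
        self.doc = np.asarray(self.doc, dtype=float)
        if self.doc.ndim != 1 or len(self.doc) != len(self.regions):
            raise InputError(
                f"depth vector length {self.doc.size} does not match "
                f"{len(self.regions)} regions"
            )
        if self.doc.size and np.min(self.doc) < 0:
            i = int(np.argmin(self.doc))
            raise InputError(f"negative depth {self.doc[i]} at region index {i}")
        if self.normalized and self.doc.size:
            mean = float(self.doc.mean())
            if abs(mean - 1.0) > 1e-9:
                raise InputError(f"profile flagged normalized but mean doc is {mean}")

    def __len__(self) -> int:
        return len(self.regions)

    def subset(self, mask: np.ndarray) -> "DepthProfile":
        """Profile restricted to ``mask`` (boolean or index array), order kept."""
        idx = np.arange(len(self))[mask] if np.asarray(mask).dtype == bool else np.asarray(mask)
        return DepthProfile(
            regions=[self.regions[i] for i in idx],
            doc=self.doc[idx],
            sample_id=self.sample_id,
            normalized=False,
        )

    def sorted(self) -> "DepthProfile":
        regions, idx = sort_regions_with_index(self.regions)
        return replace(self, regions=regions, doc=self.doc[idx])


def read_targets(path: str | Path) -> list[TargetRegion]:
    """Read capture targets from a 3+ column BED file (file order kept)."""
    path = Path(path)
    regions: list[TargetRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise InputError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 and fields[3] else None
            try:
                regions.append(TargetRegion(fields[0], start, end, name))
            except InputError as exc:
                raise InputError(f"{path}:{lineno}: {exc}") from exc
    return regions


def write_targets(regions: Iterable[TargetRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            name = "" if r.id is None else f"\t{r.id}"
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}{name}\n")


def read_depth_table(path: str | Path, sample_id: str | None = None) -> DepthProfile:
    """Read a 4-column depth table (chrom, start, end, doc TSV with header).

    Row order of the file is preserved; sorting is the caller's choice.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"chrom", "start", "end", "doc"}
    if not required.issubset(df.columns):
        raise InputError(f"{path}: depth table must have columns {sorted(required)}")
    if (df["doc"] < 0).any():
        bad = df.index[df["doc"] < 0][0]
        raise InputError(f"{path}: negative doc at row {bad}")
    if df.duplicated(subset=["chrom", "start", "end"]).any():
        bad = df[df.duplicated(subset=["chrom", "start", "end"])].iloc[0]
        raise InputError(
            f"{path}: duplicate region {bad['chrom']}:{bad['start']}-{bad['end']}"
        )
    regions = [
        TargetRegion(str(c), int(s), int(e))
        for c, s, e in zip(df["chrom"], df["start"], df["end"])
    ]
    return DepthProfile(
        regions=regions,
        doc=df["doc"].to_numpy(dtype=float),
        sample_id=sample_id or path.stem,
        normalized=False,
    )


def write_depth_table(profile: DepthProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tdoc\n")
        for r, d in zip(profile.regions, profile.doc):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{d:.6g}\n")


def exon_doc_from_per_base(depths: Sequence[float] | np.ndarray) -> float:
    """Exon-level DOC: arithmetic mean of the per-base coverage of the exon."""
    depths = np.asarray(depths, dtype=float)
    if depths.size == 0:
        raise InputError("empty per-base depth vector")
    return float(depths.mean())
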