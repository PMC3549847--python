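"""End-to-end orchestration: depth tables -> QC -> ratios -> smoothing -> HMM.

``call_copy_number`` is the in-memory pipeline used by both the CLI and the
simulation study; ``run_pipeline`` is the file-to-file wrapper around it.
All randomness lives in the simulator — calling is fully deterministic, so
identical inputs and parameters give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .evaluate import ConfusionMetrics, score_exons
from .hmm import (
    HMMModel,
    Segment,
    StatePath,
    call_segments,
    decode_track,
    default_model,
    fit_sigma,
    initial_sigma,
)
from .preprocess import (
    DEFAULT_MIN_DOC,
    RatioTrack,
    compute_ratio,
    median_normalize,
    normalize_library,
    qc_filter,
)
from .targets_io import DepthProfile, InputError, read_depth_table, read_targets
from .wavelet import SmoothingConfig, smooth_track

__all__ = ["CallParams", "CallResult", "RunConfig", "call_copy_number", "run_pipeline"]

logger = logging.getLogger("convexcnv")


@dataclass
class CallParams:
    """Parameters of one calling run (defaults follow the method's)."""

    min_doc: float = DEFAULT_MIN_DOC
    alpha: float = 0.0
    tumour_ploidy: float = 2.0
    K: int = 6
    smoothing: bool = True
    sigma_override: float | None = None
    sigma_bounds: tuple[float, float] = (0.01, 1.0)


@dataclass
class CallResult:
    """Everything one calling run produced, aligned to the retained exons."""

    retained: np.ndarray  # boolean mask over the input region list
    raw_track: RatioTrack
    smoothed_track: RatioTrack
    model: HMMModel
    path: StatePath
    segments: list[Segment]

    def score(self, truth: np.ndarray, strict_copy: bool = False) -> ConfusionMetrics:
        """Score the decoded states against a truth table over the *input* exons.

        Exons removed by QC are excluded from the metrics.
        """
        truth = np.asarray(truth, dtype=int)
        if truth.size != self.retained.size:
            raise InputError("truth table length does not match input region count")
        return score_exons(truth[self.retained], self.path.states, strict_copy)


def call_copy_number(
    control: DepthProfile,
    tumour: DepthProfile,
    params: CallParams | None = None,
) -> CallResult:
    """Run the full calling pipeline on a pair of depth profiles.

    Stages: QC filter on control depth -> per-sample mean normalization ->
    tumour/control ratio -> genome-wide median normalization -> per-chromosome
    Haar/SURE smoothing -> sigma fit -> per-chromosome Viterbi -> segments.
    Both profiles are natural-sorted by (chrom, start) first.
    """
    params = params or CallParams()
    control = control.sorted()
    tumour = tumour.sorted()

    n_in = len(control)
    control_f, tumour_f = qc_filter(control, tumour, params.min_doc)
    if len(control_f) == 0:
        raise InputError("no regions survive QC")
    retained_set = {(r.chrom, r.start, r.end) for r in control_f.regions}
    retained = np.array(
        [(r.chrom, r.start, r.end) in retained_set for r in control.regions]
    )
    logger.info("QC: %d of %d regions retained (min control DOC %g)",
                len(control_f), n_in, params.min_doc)

    ratio = compute_ratio(normalize_library(tumour_f), normalize_library(control_f))
    ratio = median_normalize(ratio)
    smoothed = smooth_track(ratio, SmoothingConfig()) if params.smoothing \
        else ratio.with_values(ratio.values, stage="smoothed")

    sigma0 = params.sigma_override or initial_sigma(smoothed.values, params.sigma_bounds)
    model = default_model(
        K=params.K,
        alpha=params.alpha,
        tumour_ploidy=params.tumour_ploidy,
        sigma0=sigma0,
    )
    if params.sigma_override is None:
        model = fit_sigma(model, smoothed.values, params.sigma_bounds)
    logger.info("emission sigma: %.4f (initial %.4f)", model.sigma, sigma0)

    path = decode_track(model, smoothed)
    segments = call_segments(path, smoothed)
    return CallResult(
        retained=retained,
        raw_track=ratio,
        smoothed_track=smoothed,
        model=model,
        path=path,
        segments=segments,
    )


@dataclass
class RunConfig:
    """File-level configuration of one `convex call` run."""

    tumour_path: Path
    control_path: Path
    out_dir: Path
    targets_path: Path | None = None
    params: CallParams = field(default_factory=CallParams)
    plot: bool = False
    log_level: str = "INFO"


def _param_header(params: CallParams) -> str:
    fields = ", ".join(
        f"{f.name}={getattr(params, f.name)}" for f in dataclasses.fields(params)
    )
    return f"# convexcnv {__version__}; {fields}\n"


def run_pipeline(config: RunConfig) -> CallResult:
    """Read inputs, call copy number, and write the result files.

    Writes ``exons.tsv`` (per-exon ratios and copy calls), ``segments.tsv``
    (BED-like segment table) and ``report.txt`` into ``config.out_dir``.
    """
    logging.basicConfig(stream=sys.stderr, level=config.log_level,
                        format="%(levelname)s %(message)s")
    for p in (config.tumour_path, config.control_path, config.targets_path):
        if p is not None and not Path(p).exists():
            raise InputError(f"input file not found: {p}")

    control = read_depth_table(config.control_path, "control")
    tumour = read_depth_table(config.tumour_path, "tumour")
    if config.targets_path is not None:
        targets = {(r.chrom, r.start, r.end) for r in read_targets(config.targets_path)}
        keep_c = np.array([(r.chrom, r.start, r.end) in targets for r in control.regions])
        keep_t = np.array([(r.chrom, r.start, r.end) in targets for r in tumour.regions])
        control, tumour = control.subset(keep_c), tumour.subset(keep_t)

    result = call_copy_number(control, tumour, config.params)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = _param_header(config.params)

    with open(out / "exons.tsv", "w") as fh:
        fh.write(header)
        fh.write("chrom\tstart\tend\traw_ratio\tsmoothed_ratio\tcopy_number\n")
        for r, raw, sm, cn in zip(
            result.raw_track.regions,
            result.raw_track.values,
            result.smoothed_track.values,
            result.path.states,
        ):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{raw:.6g}\t{sm:.6g}\t{cn}\n")

    with open(out / "segments.tsv", "w") as fh:
        fh.write(header)
        fh.write("chrom\tstart\tend\tcopy_number\tn_exons\tmean_ratio\tis_cnv\n")
        for s in result.segments:
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{s.copy_number}\t"
                f"{s.n_exons}\t{s.mean_ratio:.6g}\t{int(s.is_cnv)}\n"
            )

    per_chrom = {}
    for s in result.segments:
        per_chrom[s.chrom] = per_chrom.get(s.chrom, 0) + 1
    with open(out / "report.txt", "w") as fh:
        fh.write(header)
        fh.write(f"regions_in_input\t{result.retained.size}\n")
        fh.write(f"regions_after_qc\t{int(result.retained.sum())}\n")
        fh.write(f"fitted_sigma\t{result.model.sigma:.6g}\n")
        fh.write(f"cnv_segments\t{sum(s.is_cnv for s in result.segments)}\n")
        for chrom, n in per_chrom.items():
            fh.write(f"segments_{chrom}\t{n}\n")

    if config.plot:
        _plot_tracks(result, out)
    return result


def _plot_tracks(result: CallResult, out: Path) -> None:
    """Static ratio-vs-position plot per chromosome (convenience output)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for chrom, sl in result.smoothed_track.chrom_index.items():
        fig, ax = plt.subplots(figsize=(10, 3))
        x = np.arange(sl.start, sl.stop)
        ax.plot(x, result.raw_track.values[sl], ".", ms=2, alpha=0.4, label="raw ratio")
        ax.plot(x, result.smoothed_track.values[sl], "-", lw=1, label="smoothed")
        ax.step(x, result.path.states[sl] / 2.0, where="mid", lw=1,
                label="copy/2", color="red")
        ax.set_xlabel("exon index")
        ax.set_ylabel("DOC ratio")
        ax.set_title(chrom)
        ax.legend(loc="upper right", fontsize=8)
        fig.tight_layout()
        fig.savefig(out / f"ratio_{chrom}.png", dpi=120)
        plt.close(fig)
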