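"""Raw bin counts -> GC-corrected copy-ratio profiles (diploid baseline 1.0).

The normalization chain is: assign reads to bins, remove the multiplicative
count-vs-GC trend, rescale each bin to a full-bin-width equivalent, then
divide by the autosomal median so that two copies sit at ratio 1.0 (a gain
to three copies raises bin counts by 50%, a loss to one copy lowers them
by 50%).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import median_abs_deviation
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from .counts import BinCountTable
from .errors import FormatError
from .reference import ReferenceModel

__all__ = [
    "CopyRatioProfile",
    "count_positions_to_bins",
    "gc_correct",
    "to_copy_ratio",
    "profile_from_counts",
]

logger = logging.getLogger(__name__)

#: Below this many usable bins, local regression is unreliable; fall back to
#: per-GC-decile medians.
MIN_BINS_LOWESS = 50


@dataclass
class CopyRatioProfile:
    """Normalized per-bin copy ratios for one sample.

    ``corrected`` is the GC-corrected count rescaled to a full-bin-width
    equivalent, so ``ratio = corrected / baseline_count`` bin-wise with
    ``baseline_count`` the autosomal median corrected count.  ``qc_noise``
    is the (unscaled) median absolute deviation of autosomal ratios.
    """

    sample_id: str
    sample_type: str
    ratio: np.ndarray
    corrected: np.ndarray
    baseline_count: float
    qc_noise: float
    total_reads: int
    qc_zero_baseline: bool = False
    skipped_reads: int = 0
    warnings: list[str] = field(default_factory=list)


def count_positions_to_bins(path, ref: ReferenceModel) -> BinCountTable:
    """Count BED read-start positions into the reference bins.

    Each read is assigned to the unique bin whose half-open interval contains
    its start.  Reads on chromosomes absent from the reference (or starting
    past the chromosome end) are skipped; the skipped count is logged and
    attached to the result as ``skipped_reads``.
    """
    counts = np.zeros(ref.n_bins, dtype=np.int64)
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected 'chrom<TAB>start'")
            chrom = parts[0]
            try:
                start = int(parts[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad start: {exc}") from exc
            if start < 0:
                raise FormatError(f"{path}:{lineno}: negative position")
            sl = ref.chrom_slices.get(chrom)
            if sl is None or start >= ref.chrom_length(chrom):
                skipped += 1
                continue
            local = int(np.searchsorted(ref.starts[sl], start, side="right")) - 1
            counts[sl.start + local] += 1
    if skipped:
        logger.info("count_positions_to_bins: skipped %d reads", skipped)
    table = BinCountTable(sample_id=str(path), sample_type="RE", counts=counts)
    table.skipped_reads = skipped  # type: ignore[attr-defined]
    return table


def _decile_trend(counts: np.ndarray, gc: np.ndarray, fit_mask: np.ndarray,
                  n_groups: int = 10) -> np.ndarray:
    """Per-GC-decile median trend, evaluated for every bin (clamped)."""
    edges = np.quantile(gc[fit_mask], np.linspace(0, 1, n_groups + 1))
    # assign every bin to a decile of the *fitted* GC distribution
    group = np.clip(np.searchsorted(edges[1:-1], gc, side="right"), 0, n_groups - 1)
    trend = np.empty_like(gc, dtype=float)
    medians = np.full(n_groups, np.nan)
    for g in range(n_groups):
        sel = fit_mask & (group == g)
        if sel.any():
            medians[g] = np.median(counts[sel])
    overall = np.nanmedian(medians) if np.isfinite(medians).any() else 0.0
    medians = np.where(np.isfinite(medians), medians, overall)
    trend = medians[group]
    return trend


def gc_correct(
    table: BinCountTable,
    ref: ReferenceModel,
    method: str = "lowess",
    span: float = 0.3,
) -> np.ndarray:
    """Remove the multiplicative count-vs-GC trend.

    The trend ``f`` is fitted on autosomal bins (sex-chromosome bins can be
    legitimately empty) and evaluated for every bin with boundary clamping;
    the corrected count is ``count / f(gc) * mean(f)``, which preserves the
    mean count scale.

    ``method`` is ``"lowess"`` (local regression, default span 0.3) or
    ``"gc_deciles"`` (per-GC-decile medians).  With fewer than 50 usable
    bins, lowess falls back to deciles with a warning.
    """
    if method not in ("lowess", "gc_deciles"):
        raise ValueError(f"unknown GC-correction method {method!r}")
    counts = table.counts.astype(float)
    if len(counts) != ref.n_bins:
        raise ValueError("count vector does not match reference")
    if counts.sum() == 0:
        raise ValueError("all-zero counts: nothing to correct (QC failure)")
    # fit the trend on width-normalized rates so short terminal bins do not
    # drag the curve; the correction factor itself is dimensionless
    rate = counts * (ref.bin_size / ref.widths.astype(float))
    fit_mask = ref.autosomal_mask
    if not fit_mask.any():
        fit_mask = np.ones(ref.n_bins, dtype=bool)
    gc = ref.gc
    if method == "lowess" and int(fit_mask.sum()) < MIN_BINS_LOWESS:
        msg = (
            f"only {int(fit_mask.sum())} usable bins; "
            "falling back to gc_deciles correction"
        )
        logger.warning(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
        method = "gc_deciles"
    if method == "lowess":
        gc_fit = gc[fit_mask]
        delta = 0.01 * (gc_fit.max() - gc_fit.min())
        fitted = sm_lowess(
            rate[fit_mask], gc_fit, frac=span, it=2, delta=delta,
            return_sorted=True,
        )
        # evaluate at every bin's GC; np.interp clamps at the boundaries
        trend = np.interp(gc, fitted[:, 0], fitted[:, 1])
    else:
        trend = _decile_trend(rate, gc, fit_mask)
    mean_trend = float(np.mean(trend[fit_mask]))
    if mean_trend <= 0:
        raise ValueError("degenerate GC trend (non-positive mean)")
    floor = 0.01 * mean_trend
    trend = np.maximum(trend, floor)
    return counts / trend * mean_trend


def to_copy_ratio(
    corrected: np.ndarray, ref: ReferenceModel,
    sample_id: str = "sample", sample_type: str = "RE",
    total_reads: int | None = None,
) -> CopyRatioProfile:
    """Scale corrected counts to copy ratios with diploid baseline 1.0.

    Corrected counts are first rescaled to full-bin-width equivalents (the
    remainder bin at a chromosome end would otherwise mimic a loss), then
    divided by the autosomal median.  A zero baseline marks the sample as a
    QC failure.
    """
    corrected = np.asarray(corrected, dtype=float)
    if corrected.shape != (ref.n_bins,):
        raise ValueError("corrected vector does not match reference")
    width_adj = corrected * (ref.bin_size / ref.widths.astype(float))
    auto = ref.autosomal_mask
    baseline = float(np.median(width_adj[auto])) if auto.any() else float(
        np.median(width_adj)
    )
    if total_reads is None:
        total_reads = int(round(corrected.sum()))
    if baseline <= 0:
        return CopyRatioProfile(
            sample_id=sample_id,
            sample_type=sample_type,
            ratio=np.zeros(ref.n_bins),
            corrected=width_adj,
            baseline_count=0.0,
            qc_noise=float("inf"),
            total_reads=total_reads,
            qc_zero_baseline=True,
        )
    ratio = width_adj / baseline
    noise = float(median_abs_deviation(ratio[auto] if auto.any() else ratio, scale=1.0))
    return CopyRatioProfile(
        sample_id=sample_id,
        sample_type=sample_type,
        ratio=ratio,
        corrected=width_adj,
        baseline_count=baseline,
        qc_noise=noise,
        total_reads=total_reads,
    )


def profile_from_counts(
    table: BinCountTable,
    ref: ReferenceModel,
    method: str = "lowess",
    span: float = 0.3,
) -> CopyRatioProfile:
    """Full normalization chain for one sample (GC-correct, then ratio).

    All-zero samples come back as zero-baseline QC failures rather than
    raising.
    """
    if table.counts.sum() == 0:
        profile = to_copy_ratio(
            np.zeros(ref.n_bins), ref,
            sample_id=table.sample_id, sample_type=table.sample_type,
            total_reads=0,
        )
        profile.qc_zero_baseline = True
        return profile
    corrected = gc_correct(table, ref, method=method, span=span)
    return to_copy_ratio(
        corrected, ref,
        sample_id=table.sample_id, sample_type=table.sample_type,
        total_reads=table.total_reads,
    )
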