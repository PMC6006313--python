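"""Chromosome- and segment-level aneuploidy calling from copy-ratio profiles.

Dosage model: with abnormal-clone fraction ``f``, a mosaic trisomy gives a
mean ratio ``1 + f/2`` and a mosaic monosomy ``1 - f/2``; so ``f`` is
estimated as ``2*|ratio - 1|``.  Mosaicism below 30% is reported as normal
and above 80% as a full gain/loss, giving ratio cut-points: normal within
(0.85, 1.15); mosaic in [0.60, 0.85] or [1.15, 1.40]; full outside.
Sub-chromosomal events are found by recursive binary segmentation with a
50 Mb minimum segment size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .normalize import CopyRatioProfile
from .reference import ReferenceModel

__all__ = [
    "CallerParams",
    "SegmentCall",
    "ChromosomeCall",
    "SampleCallSet",
    "qc_sample",
    "call_chromosome",
    "call_segments",
    "call_sex",
    "call_sample",
]

STATUSES = ("normal", "gain", "loss", "mosaic_gain", "mosaic_loss", "no_call")
ABNORMAL_STATUSES = frozenset({"gain", "loss", "mosaic_gain", "mosaic_loss"})
#: Name of the combined sex-chromosome call entity (22 autosomes + this = 23).
SEX_ENTITY = "sex"

# tolerance for the boundary ratios 0.60/0.85/1.15/1.40 landing exactly on
# the mosaic band edges despite float rounding
_EPS = 1e-9


@dataclass
class CallerParams:
    """Caller thresholds (defaults justified by simulation).

    mosaic_floor / mosaic_ceiling
        The reportable mosaic-fraction band: below the floor a chromosome is
        called normal, above the ceiling a full gain/loss.
    min_segment_bp
        Smallest reportable sub-chromosomal event (50 Mb).
    t_threshold
        Two-sample t-statistic required to accept a segmentation split.
    max_noise / min_total_reads
        Sample QC: maximum MAD of autosomal ratios, minimum library size.
    y_presence
        Mean Y-bin ratio above which a Y chromosome is considered present.
    mosaic_counts_as_abnormal
        Whether mosaic calls in the 30-80% band count as abnormal in
        concordance statistics (default True).
    """

    mosaic_floor: float = 0.30
    mosaic_ceiling: float = 0.80
    min_segment_bp: int = 50_000_000
    t_threshold: float = 5.0
    max_noise: float = 0.35
    min_total_reads: int = 200_000
    y_presence: float = 0.25
    mosaic_counts_as_abnormal: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.mosaic_floor < self.mosaic_ceiling <= 1.0:
            raise ValueError("need 0 < mosaic_floor < mosaic_ceiling <= 1")
        if self.min_segment_bp <= 0:
            raise ValueError("min_segment_bp must be positive")


@dataclass(frozen=True)
class SegmentCall:
    start: int
    end: int
    status: str
    mean_ratio: float
    n_bins: int
    mosaic_fraction: float | None = None


@dataclass
class ChromosomeCall:
    chromosome: str
    status: str
    mean_ratio: float
    mosaic_fraction: float | None = None
    segments: list[SegmentCall] = field(default_factory=list)
    sem: float | None = None

    @property
    def abnormal(self) -> bool:
        if self.status in ABNORMAL_STATUSES:
            return True
        return any(s.status in ABNORMAL_STATUSES for s in self.segments)

    @property
    def directions(self) -> frozenset[str]:
        """Abnormality directions ({'gain'}, {'loss'}, both, or empty)."""
        dirs = set()
        if self.status in ("gain", "mosaic_gain"):
            dirs.add("gain")
        if self.status in ("loss", "mosaic_loss"):
            dirs.add("loss")
        for s in self.segments:
            if s.status in ("gain", "mosaic_gain"):
                dirs.add("gain")
            if s.status in ("loss", "mosaic_loss"):
                dirs.add("loss")
        return frozenset(dirs)


@dataclass
class SampleCallSet:
    """Per-sample verdict: one call per autosome plus a combined sex entity."""

    sample_id: str
    sample_type: str
    calls: dict[str, ChromosomeCall]
    sex_call: str
    sex_entity_abnormal: bool
    qc_pass: bool

    @property
    def abnormal(self) -> bool | None:
        """Any non-normal call; undefined (None) for QC-fail samples."""
        if not self.qc_pass:
            return None
        return self.sex_entity_abnormal or any(
            c.abnormal for c in self.calls.values()
        )

    def entity_abnormal(self, entity: str) -> bool:
        if entity == SEX_ENTITY:
            return self.sex_entity_abnormal
        return self.calls[entity].abnormal


def qc_sample(profile: CopyRatioProfile, params: CallerParams | None = None) -> bool:
    """Sample passes QC iff its noise and library size are acceptable.

    Failure modes mirror amplification failure: a zero diploid baseline, an
    autosomal-ratio MAD above ``max_noise``, or fewer than
    ``min_total_reads`` reads.
    """
    params = params or CallerParams()
    if profile.qc_zero_baseline or profile.baseline_count <= 0:
        return False
    if not np.isfinite(profile.qc_noise) or profile.qc_noise > params.max_noise:
        return False
    if profile.total_reads < params.min_total_reads:
        return False
    return True


def call_chromosome(
    mean_ratio: float, params: CallerParams | None = None
) -> tuple[str, float]:
    """Map a mean copy ratio to a status and a mosaic-fraction estimate.

    Returns ``(status, f)`` where ``f = 2*|ratio - 1|`` clipped to [0, 1].
    ``f`` below the mosaic floor gives ``normal``; within [floor, ceiling]
    a mosaic call; above the ceiling a full gain/loss.
    """
    params = params or CallerParams()
    if not np.isfinite(mean_ratio) or mean_ratio < 0:
        raise ValueError(f"invalid mean ratio {mean_ratio}")
    f = 2.0 * abs(mean_ratio - 1.0)
    f_clipped = min(f, 1.0)
    if f < params.mosaic_floor - _EPS:
        return "normal", 0.0
    direction = "gain" if mean_ratio > 1.0 else "loss"
    if f <= params.mosaic_ceiling + _EPS:
        return f"mosaic_{direction}", f_clipped
    return direction, f_clipped


def _pooled_t(x: np.ndarray, k: int) -> float:
    """Two-sample pooled-variance t statistic for splitting x at k."""
    n1, n2 = k, len(x) - k
    a, b = x[:k], x[k:]
    v1 = a.var(ddof=1) if n1 > 1 else 0.0
    v2 = b.var(ddof=1) if n2 > 1 else 0.0
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / max(n1 + n2 - 2, 1)
    denom = np.sqrt(max(sp2, 1e-300) * (1.0 / n1 + 1.0 / n2))
    return float((a.mean() - b.mean()) / denom)


def _best_split(x: np.ndarray, valid: np.ndarray) -> tuple[int, float]:
    """Split index (into x) maximizing |pooled t| over the valid candidates.

    Vectorized over all candidate splits via cumulative sums.
    """
    n = len(x)
    ks = np.flatnonzero(valid)
    ks = ks[(ks >= 2) & (ks <= n - 2)]
    if ks.size == 0:
        return -1, 0.0
    cs = np.concatenate(([0.0], np.cumsum(x)))
    cs2 = np.concatenate(([0.0], np.cumsum(x * x)))
    n1 = ks.astype(float)
    n2 = n - n1
    s1, s2 = cs[ks], cs[n] - cs[ks]
    q1, q2 = cs2[ks], cs2[n] - cs2[ks]
    m1, m2 = s1 / n1, s2 / n2
    ss1 = q1 - n1 * m1 * m1
    ss2 = q2 - n2 * m2 * m2
    sp2 = (ss1 + ss2) / (n - 2)
    denom = np.sqrt(np.maximum(sp2, 1e-300) * (1.0 / n1 + 1.0 / n2))
    t = np.abs(m1 - m2) / denom
    best = int(np.argmax(t))
    return int(ks[best]), float(t[best])


def call_segments(
    profile: CopyRatioProfile,
    ref: ReferenceModel,
    chrom: str,
    params: CallerParams | None = None,
) -> list[SegmentCall]:
    """Recursive binary segmentation of one chromosome's bin ratios.

    At each step the split maximizing the two-sample t statistic is accepted
    iff |t| >= ``t_threshold`` and both resulting pieces span at least
    ``min_segment_bp``; otherwise recursion stops.  Each final segment is
    classified by :func:`call_chromosome` on its mean ratio.  Chromosomes
    shorter than twice the minimum size can never split and yield a single
    whole-chromosome segment.
    """
    params = params or CallerParams()
    sl = ref.chrom_slices[chrom]
    ratios = profile.ratio[sl]
    starts = ref.starts[sl]
    ends = ref.ends[sl]

    segments: list[SegmentCall] = []

    def recurse(lo: int, hi: int) -> None:
        x = ratios[lo:hi]
        n = hi - lo
        if n >= 4:
            # candidate splits: both pieces >= min_segment_bp
            cut_pos = starts[lo + 1 : hi]  # bp position of each split
            left_bp = cut_pos - starts[lo]
            right_bp = ends[hi - 1] - cut_pos
            valid = np.zeros(n, dtype=bool)
            valid[1:] = (left_bp >= params.min_segment_bp) & (
                right_bp >= params.min_segment_bp
            )
            k, t = _best_split(x, valid)
            if k > 0 and t >= params.t_threshold:
                recurse(lo, lo + k)
                recurse(lo + k, hi)
                return
        mean = float(x.mean())
        status, f = call_chromosome(mean, params)
        segments.append(
            SegmentCall(
                start=int(starts[lo]),
                end=int(ends[hi - 1]),
                status=status,
                mean_ratio=mean,
                n_bins=n,
                mosaic_fraction=f if status.startswith("mosaic") else None,
            )
        )

    recurse(0, len(ratios))
    segments.sort(key=lambda s: s.start)
    return segments


def call_sex(
    profile: CopyRatioProfile,
    ref: ReferenceModel,
    params: CallerParams | None = None,
) -> str:
    """Sex call from X and Y dosage.

    Y is present iff mean Y-bin ratio exceeds ``y_presence``; X copies are
    ``round(2 * mean X ratio)`` clipped to [0, 3].  (2X, no Y) -> XX;
    (1X, Y) -> XY; (1X, no Y) -> X0; anything else -> other.  Genomes
    without sex chromosomes get ``no_call``.
    """
    params = params or CallerParams()
    if not ref.x_mask.any():
        return "no_call"
    d_x = float(profile.ratio[ref.x_mask].mean())
    y_present = False
    if ref.y_mask.any():
        y_present = float(profile.ratio[ref.y_mask].mean()) > params.y_presence
    x_copies = int(np.clip(round(2.0 * d_x), 0, 3))
    if x_copies == 2 and not y_present:
        return "XX"
    if x_copies == 1 and y_present:
        return "XY"
    if x_copies == 1 and not y_present:
        return "X0"
    return "other"


def _expected_sex_dosage(sex_call: str) -> tuple[float, float] | None:
    return {"XX": (1.0, 0.0), "XY": (0.5, 0.5), "X0": (0.5, 0.0)}.get(sex_call)


def call_sample(
    profile: CopyRatioProfile,
    ref: ReferenceModel,
    params: CallerParams | None = None,
) -> SampleCallSet:
    """Full per-sample verdict: QC, 22 autosome calls, sex entity, sex call.

    A QC-fail sample gets ``no_call`` everywhere and an undefined abnormal
    flag.  An autosome is abnormal if its whole-chromosome call or any
    reported sub-chromosomal segment is non-normal.  The combined
    sex-chromosome entity is abnormal iff the sex dosage is inconsistent
    with the sample's own sex call (sex_call ``other``).
    """
    params = params or CallerParams()
    autosomes = ref.autosome_names
    if not qc_sample(profile, params):
        return SampleCallSet(
            sample_id=profile.sample_id,
            sample_type=profile.sample_type,
            calls={
                c: ChromosomeCall(c, "no_call", float("nan")) for c in autosomes
            },
            sex_call="no_call",
            sex_entity_abnormal=False,
            qc_pass=False,
        )
    calls: dict[str, ChromosomeCall] = {}
    for chrom in autosomes:
        sl = ref.chrom_slices[chrom]
        ratios = profile.ratio[sl]
        mean = float(ratios.mean())
        status, f = call_chromosome(mean, params)
        segs = call_segments(profile, ref, chrom, params)
        if len(segs) == 1:
            segs = []  # no split: the whole-chromosome call stands alone
        sem = float(ratios.std(ddof=1) / np.sqrt(len(ratios))) if len(ratios) > 1 else None
        calls[chrom] = ChromosomeCall(
            chromosome=chrom,
            status=status,
            mean_ratio=mean,
            mosaic_fraction=f if status.startswith("mosaic") else None,
            segments=segs,
            sem=sem,
        )
    sex = call_sex(profile, ref, params)
    return SampleCallSet(
        sample_id=profile.sample_id,
        sample_type=profile.sample_type,
        calls=calls,
        sex_call=sex,
        sex_entity_abnormal=(sex == "other"),
        qc_pass=True,
    )
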