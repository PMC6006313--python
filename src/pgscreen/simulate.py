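"""Synthetic embryo cohorts: clonal mosaicism, sample-type models, read counts.

The generator stands in for the study's raw data (none is deposited).  An
embryo is a mixture of clonal cell populations, each with its own karyotype.
The three sample types probe that mixture differently:

* **TE** (trophectoderm biopsy): 3-5 cells drawn multinomially from the clone
  fractions; the biopsy reflects only the cells that happened to be picked.
* **RE** (remaining embryo): many cells, so the deterministic mix-weighted
  average copy number.
* **ECB** (spent culture medium + blastocoel fluid): cell-free DNA enriched
  for apoptotic/shed cells; abnormal clones are up-weighted by a factor
  ``1 + w`` before renormalization, reflecting preferential elimination of
  abnormal cells.

Counts are then drawn per bin with expected value proportional to
``copy x bin-width x g(GC)`` where ``g`` is a multiplicative GC-bias curve,
multinomially (``dispersion = 0``) or with Gamma-Poisson (negative-binomial)
overdispersion where ``dispersion`` is the extra-Poisson coefficient of
variation per bin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .counts import BinCountTable
from .reference import HG19_CHROM_LENGTHS, ReferenceModel, chrom_sex_class

__all__ = [
    "SegmentCN",
    "CloneKaryotype",
    "CloneMix",
    "EmbryoSpec",
    "EffectiveKaryotype",
    "GCBias",
    "DEFAULT_GC_BIAS",
    "CohortParams",
    "euploid_karyotype",
    "effective_karyotype_te",
    "effective_karyotype_re",
    "effective_karyotype_ecb",
    "simulate_counts",
    "simulate_negative_control",
    "simulate_cohort",
    "simulate_trio",
]

SEXES = ("XX", "XY", "X0")
#: Copy number of X and Y for each sex's euploid karyotype.
SEX_COPIES = {"XX": (2, 0), "XY": (1, 1), "X0": (1, 0)}


@dataclass(frozen=True)
class SegmentCN:
    """A sub-chromosomal copy-number override on a half-open interval."""

    chrom: str
    start: int
    end: int
    copy: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError("invalid segment interval")
        if self.copy < 0:
            raise ValueError("negative copy number")


@dataclass
class CloneKaryotype:
    """Whole-chromosome copy numbers plus optional segmental overrides.

    Chromosomes absent from ``copy_number`` default to 2 copies.
    """

    copy_number: dict[str, int] = field(default_factory=dict)
    segments: list[SegmentCN] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, cn in self.copy_number.items():
            if cn < 0:
                raise ValueError(f"negative copy number for {chrom}")
        by_chrom: dict[str, list[SegmentCN]] = {}
        for seg in self.segments:
            by_chrom.setdefault(seg.chrom, []).append(seg)
        for chrom, segs in by_chrom.items():
            segs = sorted(segs, key=lambda s: s.start)
            for a, b in zip(segs, segs[1:]):
                if b.start < a.end:
                    raise ValueError(f"overlapping segments on {chrom}")

    def chrom_copy(self, chrom: str) -> int:
        return self.copy_number.get(chrom, 2)

    def bin_copy(self, ref: ReferenceModel) -> np.ndarray:
        """Per-bin copy number (overlap-weighted where segments cut a bin)."""
        copy = np.empty(ref.n_bins, dtype=float)
        for chrom, _ in ref.chromosomes:
            sl = ref.chrom_slices[chrom]
            copy[sl] = self.chrom_copy(chrom)
        for seg in self.segments:
            if seg.chrom not in ref.chrom_slices:
                continue
            if seg.end > ref.chrom_length(seg.chrom):
                raise ValueError(f"segment beyond end of {seg.chrom}")
            sl = ref.chrom_slices[seg.chrom]
            starts, ends = ref.starts[sl], ref.ends[sl]
            overlap = np.clip(
                np.minimum(ends, seg.end) - np.maximum(starts, seg.start), 0, None
            )
            width = (ends - starts).astype(float)
            base = self.chrom_copy(seg.chrom)
            frac = overlap / width
            copy[sl] = copy[sl] + frac * (seg.copy - base)
        return copy

    def to_dict(self) -> dict:
        return {
            "copy_number": dict(self.copy_number),
            "segments": [
                [s.chrom, s.start, s.end, s.copy] for s in self.segments
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CloneKaryotype":
        return cls(
            copy_number={k: int(v) for k, v in d.get("copy_number", {}).items()},
            segments=[SegmentCN(c, int(s), int(e), int(cn))
                      for c, s, e, cn in d.get("segments", [])],
        )


def euploid_karyotype(sex: str, chrom_names: list[str]) -> CloneKaryotype:
    """The normal karyotype for a given sex over the named chromosomes."""
    if sex not in SEX_COPIES:
        raise ValueError(f"unknown sex {sex!r}")
    x_cn, y_cn = SEX_COPIES[sex]
    cn = {}
    for name in chrom_names:
        cls = chrom_sex_class(name)
        cn[name] = x_cn if cls == "X" else y_cn if cls == "Y" else 2
    return CloneKaryotype(copy_number=cn)


@dataclass
class CloneMix:
    """An embryo's cell population: clones with fractions summing to 1."""

    clones: list[tuple[CloneKaryotype, float]]
    sex: str = "XX"

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if not self.clones:
            raise ValueError("empty clone mix")
        fracs = np.array([f for _, f in self.clones], dtype=float)
        if np.any(fracs <= 0):
            raise ValueError("clone fractions must be positive")
        if abs(fracs.sum() - 1.0) > 1e-9:
            raise ValueError("clone fractions must sum to 1")

    def clone_is_abnormal(self, karyotype: CloneKaryotype) -> bool:
        """A clone is abnormal if it deviates from this sex's euploid state."""
        if karyotype.segments:
            return True
        x_cn, y_cn = SEX_COPIES[self.sex]
        for chrom, cn in karyotype.copy_number.items():
            cls = chrom_sex_class(chrom)
            expected = x_cn if cls == "X" else y_cn if cls == "Y" else 2
            if cn != expected:
                return True
        return False

    def to_dict(self) -> dict:
        return {
            "sex": self.sex,
            "clones": [[k.to_dict(), f] for k, f in self.clones],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CloneMix":
        return cls(
            clones=[(CloneKaryotype.from_dict(k), float(f)) for k, f in d["clones"]],
            sex=d["sex"],
        )


@dataclass
class EmbryoSpec:
    """Ground truth for one embryo and its three samples."""

    embryo_id: str
    mix: CloneMix
    te_cells: int = 4
    ecb_apoptosis_weight: float = 0.5
    failure_flags: dict[str, bool] = field(
        default_factory=lambda: {"ECB": False, "TE": False, "RE": False}
    )

    def __post_init__(self) -> None:
        if not 3 <= self.te_cells <= 5:
            raise ValueError("te_cells must be in [3, 5]")
        if not math.isfinite(self.ecb_apoptosis_weight) or self.ecb_apoptosis_weight < 0:
            raise ValueError("ecb_apoptosis_weight must be finite and >= 0")

    def to_dict(self) -> dict:
        return {
            "embryo_id": self.embryo_id,
            "mix": self.mix.to_dict(),
            "te_cells": self.te_cells,
            "ecb_apoptosis_weight": self.ecb_apoptosis_weight,
            "failure_flags": dict(self.failure_flags),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EmbryoSpec":
        return cls(
            embryo_id=d["embryo_id"],
            mix=CloneMix.from_dict(d["mix"]),
            te_cells=int(d["te_cells"]),
            ecb_apoptosis_weight=float(d["ecb_apoptosis_weight"]),
            failure_flags={k: bool(v) for k, v in d["failure_flags"].items()},
        )


@dataclass
class EffectiveKaryotype:
    """A reweighted clone mixture: what a particular sample actually sees."""

    weights: list[tuple[CloneKaryotype, float]]

    def chromosome_copy(self, chrom: str) -> float:
        """Weighted mean whole-chromosome copy number."""
        return float(sum(w * k.chrom_copy(chrom) for k, w in self.weights))

    def bin_copy(self, ref: ReferenceModel) -> np.ndarray:
        out = np.zeros(ref.n_bins, dtype=float)
        for k, w in self.weights:
            out += w * k.bin_copy(ref)
        return out


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def effective_karyotype_te(spec: EmbryoSpec, seed=None) -> EffectiveKaryotype:
    """Cell-averaged karyotype of a 3-5 cell trophectoderm biopsy.

    Cells are drawn multinomially from the clone fractions, so a minority
    clone can be over- or under-represented (or missed entirely) in the
    biopsy -- the mechanistic source of TE-vs-RE discordance.
    """
    rng = _as_rng(seed)
    fracs = [f for _, f in spec.mix.clones]
    cells = rng.multinomial(spec.te_cells, fracs)
    weights = [
        (k, c / spec.te_cells)
        for (k, _), c in zip(spec.mix.clones, cells)
        if c > 0
    ]
    return EffectiveKaryotype(weights)


def effective_karyotype_re(spec: EmbryoSpec) -> EffectiveKaryotype:
    """Mix-weighted average karyotype of the whole remaining embryo."""
    return EffectiveKaryotype([(k, f) for k, f in spec.mix.clones])


def effective_karyotype_ecb(spec: EmbryoSpec) -> EffectiveKaryotype:
    """Apoptosis-weighted karyotype of cell-free culture-medium DNA.

    Each abnormal clone's fraction is multiplied by ``1 + w`` (w >= 0) and the
    mixture renormalized; ``w = 0`` reduces exactly to the remaining-embryo
    average.
    """
    w = spec.ecb_apoptosis_weight
    raw = [
        (k, f * (1.0 + w) if spec.mix.clone_is_abnormal(k) else f)
        for k, f in spec.mix.clones
    ]
    total = sum(f for _, f in raw)
    return EffectiveKaryotype([(k, f / total) for k, f in raw])


@dataclass(frozen=True)
class GCBias:
    """Multiplicative quadratic GC-bias curve ``c0 + c1*gc + c2*gc^2``, floored."""

    coeffs: tuple[float, float, float] = (0.19, 3.6, -4.0)
    floor: float = 0.1

    def curve(self, gc: np.ndarray) -> np.ndarray:
        c0, c1, c2 = self.coeffs
        return np.maximum(c0 + c1 * gc + c2 * gc * gc, self.floor)


#: Default bias 1 - 4*(gc - 0.45)^2, floored at 0.1: unimodal with optimum at
#: GC 0.45, typical of WGA/low-pass libraries.
DEFAULT_GC_BIAS = GCBias()


def _expected_proportions(
    copy: np.ndarray, ref: ReferenceModel, gc_bias: GCBias | None
) -> np.ndarray:
    weight = copy * ref.widths.astype(float)
    if gc_bias is not None:
        weight = weight * gc_bias.curve(ref.gc)
    total = weight.sum()
    if total <= 0:
        raise ValueError("all-zero expected counts")
    return weight / total


def simulate_counts(
    karyotype,
    ref: ReferenceModel,
    total_reads: int = 2_000_000,
    gc_bias: GCBias | None = None,
    dispersion: float = 0.0,
    seed=None,
    sample_id: str = "sample",
    sample_type: str = "RE",
) -> BinCountTable:
    """Draw a low-pass bin-count table for an (effective) karyotype.

    Parameters
    ----------
    karyotype : EffectiveKaryotype, CloneKaryotype or per-bin array
        Mean copy number per bin (2.0 = diploid).
    total_reads : int
        Library size; with ``dispersion = 0`` counts are multinomial and sum
        to exactly this value.
    gc_bias : GCBias or None
        Multiplicative GC-bias curve; ``None`` disables bias.
    dispersion : float
        Extra-Poisson coefficient of variation per bin (Gamma-Poisson
        mixing CV); 0 gives pure multinomial sampling.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = _as_rng(seed)
    if isinstance(karyotype, (EffectiveKaryotype, CloneKaryotype)):
        copy = karyotype.bin_copy(ref)
    else:
        copy = np.asarray(karyotype, dtype=float)
        if copy.shape != (ref.n_bins,):
            raise ValueError("per-bin copy vector does not match reference")
    p = _expected_proportions(copy, ref, gc_bias)
    if dispersion == 0.0:
        counts = rng.multinomial(total_reads, p)
    else:
        mu = total_reads * p
        r = 1.0 / dispersion**2
        counts = np.zeros(ref.n_bins, dtype=np.int64)
        pos = mu > 0
        counts[pos] = rng.negative_binomial(r, r / (r + mu[pos]))
    return BinCountTable(sample_id=sample_id, sample_type=sample_type, counts=counts)


def simulate_negative_control(
    ref: ReferenceModel,
    total_reads: int = 20_000,
    dispersion: float = 5.0,
    seed=None,
    sample_id: str = "NC",
) -> BinCountTable:
    """An amplification-failure table: very low input, heavy overdispersion.

    Emulates the 'splattering dots' of a blank culture-medium control in
    which no embryonic DNA amplified.
    """
    flat = np.full(ref.n_bins, 2.0)
    return simulate_counts(
        flat,
        ref,
        total_reads=total_reads,
        gc_bias=None,
        dispersion=dispersion,
        seed=seed,
        sample_id=sample_id,
        sample_type="NC",
    )


@dataclass
class CohortParams:
    """Study conditions for cohort simulation.

    Defaults emulate the study setting: ~2 million reads per sample in 2 Mb
    bins, 3-5 TE cells, sex frequencies 22:17:1 (XX:XY:X0) and a 3/120
    per-sample amplification-failure rate.  ``dispersion`` is the
    extra-Poisson per-bin CV (0.1 ~ typical WGA noise).
    """

    p_aneuploid: float = 0.7
    p_mosaic: float = 0.7
    mosaic_fraction_range: tuple[float, float] = (0.05, 0.95)
    p_segmental: float = 0.1
    sex_probs: dict[str, float] = field(
        default_factory=lambda: {"XX": 22 / 40, "XY": 17 / 40, "X0": 1 / 40}
    )
    p_sample_failure: float = 3 / 120
    ecb_apoptosis_weight: float = 0.5
    te_cells_range: tuple[int, int] = (3, 5)
    max_affected_chromosomes: int = 3
    total_reads: int = 2_000_000
    dispersion: float = 0.1
    gc_bias: GCBias | None = DEFAULT_GC_BIAS
    nc_read_fraction: float = 0.01
    nc_dispersion: float = 5.0
    min_segmental_bp: int = 50_000_000

    def __post_init__(self) -> None:
        for name in ("p_aneuploid", "p_mosaic", "p_segmental", "p_sample_failure"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.mosaic_fraction_range
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError("mosaic_fraction_range must satisfy 0 < lo <= hi < 1")
        probs = np.array(list(self.sex_probs.values()), dtype=float)
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("sex_probs must be non-negative and sum to 1")
        if set(self.sex_probs) - set(SEXES):
            raise ValueError(f"sex_probs keys must be among {SEXES}")


def _random_abnormal_karyotype(
    sex: str,
    chrom_lengths: list[tuple[str, int]],
    params: CohortParams,
    rng: np.random.Generator,
) -> CloneKaryotype:
    """One abnormal clone: 1-3 affected autosomes, gain/loss equiprobable,
    occasionally segmental (>= 50 Mb) on a chromosome long enough to host it."""
    names = [c for c, _ in chrom_lengths]
    lengths = dict(chrom_lengths)
    autosomes = [c for c in names if chrom_sex_class(c) == "autosome"]
    k = euploid_karyotype(sex, names)
    n_aff = int(rng.integers(1, params.max_affected_chromosomes + 1))
    n_aff = min(n_aff, len(autosomes))
    affected = rng.choice(autosomes, size=n_aff, replace=False)
    segments: list[SegmentCN] = []
    for chrom in affected:
        gain = bool(rng.random() < 0.5)
        cn = 3 if gain else 1
        length = lengths[chrom]
        min_bp = params.min_segmental_bp
        if rng.random() < params.p_segmental and length >= 2.5 * min_bp:
            seg_len = int(rng.uniform(min_bp, min(2 * min_bp, 0.8 * length)))
            seg_len = (seg_len // 1_000_000) * 1_000_000
            start = int(rng.integers(0, (length - seg_len) // 1_000_000 + 1))
            start *= 1_000_000
            segments.append(SegmentCN(chrom, start, start + seg_len, cn))
        else:
            k.copy_number[chrom] = cn
    k.segments = segments
    return CloneKaryotype(copy_number=k.copy_number, segments=segments)


def simulate_cohort(
    n_embryos: int,
    params: CohortParams | None = None,
    seed=None,
    chrom_lengths: list[tuple[str, int]] | None = None,
) -> list[EmbryoSpec]:
    """Draw ground-truth embryos reproducibly under ``seed``."""
    if n_embryos <= 0:
        raise ValueError("n_embryos must be positive")
    params = params or CohortParams()
    chrom_lengths = chrom_lengths or HG19_CHROM_LENGTHS
    names = [c for c, _ in chrom_lengths]
    rng = _as_rng(seed)
    sexes = sorted(params.sex_probs)
    sex_p = np.array([params.sex_probs[s] for s in sexes])
    specs: list[EmbryoSpec] = []
    for i in range(n_embryos):
        sex = str(rng.choice(sexes, p=sex_p))
        euploid = euploid_karyotype(sex, names)
        if rng.random() < params.p_aneuploid:
            abnormal = _random_abnormal_karyotype(sex, chrom_lengths, params, rng)
            if rng.random() < params.p_mosaic:
                f = float(rng.uniform(*params.mosaic_fraction_range))
                mix = CloneMix([(euploid, 1.0 - f), (abnormal, f)], sex=sex)
            else:
                mix = CloneMix([(abnormal, 1.0)], sex=sex)
        else:
            mix = CloneMix([(euploid, 1.0)], sex=sex)
        te_lo, te_hi = params.te_cells_range
        specs.append(
            EmbryoSpec(
                embryo_id=f"E{i + 1:03d}",
                mix=mix,
                te_cells=int(rng.integers(te_lo, te_hi + 1)),
                ecb_apoptosis_weight=params.ecb_apoptosis_weight,
                failure_flags={
                    st: bool(rng.random() < params.p_sample_failure)
                    for st in ("ECB", "TE", "RE")
                },
            )
        )
    return specs


def simulate_trio(
    spec: EmbryoSpec,
    ref: ReferenceModel,
    params: CohortParams | None = None,
    seed=None,
) -> dict[str, BinCountTable]:
    """Simulate the ECB, TE and RE count tables for one embryo.

    A sample whose failure flag is set is replaced by a negative-control-like
    table (amplification failure); its sample_type still names the arm so the
    caller's QC must detect it from the data.
    """
    params = params or CohortParams()
    rng = _as_rng(seed)
    karyotypes = {
        "ECB": effective_karyotype_ecb(spec),
        "TE": effective_karyotype_te(spec, rng),
        "RE": effective_karyotype_re(spec),
    }
    out: dict[str, BinCountTable] = {}
    for st in ("ECB", "TE", "RE"):
        sid = f"{spec.embryo_id}-{st}"
        if spec.failure_flags.get(st, False):
            nc = simulate_negative_control(
                ref,
                total_reads=max(1, int(params.nc_read_fraction * params.total_reads)),
                dispersion=params.nc_dispersion,
                seed=rng,
                sample_id=sid,
            )
            out[st] = BinCountTable(sample_id=sid, sample_type=st, counts=nc.counts)
        else:
            out[st] = simulate_counts(
                karyotypes[st],
                ref,
                total_reads=params.total_reads,
                gc_bias=params.gc_bias,
                dispersion=params.dispersion,
                seed=rng,
                sample_id=sid,
                sample_type=st,
            )
    return out
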