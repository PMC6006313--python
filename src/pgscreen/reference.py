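"""Genome coordinate system: chromosomes, fixed-width bins, per-bin GC fraction.

Everything downstream (count simulation, GC correction, copy-ratio
normalization, calling) is keyed to a :class:`ReferenceModel`.  Coordinates are
0-based half-open (BED convention) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd

from .errors import FormatError

__all__ = [
    "ReferenceModel",
    "build_reference",
    "read_bins_bed",
    "write_bins_bed",
    "read_chrom_sizes",
    "chrom_sex_class",
    "HG19_CHROM_LENGTHS",
    "DEFAULT_BIN_SIZE",
]

DEFAULT_BIN_SIZE = 2_000_000

#: hg19 (GRCh37) chromosome lengths in bp, UCSC naming.
HG19_CHROM_LENGTHS: list[tuple[str, int]] = [
    ("chr1", 249_250_621),
    ("chr2", 243_199_373),
    ("chr3", 198_022_430),
    ("chr4", 191_154_276),
    ("chr5", 180_915_260),
    ("chr6", 171_115_067),
    ("chr7", 159_138_663),
    ("chr8", 146_364_022),
    ("chr9", 141_213_431),
    ("chr10", 135_534_747),
    ("chr11", 135_006_516),
    ("chr12", 133_851_895),
    ("chr13", 115_169_878),
    ("chr14", 107_349_540),
    ("chr15", 102_531_392),
    ("chr16", 90_354_753),
    ("chr17", 81_195_210),
    ("chr18", 78_077_248),
    ("chr19", 59_128_983),
    ("chr20", 63_025_520),
    ("chr21", 48_129_895),
    ("chr22", 51_304_566),
    ("chrX", 155_270_560),
    ("chrY", 59_373_566),
]


def chrom_sex_class(name: str) -> str:
    """Classify a chromosome name as ``autosome``, ``X`` or ``Y``."""
    stripped = name.removeprefix("chr").removeprefix("Chr").upper()
    if stripped == "X":
        return "X"
    if stripped == "Y":
        return "Y"
    return "autosome"


@dataclass
class ReferenceModel:
    """Binned genome: chromosome lengths plus a GC-annotated bin tiling.

    Attributes
    ----------
    chromosomes : list of (name, length)
        Ordered chromosome table; names unique, lengths in bp.
    bin_size : int
        Nominal bin width in bp; the last bin of each chromosome may be
        shorter.
    bins : pandas.DataFrame
        One row per bin with columns ``chrom``, ``start``, ``end``, ``gc``,
        sorted by chromosome (in table order) then start.
    """

    chromosomes: list[tuple[str, int]]
    bin_size: int
    bins: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        lengths = dict(self.chromosomes)
        required = ["chrom", "start", "end", "gc"]
        if list(self.bins.columns[:4]) != required:
            raise FormatError(f"bin table must have columns {required}")
        gc = self.bins["gc"].to_numpy(dtype=float)
        if np.any(gc < 0.0) or np.any(gc > 1.0):
            raise ValueError("GC fraction outside [0, 1]")
        # Tiling invariant: contiguous, half-open, covering [0, length).
        for chrom, grp in self.bins.groupby("chrom", sort=False):
            if chrom not in lengths:
                raise ValueError(f"bin on unknown chromosome {chrom!r}")
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if np.any(starts >= ends):
                raise FormatError(f"{chrom}: degenerate bin (start >= end)")
            if starts[0] != 0 or ends[-1] != lengths[chrom]:
                raise FormatError(f"{chrom}: bins do not cover [0, length)")
            if np.any(starts[1:] != ends[:-1]):
                raise FormatError(f"{chrom}: bins not contiguous/sorted")

    # -- cached vector views -------------------------------------------------

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @cached_property
    def starts(self) -> np.ndarray:
        return self.bins["start"].to_numpy(dtype=np.int64)

    @cached_property
    def ends(self) -> np.ndarray:
        return self.bins["end"].to_numpy(dtype=np.int64)

    @cached_property
    def widths(self) -> np.ndarray:
        return self.ends - self.starts

    @cached_property
    def gc(self) -> np.ndarray:
        return self.bins["gc"].to_numpy(dtype=float)

    @cached_property
    def chrom_slices(self) -> dict[str, slice]:
        """Bin-index slice for each chromosome (bins are chromosome-blocked)."""
        out: dict[str, slice] = {}
        codes = self.bins["chrom"].to_numpy()
        for chrom, _ in self.chromosomes:
            idx = np.flatnonzero(codes == chrom)
            if idx.size:
                out[chrom] = slice(int(idx[0]), int(idx[-1]) + 1)
        return out

    @cached_property
    def sex_class_per_bin(self) -> np.ndarray:
        classes = {c: chrom_sex_class(c) for c, _ in self.chromosomes}
        return self.bins["chrom"].map(classes).to_numpy()

    @cached_property
    def autosomal_mask(self) -> np.ndarray:
        return self.sex_class_per_bin == "autosome"

    @cached_property
    def x_mask(self) -> np.ndarray:
        return self.sex_class_per_bin == "X"

    @cached_property
    def y_mask(self) -> np.ndarray:
        return self.sex_class_per_bin == "Y"

    @property
    def autosome_names(self) -> list[str]:
        return [c for c, _ in self.chromosomes if chrom_sex_class(c) == "autosome"]

    def chrom_length(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(chrom)

    def bin_index(self, chrom: str, pos: int) -> int:
        """Index of the unique bin whose half-open interval contains ``pos``."""
        sl = self.chrom_slices[chrom]
        if not 0 <= pos < self.chrom_length(chrom):
            raise ValueError(f"position {pos} outside {chrom}")
        local = int(np.searchsorted(self.starts[sl], pos, side="right")) - 1
        return sl.start + local


def _tile_chromosomes(
    chrom_lengths: list[tuple[str, int]], bin_size: int
) -> pd.DataFrame:
    rows = []
    for chrom, length in chrom_lengths:
        starts = np.arange(0, length, bin_size, dtype=np.int64)
        ends = np.minimum(starts + bin_size, length)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


def build_reference(
    chrom_lengths: list[tuple[str, int]],
    bin_size: int = DEFAULT_BIN_SIZE,
    gc: np.ndarray | list[float] | None = None,
    seed: int | None = None,
    gc_mean: float = 0.41,
    gc_sd: float = 0.05,
    gc_clip: tuple[float, float] = (0.2, 0.8),
) -> ReferenceModel:
    """Tile chromosomes into fixed-width bins and attach per-bin GC.

    When ``gc`` is not supplied, GC fractions are drawn from a Beta
    distribution with the given mean and standard deviation (human-like
    defaults: mean 0.41, sd 0.05) and clipped to ``gc_clip``, reproducibly
    under ``seed``.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if not chrom_lengths:
        raise ValueError("need at least one chromosome")
    for chrom, length in chrom_lengths:
        if length <= 0:
            raise ValueError(f"non-positive length for {chrom}")
    table = _tile_chromosomes(chrom_lengths, bin_size)
    n = len(table)
    if gc is None:
        rng = np.random.default_rng(seed)
        # Beta with given mean/sd: nu = m(1-m)/s^2 - 1, a = m*nu, b = (1-m)*nu
        nu = gc_mean * (1.0 - gc_mean) / gc_sd**2 - 1.0
        if nu <= 0:
            raise ValueError("gc_sd too large for a Beta distribution")
        draws = rng.beta(gc_mean * nu, (1.0 - gc_mean) * nu, size=n)
        table["gc"] = np.clip(draws, *gc_clip)
    else:
        gc_arr = np.asarray(gc, dtype=float)
        if gc_arr.shape != (n,):
            raise FormatError(
                f"gc table has {gc_arr.size} values, expected {n} bins"
            )
        table["gc"] = gc_arr
    return ReferenceModel(list(chrom_lengths), bin_size, table)


def write_bins_bed(ref: ReferenceModel, path) -> None:
    """Write the bin tiling as BED4 (chrom, start, end, gc)."""
    with open(path, "w") as fh:
        for row in ref.bins.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.gc!r}\n")


def read_bins_bed(path) -> ReferenceModel:
    """Read a BED4 bin definition back into a :class:`ReferenceModel`.

    Chromosome lengths are inferred from the last bin end; the nominal bin
    size is the modal bin width.  Round-trips :func:`write_bins_bed` exactly.
    """
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    gcs: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
                gc = float(parts[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            if not 0.0 <= gc <= 1.0:
                raise ValueError(f"{path}:{lineno}: GC {gc} outside [0, 1]")
            chroms.append(parts[0])
            starts.append(start)
            ends.append(end)
            gcs.append(gc)
    if not chroms:
        raise FormatError(f"{path}: empty bin file")
    table = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends, "gc": gcs})
    seen: list[str] = []
    for c in chroms:
        if c not in seen:
            seen.append(c)
        elif seen[-1] != c:
            raise FormatError(f"{path}: chromosome {c} bins are not grouped")
    chrom_lengths = [(c, int(table.loc[table["chrom"] == c, "end"].max())) for c in seen]
    widths = table["end"] - table["start"]
    bin_size = int(widths.mode().iat[0])
    try:
        return ReferenceModel(chrom_lengths, bin_size, table)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def read_chrom_sizes(path) -> list[tuple[str, int]]:
    """Read a two-column ``chrom<TAB>length`` table."""
    out: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected 'chrom<TAB>length'")
            try:
                out.append((parts[0], int(parts[1])))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out
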