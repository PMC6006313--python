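"""Per-bin read-count tables: the pipeline's raw-data container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError
from .reference import ReferenceModel

__all__ = ["BinCountTable", "SAMPLE_TYPES", "write_counts_tsv", "read_counts_tsv"]

#: ECB = spent culture medium + blastocoel fluid; TE = trophectoderm biopsy;
#: RE = remaining embryo; NC = negative control.
SAMPLE_TYPES = ("ECB", "TE", "RE", "NC")


@dataclass
class BinCountTable:
    """Raw integer read counts per bin for one sample."""

    sample_id: str
    sample_type: str
    counts: np.ndarray
    total_reads: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.sample_type not in SAMPLE_TYPES:
            raise ValueError(f"unknown sample type {self.sample_type!r}")
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(self.counts < 0):
            raise ValueError("negative bin count")
        if self.total_reads < 0:
            self.total_reads = int(self.counts.sum())
        elif self.total_reads != int(self.counts.sum()):
            raise ValueError("total_reads does not match sum of counts")


def write_counts_tsv(table: BinCountTable, ref: ReferenceModel, path) -> None:
    """Write counts as TSV: bin_index, chrom, start, end, count (+ header)."""
    if len(table.counts) != ref.n_bins:
        raise ValueError("count vector does not match reference bin count")
    df = pd.DataFrame(
        {
            "bin_index": np.arange(ref.n_bins),
            "chrom": ref.bins["chrom"],
            "start": ref.starts,
            "end": ref.ends,
            "count": table.counts,
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# sample_id={table.sample_id}\tsample_type={table.sample_type}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_counts_tsv(path, ref: ReferenceModel) -> BinCountTable:
    """Read a count TSV written by :func:`write_counts_tsv`, validated against ``ref``."""
    sample_id, sample_type = "", ""
    with open(path) as fh:
        first = fh.readline().strip()
        if first.startswith("#"):
            meta = dict(
                kv.split("=", 1) for kv in first.lstrip("# ").split("\t") if "=" in kv
            )
            sample_id = meta.get("sample_id", "")
            sample_type = meta.get("sample_type", "")
            df = pd.read_csv(fh, sep="\t")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t")
    for col in ("chrom", "start", "end", "count"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    if len(df) != ref.n_bins:
        raise FormatError(
            f"{path}: {len(df)} rows but reference has {ref.n_bins} bins"
        )
    if not (
        (df["chrom"].to_numpy() == ref.bins["chrom"].to_numpy()).all()
        and (df["start"].to_numpy() == ref.starts).all()
        and (df["end"].to_numpy() == ref.ends).all()
    ):
        raise FormatError(f"{path}: bin coordinates do not match the reference")
    if not sample_type:
        sample_type = "RE"
    return BinCountTable(
        sample_id=sample_id or str(path),
        sample_type=sample_type,
        counts=df["count"].to_numpy(dtype=np.int64),
    )
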