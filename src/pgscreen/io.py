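"""Plain-text interchange for call sets and cohort reports.

Everything is line-oriented TSV/JSON so intermediates are inspectable and
diffable.  The cohort call matrix has one row per embryo x sample_type x
call entity (22 autosomes plus the combined ``sex`` entity).
"""

from __future__ import annotations

import json
from dataclasses import asdict

import pandas as pd

from .caller import ChromosomeCall, SEX_ENTITY, SampleCallSet, SegmentCall
from .concordance import CohortReport
from .errors import FormatError

__all__ = [
    "write_callset_tsv",
    "read_callset_tsv",
    "write_call_matrix",
    "read_call_matrix",
    "write_report_json",
    "write_report_tables",
]

_COLUMNS = [
    "embryo_id", "sample_id", "sample_type", "entity", "status",
    "mean_ratio", "mosaic_fraction", "segments", "sex_call", "qc_pass",
]


def _callset_rows(callset: SampleCallSet, embryo_id: str) -> list[dict]:
    rows = []
    for chrom, call in callset.calls.items():
        rows.append(
            {
                "embryo_id": embryo_id,
                "sample_id": callset.sample_id,
                "sample_type": callset.sample_type,
                "entity": chrom,
                "status": call.status,
                "mean_ratio": call.mean_ratio,
                "mosaic_fraction": (
                    "" if call.mosaic_fraction is None else call.mosaic_fraction
                ),
                "segments": json.dumps([asdict(s) for s in call.segments]),
                "sex_call": callset.sex_call,
                "qc_pass": int(callset.qc_pass),
            }
        )
    rows.append(
        {
            "embryo_id": embryo_id,
            "sample_id": callset.sample_id,
            "sample_type": callset.sample_type,
            "entity": SEX_ENTITY,
            "status": (
                "no_call" if not callset.qc_pass
                else "abnormal" if callset.sex_entity_abnormal else "normal"
            ),
            "mean_ratio": "",
            "mosaic_fraction": "",
            "segments": "[]",
            "sex_call": callset.sex_call,
            "qc_pass": int(callset.qc_pass),
        }
    )
    return rows


def write_callset_tsv(callset: SampleCallSet, path, embryo_id: str = "") -> None:
    pd.DataFrame(_callset_rows(callset, embryo_id or callset.sample_id)).to_csv(
        path, sep="\t", index=False
    )


def write_call_matrix(
    callsets: dict[str, dict[str, SampleCallSet]], path
) -> None:
    """One TSV for the whole cohort: embryo x sample_type x entity."""
    rows: list[dict] = []
    for embryo_id in sorted(callsets):
        for sample_type in ("ECB", "TE", "RE"):
            if sample_type in callsets[embryo_id]:
                rows.extend(
                    _callset_rows(callsets[embryo_id][sample_type], embryo_id)
                )
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)


def _callset_from_rows(rows: pd.DataFrame) -> SampleCallSet:
    sex_rows = rows[rows["entity"] == SEX_ENTITY]
    if len(sex_rows) != 1:
        raise FormatError("call matrix: expected exactly one sex-entity row per sample")
    sex_row = sex_rows.iloc[0]
    qc_pass = bool(int(sex_row["qc_pass"]))
    calls: dict[str, ChromosomeCall] = {}
    for row in rows[rows["entity"] != SEX_ENTITY].itertuples(index=False):
        segments = [
            SegmentCall(**{k: v for k, v in seg.items()})
            for seg in json.loads(row.segments or "[]")
        ]
        mf = row.mosaic_fraction
        mf = None if (pd.isna(mf) or mf == "") else float(mf)
        calls[row.entity] = ChromosomeCall(
            chromosome=row.entity,
            status=row.status,
            mean_ratio=float(row.mean_ratio) if not pd.isna(row.mean_ratio) else float("nan"),
            mosaic_fraction=mf,
            segments=segments,
        )
    return SampleCallSet(
        sample_id=str(sex_row["sample_id"]),
        sample_type=str(sex_row["sample_type"]),
        calls=calls,
        sex_call=str(sex_row["sex_call"]),
        sex_entity_abnormal=(str(sex_row["status"]) == "abnormal"),
        qc_pass=qc_pass,
    )


def read_callset_tsv(path) -> SampleCallSet:
    df = pd.read_csv(path, sep="\t")
    return _callset_from_rows(df)


def read_call_matrix(path) -> dict[str, dict[str, SampleCallSet]]:
    df = pd.read_csv(path, sep="\t")
    for col in _COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    out: dict[str, dict[str, SampleCallSet]] = {}
    for (embryo_id, sample_type), rows in df.groupby(
        ["embryo_id", "sample_type"], sort=True
    ):
        out.setdefault(str(embryo_id), {})[str(sample_type)] = _callset_from_rows(rows)
    return out


def write_report_json(report: CohortReport, path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_report_tables(report: CohortReport, outdir) -> None:
    """Human-readable TSVs mirroring the cohort result tables."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {"group": g, "n": report.group_counts[g]}
            for g in sorted(report.group_counts)
        ]
    ).to_csv(outdir / "groups.tsv", sep="\t", index=False)
    rows = []
    for level, conf in (
        ("embryo", report.embryo_confusion),
        ("chromosome", report.chromosome_confusion),
    ):
        for method, cc in conf.items():
            d = cc.to_dict()
            d.update({"level": level, "method": method})
            rows.append(d)
    pd.DataFrame(rows).to_csv(outdir / "confusion.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"pair": k, **v} for k, v in report.discordance.items()]
    ).to_csv(outdir / "discordance.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"embryo_id": t.embryo_id, "group": t.group}
            for t in report.trios
        ]
    ).to_csv(outdir / "trio_groups.tsv", sep="\t", index=False)
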