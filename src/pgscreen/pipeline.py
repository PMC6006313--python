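"""End-to-end orchestration: simulate -> normalize -> call -> compare."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .caller import SampleCallSet, call_sample
from .concordance import CohortReport, cohort_report
from .config import RunConfig
from .counts import BinCountTable, write_counts_tsv
from .io import write_call_matrix, write_report_json, write_report_tables
from .normalize import profile_from_counts
from .reference import (
    HG19_CHROM_LENGTHS,
    ReferenceModel,
    build_reference,
    read_bins_bed,
    write_bins_bed,
)
from .simulate import EmbryoSpec, simulate_cohort, simulate_trio

__all__ = ["simulate_study", "call_cohort", "run_end_to_end"]

logger = logging.getLogger(__name__)


def _reference_for(config: RunConfig) -> ReferenceModel:
    if config.bins_path:
        return read_bins_bed(config.bins_path)
    # GC landscape seeded independently of the cohort stream
    return build_reference(
        HG19_CHROM_LENGTHS, config.bin_size, seed=config.seed + 1_000_003
    )


def simulate_study(
    config: RunConfig, ref: ReferenceModel, out_dir: Path | None = None
) -> tuple[list[EmbryoSpec], dict[str, dict[str, BinCountTable]]]:
    """Simulate the cohort and all three count tables per embryo.

    With ``out_dir`` set, writes per-sample count TSVs, a cohort manifest and
    the ground-truth JSON.
    """
    specs = simulate_cohort(
        config.n_embryos,
        config.simulator,
        seed=config.seed,
        chrom_lengths=ref.chromosomes,
    )
    tables: dict[str, dict[str, BinCountTable]] = {}
    child_seeds = np.random.SeedSequence(config.seed).spawn(len(specs))
    manifest_rows = []
    for spec, child in zip(specs, child_seeds):
        trio = simulate_trio(
            spec, ref, config.simulator, seed=np.random.default_rng(child)
        )
        tables[spec.embryo_id] = trio
        if out_dir is not None:
            for st, table in trio.items():
                fname = f"{spec.embryo_id}_{st}.counts.tsv"
                write_counts_tsv(table, ref, out_dir / fname)
                manifest_rows.append(
                    {
                        "embryo_id": spec.embryo_id,
                        "sample_type": st,
                        "file": fname,
                        "failed": int(spec.failure_flags.get(st, False)),
                        "sex": spec.mix.sex,
                        "n_clones": len(spec.mix.clones),
                    }
                )
    if out_dir is not None:
        pd.DataFrame(manifest_rows).to_csv(
            out_dir / "manifest.tsv", sep="\t", index=False
        )
        with open(out_dir / "truth.json", "w") as fh:
            json.dump([s.to_dict() for s in specs], fh, indent=2)
    logger.info(
        "simulated %d embryos (%d samples) at %d reads/sample",
        len(specs), 3 * len(specs), config.simulator.total_reads,
    )
    return specs, tables


def call_cohort(
    tables: dict[str, dict[str, BinCountTable]],
    ref: ReferenceModel,
    config: RunConfig,
) -> dict[str, dict[str, SampleCallSet]]:
    """Normalize and call every sample in the cohort."""
    out: dict[str, dict[str, SampleCallSet]] = {}
    for embryo_id, trio in tables.items():
        out[embryo_id] = {}
        for st, table in trio.items():
            profile = profile_from_counts(table, ref)
            out[embryo_id][st] = call_sample(profile, ref, config.caller)
    n_fail = sum(
        not cs.qc_pass for trio in out.values() for cs in trio.values()
    )
    logger.info("called %d samples; %d failed QC",
                sum(len(t) for t in out.values()), n_fail)
    return out


def run_end_to_end(config: RunConfig, write: bool = True) -> CohortReport:
    """simulate -> normalize -> call -> compare, reproducibly under the seed.

    With ``write=True`` every stage's artifact lands under ``config.out_dir``:
    bin BED, per-sample count TSVs, truth JSON, manifest, call matrix, report
    JSON and tables.
    """
    logger.info("run config: %s", json.dumps(config.to_dict(), sort_keys=True, default=str))
    out_dir = Path(config.out_dir)
    counts_dir = None
    if write:
        out_dir.mkdir(parents=True, exist_ok=True)
        counts_dir = out_dir / "counts"
        counts_dir.mkdir(exist_ok=True)
    ref = _reference_for(config)
    if write:
        write_bins_bed(ref, out_dir / "bins.bed")
    specs, tables = simulate_study(config, ref, counts_dir)
    callsets = call_cohort(tables, ref, config)
    report = cohort_report(
        callsets, include_mosaic=config.caller.mosaic_counts_as_abnormal
    )
    if write:
        write_call_matrix(callsets, out_dir / "calls.tsv")
        write_report_json(report, out_dir / "report.json")
        write_report_tables(report, out_dir / "report")
    logger.info(
        "report: groups=%s excluded=%d",
        report.group_counts, report.n_excluded,
    )
    return report
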