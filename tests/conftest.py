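import numpy as np
import pytest

from pgscreen.caller import ChromosomeCall, SampleCallSet
from pgscreen.normalize import CopyRatioProfile
from pgscreen.reference import HG19_CHROM_LENGTHS, build_reference

#: Small genome with X/Y and enough autosomal bins for local regression.
TOY_CHROMS = [("A", 60_000_000), ("B", 40_000_000), ("X", 20_000_000), ("Y", 10_000_000)]


@pytest.fixture(scope="session")
def hg19_ref():
    return build_reference(HG19_CHROM_LENGTHS, 2_000_000, seed=7)


@pytest.fixture(scope="session")
def toy_ref():
    return build_reference(TOY_CHROMS, 2_000_000, seed=11)


def make_profile(ref, ratio, sample_id="s", sample_type="RE", total_reads=2_000_000):
    """Wrap a raw ratio vector in a CopyRatioProfile for caller tests."""
    ratio = np.asarray(ratio, dtype=float)
    auto = ref.autosomal_mask
    from scipy.stats import median_abs_deviation

    return CopyRatioProfile(
        sample_id=sample_id,
        sample_type=sample_type,
        ratio=ratio,
        corrected=ratio * 1000.0,
        baseline_count=1000.0,
        qc_noise=float(median_abs_deviation(ratio[auto], scale=1.0)),
        total_reads=total_reads,
    )


def make_callset(
    statuses: dict[str, str],
    autosomes=("chr1", "chr2", "chr3"),
    sample_id="s",
    sample_type="RE",
    sex_call="XX",
    sex_abnormal=False,
    qc_pass=True,
):
    """Build a SampleCallSet from a chrom -> status mapping (rest normal)."""
    calls = {}
    for chrom in autosomes:
        status = statuses.get(chrom, "normal")
        ratio = {
            "normal": 1.0, "gain": 1.5, "loss": 0.5,
            "mosaic_gain": 1.25, "mosaic_loss": 0.75, "no_call": float("nan"),
        }[status]
        calls[chrom] = ChromosomeCall(
            chromosome=chrom,
            status=status,
            mean_ratio=ratio,
            mosaic_fraction=0.5 if status.startswith("mosaic") else None,
        )
    return SampleCallSet(
        sample_id=sample_id,
        sample_type=sample_type,
        calls=calls,
        sex_call=sex_call,
        sex_entity_abnormal=sex_abnormal,
        qc_pass=qc_pass,
    )
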