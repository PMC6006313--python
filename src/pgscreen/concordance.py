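"""Three-way concordance: confusion counts, five trio groups, discordance.

The remaining embryo (RE) is the reference standard.  Two call sets agree
when they report the same set of (chromosome, direction) abnormalities --
mosaic and full events in the same direction count as the same finding.
Trios are classified into five groups by their pairwise agreement pattern:

1. all three agree; 2. ECB = TE but both differ from RE; 3. TE = RE but ECB
differs; 4. ECB = RE but TE differs; 5. all three differ.

Because agreement is equality of canonical abnormality sets, it is an
equivalence relation and every complete trio lands in exactly one group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction

from .caller import SEX_ENTITY, SampleCallSet

__all__ = [
    "ConfusionCounts",
    "TrioComparison",
    "CohortReport",
    "round_half_up",
    "abnormality_signature",
    "callsets_agree",
    "classify_trio",
    "confusion_embryo_level",
    "confusion_chromosome_level",
    "discordance_rates",
    "cohort_report",
]

PAIRS = (("TE", "RE"), ("ECB", "RE"), ("TE", "ECB"))


def round_half_up(value: float | Fraction, ndigits: int = 2) -> float:
    """Round with ties away from zero (the convention behind 59.375 -> 59.38)."""
    if isinstance(value, Fraction):
        dec = Decimal(value.numerator) / Decimal(value.denominator)
    else:
        dec = Decimal(repr(float(value)))
    q = Decimal(1).scaleb(-ndigits)
    return float(dec.quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion table against the RE standard.

    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP); each is undefined
    (None) when its denominator is zero.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> Fraction | None:
        den = self.tp + self.fn
        return Fraction(self.tp, den) if den else None

    @property
    def specificity(self) -> Fraction | None:
        den = self.tn + self.fp
        return Fraction(self.tn, den) if den else None

    @property
    def sensitivity_pct(self) -> float | None:
        s = self.sensitivity
        return None if s is None else round_half_up(100 * s)

    @property
    def specificity_pct(self) -> float | None:
        s = self.specificity
        return None if s is None else round_half_up(100 * s)

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "total": self.total,
            "sensitivity_pct": self.sensitivity_pct,
            "specificity_pct": self.specificity_pct,
        }


def abnormality_signature(
    callset: SampleCallSet, include_mosaic: bool = True
) -> frozenset[tuple[str, str]]:
    """Canonical set of (entity, direction) abnormalities for one sample.

    Mosaic and full events in the same direction are merged (a 'half
    decrease' and a full loss of the same chromosome are the same finding).
    With ``include_mosaic=False``, mosaic-level events are dropped from the
    signature.
    """
    if not callset.qc_pass:
        raise ValueError("abnormality signature undefined for QC-fail sample")
    sig: set[tuple[str, str]] = set()
    for chrom, call in callset.calls.items():
        statuses = [call.status] + [s.status for s in call.segments]
        for status in statuses:
            if status in ("gain", "loss"):
                sig.add((chrom, status))
            elif status in ("mosaic_gain", "mosaic_loss") and include_mosaic:
                sig.add((chrom, status.removeprefix("mosaic_")))
    if callset.sex_entity_abnormal:
        sig.add((SEX_ENTITY, "abnormal"))
    return frozenset(sig)


def callsets_agree(
    a: SampleCallSet, b: SampleCallSet, include_mosaic: bool = True
) -> bool:
    """True iff both samples report the same abnormality signature."""
    return abnormality_signature(a, include_mosaic) == abnormality_signature(
        b, include_mosaic
    )


@dataclass(frozen=True)
class TrioComparison:
    """One embryo's three-way agreement pattern and group label."""

    embryo_id: str
    group: int
    agree_ecb_te: bool
    agree_te_re: bool
    agree_ecb_re: bool
    abnormal: dict = field(hash=False, default_factory=dict)


def classify_trio(
    ecb: SampleCallSet,
    te: SampleCallSet,
    re: SampleCallSet,
    embryo_id: str = "",
    include_mosaic: bool = True,
) -> TrioComparison:
    """Assign a complete (all QC-pass) trio to one of the five groups."""
    for cs in (ecb, te, re):
        if not cs.qc_pass:
            raise ValueError("classify_trio requires all three samples QC-pass")
    s_e = abnormality_signature(ecb, include_mosaic)
    s_t = abnormality_signature(te, include_mosaic)
    s_r = abnormality_signature(re, include_mosaic)
    a_et, a_tr, a_er = s_e == s_t, s_t == s_r, s_e == s_r
    if a_et and a_tr:
        group = 1
    elif a_et:
        group = 2
    elif a_tr:
        group = 3
    elif a_er:
        group = 4
    else:
        group = 5
    return TrioComparison(
        embryo_id=embryo_id or re.sample_id,
        group=group,
        agree_ecb_te=a_et,
        agree_te_re=a_tr,
        agree_ecb_re=a_er,
        abnormal={"ECB": ecb.abnormal, "TE": te.abnormal, "RE": re.abnormal},
    )


def _paired(method_calls, standard_calls):
    if len(method_calls) != len(standard_calls):
        raise ValueError("method and standard lists must be paired by embryo")
    kept, dropped = [], 0
    for m, s in zip(method_calls, standard_calls):
        if m.qc_pass and s.qc_pass:
            kept.append((m, s))
        else:
            dropped += 1
    return kept, dropped


def confusion_embryo_level(
    method_calls: list[SampleCallSet],
    standard_calls: list[SampleCallSet],
) -> tuple[ConfusionCounts, int]:
    """Embryo-level confusion: positive = RE (standard) abnormal.

    QC-fail pairs are dropped; the dropped count is returned alongside.
    """
    kept, dropped = _paired(method_calls, standard_calls)
    tp = fp = tn = fn = 0
    for m, s in kept:
        if s.abnormal:
            if m.abnormal:
                tp += 1
            else:
                fn += 1
        else:
            if m.abnormal:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp, fp, tn, fn), dropped


def confusion_chromosome_level(
    method_calls: list[SampleCallSet],
    standard_calls: list[SampleCallSet],
) -> tuple[ConfusionCounts, int]:
    """Chromosome-level confusion over 23 entities per compared embryo
    (22 autosomes plus the combined sex entity)."""
    kept, dropped = _paired(method_calls, standard_calls)
    tp = fp = tn = fn = 0
    for m, s in kept:
        entities = list(s.calls.keys()) + [SEX_ENTITY]
        for entity in entities:
            truth = s.entity_abnormal(entity)
            pred = m.entity_abnormal(entity)
            if truth:
                if pred:
                    tp += 1
                else:
                    fn += 1
            else:
                if pred:
                    fp += 1
                else:
                    tn += 1
    return ConfusionCounts(tp, fp, tn, fn), dropped


def discordance_rates(
    trios: list[dict[str, SampleCallSet]],
    denominator: int | None = None,
    include_mosaic: bool = True,
) -> dict[str, dict]:
    """Pairwise discordance fractions over the full cohort denominator.

    The denominator defaults to the total number of trios (as the study
    reports: discordant cases over all 40, not over the comparable subset);
    pairs with a QC-fail member cannot be discordant and are tallied as
    ``incomparable``.
    """
    n = denominator if denominator is not None else len(trios)
    out: dict[str, dict] = {}
    for a, b in PAIRS:
        disc = 0
        incomparable = 0
        for trio in trios:
            ca, cb = trio[a], trio[b]
            if not (ca.qc_pass and cb.qc_pass):
                incomparable += 1
                continue
            if not callsets_agree(ca, cb, include_mosaic):
                disc += 1
        out[f"{a}_vs_{b}"] = {
            "discordant": disc,
            "denominator": n,
            "incomparable": incomparable,
            "fraction": disc / n if n else float("nan"),
            "pct": round_half_up(Fraction(100 * disc, n)) if n else None,
        }
    return out


@dataclass
class CohortReport:
    """The cohort's result tables: groups, confusions, discordance."""

    n_embryos: int
    n_excluded: int
    excluded_ids: list[str]
    group_counts: dict[int, int]
    embryo_confusion: dict[str, ConfusionCounts]
    chromosome_confusion: dict[str, ConfusionCounts]
    discordance: dict[str, dict]
    trios: list[TrioComparison] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_embryos": self.n_embryos,
            "n_excluded": self.n_excluded,
            "excluded_ids": list(self.excluded_ids),
            "group_counts": {str(g): self.group_counts[g] for g in sorted(self.group_counts)},
            "embryo_confusion": {k: v.to_dict() for k, v in self.embryo_confusion.items()},
            "chromosome_confusion": {
                k: v.to_dict() for k, v in self.chromosome_confusion.items()
            },
            "discordance": self.discordance,
            "groups_by_embryo": {t.embryo_id: t.group for t in self.trios},
        }


def cohort_report(
    callsets: dict[str, dict[str, SampleCallSet]],
    include_mosaic: bool = True,
) -> CohortReport:
    """Aggregate a cohort of trios into the full concordance report.

    ``callsets`` maps embryo_id -> {"ECB"|"TE"|"RE" -> SampleCallSet}.
    Group classification uses only complete (all-pass) trios; embryos with
    any QC-fail member are listed as excluded.  Confusion tables use the
    QC-complete pairs for each comparison; discordance fractions use the
    full cohort size as denominator.
    """
    embryo_ids = sorted(callsets)
    trios_cs = []
    for eid in embryo_ids:
        trio = callsets[eid]
        missing = {"ECB", "TE", "RE"} - set(trio)
        if missing:
            raise ValueError(f"embryo {eid}: missing sample types {sorted(missing)}")
        trios_cs.append(trio)

    comparisons: list[TrioComparison] = []
    excluded: list[str] = []
    for eid, trio in zip(embryo_ids, trios_cs):
        if all(trio[t].qc_pass for t in ("ECB", "TE", "RE")):
            comparisons.append(
                classify_trio(
                    trio["ECB"], trio["TE"], trio["RE"],
                    embryo_id=eid, include_mosaic=include_mosaic,
                )
            )
        else:
            excluded.append(eid)
    group_counts = {g: 0 for g in range(1, 6)}
    for t in comparisons:
        group_counts[t.group] += 1
    if sum(group_counts.values()) != len(comparisons):
        raise AssertionError("group counts do not partition the classified trios")

    embryo_conf: dict[str, ConfusionCounts] = {}
    chrom_conf: dict[str, ConfusionCounts] = {}
    standard = [callsets[eid]["RE"] for eid in embryo_ids]
    for method in ("TE", "ECB"):
        method_list = [callsets[eid][method] for eid in embryo_ids]
        embryo_conf[method], _ = confusion_embryo_level(method_list, standard)
        chrom_conf[method], _ = confusion_chromosome_level(method_list, standard)

    disc = discordance_rates(
        trios_cs, denominator=len(embryo_ids), include_mosaic=include_mosaic
    )
    return CohortReport(
        n_embryos=len(embryo_ids),
        n_excluded=len(excluded),
        excluded_ids=excluded,
        group_counts=group_counts,
        embryo_confusion=embryo_conf,
        chromosome_confusion=chrom_conf,
        discordance=disc,
        trios=comparisons,
    )
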