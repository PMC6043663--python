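"""The variant triage cascade: QC exclusion, consequence restriction,
population-database exclusion, and the in-silico consensus vote.

Stage order is qc -> consequence -> population -> prediction; the first
failing stage terminates a record's evaluation. Null-consequence variants
(nonsense, frameshift, canonical splice, start loss) bypass the prediction
stage: truncating alleles are not scored by missense predictors, so their
predictor fields are typically absent and they proceed on consequence alone.

Design notes on the underspecified knobs, all exposed in :class:`QcThresholds`:

* strand bias: two-sided Fisher exact test on the 2x2 per-strand table
  (ref_fwd, ref_rev; alt_fwd, alt_rev), failing below ``strand_bias_p``
  (default 1e-3);
* clustered variants: >=3 variants within a 10 bp window in one sample flags
  the whole cluster, mirroring common amplicon-artifact heuristics;
* a missing QC metric passes with a warning (absence of evidence is not
  evidence of failure); ``strict`` mode fails instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache
from typing import Iterable, Optional, Sequence

from scipy.stats import fisher_exact as _scipy_fisher

from .io import CaseRecord, Consequence, AnnotationBundle, DataError, VariantRecord

__all__ = [
    "QcThresholds",
    "StageResult",
    "FilterTrace",
    "qc_filter",
    "consequence_filter",
    "population_filter",
    "prediction_consensus",
    "find_clustered_keys",
    "run_cascade",
]

RETAINED_CONSEQUENCES = frozenset(
    {
        Consequence.NONSENSE,
        Consequence.MISSENSE,
        Consequence.CANONICAL_SPLICE,
        Consequence.FRAMESHIFT,
        Consequence.START_LOSS,
    }
)


@dataclass(frozen=True)
class QcThresholds:
    """Exclusion thresholds for the QC stage. A variant fails on mapping
    quality < 30, base quality < 20, read depth < 20, significant strand
    bias, or membership in a variant cluster (boundary values pass)."""

    min_mapping_quality: float = 30.0
    min_base_quality: float = 20.0
    min_depth: int = 20
    strand_bias_p: float = 1e-3
    cluster_window_bp: int = 10
    cluster_min_count: int = 3
    strict: bool = False  # fail (rather than warn) on missing QC metrics

    def __post_init__(self) -> None:
        if min(self.min_mapping_quality, self.min_base_quality, self.min_depth,
               self.strand_bias_p, self.cluster_window_bp, self.cluster_min_count) <= 0:
            raise ValueError("all thresholds must be positive")


class Verdict(str, Enum):
    PASS = "pass"
    FAIL = "fail"


@dataclass(frozen=True)
class StageResult:
    stage: str
    verdict: Verdict
    reason: str = ""

    @property
    def passed(self) -> bool:
        return self.verdict is Verdict.PASS


@dataclass
class FilterTrace:
    """Ordered audit trail of a record through the cascade. The first failing
    stage terminates the trace with final_status='excluded'."""

    stages: list[StageResult] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def final_status(self) -> str:
        return "excluded" if any(not s.passed for s in self.stages) else "retained"

    @property
    def failed_stage(self) -> Optional[str]:
        for s in self.stages:
            if not s.passed:
                return s.stage
        return None


@lru_cache(maxsize=65536)
def _strand_bias_p(counts: tuple[int, int, int, int]) -> float:
    table = [[counts[0], counts[1]], [counts[2], counts[3]]]
    return float(_scipy_fisher(table, alternative="two-sided")[1])


def qc_filter(
    record: VariantRecord,
    thresholds: QcThresholds = QcThresholds(),
    clustered: bool = False,
) -> tuple[StageResult, list[str]]:
    """Apply the QC exclusion criteria to one record.

    Returns the stage result plus warnings for metrics that were absent.
    The reason names the first violated criterion.
    """
    warnings: list[str] = []

    def check(name: str, value, predicate) -> Optional[StageResult]:
        if value is None:
            if thresholds.strict:
                return StageResult("qc", Verdict.FAIL, f"{name} missing (strict mode)")
            warnings.append(f"{name} missing; criterion skipped")
            return None
        if isinstance(value, (int, float)) and value < 0:
            raise DataError(f"{record.chrom}:{record.pos} negative {name}: {value}")
        if not predicate(value):
            return StageResult("qc", Verdict.FAIL, name)
        return None

    for result in (
        check("mapping quality", record.mapping_quality,
              lambda v: v >= thresholds.min_mapping_quality),
        check("base quality", record.base_quality,
              lambda v: v >= thresholds.min_base_quality),
        check("coverage", record.depth, lambda v: v >= thresholds.min_depth),
    ):
        if result is not None:
            return result, warnings

    if record.strand_counts is not None:
        if any(c < 0 for c in record.strand_counts):
            raise DataError(f"{record.chrom}:{record.pos} negative strand count")
        if _strand_bias_p(tuple(record.strand_counts)) < thresholds.strand_bias_p:
            return StageResult("qc", Verdict.FAIL, "strand bias"), warnings
    else:
        if thresholds.strict:
            return StageResult("qc", Verdict.FAIL, "strand counts missing (strict mode)"), warnings
        warnings.append("strand counts missing; criterion skipped")

    if clustered:
        return StageResult("qc", Verdict.FAIL, "clustered variants"), warnings
    return StageResult("qc", Verdict.PASS), warnings


def consequence_filter(record: VariantRecord) -> StageResult:
    """Retain only nonsense, missense, canonical-splice, frameshift (and
    start-loss) variants; synonymous, intronic and other classes fail."""
    if record.consequence in RETAINED_CONSEQUENCES:
        return StageResult("consequence", Verdict.PASS)
    return StageResult("consequence", Verdict.FAIL, record.consequence.value)


def population_filter(ann: AnnotationBundle) -> StageResult:
    """Ultra-rarity gate: exclude variants present in TGP or EVS, with more
    than 1 ExAC allele, or more than 5 gnomAD alleles. A pass defines the
    variant as ultra-rare."""
    if ann.in_tgp:
        return StageResult("population", Verdict.FAIL, "present in TGP")
    if ann.in_evs:
        return StageResult("population", Verdict.FAIL, "present in EVS")
    if ann.exac_hits > 1:
        return StageResult("population", Verdict.FAIL, f"ExAC hits {ann.exac_hits} > 1")
    if ann.gnomad_hits > 5:
        return StageResult("population", Verdict.FAIL, f"gnomAD hits {ann.gnomad_hits} > 5")
    return StageResult("population", Verdict.PASS)


def prediction_consensus(ann: AnnotationBundle, cadd_cutoff: float = 20.0) -> tuple[int, bool]:
    """Consensus damaging vote over SIFT, PolyPhen-2, MutationTaster and CADD.

    Damaging calls: SIFT D; PolyPhen-2 D or P (possibly damaging counts);
    MutationTaster D or A; CADD phred >= cutoff (boundary inclusive, default
    20). Absent predictors abstain. The verdict is votes >= 3 of 4.
    """
    votes = (
        int(ann.sift == "D")
        + int(ann.polyphen2 in ("D", "P"))
        + int(ann.mutation_taster in ("D", "A"))
        + int(ann.cadd_phred is not None and ann.cadd_phred >= cadd_cutoff)
    )
    return votes, votes >= 3


def find_clustered_keys(
    records: Sequence[CaseRecord], thresholds: QcThresholds = QcThresholds()
) -> set[tuple]:
    """Identify per-sample variant clusters: any window of
    ``cluster_window_bp`` containing >= ``cluster_min_count`` variants of one
    sample on one chromosome flags every variant in the window."""
    by_sample: dict[tuple[str, str], list[CaseRecord]] = {}
    for rec in records:
        by_sample.setdefault((rec.variant.sample_id, rec.variant.chrom), []).append(rec)
    flagged: set[tuple] = set()
    for group in by_sample.values():
        group.sort(key=lambda r: r.variant.pos)
        positions = [r.variant.pos for r in group]
        n = len(group)
        i = 0
        for j in range(n):
            while positions[j] - positions[i] > thresholds.cluster_window_bp:
                i += 1
            if j - i + 1 >= thresholds.cluster_min_count:
                for k in range(i, j + 1):
                    flagged.add((group[k].variant.sample_id,) + group[k].key)
    return flagged


def run_cascade(
    records: Sequence[CaseRecord],
    thresholds: QcThresholds = QcThresholds(),
    cadd_cutoff: float = 20.0,
) -> tuple[list[CaseRecord], list[FilterTrace]]:
    """Run the four-stage cascade over joined records.

    Returns the retained records and one trace per input record (parallel to
    ``records``). Conservation holds at every boundary: every record is either
    retained or excluded with a trace ending at its failing stage.
    """
    clustered = find_clustered_keys(records, thresholds)
    retained: list[CaseRecord] = []
    traces: list[FilterTrace] = []
    for rec in records:
        trace = FilterTrace()
        is_clustered = (rec.variant.sample_id,) + rec.key in clustered
        qc_result, warnings = qc_filter(rec.variant, thresholds, clustered=is_clustered)
        trace.stages.append(qc_result)
        trace.warnings.extend(warnings)
        if qc_result.passed:
            trace.stages.append(consequence_filter(rec.variant))
        if trace.final_status == "retained":
            trace.stages.append(population_filter(rec.annotation))
        if trace.final_status == "retained":
            if rec.variant.consequence.is_null:
                trace.stages.append(
                    StageResult("prediction", Verdict.PASS, "bypass: null consequence")
                )
            else:
                votes, damaging = prediction_consensus(rec.annotation, cadd_cutoff)
                trace.stages.append(
                    StageResult(
                        "prediction",
                        Verdict.PASS if damaging else Verdict.FAIL,
                        f"{votes}/4 damaging votes",
                    )
                )
        if trace.final_status == "retained":
            retained.append(rec)
        traces.append(trace)
    return retained, traces
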