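"""Diagnostic-yield statistics: overall and stratified yields, 2x2 Fisher
exact comparisons, and the cohort summary report.

Yields are always recomputed from raw counts; the JSON report carries full
precision and the human-readable table rounds for display only. The Fisher
test is the exact hypergeometric test with the two-sided point-probability
convention: p is the sum over all tables with the observed margins whose
probability does not exceed the observed table's.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence

from scipy.stats import fisher_exact as _scipy_fisher

from .classify import ClassificationResult, PathClass
from .io import PatientPhenotype
from .panel import SYNDROMIC_TAGS

__all__ = [
    "ContingencyTable2x2",
    "StratumYield",
    "YieldSummary",
    "fisher_exact",
    "compute_yield",
    "stratified_yield",
    "fh_stratifier",
    "syndromic_stratifier",
    "summary_report",
    "write_summary",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Carriers/non-carriers x stratum-1/stratum-2 counts (a, b; c, d)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    def as_rows(self) -> list[list[int]]:
        return [[self.a, self.b], [self.c, self.d]]


def fisher_exact(table: ContingencyTable2x2) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table.

    Returns (odds ratio, two-sided p). The odds ratio is the sample estimate
    a*d / (b*c): infinity when b*c == 0 with a*d > 0, NaN for 0/0.
    """
    oddsratio, p = _scipy_fisher(table.as_rows(), alternative="two-sided")
    return float(oddsratio), min(float(p), 1.0)


@dataclass(frozen=True)
class StratumYield:
    stratum: str
    n: int
    carriers: int

    @property
    def yield_percent(self) -> float:
        return 100.0 * self.carriers / self.n if self.n else 0.0


@dataclass
class YieldSummary:
    n_cohort: int
    n_plp_variants: int
    n_carriers: int
    strata: list[StratumYield] = field(default_factory=list)
    odds_ratio: Optional[float] = None
    p_two_sided: Optional[float] = None

    @property
    def yield_percent(self) -> float:
        """Variant-based yield: P/LP variants per cohort member, in percent."""
        return 100.0 * self.n_plp_variants / self.n_cohort

    @property
    def carrier_yield_percent(self) -> float:
        """Carrier-based yield: distinct P/LP-carrying patients, in percent."""
        return 100.0 * self.n_carriers / self.n_cohort


def _plp(results: Sequence[ClassificationResult]) -> list[ClassificationResult]:
    return [r for r in results
            if r.path_class in (PathClass.PATHOGENIC, PathClass.LIKELY_PATHOGENIC)]


def compute_yield(results: Sequence[ClassificationResult], n_cohort: int) -> YieldSummary:
    """Overall diagnostic yield: P/LP variant count over cohort size."""
    if n_cohort <= 0:
        raise ValueError("n_cohort must be positive")
    plp = _plp(results)
    carriers = {r.sample_id for r in plp}
    if n_cohort < len(carriers):
        raise ValueError("n_cohort smaller than the number of distinct carriers")
    return YieldSummary(
        n_cohort=n_cohort, n_plp_variants=len(plp), n_carriers=len(carriers)
    )


def fh_stratifier(p: PatientPhenotype) -> str:
    """Family-history partition; unknown family history maps to sporadic."""
    return "familial" if p.family_history == "yes" else "sporadic"


def syndromic_stratifier(p: PatientPhenotype) -> str:
    """Specific-syndrome / intellectual-disability stratum versus
    garden-variety ("non-syndromic") focal epilepsy."""
    if p.intellectual_disability or (p.phenotype_tags & SYNDROMIC_TAGS):
        return "syndromic"
    return "non_syndromic"


STRATIFIERS: dict[str, Callable[[PatientPhenotype], str]] = {
    "fh": fh_stratifier,
    "syndromic": syndromic_stratifier,
}


def stratified_yield(
    results: Sequence[ClassificationResult],
    phenotypes: Mapping[str, PatientPhenotype],
    stratifier: str | Callable[[PatientPhenotype], str],
    with_fisher: bool = True,
) -> YieldSummary:
    """Per-stratum carrier yields over a named partition of the cohort.

    The stratifier must assign every patient to exactly one stratum; carriers
    are counted as distinct P/LP-carrying patients. When the partition has
    exactly two strata and ``with_fisher``, a 2x2 Fisher exact comparison of
    carrier proportions is attached.
    """
    fn = STRATIFIERS[stratifier] if isinstance(stratifier, str) else stratifier
    strata: dict[str, set[str]] = {}
    for pid, pheno in phenotypes.items():
        stratum = fn(pheno)
        if not isinstance(stratum, str) or not stratum:
            raise ValueError(f"stratifier returned invalid stratum for {pid!r}")
        strata.setdefault(stratum, set()).add(pid)
    plp = _plp(results)
    carriers = {r.sample_id for r in plp}
    missing = carriers - set(phenotypes)
    if missing:
        raise ValueError(f"carriers missing from phenotype table: {sorted(missing)}")

    rows = [
        StratumYield(stratum=name, n=len(pids), carriers=len(carriers & pids))
        for name, pids in sorted(strata.items())
    ]
    summary = YieldSummary(
        n_cohort=len(phenotypes),
        n_plp_variants=len(plp),
        n_carriers=len(carriers),
        strata=rows,
    )
    if with_fisher and len(rows) == 2:
        s1, s2 = rows
        table = ContingencyTable2x2(
            s1.carriers, s1.n - s1.carriers, s2.carriers, s2.n - s2.carriers
        )
        summary.odds_ratio, summary.p_two_sided = fisher_exact(table)
    return summary


def summary_report(
    results: Sequence[ClassificationResult],
    phenotypes: Mapping[str, PatientPhenotype],
    n_cohort: Optional[int] = None,
) -> dict:
    """Assemble the machine-readable cohort summary: overall yield, family-
    history and syndromic stratifications with Fisher comparisons, per-gene
    P/LP tallies and the VUS count."""
    n = n_cohort if n_cohort is not None else len(phenotypes)
    overall = compute_yield(results, n)
    plp = _plp(results)
    per_gene: dict[str, int] = {}
    for r in plp:
        per_gene[r.gene_symbol] = per_gene.get(r.gene_symbol, 0) + 1

    report: dict = {
        "n_cohort": n,
        "n_plp_variants": overall.n_plp_variants,
        "n_carriers": overall.n_carriers,
        "yield_percent": overall.yield_percent,
        "carrier_yield_percent": overall.carrier_yield_percent,
        "n_vus": sum(r.path_class is PathClass.VUS for r in results),
        "per_gene_plp": dict(sorted(per_gene.items(), key=lambda kv: (-kv[1], kv[0]))),
        "strata": {},
    }
    for name in ("fh", "syndromic"):
        s = stratified_yield(results, phenotypes, name)
        report["strata"][name] = {
            "rows": [
                {"stratum": row.stratum, "n": row.n, "carriers": row.carriers,
                 "yield_percent": row.yield_percent}
                for row in s.strata
            ],
            "odds_ratio": s.odds_ratio,
            "p_two_sided": s.p_two_sided,
        }
    return report


def write_summary(report: dict, json_path: str | Path, tsv_path: Optional[str | Path] = None) -> None:
    """Write the summary as JSON (full precision) and optionally as a
    display TSV with rounded percentages."""
    with open(json_path, "w") as fh:
        json.dump(report, fh, indent=2, default=float)
        fh.write("\n")
    if tsv_path is not None:
        lines = [
            "metric\tvalue",
            f"n_cohort\t{report['n_cohort']}",
            f"n_plp_variants\t{report['n_plp_variants']}",
            f"n_carriers\t{report['n_carriers']}",
            f"yield_percent\t{report['yield_percent']:.2f}",
            f"n_vus\t{report['n_vus']}",
        ]
        for gene, count in report["per_gene_plp"].items():
            lines.append(f"plp[{gene}]\t{count}")
        for name, stratum in report["strata"].items():
            for row in stratum["rows"]:
                lines.append(
                    f"yield[{name}:{row['stratum']}]\t"
                    f"{row['carriers']}/{row['n']} ({row['yield_percent']:.1f}%)"
                )
            if stratum["p_two_sided"] is not None:
                lines.append(f"fisher_p[{name}]\t{stratum['p_two_sided']:.3f}")
        Path(tsv_path).write_text("\n".join(lines) + "\n")
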