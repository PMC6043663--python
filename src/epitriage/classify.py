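"""Evidence assembly and the modified-ACMG pathogenicity decision tree.

Cascade-retained variants are classified by rules evaluated in priority
order, first match fires:

R1 known_db            in a disease database (HGMD/ClinVar/LOVD)  -> Pathogenic
R2 null_lof            null consequence in a gene with an established
                       loss-of-function mechanism                  -> Pathogenic
R3 denovo_match        de novo + phenotype in gene spectrum +
                       damaging consensus (or a null consequence)  -> Pathogenic
R4 functional_match    curator-provided functional evidence +
                       phenotype in gene spectrum                  -> Pathogenic
R5 rare_missense_match ultra-rare + damaging consensus +
                       phenotype in gene spectrum                  -> Likely pathogenic
R6 default                                                         -> VUS

Segregation: an affected tested relative who does not carry the variant
(segregates=no) demotes R3-R5 outcomes to VUS; positive segregation is
recorded in the trace but does not alone upgrade a class. For X-linked
female-restricted genes (PCDH19), R2-R5 additionally require a female
proband or an explicit override.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence

from .io import (
    CarrierStatus,
    CaseRecord,
    Consequence,
    DataError,
    PedigreeRecord,
)
from .filters import (
    FilterTrace,
    QcThresholds,
    population_filter,
    prediction_consensus,
    run_cascade,
)
from .panel import (
    GenePanelEntry,
    InheritanceMode,
    MatchStatus,
    panel_index,
    phenotype_match,
)

__all__ = [
    "Inheritance",
    "Segregation",
    "PathClass",
    "EvidenceProfile",
    "ClassificationResult",
    "infer_inheritance",
    "infer_segregation",
    "build_evidence",
    "classify_variant",
    "classify_cohort",
    "RULE_ORDER",
]


class Inheritance(str, Enum):
    DE_NOVO = "de_novo"
    INHERITED = "inherited"
    UNKNOWN = "unknown"


class Segregation(str, Enum):
    YES = "yes"
    NO = "no"
    UNTESTED = "untested"


class PathClass(str, Enum):
    PATHOGENIC = "PATHOGENIC"
    LIKELY_PATHOGENIC = "LIKELY_PATHOGENIC"
    VUS = "VUS"


RULE_ORDER = ("known_db", "null_lof", "denovo_match", "functional_match",
              "rare_missense_match", "default")


@dataclass(frozen=True)
class EvidenceProfile:
    """All evidence the decision tree consumes for one retained variant."""

    ultra_rare: bool
    consensus_damaging: bool
    votes: int
    consequence: Consequence
    in_disease_db: bool
    functional_evidence: bool
    inheritance: Inheritance
    segregates: Segregation
    phenotype_match: MatchStatus
    gene_lof_mechanism: bool
    female_restricted_gene: bool = False
    patient_sex: str = "unknown"
    sex_override: bool = False


@dataclass(frozen=True)
class ClassificationResult:
    sample_id: str
    key: tuple[str, int, str, str]
    gene_symbol: str
    protein_change: str
    path_class: PathClass
    rule_fired: str
    trace: tuple[str, ...] = ()


def infer_inheritance(
    key: tuple[str, int, str, str], pedigree: Optional[PedigreeRecord]
) -> Inheritance:
    """De novo iff both parents are genotyped non-carriers; inherited iff at
    least one parent carries the variant; unknown otherwise (including any
    untested parent)."""
    if pedigree is None:
        return Inheritance.UNKNOWN
    proband = pedigree.genotype_of(key, pedigree.patient_id)
    if proband is CarrierStatus.NON_CARRIER:
        raise DataError(
            f"{pedigree.patient_id}: proband genotyped non-carrier at own variant {key}"
        )
    father = pedigree.genotype_of(key, pedigree.father_id)
    mother = pedigree.genotype_of(key, pedigree.mother_id)
    if CarrierStatus.CARRIER in (father, mother):
        return Inheritance.INHERITED
    if father is CarrierStatus.NON_CARRIER and mother is CarrierStatus.NON_CARRIER:
        return Inheritance.DE_NOVO
    return Inheritance.UNKNOWN


def infer_segregation(
    key: tuple[str, int, str, str], pedigree: Optional[PedigreeRecord]
) -> Segregation:
    """Segregation over tested relatives (parents excluded from the negative
    call only when unaffected): 'no' if any affected tested relative lacks
    the variant; 'yes' if at least one affected tested relative carries it
    and none contradicts; 'untested' otherwise. Unaffected carriers are
    tolerated (incomplete penetrance)."""
    if pedigree is None:
        return Segregation.UNTESTED
    affected_carrier = False
    for (gkey, member), status in pedigree.genotypes.items():
        if gkey != key or member == pedigree.patient_id:
            continue
        if status is CarrierStatus.UNAVAILABLE:
            continue
        if pedigree.affected.get(member) == "yes":
            if status is CarrierStatus.NON_CARRIER:
                return Segregation.NO
            affected_carrier = True
    return Segregation.YES if affected_carrier else Segregation.UNTESTED


def build_evidence(
    rec: CaseRecord,
    panel: Mapping[str, GenePanelEntry],
    cadd_cutoff: float = 20.0,
) -> EvidenceProfile:
    """Assemble the evidence profile for a cascade-retained record."""
    gene = panel.get(rec.variant.gene_symbol)
    votes, damaging = prediction_consensus(rec.annotation, cadd_cutoff)
    return EvidenceProfile(
        ultra_rare=population_filter(rec.annotation).passed,
        consensus_damaging=damaging,
        votes=votes,
        consequence=rec.variant.consequence,
        in_disease_db=rec.annotation.in_disease_db,
        functional_evidence=rec.annotation.functional_evidence,
        inheritance=infer_inheritance(rec.key, rec.pedigree),
        segregates=infer_segregation(rec.key, rec.pedigree),
        phenotype_match=(
            phenotype_match(rec.phenotype.phenotype_tags, gene)
            if gene is not None
            else MatchStatus.UNKNOWN
        ),
        gene_lof_mechanism=gene.lof_mechanism if gene is not None else False,
        female_restricted_gene=(
            gene is not None
            and gene.inheritance_mode is InheritanceMode.X_LINKED_FEMALE_RESTRICTED
        ),
        patient_sex=rec.phenotype.sex,
        sex_override=False,
    )


def _rule_applies(rule: str, ev: EvidenceProfile) -> bool:
    if rule == "known_db":
        return ev.in_disease_db
    # mechanism fidelity for female-restricted X-linked genes
    if ev.female_restricted_gene and ev.patient_sex != "female" and not ev.sex_override:
        return False
    if rule == "null_lof":
        return ev.consequence.is_null and ev.gene_lof_mechanism
    if rule == "denovo_match":
        return (
            ev.inheritance is Inheritance.DE_NOVO
            and ev.phenotype_match is MatchStatus.MATCH
            and (ev.consensus_damaging or ev.consequence.is_null)
        )
    if rule == "functional_match":
        return ev.functional_evidence and ev.phenotype_match is MatchStatus.MATCH
    if rule == "rare_missense_match":
        return (
            ev.ultra_rare
            and ev.consensus_damaging
            and ev.phenotype_match is MatchStatus.MATCH
        )
    raise ValueError(f"unknown rule {rule!r}")


_RULE_CLASS = {
    "known_db": PathClass.PATHOGENIC,
    "null_lof": PathClass.PATHOGENIC,
    "denovo_match": PathClass.PATHOGENIC,
    "functional_match": PathClass.PATHOGENIC,
    "rare_missense_match": PathClass.LIKELY_PATHOGENIC,
}

#: Rules demotable to VUS by contradictory segregation (an affected tested
#: relative lacking the variant). Database and mechanism calls are not.
_SEGREGATION_SENSITIVE = frozenset({"denovo_match", "functional_match", "rare_missense_match"})


def classify_variant(
    ev: EvidenceProfile, rule_order: Sequence[str] = RULE_ORDER
) -> tuple[PathClass, str, tuple[str, ...]]:
    """Pure decision function: evidence in, (class, rule fired, trace) out.

    Deterministic and side-effect free; ``rule_order`` permutes rule priority
    for sensitivity analysis (the default is the canonical order).
    """
    trace: list[str] = []
    for rule in rule_order:
        if rule == "default":
            continue
        if _rule_applies(rule, ev):
            if rule in _SEGREGATION_SENSITIVE and ev.segregates is Segregation.NO:
                trace.append(f"{rule}: demoted to VUS (affected relative non-carrier)")
                continue
            trace.append(f"{rule}: fired")
            if ev.segregates is Segregation.YES:
                trace.append("segregation consistent (recorded, no upgrade)")
            return _RULE_CLASS[rule], rule, tuple(trace)
        trace.append(f"{rule}: not applicable")
    trace.append("default: VUS")
    return PathClass.VUS, "default", tuple(trace)


def classify_cohort(
    records: Sequence[CaseRecord],
    panel: Sequence[GenePanelEntry],
    thresholds: QcThresholds = QcThresholds(),
    cadd_cutoff: float = 20.0,
) -> tuple[list[ClassificationResult], list[FilterTrace]]:
    """Run the cascade then the decision tree over joined records.

    Returns one :class:`ClassificationResult` per retained variant and one
    :class:`FilterTrace` per input record (parallel to ``records``).
    Deterministic given its inputs; two-variant carriers keep one result per
    variant.
    """
    index = panel_index(panel)
    retained, traces = run_cascade(records, thresholds, cadd_cutoff)
    results: list[ClassificationResult] = []
    for rec in retained:
        ev = build_evidence(rec, index, cadd_cutoff)
        path_class, rule, trace = classify_variant(ev)
        results.append(
            ClassificationResult(
                sample_id=rec.variant.sample_id,
                key=rec.key,
                gene_symbol=rec.variant.gene_symbol,
                protein_change=rec.variant.protein_change,
                path_class=path_class,
                rule_fired=rule,
                trace=trace,
            )
        )
    return results, traces
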