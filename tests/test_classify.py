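"""Inheritance inference and the pathogenicity decision tree."""

import dataclasses
from itertools import permutations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epitriage import (
    CarrierStatus,
    Consequence,
    Inheritance,
    MatchStatus,
    PathClass,
    PedigreeRecord,
    Segregation,
    classify_cohort,
    classify_variant,
    infer_inheritance,
    infer_segregation,
)
from epitriage.classify import EvidenceProfile, RULE_ORDER, build_evidence
from epitriage.io import DataError
from epitriage.panel import panel_index
from epitriage.simulate import fixture_case_records

KEY = ("2", 166894563, "A", "G")


def _pedigree(father=None, mother=None, extra=()):
    ped = PedigreeRecord(patient_id="P", father_id="F", mother_id="M",
                         affected={"P": "yes", "F": "no", "M": "no"})
    ped.genotypes[(KEY, "P")] = CarrierStatus.CARRIER
    if father is not None:
        ped.genotypes[(KEY, "F")] = father
    if mother is not None:
        ped.genotypes[(KEY, "M")] = mother
    for member, affected, status in extra:
        ped.affected[member] = affected
        ped.genotypes[(KEY, member)] = status
    return ped


@pytest.mark.parametrize(
    "father,mother,expected",
    [
        (CarrierStatus.NON_CARRIER, CarrierStatus.NON_CARRIER, Inheritance.DE_NOVO),
        (CarrierStatus.NON_CARRIER, CarrierStatus.CARRIER, Inheritance.INHERITED),
        (CarrierStatus.CARRIER, None, Inheritance.INHERITED),
        (None, None, Inheritance.UNKNOWN),
        (CarrierStatus.NON_CARRIER, None, Inheritance.UNKNOWN),
    ],
)
def test_infer_inheritance(father, mother, expected):
    assert infer_inheritance(KEY, _pedigree(father, mother)) is expected


def test_infer_inheritance_without_pedigree_is_unknown():
    assert infer_inheritance(KEY, None) is Inheritance.UNKNOWN


def test_proband_non_carrier_is_data_error():
    ped = _pedigree()
    ped.genotypes[(KEY, "P")] = CarrierStatus.NON_CARRIER
    with pytest.raises(DataError):
        infer_inheritance(KEY, ped)


def test_segregation_calls():
    # affected relative carries -> yes
    ped = _pedigree(extra=[("SIB", "yes", CarrierStatus.CARRIER)])
    assert infer_segregation(KEY, ped) is Segregation.YES
    # affected relative lacks the variant -> no
    ped = _pedigree(extra=[("SIB", "yes", CarrierStatus.NON_CARRIER)])
    assert infer_segregation(KEY, ped) is Segregation.NO
    # unaffected carrier tolerated (incomplete penetrance), nothing tested -> untested
    ped = _pedigree(extra=[("SIB", "no", CarrierStatus.CARRIER)])
    assert infer_segregation(KEY, ped) is Segregation.UNTESTED


def _evidence(**kw):
    base = dict(
        ultra_rare=True, consensus_damaging=True, votes=4,
        consequence=Consequence.MISSENSE, in_disease_db=False,
        functional_evidence=False, inheritance=Inheritance.UNKNOWN,
        segregates=Segregation.UNTESTED, phenotype_match=MatchStatus.MATCH,
        gene_lof_mechanism=False,
    )
    base.update(kw)
    return EvidenceProfile(**base)


@pytest.mark.parametrize(
    "kw,expected_class,expected_rule",
    [
        (dict(in_disease_db=True), PathClass.PATHOGENIC, "known_db"),
        (dict(consequence=Consequence.NONSENSE, gene_lof_mechanism=True),
         PathClass.PATHOGENIC, "null_lof"),
        (dict(consequence=Consequence.START_LOSS, gene_lof_mechanism=True),
         PathClass.PATHOGENIC, "null_lof"),
        (dict(inheritance=Inheritance.DE_NOVO), PathClass.PATHOGENIC, "denovo_match"),
        (dict(functional_evidence=True), PathClass.PATHOGENIC, "functional_match"),
        (dict(), PathClass.LIKELY_PATHOGENIC, "rare_missense_match"),
        (dict(phenotype_match=MatchStatus.NO_MATCH), PathClass.VUS, "default"),
        (dict(phenotype_match=MatchStatus.UNKNOWN), PathClass.VUS, "default"),
        (dict(consensus_damaging=False, votes=2), PathClass.VUS, "default"),
    ],
)
def test_decision_tree_rules(kw, expected_class, expected_rule):
    path_class, rule, _ = classify_variant(_evidence(**kw))
    assert (path_class, rule) == (expected_class, expected_rule)


def test_contradictory_segregation_demotes_to_vus():
    ev = _evidence(segregates=Segregation.NO)
    assert classify_variant(ev)[0] is PathClass.VUS
    # but not database or mechanism calls
    ev = _evidence(in_disease_db=True, segregates=Segregation.NO)
    assert classify_variant(ev)[0] is PathClass.PATHOGENIC
    ev = _evidence(consequence=Consequence.FRAMESHIFT, gene_lof_mechanism=True,
                   segregates=Segregation.NO)
    assert classify_variant(ev)[0] is PathClass.PATHOGENIC


def test_female_restricted_gene_requires_female_proband():
    ev = _evidence(female_restricted_gene=True, patient_sex="male",
                   inheritance=Inheritance.DE_NOVO)
    assert classify_variant(ev)[0] is PathClass.VUS
    ev = dataclasses.replace(ev, patient_sex="female")
    assert classify_variant(ev)[0] is PathClass.PATHOGENIC
    ev = dataclasses.replace(ev, patient_sex="male", sex_override=True)
    assert classify_variant(ev)[0] is PathClass.PATHOGENIC
    # the database rule is exempt
    ev = _evidence(female_restricted_gene=True, patient_sex="male", in_disease_db=True)
    assert classify_variant(ev)[0] is PathClass.PATHOGENIC


def test_fixture_classification_matches_published_calls(fixture_records, panel):
    results, _ = classify_cohort(fixture_records, panel)
    by_case = {r.sample_id: r for r in results}
    assert len(results) == 11
    expected = {
        "K91": PathClass.PATHOGENIC, "K39": PathClass.LIKELY_PATHOGENIC,
        "K903": PathClass.PATHOGENIC, "K94": PathClass.PATHOGENIC,
        "K400": PathClass.PATHOGENIC, "K234": PathClass.PATHOGENIC,
        "K6042": PathClass.PATHOGENIC, "K5120": PathClass.LIKELY_PATHOGENIC,
        "K5091": PathClass.PATHOGENIC, "K1014": PathClass.PATHOGENIC,
        "K977": PathClass.PATHOGENIC,
    }
    assert {c: r.path_class for c, r in by_case.items()} == expected


def test_fixture_inheritance_column(fixture_records, panel):
    idx = panel_index(panel)
    got = {
        rec.variant.sample_id: build_evidence(rec, idx).inheritance
        for rec in fixture_records
    }
    assert got == {
        "K91": Inheritance.DE_NOVO, "K39": Inheritance.INHERITED,
        "K903": Inheritance.DE_NOVO, "K94": Inheritance.INHERITED,
        "K400": Inheritance.INHERITED, "K234": Inheritance.UNKNOWN,
        "K6042": Inheritance.UNKNOWN, "K5120": Inheritance.UNKNOWN,
        "K5091": Inheritance.UNKNOWN, "K1014": Inheritance.DE_NOVO,
        "K977": Inheritance.DE_NOVO,
    }


def test_blanked_phenotypes_leave_only_db_and_mechanism_calls(fixture_records, panel):
    """With every phenotype tag removed, rules needing phenotype concordance
    cannot fire: only database-known and null-in-LOF-gene calls survive."""
    blanked = [
        dataclasses.replace(
            rec, phenotype=dataclasses.replace(rec.phenotype, phenotype_tags=frozenset())
        )
        for rec in fixture_records
    ]
    results, _ = classify_cohort(blanked, panel)
    by_rule = {r.sample_id: r.rule_fired for r in results}
    pathogenic = {r.sample_id for r in results if r.path_class is PathClass.PATHOGENIC}
    # derived by replaying the rubric over the 11 rows with match=unknown
    assert pathogenic == {"K903", "K94", "K400", "K6042", "K5091", "K977"}
    assert all(by_rule[c] in ("known_db", "null_lof") for c in pathogenic)
    assert all(
        r.path_class is PathClass.VUS for r in results if r.sample_id not in pathogenic
    )


def test_rule_priority_permutation_keeps_plp_set(fixture_records, panel):
    """Permuting rule priority may swap Pathogenic and Likely-pathogenic
    labels but never changes which variants are P or LP overall."""
    idx = panel_index(panel)
    evidences = {rec.variant.sample_id: build_evidence(rec, idx)
                 for rec in fixture_records}
    canonical = {
        case: classify_variant(ev)[0] is not PathClass.VUS
        for case, ev in evidences.items()
    }
    for perm in permutations(RULE_ORDER[:-1]):
        order = perm + ("default",)
        plp = {
            case: classify_variant(ev, order)[0] is not PathClass.VUS
            for case, ev in evidences.items()
        }
        assert plp == canonical


_evidence_strategy = st.builds(
    _evidence,
    ultra_rare=st.booleans(),
    consensus_damaging=st.booleans(),
    consequence=st.sampled_from(list(Consequence)),
    in_disease_db=st.booleans(),
    functional_evidence=st.booleans(),
    inheritance=st.sampled_from(list(Inheritance)),
    segregates=st.sampled_from(list(Segregation)),
    phenotype_match=st.sampled_from(list(MatchStatus)),
    gene_lof_mechanism=st.booleans(),
)

_RANK = {PathClass.VUS: 0, PathClass.LIKELY_PATHOGENIC: 1, PathClass.PATHOGENIC: 2}


@given(ev=_evidence_strategy)
@settings(max_examples=200)
def test_disease_db_evidence_never_downgrades(ev):
    before = classify_variant(ev)[0]
    after = classify_variant(dataclasses.replace(ev, in_disease_db=True))[0]
    assert _RANK[after] >= _RANK[before]


def test_empty_cohort_classifies_to_nothing(panel):
    results, traces = classify_cohort([], panel)
    assert results == [] and traces == []


def test_two_variant_carriers_keep_both_results(panel):
    records, _ = fixture_case_records()
    twin = dataclasses.replace(
        records[0],
        variant=dataclasses.replace(records[0].variant, pos=166894563 + 500),
    )
    results, _ = classify_cohort(records + [twin], panel)
    assert sum(r.sample_id == "K91" for r in results) == 2
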