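"""The four-stage triage cascade: boundaries, bypass, invariants."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import enum_fisher_p
from epitriage import (
    AnnotationBundle,
    CaseRecord,
    Consequence,
    PatientPhenotype,
    QcThresholds,
    VariantRecord,
    consequence_filter,
    population_filter,
    prediction_consensus,
    qc_filter,
    run_cascade,
)
from epitriage.io import DataError
from epitriage.simulate import SimulationConfig, generate_cohort, generate_variants


def _variant(**kw):
    base = dict(
        chrom="1", pos=1000, ref="A", alt="G", sample_id="S1",
        consequence=Consequence.MISSENSE, mapping_quality=55.0,
        base_quality=33.0, depth=60, strand_counts=(15, 15, 15, 15),
    )
    base.update(kw)
    return VariantRecord(**base)


@pytest.mark.parametrize(
    "kw,expect_pass,reason",
    [
        (dict(depth=19), False, "coverage"),
        (dict(depth=20), True, ""),
        (dict(mapping_quality=29.9), False, "mapping quality"),
        (dict(mapping_quality=30.0, base_quality=20.0, depth=20,
              strand_counts=(5, 5, 5, 5)), True, ""),
        (dict(base_quality=19.5), False, "base quality"),
        # spec'd strand-bias example: all alt reads on one strand
        (dict(strand_counts=(10, 10, 20, 0)), False, "strand bias"),
    ],
)
def test_qc_boundaries(kw, expect_pass, reason):
    result, _ = qc_filter(_variant(**kw))
    assert result.passed is expect_pass
    if not expect_pass:
        assert reason in result.reason


def test_qc_strand_bias_threshold_verified_by_enumeration():
    """The example table's hypergeometric p, computed by full enumeration,
    is below the 1e-3 exclusion threshold; a balanced table's is not."""
    assert enum_fisher_p(10, 10, 20, 0) < 1e-3
    assert enum_fisher_p(15, 15, 15, 15) > 1e-3


def test_qc_missing_metric_warns_not_fails():
    result, warnings = qc_filter(_variant(depth=None, strand_counts=None))
    assert result.passed
    assert any("coverage" in w or "strand" in w for w in warnings)
    strict = dataclasses.replace(QcThresholds(), strict=True)
    result, _ = qc_filter(_variant(depth=None), strict)
    assert not result.passed


def test_qc_negative_metric_is_data_error():
    with pytest.raises(DataError):
        qc_filter(_variant(mapping_quality=-1.0))


@pytest.mark.parametrize(
    "csq,expect",
    [
        (Consequence.FRAMESHIFT, True),
        (Consequence.NONSENSE, True),
        (Consequence.CANONICAL_SPLICE, True),
        (Consequence.MISSENSE, True),
        (Consequence.SYNONYMOUS, False),
        (Consequence.INTRONIC, False),  # e.g. splice-region at +7
        (Consequence.OTHER, False),
    ],
)
def test_consequence_filter(csq, expect):
    assert consequence_filter(_variant(consequence=csq)).passed is expect


@pytest.mark.parametrize(
    "kw,expect",
    [
        (dict(), True),  # all absent ("np")
        (dict(in_tgp=True), False),
        (dict(in_evs=True), False),
        (dict(exac_hits=1), True),
        (dict(exac_hits=2), False),
        (dict(gnomad_hits=5), True),
        (dict(gnomad_hits=6), False),
    ],
)
def test_population_filter_boundaries(kw, expect):
    assert population_filter(AnnotationBundle(**kw)).passed is expect


@pytest.mark.parametrize(
    "sift,pp2,mt,cadd,votes,verdict",
    [
        ("D", "D", "A", 32.0, 4, True),    # CHRNA4 p.Ser284Leu pattern
        ("D", "NA", "D", 42.0, 3, True),   # SLC2A1 p.Ser414Ter pattern
        ("D", "P", "D", 22.6, 4, True),    # PolyPhen possibly-damaging counts
        ("T", "B", "N", 5.0, 0, False),
        ("D", "D", "NA", 19.9, 2, False),  # CADD below cutoff casts no vote
        ("NA", "NA", "NA", 20.0, 1, False),  # boundary-inclusive CADD vote
    ],
)
def test_prediction_consensus_votes(sift, pp2, mt, cadd, votes, verdict):
    ann = AnnotationBundle(sift=sift, polyphen2=pp2, mutation_taster=mt, cadd_phred=cadd)
    assert prediction_consensus(ann) == (votes, verdict)


def _case(variant, ann=None, pid=None):
    return CaseRecord(
        variant=variant,
        annotation=ann or AnnotationBundle(consequence=variant.consequence),
        phenotype=PatientPhenotype(patient_id=pid or variant.sample_id),
    )


def test_cascade_null_variants_bypass_prediction(fixture_records):
    """All 11 worked-example variants pass the cascade even though the
    truncating ones have no predictor calls at all."""
    retained, traces = run_cascade(fixture_records)
    assert len(retained) == 11
    for rec, trace in zip(fixture_records, traces):
        assert trace.final_status == "retained"
        prediction = trace.stages[-1]
        if rec.variant.consequence.is_null:
            assert "bypass" in prediction.reason


def test_cascade_short_circuits_on_qc(fixture_records):
    bad = dataclasses.replace(
        fixture_records[0],
        variant=dataclasses.replace(fixture_records[0].variant, depth=5),
    )
    retained, traces = run_cascade([bad])
    assert retained == []
    assert [s.stage for s in traces[0].stages] == ["qc"]


def test_cascade_flags_clustered_variants():
    damaging = AnnotationBundle(
        consequence=Consequence.MISSENSE, sift="D", polyphen2="D",
        mutation_taster="D", cadd_phred=30.0,
    )
    records = [
        _case(_variant(pos=1000 + off, sample_id="S1"), damaging) for off in (0, 4, 9)
    ] + [_case(_variant(pos=1000, sample_id="S2"), damaging)]
    retained, traces = run_cascade(records)
    assert {r.variant.sample_id for r in retained} == {"S2"}
    assert all("cluster" in t.stages[0].reason for t in traces[:3])


def test_cascade_conservation_and_planted_common_exclusion():
    cfg = SimulationConfig(n_patients=120, seed=11)
    phenos, _ = generate_cohort(cfg)
    pairs, truth = generate_variants(cfg, phenos)
    records = [_case(v, a) for v, a in pairs]
    retained, traces = run_cascade(records)
    excluded = [t for t in traces if t.final_status == "excluded"]
    assert len(retained) + len(excluded) == len(records)
    truth_by_key = truth.by_key()
    for rec, trace in zip(records, traces):
        entry = truth_by_key[(rec.variant.sample_id,) + rec.key]
        if entry.variant_class == "common":
            assert trace.failed_stage == "population"


def test_cascade_matches_brute_force_oracle():
    """For a small batch, any-order re-evaluation of the four predicates
    (with the null bypass honored) retains the same set."""
    cfg = SimulationConfig(n_patients=12, seed=3)
    phenos, _ = generate_cohort(cfg)
    pairs, _ = generate_variants(cfg, phenos)
    records = [_case(v, a) for v, a in pairs[:20]]
    thresholds = QcThresholds()
    retained, _ = run_cascade(records, thresholds)

    def brute_force(rec):
        v, a = rec.variant, rec.annotation
        qc_ok = (
            (v.mapping_quality is None or v.mapping_quality >= 30)
            and (v.base_quality is None or v.base_quality >= 20)
            and (v.depth is None or v.depth >= 20)
            and (v.strand_counts is None or enum_fisher_p(*v.strand_counts) >= 1e-3)
        )
        csq_ok = v.consequence.value in {
            "nonsense", "missense", "canonical_splice", "frameshift", "start_loss"
        }
        pop_ok = (not a.in_tgp and not a.in_evs
                  and a.exac_hits <= 1 and a.gnomad_hits <= 5)
        votes = (
            (a.sift == "D") + (a.polyphen2 in ("D", "P"))
            + (a.mutation_taster in ("D", "A"))
            + (a.cadd_phred is not None and a.cadd_phred >= 20)
        )
        pred_ok = v.consequence.value in {"nonsense", "frameshift",
                                          "canonical_splice", "start_loss"} or votes >= 3
        return qc_ok and csq_ok and pop_ok and pred_ok

    # clusters: none in a 20-record synthetic batch (construction guarantees
    # >10 bp same-sample spacing), so the predicates are order-independent
    expected = {id(r) for r in records if brute_force(r)}
    assert {id(r) for r in retained} == expected


_relax = st.fixed_dictionaries(
    {
        "min_mapping_quality": st.floats(1.0, 30.0),
        "min_base_quality": st.floats(1.0, 20.0),
        "min_depth": st.integers(1, 20),
        "strand_bias_p": st.floats(1e-6, 1e-3),
    }
)


@given(relaxed=_relax)
@settings(max_examples=25)
def test_relaxing_thresholds_never_shrinks_retained_set(relaxed):
    cfg = SimulationConfig(n_patients=40, seed=5)
    phenos, _ = generate_cohort(cfg)
    pairs, _ = generate_variants(cfg, phenos)
    records = [_case(v, a) for v, a in pairs]
    strict_retained, _ = run_cascade(records, QcThresholds())
    lax_retained, _ = run_cascade(records, QcThresholds(**relaxed))
    assert {id(r) for r in strict_retained} <= {id(r) for r in lax_retained}
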