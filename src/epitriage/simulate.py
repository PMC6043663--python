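"""Synthetic cohorts with truth labels, and the packaged worked-example
fixture.

The generator emulates the statistical structure of a ~600-patient focal
non-lesional epilepsy panel screen: per-patient phenotype tags, family
history at the cohort's observed familial fraction, a syndromic/ID subgroup,
optional trios, and annotated variants planted in classes whose triage fate
is guaranteed by construction (common, QC-failing, synonymous, ultra-rare
in-spectrum damaging, null-in-LOF-gene, out-of-spectrum damaging, and
disease-database-known). Every planted variant carries a truth label naming
the stage expected to exclude it, or its expected final class, so the whole
cascade and classifier are testable without external data.

Predictor scores per class come from simple parametric draws (damaging class
CADD uniform on [20, 45], benign below 20); the pipeline consumes scores and
never validates them, so realism of the score distributions is immaterial.
Variant positions are drawn uniformly inside fixed per-gene coordinate
windows; they only need to be well-formed and gene-assignable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io import (
    AnnotationBundle,
    CarrierStatus,
    CaseRecord,
    Consequence,
    Genotype,
    PatientPhenotype,
    PedigreeRecord,
    VariantRecord,
    variant_key,
    write_phenotypes,
    write_variant_table,
)
from .panel import GenePanelEntry, SYNDROMIC_TAGS, default_panel

__all__ = [
    "SimulationConfig",
    "TruthEntry",
    "TruthTable",
    "generate_cohort",
    "generate_variants",
    "write_vcf",
    "write_truth_table",
    "make_paper_fixture",
    "fixture_case_records",
    "FIXTURE_COHORT_SIZE",
]

# Planting classes and their guaranteed fates.
VARIANT_CLASSES = (
    "common", "qc_fail", "synonymous", "ultra_rare_match",
    "null_lof", "out_of_spectrum", "db_known",
)

_CLASS_FATE = {
    "common": ("population", None),
    "qc_fail": ("qc", None),
    "synonymous": ("consequence", None),
    "ultra_rare_match": ("retained", "LIKELY_PATHOGENIC"),
    "null_lof": ("retained", "PATHOGENIC"),
    "out_of_spectrum": ("retained", "VUS"),
    "db_known": ("retained", "PATHOGENIC"),
}

# Fixed per-gene simulation windows (chromosome, window start); positions are
# drawn uniformly within _GENE_SPAN of the anchor.
_GENE_ANCHORS: dict[str, tuple[str, int]] = {
    "SCN1A": ("2", 166845000), "SCN1B": ("19", 35521000), "SCN2A": ("2", 166095000),
    "SCN9A": ("2", 167050000), "DEPDC5": ("22", 32150000), "GRIN2A": ("16", 9850000),
    "GRIN2B": ("12", 13700000), "PRRT2": ("16", 29820000), "SLC2A1": ("1", 43390000),
    "PCDH19": ("X", 99540000), "KCNT1": ("9", 138590000), "KCNQ2": ("20", 62030000),
    "KCNQ3": ("8", 133130000), "KCNA2": ("1", 111140000), "CHRNA4": ("20", 61975000),
    "CHRNB2": ("1", 154540000), "CHRNA2": ("8", 27320000), "LGI1": ("10", 95520000),
    "GABRG2": ("5", 161490000), "HCN1": ("5", 45250000), "CHD2": ("15", 93000000),
}
_GENE_SPAN = 60000

_SYNDROMIC_SIM_TAGS = ("DRAVET", "GEFS_PLUS", "GLUT1_DS", "LGS", "EAS")
_FOCAL_SIM_TAGS = ("TLE", "FLE", "NFLE", "FOCAL_EPILEPSY", "BECTS")

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort and planting parameters. Defaults reproduce the study
    conditions: 593 patients, 99/593 with a positive family history, 39/593
    in the syndromic/ID subgroup, and per-patient planting rates sized so a
    default run carries ~2000 variants with a pathogenic/likely-pathogenic
    yield near 2%."""

    n_patients: int = 593
    fraction_family_history: float = 99 / 593
    fraction_syndromic: float = 39 / 593
    trio_fraction: float = 0.3
    # expected planted variants per patient, by class
    rate_common: float = 2.2
    rate_qc_fail: float = 0.35
    rate_synonymous: float = 0.5
    rate_ultra_rare_match: float = 0.007
    rate_null_lof: float = 0.008
    rate_out_of_spectrum: float = 0.027
    rate_db_known: float = 0.004
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_family_history", "fraction_syndromic", "trio_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name, v in self.rates.items():
            if v < 0:
                raise ValueError(f"rate for {name} must be >= 0, got {v}")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")

    @property
    def rates(self) -> dict[str, float]:
        return {c: getattr(self, f"rate_{c}") for c in VARIANT_CLASSES}


@dataclass(frozen=True)
class TruthEntry:
    sample_id: str
    key: tuple[str, int, str, str]
    variant_class: str
    intended_stage: str           # qc / consequence / population / retained
    intended_class: Optional[str]  # PATHOGENIC / LIKELY_PATHOGENIC / VUS / None


@dataclass
class TruthTable:
    entries: list[TruthEntry] = field(default_factory=list)

    def by_key(self) -> dict[tuple, TruthEntry]:
        return {(e.sample_id,) + e.key: e for e in self.entries}


def generate_cohort(
    cfg: SimulationConfig,
) -> tuple[dict[str, PatientPhenotype], dict[str, PedigreeRecord]]:
    """Draw the patient table and trio pedigrees.

    Family-history and syndromic flags are independent Bernoulli draws at the
    configured fractions, so realized counts match the fractions in
    expectation; identical seeds give identical cohorts.
    """
    rng = np.random.default_rng(cfg.seed)
    phenotypes: dict[str, PatientPhenotype] = {}
    pedigrees: dict[str, PedigreeRecord] = {}
    width = len(str(cfg.n_patients))
    for i in range(cfg.n_patients):
        pid = f"S{i + 1:0{width}d}"
        syndromic = rng.random() < cfg.fraction_syndromic
        if syndromic:
            tag = _SYNDROMIC_SIM_TAGS[rng.integers(len(_SYNDROMIC_SIM_TAGS))]
            intellectual_disability = bool(rng.random() < 0.4)
        else:
            tag = _FOCAL_SIM_TAGS[rng.integers(len(_FOCAL_SIM_TAGS))]
            intellectual_disability = False
        phenotypes[pid] = PatientPhenotype(
            patient_id=pid,
            phenotype_tags=frozenset({tag}),
            family_history="yes" if rng.random() < cfg.fraction_family_history else "no",
            intellectual_disability=intellectual_disability,
            sex="female" if rng.random() < 0.5 else "male",
            site="TW" if rng.random() < 0.5 else "MY",
        )
        if rng.random() < cfg.trio_fraction:
            pedigrees[pid] = PedigreeRecord(
                patient_id=pid,
                father_id=f"{pid}F",
                mother_id=f"{pid}M",
                affected={pid: "yes", f"{pid}F": "no", f"{pid}M": "no"},
            )
    return phenotypes, pedigrees


def _clean_qc(rng: np.random.Generator, genotype: Genotype) -> dict:
    depth = int(rng.integers(40, 250))
    alt = depth if genotype is Genotype.HEMI else depth // 2
    ref = depth - alt
    return {
        "mapping_quality": float(np.round(rng.uniform(40, 60), 1)),
        "base_quality": float(np.round(rng.uniform(25, 40), 1)),
        "depth": depth,
        "strand_counts": (ref - ref // 2, ref // 2, alt - alt // 2, alt // 2),
    }


def _snv(rng: np.random.Generator) -> tuple[str, str]:
    i = int(rng.integers(4))
    j = (i + 1 + int(rng.integers(3))) % 4
    return _BASES[i], _BASES[j]


def _damaging_bundle(rng: np.random.Generator) -> dict:
    return {
        "sift": "D",
        "polyphen2": "D" if rng.random() < 0.7 else "P",
        "mutation_taster": "D" if rng.random() < 0.7 else "A",
        "cadd_phred": float(np.round(rng.uniform(20, 45), 1)),
    }


def _benign_bundle(rng: np.random.Generator) -> dict:
    return {
        "sift": "T",
        "polyphen2": "B",
        "mutation_taster": "N",
        "cadd_phred": float(np.round(rng.uniform(0, 15), 1)),
    }


def generate_variants(
    cfg: SimulationConfig,
    phenotypes: dict[str, PatientPhenotype],
    panel: Optional[Sequence[GenePanelEntry]] = None,
) -> tuple[list[tuple[VariantRecord, AnnotationBundle]], TruthTable]:
    """Plant annotated variants whose triage fate is guaranteed by
    construction, with a truth label per variant.

    Per patient and class, counts are Poisson at the configured rate.
    Positions are globally unique and at least 11 bp from any other variant
    of the same sample, so no planted variant trips the cluster filter by
    accident.
    """
    panel = list(panel) if panel is not None else default_panel()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    lof_genes = [g for g in panel if g.lof_mechanism and g.gene_symbol != "PCDH19"]

    used_positions: dict[str, set[int]] = {}
    sample_positions: dict[tuple[str, str], list[int]] = {}

    def draw_position(gene: GenePanelEntry, sample_id: str) -> tuple[str, int]:
        chrom, anchor = _GENE_ANCHORS[gene.gene_symbol]
        taken = used_positions.setdefault(chrom, set())
        nearby = sample_positions.setdefault((sample_id, chrom), [])
        for _ in range(200):
            pos = anchor + int(rng.integers(_GENE_SPAN))
            if pos in taken:
                continue
            if any(abs(pos - p) <= 10 for p in nearby):
                continue
            taken.add(pos)
            nearby.append(pos)
            return chrom, pos
        raise RuntimeError("could not place variant; window exhausted")

    pairs: list[tuple[VariantRecord, AnnotationBundle]] = []
    truth = TruthTable()

    for pid in sorted(phenotypes):
        pheno = phenotypes[pid]
        tags = pheno.phenotype_tags
        matching = [g for g in panel
                    if g.phenotype_spectrum & tags and g.gene_symbol != "PCDH19"]
        disjoint = [g for g in panel if not (g.phenotype_spectrum & tags)]
        for vclass in VARIANT_CLASSES:
            for _ in range(int(rng.poisson(cfg.rates[vclass]))):
                pair = _plant(rng, vclass, pid, pheno, panel, matching, disjoint,
                              lof_genes, draw_position)
                if pair is None:
                    continue
                pairs.append(pair)
                stage, pclass = _CLASS_FATE[vclass]
                truth.entries.append(
                    TruthEntry(pid, pair[0].key, vclass, stage, pclass)
                )
    return pairs, truth


def _plant(
    rng, vclass, pid, pheno, panel, matching, disjoint, lof_genes, draw_position
) -> Optional[tuple[VariantRecord, AnnotationBundle]]:
    if vclass == "ultra_rare_match":
        if not matching:
            return None
        gene = matching[int(rng.integers(len(matching)))]
    elif vclass == "out_of_spectrum":
        if not disjoint:
            return None
        gene = disjoint[int(rng.integers(len(disjoint)))]
    elif vclass == "null_lof":
        gene = lof_genes[int(rng.integers(len(lof_genes)))]
    else:
        gene = panel[int(rng.integers(len(panel)))]

    chrom, pos = draw_position(gene, pid)
    genotype = Genotype.HEMI if chrom == "X" and pheno.sex == "male" else Genotype.HET

    consequence = Consequence.MISSENSE
    ref, alt = _snv(rng)
    if vclass == "synonymous":
        consequence = Consequence.SYNONYMOUS
    elif vclass == "null_lof":
        consequence = (Consequence.NONSENSE, Consequence.FRAMESHIFT,
                       Consequence.CANONICAL_SPLICE)[int(rng.integers(3))]
        if consequence is Consequence.FRAMESHIFT:
            base = _BASES[int(rng.integers(4))]
            ins = _BASES[int(rng.integers(4))]
            if rng.random() < 0.5:
                ref, alt = base, base + ins           # duplication/insertion
            else:
                ref, alt = base + ins, base           # deletion

    qc = _clean_qc(rng, genotype)
    if vclass == "qc_fail":
        mode = int(rng.integers(3))
        if mode == 0:
            depth = int(rng.integers(1, 20))
            alt_n = depth if genotype is Genotype.HEMI else depth // 2
            ref_n = depth - alt_n
            qc["depth"] = depth
            qc["strand_counts"] = (ref_n - ref_n // 2, ref_n // 2,
                                   alt_n - alt_n // 2, alt_n // 2)
        elif mode == 1:
            qc["mapping_quality"] = float(np.round(rng.uniform(1, 29.9), 1))
        else:
            qc["base_quality"] = float(np.round(rng.uniform(1, 19.9), 1))

    ann_fields: dict = {"in_tgp": False, "in_evs": False, "exac_hits": 0, "gnomad_hits": 0,
                        "sift": "NA", "polyphen2": "NA", "mutation_taster": "NA",
                        "cadd_phred": None, "in_disease_db": False, "functional_evidence": False}
    if vclass == "common":
        ann_fields["gnomad_hits"] = int(rng.integers(6, 500))
        ann_fields["exac_hits"] = int(rng.integers(0, 200))
        ann_fields.update(_benign_bundle(rng))
    elif vclass in ("ultra_rare_match", "out_of_spectrum", "db_known"):
        ann_fields["exac_hits"] = int(rng.integers(0, 2))
        ann_fields["gnomad_hits"] = int(rng.integers(0, 6))
        ann_fields.update(_damaging_bundle(rng))
        if vclass == "db_known":
            ann_fields["in_disease_db"] = True
    elif vclass == "qc_fail":
        ann_fields.update(_damaging_bundle(rng))

    aa = int(rng.integers(20, 1500))
    bundle = AnnotationBundle(
        gene_symbol=gene.gene_symbol,
        transcript=gene.transcript,
        consequence=consequence,
        cdna_change=f"c.{pos % 4000 + 1}{ref if len(ref) == 1 else 'del'}>{alt if len(alt) == 1 else 'ins'}",
        protein_change=f"p.Xaa{aa}{'Ter' if consequence is Consequence.NONSENSE else 'Yaa'}",
        **ann_fields,
    )
    variant = VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alt=alt, sample_id=pid,
        gene_symbol=gene.gene_symbol, transcript=gene.transcript,
        consequence=consequence, cdna_change=bundle.cdna_change,
        protein_change=bundle.protein_change, genotype=genotype, **qc,
    )
    return variant, bundle


# ---------------------------------------------------------------------------
# Output writers
# ---------------------------------------------------------------------------

def _anchored(v: VariantRecord) -> tuple[int, str, str]:
    if v.ref not in ("-", "") and v.alt not in ("-", ""):
        return v.pos, v.ref, v.alt
    ref = "" if v.ref in ("-", "") else v.ref
    alt = "" if v.alt in ("-", "") else v.alt
    return v.pos - 1, "N" + ref, "N" + alt


_CHROM_ORDER = {str(c): c for c in range(1, 23)} | {"X": 23, "Y": 24}


def write_vcf(
    pairs: Sequence[tuple[VariantRecord, AnnotationBundle]],
    sample_ids: Sequence[str],
    path: str | Path,
) -> None:
    """Emit a VCF 4.2 with INFO MQ/BQ and FORMAT GT:DP:SB. Each planted
    variant occupies its own site (positions are globally unique), carriers
    get genotypes and the remaining samples are uncalled. Deterministic:
    identical inputs give byte-identical files."""
    samples = list(sample_ids)
    col = {s: i for i, s in enumerate(samples)}
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">',
        '##INFO=<ID=BQ,Number=1,Type=Float,Description="Mean base quality">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=SB,Number=4,Type=Integer,Description="Strand counts: ref-fwd,ref-rev,alt-fwd,alt-rev">',
    ]
    chroms = sorted({v.chrom for v, _ in pairs}, key=lambda c: _CHROM_ORDER.get(c, 99))
    for c in chroms:
        lines.append(f"##contig=<ID={c}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))

    def sort_key(pair):
        v = pair[0]
        return (_CHROM_ORDER.get(v.chrom, 99), v.pos)

    for v, _a in sorted(pairs, key=sort_key):
        pos, ref, alt = _anchored(v)
        info_parts = []
        if v.mapping_quality is not None:
            info_parts.append(f"MQ={v.mapping_quality:g}")
        if v.base_quality is not None:
            info_parts.append(f"BQ={v.base_quality:g}")
        info = ";".join(info_parts) or "."
        gt = {"het": "0/1", "hom": "1/1", "hemi": "1"}[v.genotype.value]
        dp = str(v.depth) if v.depth is not None else "."
        sb = ",".join(str(x) for x in v.strand_counts) if v.strand_counts else "."
        fields = ["./.:.:."] * len(samples)
        fields[col[v.sample_id]] = f"{gt}:{dp}:{sb}"
        lines.append(
            f"{v.chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\tGT:DP:SB\t" + "\t".join(fields)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_truth_table(truth: TruthTable, path: str | Path) -> None:
    lines = ["sample_id\tchrom\tpos\tref\talt\tvariant_class\tintended_stage\tintended_class"]
    for e in truth.entries:
        chrom, pos, ref, alt = e.key
        lines.append(
            f"{e.sample_id}\t{chrom}\t{pos}\t{ref}\t{alt}\t{e.variant_class}"
            f"\t{e.intended_stage}\t{e.intended_class or '.'}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# The packaged worked-example fixture
# ---------------------------------------------------------------------------
#
# Eleven pathogenic / likely pathogenic panel variants with their published
# annotations (positions on GRCh37, predictor calls, CADD, inheritance) and
# the carriers' phenotypes. The in_disease_db flags mark the four previously
# reported mutations (SCN1A p.Arg1636Ter, the two PRRT2 p.Arg217Profs*8
# hotspot alleles, CHRNA4 p.Ser284Leu); functional_evidence marks PRRT2
# p.Leu298Pro (mutant protein shown to lack membrane localization). Both are
# curation flags, not predictor output. The pedigree stubs are synthetic
# curation: they encode the published inheritance calls (de novo where both
# unaffected parents tested negative, inherited where a carrier relative is
# drawn) without reproducing full published pedigrees.

_FIX = [
    # case, chrom, pos, ref, alt, gene, transcript, csq, cdna, protein,
    # sift, pp2, mt, cadd, in_db, functional
    ("K91", "2", 166894563, "A", "G", "SCN1A", "NM_001165963.1", "missense",
     "c.T2669C", "p.Leu890Pro", "D", "P", "D", 26.5, False, False),
    ("K39", "2", 166848645, "T", "C", "SCN1A", "NM_001165963.1", "missense",
     "c.A5140G", "p.Met1714Val", "D", "P", "D", 22.6, False, False),
    ("K903", "2", 166848879, "G", "A", "SCN1A", "NM_001165963.1", "nonsense",
     "c.C4906T", "p.Arg1636Ter", "n/a", "n/a", "D", 43.0, True, False),
    ("K94", "16", 29825024, "-", "C", "PRRT2", "NM_145239.2", "frameshift",
     "c.649dupC", "p.Arg217Profs*8", "n/a", "n/a", "n/a", None, True, False),
    ("K400", "16", 29825024, "-", "C", "PRRT2", "NM_145239.2", "frameshift",
     "c.649dupC", "p.Arg217Profs*8", "n/a", "n/a", "n/a", None, True, False),
    ("K234", "16", 29825667, "T", "C", "PRRT2", "NM_145239.2", "missense",
     "c.T893C", "p.Leu298Pro", "D", "D", "D", 26.1, False, True),
    ("K6042", "20", 61981912, "G", "A", "CHRNA4", "NM_000744.6", "missense",
     "c.C851T", "p.Ser284Leu", "D", "D", "A", 32.0, True, False),
    ("K5120", "20", 61981801, "A", "T", "CHRNA4", "NM_000744.6", "missense",
     "c.T962A", "p.Ile321Asn", "D", "D", "D", 27.9, False, False),
    ("K5091", "22", 32211078, "G", "-", "DEPDC5", "NM_001242896.1", "nonsense",
     "c.1546delG", "p.Val516Ter", "n/a", "n/a", "n/a", None, False, False),
    ("K1014", "X", 99662899, "C", "T", "PCDH19", "NM_001184880.1", "missense",
     "c.G697A", "p.Asp233Asn", "D", "D", "D", 28.2, False, False),
    ("K977", "1", 43393313, "G", "C", "SLC2A1", "NM_006516", "nonsense",
     "c.C1241G", "p.Ser414Ter", "D", "n/a", "D", 42.0, False, False),
]

# case: sex, tags, family history, intellectual disability
_FIX_PHENO = {
    "K91": ("male", {"DRAVET"}, "no", False),
    "K39": ("male", {"GEFS_PLUS"}, "yes", False),
    "K903": ("female", {"DRAVET"}, "no", False),
    "K94": ("female", {"FOCAL_EPILEPSY"}, "yes", False),
    "K400": ("male", {"BFIE", "FOCAL_EPILEPSY"}, "yes", False),
    "K234": ("male", {"FOCAL_EPILEPSY", "PKD"}, "yes", False),
    "K6042": ("male", {"NFLE"}, "no", False),
    "K5120": ("male", {"NFLE"}, "unknown", False),
    "K5091": ("male", {"FOCAL_EPILEPSY"}, "no", False),
    "K1014": ("female", {"EFMR"}, "no", True),
    "K977": ("female", {"GLUT1_DS"}, "no", True),
}

# case -> list of (member suffix or id, relation, affected, carrier status);
# father/mother entries drive the de novo / inherited call.
_FIX_PED = {
    "K91": [("K91F", "father", "no", "non_carrier"), ("K91M", "mother", "no", "non_carrier")],
    "K903": [("K903F", "father", "no", "non_carrier"), ("K903M", "mother", "no", "non_carrier")],
    "K1014": [("K1014F", "father", "no", "non_carrier"), ("K1014M", "mother", "no", "non_carrier")],
    "K977": [("K977F", "father", "no", "non_carrier"), ("K977M", "mother", "no", "non_carrier")],
    "K39": [("K39M", "mother", "yes", "carrier"), ("K39S", "son", "yes", "carrier")],
    "K94": [("K94M", "mother", "no", "carrier"), ("K94S", "son", "yes", "carrier")],
    "K400": [("K400F", "father", "no", "carrier")],
    "K234": [("K234S", "sister", "no", "non_carrier")],
}

#: Total screened cohort behind the fixture carriers.
FIXTURE_COHORT_SIZE = 593
_BACKGROUND_FH = 95         # + 4 familial carriers -> 99 familial patients
_BACKGROUND_SYNDROMIC = 34  # + 5 syndromic carriers -> 39 syndromic patients


def _fixture_pairs() -> list[tuple[VariantRecord, AnnotationBundle]]:
    pairs = []
    for (case, chrom, pos, ref, alt, gene, tx, csq, cdna, prot,
         sift, pp2, mt, cadd, in_db, func) in _FIX:
        consequence = Consequence(csq)
        bundle = AnnotationBundle(
            gene_symbol=gene, transcript=tx, consequence=consequence,
            cdna_change=cdna, protein_change=prot,
            in_tgp=False, in_evs=False, exac_hits=0, gnomad_hits=0,
            sift="NA" if sift == "n/a" else sift,
            polyphen2="NA" if pp2 == "n/a" else pp2,
            mutation_taster="NA" if mt == "n/a" else mt,
            cadd_phred=cadd, in_disease_db=in_db, functional_evidence=func,
        )
        variant = VariantRecord(
            chrom=chrom, pos=pos, ref=ref, alt=alt, sample_id=case,
            gene_symbol=gene, transcript=tx, consequence=consequence,
            cdna_change=cdna, protein_change=prot, genotype=Genotype.HET,
        )
        pairs.append((variant, bundle))
    return pairs


def _fixture_phenotypes(full_cohort: bool) -> dict[str, PatientPhenotype]:
    phenos: dict[str, PatientPhenotype] = {}
    for case, (sex, tags, fh, idd) in _FIX_PHENO.items():
        phenos[case] = PatientPhenotype(
            patient_id=case, phenotype_tags=frozenset(tags),
            family_history=fh, intellectual_disability=idd, sex=sex,
        )
    if full_cohort:
        n_background = FIXTURE_COHORT_SIZE - len(_FIX_PHENO)
        for i in range(n_background):
            pid = f"B{i + 1:03d}"
            tags = {"LGS"} if i < _BACKGROUND_SYNDROMIC else {"TLE"}
            phenos[pid] = PatientPhenotype(
                patient_id=pid,
                phenotype_tags=frozenset(tags),
                family_history="yes" if i < _BACKGROUND_FH else "no",
                intellectual_disability=False,
                sex="female" if i % 2 else "male",
                site="TW" if i % 2 else "MY",
            )
    return phenos


def _fixture_pedigrees() -> dict[str, PedigreeRecord]:
    pairs = {v.sample_id: v for v, _ in _fixture_pairs()}
    out: dict[str, PedigreeRecord] = {}
    for case, members in _FIX_PED.items():
        key = pairs[case].key
        father = next((m for m, rel, _, _ in members if rel == "father"), None)
        mother = next((m for m, rel, _, _ in members if rel == "mother"), None)
        rec = PedigreeRecord(
            patient_id=case, father_id=father, mother_id=mother,
            affected={case: "yes"},
        )
        rec.genotypes[(key, case)] = CarrierStatus.CARRIER
        for member, _rel, affected, status in members:
            rec.affected[member] = affected
            rec.genotypes[(key, member)] = CarrierStatus(status)
        out[case] = rec
    return out


def fixture_case_records(full_cohort: bool = False) -> tuple[
    list[CaseRecord], dict[str, PatientPhenotype]
]:
    """The eleven packaged worked-example variants, joined and ready for
    classification; with ``full_cohort`` the phenotype table is padded with
    variant-free background patients to the full screened-cohort size and
    its published familial / syndromic composition."""
    phenos = _fixture_phenotypes(full_cohort)
    peds = _fixture_pedigrees()
    records = [
        CaseRecord(variant=v, annotation=a, phenotype=phenos[v.sample_id],
                   pedigree=peds.get(v.sample_id))
        for v, a in _fixture_pairs()
    ]
    return records, phenos


def make_paper_fixture(out_dir: str | Path, full_cohort: bool = False) -> dict[str, Path]:
    """Write the worked-example fixture to disk: the combined per-sample
    variant table, a deduplicated annotation TSV, the phenotype TSV, and the
    pedigree stubs (PED + carrier genotypes)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pairs = _fixture_pairs()
    paths = {
        "variants": out / "variants.tsv",
        "annotations": out / "annotations.tsv",
        "phenotypes": out / "phenotypes.tsv",
        "ped": out / "trios.ped",
        "carriers": out / "carriers.tsv",
    }
    write_variant_table(pairs, paths["variants"])
    seen: set[tuple] = set()
    unique_pairs = []
    for v, a in pairs:
        k = v.key + (a.transcript,)
        if k not in seen:
            seen.add(k)
            unique_pairs.append((v, a))
    write_variant_table(unique_pairs, paths["annotations"])
    write_phenotypes(_fixture_phenotypes(full_cohort).values(), paths["phenotypes"])

    ped_lines = []
    carrier_lines = ["proband_id\tchrom\tpos\tref\talt\tmember_id\tcarrier"]
    by_case = {v.sample_id: v for v, _ in pairs}
    for case, members in _FIX_PED.items():
        father = next((m for m, rel, _, _ in members if rel == "father"), "0")
        mother = next((m for m, rel, _, _ in members if rel == "mother"), "0")
        ped_lines.append(f"FAM_{case}\t{case}\t{father}\t{mother}\t0\t2")
        v = by_case[case]
        carrier_lines.append(
            f"{case}\t{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{case}\tcarrier"
        )
        for member, rel, affected, status in members:
            child_of = case if rel in ("son", "daughter") else "0"
            pheno_code = {"yes": "2", "no": "1"}.get(affected, "0")
            ped_lines.append(f"FAM_{case}\t{member}\t{child_of}\t0\t0\t{pheno_code}")
            carrier_lines.append(
                f"{case}\t{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{member}\t{status}"
            )
    paths["ped"].write_text("\n".join(ped_lines) + "\n")
    paths["carriers"].write_text("\n".join(carrier_lines) + "\n")
    return paths
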