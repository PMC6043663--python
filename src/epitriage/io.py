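"""Readers, writers and the join layer for variants, annotations, phenotypes
and pedigrees.

Coordinate convention: VCF 1-based positions with normalized (left-aligned,
minimal) alleles; an empty allele side (pure insertion/deletion after
trimming) is serialized as ``-`` in tab-delimited files, the convention of
ANNOVAR-style tables. One canonical key ``(chrom, pos, ref, alt)`` prevents
join misses between the HGVS-flavoured annotation side and the VCF side.

Population-database columns: ``np`` (not present) maps to absent/zero. ExAC
and gnomAD "hits" are read as allele counts, not carrier counts.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pysam

from .panel import validate_tags

__all__ = [
    "Consequence",
    "Genotype",
    "CarrierStatus",
    "VariantRecord",
    "AnnotationBundle",
    "PatientPhenotype",
    "PedigreeRecord",
    "CaseRecord",
    "VcfParseError",
    "AnnotationParseError",
    "JoinError",
    "DataError",
    "normalize_alleles",
    "variant_key",
    "read_vcf",
    "read_annotations",
    "read_variant_table",
    "write_variant_table",
    "read_phenotypes",
    "write_phenotypes",
    "read_pedigrees",
    "join_records",
]

NULL_CONSEQUENCES = frozenset({"nonsense", "frameshift", "canonical_splice", "start_loss"})


class Consequence(str, Enum):
    NONSENSE = "nonsense"
    MISSENSE = "missense"
    CANONICAL_SPLICE = "canonical_splice"
    FRAMESHIFT = "frameshift"
    START_LOSS = "start_loss"
    SYNONYMOUS = "synonymous"
    INTRONIC = "intronic"
    OTHER = "other"

    @property
    def is_null(self) -> bool:
        """Protein-truncating / loss-of-function consequence class."""
        return self.value in NULL_CONSEQUENCES


class Genotype(str, Enum):
    HET = "het"
    HOM = "hom"
    HEMI = "hemi"


class CarrierStatus(str, Enum):
    CARRIER = "carrier"
    NON_CARRIER = "non_carrier"
    UNAVAILABLE = "unavailable"


class VcfParseError(ValueError):
    pass


class AnnotationParseError(ValueError):
    pass


class JoinError(ValueError):
    pass


class DataError(ValueError):
    pass


def normalize_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Minimal representation: trim shared suffix then shared prefix.

    ``-`` (the tab-table spelling of an empty allele) is treated as empty.
    """
    ref = "" if ref in ("-", ".") else ref
    alt = "" if alt in ("-", ".") else alt
    while len(ref) > 0 and len(alt) > 0 and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 0 and len(alt) > 0 and ref[0] == alt[0] and (len(ref) > 1 or len(alt) > 1):
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def variant_key(chrom: str, pos: int, ref: str, alt: str) -> tuple[str, int, str, str]:
    npos, nref, nalt = normalize_alleles(int(pos), ref, alt)
    return (str(chrom), npos, nref or "-", nalt or "-")


@dataclass(frozen=True)
class VariantRecord:
    """One called variant in one patient, with its QC metrics."""

    chrom: str
    pos: int
    ref: str
    alt: str
    sample_id: str
    gene_symbol: str = ""
    transcript: str = ""
    consequence: Consequence = Consequence.OTHER
    cdna_change: str = ""
    protein_change: str = ""
    mapping_quality: Optional[float] = None
    base_quality: Optional[float] = None
    depth: Optional[int] = None
    strand_counts: Optional[tuple[int, int, int, int]] = None  # ref_fwd, ref_rev, alt_fwd, alt_rev
    genotype: Genotype = Genotype.HET

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise DataError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise DataError(f"{self.chrom}:{self.pos} ref equals alt ({self.ref})")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return variant_key(self.chrom, self.pos, self.ref, self.alt)


_SIFT_CODES = {"D", "T"}
_PP2_CODES = {"D", "P", "B"}
_MT_CODES = {"D", "A", "N", "P"}
_NA_SPELLINGS = {"n/a", "na", ".", "", "nan", "none"}


@dataclass(frozen=True)
class AnnotationBundle:
    """Per-variant annotations: gene model, population presence, predictions,
    and curator-provided disease-database / functional flags."""

    gene_symbol: str = ""
    transcript: str = ""
    consequence: Consequence = Consequence.OTHER
    cdna_change: str = ""
    protein_change: str = ""
    in_tgp: bool = False
    in_evs: bool = False
    exac_hits: int = 0
    gnomad_hits: int = 0
    sift: str = "NA"         # D damaging / T tolerated / NA
    polyphen2: str = "NA"    # D probably / P possibly damaging / B benign / NA
    mutation_taster: str = "NA"  # D disease causing / A d.c. automatic / N / P / NA
    cadd_phred: Optional[float] = None
    in_disease_db: bool = False
    functional_evidence: bool = False

    def __post_init__(self) -> None:
        if self.exac_hits < 0 or self.gnomad_hits < 0:
            raise DataError("population hit counts must be non-negative")


@dataclass(frozen=True)
class PatientPhenotype:
    patient_id: str
    phenotype_tags: frozenset[str] = frozenset()
    family_history: str = "unknown"  # yes / no / unknown
    intellectual_disability: bool = False
    sex: str = "unknown"  # female / male / unknown
    site: str = ""


@dataclass
class PedigreeRecord:
    """Proband-centric pedigree: parental identity, affection status of
    tested members, and per-variant carrier genotypes of each member."""

    patient_id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    affected: dict[str, str] = field(default_factory=dict)  # member -> yes/no/unknown
    # (variant key, member id) -> CarrierStatus
    genotypes: dict[tuple[tuple[str, int, str, str], str], CarrierStatus] = field(default_factory=dict)

    def genotype_of(self, key: tuple[str, int, str, str], member: Optional[str]) -> CarrierStatus:
        if member is None:
            return CarrierStatus.UNAVAILABLE
        return self.genotypes.get((key, member), CarrierStatus.UNAVAILABLE)


@dataclass(frozen=True)
class CaseRecord:
    """A variant joined with its annotation, the carrier's phenotype, and
    (when available) the carrier's pedigree."""

    variant: VariantRecord
    annotation: AnnotationBundle
    phenotype: PatientPhenotype
    pedigree: Optional[PedigreeRecord] = None

    @property
    def key(self) -> tuple[str, int, str, str]:
        return self.variant.key


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _classify_gt(allele_indices: tuple, alt_index: int) -> Genotype:
    called = [a for a in allele_indices if a is not None]
    if len(called) == 1:
        return Genotype.HEMI
    if all(a == alt_index for a in called):
        return Genotype.HOM
    return Genotype.HET


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Read a VCF 4.x into per-sample, per-alt-allele records.

    Multi-allelic sites are decomposed. Mapping quality is taken from
    INFO/MQ, base quality from INFO/BQ, depth from FORMAT/DP and strand
    counts from FORMAT/SB (ref_fwd, ref_rev, alt_fwd, alt_rev); a missing
    metric is recorded as absent, never as zero.
    """
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"{path}: cannot parse VCF header: {exc}") from exc
    records: list[VariantRecord] = []
    try:
        for rec in vf:
            mq = rec.info.get("MQ")
            bq = rec.info.get("BQ")
            if isinstance(mq, tuple):
                mq = mq[0]
            if isinstance(bq, tuple):
                bq = bq[0]
            alts = rec.alts or ()
            for sample_name, sample in rec.samples.items():
                gt = sample.get("GT")
                if gt is None or all(a in (None, 0) for a in gt):
                    continue
                depth = sample.get("DP")
                sb = sample.get("SB")
                strand = tuple(int(x) for x in sb) if sb is not None else None
                for alt_index in sorted({a for a in gt if a not in (None, 0)}):
                    alt = alts[alt_index - 1]
                    npos, nref, nalt = normalize_alleles(rec.pos, rec.ref, alt)
                    records.append(
                        VariantRecord(
                            chrom=rec.chrom,
                            pos=npos,
                            ref=nref or "-",
                            alt=nalt or "-",
                            sample_id=sample_name,
                            mapping_quality=float(mq) if mq is not None else None,
                            base_quality=float(bq) if bq is not None else None,
                            depth=int(depth) if depth is not None else None,
                            strand_counts=strand,
                            genotype=_classify_gt(gt, alt_index),
                        )
                    )
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"{path}: malformed VCF record: {exc}") from exc
    return records


# ---------------------------------------------------------------------------
# Tab-delimited variant/annotation tables
# ---------------------------------------------------------------------------

VARIANT_TABLE_COLUMNS = [
    "sample_id", "chrom", "pos", "ref", "alt", "gene", "transcript",
    "consequence", "cdna_change", "protein_change",
    "mapping_quality", "base_quality", "depth",
    "ref_fwd", "ref_rev", "alt_fwd", "alt_rev", "genotype",
    "tgp", "evs", "exac_hits", "gnomad_hits",
    "sift", "polyphen2", "mutation_taster", "cadd_phred",
    "in_disease_db", "functional_evidence",
]

ANNOTATION_COLUMNS = VARIANT_TABLE_COLUMNS[1:10] + VARIANT_TABLE_COLUMNS[18:]


def _parse_predictor(raw: str, allowed: set[str], column: str, row_no: int) -> str:
    val = (raw or "").strip()
    if val.lower() in _NA_SPELLINGS:
        return "NA"
    val = val.upper()
    if val not in allowed:
        raise AnnotationParseError(f"row {row_no}: unknown {column} code {raw!r}")
    return val


def _parse_presence(raw: str) -> bool:
    return (raw or "").strip().lower() not in ({"np", "no", "false", "0"} | _NA_SPELLINGS)


def _parse_hits(raw: str) -> int:
    val = (raw or "").strip().lower()
    if val in _NA_SPELLINGS or val == "np":
        return 0
    return int(val)


def _parse_bool(raw: str) -> bool:
    return (raw or "").strip().lower() in {"yes", "true", "1"}


def _parse_optfloat(raw: str) -> Optional[float]:
    val = (raw or "").strip().lower()
    if val in _NA_SPELLINGS:
        return None
    return float(val)


def _parse_optint(raw: str) -> Optional[int]:
    val = (raw or "").strip().lower()
    if val in _NA_SPELLINGS:
        return None
    return int(float(val))


def _bundle_from_row(row: Mapping[str, str], row_no: int) -> AnnotationBundle:
    try:
        consequence = Consequence(row["consequence"].strip().lower())
    except ValueError as exc:
        raise AnnotationParseError(
            f"row {row_no}: unknown consequence {row['consequence']!r}"
        ) from exc
    return AnnotationBundle(
        gene_symbol=row.get("gene", "").strip(),
        transcript=row.get("transcript", "").strip(),
        consequence=consequence,
        cdna_change=row.get("cdna_change", "").strip(),
        protein_change=row.get("protein_change", "").strip(),
        in_tgp=_parse_presence(row.get("tgp", "np")),
        in_evs=_parse_presence(row.get("evs", "np")),
        exac_hits=_parse_hits(row.get("exac_hits", "np")),
        gnomad_hits=_parse_hits(row.get("gnomad_hits", "np")),
        sift=_parse_predictor(row.get("sift", "n/a"), _SIFT_CODES, "SIFT", row_no),
        polyphen2=_parse_predictor(row.get("polyphen2", "n/a"), _PP2_CODES, "PolyPhen-2", row_no),
        mutation_taster=_parse_predictor(
            row.get("mutation_taster", "n/a"), _MT_CODES, "MutationTaster", row_no
        ),
        cadd_phred=_parse_optfloat(row.get("cadd_phred", "n/a")),
        in_disease_db=_parse_bool(row.get("in_disease_db", "no")),
        functional_evidence=_parse_bool(row.get("functional_evidence", "no")),
    )


def _read_tsv_rows(path: str | Path) -> list[dict[str, str]]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise AnnotationParseError(f"{path}: empty file")
        return list(reader)


def read_annotations(path: str | Path) -> dict[tuple, AnnotationBundle]:
    """Read a one-row-per-variant annotation TSV, keyed by
    (chrom, pos, ref, alt, transcript) with normalized alleles."""
    out: dict[tuple, AnnotationBundle] = {}
    for row_no, row in enumerate(_read_tsv_rows(path), start=2):
        bundle = _bundle_from_row(row, row_no)
        key = variant_key(row["chrom"], int(row["pos"]), row["ref"], row["alt"]) + (bundle.transcript,)
        if key in out:
            raise AnnotationParseError(f"row {row_no}: duplicate variant key {key}")
        out[key] = bundle
    return out


def read_variant_table(path: str | Path) -> list[tuple[VariantRecord, AnnotationBundle]]:
    """Read a combined per-sample variant+annotation table (the report/fixture
    format written by :func:`write_variant_table`)."""
    out = []
    for row_no, row in enumerate(_read_tsv_rows(path), start=2):
        bundle = _bundle_from_row(row, row_no)
        strand = None
        if all(row.get(c, "").strip() not in ("", ".") for c in ("ref_fwd", "ref_rev", "alt_fwd", "alt_rev")):
            strand = (int(row["ref_fwd"]), int(row["ref_rev"]), int(row["alt_fwd"]), int(row["alt_rev"]))
        variant = VariantRecord(
            chrom=row["chrom"].strip(),
            pos=int(row["pos"]),
            ref=row["ref"].strip(),
            alt=row["alt"].strip(),
            sample_id=row["sample_id"].strip(),
            gene_symbol=bundle.gene_symbol,
            transcript=bundle.transcript,
            consequence=bundle.consequence,
            cdna_change=bundle.cdna_change,
            protein_change=bundle.protein_change,
            mapping_quality=_parse_optfloat(row.get("mapping_quality", ".")),
            base_quality=_parse_optfloat(row.get("base_quality", ".")),
            depth=_parse_optint(row.get("depth", ".")),
            strand_counts=strand,
            genotype=Genotype(row.get("genotype", "het").strip() or "het"),
        )
        out.append((variant, bundle))
    return out


def _fmt(value) -> str:
    if value is None:
        return "."
    if isinstance(value, bool):
        return "yes" if value else "no"
    if isinstance(value, float):
        return format(value, "g")
    return str(value)


def write_variant_table(
    pairs: Iterable[tuple[VariantRecord, AnnotationBundle]], path: str | Path
) -> None:
    """Write the combined per-sample variant+annotation TSV. Round-trips
    through :func:`read_variant_table` with identical field values."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(VARIANT_TABLE_COLUMNS)
        for v, a in pairs:
            sc = v.strand_counts or (None, None, None, None)
            writer.writerow([
                v.sample_id, v.chrom, v.pos, v.ref, v.alt, a.gene_symbol, a.transcript,
                a.consequence.value, a.cdna_change, a.protein_change,
                _fmt(v.mapping_quality), _fmt(v.base_quality), _fmt(v.depth),
                _fmt(sc[0]), _fmt(sc[1]), _fmt(sc[2]), _fmt(sc[3]), v.genotype.value,
                "present" if a.in_tgp else "np", "present" if a.in_evs else "np",
                a.exac_hits, a.gnomad_hits,
                a.sift if a.sift != "NA" else "n/a",
                a.polyphen2 if a.polyphen2 != "NA" else "n/a",
                a.mutation_taster if a.mutation_taster != "NA" else "n/a",
                _fmt(a.cadd_phred) if a.cadd_phred is not None else "n/a",
                _fmt(a.in_disease_db), _fmt(a.functional_evidence),
            ])


# ---------------------------------------------------------------------------
# Phenotypes and pedigrees
# ---------------------------------------------------------------------------

PHENOTYPE_COLUMNS = ["patient_id", "sex", "phenotype_tags", "family_history",
                     "intellectual_disability", "site"]


def read_phenotypes(path: str | Path) -> dict[str, PatientPhenotype]:
    out: dict[str, PatientPhenotype] = {}
    for row_no, row in enumerate(_read_tsv_rows(path), start=2):
        pid = row["patient_id"].strip()
        if pid in out:
            raise AnnotationParseError(f"row {row_no}: duplicate patient_id {pid!r}")
        fh_raw = (row.get("family_history", "unknown") or "unknown").strip().lower()
        if fh_raw not in {"yes", "no", "unknown"}:
            raise AnnotationParseError(f"row {row_no}: bad family_history {fh_raw!r}")
        out[pid] = PatientPhenotype(
            patient_id=pid,
            phenotype_tags=validate_tags((row.get("phenotype_tags", "") or "").split(";")),
            family_history=fh_raw,
            intellectual_disability=_parse_bool(row.get("intellectual_disability", "no")),
            sex=(row.get("sex", "unknown") or "unknown").strip().lower(),
            site=(row.get("site", "") or "").strip(),
        )
    return out


def write_phenotypes(phenotypes: Iterable[PatientPhenotype], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(PHENOTYPE_COLUMNS)
        for p in phenotypes:
            writer.writerow([
                p.patient_id, p.sex, ";".join(sorted(p.phenotype_tags)),
                p.family_history, _fmt(p.intellectual_disability), p.site,
            ])


def _check_no_ancestry_cycle(parents: dict[str, tuple[Optional[str], Optional[str]]]) -> None:
    for start in parents:
        seen = {start}
        frontier = [p for p in parents.get(start, (None, None)) if p]
        while frontier:
            node = frontier.pop()
            if node in seen and node == start:
                raise DataError(f"pedigree cycle: {start} is its own ancestor")
            if node in seen:
                continue
            seen.add(node)
            frontier.extend(p for p in parents.get(node, (None, None)) if p)


def read_pedigrees(
    ped_path: str | Path, carriers_path: Optional[str | Path] = None
) -> dict[str, PedigreeRecord]:
    """Read family structure from a 6-column PED file and per-variant carrier
    genotypes from a companion TSV (proband_id, chrom, pos, ref, alt,
    member_id, carrier)."""
    parents: dict[str, tuple[Optional[str], Optional[str]]] = {}
    affected: dict[str, str] = {}
    with open(ped_path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise DataError(f"{ped_path}:{line_no}: PED line needs 6 columns")
            _fam, iid, fid, mid, _sex, pheno = fields[:6]
            parents[iid] = (fid if fid != "0" else None, mid if mid != "0" else None)
            affected[iid] = {"2": "yes", "1": "no"}.get(pheno, "unknown")
    _check_no_ancestry_cycle(parents)

    records: dict[str, PedigreeRecord] = {}
    for iid, (fid, mid) in parents.items():
        records[iid] = PedigreeRecord(
            patient_id=iid, father_id=fid, mother_id=mid, affected=dict(affected)
        )
    if carriers_path is not None:
        for row_no, row in enumerate(_read_tsv_rows(carriers_path), start=2):
            pid = row["proband_id"].strip()
            rec = records.setdefault(pid, PedigreeRecord(patient_id=pid, affected=dict(affected)))
            key = variant_key(row["chrom"], int(row["pos"]), row["ref"], row["alt"])
            status = CarrierStatus(row["carrier"].strip())
            rec.genotypes[(key, row["member_id"].strip())] = status
    return records


# ---------------------------------------------------------------------------
# Join
# ---------------------------------------------------------------------------

def join_records(
    variants: Sequence[VariantRecord],
    annotations: Mapping[tuple, AnnotationBundle],
    phenotypes: Mapping[str, PatientPhenotype],
    pedigrees: Optional[Mapping[str, PedigreeRecord]] = None,
) -> tuple[list[CaseRecord], list[tuple[VariantRecord, str]]]:
    """Left-join variants with annotations, phenotypes and pedigrees.

    Returns (joined records, reject log). Variants without an annotation row
    go to the reject log, never silently dropped; a variant whose patient is
    absent from the phenotype table raises :class:`JoinError`.
    Conservation: ``len(variants) == len(joined) + len(rejected)``.
    """
    unknown = sorted({v.sample_id for v in variants} - set(phenotypes))
    if unknown:
        raise JoinError(f"variants reference unknown patients: {', '.join(unknown)}")

    # index on (key, transcript) with a fallback on the bare variant key
    by_key: dict[tuple, AnnotationBundle] = {}
    for akey, bundle in annotations.items():
        if len(akey) == 5:
            by_key.setdefault(akey[:4], bundle)
            by_key[akey] = bundle
        else:
            by_key[tuple(akey)] = bundle

    joined: list[CaseRecord] = []
    rejected: list[tuple[VariantRecord, str]] = []
    for v in variants:
        bundle = by_key.get(v.key + (v.transcript,)) if v.transcript else None
        if bundle is None:
            bundle = by_key.get(v.key)
        if bundle is None:
            rejected.append((v, "no annotation for variant key"))
            continue
        filled = replace(
            v,
            gene_symbol=v.gene_symbol or bundle.gene_symbol,
            transcript=v.transcript or bundle.transcript,
            consequence=bundle.consequence if v.consequence == Consequence.OTHER else v.consequence,
            cdna_change=v.cdna_change or bundle.cdna_change,
            protein_change=v.protein_change or bundle.protein_change,
        )
        joined.append(
            CaseRecord(
                variant=filled,
                annotation=bundle,
                phenotype=phenotypes[v.sample_id],
                pedigree=(pedigrees or {}).get(v.sample_id),
            )
        )
    return joined, rejected
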