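"""Gene-panel model: gene identities, disease mechanism, phenotype spectra.

The panel drives two decisions downstream of filtering: whether a null
(protein-truncating) variant can be called pathogenic on mechanism alone
(``lof_mechanism``), and whether a retained missense variant's carrier has a
phenotype inside the gene's reported spectrum (``phenotype_match``).
Phenotypes are flat controlled-vocabulary tags, not an ontology; the shipped
spectra are editable defaults.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import yaml

__all__ = [
    "PHENOTYPE_VOCABULARY",
    "SYNDROMIC_TAGS",
    "InheritanceMode",
    "MatchStatus",
    "GenePanelEntry",
    "PanelConfigError",
    "PhenotypeVocabularyError",
    "normalize_tag",
    "validate_tags",
    "load_panel",
    "default_panel",
    "write_panel",
    "phenotype_match",
]

#: Controlled phenotype vocabulary. Tags name epilepsy syndromes and seizure
#: localizations used for genotype-phenotype matching and cohort stratification.
PHENOTYPE_VOCABULARY = frozenset(
    {
        "DRAVET",                    # Dravet syndrome
        "GEFS_PLUS",                 # genetic epilepsy with febrile seizures plus
        "FEBRILE_SEIZURES",
        "FOCAL_EPILEPSY",            # non-lesional focal epilepsy, unspecified focus
        "TLE",                       # temporal lobe epilepsy
        "FLE",                       # frontal lobe epilepsy
        "OLE",                       # occipital lobe epilepsy
        "PLE",                       # parietal lobe epilepsy
        "NFLE",                      # nocturnal frontal lobe epilepsy
        "BFIE",                      # benign familial infantile epilepsy
        "BFNE",                      # benign familial neonatal epilepsy
        "BECTS",                     # benign epilepsy with centrotemporal spikes
        "PKD",                       # paroxysmal kinesigenic dyskinesia
        "EFMR",                      # epilepsy and mental retardation restricted to females
        "GLUT1_DS",                  # GLUT1 deficiency syndrome
        "EPILEPTIC_ENCEPHALOPATHY",
        "LGS",                       # Lennox-Gastaut syndrome
        "EAS",                       # epilepsy-aphasia spectrum
    }
)

#: Tags whose carriers are assigned to the "syndromic" stratum (together with
#: an intellectual-disability flag) when the cohort is split into specific
#: syndromes / ID versus garden-variety focal epilepsies.
SYNDROMIC_TAGS = frozenset({"DRAVET", "GEFS_PLUS", "EFMR", "GLUT1_DS", "LGS", "EAS"})


class InheritanceMode(str, Enum):
    AUTOSOMAL_DOMINANT = "autosomal_dominant"
    X_LINKED_FEMALE_RESTRICTED = "x_linked_female_restricted"
    OTHER = "other"


class MatchStatus(str, Enum):
    MATCH = "match"
    NO_MATCH = "no_match"
    UNKNOWN = "unknown"


class PanelConfigError(ValueError):
    """Malformed or incomplete panel configuration."""


class PhenotypeVocabularyError(ValueError):
    """A phenotype tag outside the controlled vocabulary."""


@dataclass(frozen=True)
class GenePanelEntry:
    """One panel gene with its matching and mechanism metadata."""

    gene_symbol: str
    transcript: str
    lof_mechanism: bool
    phenotype_spectrum: frozenset[str]
    inheritance_mode: InheritanceMode = InheritanceMode.AUTOSOMAL_DOMINANT

    def __post_init__(self) -> None:
        if not self.gene_symbol:
            raise PanelConfigError("gene_symbol must be non-empty")
        if not self.phenotype_spectrum:
            raise PanelConfigError(
                f"gene {self.gene_symbol}: phenotype_spectrum must be non-empty"
            )


def normalize_tag(tag: str) -> str:
    """Case-normalize a phenotype tag and check it against the vocabulary."""
    norm = tag.strip().upper().replace("-", "_").replace(" ", "_")
    if norm not in PHENOTYPE_VOCABULARY:
        raise PhenotypeVocabularyError(f"unknown phenotype tag: {tag!r}")
    return norm


def validate_tags(tags: Iterable[str]) -> frozenset[str]:
    return frozenset(normalize_tag(t) for t in tags if str(t).strip())


_REQUIRED_FIELDS = ("symbol", "transcript", "lof_mechanism", "phenotypes", "inheritance")


def _entry_from_mapping(rec: dict) -> GenePanelEntry:
    symbol = rec.get("symbol", "<missing symbol>")
    for f in _REQUIRED_FIELDS:
        if f not in rec:
            raise PanelConfigError(f"gene {symbol}: missing field {f!r}")
    try:
        mode = InheritanceMode(rec["inheritance"])
    except ValueError as exc:
        raise PanelConfigError(f"gene {symbol}: unknown inheritance mode") from exc
    return GenePanelEntry(
        gene_symbol=str(rec["symbol"]),
        transcript=str(rec["transcript"]),
        lof_mechanism=bool(rec["lof_mechanism"]),
        phenotype_spectrum=validate_tags(rec["phenotypes"]),
        inheritance_mode=mode,
    )


def load_panel(path: str | Path) -> list[GenePanelEntry]:
    """Load and validate a panel config (YAML or JSON; JSON is valid YAML).

    Raises :class:`PanelConfigError` on missing fields or duplicate gene
    symbols, :class:`PhenotypeVocabularyError` on out-of-vocabulary tags.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not doc or "genes" not in doc or not doc["genes"]:
        raise PanelConfigError(f"{path}: no genes defined")
    entries = [_entry_from_mapping(rec) for rec in doc["genes"]]
    seen: set[str] = set()
    for e in entries:
        if e.gene_symbol in seen:
            raise PanelConfigError(f"duplicate gene symbol: {e.gene_symbol}")
        seen.add(e.gene_symbol)
    return entries


def default_panel() -> list[GenePanelEntry]:
    """The shipped 21-gene focal-epilepsy panel."""
    ref = importlib.resources.files("epitriage").joinpath("data/default_panel.yaml")
    with importlib.resources.as_file(ref) as path:
        return load_panel(path)


def write_panel(entries: Sequence[GenePanelEntry], path: str | Path) -> None:
    """Serialize panel entries back to the YAML config format (round-trips)."""
    doc = {
        "genes": [
            {
                "symbol": e.gene_symbol,
                "transcript": e.transcript,
                "lof_mechanism": e.lof_mechanism,
                "inheritance": e.inheritance_mode.value,
                "phenotypes": sorted(e.phenotype_spectrum),
            }
            for e in entries
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def phenotype_match(patient_tags: Iterable[str], gene: GenePanelEntry) -> MatchStatus:
    """Does the patient's phenotype fall inside the gene's reported spectrum?

    Returns ``match`` iff the tag sets intersect, ``unknown`` when the patient
    has no phenotype information, ``no_match`` otherwise. Monotone in the
    patient tag set: adding tags can only turn no_match into match.
    """
    tags = frozenset(patient_tags)
    if not tags:
        return MatchStatus.UNKNOWN
    return MatchStatus.MATCH if tags & gene.phenotype_spectrum else MatchStatus.NO_MATCH


def panel_index(entries: Sequence[GenePanelEntry]) -> dict[str, GenePanelEntry]:
    return {e.gene_symbol: e for e in entries}
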