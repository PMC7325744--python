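"""Domain types, table readers/writers, and analysis configuration.

Canonical on-disk dialects (all plain CSV):

* field book  — long/tidy, one row per plot per trait:
  ``location, block, genotype, maternal, paternal, trait, value``
* pedigree    — ``inbred, qpm_parent, popcorn_parent, heterotic_pool``
* amino acids — ``genotype, class, residue, fraction, treatment, replicate,
  value``

Proportion traits are stored internally in [0, 1]; a trailing ``%`` on a
trait name marks percent-scale input and is divided by 100 at ingest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import yaml

from .errors import (
    ConfigError,
    FieldbookFormatError,
    IntegrityError,
    ValueParseError,
)

# ---------------------------------------------------------------------------
# Canonical trait registry
# ---------------------------------------------------------------------------

#: (name, orientation, default selection-intensity weight, units)
DEFAULT_TRAIT_TABLE: tuple[tuple[str, str, float, str], ...] = (
    ("germination", "maximize", 0.70, "proportion"),
    ("dap", "excluded", 0.00, "days"),
    ("rot", "complement_then_maximize", 0.50, "proportion"),
    ("neh", "maximize", 0.60, "ears/row"),
    ("el", "maximize", 0.50, "cm"),
    ("rpe", "maximize", 0.40, "rows/ear"),
    ("weg", "maximize", 0.80, "g"),
    ("ks", "excluded", 0.00, "kernels/10 g"),
    ("hgw", "maximize", 0.70, "g"),
    ("vit", "maximize", 0.60, "score 1-7"),
    ("pa", "maximize", 0.85, "proportion"),
    ("ev", "maximize", 0.85, "mL/20 g"),
)

#: Traits stored as proportions in [0, 1].
PROPORTION_TRAITS = frozenset({"germination", "rot", "pa"})

#: Count-like traits that must be nonnegative.
COUNT_TRAITS = frozenset({"neh", "rpe", "ks"})

VALID_ORIENTATIONS = frozenset(
    {"maximize", "complement_then_maximize", "excluded"}
)

AMINO_FRACTIONS = frozenset({"protein_bound", "free"})
AMINO_TREATMENTS = frozenset({"raw", "air", "microwave", "oil"})
GERMPLASM_CLASSES = frozenset(
    {"QPP_hybrid", "QPP_inbred", "popcorn", "QPM", "dent_check"}
)

#: Acid hydrolysis destroys these residues; they may never appear bound.
HYDROLYSIS_DESTROYED = frozenset({"Trp", "Cys"})


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlotObservation:
    """One plot-level measurement of one trait."""

    location: str
    block: str
    genotype: str
    trait: str
    value: float
    maternal: Optional[str] = None
    paternal: Optional[str] = None

    def validate(self) -> None:
        if self.trait in PROPORTION_TRAITS and not (0.0 <= self.value <= 1.0):
            raise IntegrityError(
                f"proportion trait {self.trait!r} outside [0,1]: {self.value}"
            )
        if self.trait == "vit" and not (1.0 <= self.value <= 7.0):
            raise IntegrityError(f"vitreousness outside [1,7]: {self.value}")
        if self.trait in COUNT_TRAITS and self.value < 0:
            raise IntegrityError(
                f"count trait {self.trait!r} negative: {self.value}"
            )


@dataclass(frozen=True)
class TraitSpec:
    """Ranking configuration for one trait."""

    name: str
    orientation: str
    weight: float
    units: str = ""

    def __post_init__(self) -> None:
        if self.orientation not in VALID_ORIENTATIONS:
            raise ConfigError(f"unknown orientation {self.orientation!r}")
        if not (0.0 <= self.weight <= 1.0):
            raise ConfigError(
                f"trait {self.name!r}: weight {self.weight} outside [0,1]"
            )
        # excluded <=> zero weight
        if self.orientation == "excluded" and self.weight != 0.0:
            raise ConfigError(
                f"trait {self.name!r}: excluded traits must carry weight 0"
            )
        if self.weight == 0.0 and self.orientation != "excluded":
            object.__setattr__(self, "orientation", "excluded")


@dataclass(frozen=True)
class PedigreeRecord:
    """Ancestry of one inbred line."""

    inbred: str
    qpm_parent: str
    popcorn_parent: str
    heterotic_pool: str


@dataclass(frozen=True)
class AminoAcidRecord:
    """One amino-acid quantification (g / 100 g flour)."""

    genotype: str
    germplasm_class: str
    residue: str
    fraction: str
    treatment: str
    replicate: int
    value: float

    def validate(self) -> None:
        if self.value < 0:
            raise IntegrityError(
                f"negative amino-acid value {self.value} for {self.residue}"
            )
        if self.fraction not in AMINO_FRACTIONS:
            raise IntegrityError(f"unknown fraction {self.fraction!r}")
        if self.treatment not in AMINO_TREATMENTS:
            raise IntegrityError(f"unknown treatment {self.treatment!r}")
        if (
            self.fraction == "protein_bound"
            and self.residue in HYDROLYSIS_DESTROYED
        ):
            raise IntegrityError(
                f"{self.residue} cannot be quantified in the protein-bound "
                "fraction (destroyed by acidic hydrolysis)"
            )


@dataclass
class AnalysisConfig:
    """Pipeline-wide knobs: trait specs, seed, alpha, estimator variants."""

    traits: list[TraitSpec] = field(default_factory=list)
    seed: int = 0
    alpha: float = 0.05
    clip_negative_varcomp: bool = True
    #: Eq.-7 variability term: multiply by (sd/sd_max) or divide by it.
    sigma_ratio: str = "multiplicative"

    def __post_init__(self) -> None:
        if not self.traits:
            self.traits = default_trait_specs()
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError(f"alpha {self.alpha} outside (0,1)")
        if self.sigma_ratio not in ("multiplicative", "divisive"):
            raise ConfigError(f"unknown sigma_ratio {self.sigma_ratio!r}")

    def trait_spec(self, name: str) -> TraitSpec:
        for spec in self.traits:
            if spec.name == name:
                return spec
        raise KeyError(name)


def default_trait_specs() -> list[TraitSpec]:
    """The default 12-trait selection-intensity configuration."""
    return [
        TraitSpec(name=n, orientation=o, weight=w, units=u)
        for n, o, w, u in DEFAULT_TRAIT_TABLE
    ]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

FIELDBOOK_REQUIRED = ("location", "block", "genotype", "trait", "value")
FIELDBOOK_COLUMNS = (
    "location",
    "block",
    "genotype",
    "maternal",
    "paternal",
    "trait",
    "value",
)
PEDIGREE_COLUMNS = ("inbred", "qpm_parent", "popcorn_parent", "heterotic_pool")
AMINO_COLUMNS = (
    "genotype",
    "class",
    "residue",
    "fraction",
    "treatment",
    "replicate",
    "value",
)


def _require_columns(
    df: pd.DataFrame, required: Sequence[str], kind: str
) -> None:
    for col in required:
        if col not in df.columns:
            raise FieldbookFormatError(
                f"{kind} file lacks required column {col!r}"
            )


def read_fieldbook(
    path: str | Path,
    known_traits: Optional[Iterable[str]] = None,
    validate: bool = True,
) -> list[PlotObservation]:
    """Read a tidy field-book CSV into typed plot observations.

    Trait names ending in ``%`` are treated as percent-scale and divided
    by 100. Unknown trait names raise unless listed in *known_traits*.
    """
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, FIELDBOOK_REQUIRED, "field-book")
    known = set(
        known_traits
        if known_traits is not None
        else (t[0] for t in DEFAULT_TRAIT_TABLE)
    )
    out: list[PlotObservation] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        trait = str(row.trait).strip()
        percent = trait.endswith("%")
        if percent:
            trait = trait[:-1].strip()
        if trait not in known:
            raise FieldbookFormatError(
                f"unknown trait {trait!r} at row {idx}; declare it in the "
                "configuration to accept it"
            )
        try:
            value = float(row.value)
        except (TypeError, ValueError):
            raise ValueParseError(
                f"non-numeric value {row.value!r} at row {idx}"
            ) from None
        if percent:
            value /= 100.0
        maternal = getattr(row, "maternal", None)
        paternal = getattr(row, "paternal", None)
        obs = PlotObservation(
            location=str(row.location),
            block=str(row.block),
            genotype=str(row.genotype),
            trait=trait,
            value=value,
            maternal=None if pd.isna(maternal) else str(maternal),
            paternal=None if pd.isna(paternal) else str(paternal),
        )
        if validate:
            obs.validate()
        out.append(obs)
    return out


def write_fieldbook(
    plots: Iterable[PlotObservation], path: str | Path
) -> None:
    fieldbook_frame(plots).to_csv(path, index=False)


def fieldbook_frame(plots: Iterable[PlotObservation]) -> pd.DataFrame:
    """Tidy DataFrame view of plot observations (analysis workhorse)."""
    return pd.DataFrame(
        [
            {
                "location": p.location,
                "block": p.block,
                "genotype": p.genotype,
                "maternal": p.maternal,
                "paternal": p.paternal,
                "trait": p.trait,
                "value": p.value,
            }
            for p in plots
        ],
        columns=list(FIELDBOOK_COLUMNS),
    )


def read_pedigree(path: str | Path) -> list[PedigreeRecord]:
    """Read a pedigree CSV; one record per inbred, duplicates rejected."""
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, PEDIGREE_COLUMNS, "pedigree")
    if df.empty:
        warnings.warn("pedigree file is empty", stacklevel=2)
        return []
    dupes = df["inbred"][df["inbred"].duplicated()].tolist()
    if dupes:
        raise IntegrityError(f"duplicate inbred id(s): {sorted(set(dupes))}")
    return [
        PedigreeRecord(
            inbred=str(r.inbred),
            qpm_parent=str(r.qpm_parent),
            popcorn_parent=str(r.popcorn_parent),
            heterotic_pool=str(r.heterotic_pool),
        )
        for r in df.itertuples(index=False)
    ]


def write_pedigree(
    records: Iterable[PedigreeRecord], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "inbred": r.inbred,
                "qpm_parent": r.qpm_parent,
                "popcorn_parent": r.popcorn_parent,
                "heterotic_pool": r.heterotic_pool,
            }
            for r in records
        ],
        columns=list(PEDIGREE_COLUMNS),
    ).to_csv(path, index=False)


def read_amino_profiles(path: str | Path) -> list[AminoAcidRecord]:
    """Read an amino-acid CSV; records validated against domain invariants."""
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, AMINO_COLUMNS, "amino-acid")
    df = df.rename(columns={"class": "germplasm_class"})
    out: list[AminoAcidRecord] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        try:
            value = float(row.value)
            replicate = int(row.replicate)
        except (TypeError, ValueError):
            raise ValueParseError(
                f"non-numeric value/replicate at row {idx}"
            ) from None
        rec = AminoAcidRecord(
            genotype=str(row.genotype),
            germplasm_class=str(row.germplasm_class),
            residue=str(row.residue),
            fraction=str(row.fraction),
            treatment=str(row.treatment),
            replicate=replicate,
            value=value,
        )
        rec.validate()
        out.append(rec)
    return out


def write_amino_profiles(
    records: Iterable[AminoAcidRecord], path: str | Path
) -> None:
    amino_frame(records).to_csv(path, index=False)


def amino_frame(records: Iterable[AminoAcidRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "genotype": r.genotype,
                "class": r.germplasm_class,
                "residue": r.residue,
                "fraction": r.fraction,
                "treatment": r.treatment,
                "replicate": r.replicate,
                "value": r.value,
            }
            for r in records
        ],
        columns=list(AMINO_COLUMNS),
    )


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


def load_config(path: Optional[str | Path] = None) -> AnalysisConfig:
    """Load YAML configuration; absent file yields full defaults.

    The YAML may carry ``seed``, ``alpha``, ``sigma_ratio``, and a
    ``traits:`` list of mappings with ``name`` plus optional
    ``orientation`` / ``weight`` / ``units`` overrides of the defaults.
    """
    if path is None:
        return AnalysisConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    defaults = {s.name: s for s in default_trait_specs()}
    for entry in raw.get("traits", []):
        if "name" not in entry:
            raise ConfigError("trait override without a name")
        name = entry["name"]
        base = defaults.get(name)
        orientation = entry.get(
            "orientation", base.orientation if base else "maximize"
        )
        weight = float(entry.get("weight", base.weight if base else 0.0))
        units = entry.get("units", base.units if base else "")
        if weight == 0.0:
            orientation = "excluded"
        defaults[name] = TraitSpec(
            name=name, orientation=orientation, weight=weight, units=units
        )
    return AnalysisConfig(
        traits=list(defaults.values()),
        seed=int(raw.get("seed", 0)),
        alpha=float(raw.get("alpha", 0.05)),
        clip_negative_varcomp=bool(raw.get("clip_negative_varcomp", True)),
        sigma_ratio=str(raw.get("sigma_ratio", "multiplicative")),
    )
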