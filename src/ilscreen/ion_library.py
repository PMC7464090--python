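"""Cation/anion inventory for ionic-liquid screening.

The packaged library holds the 16 cations and 22 anions screened against the
DHA solute (imidazolium, pyridinium, pyrrolidinium, piperidinium and
tetramethyl-ammonium cations with inorganic and organic anions).  Candidate
ionic liquids are the full Cartesian product of the two lists — 352 pairs.

Chain-length metadata is the carbon count of the longest N-substituent alkyl
chain (ethyl=2, butyl=4, ...).  Anion class is ``inorganic`` for the halides,
sulfate/hydrogen sulfate, nitrate, BF4, PF6, AlCl4 and SCN and ``organic`` for
the carbon-skeleton anions; the classes drive the anion-type trend reports.

Note on sulfate: the source inventory lists [SO4]- with a single negative
charge even though free sulfate is divalent; the library stores charge -1 as
listed and flags the discrepancy in :attr:`IonLibrary.notes` rather than
guessing intent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .exceptions import FormatError, ValidationError

__all__ = [
    "Ion",
    "IonLibrary",
    "ILPair",
    "CATION_FAMILIES",
    "load_ion_library",
    "packaged_library_path",
    "enumerate_pairs",
]

logger = logging.getLogger(__name__)

CATION_FAMILIES = frozenset(
    {"imidazolium", "pyridinium", "pyrrolidinium", "piperidinium", "ammonium"}
)
_FAMILIES = CATION_FAMILIES | {"anion"}
_ANION_CLASSES = frozenset({"inorganic", "organic"})
_REQUIRED_COLUMNS = ["abbrev", "name", "charge", "family", "chain_length", "anion_class"]


@dataclass(frozen=True)
class Ion:
    """One cation or anion with the metadata the screening pipeline needs."""

    abbreviation: str
    full_name: str
    charge: int
    family: str
    alkyl_chain_length: int | None = None
    anion_class: str | None = None

    def __post_init__(self) -> None:
        if self.charge not in (+1, -1):
            raise ValidationError(
                f"{self.abbreviation}: charge must be +1 or -1, got {self.charge}"
            )
        if self.family not in _FAMILIES:
            raise ValidationError(
                f"{self.abbreviation}: unknown family {self.family!r}"
            )
        if self.is_cation:
            if self.charge != +1:
                raise ValidationError(f"{self.abbreviation}: cation must have charge +1")
            if self.alkyl_chain_length is None or self.alkyl_chain_length < 1:
                raise ValidationError(
                    f"{self.abbreviation}: cation needs an alkyl chain length >= 1"
                )
        else:
            if self.charge != -1:
                raise ValidationError(f"{self.abbreviation}: anion must have charge -1")
            if self.anion_class not in _ANION_CLASSES:
                raise ValidationError(
                    f"{self.abbreviation}: anion needs anion_class inorganic|organic"
                )

    @property
    def is_cation(self) -> bool:
        return self.family != "anion"


@dataclass(frozen=True)
class ILPair:
    """An electroneutral cation-anion combination (one candidate ionic liquid)."""

    cation: Ion
    anion: Ion

    def __post_init__(self) -> None:
        if self.cation.charge + self.anion.charge != 0:
            raise ValidationError("ion pair must be electroneutral")

    @property
    def label(self) -> str:
        # "[EMIM]+" + "[Cl]-" -> "[EMIM][Cl]"
        return self.cation.abbreviation.rstrip("+") + self.anion.abbreviation.rstrip("-")


@dataclass
class IonLibrary:
    cations: list[Ion]
    anions: list[Ion]
    notes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for ion in self.cations + self.anions:
            if ion.abbreviation in seen:
                raise ValidationError(f"duplicate abbreviation {ion.abbreviation!r}")
            seen.add(ion.abbreviation)
        for ion in self.cations:
            if not ion.is_cation:
                raise ValidationError(f"{ion.abbreviation} listed as cation but is not")
        for ion in self.anions:
            if ion.is_cation:
                raise ValidationError(f"{ion.abbreviation} listed as anion but is not")

    def get(self, abbreviation: str) -> Ion:
        for ion in self.cations + self.anions:
            if ion.abbreviation == abbreviation:
                return ion
        raise KeyError(abbreviation)

    def ions(self) -> list[Ion]:
        return self.cations + self.anions


def packaged_library_path() -> Path:
    """Path of the CSV inventory shipped with the package."""
    return Path(resources.files("ilscreen").joinpath("data/ion_library.csv"))  # type: ignore[arg-type]


def load_ion_library(path: str | Path | None = None) -> IonLibrary:
    """Load and validate an ion inventory CSV.

    Columns: ``abbrev,name,charge,family,chain_length,anion_class`` (blank
    fields where not applicable).  ``path=None`` loads the packaged inventory.
    """
    if path is None:
        path = packaged_library_path()
    df = pd.read_csv(path, dtype={"abbrev": str, "name": str, "family": str})
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    cations: list[Ion] = []
    anions: list[Ion] = []
    for row in df.itertuples(index=False):
        chain = None if pd.isna(row.chain_length) else int(row.chain_length)
        klass = None if pd.isna(row.anion_class) else str(row.anion_class)
        ion = Ion(
            abbreviation=str(row.abbrev),
            full_name=str(row.name),
            charge=int(row.charge),
            family=str(row.family),
            alkyl_chain_length=chain,
            anion_class=klass,
        )
        (cations if ion.is_cation else anions).append(ion)
    notes = {}
    if any(a.abbreviation == "[SO4]-" for a in anions):
        notes["[SO4]-"] = (
            "listed with charge -1 in the source inventory although free sulfate "
            "is divalent; stored as listed"
        )
    library = IonLibrary(cations=cations, anions=anions, notes=notes)
    logger.info(
        "loaded ion library: %d cations, %d anions from %s",
        len(cations), len(anions), path,
    )
    return library


def enumerate_pairs(library: IonLibrary) -> list[ILPair]:
    """Cartesian product of cations x anions, in library file order."""
    return [ILPair(cation=c, anion=a) for c in library.cations for a in library.anions]
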