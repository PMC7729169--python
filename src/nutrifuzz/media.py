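"""Salt-based culture media and their ion profiles.

Plant tissue-culture media are defined as lists of mineral salts (mg/L).
Varying whole salts confounds the effects of the individual ions they carry
(one salt moves two or more ions at once), so before any modeling each medium
is re-expressed as molar concentrations of its constituent ions.  This module
holds the salt registry (molar masses and stoichiometry), the Murashige &
Skoog (MS)-based media used in the *Bryophyllum* nutrition experiment, the
macro/micronutrient dilution-series constructor, and the builder for the
factorial genotype x medium x subculture input table.

Units: salt amounts in mg/L; ion concentrations in mM (mg/L divided by g/mol
gives mmol/L directly).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "SaltDefinition",
    "MediumFormulation",
    "IonProfile",
    "UnresolvedSaltError",
    "MACRO_SALTS",
    "MICRO_SALTS",
    "IRON_SALTS",
    "ION_ORDER",
    "load_salt_registry",
    "load_ms_media",
    "ion_profile",
    "dilution_series",
    "variable_ions",
    "build_factor_table",
    "round_half_up",
]


class UnresolvedSaltError(KeyError):
    """A medium references a salt absent from the registry."""


@dataclass(frozen=True)
class SaltDefinition:
    """A mineral salt: molar mass (g/mol) and the ions it dissociates into.

    ``ions`` maps ion id -> stoichiometric count per formula unit, e.g.
    CaCl2.2H2O -> {"Ca2+": 1, "Cl-": 2}.  Waters of hydration contribute to
    the molar mass but not to the ion list.
    """

    name: str
    molar_mass: float
    ions: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValueError(f"{self.name}: molar mass must be positive")
        if not self.ions:
            raise ValueError(f"{self.name}: ion list must be non-empty")
        for ion, count in self.ions:
            if count < 1:
                raise ValueError(f"{self.name}: stoichiometry of {ion} must be >= 1")


@dataclass(frozen=True)
class MediumFormulation:
    """A named medium: salt name -> concentration in mg/L (all >= 0)."""

    name: str
    salt_amounts: Mapping[str, float]

    def __post_init__(self) -> None:
        for salt, amount in self.salt_amounts.items():
            if amount < 0:
                raise ValueError(f"{self.name}: negative amount for {salt}")

    def scaled(self, factor: float, salts: Iterable[str] | None = None, name: str | None = None) -> "MediumFormulation":
        """Return a copy with ``salts`` (default: all) scaled by ``factor``."""
        subset = set(self.salt_amounts if salts is None else salts)
        amounts = {
            s: a * factor if s in subset else a for s, a in self.salt_amounts.items()
        }
        return MediumFormulation(name or self.name, amounts)


@dataclass(frozen=True)
class IonProfile:
    """Ion id -> molar concentration (mM), tagged with the source medium."""

    concentrations: Mapping[str, float]
    medium: str

    def __getitem__(self, ion: str) -> float:
        return self.concentrations.get(ion, 0.0)


# Salt groups as diluted in the experimental design.  The iron source
# (EDTA-chelated iron) is supplied at full strength in every medium and is
# never scaled.
MACRO_SALTS = ("KNO3", "NH4NO3", "CaCl2.2H2O", "MgSO4.7H2O", "KH2PO4")
MICRO_SALTS = (
    "MnSO4.4H2O",
    "ZnSO4.7H2O",
    "H3BO3",
    "KI",
    "Na2MoO4.2H2O",
    "CuSO4.5H2O",
    "CoCl2.6H2O",
)
IRON_SALTS = ("Na2EDTA", "FeSO4.7H2O")

# Canonical reporting order: macronutrient ions first, then micronutrients.
ION_ORDER = (
    "K+", "NO3-", "NH4+", "Ca2+", "Cl-", "Mg2+", "SO42-", "H2PO4-",
    "Mn2+", "Zn2+", "BO33-", "I-", "Na+", "MoO42-", "Cu2+", "Co2+",
    "Fe2+", "EDTA",
)

# Ions conventionally reported in uM rather than mM (micronutrient-derived).
MICRO_IONS = ("Mn2+", "Zn2+", "BO33-", "I-", "MoO42-", "Cu2+", "Co2+", "Fe2+")


def _data_path(name: str):
    return resources.files("nutrifuzz.data").joinpath(name)


def load_salt_registry(path=None) -> list[SaltDefinition]:
    """Read a salt registry (columns: salt, molar_mass, ions as ``ion:count;...``).

    With no ``path`` the packaged registry covering the MS salts is returned.
    """
    src = path if path is not None else _data_path("salt_registry.csv")
    df = pd.read_csv(src, dtype={"salt": str, "ions": str})
    registry = []
    for _, row in df.iterrows():
        ions = tuple(
            (part.split(":")[0], int(part.split(":")[1]))
            for part in row["ions"].split(";")
        )
        registry.append(SaltDefinition(row["salt"], float(row["molar_mass"]), ions))
    return registry


def load_ms_media(path=None) -> list[MediumFormulation]:
    """Read a media-definition table (columns: salt, then one column per medium).

    With no ``path`` the packaged table of the nine MS-based media (full MS,
    the macronutrient dilution series MSM and the micronutrient series MSμ)
    is returned, holding the published mg/L values.
    """
    src = path if path is not None else _data_path("media_table1.csv")
    df = pd.read_csv(src, index_col="salt")
    media = []
    for medium in df.columns:
        amounts = {salt: float(v) for salt, v in df[medium].items()}
        media.append(MediumFormulation(medium, amounts))
    return media


def _registry_map(registry: Sequence[SaltDefinition]) -> dict[str, SaltDefinition]:
    return {s.name: s for s in registry}


def ion_profile(medium: MediumFormulation, registry: Sequence[SaltDefinition]) -> IonProfile:
    """Convert a salt formulation to ion molar concentrations (mM).

    Each salt contributes ``(mg/L) / (g/mol) * stoichiometry`` mmol/L of each
    of its ions; contributions are summed over salts.  Ions contributed by no
    salt are simply absent (treated as zero by :meth:`IonProfile.__getitem__`).

    Raises
    ------
    UnresolvedSaltError
        If the medium lists a salt the registry does not define.
    """
    lookup = _registry_map(registry)
    conc: dict[str, float] = {}
    for salt, mg_per_l in medium.salt_amounts.items():
        if salt not in lookup:
            raise UnresolvedSaltError(f"unknown salt {salt!r} in medium {medium.name!r}")
        definition = lookup[salt]
        mmol = mg_per_l / definition.molar_mass
        for ion, count in definition.ions:
            conc[ion] = conc.get(ion, 0.0) + mmol * count
    ordered = {ion: conc[ion] for ion in ION_ORDER if ion in conc}
    for ion in conc:  # ions outside the canonical order, if any
        ordered.setdefault(ion, conc[ion])
    return IonProfile(ordered, medium.name)


def _fraction_label(factor: float) -> str:
    frac = Fraction(factor).limit_denominator(1000)
    if frac == 0:
        return "0"
    if frac == 1:
        return ""
    return f"{frac.numerator}/{frac.denominator}"


def dilution_series(
    base: MediumFormulation,
    group: str,
    factors: Sequence[float],
) -> list[MediumFormulation]:
    """Scale one salt group of ``base`` by each factor, leaving the rest intact.

    ``group`` is ``"macro"`` or ``"micro"``; the iron source and any other
    salts are never touched (they are supplied at the same concentration in
    every medium).  Media are named ``<fraction><base><M|μ>``, e.g. full MS
    with macronutrients halved becomes ``1/2MSM``.
    """
    groups = {"macro": (MACRO_SALTS, "M"), "micro": (MICRO_SALTS, "μ")}
    if group not in groups:
        raise ValueError(f"group must be 'macro' or 'micro', got {group!r}")
    salts, suffix = groups[group]
    media = []
    for factor in factors:
        if not 0 <= factor <= 1:
            raise ValueError(f"invalid dilution factor {factor!r}: must be in [0, 1]")
        name = f"{_fraction_label(factor)}{base.name}{suffix}"
        media.append(base.scaled(factor, salts=salts, name=name))
    return media


def variable_ions(
    media: Sequence[MediumFormulation],
    registry: Sequence[SaltDefinition],
    tol: float = 1e-12,
) -> list[str]:
    """Ions whose concentration differs across the media set.

    Species held constant in every medium (Fe2+ and EDTA from the iron
    source) are thereby excluded; on the nine MS-based media this leaves the
    16 ion inputs of the factorial design.
    """
    if not media:
        raise ValueError("media list must be non-empty")
    if len(media) < 2:
        return []
    profiles = [ion_profile(m, registry) for m in media]
    ions = {ion for p in profiles for ion in p.concentrations}
    varying = [
        ion
        for ion in ions
        if max(p[ion] for p in profiles) - min(p[ion] for p in profiles) > tol
    ]
    order = {ion: i for i, ion in enumerate(ION_ORDER)}
    return sorted(varying, key=lambda ion: (order.get(ion, len(order)), ion))


def build_factor_table(
    genotypes: Sequence[str],
    media: Sequence[MediumFormulation],
    subcultures: Sequence[int],
    registry: Sequence[SaltDefinition],
) -> pd.DataFrame:
    """Full factorial crossing of genotype x medium x subculture with ion columns.

    Returns one row per treatment: categorical columns ``genotype``,
    ``medium`` (provenance), ``subculture``, followed by one column per
    varying ion (mM).  Row count is the product of the level counts.
    """
    if not genotypes or not media or not subcultures:
        raise ValueError("genotypes, media and subcultures must be non-empty")
    names = [m.name for m in media]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate medium names in {names}")
    ions = variable_ions(media, registry) if len(media) > 1 else [
        ion for ion in ion_profile(media[0], registry).concentrations
    ]
    profiles = {m.name: ion_profile(m, registry) for m in media}
    rows = []
    for genotype, medium, subculture in itertools.product(genotypes, names, subcultures):
        row = {"genotype": genotype, "medium": medium, "subculture": subculture}
        row.update({ion: profiles[medium][ion] for ion in ions})
        rows.append(row)
    table = pd.DataFrame(rows)
    table["subculture"] = table["subculture"].astype(int)
    return table


def round_half_up(value: float, decimals: int) -> float:
    """Round with ties away from zero, as printed tables conventionally do."""
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))
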