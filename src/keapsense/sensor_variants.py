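"""Classification of KEAP1 sensor-residue variants and fail-safe combinatorics.

KEAP1 senses oxidative stress through four cysteines (Cys226, Cys613, Cys622,
Cys624) that form intramolecular disulfides, organised as three redundant
"parts": P1 = {226}, P2 = {613}, P3 = {622, 624}.  Any two intact parts can
still form a functional disulfide, so the sensor tolerates loss of any single
part — a fail-safe.  Electrophiles are sensed by a disjoint cysteine set
(Cys151, Cys273, Cys288) via C-S adduction, with inducer classes defined by
which of those residues a compound requires (Class I: 151; Class II: 288;
Class III: any of the three; Class IV: reactive oxygen species acting through
the oxidative set).

This module parses protein-level substitutions (HGVS p. notation), places them
on the sensor residue map, and evaluates the combinatorial consequence of a
set of lost residues for both sensor systems.
"""

from __future__ import annotations

import itertools
import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum

logger = logging.getLogger(__name__)

__all__ = [
    "SensorMap",
    "KeapVariant",
    "VariantCategory",
    "VariantClassification",
    "FailSafeState",
    "InducerClass",
    "VariantParseError",
    "parse_protein_variant",
    "classify_variant",
    "failsafe_oxidative",
    "electrophile_response",
    "count_by_category",
]

_AA3_TO_1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}
_AA1 = set(_AA3_TO_1.values())
_BASIC = {"H", "R", "K"}

_VARIANT_RE = re.compile(
    r"^(?:p\.)?(?P<ref>[A-Za-z]{1,3})(?P<pos>\d+)(?P<alt>[A-Za-z]{1,3})$"
)


class VariantParseError(ValueError):
    """Protein-change text that does not parse as a simple substitution."""


class VariantCategory(str, Enum):
    OXIDATIVE_SENSOR_CYS = "oxidative_sensor_cys"
    OXIDATIVE_NEIGHBOR_BASIC = "oxidative_neighbor_basic"
    ELECTROPHILE_SENSOR_CYS = "electrophile_sensor_cys"
    NON_SENSOR = "non_sensor"


class InducerClass(str, Enum):
    """NRF2-inducer classes by required sensor residue(s)."""

    I = "I"
    II = "II"
    III = "III"
    IV = "IV"


@dataclass(frozen=True)
class SensorMap:
    """Residue map of the KEAP1 stress-sensor systems.

    Defaults use the mouse-convention numbering the field applies to both
    mouse and human KEAP1; alternative tables (species offsets, extended
    neighbor windows) can be supplied without code change.
    """

    oxidative_cys: frozenset[int] = frozenset({226, 613, 622, 624})
    oxidative_neighbor_basic: dict[int, str] = field(
        default_factory=lambda: {225: "H", 614: "R"}
    )
    electrophile_cys: frozenset[int] = frozenset({151, 273, 288})
    parts: dict[str, frozenset[int]] = field(
        default_factory=lambda: {
            "P1": frozenset({226}),
            "P2": frozenset({613}),
            "P3": frozenset({622, 624}),
        }
    )

    def __post_init__(self) -> None:
        if self.oxidative_cys & self.electrophile_cys:
            raise ValueError("oxidative and electrophile cysteine sets must be disjoint")
        if any(not residues for residues in self.parts.values()):
            raise ValueError("every sensor part must contain at least one residue")


@dataclass(frozen=True)
class KeapVariant:
    """A protein-level amino-acid substitution, 1-letter codes internally."""

    position: int
    ref_aa: str
    alt_aa: str
    allele_freq_panels: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        for name in ("ref_aa", "alt_aa"):
            aa = getattr(self, name)
            if aa not in _AA1:
                raise ValueError(f"{name} {aa!r} is not a standard amino acid")
        if self.ref_aa == self.alt_aa:
            raise ValueError(f"synonymous change at {self.position}: ref == alt")


@dataclass(frozen=True)
class VariantClassification:
    category: VariantCategory
    destroys_thiol: bool
    destroys_basicity: bool


@dataclass(frozen=True)
class FailSafeState:
    """Combinatorial status of the oxidative sensor after residue loss."""

    lost_residues: frozenset[int]
    intact_parts: frozenset[str]
    viable_pairs: frozenset[tuple[str, str]]
    functional: bool


def _normalize_aa(token: str) -> str:
    if len(token) == 1 and token.upper() in _AA1:
        return token.upper()
    if len(token) == 3 and token.capitalize() in _AA3_TO_1:
        return _AA3_TO_1[token.capitalize()]
    raise VariantParseError(f"unknown amino-acid code {token!r}")


def parse_protein_variant(text: str) -> KeapVariant:
    """Parse a protein change like ``Cys622Ser``, ``p.C622S`` or ``His225Tyr``.

    Accepts an optional ``p.`` prefix and either 1- or 3-letter amino-acid
    codes (mixed is allowed); normalizes to 1-letter codes.
    """
    m = _VARIANT_RE.match(text.strip())
    if m is None:
        raise VariantParseError(f"cannot parse protein change {text!r}")
    ref = _normalize_aa(m.group("ref"))
    alt = _normalize_aa(m.group("alt"))
    if ref == alt:
        raise VariantParseError(f"synonymous change {text!r}: ref equals alt")
    return KeapVariant(position=int(m.group("pos")), ref_aa=ref, alt_aa=alt)


def classify_variant(
    variant: KeapVariant, sensor_map: SensorMap | None = None
) -> VariantClassification:
    """Place a substitution on the sensor residue map.

    ``destroys_thiol`` flags Cys residues replaced by a non-thiol amino acid
    (which abolishes disulfide/adduct formation at that position);
    ``destroys_basicity`` flags basic residues replaced by non-basic ones
    (which diminishes the reactivity of the adjacent sensor cysteine).
    A ref amino acid that disagrees with the map's expectation is classified
    non_sensor with a warning, tolerating annotation drift across transcripts.
    """
    smap = sensor_map or SensorMap()
    pos, ref, alt = variant.position, variant.ref_aa, variant.alt_aa
    destroys_thiol = ref == "C" and alt != "C"
    destroys_basicity = ref in _BASIC and alt not in _BASIC

    if pos in smap.oxidative_cys or pos in smap.electrophile_cys:
        if ref != "C":
            logger.warning(
                "position %d is a mapped sensor cysteine but ref is %s; "
                "classifying as non_sensor", pos, ref,
            )
            return VariantClassification(
                VariantCategory.NON_SENSOR, destroys_thiol, destroys_basicity
            )
        category = (
            VariantCategory.OXIDATIVE_SENSOR_CYS
            if pos in smap.oxidative_cys
            else VariantCategory.ELECTROPHILE_SENSOR_CYS
        )
        return VariantClassification(category, destroys_thiol, destroys_basicity)

    if pos in smap.oxidative_neighbor_basic:
        if ref != smap.oxidative_neighbor_basic[pos]:
            logger.warning(
                "position %d expected %s but ref is %s; classifying as non_sensor",
                pos, smap.oxidative_neighbor_basic[pos], ref,
            )
            return VariantClassification(
                VariantCategory.NON_SENSOR, destroys_thiol, destroys_basicity
            )
        return VariantClassification(
            VariantCategory.OXIDATIVE_NEIGHBOR_BASIC, destroys_thiol, destroys_basicity
        )

    return VariantClassification(
        VariantCategory.NON_SENSOR, destroys_thiol, destroys_basicity
    )


def failsafe_oxidative(
    lost_residues: set[int] | frozenset[int], sensor_map: SensorMap | None = None
) -> FailSafeState:
    """Evaluate the oxidative sensor's redundancy after losing residues.

    A part stays intact while at least one of its cysteines survives (P3 needs
    only one of 622/624).  The sensor is functional while at least one pair of
    intact parts remains to form the disulfide.  Residues outside the oxidative
    set are ignored with a warning.
    """
    smap = sensor_map or SensorMap()
    lost = frozenset(lost_residues)
    foreign = lost - smap.oxidative_cys
    if foreign:
        logger.warning(
            "ignoring non-oxidative-sensor residues in loss set: %s",
            sorted(foreign),
        )
        lost = lost & smap.oxidative_cys
    intact = frozenset(
        name for name, residues in smap.parts.items() if residues - lost
    )
    viable = frozenset(
        pair for pair in itertools.combinations(sorted(intact), 2)
    )
    return FailSafeState(
        lost_residues=lost,
        intact_parts=intact,
        viable_pairs=viable,
        functional=bool(viable),
    )


def electrophile_response(
    inducer_class: InducerClass | str,
    lost_residues: set[int] | frozenset[int],
    sensor_map: SensorMap | None = None,
) -> bool:
    """Whether KEAP1 lacking ``lost_residues`` still responds to an inducer class.

    Class I compounds (e.g. sulforaphane, CDDO-Im) require Cys151; Class II
    (15d-PGJ2) requires Cys288; Class III compounds react with any of
    Cys151/273/288; Class IV (reactive oxygen species) acts through the
    oxidative fail-safe sensor.
    """
    smap = sensor_map or SensorMap()
    cls = InducerClass(inducer_class)
    lost = frozenset(lost_residues)
    if cls is InducerClass.I:
        return 151 not in lost
    if cls is InducerClass.II:
        return 288 not in lost
    if cls is InducerClass.III:
        return not smap.electrophile_cys <= lost
    return failsafe_oxidative(lost, smap).functional


def count_by_category(
    variants: list[KeapVariant], sensor_map: SensorMap | None = None
) -> dict[VariantCategory, int]:
    """Tally classifications over a variant list; all categories reported.

    The oxidative-affecting total used in screening reports is the sum of the
    sensor-cysteine and neighbor-basic counts.
    """
    smap = sensor_map or SensorMap()
    counts: Counter[VariantCategory] = Counter(
        classify_variant(v, smap).category for v in variants
    )
    return {cat: counts.get(cat, 0) for cat in VariantCategory}
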