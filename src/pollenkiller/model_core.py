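"""Domain types and transmission rules for sporophytically gated pollen killers.

A killer locus acts gametophytically: in a heterozygous plant it aborts
pollen grains carrying the targeted allele, so the opposite allele is
transmitted through the male side at frequency ``k = 1/(1 + s) > 0.5``,
where ``s`` is the survival probability of a targeted pollen grain.
Whether the killer acts at all is decided by the diploid (sporophyte)
genotype at an unlinked partner locus: either an *activator* (one copy of
the donor allele switches the killer on) or a *suppressor* (one copy of
the donor allele switches it off).  Female transmission is always
Mendelian.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Union

__all__ = [
    "ALLELES",
    "ContractError",
    "MissingLocusError",
    "Role",
    "PartnerMode",
    "GenotypeCode",
    "LocusDef",
    "KillerSystem",
    "SporophyteGenotype",
    "GameteDistribution",
    "k_from_s",
    "s_from_k",
    "killer_is_active",
    "male_gamete_distribution",
    "female_gamete_distribution",
]

#: Allele symbols: ``I`` = donor (distorter-carrying) parent, ``J`` = recurrent parent.
ALLELES = ("I", "J")

_PROB_TOL = 1e-12


class ContractError(ValueError):
    """A model-level precondition was violated."""


class MissingLocusError(ContractError):
    """A sporophyte genotype does not cover a locus required by a system."""

    def __init__(self, locus_name: str):
        super().__init__(f"sporophyte genotype has no entry for locus {locus_name!r}")
        self.locus_name = locus_name


class Role(str, enum.Enum):
    KILLER = "killer"
    PARTNER = "partner"
    NEUTRAL_MARKER = "neutral_marker"


class PartnerMode(str, enum.Enum):
    ACTIVATOR = "activator"
    SUPPRESSOR = "suppressor"


class GenotypeCode(str, enum.Enum):
    """Diploid genotype at one locus. ``NA`` is legal only in observed tables."""

    II = "II"
    H = "H"
    JJ = "JJ"
    NA = "NA"

    @classmethod
    def coerce(cls, value: Union["GenotypeCode", str]) -> "GenotypeCode":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value))
        except ValueError:
            raise ContractError(
                f"unknown genotype code {value!r}; expected one of II, H, JJ, NA"
            ) from None


@dataclass(frozen=True)
class LocusDef:
    """A named position on a chromosome with a functional role."""

    name: str
    chrom: str
    pos_bp: int
    role: Role = Role.NEUTRAL_MARKER

    def __post_init__(self) -> None:
        if not self.name:
            raise ContractError("locus name must be non-empty")
        if int(self.pos_bp) <= 0:
            raise ContractError(f"locus {self.name!r}: pos_bp must be > 0, got {self.pos_bp}")
        object.__setattr__(self, "pos_bp", int(self.pos_bp))
        object.__setattr__(self, "role", Role(self.role))


def k_from_s(s: float) -> float:
    """Transmission frequency of the non-targeted allele given targeted survival s."""
    if not 0.0 <= s <= 1.0:
        raise ContractError(f"survival s must lie in [0, 1], got {s}")
    return 1.0 / (1.0 + s)


def s_from_k(k: float) -> float:
    """Inverse of :func:`k_from_s`; k must lie in [0.5, 1]."""
    if not 0.5 <= k <= 1.0:
        raise ContractError(f"transmission parameter k must lie in [0.5, 1], got {k}")
    return 1.0 / k - 1.0


@dataclass(frozen=True)
class KillerSystem:
    """One gametophytic killer locus gated by one sporophytic partner locus.

    ``survival_s`` is the probability that a male gamete carrying
    ``targeted_allele`` survives when the system is active; ``collateral_c``
    is the death rate of non-targeted pollen (affects visible fertility
    only, never transmission ratios).  Killing is male-limited.
    """

    killer: LocusDef
    partner: LocusDef
    partner_mode: PartnerMode
    targeted_allele: str = "J"
    survival_s: float = 0.0
    collateral_c: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "partner_mode", PartnerMode(self.partner_mode))
        if self.targeted_allele not in ALLELES:
            raise ContractError(
                f"targeted_allele must be one of {ALLELES}, got {self.targeted_allele!r}"
            )
        if not 0.0 <= self.survival_s <= 1.0:
            raise ContractError(f"survival_s must lie in [0, 1], got {self.survival_s}")
        if not 0.0 <= self.collateral_c <= 1.0:
            raise ContractError(f"collateral_c must lie in [0, 1], got {self.collateral_c}")
        if self.killer.name == self.partner.name:
            raise ContractError("killer and partner must be distinct loci")

    @property
    def k(self) -> float:
        """Transmission frequency of the favored allele when active."""
        return k_from_s(self.survival_s)

    @property
    def favored_allele(self) -> str:
        return "I" if self.targeted_allele == "J" else "J"

    @property
    def name(self) -> str:
        return f"{self.partner.name}-{self.killer.name}"


def _locus_name(locus: Union[LocusDef, str]) -> str:
    return locus.name if isinstance(locus, LocusDef) else str(locus)


class SporophyteGenotype:
    """Diploid multilocus genotype of a parent plant, keyed by locus name.

    ``NA`` codes are rejected: a model input must be fully genotyped.
    """

    def __init__(self, genotypes: Mapping[Union[LocusDef, str], Union[GenotypeCode, str]]):
        table = {}
        for locus, code in genotypes.items():
            name = _locus_name(locus)
            g = GenotypeCode.coerce(code)
            if g is GenotypeCode.NA:
                raise ContractError(f"locus {name!r}: NA not permitted in a sporophyte genotype")
            table[name] = g
        self._table = table

    def of(self, locus: Union[LocusDef, str]) -> GenotypeCode:
        name = _locus_name(locus)
        try:
            return self._table[name]
        except KeyError:
            raise MissingLocusError(name) from None

    @property
    def loci(self) -> tuple:
        return tuple(self._table)

    def __contains__(self, locus: object) -> bool:
        return _locus_name(locus) in self._table  # type: ignore[arg-type]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SporophyteGenotype) and self._table == other._table

    def __repr__(self) -> str:
        inner = ", ".join(f"{k}={v.value}" for k, v in self._table.items())
        return f"SporophyteGenotype({inner})"


@dataclass(frozen=True)
class GameteDistribution:
    """Per-allele transmission probabilities from one sporophyte at one locus."""

    probs: Mapping[str, float]
    sex: str

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ContractError(f"sex must be 'male' or 'female', got {self.sex!r}")
        probs = dict(self.probs)
        total = sum(probs.values())
        if any(p < 0 for p in probs.values()):
            raise ContractError(f"negative probability in {probs}")
        if abs(total - 1.0) > _PROB_TOL:
            raise ContractError(f"probabilities sum to {total}, not 1")
        object.__setattr__(self, "probs", probs)

    def p(self, allele: str) -> float:
        return self.probs.get(allele, 0.0)


def killer_is_active(system: KillerSystem, sporophyte: SporophyteGenotype) -> bool:
    """Decide whether ``system`` kills pollen in this plant.

    The killer locus must be heterozygous (a homozygote has no
    targeted-vs-nontargeted contrast among its gametes).  An activator
    partner must carry at least one donor allele; a suppressor partner
    must carry none (donor partner alleles are fully dominant).
    """
    killer_g = sporophyte.of(system.killer)
    partner_g = sporophyte.of(system.partner)
    if killer_g is not GenotypeCode.H:
        return False
    if system.partner_mode is PartnerMode.ACTIVATOR:
        return partner_g in (GenotypeCode.H, GenotypeCode.II)
    return partner_g is GenotypeCode.JJ


_HOMOZYGOUS_ALLELE = {GenotypeCode.II: "I", GenotypeCode.JJ: "J"}


def male_gamete_distribution(
    sporophyte: SporophyteGenotype,
    systems: Iterable[KillerSystem],
    locus: Union[LocusDef, str],
) -> GameteDistribution:
    """Allele transmission probabilities through pollen at ``locus``.

    A heterozygote emits ``I`` and ``J`` gametes in equal numbers; every
    active system whose killer locus is ``locus`` then multiplies the
    targeted class by its survival probability, and the result is
    renormalized over surviving pollen.  With one active system this gives
    P(targeted) = s/(1+s) and P(favored) = 1/(1+s) = k.
    """
    g = sporophyte.of(locus)
    if g is not GenotypeCode.H:
        return GameteDistribution({_HOMOZYGOUS_ALLELE[g]: 1.0}, sex="male")
    name = _locus_name(locus)
    weights = {a: 0.5 for a in ALLELES}
    for system in systems:
        if system.killer.name == name and killer_is_active(system, sporophyte):
            weights[system.targeted_allele] *= system.survival_s
    total = sum(weights.values())
    if total == 0.0:
        raise ContractError(
            f"no surviving male gamete at locus {name!r}: all alleles targeted with s=0"
        )
    return GameteDistribution({a: w / total for a, w in weights.items()}, sex="male")


def female_gamete_distribution(
    sporophyte: SporophyteGenotype, locus: Union[LocusDef, str]
) -> GameteDistribution:
    """Egg-side transmission: always Mendelian (killing is male-limited)."""
    g = sporophyte.of(locus)
    if g is GenotypeCode.H:
        return GameteDistribution({a: 0.5 for a in ALLELES}, sex="female")
    return GameteDistribution({_HOMOZYGOUS_ALLELE[g]: 1.0}, sex="female")
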