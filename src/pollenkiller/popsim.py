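"""Forward Monte-Carlo simulation of multilocus crosses under pollen killers.

Haplotypes are int8 vectors over the loci of a :class:`GeneticMap`
(0 = donor allele ``I``, 1 = recurrent allele ``J``).  Meioses use one
crossover draw per adjacent interval with Haldane map-function
probabilities; loci on different chromosomes recombine freely.  Killer
selection is implemented as rejection sampling on candidate male gametes —
activation is evaluated on the diploid parent (sporophyte), the kill on the
gamete's own allele — so the realized transmission converges to the
analytic k = 1/(1+s) of :mod:`pollenkiller.segregation`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .model_core import ContractError, KillerSystem, LocusDef, PartnerMode, SporophyteGenotype

__all__ = [
    "I_ALLELE",
    "J_ALLELE",
    "haldane",
    "GeneticMapEntry",
    "GeneticMap",
    "Individual",
    "CrossDesign",
    "AssociationResult",
    "founder_pair",
    "homozygous_line",
    "f1_hybrid",
    "make_gamete",
    "make_gametes",
    "simulate_population",
    "two_locus_association",
]

I_ALLELE = np.int8(0)
J_ALLELE = np.int8(1)
_ALLELE_CODE = {"I": I_ALLELE, "J": J_ALLELE}

_DESIGNS = ("F2", "testcross", "backcross", "SSD_RI")
_MAX_REJECTION_ROUNDS = 10_000


def haldane(d_cM: float) -> float:
    """Recombination fraction for a map distance in centimorgans (no interference)."""
    if d_cM < 0:
        raise ContractError(f"map distance must be >= 0, got {d_cM}")
    return 0.5 * (1.0 - math.exp(-2.0 * d_cM / 100.0))


@dataclass(frozen=True)
class GeneticMapEntry:
    locus: LocusDef
    cM: float

    def __post_init__(self) -> None:
        if self.cM < 0:
            raise ContractError(f"cM position must be >= 0, got {self.cM} at {self.locus.name}")


class GeneticMap:
    """Ordered loci with genetic positions; ordering is (chromosome, cM)."""

    def __init__(self, entries: Iterable[GeneticMapEntry]):
        entries = sorted(entries, key=lambda e: (e.locus.chrom, e.cM, e.locus.name))
        if not entries:
            raise ContractError("a genetic map needs at least one locus")
        names = [e.locus.name for e in entries]
        if len(set(names)) != len(names):
            raise ContractError("locus names in a map must be unique")
        self.entries: Tuple[GeneticMapEntry, ...] = tuple(entries)
        self.names: Tuple[str, ...] = tuple(names)
        self._index = {n: i for i, n in enumerate(names)}
        # r[0] = 0.5 randomizes the starting haplotype of each meiosis;
        # chromosome boundaries also recombine freely.
        r = [0.5]
        for prev, cur in zip(self.entries, self.entries[1:]):
            if prev.locus.chrom != cur.locus.chrom:
                r.append(0.5)
            else:
                r.append(haldane(cur.cM - prev.cM))
        self.recomb = np.asarray(r, dtype=float)

    @classmethod
    def from_loci(cls, loci: Sequence[LocusDef], cM: dict) -> "GeneticMap":
        missing = [l.name for l in loci if l.name not in cM]
        if missing:
            raise ContractError(f"no cM position for loci: {', '.join(missing)}")
        return cls(GeneticMapEntry(l, float(cM[l.name])) for l in loci)

    def index(self, locus: Union[LocusDef, str]) -> int:
        name = locus.name if isinstance(locus, LocusDef) else str(locus)
        try:
            return self._index[name]
        except KeyError:
            raise ContractError(f"locus {name!r} is not on the map") from None

    @property
    def loci(self) -> Tuple[LocusDef, ...]:
        return tuple(e.locus for e in self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, locus: object) -> bool:
        name = locus.name if isinstance(locus, LocusDef) else str(locus)
        return name in self._index


@dataclass
class Individual:
    """One diploid plant: two haplotypes over a map's loci (0 = I, 1 = J)."""

    hap_a: np.ndarray
    hap_b: np.ndarray

    def __post_init__(self) -> None:
        self.hap_a = np.asarray(self.hap_a, dtype=np.int8)
        self.hap_b = np.asarray(self.hap_b, dtype=np.int8)
        if self.hap_a.shape != self.hap_b.shape or self.hap_a.ndim != 1:
            raise ContractError("haplotypes must be 1-D arrays of equal length")
        for hap in (self.hap_a, self.hap_b):
            if not np.isin(hap, (0, 1)).all():
                raise ContractError("haplotype alleles must be 0 (I) or 1 (J)")

    def to_sporophyte(self, gmap: GeneticMap) -> SporophyteGenotype:
        codes = {}
        for i, name in enumerate(gmap.names):
            a, b = int(self.hap_a[i]), int(self.hap_b[i])
            codes[name] = "II" if a + b == 0 else ("JJ" if a + b == 2 else "H")
        return SporophyteGenotype(codes)


@dataclass(frozen=True)
class CrossDesign:
    """Breeding scheme parameters; ``generations`` applies to SSD_RI only."""

    type: str
    n_offspring: int
    generations: int = 1
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.type not in _DESIGNS:
            raise ContractError(f"design type must be one of {_DESIGNS}, got {self.type!r}")
        if self.n_offspring <= 0:
            raise ContractError(f"n_offspring must be positive, got {self.n_offspring}")
        if self.type == "SSD_RI" and self.generations < 1:
            raise ContractError("SSD_RI requires generations >= 1")


def founder_pair(gmap: GeneticMap) -> Tuple[Individual, Individual]:
    """Fully homozygous donor (all-I) and recurrent (all-J) founders."""
    n = len(gmap)
    return (
        Individual(np.zeros(n, dtype=np.int8), np.zeros(n, dtype=np.int8)),
        Individual(np.ones(n, dtype=np.int8), np.ones(n, dtype=np.int8)),
    )


def homozygous_line(gmap: GeneticMap, alleles: dict) -> Individual:
    """A fully homozygous line with the given allele ('I' or 'J') per locus name.

    Useful for NIL-style founders that differ from their cross partner at a
    subset of loci only (e.g. a killer heterozygote in a fixed-activator
    background).
    """
    hap = np.empty(len(gmap), dtype=np.int8)
    for i, name in enumerate(gmap.names):
        try:
            hap[i] = _ALLELE_CODE[alleles[name]]
        except KeyError:
            raise ContractError(f"no allele ('I' or 'J') given for locus {name!r}") from None
    return Individual(hap, hap.copy())


def f1_hybrid(gmap: GeneticMap) -> Individual:
    n = len(gmap)
    return Individual(np.zeros(n, dtype=np.int8), np.ones(n, dtype=np.int8))


def _meiosis(hap_a: np.ndarray, hap_b: np.ndarray, recomb: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete per row of the (n, L) parental haplotype arrays."""
    switch = rng.random(hap_a.shape) < recomb
    use_b = np.logical_xor.accumulate(switch, axis=1)
    return np.where(use_b, hap_b, hap_a)


def _activation_matrix(
    hap_a: np.ndarray, hap_b: np.ndarray, gmap: GeneticMap, systems: Sequence[KillerSystem]
) -> np.ndarray:
    """(n, n_systems) bool: is each system active in each parent plant."""
    n = hap_a.shape[0]
    active = np.zeros((n, len(systems)), dtype=bool)
    for j, system in enumerate(systems):
        ki = gmap.index(system.killer)
        pi = gmap.index(system.partner)
        killer_het = hap_a[:, ki] != hap_b[:, ki]
        has_donor = (hap_a[:, pi] == I_ALLELE) | (hap_b[:, pi] == I_ALLELE)
        if system.partner_mode is PartnerMode.ACTIVATOR:
            active[:, j] = killer_het & has_donor
        else:
            active[:, j] = killer_het & ~has_donor
    return active


def _survival(
    gametes: np.ndarray, active: np.ndarray, gmap: GeneticMap, systems: Sequence[KillerSystem]
) -> np.ndarray:
    """Per-gamete survival probability under all active systems of its parent."""
    surv = np.ones(gametes.shape[0])
    for j, system in enumerate(systems):
        ki = gmap.index(system.killer)
        hit = active[:, j] & (gametes[:, ki] == _ALLELE_CODE[system.targeted_allele])
        surv[hit] *= system.survival_s
    return surv


def _gamete_batch(
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    gmap: GeneticMap,
    systems: Sequence[KillerSystem],
    sex: str,
    rng: np.random.Generator,
) -> np.ndarray:
    if sex not in ("male", "female"):
        raise ContractError(f"sex must be 'male' or 'female', got {sex!r}")
    gametes = _meiosis(hap_a, hap_b, gmap.recomb, rng)
    if sex == "female" or not systems:
        return gametes
    active = _activation_matrix(hap_a, hap_b, gmap, systems)
    if not active.any():
        return gametes
    pending = rng.random(gametes.shape[0]) >= _survival(gametes, active, gmap, systems)
    rounds = 0
    while pending.any():
        rounds += 1
        if rounds > _MAX_REJECTION_ROUNDS:
            raise ContractError(
                "no surviving male gamete after bounded retries; "
                "check survival parameters and parental genotypes"
            )
        idx = np.nonzero(pending)[0]
        redraw = _meiosis(hap_a[idx], hap_b[idx], gmap.recomb, rng)
        gametes[idx] = redraw
        ok = rng.random(idx.size) < _survival(redraw, active[idx], gmap, systems)
        pending[idx[ok]] = False
    return gametes


def make_gametes(
    parent: Individual,
    gmap: GeneticMap,
    systems: Sequence[KillerSystem],
    sex: str,
    rng: np.random.Generator,
    n: int = 1,
) -> np.ndarray:
    """Draw ``n`` surviving gametes from one parent; returns an (n, L) array."""
    if n <= 0:
        raise ContractError(f"n must be positive, got {n}")
    if parent.hap_a.size != len(gmap):
        raise ContractError("parent haplotype length does not match the map")
    hap_a = np.broadcast_to(parent.hap_a, (n, parent.hap_a.size)).copy()
    hap_b = np.broadcast_to(parent.hap_b, (n, parent.hap_b.size)).copy()
    return _gamete_batch(hap_a, hap_b, gmap, systems, sex, rng)


def make_gamete(
    parent: Individual,
    gmap: GeneticMap,
    systems: Sequence[KillerSystem],
    sex: str,
    rng: np.random.Generator,
) -> np.ndarray:
    return make_gametes(parent, gmap, systems, sex, rng, n=1)[0]


def _codes_frame(hap_a: np.ndarray, hap_b: np.ndarray, gmap: GeneticMap) -> pd.DataFrame:
    total = hap_a.astype(np.int16) + hap_b.astype(np.int16)
    codes = np.where(total == 0, "II", np.where(total == 2, "JJ", "H"))
    ids = [f"L{i + 1:05d}" for i in range(hap_a.shape[0])]
    df = pd.DataFrame(codes, columns=list(gmap.names), index=pd.Index(ids, name="sample_id"))
    return df


def _tiled(ind: Individual, n: int) -> Tuple[np.ndarray, np.ndarray]:
    return (
        np.broadcast_to(ind.hap_a, (n, ind.hap_a.size)).copy(),
        np.broadcast_to(ind.hap_b, (n, ind.hap_b.size)).copy(),
    )


def simulate_population(
    founders: Tuple[Individual, Individual],
    design: CrossDesign,
    gmap: GeneticMap,
    systems: Sequence[KillerSystem],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate one population and return its genotype table (samples x markers).

    ``founders`` is a (donor line, recurrent line) pair; each must be fully
    homozygous, since every design starts from their F1.  The founders need
    not be opposite at every locus: NIL-style founders that differ only at
    a killer locus model a segregating killer in a fixed background.
    Designs: ``F2`` (F1 selfed), ``testcross`` (recurrent female x F1 male),
    ``backcross`` (F1 female x recurrent male; Mendelian by construction),
    and ``SSD_RI`` (one offspring per line per selfing generation).
    """
    donor, recurrent = founders
    for ind in (donor, recurrent):
        if ind.hap_a.size != len(gmap):
            raise ContractError("founder haplotype length does not match the map")
        if not (ind.hap_a == ind.hap_b).all():
            raise ContractError("founders must be fully homozygous")
    if (donor.hap_a == recurrent.hap_a).all():
        raise ContractError("founders are identical: their F1 segregates at no locus")
    n = design.n_offspring
    f1 = Individual(donor.hap_a.copy(), recurrent.hap_a.copy())
    if design.type == "F2":
        a, b = _tiled(f1, n)
        eggs = _gamete_batch(a, b, gmap, systems, "female", rng)
        sperm = _gamete_batch(a, b, gmap, systems, "male", rng)
        return _codes_frame(eggs, sperm, gmap)
    if design.type == "testcross":
        a, b = _tiled(f1, n)
        eggs, _ = _tiled(recurrent, n)
        sperm = _gamete_batch(a, b, gmap, systems, "male", rng)
        return _codes_frame(eggs, sperm, gmap)
    if design.type == "backcross":
        a, b = _tiled(f1, n)
        eggs = _gamete_batch(a, b, gmap, systems, "female", rng)
        sperm, _ = _tiled(recurrent, n)
        return _codes_frame(eggs, sperm, gmap)
    # SSD_RI: each of n lines propagated by selfing, one seed per generation.
    a, b = _tiled(f1, n)
    for _ in range(design.generations):
        eggs = _gamete_batch(a, b, gmap, systems, "female", rng)
        sperm = _gamete_batch(a, b, gmap, systems, "male", rng)
        a, b = eggs, sperm
    return _codes_frame(a, b, gmap)


@dataclass(frozen=True)
class AssociationResult:
    """Parental-excess statistic over two-locus homozygous classes."""

    statistic: float
    n_parental: int
    n_recombinant: int
    chi2: float
    p_value: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.statistic <= 1.0:
            raise ContractError("parental-excess statistic must lie in [-1, 1]")


def two_locus_association(
    table: pd.DataFrame, locus_a: Union[LocusDef, str], locus_b: Union[LocusDef, str]
) -> AssociationResult:
    """Quantify pseudo-linkage between two loci from a genotype table.

    Uses only lines homozygous at both loci.  Parental classes are (II, II)
    and (JJ, JJ); recombinant classes are (II, JJ) and (JJ, II).  The
    statistic is (n_parental - n_recombinant) / (n_parental + n_recombinant),
    so 0 means free recombination and 1 perfect co-inheritance; a chi-square
    test of independence on the 2x2 homozygous table is attached (NaN when a
    margin is empty).
    """
    name_a = locus_a.name if isinstance(locus_a, LocusDef) else str(locus_a)
    name_b = locus_b.name if isinstance(locus_b, LocusDef) else str(locus_b)
    for name in (name_a, name_b):
        if name not in table.columns:
            raise ContractError(f"locus {name!r} not present in the genotype table")
    ga = table[name_a]
    gb = table[name_b]
    hom = ga.isin(("II", "JJ")) & gb.isin(("II", "JJ"))
    if int(hom.sum()) < 2:
        raise ContractError("fewer than 2 lines homozygous at both loci")
    a_ii = (ga[hom] == "II").to_numpy()
    b_ii = (gb[hom] == "II").to_numpy()
    n_pp = int((a_ii & b_ii).sum())
    n_qq = int((~a_ii & ~b_ii).sum())
    n_pq = int((a_ii & ~b_ii).sum())
    n_qp = int((~a_ii & b_ii).sum())
    n_par = n_pp + n_qq
    n_rec = n_pq + n_qp
    statistic = (n_par - n_rec) / (n_par + n_rec)
    contingency = np.array([[n_pp, n_pq], [n_qp, n_qq]])
    if (contingency.sum(axis=0) == 0).any() or (contingency.sum(axis=1) == 0).any():
        chi2, p_value = float("nan"), float("nan")
    else:
        chi2, p_value, _, _ = stats.chi2_contingency(contingency, correction=False)
    return AssociationResult(
        statistic=statistic,
        n_parental=n_par,
        n_recombinant=n_rec,
        chi2=float(chi2),
        p_value=float(p_value),
    )
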