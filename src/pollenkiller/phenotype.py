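"""Pollen-fertility prediction, classification, and observation modeling."""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .model_core import ContractError, KillerSystem, SporophyteGenotype, killer_is_active

__all__ = [
    "FertilityClass",
    "PollenObservation",
    "ObservationModel",
    "DEFAULT_CLASS_BOUNDS",
    "predict_fertility",
    "classify_fertility",
    "sample_pollen_counts",
    "seed_set_rate",
]


class FertilityClass(str, enum.Enum):
    STERILE = "sterile"
    SEMISTERILE = "semisterile"
    PARTIAL_STERILE = "partial_sterile"
    FERTILE = "fertile"


#: Upper-open boundaries (%) between sterile/semisterile/partial_sterile/fertile.
#: The upper class owns each boundary: 40 -> semisterile, 70 -> partial, 90 -> fertile.
DEFAULT_CLASS_BOUNDS: Tuple[float, float, float] = (40.0, 70.0, 90.0)


@dataclass(frozen=True)
class PollenObservation:
    """Stained/unstained pollen counts for one plant."""

    n_scored: int
    n_stained: int

    def __post_init__(self) -> None:
        if self.n_scored <= 0:
            raise ContractError(f"n_scored must be positive, got {self.n_scored}")
        if not 0 <= self.n_stained <= self.n_scored:
            raise ContractError(
                f"n_stained must lie in [0, {self.n_scored}], got {self.n_stained}"
            )

    @property
    def fertility_pct(self) -> float:
        return 100.0 * self.n_stained / self.n_scored


@dataclass(frozen=True)
class ObservationModel:
    """Staining observation model.

    ``gamma`` is the probability that an aborted grain is misscored as
    fertile (arrested-but-filled grains stain); ``baseline_f0`` is the
    fertility of a fully fertile plant.  The defaults are illustrative.
    """

    gamma: float = 0.2
    baseline_f0: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ContractError(f"gamma must lie in [0, 1], got {self.gamma}")
        if not 0.0 <= self.baseline_f0 <= 1.0:
            raise ContractError(f"baseline_f0 must lie in [0, 1], got {self.baseline_f0}")


_IDENTITY_OBS = ObservationModel(gamma=0.0, baseline_f0=1.0)


def predict_fertility(
    sporophyte: SporophyteGenotype,
    systems: Sequence[KillerSystem],
    obs_model: Optional[ObservationModel] = None,
) -> Tuple[float, float]:
    """Predict (true, observed) surviving-pollen fractions for one plant.

    Half of the pollen carries non-targeted alleles and suffers only
    collateral damage; the targeted half must survive every active system:

        core = 1/2 * prod(1 - c_m) + 1/2 * prod(s_m)   over active systems m

    (empty products are 1, so a plant with no active system has core 1).
    The observed fraction inflates the dead class by gamma misscoring,
    and both fractions are scaled by the fertile baseline f0.  With
    ``obs_model=None`` the observation is the identity (gamma 0, f0 1).
    """
    om = obs_model if obs_model is not None else _IDENTITY_OBS
    active = [s for s in systems if killer_is_active(s, sporophyte)]
    survive_nontargeted = math.prod(1.0 - s.collateral_c for s in active)
    survive_targeted = math.prod(s.survival_s for s in active)
    core = 0.5 * survive_nontargeted + 0.5 * survive_targeted
    true_fraction = om.baseline_f0 * core
    observed_fraction = om.baseline_f0 * (core + om.gamma * (1.0 - core))
    return (true_fraction, observed_fraction)


def classify_fertility(
    pct: float, bounds: Tuple[float, float, float] = DEFAULT_CLASS_BOUNDS
) -> FertilityClass:
    """Map a pollen-fertility percentage to its class.

    Intervals are half-open with the upper class owning each boundary:
    [0, b1) sterile, [b1, b2) semisterile, [b2, b3) partial_sterile,
    [b3, 100] fertile.
    """
    if not 0.0 <= pct <= 100.0:
        raise ContractError(f"fertility percentage must lie in [0, 100], got {pct}")
    b1, b2, b3 = bounds
    if not 0.0 < b1 < b2 < b3 <= 100.0:
        raise ContractError(f"class boundaries must be increasing within (0, 100], got {bounds}")
    if pct < b1:
        return FertilityClass.STERILE
    if pct < b2:
        return FertilityClass.SEMISTERILE
    if pct < b3:
        return FertilityClass.PARTIAL_STERILE
    return FertilityClass.FERTILE


def sample_pollen_counts(
    true_fraction: float,
    obs_model: ObservationModel,
    n_scored: int,
    rng: np.random.Generator,
) -> PollenObservation:
    """Draw a stained-pollen count: binomial at the misscoring-inflated fraction."""
    if not 0.0 <= true_fraction <= 1.0:
        raise ContractError(f"true_fraction must lie in [0, 1], got {true_fraction}")
    if n_scored <= 0:
        raise ContractError(f"n_scored must be positive, got {n_scored}")
    observed_fraction = true_fraction + obs_model.gamma * (1.0 - true_fraction)
    n_stained = int(rng.binomial(n_scored, observed_fraction))
    return PollenObservation(n_scored=n_scored, n_stained=n_stained)


def seed_set_rate(n_filled: int, n_unfilled: int) -> float:
    """Filled grains over all grains."""
    if n_filled < 0 or n_unfilled < 0:
        raise ContractError("grain counts must be non-negative")
    total = n_filled + n_unfilled
    if total == 0:
        raise ContractError("total grain count must be positive")
    return n_filled / total
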