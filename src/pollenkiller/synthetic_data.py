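"""Seeded generators for every fixture the analysis modules consume."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .finemap import RecombinantLine, RecombinantPanel, resolve_carrier_rule
from .model_core import ContractError, KillerSystem, LocusDef
from .phenotype import ObservationModel
from .segregation import CountData, selfing_freq

__all__ = [
    "SimConfig",
    "gen_testcross_counts",
    "gen_selfed_table",
    "gen_recombinant_panel",
]

_CODES = ("II", "H", "JJ")


def _rng(seed: Union[int, np.random.Generator]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    if seed is None:
        raise ContractError("a seed is mandatory for every generator")
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class SimConfig:
    """Bundle of simulation parameters for scripted scenario generation."""

    systems: Tuple[KillerSystem, ...]
    design: str
    n: int
    seed: int
    cM: Dict[str, float] = field(default_factory=dict)
    generations: int = 1
    obs_model: Optional[ObservationModel] = None
    misgenotyping_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ContractError("seed is mandatory")
        if not 0.0 <= self.misgenotyping_rate <= 1.0:
            raise ContractError(
                f"misgenotyping_rate must lie in [0, 1], got {self.misgenotyping_rate}"
            )
        if self.n <= 0:
            raise ContractError(f"n must be positive, got {self.n}")


def gen_testcross_counts(
    k: float, n: int, seed: Union[int, np.random.Generator]
) -> CountData:
    """Testcross progeny counts: n_H ~ Binomial(n, k), n_JJ the remainder."""
    if not 0.0 <= k <= 1.0:
        raise ContractError(f"k must lie in [0, 1], got {k}")
    if n <= 0:
        raise ContractError(f"n must be positive, got {n}")
    rng = _rng(seed)
    n_h = int(rng.binomial(n, k))
    return CountData(n_H=n_h, n_JJ=n - n_h)


def gen_selfed_table(
    k: float,
    n: int,
    seed: Union[int, np.random.Generator],
    misgenotyping_rate: float = 0.0,
    na_rate: float = 0.0,
    marker: str = "S35",
) -> pd.DataFrame:
    """Single-marker genotype table of n selfed progeny of a heterozygote.

    True genotypes are drawn from the analytic selfing distribution; each
    record is then flipped to a uniformly random *other* code with
    ``misgenotyping_rate`` and blanked to NA with ``na_rate``.
    """
    if n <= 0:
        raise ContractError(f"n must be positive, got {n}")
    for label, rate in (("misgenotyping_rate", misgenotyping_rate), ("na_rate", na_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ContractError(f"{label} must lie in [0, 1], got {rate}")
    rng = _rng(seed)
    freq = selfing_freq(k)
    draws = rng.choice(3, size=n, p=list(freq.as_tuple()))
    codes = np.array(_CODES, dtype=object)[draws]
    if misgenotyping_rate > 0.0:
        flip = rng.random(n) < misgenotyping_rate
        for i in np.nonzero(flip)[0]:
            others = [c for c in _CODES if c != codes[i]]
            codes[i] = others[int(rng.integers(len(others)))]
    if na_rate > 0.0:
        codes[rng.random(n) < na_rate] = "NA"
    ids = [f"P{i + 1:05d}" for i in range(n)]
    return pd.DataFrame({marker: codes}, index=pd.Index(ids, name="sample_id"))


def gen_recombinant_panel(
    n_markers: int,
    n_lines: int,
    seed: Union[int, np.random.Generator],
    causal_index: Optional[int] = None,
    carrier_rule: Union[str, FrozenSet[str], set] = "dominant-donor",
    span_bp: Tuple[int, int] = (1_000_000, 5_000_000),
    max_breakpoints: int = 3,
    chrom: str = "chr1",
    na_rate: float = 0.0,
) -> Tuple[RecombinantPanel, dict]:
    """Random fine-mapping panel with a known (marker-coincident) causal position.

    Marker positions are uniform over ``span_bp``; each line gets 0 to
    ``max_breakpoints`` uniform breakpoints with an independently drawn
    genotype state per segment.  The causal locus sits exactly at one
    marker, so its column is consistent by construction and the true
    position always survives interval inference.  Returns the panel plus a
    truth record (causal marker/position, carrier states, per-line causal
    genotypes).
    """
    if n_markers < 2:
        raise ContractError(f"n_markers must be >= 2, got {n_markers}")
    if n_lines < 1:
        raise ContractError(f"n_lines must be >= 1, got {n_lines}")
    lo, hi = span_bp
    if not 0 < lo < hi:
        raise ContractError(f"span_bp must satisfy 0 < lo < hi, got {span_bp}")
    if hi - lo < 10 * n_markers:
        raise ContractError("span too small for the requested number of markers")
    carrier_states = resolve_carrier_rule(carrier_rule)
    rng = _rng(seed)

    positions = np.sort(rng.choice(np.arange(lo, hi + 1), size=n_markers, replace=False))
    markers = tuple(
        LocusDef(name=f"m{i + 1:02d}", chrom=chrom, pos_bp=int(p))
        for i, p in enumerate(positions)
    )
    if causal_index is None:
        causal_index = int(rng.integers(n_markers))
    if not 0 <= causal_index < n_markers:
        raise ContractError(f"causal_index {causal_index} outside [0, {n_markers})")
    causal_pos = int(positions[causal_index])

    lines = []
    causal_genotypes = {}
    for li in range(n_lines):
        n_bk = int(rng.integers(0, max_breakpoints + 1))
        breaks = np.sort(rng.uniform(lo, hi, size=n_bk))
        seg_states = [str(rng.choice(_CODES)) for _ in range(n_bk + 1)]
        seg_of = lambda pos: int(np.searchsorted(breaks, pos))
        genotypes = [seg_states[seg_of(p)] for p in positions]
        causal_g = seg_states[seg_of(causal_pos)]
        phenotype = "carrier" if causal_g in carrier_states else "noncarrier"
        if na_rate > 0.0:
            mask = rng.random(n_markers) < na_rate
            mask[causal_index] = False  # never blind the panel at the causal marker
            genotypes = ["NA" if m else g for g, m in zip(genotypes, mask)]
        line_id = f"R{li + 1:03d}"
        causal_genotypes[line_id] = causal_g
        lines.append(RecombinantLine(line_id=line_id, genotypes=tuple(genotypes), phenotype=phenotype))

    panel = RecombinantPanel(markers=markers, lines=tuple(lines))
    truth = {
        "causal_marker": markers[causal_index].name,
        "causal_index": causal_index,
        "causal_pos": causal_pos,
        "carrier_states": sorted(carrier_states),
        "causal_genotypes": causal_genotypes,
    }
    return panel, truth
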