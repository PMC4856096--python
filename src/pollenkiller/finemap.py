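"""Breakpoint fine mapping: minimal candidate interval from recombinant panels.

Each line in a panel carries marker genotypes along one chromosome plus a
binary phenotype (carrier / noncarrier of the causal factor's effect).  A
marker position is *consistent* with being causal when every line's carrier
status matches its genotype there under the chosen carrier rule.  The
candidate interval is the open span between the closest contradicting
markers flanking the consistent region — deterministic breakpoint logic,
no likelihoods.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Sequence, Tuple, Union

from .model_core import ContractError, LocusDef

__all__ = [
    "CARRIER_PHENOTYPE",
    "NONCARRIER_PHENOTYPE",
    "CARRIER_RULES",
    "resolve_carrier_rule",
    "RecombinantLine",
    "RecombinantPanel",
    "CandidateInterval",
    "InconsistentPanelError",
    "infer_interval",
    "interval_report",
]

CARRIER_PHENOTYPE = "carrier"
NONCARRIER_PHENOTYPE = "noncarrier"

_VALID_GENOTYPES = frozenset({"II", "H", "JJ", "NA"})

#: Named carrier predicates: which genotypes at the causal position express the
#: carrier phenotype.  ``dominant-donor`` suits sporophytic activators (one
#: donor copy suffices); ``het-only`` suits gametophytic killers whose
#: phenotype exists only in heterozygotes; ``donor-homozygote`` is recessive.
CARRIER_RULES: Dict[str, FrozenSet[str]] = {
    "dominant-donor": frozenset({"II", "H"}),
    "het-only": frozenset({"H"}),
    "donor-homozygote": frozenset({"II"}),
}


def resolve_carrier_rule(rule: Union[str, FrozenSet[str], set]) -> FrozenSet[str]:
    if isinstance(rule, str):
        try:
            return CARRIER_RULES[rule]
        except KeyError:
            raise ContractError(
                f"unknown carrier rule {rule!r}; expected one of {sorted(CARRIER_RULES)}"
            ) from None
    states = frozenset(rule)
    if not states or not states <= frozenset({"II", "H", "JJ"}):
        raise ContractError(f"carrier states must be a non-empty subset of II/H/JJ, got {states}")
    return states


class InconsistentPanelError(ContractError):
    """No marker position satisfies every line — phenotyping error or second locus."""

    def __init__(self, message: str, conflicting_lines: Sequence[str]):
        super().__init__(message)
        self.conflicting_lines = tuple(conflicting_lines)


@dataclass(frozen=True)
class RecombinantLine:
    line_id: str
    genotypes: Tuple[str, ...]
    phenotype: str

    def __post_init__(self) -> None:
        if self.phenotype not in (CARRIER_PHENOTYPE, NONCARRIER_PHENOTYPE):
            raise ContractError(
                f"line {self.line_id!r}: phenotype must be "
                f"'{CARRIER_PHENOTYPE}' or '{NONCARRIER_PHENOTYPE}', got {self.phenotype!r}"
            )
        bad = [g for g in self.genotypes if g not in _VALID_GENOTYPES]
        if bad:
            raise ContractError(f"line {self.line_id!r}: unknown genotype codes {bad}")
        object.__setattr__(self, "genotypes", tuple(self.genotypes))

    @property
    def is_carrier(self) -> bool:
        return self.phenotype == CARRIER_PHENOTYPE


@dataclass(frozen=True)
class RecombinantPanel:
    """Ordered markers on one chromosome plus genotyped, phenotyped lines."""

    markers: Tuple[LocusDef, ...]
    lines: Tuple[RecombinantLine, ...]

    def __post_init__(self) -> None:
        markers = tuple(self.markers)
        if len(markers) < 2:
            raise ContractError("a panel needs at least 2 markers")
        chroms = {m.chrom for m in markers}
        if len(chroms) != 1:
            raise ContractError(f"panel markers must share one chromosome, got {sorted(chroms)}")
        positions = [m.pos_bp for m in markers]
        if positions != sorted(positions) or len(set(positions)) != len(positions):
            raise ContractError("panel markers must be sorted by pos_bp with unique positions")
        lines = tuple(self.lines)
        if not lines:
            raise ContractError("a panel needs at least one line")
        for line in lines:
            if len(line.genotypes) != len(markers):
                raise ContractError(
                    f"line {line.line_id!r} has {len(line.genotypes)} genotypes "
                    f"for {len(markers)} markers"
                )
        object.__setattr__(self, "markers", markers)
        object.__setattr__(self, "lines", lines)

    @property
    def marker_names(self) -> Tuple[str, ...]:
        return tuple(m.name for m in self.markers)


@dataclass(frozen=True)
class CandidateInterval:
    """Open interval between the contradicting markers flanking the causal locus."""

    left_marker: LocusDef
    right_marker: LocusDef
    consistent_markers: Tuple[str, ...] = field(default=())
    carrier_states: Tuple[str, ...] = field(default=("II", "H"))

    def __post_init__(self) -> None:
        if self.left_marker.pos_bp >= self.right_marker.pos_bp:
            raise ContractError("interval requires left_bp < right_bp")

    @property
    def left_bp(self) -> int:
        return self.left_marker.pos_bp

    @property
    def right_bp(self) -> int:
        return self.right_marker.pos_bp

    @property
    def length_bp(self) -> int:
        return self.right_bp - self.left_bp

    def contains(self, pos_bp: int) -> bool:
        return self.left_bp <= pos_bp <= self.right_bp


def _admissible(line: RecombinantLine, carrier_states: FrozenSet[str]) -> List[bool]:
    """Per-marker: could the causal locus sit here given this line? NA constrains nothing."""
    out = []
    for g in line.genotypes:
        if g == "NA":
            out.append(True)
        else:
            out.append((g in carrier_states) == line.is_carrier)
    return out


def infer_interval(
    panel: RecombinantPanel,
    carrier_rule: Union[str, FrozenSet[str], set] = "dominant-donor",
) -> CandidateInterval:
    """Intersect per-line admissible regions into the minimal candidate interval.

    Raises :class:`InconsistentPanelError` when no marker position survives
    every line (and names contradictory line pairs when they exist).
    """
    carrier_states = resolve_carrier_rule(carrier_rule)
    n_markers = len(panel.markers)
    consistent = [True] * n_markers
    per_line = {}
    for line in panel.lines:
        adm = _admissible(line, carrier_states)
        per_line[line.line_id] = adm
        consistent = [c and a for c, a in zip(consistent, adm)]
    if not any(consistent):
        pairs = []
        for i, a in enumerate(panel.lines):
            for b in panel.lines[i + 1 :]:
                if a.genotypes == b.genotypes and a.phenotype != b.phenotype:
                    pairs.append((a.line_id, b.line_id))
        if pairs:
            names = sorted({lid for pair in pairs for lid in pair})
            detail = "; contradictory pairs: " + ", ".join(f"{a}/{b}" for a, b in pairs)
        else:
            # report the lines rejecting the least-contradicted marker
            n_conflicts = [
                sum(not per_line[l.line_id][j] for l in panel.lines) for j in range(n_markers)
            ]
            j = n_conflicts.index(min(n_conflicts))
            names = [l.line_id for l in panel.lines if not per_line[l.line_id][j]]
            detail = f"; lines conflicting at marker {panel.markers[j].name!r}: " + ", ".join(names)
        raise InconsistentPanelError(
            "no marker position is consistent with every line "
            "(phenotyping error or a second causal locus?)" + detail,
            names,
        )
    first = consistent.index(True)
    last = n_markers - 1 - consistent[::-1].index(True)
    left = panel.markers[first - 1] if first > 0 else panel.markers[0]
    right = panel.markers[last + 1] if last < n_markers - 1 else panel.markers[-1]
    names = tuple(m.name for m, c in zip(panel.markers, consistent) if c)
    return CandidateInterval(
        left_marker=left,
        right_marker=right,
        consistent_markers=names,
        carrier_states=tuple(sorted(carrier_states)),
    )


def interval_report(interval: CandidateInterval, panel: RecombinantPanel) -> dict:
    """JSON-serializable summary: flanking markers, length, per-line support."""
    states = frozenset(interval.carrier_states)
    lines = []
    for line in panel.lines:
        # markers this line alone rules out under the rule used at inference
        excluded = sum(1 for ok in _admissible(line, states) if not ok)
        lines.append(
            {
                "line_id": line.line_id,
                "phenotype": line.phenotype,
                "n_markers_excluded": excluded,
            }
        )
    return {
        "left_marker": interval.left_marker.name,
        "right_marker": interval.right_marker.name,
        "chrom": interval.left_marker.chrom,
        "left_bp": interval.left_bp,
        "right_bp": interval.right_bp,
        "length_bp": interval.length_bp,
        "consistent_markers": list(interval.consistent_markers),
        "n_lines": len(panel.lines),
        "lines": lines,
    }
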