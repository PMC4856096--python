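"""TSV and YAML/JSON readers and writers for genotype tables, marker maps, panels."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, List, Tuple, Union

import pandas as pd
import yaml

from .finemap import RecombinantLine, RecombinantPanel
from .model_core import ContractError, KillerSystem, LocusDef, PartnerMode, Role
from .popsim import GeneticMap, GeneticMapEntry

__all__ = [
    "FormatError",
    "ConfigError",
    "SystemsConfig",
    "read_genotype_table",
    "write_genotype_table",
    "read_marker_map",
    "write_marker_map",
    "load_systems_config",
    "default_config_path",
    "load_panel",
]

log = logging.getLogger(__name__)

VALID_CODES = frozenset({"II", "H", "JJ", "NA"})
#: Non-marker columns a genotype table may carry.
RESERVED_COLUMNS = ("phenotype", "population")


class FormatError(ValueError):
    """A tabular input file violates its format contract."""


class ConfigError(ValueError):
    """A systems configuration file violates its schema."""


def read_genotype_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a samples x markers TSV (codes II/H/JJ/NA) indexed by sample_id.

    ``phenotype``/``population`` columns pass through unvalidated; any other
    column must hold genotype codes, and violations are reported with the
    1-based file line number and column name.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty genotype table") from None
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: ragged row — {exc}") from None
    if df.columns.empty or df.columns[0] != "sample_id":
        raise FormatError(f"{path}: first column must be 'sample_id', got {list(df.columns[:1])}")
    marker_cols = [c for c in df.columns[1:] if c not in RESERVED_COLUMNS]
    if not marker_cols:
        raise FormatError(f"{path}: no marker columns")
    if df.empty:
        raise FormatError(f"{path}: table has a header but no rows")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"{path}: duplicate sample_id {dup!r}")
    for col in marker_cols:
        bad = ~df[col].isin(VALID_CODES)
        if bad.any():
            row = int(bad.idxmax())
            value = df.loc[row, col]
            raise FormatError(
                f"{path}: line {row + 2}, column {col!r}: unknown genotype code {value!r}"
            )
    return df.set_index("sample_id")


def write_genotype_table(table: pd.DataFrame, path: Union[str, Path]) -> None:
    table = table.copy()
    table.index.name = "sample_id"
    table.to_csv(path, sep="\t")


def read_marker_map(path: Union[str, Path]) -> Tuple[List[LocusDef], Dict[str, float]]:
    """Read a marker map TSV (marker, chrom, pos_bp[, cM]); returns (loci, cM)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty marker map") from None
    required = {"marker", "chrom", "pos_bp"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: marker map needs columns {sorted(required)}")
    if df["marker"].duplicated().any():
        dup = df.loc[df["marker"].duplicated(), "marker"].iloc[0]
        raise FormatError(f"{path}: duplicate marker name {dup!r}")
    loci: List[LocusDef] = []
    cm: Dict[str, float] = {}
    for row_i, row in df.iterrows():
        try:
            pos = int(row["pos_bp"])
        except ValueError:
            raise FormatError(
                f"{path}: line {row_i + 2}: pos_bp must be an integer, got {row['pos_bp']!r}"
            ) from None
        try:
            loci.append(LocusDef(name=row["marker"], chrom=row["chrom"], pos_bp=pos))
        except ContractError as exc:
            raise FormatError(f"{path}: line {row_i + 2}: {exc}") from None
        if "cM" in df.columns and row["cM"] != "":
            cm[row["marker"]] = float(row["cM"])
    return loci, cm


def write_marker_map(
    loci: List[LocusDef], path: Union[str, Path], cM: Dict[str, float] = None
) -> None:
    records = []
    for locus in loci:
        rec = {"marker": locus.name, "chrom": locus.chrom, "pos_bp": locus.pos_bp}
        if cM:
            rec["cM"] = cM.get(locus.name, "")
        records.append(rec)
    pd.DataFrame.from_records(records).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class SystemsConfig:
    """Validated killer-system declaration: loci, systems, optional cM map."""

    loci: Dict[str, LocusDef]
    systems: Tuple[KillerSystem, ...]
    cM: Dict[str, float]

    def genetic_map(self) -> GeneticMap:
        missing = [n for n in self.loci if n not in self.cM]
        if missing:
            raise ConfigError(f"config has no cM position for loci: {', '.join(missing)}")
        return GeneticMap(
            GeneticMapEntry(locus, self.cM[name]) for name, locus in self.loci.items()
        )


def default_config_path() -> Path:
    """Path of the bundled two-pathway (activator + suppressor) network config."""
    return Path(str(resources.files("pollenkiller").joinpath("data/efs_s24_ink_s35.yaml")))


def load_systems_config(path: Union[str, Path]) -> SystemsConfig:
    """Load and validate a YAML (or JSON) killer-systems declaration."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML/JSON — {exc}") from None
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping with 'loci' and 'systems'")
    for key in ("loci", "systems"):
        if key not in raw or not isinstance(raw[key], list) or not raw[key]:
            raise ConfigError(f"{path}: missing or empty {key!r} list")

    loci: Dict[str, LocusDef] = {}
    for i, entry in enumerate(raw["loci"]):
        if not isinstance(entry, dict) or not {"name", "chrom", "pos_bp"} <= set(entry):
            raise ConfigError(f"{path}: loci[{i}] needs keys name, chrom, pos_bp")
        try:
            locus = LocusDef(
                name=str(entry["name"]),
                chrom=str(entry["chrom"]),
                pos_bp=int(entry["pos_bp"]),
                role=Role(entry.get("role", "neutral_marker")),
            )
        except (ContractError, ValueError) as exc:
            raise ConfigError(f"{path}: loci[{i}]: {exc}") from None
        if locus.name in loci:
            raise ConfigError(f"{path}: duplicate locus name {locus.name!r}")
        loci[locus.name] = locus

    systems: List[KillerSystem] = []
    for i, entry in enumerate(raw["systems"]):
        if not isinstance(entry, dict) or not {"killer", "partner", "partner_mode"} <= set(entry):
            raise ConfigError(f"{path}: systems[{i}] needs keys killer, partner, partner_mode")
        for role_key in ("killer", "partner"):
            if entry[role_key] not in loci:
                raise ConfigError(
                    f"{path}: systems[{i}]: {role_key} {entry[role_key]!r} not declared in loci"
                )
        try:
            system = KillerSystem(
                killer=loci[entry["killer"]],
                partner=loci[entry["partner"]],
                partner_mode=PartnerMode(entry["partner_mode"]),
                targeted_allele=str(entry.get("targeted_allele", "J")),
                survival_s=float(entry.get("survival_s", 0.0)),
                collateral_c=float(entry.get("collateral_c", 0.0)),
            )
        except (ContractError, ValueError) as exc:
            raise ConfigError(f"{path}: systems[{i}]: {exc}") from None
        systems.append(system)
        log.info("loaded system %s: s=%.4g -> k=%.4f", system.name, system.survival_s, system.k)

    cm_raw = raw.get("map", {}) or {}
    if not isinstance(cm_raw, dict):
        raise ConfigError(f"{path}: 'map' must be a mapping of locus name -> cM")
    cm = {str(name): float(pos) for name, pos in cm_raw.items()}
    unknown = [n for n in cm if n not in loci]
    if unknown:
        raise ConfigError(f"{path}: map references undeclared loci: {', '.join(unknown)}")
    return SystemsConfig(loci=loci, systems=tuple(systems), cM=cm)


_PHENOTYPE_ALIASES = {
    "carrier": "carrier",
    "noncarrier": "noncarrier",
    "sterile": "carrier",
    "fertile": "noncarrier",
}


def load_panel(panel_path: Union[str, Path], map_path: Union[str, Path]) -> RecombinantPanel:
    """Assemble a fine-mapping panel from a genotype table and a marker map.

    The table must carry a ``phenotype`` column (carrier/noncarrier; the
    sterile/fertile aliases are accepted).  Markers are ordered by map
    position; table columns not on the map are rejected.
    """
    table = read_genotype_table(panel_path)
    if "phenotype" not in table.columns:
        raise FormatError(f"{panel_path}: panel table needs a 'phenotype' column")
    loci, _ = read_marker_map(map_path)
    by_name = {l.name: l for l in loci}
    marker_cols = [c for c in table.columns if c not in RESERVED_COLUMNS]
    unknown = [c for c in marker_cols if c not in by_name]
    if unknown:
        raise FormatError(f"{panel_path}: markers not on the map: {', '.join(unknown)}")
    markers = tuple(sorted((by_name[c] for c in marker_cols), key=lambda l: l.pos_bp))
    order = [m.name for m in markers]
    lines = []
    for sample_id, row in table.iterrows():
        phenotype = _PHENOTYPE_ALIASES.get(str(row["phenotype"]).strip().lower())
        if phenotype is None:
            raise FormatError(
                f"{panel_path}: sample {sample_id!r}: phenotype must be carrier/noncarrier, "
                f"got {row['phenotype']!r}"
            )
        lines.append(
            RecombinantLine(
                line_id=str(sample_id),
                genotypes=tuple(str(row[name]) for name in order),
                phenotype=phenotype,
            )
        )
    return RecombinantPanel(markers=markers, lines=tuple(lines))
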