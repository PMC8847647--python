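"""Reading, validating and writing study tables and network configurations.

The canonical abundance table is wide: one row per sample, a sample-id
column, a compartment column, a group column, and one column per lipid
variable in shorthand nomenclature.  Missing cells and explicit ``NA`` are
coerced to 0 (= not detected), because presence is defined on signal > 0; a
warning counts the coercions.  Network configurations are YAML with a
compartment list, an edge list and optional terminus annotations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .nomenclature import LipidParseError, LipidSpecies, parse_lipid_name
from .network import NetworkConfigError, TissueNetwork

__all__ = [
    "ColumnSchema",
    "DatasetValidationError",
    "LipidomicsDataset",
    "load_lipidomics_table",
    "write_lipidomics_table",
    "load_network_config",
    "write_network_config",
]


class DatasetValidationError(ValueError):
    """Collects every validation violation found in an input table."""

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__(
            "invalid lipidomics table:\n  - " + "\n  - ".join(self.violations)
        )


@dataclass(frozen=True)
class ColumnSchema:
    """Names of the three annotation columns in a wide abundance table."""

    sample_id: str = "sample_id"
    compartment: str = "compartment"
    group: str = "group"


@dataclass
class LipidomicsDataset:
    """Sample x lipid abundance matrix with compartment/group annotation.

    ``samples`` is indexed by sample id with columns ``compartment`` and
    ``group``; ``abundance`` shares the same index with one column per lipid
    variable (raw names).  ``variables`` holds the parsed identities in table
    column order.  ``mode`` optionally tags each variable with an ionisation
    mode.
    """

    samples: pd.DataFrame
    abundance: pd.DataFrame
    variables: list[LipidSpecies]
    mode: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        violations: list[str] = []
        if not self.samples.index.equals(self.abundance.index):
            violations.append("samples and abundance indices differ")
        if self.samples.index.has_duplicates:
            dups = sorted(self.samples.index[self.samples.index.duplicated()])
            violations.append(f"duplicate sample ids: {dups}")
        names = [v.raw_name for v in self.variables]
        if list(self.abundance.columns) != names:
            violations.append("variable records do not match abundance columns")
        if len(set(names)) != len(names):
            violations.append("duplicate variable columns")
        if (self.abundance.to_numpy() < 0).any():
            bad = self.abundance.columns[(self.abundance < 0).any()].tolist()
            violations.append(f"negative abundances in: {bad}")
        if self.samples["compartment"].isna().any() or self.samples["group"].isna().any():
            violations.append("missing compartment or group labels")
        if self.samples["compartment"].nunique() < 2:
            violations.append("at least 2 compartments required")
        if violations:
            raise DatasetValidationError(violations)

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(sorted(self.samples["group"].unique()))

    @property
    def compartments(self) -> tuple[str, ...]:
        return tuple(sorted(self.samples["compartment"].unique()))

    @property
    def variable_names(self) -> list[str]:
        return list(self.abundance.columns)

    def species(self, name: str) -> LipidSpecies:
        for v in self.variables:
            if v.raw_name == name:
                return v
        raise KeyError(name)

    def require_two_groups(self) -> None:
        """A standard switch-analysis run compares exactly two phenotypes."""
        if len(self.groups) != 2:
            raise DatasetValidationError(
                [f"switch analysis requires exactly 2 groups, found {self.groups}"]
            )

    def values(self, group: str, compartment: str, variable: str) -> np.ndarray:
        mask = (self.samples["group"] == group) & (
            self.samples["compartment"] == compartment
        )
        return self.abundance.loc[mask, variable].to_numpy(dtype=float)


def _read_delimited(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","
    return pd.read_csv(path, sep=sep, dtype=str)


def load_lipidomics_table(
    path: str | Path,
    schema: ColumnSchema = ColumnSchema(),
    *,
    transposed: bool = False,
) -> LipidomicsDataset:
    """Load and validate a wide CSV/TSV abundance table.

    With ``transposed=True`` the file has variables in rows and samples in
    columns (annotation rows named after the schema columns); it is pivoted
    to the canonical wide orientation before validation.  All violations are
    collected and reported together.
    """
    raw = _read_delimited(path)
    if transposed:
        raw = raw.set_index(raw.columns[0]).T.reset_index(names=schema.sample_id)

    violations: list[str] = []
    for col in (schema.sample_id, schema.compartment, schema.group):
        if col not in raw.columns:
            violations.append(f"missing schema column {col!r}")
    if violations:
        raise DatasetValidationError(violations)

    annot_cols = [schema.sample_id, schema.compartment, schema.group]
    var_cols = [c for c in raw.columns if c not in annot_cols]
    if not var_cols:
        raise DatasetValidationError(["no lipid variable columns found"])

    seen: set[str] = set()
    variables: list[LipidSpecies] = []
    for name in var_cols:
        if name in seen:
            violations.append(f"duplicate variable column {name!r}")
            continue
        seen.add(name)
        try:
            variables.append(parse_lipid_name(name))
        except LipidParseError as exc:
            violations.append(str(exc))

    ids = raw[schema.sample_id]
    if ids.isna().any():
        violations.append("missing sample ids")
    if ids.duplicated().any():
        violations.append(f"duplicate sample ids: {sorted(ids[ids.duplicated()])}")

    abundance = raw[var_cols].apply(pd.to_numeric, errors="coerce")
    n_missing = int(abundance.isna().to_numpy().sum())
    if n_missing:
        warnings.warn(
            f"{n_missing} missing/NA abundance cells coerced to 0 (not detected)",
            stacklevel=2,
        )
        abundance = abundance.fillna(0.0)
    if (abundance.to_numpy() < 0).any():
        bad = abundance.columns[(abundance < 0).any()].tolist()
        violations.append(f"negative abundances in: {bad}")

    if violations:
        raise DatasetValidationError(violations)

    samples = raw[annot_cols].set_index(schema.sample_id)
    samples.index.name = "sample_id"
    samples.columns = ["compartment", "group"]
    abundance.index = samples.index
    return LipidomicsDataset(samples=samples, abundance=abundance, variables=variables)


def write_lipidomics_table(dataset: LipidomicsDataset, path: str | Path) -> None:
    """Write the canonical wide CSV (RFC-4180, comma separated)."""
    out = pd.concat([dataset.samples, dataset.abundance], axis=1).reset_index()
    out.to_csv(path, index=False, lineterminator="\n")


def load_network_config(path: str | Path) -> TissueNetwork:
    """Load a YAML network configuration.

    Expected keys: ``compartments`` (list of labels), ``edges`` (list of
    2-item lists) and optional ``termini`` (mapping label -> role).
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "compartments" not in cfg or "edges" not in cfg:
        raise NetworkConfigError(
            f"{path}: network config needs 'compartments' and 'edges' keys"
        )
    edges = []
    for e in cfg["edges"]:
        if not isinstance(e, (list, tuple)) or len(e) != 2:
            raise NetworkConfigError(f"{path}: malformed edge {e!r}")
        edges.append((str(e[0]), str(e[1])))
    return TissueNetwork(
        compartments=tuple(str(c) for c in cfg["compartments"]),
        edges=tuple(edges),
        termini={str(k): str(v) for k, v in (cfg.get("termini") or {}).items()},
    )


def write_network_config(network: TissueNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "compartments": list(network.compartments),
                "edges": [list(e) for e in network.edges],
                "termini": dict(network.termini),
            },
            fh,
            sort_keys=False,
        )
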