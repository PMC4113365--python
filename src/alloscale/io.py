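"""CSV / config I/O.

Conventions: comma-separated, UTF-8, '.' decimal, header row required.
Units travel inside the files (the organ table has a ``mass_unit`` column;
EE datasets carry units in a ``# key=value`` header comment written by this
package).  CLI unit flags are declarations validated against file contents,
never silent conversions.
"""
from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd
import yaml

from .fitting import EEDataset
from .organs import OrganCompartment, OrganModel
from .simulate import SimulationConfig
from .units import DEFAULT_EE_UNIT, MassUnit, UnitError

__all__ = [
    "read_organ_table",
    "write_organ_table",
    "read_ee_dataset",
    "write_ee_dataset",
    "load_simulation_config",
]

ORGAN_COLUMNS = ("organ", "c", "k", "f", "mass_unit")
DATASET_COLUMNS = ("id", "mass", "ee")


class ParseError(ValueError):
    pass


def read_organ_table(
    path: str | Path,
    declared_mass_unit: MassUnit | str | None = None,
    ee_unit: str = DEFAULT_EE_UNIT,
) -> OrganModel:
    """Read an organ-compartment table (columns organ,c,k,f,mass_unit).

    All rows must agree on the mass unit; if ``declared_mass_unit`` is given
    it must match the file (mismatch is an error, not a conversion).  Empty
    ``f`` cells mean "fraction unknown".
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ORGAN_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(
            f"{path}: missing required column(s) {missing}; expected header "
            f"{','.join(ORGAN_COLUMNS)}"
        )
    units = {MassUnit.parse(u) for u in df["mass_unit"]}
    if len(units) != 1:
        raise ParseError(f"{path}: rows mix mass units {sorted(u.value for u in units)}")
    (unit,) = units
    if declared_mass_unit is not None and MassUnit.parse(declared_mass_unit) != unit:
        raise UnitError(
            f"{path}: file is in {unit.value!r} but {MassUnit.parse(declared_mass_unit).value!r} "
            "was declared; units are data — re-export the table instead of re-declaring"
        )
    comps = []
    for row in df.itertuples(index=True):
        try:
            comps.append(
                OrganCompartment(
                    name=str(row.organ),
                    c=float(row.c),
                    k=float(row.k),
                    f=None if pd.isna(row.f) else float(row.f),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: row {row.Index + 2}: {exc}") from exc
    return OrganModel(compartments=tuple(comps), mass_unit=unit, ee_unit=ee_unit)


def write_organ_table(model: OrganModel, path: str | Path) -> None:
    """Write an organ table in the same dialect ``read_organ_table`` accepts."""
    df = pd.DataFrame(
        {
            "organ": [c.name for c in model.compartments],
            "c": [repr(c.c) for c in model.compartments],
            "k": [repr(c.k) for c in model.compartments],
            "f": ["" if c.f is None else repr(c.f) for c in model.compartments],
            "mass_unit": [model.mass_unit.value] * len(model.compartments),
        }
    )
    df.to_csv(path, index=False)


def read_ee_dataset(
    path: str | Path,
    mass_unit: MassUnit | str,
    ee_unit: str = DEFAULT_EE_UNIT,
    mass_kind: str = "total",
) -> EEDataset:
    """Read an EE dataset CSV (columns id,mass,ee).

    Units are declared by the caller; if the file carries a ``# mass_unit=``
    header comment (as written by :func:`write_ee_dataset`) it must agree
    with the declaration.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    meta: dict[str, str] = {}
    body_lines = []
    for line in text.splitlines():
        if line.startswith("#"):
            for token in line.lstrip("# ").split():
                if "=" in token:
                    key, val = token.split("=", 1)
                    meta[key] = val
        else:
            body_lines.append(line)
    if "mass_unit" in meta and MassUnit.parse(meta["mass_unit"]) != MassUnit.parse(mass_unit):
        raise UnitError(
            f"{path}: file records mass_unit={meta['mass_unit']!r} but "
            f"{MassUnit.parse(mass_unit).value!r} was declared"
        )
    df = pd.read_csv(_io.StringIO("\n".join(body_lines)), float_precision="round_trip")
    missing = [c for c in ("mass", "ee") if c not in df.columns]
    if missing:
        raise ParseError(
            f"{path}: missing required column(s) {missing}; expected header "
            f"{','.join(DATASET_COLUMNS)}"
        )
    bad = df.index[~(df["mass"].astype(float).gt(0) & df["ee"].astype(float).gt(0))]
    if len(bad):
        raise ParseError(
            f"{path}: non-positive mass or ee on data row(s) {[int(i) + 2 for i in bad]}"
        )
    return EEDataset.from_dataframe(
        df, mass_unit=mass_unit, ee_unit=meta.get("ee_unit", ee_unit), mass_kind=mass_kind
    )


def write_ee_dataset(data: EEDataset, path: str | Path) -> None:
    path = Path(path)
    header = f"# mass_unit={data.mass_unit.value} ee_unit={data.ee_unit} mass_kind={data.mass_kind}\n"
    df = data.to_dataframe()
    path.write_text(header + df.to_csv(index=False), encoding="utf-8")


def load_simulation_config(path: str | Path) -> SimulationConfig:
    """Load a YAML simulation config whose keys mirror SimulationConfig fields."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ParseError(f"{path}: expected a mapping of SimulationConfig fields")
    valid = set(SimulationConfig.__dataclass_fields__)
    unknown = set(raw) - valid
    if unknown:
        raise ParseError(f"{path}: unknown config key(s) {sorted(unknown)}")
    return SimulationConfig(**raw)
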