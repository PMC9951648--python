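"""Domain types and delimited-file I/O for longitudinal herd and slaughter data.

A herd dataset is three tables keyed by ``animal_id``:

* **animals** — one row per animal: sex, sire line, bloodline, dam live weight;
* **observations** — long-format trait measurements (live weight and body
  measurements) at the ontogenesis ages birth (coded 0), 3, 6, 9, 12, 15 and
  18 months;
* **slaughter** — post-slaughter masses (pre-slaughter, paired carcass,
  internal fat, slaughter, chilled carcass, pulp, bone, tendon, half carcass),
  possibly empty for herds still on the barn.

Masses are kilograms, body measurements centimetres throughout; no unit
inference is attempted.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "AGES",
    "LIVE_WEIGHT",
    "MEASUREMENTS",
    "OPTIONAL_MEASUREMENTS",
    "TRAITS",
    "DAM_WEIGHT",
    "BIRTH_LIVE_WEIGHT",
    "BIRTH_WITHERS_HEIGHT",
    "DEFAULT_MARKERS",
    "SLAUGHTER_TRAITS",
    "DEFAULT_TARGETS",
    "ANIMAL_COLUMNS",
    "OBSERVATION_COLUMNS",
    "SLAUGHTER_COLUMNS",
    "TraitKey",
    "Dialect",
    "HerdDataset",
    "HerdError",
    "SchemaError",
    "RowParseError",
    "HerdValidationError",
    "read_herd",
    "write_herd",
    "subset_by_group",
    "round_half_up",
]

#: Measurement ages in months; 0 codes "at birth".
AGES: tuple[int, ...] = (0, 3, 6, 9, 12, 15, 18)

LIVE_WEIGHT = "live_weight_kg"

#: Body measurements taken with the live-weight record at every age.
MEASUREMENTS: tuple[str, ...] = (
    "height_withers_cm",
    "height_sacrum_cm",
    "oblique_trunk_length_cm",
    "chest_depth_cm",
    "chest_girth_cm",
    "pastern_girth_cm",
)

#: Measurements that appear in some correlation summaries but are optional
#: in datasets.
OPTIONAL_MEASUREMENTS: tuple[str, ...] = (
    "chest_width_cm",
    "width_makloks_cm",
    "butt_half_girth_cm",
)

TRAITS: tuple[str, ...] = (LIVE_WEIGHT,) + MEASUREMENTS + OPTIONAL_MEASUREMENTS

#: A (trait, age_months) pair; the dam's live weight carries age ``None``
#: because it is a property of the mother, not an ontogenesis point.
TraitKey = tuple[str, Optional[int]]

DAM_WEIGHT: TraitKey = ("dam_live_weight_kg", None)
BIRTH_LIVE_WEIGHT: TraitKey = (LIVE_WEIGHT, 0)
BIRTH_WITHERS_HEIGHT: TraitKey = ("height_withers_cm", 0)

#: The three birth-time marker traits used for the meat-productivity forecast.
DEFAULT_MARKERS: tuple[TraitKey, ...] = (
    DAM_WEIGHT,
    BIRTH_LIVE_WEIGHT,
    BIRTH_WITHERS_HEIGHT,
)

SLAUGHTER_TRAITS: tuple[str, ...] = (
    "pre_slaughter_mass_kg",
    "paired_carcass_mass_kg",
    "internal_fat_mass_kg",
    "slaughter_mass_kg",
    "chilled_carcass_mass_kg",
    "pulp_mass_kg",
    "bone_mass_kg",
    "tendon_mass_kg",
    "half_carcass_mass_kg",
)

#: Slaughter indices the forecast targets: pre-slaughter, slaughter and pulp
#: mass — the three indices the prognosis is built on.
DEFAULT_TARGETS: tuple[str, ...] = (
    "pre_slaughter_mass_kg",
    "slaughter_mass_kg",
    "pulp_mass_kg",
)

ANIMAL_COLUMNS = ["animal_id", "sex", "sire_line", "bloodline", "dam_live_weight_kg"]
OBSERVATION_COLUMNS = ["animal_id", "trait", "age_months", "value"]
SLAUGHTER_COLUMNS = ["animal_id"] + list(SLAUGHTER_TRAITS)


class HerdError(Exception):
    """Base class for herd-data errors."""


class SchemaError(HerdError):
    """A required column is missing or mis-named."""


class RowParseError(HerdError):
    """A cell failed numeric conversion; carries the 1-based data row."""


class HerdValidationError(HerdError):
    """Cross-table invariants violated (e.g. unresolved animal ids)."""


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties away from zero, the convention of printed field tables."""
    q = decimal.Decimal(10) ** -decimals
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclass
class Dialect:
    """Delimited-file dialect: delimiter and decimal places on output."""

    delimiter: str = ","
    decimals: int = 1


@dataclass
class HerdDataset:
    """Validated container for one herd's longitudinal and slaughter tables."""

    animals: pd.DataFrame
    observations: pd.DataFrame
    slaughter: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=SLAUGHTER_COLUMNS))
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.animals = self.animals.reset_index(drop=True)
        self.observations = self.observations.reset_index(drop=True)
        self.slaughter = self.slaughter.reset_index(drop=True)

    # -- accessors -------------------------------------------------------

    @property
    def n_animals(self) -> int:
        return len(self.animals)

    def trait_values(self, key: TraitKey) -> pd.Series:
        """Values of one (trait, age) pair indexed by animal_id.

        ``DAM_WEIGHT`` and slaughter traits are resolved from the animals and
        slaughter tables respectively; everything else from observations.
        Missing values are dropped.
        """
        trait, age = key
        if key == DAM_WEIGHT:
            s = self.animals.set_index("animal_id")["dam_live_weight_kg"]
        elif trait in SLAUGHTER_TRAITS:
            if self.slaughter.empty:
                return pd.Series(dtype=float, name=trait)
            s = self.slaughter.set_index("animal_id")[trait]
        else:
            obs = self.observations
            mask = (obs["trait"] == trait) & (obs["age_months"] == age)
            s = obs.loc[mask].set_index("animal_id")["value"]
        return s.dropna().astype(float)

    def marker_values(self, markers: Iterable[TraitKey]) -> pd.DataFrame:
        """Wide frame of marker values, complete cases only, one row per animal."""
        cols = {marker_label(m): self.trait_values(m) for m in markers}
        return pd.DataFrame(cols).dropna()

    # -- validation ------------------------------------------------------

    def validate(self, atol: float = 1.0) -> None:
        """Check cross-table invariants, raising HerdValidationError.

        ``atol`` is the slack (kg) allowed on the carcass composition
        identity pulp + bone + tendon <= chilled carcass mass.
        """
        problems: list[str] = []
        ids = self.animals["animal_id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            problems.append(f"duplicate animal_id(s): {dupes}")
        known = set(ids)
        for name, table in (("observations", self.observations), ("slaughter", self.slaughter)):
            if table.empty:
                continue
            orphans = sorted(set(table["animal_id"]) - known)
            if orphans:
                problems.append(f"{name} reference unknown animal_id(s): {orphans}")
        dam = self.animals["dam_live_weight_kg"].dropna()
        if (dam <= 0).any():
            problems.append("dam_live_weight_kg must be positive where present")
        if not self.observations.empty:
            vals = self.observations["value"].dropna()
            if (vals <= 0).any():
                problems.append("trait observations must be positive")
            key_cols = ["animal_id", "trait", "age_months"]
            if self.observations.duplicated(key_cols).any():
                problems.append("duplicate (animal_id, trait, age_months) observations")
            bad_age = set(self.observations["age_months"]) - set(AGES)
            if bad_age:
                problems.append(f"unknown age_months value(s): {sorted(bad_age)}")
        if not self.slaughter.empty:
            sl = self.slaughter
            comp = sl["pulp_mass_kg"] + sl["bone_mass_kg"] + sl["tendon_mass_kg"]
            if (comp > sl["chilled_carcass_mass_kg"] + atol).any():
                problems.append("pulp + bone + tendon exceeds chilled carcass mass")
            for col in SLAUGHTER_TRAITS[1:]:
                if (sl[col] >= sl["pre_slaughter_mass_kg"]).any():
                    problems.append(f"{col} not below pre_slaughter_mass_kg")
        if problems:
            raise HerdValidationError("; ".join(problems))

    def copy(self) -> "HerdDataset":
        return HerdDataset(
            self.animals.copy(),
            self.observations.copy(),
            self.slaughter.copy(),
            dict(self.provenance),
        )


def marker_label(key: TraitKey) -> str:
    """Stable column label for a (trait, age) pair, e.g. ``live_weight_kg@0``."""
    trait, age = key
    return trait if age is None else f"{trait}@{age}"


# ---------------------------------------------------------------------------
# delimited I/O


def _require_columns(df: pd.DataFrame, required: list[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _numeric(df: pd.DataFrame, cols: list[str], path: Path) -> pd.DataFrame:
    for col in cols:
        raw = df[col]
        converted = pd.to_numeric(raw, errors="coerce")
        # empty cells are legitimate missing values; anything else that fails
        # conversion is a parse error reported with its data row number
        bad = converted.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        if bad.any():
            row = int(bad.idxmax()) + 2  # header is line 1
            raise RowParseError(f"{path}, line {row}: non-numeric value {raw[bad.idxmax()]!r} in column {col!r}")
        df[col] = converted
    return df


def read_herd(
    animals_path: str | Path,
    observations_path: str | Path,
    slaughter_path: str | Path | None = None,
    dialect: Dialect | None = None,
) -> HerdDataset:
    """Read and validate a herd from its delimited tables.

    ``slaughter_path`` may be None (or point to a header-only file) for herds
    without slaughter records.
    """
    dialect = dialect or Dialect()
    kw = dict(sep=dialect.delimiter, dtype=str, skipinitialspace=True)

    animals_path, observations_path = Path(animals_path), Path(observations_path)
    animals = pd.read_csv(animals_path, **kw)
    _require_columns(animals, ANIMAL_COLUMNS, animals_path)
    animals = _numeric(animals[ANIMAL_COLUMNS].copy(), ["dam_live_weight_kg"], animals_path)

    obs = pd.read_csv(observations_path, **kw)
    _require_columns(obs, OBSERVATION_COLUMNS, observations_path)
    obs = _numeric(obs[OBSERVATION_COLUMNS].copy(), ["age_months", "value"], observations_path)
    if not obs.empty:
        obs["age_months"] = obs["age_months"].astype(int)

    if slaughter_path is not None:
        slaughter_path = Path(slaughter_path)
        sl = pd.read_csv(slaughter_path, **kw)
        _require_columns(sl, SLAUGHTER_COLUMNS, slaughter_path)
        sl = _numeric(sl[SLAUGHTER_COLUMNS].copy(), list(SLAUGHTER_TRAITS), slaughter_path)
    else:
        sl = pd.DataFrame(columns=SLAUGHTER_COLUMNS)

    ds = HerdDataset(animals, obs, sl, provenance={"source": str(animals_path.parent)})
    ds.validate()
    return ds


def write_herd(
    dataset: HerdDataset,
    animals_path: str | Path,
    observations_path: str | Path,
    slaughter_path: str | Path | None = None,
    dialect: Dialect | None = None,
) -> None:
    """Write a herd to delimited files readable by :func:`read_herd`.

    Numeric values are rendered with ``dialect.decimals`` decimal places
    (default 1, the precision of printed zootechnical tables).
    """
    dialect = dialect or Dialect()
    fmt = f"%.{dialect.decimals}f"
    kw = dict(sep=dialect.delimiter, index=False, float_format=fmt)
    dataset.animals[ANIMAL_COLUMNS].to_csv(animals_path, **kw)
    obs = dataset.observations[OBSERVATION_COLUMNS] if not dataset.observations.empty else pd.DataFrame(columns=OBSERVATION_COLUMNS)
    obs.to_csv(observations_path, **kw)
    if slaughter_path is not None:
        sl = dataset.slaughter[SLAUGHTER_COLUMNS] if not dataset.slaughter.empty else pd.DataFrame(columns=SLAUGHTER_COLUMNS)
        sl.to_csv(slaughter_path, **kw)


def subset_by_group(dataset: HerdDataset, grouping: str, level: str | None = None) -> HerdDataset:
    """Restrict a herd to one sire line or bloodline.

    ``grouping`` is ``"sire_line"``, ``"bloodline"`` or ``"all"`` (identity,
    the pooled "total by group" view).
    """
    if grouping == "all":
        return dataset
    if grouping not in ("sire_line", "bloodline"):
        raise KeyError(f"unknown grouping {grouping!r}")
    levels = set(dataset.animals[grouping].dropna())
    if level not in levels:
        raise KeyError(f"level {level!r} not present in {grouping!r} (have {sorted(levels)})")
    animals = dataset.animals[dataset.animals[grouping] == level]
    keep = set(animals["animal_id"])
    obs = dataset.observations[dataset.observations["animal_id"].isin(keep)]
    sl = dataset.slaughter[dataset.slaughter["animal_id"].isin(keep)] if not dataset.slaughter.empty else dataset.slaughter
    prov = dict(dataset.provenance, subset=f"{grouping}={level}")
    return HerdDataset(animals.copy(), obs.copy(), sl.copy(), prov)
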