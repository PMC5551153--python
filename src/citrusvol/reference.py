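"""Reference databases: spray targets, leaf area density, product registry.

The three databases ship with the package as human-editable structured-text
files under ``citrusvol/data`` and can be replaced by user files with the
same schema; every load — shipped or user-supplied — runs the same
validation (enumerated classes, positive values, LAD monotonicity).

Scientific constants encoded here:

* ``f_target`` — the fraction of the canopy leaf surface that must be wetted,
  fixed per application class: internal 1.0, intermediate 0.75, external 0.49.
* Minimum leaf deposit ``D`` for maximum control efficacy, per mode-of-action
  class: 3.41 µL/cm² for contact products (organophosphate reference) and
  4.72 µL/cm² for suffocating products (mineral-oil reference).
"""

from __future__ import annotations

import difflib
import enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd
import yaml
from pydantic import BaseModel, field_validator

from .errors import (
    DatabaseError,
    UnknownCultivarError,
    UnknownProductError,
    UnknownTargetError,
)

PathLike = Union[str, Path]


class ApplicationClass(str, enum.Enum):
    """Which part of the canopy an application must reach."""

    INTERNAL = "internal"  # whole canopy
    INTERMEDIATE = "intermediate"  # two thirds
    EXTERNAL = "external"  # outer third


class CultivarGroup(str, enum.Enum):
    LOW = "low"
    MEDIUM = "medium"
    HIGH = "high"


class PruningLevel(str, enum.Enum):
    SEVERE = "severe"
    NORMAL = "normal"
    WITHOUT_PRUNING = "without_pruning"


class MoaClass(str, enum.Enum):
    """Mode-of-action class of a plant-protection product."""

    CONTACT = "contact"
    SUFFOCATING = "suffocating"


#: Wetted-canopy fraction per application class (dimensionless).
F_TARGET: dict[ApplicationClass, float] = {
    ApplicationClass.INTERNAL: 1.0,
    ApplicationClass.INTERMEDIATE: 0.75,
    ApplicationClass.EXTERNAL: 0.49,
}

#: Minimum required leaf deposit per mode-of-action class (µL/cm²).
DEPOSIT_BY_MOA: dict[MoaClass, float] = {
    MoaClass.CONTACT: 3.41,
    MoaClass.SUFFOCATING: 4.72,
}


class TargetSpec(BaseModel):
    """A pest or disease target and its coverage requirement."""

    name: str
    application_class: ApplicationClass
    warnings: list[str] = []

    @property
    def f_target(self) -> float:
        return F_TARGET[self.application_class]


class ProductSpec(BaseModel):
    """An active ingredient and its deposit requirement."""

    active_ingredient: str
    moa_class: MoaClass
    label_warnings: list[str] = []

    @property
    def deposit(self) -> float:
        """Minimum required deposit D (µL/cm²)."""
        return DEPOSIT_BY_MOA[self.moa_class]


class LadEntry(BaseModel):
    """Leaf area density for one cultivar-group × pruning combination."""

    cultivar_group: CultivarGroup
    pruning: PruningLevel
    lad: float  # m² leaf / m³ canopy

    @field_validator("lad")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("lad must be positive")
        return v


def _data_path(name: str) -> Path:
    return Path(str(resources.files("citrusvol").joinpath("data", name)))


def _suggest(name: str, pool: Iterable[str]) -> list[str]:
    return difflib.get_close_matches(name, list(pool), n=3, cutoff=0.4)


class TargetDatabase:
    """Case-insensitive lookup of pest/disease targets."""

    def __init__(self, targets: list[TargetSpec], aliases: dict[str, str]):
        self.targets = {t.name: t for t in targets}
        # alias (lowercased) -> canonical name
        self._index: dict[str, str] = {t.name.lower(): t.name for t in targets}
        for alias, canonical in aliases.items():
            self._index[alias.lower()] = canonical

    @classmethod
    def load(cls, path: Optional[PathLike] = None) -> "TargetDatabase":
        path = Path(path) if path is not None else _data_path("targets.yaml")
        try:
            raw = yaml.safe_load(path.read_text())["targets"]
        except (OSError, KeyError, yaml.YAMLError) as exc:
            raise DatabaseError(f"cannot load target database {path}: {exc}") from exc
        targets, aliases = [], {}
        for entry in raw:
            try:
                spec = TargetSpec(
                    name=entry["name"],
                    application_class=entry["application_class"],
                    warnings=entry.get("warnings", []),
                )
            except Exception as exc:
                raise DatabaseError(f"invalid target entry {entry!r}: {exc}") from exc
            targets.append(spec)
            for alias in entry.get("aliases", []):
                aliases[str(alias)] = spec.name
        if len({t.name.lower() for t in targets}) != len(targets):
            raise DatabaseError("duplicate target names in database")
        return cls(targets, aliases)

    def lookup(self, target_name: str) -> TargetSpec:
        """Resolve a target by canonical name or alias (case-insensitive)."""
        key = target_name.strip().lower()
        if key in self._index:
            return self.targets[self._index[key]]
        raise UnknownTargetError(target_name, _suggest(key, self._index))

    def __len__(self) -> int:
        return len(self.targets)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "target": t.name,
                "application_class": t.application_class.value,
                "f_target": t.f_target,
                "warnings": ";".join(t.warnings),
            }
            for t in self.targets.values()
        )


class LadDatabase:
    """Leaf area density table indexed by cultivar group × pruning level.

    Monotonicity is enforced on load: for a fixed cultivar group, LAD grows
    from severe pruning to no pruning; for a fixed pruning level, LAD grows
    from low- to high-density cultivars.
    """

    _GROUP_ORDER = [CultivarGroup.LOW, CultivarGroup.MEDIUM, CultivarGroup.HIGH]
    _PRUNING_ORDER = [
        PruningLevel.SEVERE,
        PruningLevel.NORMAL,
        PruningLevel.WITHOUT_PRUNING,
    ]

    def __init__(self, entries: list[LadEntry]):
        self._table: dict[tuple[CultivarGroup, PruningLevel], float] = {
            (e.cultivar_group, e.pruning): e.lad for e in entries
        }
        self._validate()

    def _validate(self) -> None:
        expected = {(g, p) for g in self._GROUP_ORDER for p in self._PRUNING_ORDER}
        if set(self._table) != expected:
            missing = expected - set(self._table)
            raise DatabaseError(f"LAD table incomplete; missing {sorted(missing)!r}")
        for g in self._GROUP_ORDER:
            row = [self._table[(g, p)] for p in self._PRUNING_ORDER]
            if not all(a < b for a, b in zip(row, row[1:])):
                raise DatabaseError(
                    f"LAD not strictly increasing with pruning relaxation for {g.value}"
                )
        for p in self._PRUNING_ORDER:
            col = [self._table[(g, p)] for g in self._GROUP_ORDER]
            if not all(a < b for a, b in zip(col, col[1:])):
                raise DatabaseError(
                    f"LAD not strictly increasing with cultivar density for {p.value}"
                )

    @classmethod
    def load(cls, path: Optional[PathLike] = None) -> "LadDatabase":
        path = Path(path) if path is not None else _data_path("lad.csv")
        try:
            df = pd.read_csv(path)
        except Exception as exc:
            raise DatabaseError(f"cannot load LAD table {path}: {exc}") from exc
        required = {"cultivar_group", "pruning", "lad"}
        if not required.issubset(df.columns):
            raise DatabaseError(f"LAD table must have columns {sorted(required)}")
        try:
            entries = [
                LadEntry(
                    cultivar_group=r.cultivar_group, pruning=r.pruning, lad=r.lad
                )
                for r in df.itertuples()
            ]
        except Exception as exc:
            raise DatabaseError(f"invalid LAD entry: {exc}") from exc
        return cls(entries)

    def lookup(
        self,
        cultivar_group: Union[CultivarGroup, str],
        pruning: Union[PruningLevel, str],
    ) -> float:
        """Return LAD (m² leaf / m³ canopy) for a group × pruning combination."""
        try:
            g = CultivarGroup(cultivar_group)
        except ValueError:
            raise DatabaseError(
                f"invalid cultivar group {cultivar_group!r}; "
                f"allowed: {[x.value for x in CultivarGroup]}"
            ) from None
        try:
            p = PruningLevel(pruning)
        except ValueError:
            raise DatabaseError(
                f"invalid pruning level {pruning!r}; "
                f"allowed: {[x.value for x in PruningLevel]}"
            ) from None
        return self._table[(g, p)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cultivar_group": g.value, "pruning": p.value, "lad": lad}
            for (g, p), lad in sorted(
                self._table.items(),
                key=lambda kv: (
                    self._GROUP_ORDER.index(kv[0][0]),
                    self._PRUNING_ORDER.index(kv[0][1]),
                ),
            )
        )


class ProductRegistry:
    """Active-ingredient registry resolving the required deposit."""

    def __init__(self, products: list[ProductSpec], aliases: dict[str, str]):
        self.products = {p.active_ingredient: p for p in products}
        self._index = {p.active_ingredient.lower(): p.active_ingredient for p in products}
        for alias, canonical in aliases.items():
            self._index[alias.lower()] = canonical

    @classmethod
    def load(cls, path: Optional[PathLike] = None) -> "ProductRegistry":
        path = Path(path) if path is not None else _data_path("products.yaml")
        try:
            raw = yaml.safe_load(path.read_text())["products"]
        except (OSError, KeyError, yaml.YAMLError) as exc:
            raise DatabaseError(f"cannot load product registry {path}: {exc}") from exc
        products, aliases = [], {}
        for entry in raw:
            try:
                spec = ProductSpec(
                    active_ingredient=entry["active_ingredient"],
                    moa_class=entry["moa_class"],
                    label_warnings=entry.get("label_warnings", []),
                )
            except Exception as exc:
                raise DatabaseError(f"invalid product entry {entry!r}: {exc}") from exc
            products.append(spec)
            for alias in entry.get("aliases", []):
                aliases[str(alias)] = spec.active_ingredient
        return cls(products, aliases)

    def lookup(
        self,
        active_ingredient_or_class: str,
        moa_class: Optional[Union[MoaClass, str]] = None,
    ) -> ProductSpec:
        """Resolve a product by ingredient name, MoA class name, or override.

        An explicit ``moa_class`` lets unknown ingredients through with the
        class's reference deposit.
        """
        key = active_ingredient_or_class.strip().lower()
        if moa_class is not None:
            return ProductSpec(
                active_ingredient=active_ingredient_or_class,
                moa_class=MoaClass(moa_class),
            )
        if key in self._index:
            return self.products[self._index[key]]
        try:  # the class name itself is accepted ("contact", "suffocating")
            cls_ = MoaClass(key)
        except ValueError:
            raise UnknownProductError(
                active_ingredient_or_class, _suggest(key, self._index)
            ) from None
        return ProductSpec(active_ingredient=cls_.value, moa_class=cls_)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "active_ingredient": p.active_ingredient,
                "moa_class": p.moa_class.value,
                "deposit_uL_cm2": p.deposit,
            }
            for p in self.products.values()
        )


class CultivarRegistry:
    """Cultivar name → density group, with explicit-group override."""

    def __init__(self, mapping: dict[str, CultivarGroup]):
        self._index = {k.lower(): v for k, v in mapping.items()}

    @classmethod
    def load(cls, path: Optional[PathLike] = None) -> "CultivarRegistry":
        path = Path(path) if path is not None else _data_path("cultivars.yaml")
        try:
            raw = yaml.safe_load(path.read_text())["cultivars"]
        except (OSError, KeyError, yaml.YAMLError) as exc:
            raise DatabaseError(f"cannot load cultivar registry {path}: {exc}") from exc
        mapping: dict[str, CultivarGroup] = {}
        for group, names in raw.items():
            g = CultivarGroup(group)
            for name in names:
                mapping[str(name)] = g
        return cls(mapping)

    def lookup(self, cultivar: str) -> CultivarGroup:
        key = cultivar.strip().lower()
        try:  # a group name is accepted directly
            return CultivarGroup(key)
        except ValueError:
            pass
        if key in self._index:
            return self._index[key]
        raise UnknownCultivarError(cultivar, _suggest(key, self._index))


def load_all(
    targets: Optional[PathLike] = None,
    lad: Optional[PathLike] = None,
    products: Optional[PathLike] = None,
    cultivars: Optional[PathLike] = None,
) -> tuple[TargetDatabase, LadDatabase, ProductRegistry, CultivarRegistry]:
    """Load (and validate) all four reference databases."""
    return (
        TargetDatabase.load(targets),
        LadDatabase.load(lad),
        ProductRegistry.load(products),
        CultivarRegistry.load(cultivars),
    )
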