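"""Ingestion and preparation of species-level enzyme kinetic trait tables.

The table holds one row per species with the rubisco kinetic traits used
throughout the package:

``sco``
    CO2/O2 specificity :math:`S_{C/O}` (mol mol^-1).
``kcatc``
    Maximum carboxylase turnover per active site (s^-1).
``kc`` / ``ko``
    Michaelis constants for CO2 and O2 (uM).
``kc_air``
    Derived Michaelis constant for CO2 in 20.95 % O2 air,
    :math:`K_C (1 + [O_2]/K_O)` (uM).
``krubp``
    Michaelis constant for RuBP (uM), sparsely measured.

Preparation follows a fixed order: specificity normalization across assay
methods -> duplicate collapsing -> ``kc_air`` derivation -> complete-case
filtering -> log transform.  Each step appends to the table's provenance
list, and the log transform may run exactly once.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: kinetic-trait columns, in canonical order
KINETIC_TRAITS = ("sco", "kcatc", "kc", "ko", "krubp", "kc_air")

#: the four principal traits the angiosperm analysis requires
PRINCIPAL_TRAITS = ("sco", "kcatc", "kc", "ko")

#: dissolved O2 concentration (uM) equivalent to 20.95 % O2 air
O2_AIR_UM = 253.0

#: non-trait columns carried through the pipeline
META_COLUMNS = ("species", "group", "ptype", "sco_method", "source_id")

DEFAULT_SCHEMA = {c: c for c in META_COLUMNS + KINETIC_TRAITS if c != "kc_air"}

PTYPE_LEVELS = ("C3", "C3-C4", "C4-like", "C4")


class SchemaError(ValueError):
    """A required column is absent from the input file."""


class ValidationError(ValueError):
    """A cell violates a table invariant (e.g. a non-positive kinetic value)."""


class StateError(RuntimeError):
    """An operation was applied in the wrong pipeline state."""


@dataclass(frozen=True)
class TraitTable:
    """Species x kinetic-trait table with provenance.

    Parameters
    ----------
    data : pandas.DataFrame
        One row per (species, measurement); columns are `META_COLUMNS` plus
        any subset of `KINETIC_TRAITS`.  Missing values are NaN.
    log_space : bool
        True once kinetic columns hold natural logarithms.
    provenance : tuple of str
        Ordered record of the transformations applied.
    """

    data: pd.DataFrame
    log_space: bool = False
    provenance: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if "species" not in self.data.columns:
            raise SchemaError("trait table must have a 'species' column")

    def _with(self, data: pd.DataFrame, note: str, **kw) -> "TraitTable":
        return replace(self, data=data.reset_index(drop=True),
                       provenance=self.provenance + (note,), **kw)

    @property
    def traits(self) -> tuple[str, ...]:
        return tuple(t for t in KINETIC_TRAITS if t in self.data.columns)

    @property
    def species(self) -> list[str]:
        return list(self.data["species"])

    def __len__(self) -> int:
        return len(self.data)

    def trait_vector(self, trait: str, species: list[str] | None = None) -> pd.Series:
        """Return one trait as a Series indexed by species, dropping NaN."""
        s = self.data.set_index("species")[trait].dropna()
        if species is not None:
            s = s.loc[[sp for sp in species if sp in s.index]]
        return s

    def subset(self, mask: pd.Series, note: str) -> "TraitTable":
        return self._with(self.data.loc[mask], note)

    def to_csv(self, path) -> None:
        """Write the table with the provenance as a ``#`` comment header."""
        with open(path, "w") as fh:
            fh.write(f"# log_space={self.log_space}\n")
            for step in self.provenance:
                fh.write(f"# {step}\n")
            self.data.to_csv(fh, index=False)


def _validate_positive(df: pd.DataFrame, path: str = "<memory>") -> None:
    for col in KINETIC_TRAITS:
        if col not in df.columns:
            continue
        bad = df.index[df[col].notna() & (df[col] <= 0)]
        if len(bad):
            row = int(bad[0])
            raise ValidationError(
                f"{path}: non-positive value for '{col}' in row {row} "
                f"(species {df.loc[row, 'species']!r}): {df.loc[row, col]!r}"
            )


def load_trait_table(path, schema: dict[str, str] | None = None) -> TraitTable:
    """Read a kinetic-trait CSV into a :class:`TraitTable`.

    Parameters
    ----------
    path : str or Path
        CSV with a header row; empty cells or "NA" mark missing values.
    schema : dict, optional
        Mapping from canonical column names (``species``, ``sco`` ...) to
        the column names used in the file.  Unmapped optional columns are
        simply absent from the result.
    """
    schema = dict(DEFAULT_SCHEMA if schema is None else schema)
    df = pd.read_csv(path, comment="#", na_values=["NA", ""], skipinitialspace=True)
    required = {"species"}
    rename = {}
    for canon, raw in schema.items():
        if raw in df.columns:
            rename[raw] = canon
        elif canon in required:
            raise SchemaError(f"{path}: required column {raw!r} not found")
    df = df.rename(columns=rename)
    keep = [c for c in META_COLUMNS + KINETIC_TRAITS if c in df.columns]
    df = df[keep].copy()
    for col in KINETIC_TRAITS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise")
    _validate_positive(df, str(path))
    return TraitTable(df.reset_index(drop=True),
                      provenance=(f"loaded from {path} ({len(df)} rows)",))


def normalize_sco(table: TraitTable, wheat_reference: float,
                  wheat_by_study: dict[str, float]) -> TraitTable:
    """Bring O2-electrode specificity values onto the gas-phase assay scale.

    Rubisco from wheat was assayed by both methods, so each electrode
    study's values are rescaled by ``wheat_reference / study_wheat``;
    gas-phase rows are left untouched and define the reference frame.
    """
    if any(step.startswith("normalize_sco") for step in table.provenance):
        return table  # idempotent once applied
    if wheat_reference <= 0 or any(v <= 0 for v in wheat_by_study.values()):
        raise ValidationError("wheat standard values must be positive")
    df = table.data.copy()
    electrode = df.get("sco_method", pd.Series(index=df.index, dtype=object)) == "electrode"
    electrode &= df["sco"].notna()
    studies = set(df.loc[electrode, "source_id"].dropna().astype(str))
    unknown = sorted(studies - set(map(str, wheat_by_study)))
    if unknown or df.loc[electrode, "source_id"].isna().any():
        raise ValidationError(
            "electrode-method rows with no wheat standard for studies: "
            + ", ".join(unknown or ["<missing source_id>"])
        )
    wheat = {str(k): float(v) for k, v in wheat_by_study.items()}
    if electrode.any():
        mult = df.loc[electrode, "source_id"].astype(str).map(
            lambda s: wheat_reference / wheat[s])
        df.loc[electrode, "sco"] = df.loc[electrode, "sco"] * mult
    return table._with(
        df, f"normalize_sco: {int(electrode.sum())} electrode rows rescaled "
            f"to wheat reference {wheat_reference}")


def derive_kc_air(kc: float, ko: float, o2_um: float = O2_AIR_UM) -> float:
    """KC in 20.95 % O2 air: ``kc + kc * o2 / ko``.  NaN in -> NaN out."""
    if kc is None or ko is None or math.isnan(kc) or math.isnan(ko):
        return float("nan")
    if kc <= 0 or ko <= 0:
        raise ValidationError(f"kc and ko must be positive (got {kc}, {ko})")
    return kc + kc * o2_um / ko


def add_kc_air(table: TraitTable, o2_um: float = O2_AIR_UM) -> TraitTable:
    """Record-wise `derive_kc_air` over the table (raw space only)."""
    if table.log_space:
        raise StateError("kc_air must be derived before the log transform")
    df = table.data.copy()
    df["kc_air"] = [derive_kc_air(kc, ko, o2_um)
                    for kc, ko in zip(df["kc"], df["ko"])]
    return table._with(df, f"derive_kc_air: o2_um={o2_um}")


def collapse_duplicates(table: TraitTable,
                        synonyms: dict[str, str] | None = None) -> TraitTable:
    """Collapse duplicate species rows to per-trait medians.

    `synonyms` maps alias names to canonical ones before grouping, so that
    e.g. a synthetic polyploid and its progenitor merge into one record.
    Medians are taken per trait over the non-missing duplicate values.
    """
    if table.log_space:
        raise StateError("duplicates are collapsed before the log transform")
    df = table.data.copy()
    if synonyms:
        df["species"] = df["species"].map(lambda s: synonyms.get(s, s))
    traits = [t for t in KINETIC_TRAITS if t in df.columns]
    meta = [c for c in META_COLUMNS if c in df.columns and c != "species"]
    agg = {t: "median" for t in traits}
    agg.update({c: "first" for c in meta})
    n_dups = len(df) - df["species"].nunique()
    out = df.groupby("species", sort=False, as_index=False).agg(agg)
    return table._with(out[["species"] + meta + traits],
                       f"collapse_duplicates: {n_dups} duplicate rows merged")


def complete_case_filter(table: TraitTable, required: set[str] | tuple,
                         group: str | None = None) -> TraitTable:
    """Keep records measured for every trait in `required`.

    An optional taxonomic `group` restriction (matching the ``group``
    column) is applied first.  An empty result is a warning, not an error.
    """
    unknown = set(required) - set(KINETIC_TRAITS)
    if unknown:
        raise ValidationError(f"unknown trait names: {sorted(unknown)}")
    mask = pd.Series(True, index=table.data.index)
    if group is not None:
        mask &= table.data["group"] == group
    for trait in required:
        mask &= table.data[trait].notna() if trait in table.data.columns \
            else False
    note = (f"complete_case_filter: required={sorted(required)} "
            f"group={group} -> {int(mask.sum())} records")
    logger.info(note)
    if mask.sum() == 0:
        logger.warning("complete_case_filter produced an empty table")
    return table.subset(mask, note)


def log_transform(table: TraitTable) -> TraitTable:
    """Natural-log transform every kinetic column; may run exactly once."""
    if table.log_space:
        raise StateError("table is already log transformed")
    df = table.data.copy()
    _validate_positive(df)
    for col in table.traits:
        df[col] = np.log(df[col])
    return table._with(df, "log_transform: natural log", log_space=True)
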