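"""Species-level trait table: records, CSV I/O and derived traits.

The packaged study fixture (``load_study_fixture``) holds the 39-species
table of fitted p50 longevities with family/order taxonomy, endosperm
class (E/N) and dormancy class (ND/PD/PY). Continuous traits (thousand
seed weight, seed dimensions, seed-coat thickness) are optional columns;
missing values are carried explicitly (``NA``), never silently zeroed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from seedspan.errors import InvalidInputError, SchemaError

logger = logging.getLogger(__name__)

ENDOSPERM_LEVELS = frozenset({"E", "N"})
DORMANCY_LEVELS = frozenset({"ND", "PD", "PY"})
PRETREATMENT_LEVELS = frozenset({"SCAR", "STRAT", "GA3", "none"})

#: maximum possible seed-shape variance (needle limit: dims -> (1, 0, 0))
VS_MAX = 2.0 / 9.0

REQUIRED_COLUMNS = ("species", "family", "order", "endosperm", "dormancy", "p50", "p50_se")
CONTINUOUS_COLUMNS = ("tsw_mg", "length_mm", "width_mm", "height_mm", "vs", "mct_mm")
MISSING_TOKEN = "NA"


@dataclass(frozen=True)
class SpeciesRecord:
    """One species row: taxonomy, categorical seed traits and fitted p50."""

    species_id: str
    family: str
    order: str
    endosperm: str  # E | N
    dormancy: str  # ND | PD | PY
    p50_days: float
    p50_se: float
    pretreatment: Optional[str] = None
    germ_temp: Optional[str] = None
    rank: Optional[int] = None

    def __post_init__(self) -> None:
        if self.endosperm not in ENDOSPERM_LEVELS:
            raise SchemaError(f"{self.species_id}: unknown endosperm level {self.endosperm!r}")
        if self.dormancy not in DORMANCY_LEVELS:
            raise SchemaError(f"{self.species_id}: unknown dormancy level {self.dormancy!r}")
        if self.pretreatment is not None and self.pretreatment not in PRETREATMENT_LEVELS:
            raise SchemaError(
                f"{self.species_id}: unknown pretreatment level {self.pretreatment!r}"
            )
        if not (self.p50_days > 0):
            raise SchemaError(f"{self.species_id}: p50 must be positive, got {self.p50_days}")
        if self.p50_se < 0:
            raise SchemaError(f"{self.species_id}: p50 SE must be non-negative")


@dataclass(frozen=True)
class ContinuousTraits:
    """Optional continuous seed traits for one species; None marks missing."""

    species_id: str
    tsw_mg: Optional[float] = None
    length_mm: Optional[float] = None
    width_mm: Optional[float] = None
    height_mm: Optional[float] = None
    vs: Optional[float] = None
    mct_mm: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("tsw_mg", "length_mm", "width_mm", "height_mm", "mct_mm"):
            v = getattr(self, name)
            if v is not None and not (v > 0):
                raise SchemaError(f"{self.species_id}: {name} must be positive, got {v}")
        if self.vs is not None and not (0 <= self.vs <= VS_MAX + 1e-12):
            raise SchemaError(f"{self.species_id}: vs out of [0, 2/9]: {self.vs}")


@dataclass
class TraitTable:
    """Validated species table plus optional continuous traits."""

    records: list[SpeciesRecord]
    continuous: list[ContinuousTraits] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def species(self) -> list[str]:
        return [r.species_id for r in self.records]

    def record(self, species_id: str) -> SpeciesRecord:
        for r in self.records:
            if r.species_id == species_id:
                return r
        raise KeyError(species_id)

    def category_counts(self) -> dict[str, dict[str, int]]:
        counts: dict[str, dict[str, int]] = {"endosperm": {}, "dormancy": {}, "order": {}}
        for r in self.records:
            for key, val in (("endosperm", r.endosperm), ("dormancy", r.dormancy), ("order", r.order)):
                counts[key][val] = counts[key].get(val, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        cont = {c.species_id: c for c in self.continuous}
        rows = []
        for r in self.records:
            row = {
                "species": r.species_id,
                "family": r.family,
                "order": r.order,
                "endosperm": r.endosperm,
                "pretreatment": r.pretreatment,
                "dormancy": r.dormancy,
                "germ_temp": r.germ_temp,
                "p50": r.p50_days,
                "p50_se": r.p50_se,
                "rank": r.rank,
            }
            c = cont.get(r.species_id)
            for name in CONTINUOUS_COLUMNS:
                row[name] = getattr(c, name) if c is not None else None
            rows.append(row)
        return pd.DataFrame(rows)


def seed_shape_variance(length: float, width: float, height: float) -> float:
    """Population variance (n=3) of seed dimensions scaled by the longest axis.

    Dimensions are divided by the largest of the three, so the reference axis
    contributes exactly 1; the result is dimensionless in [0, 2/9], 0 for a
    perfectly round seed, approaching 2/9 for a needle.
    """
    dims = (length, width, height)
    if any(not (d > 0) or not math.isfinite(d) for d in dims):
        raise InvalidInputError(f"all seed dimensions must be positive, got {dims}")
    if length < max(dims):
        logger.warning(
            "length (%g) is not the largest dimension of %s; reordering descending", length, dims
        )
    ordered = sorted(dims, reverse=True)
    x = np.asarray(ordered, dtype=float) / ordered[0]
    return float(np.mean((x - x.mean()) ** 2))


def log10_trait(value: float) -> float:
    """Base-10 log transform; refuses non-positive input instead of yielding NaN."""
    if not (value > 0) or not math.isfinite(value):
        raise InvalidInputError(f"log10 transform requires a positive value, got {value}")
    return math.log10(value)


def _parse_optional_float(raw: object, column: str, row_label: str) -> Optional[float]:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    s = str(raw).strip()
    if s in ("", MISSING_TOKEN):
        return None
    try:
        return float(s)
    except ValueError as exc:
        raise SchemaError(f"row {row_label}: column {column!r} not numeric: {raw!r}") from exc


def load_trait_table(path: str | Path) -> TraitTable:
    """Read and validate a species trait table from CSV.

    Required columns: species, family, order, endosperm, dormancy, p50,
    p50_se. Optional: pretreatment, germ_temp, rank, and the continuous
    trait columns. Raises :class:`SchemaError` naming the offending
    row/column on any violation.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        raise SchemaError(f"{path}: no data rows")

    records: list[SpeciesRecord] = []
    continuous: list[ContinuousTraits] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        label = f"{i + 2} ({row['species']})"  # +2: header + 1-based
        sp = str(row["species"]).strip()
        if not sp:
            raise SchemaError(f"row {label}: empty species name")
        if sp in seen:
            raise SchemaError(f"row {label}: duplicate species {sp!r}")
        seen.add(sp)
        pre = str(row.get("pretreatment", "")).strip() or None
        if pre in ("", "-", "–", MISSING_TOKEN):
            pre = None
        rank_raw = str(row.get("rank", "")).strip()
        rank = int(rank_raw) if rank_raw not in ("", MISSING_TOKEN) else None
        p50 = _parse_optional_float(row["p50"], "p50", label)
        p50_se = _parse_optional_float(row["p50_se"], "p50_se", label)
        if p50 is None or p50_se is None:
            raise SchemaError(f"row {label}: p50 and p50_se are required")
        records.append(
            SpeciesRecord(
                species_id=sp,
                family=str(row["family"]).strip(),
                order=str(row["order"]).strip(),
                endosperm=str(row["endosperm"]).strip(),
                pretreatment=pre,
                dormancy=str(row["dormancy"]).strip(),
                germ_temp=str(row.get("germ_temp", "")).strip() or None,
                p50_days=p50,
                p50_se=p50_se,
                rank=rank,
            )
        )
        cont_kwargs = {
            name: _parse_optional_float(row.get(name), name, label)
            for name in CONTINUOUS_COLUMNS
            if name in df.columns
        }
        if any(v is not None for v in cont_kwargs.values()):
            continuous.append(ContinuousTraits(species_id=sp, **cont_kwargs))

    table = TraitTable(records=records, continuous=continuous)
    logger.info("loaded %d species from %s; counts %s", len(table), path, table.category_counts())
    return table


def write_trait_table(table: TraitTable, path: str | Path) -> None:
    """Write a trait table back to CSV (missing values as ``NA``)."""
    df = table.to_frame()
    # drop all-missing optional columns so load->write round-trips cleanly
    for col in list(df.columns):
        if col in CONTINUOUS_COLUMNS and df[col].isna().all():
            df = df.drop(columns=col)
    df.to_csv(path, index=False, na_rep=MISSING_TOKEN)


def load_study_fixture() -> TraitTable:
    """Load the packaged 39-species study table (taxonomy, traits, p50)."""
    with resources.as_file(resources.files("seedspan.data") / "table1.csv") as p:
        return load_trait_table(p)


def packaged_node_ages_path() -> Path:
    """Path to the packaged order/family node-age table (Myr, user-replaceable)."""
    return Path(str(resources.files("seedspan.data") / "node_ages.csv"))


def rank_by_p50(records: Sequence[SpeciesRecord]) -> list[SpeciesRecord]:
    """Return records with rank assigned: 1 = largest p50, ties broken by name."""
    ordered = sorted(records, key=lambda r: (-r.p50_days, r.species_id))
    p50s = [r.p50_days for r in ordered]
    if len(set(p50s)) != len(p50s):
        logger.warning("tied p50 values; ranks broken alphabetically by species")
    ranked = {r.species_id: i + 1 for i, r in enumerate(ordered)}
    return [
        SpeciesRecord(
            species_id=r.species_id,
            family=r.family,
            order=r.order,
            endosperm=r.endosperm,
            pretreatment=r.pretreatment,
            dormancy=r.dormancy,
            germ_temp=r.germ_temp,
            p50_days=r.p50_days,
            p50_se=r.p50_se,
            rank=ranked[r.species_id],
        )
        for r in records
    ]


def build_analysis_matrix(table: TraitTable) -> pd.DataFrame:
    """Per-species model matrix: log10 p50 response plus predictors.

    Columns: species (index), log10_p50, non_endospermic, py, pd and, when
    the corresponding continuous trait is present, log10_tsw / log10_vs /
    log10_mct (NaN where missing; model fitting drops incomplete rows and
    reports the retained n).
    """
    cont = {c.species_id: c for c in table.continuous}
    rows = []
    for r in table.records:
        c = cont.get(r.species_id)
        vs = c.vs if c is not None else None
        if vs is None and c is not None and None not in (c.length_mm, c.width_mm, c.height_mm):
            vs = seed_shape_variance(c.length_mm, c.width_mm, c.height_mm)
        rows.append(
            {
                "species": r.species_id,
                "log10_p50": log10_trait(r.p50_days),
                "non_endospermic": 1 if r.endosperm == "N" else 0,
                "py": 1 if r.dormancy == "PY" else 0,
                "pd": 1 if r.dormancy == "PD" else 0,
                "log10_tsw": log10_trait(c.tsw_mg) if c is not None and c.tsw_mg else np.nan,
                "log10_vs": log10_trait(vs) if vs else np.nan,
                "log10_mct": log10_trait(c.mct_mm) if c is not None and c.mct_mm else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("species")
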