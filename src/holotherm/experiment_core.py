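"""Shared data model for the crossed thermal-stress experiment.

The experiment crosses two holobionts (``PdC`` — *Pocillopora damicornis*
dominated by *Cladocopium*; ``PdD`` — the same host dominated by
*Durusdinium*) with two temperature arms (26 °C control, 32 °C heated).
Per holobiont, three parental colonies are fragmented into ramets and
distributed over six tanks, three per arm.  All assay tables are long
(tidy) one-row-per-measurement CSV files keyed by a composite fragment
identifier ``"<holobiont>-<colony>-<tank>-<index>"``.

Units are fixed at load time: mass in g, area in cm², density in
cells·cm⁻², isotope values in ‰ vs VPDB, qPCR in CT cycles.  Missing
values are empty cells (NaN in memory), never sentinel numbers.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HOLOBIONTS = ("PdC", "PdD")
CONTROL_TEMPERATURE = 26.0
HEAT_TEMPERATURE = 32.0
ARMS = ("control", "heat")

CENSUS_STATUSES = ("healthy", "bleached", "removed")
QPCR_PRIMERS = ("C", "D")
ISOTOPE_FRACTIONS = ("host", "symbiont")
CLONE_STAGES = ("pretreatment", "end")


class SchemaError(ValueError):
    """A table is missing a required column or has the wrong layout."""


class IntegrityError(ValueError):
    """A record references a fragment absent from the design."""


class ValidationError(ValueError):
    """A value violates a type invariant (range, enum, positivity)."""


#: required columns per CSV table, in canonical order
TABLE_SCHEMAS: dict[str, list[str]] = {
    "design": ["fragment_id", "holobiont", "colony", "tank", "temperature"],
    "pam": ["fragment_id", "day", "phase", "replicate", "yield"],
    "weights": ["fragment_id", "day", "buoyant_weight_g", "surface_area_cm2"],
    "counts": [
        "fragment_id",
        "day",
        "chamber_count",
        "dilution_factor",
        "slurry_volume_ml",
        "surface_area_cm2",
        "replicate",
    ],
    "census": ["fragment_id", "day", "status"],
    "qpcr": ["fragment_id", "day", "primer", "replicate", "ct"],
    "isotopes": [
        "fragment_id",
        "fraction",
        "labeled",
        "delta13c_permil",
        "organic_carbon_ug",
    ],
    "clones": ["fragment_id", "stage", "its2_type", "clone_count"],
}

#: key columns used to order rows for comparison / round-trip equality
_SORT_KEYS: dict[str, list[str]] = {
    "design": ["fragment_id"],
    "pam": ["fragment_id", "day", "phase", "replicate"],
    "weights": ["fragment_id", "day"],
    "counts": ["fragment_id", "day", "replicate"],
    "census": ["fragment_id", "day"],
    "qpcr": ["fragment_id", "day", "primer", "replicate"],
    "isotopes": ["fragment_id", "fraction", "labeled"],
    "clones": ["fragment_id", "stage", "its2_type"],
}


def make_fragment_id(holobiont: str, colony: int, tank: int, index: int) -> str:
    """Compose the unambiguous fragment identifier used in every table."""
    return f"{holobiont}-{colony}-{tank}-{index}"


def empty_table(name: str) -> pd.DataFrame:
    """An empty, schema-conformant table."""
    return pd.DataFrame({c: pd.Series(dtype=object) for c in TABLE_SCHEMAS[name]})


def arm_of_temperature(temperature) -> str:
    """Map a tank temperature (°C) onto its arm label."""
    t = float(temperature)
    if t == CONTROL_TEMPERATURE:
        return "control"
    if t == HEAT_TEMPERATURE:
        return "heat"
    raise ValidationError(f"temperature {t} matches neither arm (26 or 32)")


def design_with_arm(design: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of the design table with an ``arm`` column added."""
    out = design.copy()
    out["arm"] = out["temperature"].map(arm_of_temperature)
    return out


@dataclass
class AssaySet:
    """Bundle of all per-fragment assay tables for one experiment.

    Every record in every sub-table must join to exactly one row of
    ``design`` (design closure).  ``metadata`` carries provenance
    (generator seed, preset name, units) and is round-tripped as JSON.
    """

    design: pd.DataFrame
    pam: pd.DataFrame = field(default_factory=lambda: empty_table("pam"))
    weights: pd.DataFrame = field(default_factory=lambda: empty_table("weights"))
    counts: pd.DataFrame = field(default_factory=lambda: empty_table("counts"))
    census: pd.DataFrame = field(default_factory=lambda: empty_table("census"))
    qpcr: pd.DataFrame = field(default_factory=lambda: empty_table("qpcr"))
    isotopes: pd.DataFrame = field(default_factory=lambda: empty_table("isotopes"))
    clones: pd.DataFrame = field(default_factory=lambda: empty_table("clones"))
    metadata: dict = field(default_factory=dict)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in TABLE_SCHEMAS}

    # -- validation ----------------------------------------------------

    def validate(self) -> "AssaySet":
        """Check schemas, design invariants and foreign keys; return self.

        Raises :class:`SchemaError`, :class:`IntegrityError` or
        :class:`ValidationError` on the first violation found.
        """
        for name, table in self.tables().items():
            missing = [c for c in TABLE_SCHEMAS[name] if c not in table.columns]
            if missing:
                raise SchemaError(f"table '{name}' is missing column(s) {missing}")

        design = self.design
        if design.empty:
            raise ValidationError("design table is empty")
        if design["fragment_id"].duplicated().any():
            dups = design.loc[design["fragment_id"].duplicated(), "fragment_id"]
            raise IntegrityError(f"duplicate fragment ids in design: {sorted(set(dups))}")
        bad_hb = set(design["holobiont"]) - set(HOLOBIONTS)
        if bad_hb:
            raise ValidationError(f"unknown holobiont label(s) {sorted(bad_hb)}")
        for t in design["temperature"]:
            arm_of_temperature(t)  # raises on anything but 26/32
        # each tank belongs to exactly one temperature arm per holobiont
        arms = design.groupby(["holobiont", "tank"])["temperature"].nunique()
        mixed = arms[arms > 1]
        if not mixed.empty:
            raise IntegrityError(
                f"tank(s) assigned to more than one temperature arm: {list(mixed.index)}"
            )
        # each fragment in exactly one colony and one tank — guaranteed by
        # fragment_id uniqueness plus one design row per fragment.

        known = set(design["fragment_id"])
        for name, table in self.tables().items():
            if name == "design" or table.empty:
                continue
            orphan = ~table["fragment_id"].isin(known)
            if orphan.any():
                rows = table.index[orphan].tolist()[:10]
                ids = sorted(set(table.loc[orphan, "fragment_id"]))[:10]
                raise IntegrityError(
                    f"table '{name}' references fragment(s) absent from design "
                    f"{ids} (rows {rows})"
                )

        if not self.pam.empty:
            y = pd.to_numeric(self.pam["yield"], errors="coerce")
            bad = (y < 0) | (y > 1) | y.isna()
            if bad.any():
                raise ValidationError(
                    f"pam yields outside [0, 1] (or non-numeric) at rows "
                    f"{self.pam.index[bad].tolist()[:10]}"
                )
            if not set(self.pam["phase"]) <= {"dark", "light"}:
                raise ValidationError("pam phase must be 'dark' or 'light'")
        else:
            logger.warning("pam table is empty")

        if not self.weights.empty:
            if (self.weights["buoyant_weight_g"] <= 0).any():
                raise ValidationError("buoyant weights must be > 0")
            if (self.weights["surface_area_cm2"] <= 0).any():
                raise ValidationError("surface areas must be > 0")
        if not self.counts.empty:
            if (self.counts["chamber_count"] < 0).any():
                raise ValidationError("chamber counts must be >= 0")
            for col in ("dilution_factor", "slurry_volume_ml", "surface_area_cm2"):
                if (self.counts[col] <= 0).any():
                    raise ValidationError(f"counts.{col} must be > 0")
        if not self.census.empty:
            bad = set(self.census["status"]) - set(CENSUS_STATUSES)
            if bad:
                raise ValidationError(f"unknown census status {sorted(bad)}")
        if not self.qpcr.empty:
            bad = set(self.qpcr["primer"]) - set(QPCR_PRIMERS)
            if bad:
                raise ValidationError(f"unknown qPCR primer {sorted(bad)}")
            ct = pd.to_numeric(self.qpcr["ct"], errors="coerce")
            if (ct <= 0).any():  # NaN (non-detect) passes
                raise ValidationError("detected CT values must be > 0")
        if not self.isotopes.empty:
            bad = set(self.isotopes["fraction"]) - set(ISOTOPE_FRACTIONS)
            if bad:
                raise ValidationError(f"unknown isotope fraction {sorted(bad)}")
            if (self.isotopes["organic_carbon_ug"] <= 0).any():
                raise ValidationError("organic carbon must be > 0")
        if not self.clones.empty:
            bad = set(self.clones["stage"]) - set(CLONE_STAGES)
            if bad:
                raise ValidationError(f"unknown clone-library stage {sorted(bad)}")
            if (self.clones["clone_count"] < 0).any():
                raise ValidationError("clone counts must be >= 0")
        return self

    # -- comparison ----------------------------------------------------

    def equals(self, other: "AssaySet", tol: float = 1e-9) -> bool:
        """Field-wise equality up to ``tol`` on numeric columns.

        Rows are compared after sorting by each table's key columns, so
        storage order is irrelevant.
        """
        for name in TABLE_SCHEMAS:
            a = _canonical(getattr(self, name), name)
            b = _canonical(getattr(other, name), name)
            if len(a) != len(b):
                return False
            if a.empty:
                continue
            for col in TABLE_SCHEMAS[name]:
                xa, xb = a[col].to_numpy(), b[col].to_numpy()
                na = pd.to_numeric(a[col], errors="coerce")
                nb = pd.to_numeric(b[col], errors="coerce")
                if na.notna().all() and nb.notna().all():
                    if not np.allclose(na, nb, rtol=0, atol=tol, equal_nan=True):
                        return False
                else:
                    both_nan = na.isna().to_numpy() & nb.isna().to_numpy()
                    num = na.notna().to_numpy() & nb.notna().to_numpy()
                    if num.any() and not np.allclose(
                        na[num], nb[num], rtol=0, atol=tol
                    ):
                        return False
                    rest = ~num & ~both_nan
                    if not (xa[rest] == xb[rest]).all():
                        return False
        return True


def _canonical(table: pd.DataFrame, name: str) -> pd.DataFrame:
    cols = TABLE_SCHEMAS[name]
    out = table.loc[:, cols].copy()
    return out.sort_values(_SORT_KEYS[name], kind="mergesort").reset_index(drop=True)


# -- I/O ---------------------------------------------------------------

_READ_DTYPES = {"fragment_id": str, "holobiont": str, "phase": str, "status": str,
                "primer": str, "fraction": str, "stage": str, "its2_type": str}


def save_assay_set(a: AssaySet, directory: str | Path,
                   float_format: str = "%.17g") -> list[Path]:
    """Write one CSV per table plus ``metadata.json``; return written paths.

    Round-trip guarantee: ``load_assay_set(save_assay_set(a)) == a`` up to
    the floating-point text representation (1e-9 at the default precision).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in a.tables().items():
        path = directory / f"{name}.csv"
        table.loc[:, TABLE_SCHEMAS[name]].to_csv(
            path, index=False, float_format=float_format
        )
        written.append(path)
    meta_path = directory / "metadata.json"
    meta_path.write_text(json.dumps(a.metadata, indent=2, sort_keys=True))
    written.append(meta_path)
    return written


def load_assay_set(directory: str | Path, schema_version: str = "1") -> AssaySet:
    """Load and validate an :class:`AssaySet` from a directory of CSVs.

    Missing optional tables load as empty; a missing ``design.csv`` is a
    schema error.  All tables are validated (schemas, value ranges,
    foreign keys) before the set is returned.
    """
    directory = Path(directory)
    design_path = directory / "design.csv"
    if not design_path.exists():
        raise SchemaError(f"no design.csv in {directory}")
    tables = {}
    for name in TABLE_SCHEMAS:
        path = directory / f"{name}.csv"
        if path.exists():
            tables[name] = pd.read_csv(path, dtype=_READ_DTYPES)
            if tables[name].empty:
                tables[name] = empty_table(name)
        else:
            tables[name] = empty_table(name)
    meta_path = directory / "metadata.json"
    metadata = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    metadata.setdefault("schema_version", schema_version)
    return AssaySet(metadata=metadata, **tables).validate()
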