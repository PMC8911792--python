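"""Data model for factorial extraction experiments and packaged reference tables.

The central container is :class:`ExtractionDataset`: a full-factorial design
over extraction temperature (°C) and ethanol concentration (% v/v) with one
``mean ± sd`` entry per condition for each measured response.  The responses
are the four bioactive-compound yields commonly reported for plant-matrix
extractions:

* TPC — total polyphenol content (mg gallic-acid equivalents / g dry weight)
* TFC — total flavonoid content (mg GAE/g DW)
* TC  — tannin content (mg tannic-acid equivalents / g DW)
* TAC — total anthocyanin content (mg malvidin-3-glucoside equivalents / g DW)

Three reference tables from a grape-marc (wine pomace) extraction study ship
as package data: the 5 × 3 factorial yield table (``table1``), the extract
composition / antioxidant / CIELab table (``table2``) and the antimicrobial
activity table (``table3``).  Simple descriptive operations used downstream —
argmax/argmin over conditions, fold-changes, two-fold dilution series and
composition summaries — live here too.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Literal

import pandas as pd

__all__ = [
    "Condition",
    "ResponseValue",
    "ExtractionDataset",
    "CompositionProfile",
    "CompositionEntry",
    "CompositionSummary",
    "AntimicrobialRecord",
    "DatasetValidationError",
    "load_fixture",
    "read_dataset",
    "write_dataset",
    "extreme_condition",
    "fold_change",
    "dilution_series",
    "composition_summary",
    "round_half_up",
]

RESPONSE_NAMES = ("TPC", "TFC", "TC", "TAC")


class DatasetValidationError(ValueError):
    """Raised when a dataset violates the factorial-design invariants."""


def round_half_up(x: float, decimals: int) -> float:
    """Round with ties away from zero at ``decimals`` places.

    Spreadsheet-style rounding (0.125 → 0.13 at 2 decimals), as opposed to
    banker's rounding used by the builtin :func:`round`.  Reported ratios in
    the reference study match the printed table means only under this rule.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True, order=True)
class Condition:
    """One factorial cell: extraction temperature (°C) and ethanol fraction (% v/v)."""

    temperature: float
    concentration: float

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        if not 0 <= self.concentration <= 96:
            raise ValueError(
                f"ethanol concentration must lie in [0, 96] % v/v, got {self.concentration}"
            )


@dataclass(frozen=True)
class ResponseValue:
    """Replicate mean and standard deviation of one response at one condition."""

    mean: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.mean < 0:
            raise ValueError(f"response mean must be non-negative, got {self.mean}")
        if self.sd < 0:
            raise ValueError(f"response sd must be non-negative, got {self.sd}")


@dataclass
class ExtractionDataset:
    """Full-factorial extraction experiment: conditions × responses.

    Parameters
    ----------
    conditions
        Ordered factorial cells; default ordering is temperature-major
        lexicographic (temperature ascending, concentration ascending within).
    responses
        Mapping ``response name -> list of ResponseValue`` aligned with
        ``conditions``.
    units
        Mapping ``response name -> unit string``.
    annotations
        Optional per-response significance-letter strings (not interpreted).
    """

    conditions: list[Condition]
    responses: dict[str, list[ResponseValue]]
    units: dict[str, str] = field(default_factory=dict)
    annotations: dict[str, list[str]] | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if not self.conditions:
            raise DatasetValidationError("dataset has no conditions")
        if len(set(self.conditions)) != len(self.conditions):
            raise DatasetValidationError("duplicate conditions in dataset")
        n_expected = len(self.temperature_levels) * len(self.concentration_levels)
        if len(self.conditions) != n_expected:
            raise DatasetValidationError(
                f"design is not full factorial: {len(self.conditions)} conditions, "
                f"expected {len(self.temperature_levels)} × "
                f"{len(self.concentration_levels)} = {n_expected}"
            )
        for name, values in self.responses.items():
            if len(values) != len(self.conditions):
                raise DatasetValidationError(
                    f"response {name!r} has {len(values)} values for "
                    f"{len(self.conditions)} conditions"
                )

    # -- convenience ------------------------------------------------------
    @property
    def temperature_levels(self) -> list[float]:
        return sorted({c.temperature for c in self.conditions})

    @property
    def concentration_levels(self) -> list[float]:
        return sorted({c.concentration for c in self.conditions})

    @property
    def response_names(self) -> list[str]:
        return list(self.responses)

    def index_of(self, condition: Condition) -> int:
        try:
            return self.conditions.index(condition)
        except ValueError:
            raise KeyError(f"condition {condition} not in dataset") from None

    def value(self, response: str, condition: Condition) -> ResponseValue:
        return self.responses[response][self.index_of(condition)]

    def to_frame(self) -> pd.DataFrame:
        """Wide table: one row per condition, ``<resp>_mean``/``<resp>_sd`` columns."""
        data: dict[str, list] = {
            "temperature_C": [c.temperature for c in self.conditions],
            "concentration_pct": [c.concentration for c in self.conditions],
        }
        for name, values in self.responses.items():
            data[f"{name}_mean"] = [v.mean for v in values]
            data[f"{name}_sd"] = [v.sd for v in values]
            if self.annotations and name in self.annotations:
                data[f"{name}_note"] = self.annotations[name]
        return pd.DataFrame(data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExtractionDataset):
            return NotImplemented
        return (
            self.conditions == other.conditions
            and self.responses == other.responses
            and self.units == other.units
        )


@dataclass(frozen=True)
class CompositionEntry:
    analyte: str
    category: str  # polyphenol | anthocyanin | organic acid | antioxidant | chromatic
    mean: float
    sd: float
    unit: str


@dataclass
class CompositionProfile:
    """Named-analyte quantity table (individual compounds, assays, color)."""

    entries: list[CompositionEntry]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for e in self.entries:
            if e.category != "chromatic" and e.mean < 0:
                raise ValueError(f"negative mean for {e.analyte}")
            key = (e.category, e.analyte)
            if key in seen:
                raise ValueError(f"duplicate analyte {e.analyte!r} in class {e.category!r}")
            seen.add(key)

    @property
    def categories(self) -> list[str]:
        out: list[str] = []
        for e in self.entries:
            if e.category not in out:
                out.append(e.category)
        return out

    def in_category(self, category: str) -> list[CompositionEntry]:
        sel = [e for e in self.entries if e.category == category]
        if not sel:
            raise KeyError(f"unknown analyte class {category!r}")
        return sel

    def get(self, category: str, analyte: str) -> CompositionEntry:
        for e in self.in_category(category):
            if e.analyte == analyte:
                return e
        raise KeyError(f"no analyte {analyte!r} in class {category!r}")


@dataclass(frozen=True)
class AntimicrobialRecord:
    """Inhibition-zone / MIC / MBC record for one bacterial strain.

    ``mic`` and ``mbc`` are ``(mean, sd)`` in mg/mL, or ``None`` where the
    assay detected no activity ("nd"); absence is never coded as zero so the
    MBC ≥ MIC invariant stays meaningful.
    """

    strain: str
    gram: Literal["positive", "negative"]
    zone_diameter_mm: tuple[float, float]
    mic_mg_per_ml: tuple[float, float] | None = None
    mbc_mg_per_ml: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.gram not in ("positive", "negative"):
            raise ValueError(f"gram must be 'positive' or 'negative', got {self.gram!r}")
        if self.mic_mg_per_ml is not None and self.mbc_mg_per_ml is not None:
            if self.mbc_mg_per_ml[0] < self.mic_mg_per_ml[0]:
                raise ValueError(
                    f"{self.strain}: MBC {self.mbc_mg_per_ml[0]} < MIC {self.mic_mg_per_ml[0]}"
                )


# ---------------------------------------------------------------------------
# fixtures and I/O
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("marcex.data").joinpath(name)


def load_fixture(table_id: str):
    """Load a packaged reference table.

    ``table1`` → :class:`ExtractionDataset` (15-condition factorial yields),
    ``table2`` → :class:`CompositionProfile`,
    ``table3`` → list of :class:`AntimicrobialRecord`.
    """
    if table_id == "table1":
        units = json.loads(_data_path("table1.units.json").read_text())
        with resources.as_file(_data_path("table1.csv")) as p:
            return read_dataset(p, units=units)
    if table_id == "table2":
        with resources.as_file(_data_path("table2.csv")) as p:
            df = pd.read_csv(p, keep_default_na=False)
        entries = [
            CompositionEntry(r["analyte"], r["class"], float(r["mean"]), float(r["sd"]), r["unit"])
            for _, r in df.iterrows()
        ]
        return CompositionProfile(entries)
    if table_id == "table3":
        with resources.as_file(_data_path("table3.csv")) as p:
            df = pd.read_csv(p)
        records = []
        for _, r in df.iterrows():
            mic = None if pd.isna(r["mic_mean"]) else (float(r["mic_mean"]), float(r["mic_sd"]))
            mbc = None if pd.isna(r["mbc_mean"]) else (float(r["mbc_mean"]), float(r["mbc_sd"]))
            records.append(
                AntimicrobialRecord(
                    strain=r["strain"],
                    gram=r["gram"],
                    zone_diameter_mm=(float(r["zone_mean"]), float(r["zone_sd"])),
                    mic_mg_per_ml=mic,
                    mbc_mg_per_ml=mbc,
                )
            )
        return records
    raise KeyError(f"unknown table_id {table_id!r}; expected table1, table2 or table3")


def read_dataset(path, format: str = "csv", units: dict[str, str] | None = None) -> ExtractionDataset:
    """Read an :class:`ExtractionDataset` from a wide CSV.

    Expected columns: ``temperature_C``, ``concentration_pct`` and, per
    response, ``<name>_mean`` with optional ``<name>_sd`` (missing sd columns
    default to 0 with a warning) and optional ``<name>_note`` annotation
    strings.  Units come from ``units`` or from a ``<stem>.units.json``
    sidecar next to the file, if present.
    """
    if format != "csv":
        raise ValueError(f"unsupported format {format!r}")
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("temperature_C", "concentration_pct"):
        if col not in df.columns:
            raise DatasetValidationError(f"missing required column {col!r}")

    resp_names = [c[: -len("_mean")] for c in df.columns if c.endswith("_mean")]
    if not resp_names:
        raise DatasetValidationError("no '<response>_mean' columns found")

    bad = [
        (name, int(i))
        for name in resp_names
        for i in df.index[df[f"{name}_mean"] < 0]
    ]
    if bad:
        cells = ", ".join(f"{n}_mean[row {i}]" for n, i in bad)
        raise DatasetValidationError(f"negative response means: {cells}")

    conditions = [
        Condition(float(t), float(c))
        for t, c in zip(df["temperature_C"], df["concentration_pct"])
    ]
    responses: dict[str, list[ResponseValue]] = {}
    annotations: dict[str, list[str]] = {}
    for name in resp_names:
        sd_col = f"{name}_sd"
        if sd_col in df.columns:
            sds = df[sd_col].astype(float).tolist()
        else:
            warnings.warn(
                f"column {sd_col!r} missing; standard deviations set to 0", stacklevel=2
            )
            sds = [0.0] * len(df)
        responses[name] = [
            ResponseValue(float(m), float(s)) for m, s in zip(df[f"{name}_mean"], sds)
        ]
        note_col = f"{name}_note"
        if note_col in df.columns:
            annotations[name] = df[note_col].astype(str).tolist()

    if units is None:
        sidecar = path.with_suffix(".units.json")
        units = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return ExtractionDataset(
        conditions=conditions,
        responses=responses,
        units=dict(units),
        annotations=annotations or None,
    )


def write_dataset(ds: ExtractionDataset, path) -> None:
    """Write the wide CSV plus a ``<stem>.units.json`` sidecar."""
    path = Path(path)
    ds.to_frame().to_csv(path, index=False)
    path.with_suffix(".units.json").write_text(json.dumps(ds.units, indent=2) + "\n")


# ---------------------------------------------------------------------------
# descriptive operations
# ---------------------------------------------------------------------------

def extreme_condition(
    ds: ExtractionDataset, response: str, which: Literal["max", "min"]
) -> tuple[Condition, ResponseValue]:
    """Condition with the extremal mean of ``response``.

    Ties break toward lower temperature, then lower concentration.
    """
    if response not in ds.responses:
        raise KeyError(f"response {response!r} not in dataset")
    if which not in ("max", "min"):
        raise ValueError(f"which must be 'max' or 'min', got {which!r}")
    sign = -1.0 if which == "max" else 1.0
    pairs = sorted(
        zip(ds.conditions, ds.responses[response]),
        key=lambda cv: (sign * cv[1].mean, cv[0].temperature, cv[0].concentration),
    )
    return pairs[0]


def fold_change(
    ds: ExtractionDataset,
    response: str,
    cond_num: Condition,
    cond_den: Condition,
    decimals: int = 2,
) -> float:
    """Ratio of response means between two conditions, half-up rounded."""
    num = ds.value(response, cond_num).mean
    den = ds.value(response, cond_den).mean
    if den == 0:
        raise ZeroDivisionError(
            f"denominator mean is zero for {response} at {cond_den}"
        )
    return round_half_up(num / den, decimals)


def dilution_series(start_fraction: float, n_tubes: int) -> list[float]:
    """Two-fold serial dilution: ``start, start/2, …, start/2**(n_tubes-1)``.

    This is the broth-macrodilution scheme used to read MIC/MBC endpoints.
    """
    if not 0 < start_fraction <= 1:
        raise ValueError(f"start_fraction must lie in (0, 1], got {start_fraction}")
    if n_tubes < 1:
        raise ValueError(f"n_tubes must be ≥ 1, got {n_tubes}")
    return [start_fraction / 2**i for i in range(n_tubes)]


@dataclass
class CompositionSummary:
    category: str
    unit: str
    total: float
    # (analyte, mean, share) ranked by descending mean
    ranked: list[tuple[str, float, float]]

    @property
    def top_analyte(self) -> str:
        return self.ranked[0][0]


def composition_summary(profile: CompositionProfile, category: str) -> CompositionSummary:
    """Total quantity and per-analyte shares for one analyte class."""
    entries = sorted(profile.in_category(category), key=lambda e: -e.mean)
    total = sum(e.mean for e in entries)
    if total == 0:
        raise ValueError(f"class {category!r} has zero total quantity")
    units = {e.unit for e in entries}
    if len(units) > 1:
        raise ValueError(f"class {category!r} mixes units {sorted(units)}")
    ranked = [(e.analyte, e.mean, e.mean / total) for e in entries]
    return CompositionSummary(category=category, unit=entries[0].unit, total=total, ranked=ranked)
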