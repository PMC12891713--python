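"""Domain types, validation and tabular I/O for the melon trial analysis.

The trial is a 3 cultivar x 2 substrate-volume x 2 planting-density factorial
in a randomized complete block design. Per-fruit measurements (weight,
dimensions, soluble solids as Brix, panel netting grade) are exchanged as CSV
or JSON tables with a fixed header schema; reference tables transcribed from
the trial report (per-treatment yields and water productivity, market prices
per grade, planting geometry) ship with the package as CSV fixtures.

Units: yields kg per 10 a (10 a = 1,000 m2), irrigation m3 per 10 a, water
productivity kg/m3, prices USD/kg (converted at 1,382 KRW/USD), weight kg,
length/diameter cm, flesh thickness mm, sugar content degrees Brix, netting
grade on the 1 (excellent) to 5 (bad) panel scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import FixtureLookupError, SchemaError, ValidationError

CULTIVARS = ("Dalgona", "Hero", "Kingstar")
SUBSTRATE_VOLUMES = (10.0, 20.0)
PLANTING_DENSITIES = (3, 4)
GRADE_TIERS = ("Premium", "Superior", "Medium", "Inferior")

#: Exchange rate used when the price table was converted to USD.
KRW_PER_USD = 1382.0

#: Header schema for per-fruit tables (CSV and the JSON mirror).
FRUIT_COLUMNS = (
    "cultivar",
    "substrate_volume",
    "plants_per_slab",
    "block",
    "weight",
    "length",
    "diameter",
    "flesh_thickness",
    "brix",
    "net_score",
)

_FIXTURES = {
    "table1": "table1.csv",
    "table2": "table2.csv",
    "table3": "table3.csv",
    "table4": "table4.csv",
    "brix_calibration": "brix_calibration.csv",
}


@dataclass(frozen=True)
class Treatment:
    """One cultivar x substrate-volume x planting-density combination."""

    cultivar: str
    substrate_volume: float  # litres per slab
    plants_per_slab: int
    planting_distance: float | None = None  # cm, in-row
    row_spacing: float | None = None  # cm, between rows

    def __post_init__(self) -> None:
        if self.substrate_volume <= 0:
            raise ValidationError(f"substrate_volume must be > 0, got {self.substrate_volume}")
        if self.plants_per_slab < 1:
            raise ValidationError(f"plants_per_slab must be >= 1, got {self.plants_per_slab}")
        for name in ("planting_distance", "row_spacing"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValidationError(f"{name} must be > 0, got {v}")

    @property
    def key(self) -> tuple[str, float, int]:
        return (self.cultivar, self.substrate_volume, self.plants_per_slab)

    @property
    def label(self) -> str:
        return f"{self.cultivar}/{self.substrate_volume:g}L/{self.plants_per_slab}p"


@dataclass(frozen=True)
class FruitRecord:
    """A single measured fruit tied to a treatment and a block (replicate)."""

    treatment: Treatment
    block: int
    weight: float  # kg
    length: float  # cm
    diameter: float  # cm
    flesh_thickness: float  # mm
    brix: float  # degrees Brix
    net_score: float  # panel scale, 1 best .. 5 worst

    def __post_init__(self) -> None:
        for name in ("weight", "length", "diameter", "flesh_thickness", "brix"):
            v = getattr(self, name)
            if not v > 0:
                raise ValidationError(f"{name} must be > 0, got {v}")
        if not 1.0 <= self.net_score <= 5.0:
            raise ValidationError(f"net_score must lie in [1, 5], got {self.net_score}")

    @property
    def fruit_shape_index(self) -> float:
        """Length/diameter ratio; ~1 means spherical."""
        return self.length / self.diameter


@dataclass(frozen=True)
class TreatmentSummary:
    """Per-treatment aggregates feeding the economics and Pareto stages."""

    treatment: Treatment
    total_yield: float  # kg / 10 a
    irrigation_volume: float  # m3 / 10 a
    water_productivity: float  # kg / m3
    mean_weight: float
    mean_brix: float
    mean_net_score: float
    grade_counts: Mapping[str, int] = field(default_factory=dict)
    n_fruits: int = 0
    quality_score: float | None = None
    mean_flesh_thickness: float | None = None

    def __post_init__(self) -> None:
        if self.irrigation_volume > 0 and self.water_productivity > 0:
            resid = abs(self.water_productivity * self.irrigation_volume - self.total_yield)
            if resid > 1e-6 * max(1.0, abs(self.total_yield)):
                raise ValidationError(
                    f"WP x irrigation != yield for {self.treatment.label}: "
                    f"{self.water_productivity} x {self.irrigation_volume} vs {self.total_yield}"
                )
        if self.grade_counts and self.n_fruits and sum(self.grade_counts.values()) != self.n_fruits:
            raise ValidationError(
                f"grade counts sum {sum(self.grade_counts.values())} != n_fruits {self.n_fruits}"
            )
        if self.quality_score is not None and not 0.0 <= self.quality_score <= 100.0:
            raise ValidationError(f"quality_score must lie in [0, 100], got {self.quality_score}")


@dataclass(frozen=True)
class PriceStats:
    mean: float
    max: float
    min: float
    sd: float

    def __post_init__(self) -> None:
        if not self.min <= self.mean <= self.max:
            raise ValidationError(f"price stats must satisfy min <= mean <= max, got {self}")


@dataclass(frozen=True)
class PriceTable:
    """Wholesale price (USD/kg) per grade tier, with spread statistics."""

    tiers: Mapping[str, PriceStats]
    krw_per_usd: float = KRW_PER_USD

    def __post_init__(self) -> None:
        means = [self.tiers[t].mean for t in GRADE_TIERS if t in self.tiers]
        if any(a < b for a, b in zip(means, means[1:])):
            raise ValidationError("tier mean prices must be non-increasing from Premium down")

    def price(self, tier: str, stat: str = "mean") -> float:
        if tier not in self.tiers:
            raise FixtureLookupError(f"unknown grade tier {tier!r}")
        if stat not in ("mean", "max", "min"):
            raise ValidationError(f"price stat must be mean|max|min, got {stat!r}")
        return getattr(self.tiers[tier], stat)


@dataclass(frozen=True)
class CostStructure:
    """Seven-component production cost, USD per 10 a."""

    substrate: float
    seedlings: float
    labor: float
    maintenance: float
    energy: float
    fertilizer: float
    fixed: float

    def __post_init__(self) -> None:
        for name, v in self.as_dict().items():
            if v < 0:
                raise ValidationError(f"cost component {name} must be >= 0, got {v}")

    def as_dict(self) -> dict[str, float]:
        return {
            "substrate": self.substrate,
            "seedlings": self.seedlings,
            "labor": self.labor,
            "maintenance": self.maintenance,
            "energy": self.energy,
            "fertilizer": self.fertilizer,
            "fixed": self.fixed,
        }

    @property
    def total(self) -> float:
        return sum(self.as_dict().values())


@dataclass(frozen=True)
class MarketWeights:
    """Channel weights combining sugar and netting scores into a market grade.

    The premium channel (department stores, gift boxes) weighs appearance more
    heavily (alpha=0.7, beta=0.3); the public channel (direct retail, where
    fruit is mesh-packed) is driven almost entirely by sugar (0.8/0.2).
    """

    alpha: float
    beta: float
    channel: str = "premium"

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0 and 0.0 <= self.beta <= 1.0):
            raise ValidationError("weights must lie in [0, 1]")
        if abs(self.alpha + self.beta - 1.0) > 1e-9:
            raise ValidationError(f"alpha + beta must equal 1, got {self.alpha + self.beta}")


PREMIUM_CHANNEL = MarketWeights(alpha=0.7, beta=0.3, channel="premium")
PUBLIC_CHANNEL = MarketWeights(alpha=0.8, beta=0.2, channel="public")

MARKET_CHANNELS = {"premium": PREMIUM_CHANNEL, "public": PUBLIC_CHANNEL}


# ---------------------------------------------------------------------------
# Fixture loading
# ---------------------------------------------------------------------------

def _data_path(filename: str):
    return resources.files("melonopt.data").joinpath(filename)


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged reference table.

    Known names: ``table1`` (per-treatment yield, water productivity and
    fertilizer/substrate costs), ``table2`` (per-treatment fruit morphology and
    netting grade means), ``table3`` (wholesale price per grade tier),
    ``table4`` (planting geometry), ``brix_calibration`` (per-treatment sugar
    targets used by the synthetic-trial generator).

    ``table4`` planting distances include an exact fraction (100/3 cm); the
    returned frame keeps the exact value in ``planting_distance_frac`` (a
    :class:`fractions.Fraction`) alongside a float convenience column.
    """
    if name not in _FIXTURES:
        raise FixtureLookupError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        )
    with resources.as_file(_data_path(_FIXTURES[name])) as p:
        df = pd.read_csv(p, dtype={"planting_distance_cm": str} if name == "table4" else None)
    if name == "table4":
        fracs = [Fraction(s) for s in df["planting_distance_cm"]]
        df["planting_distance_frac"] = fracs
        df["planting_distance_cm"] = [float(f) for f in fracs]
    return df


def treatments(include_geometry: bool = True) -> list[Treatment]:
    """The 12 trial treatments, in Table-1 row order."""
    t1 = load_fixture("table1")
    geo = load_fixture("table4").set_index(["substrate_volume", "plants_per_slab"])
    out = []
    for _, row in t1.iterrows():
        kwargs = {}
        if include_geometry:
            g = geo.loc[(row["substrate_volume"], row["plants_per_slab"])]
            kwargs = {
                "planting_distance": float(g["planting_distance_cm"]),
                "row_spacing": float(g["row_spacing_cm"]),
            }
        out.append(
            Treatment(
                cultivar=row["cultivar"],
                substrate_volume=float(row["substrate_volume"]),
                plants_per_slab=int(row["plants_per_slab"]),
                **kwargs,
            )
        )
    return out


def load_price_table() -> PriceTable:
    """Grade-tier wholesale prices (USD/kg) as a :class:`PriceTable`."""
    df = load_fixture("table3").set_index("grade")
    tiers = {
        g: PriceStats(
            mean=float(r["mean"]), max=float(r["max"]), min=float(r["min"]), sd=float(r["sd"])
        )
        for g, r in df.iterrows()
    }
    return PriceTable(tiers=tiers)


# ---------------------------------------------------------------------------
# Fruit-table I/O
# ---------------------------------------------------------------------------

def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format
    suffix = path.suffix.lower().lstrip(".")
    return {"csv": "csv", "json": "json"}.get(suffix, "csv")


def records_to_frame(records: Iterable[FruitRecord]) -> pd.DataFrame:
    """Flatten fruit records into the documented tabular schema."""
    rows = [
        {
            "cultivar": r.treatment.cultivar,
            "substrate_volume": r.treatment.substrate_volume,
            "plants_per_slab": r.treatment.plants_per_slab,
            "block": r.block,
            "weight": r.weight,
            "length": r.length,
            "diameter": r.diameter,
            "flesh_thickness": r.flesh_thickness,
            "brix": r.brix,
            "net_score": r.net_score,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(FRUIT_COLUMNS))


def frame_to_records(df: pd.DataFrame) -> list[FruitRecord]:
    """Validate a fruit table row by row; report all bad rows at once."""
    missing = [c for c in FRUIT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"fruit table missing column(s): {', '.join(missing)}")
    records: list[FruitRecord] = []
    problems: list[str] = []
    for idx, row in df.iterrows():
        try:
            treatment = Treatment(
                cultivar=str(row["cultivar"]),
                substrate_volume=float(row["substrate_volume"]),
                plants_per_slab=int(row["plants_per_slab"]),
            )
            records.append(
                FruitRecord(
                    treatment=treatment,
                    block=int(row["block"]),
                    weight=float(row["weight"]),
                    length=float(row["length"]),
                    diameter=float(row["diameter"]),
                    flesh_thickness=float(row["flesh_thickness"]),
                    brix=float(row["brix"]),
                    net_score=float(row["net_score"]),
                )
            )
        except (ValidationError, ValueError) as exc:
            problems.append(f"row {idx}: {exc}")
    if problems:
        raise ValidationError("invalid fruit rows:\n" + "\n".join(problems))
    return records


def read_fruit_table(path: str | Path, format: str | None = None) -> list[FruitRecord]:
    """Read a per-fruit measurement table (CSV or JSON list-of-records)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        df = pd.read_csv(path)
    elif fmt == "json":
        with open(path) as fh:
            df = pd.DataFrame(json.load(fh))
    else:
        raise SchemaError(f"unsupported format {fmt!r}; use 'csv' or 'json'")
    return frame_to_records(df)


def write_fruit_table(
    records: Sequence[FruitRecord], path: str | Path, format: str | None = None
) -> Path:
    """Write fruit records; full float precision so round-trips are exact."""
    path = Path(path)
    fmt = _infer_format(path, format)
    df = records_to_frame(records)
    if fmt == "csv":
        df.to_csv(path, index=False, float_format="%.17g")
    elif fmt == "json":
        with open(path, "w") as fh:
            json.dump(df.to_dict(orient="records"), fh, indent=1)
    else:
        raise SchemaError(f"unsupported format {fmt!r}; use 'csv' or 'json'")
    return path
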