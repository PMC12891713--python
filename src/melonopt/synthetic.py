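"""Synthetic factorial-trial generator.

Generates per-fruit data for the 3 cultivar x 2 substrate-volume x 2
planting-density randomized complete block design (3 blocks, 503 fruits in
total by default). Each response (Brix, fruit weight, dimensions, flesh
thickness, panel net score) is drawn as

    treatment cell mean + block effect + Gaussian residual

where the cell-mean surface comes from a full factorial decomposition (grand
mean, three main effects, all interactions) of a packaged calibration table:

* fruit weight = total yield / plants per 10 a (one fruit kept per plant),
  which reproduces the reported per-treatment yields exactly;
* morphology and net-score means are transcribed trial report values;
* Brix means are calibrated estimates constrained by the reported extremes
  (peak 14.5 at Dalgona 10 L / 3 plants, minimum near 10.1 for Kingstar at
  20 L) and the consistent 10 L > 20 L pattern;
* per-treatment irrigation volume is yield / water productivity, so the
  water-productivity identity recovers the reported WP values.

Residual standard deviations are free parameters of the generator (the trial
report prints no within-treatment variances); defaults are documented,
plausible bench-scale values. Net scores are generated on a continuous scale
and clamped to [1, 5]; integer panel rounding is available but off by default
because reported treatment means (e.g. 1.25) are non-integer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Mapping

import numpy as np
import pandas as pd

from .core_io import load_fixture
from .exceptions import ValidationError

RESPONSES = ("weight", "length", "diameter", "flesh_thickness", "brix", "net_score")

#: Default residual standard deviations per response (same units as response).
DEFAULT_RESIDUAL_SD = {
    "weight": 0.12,  # kg
    "length": 0.45,  # cm
    "diameter": 0.35,  # cm
    "flesh_thickness": 1.8,  # mm
    "brix": 0.40,  # degrees Brix
    "net_score": 0.12,  # panel score; mean of an 8-member panel
}

#: Default seed: the trial's sowing date, kept purely as a documented constant.
DEFAULT_SEED = 20200129

_FACTORS = ("cultivar", "substrate_volume", "plants_per_slab")


@dataclass(frozen=True)
class ResponseEffects:
    """Additive factorial effects for one response.

    ``implied_mean`` reconstructs the cell mean as grand mean + main effects +
    two-way + three-way interaction terms; with the terms produced by
    :func:`decompose_cell_means` the reconstruction is exact.
    """

    grand_mean: float
    cultivar: Mapping[str, float]
    substrate: Mapping[float, float]
    density: Mapping[int, float]
    cultivar_substrate: Mapping[tuple, float]
    cultivar_density: Mapping[tuple, float]
    substrate_density: Mapping[tuple, float]
    three_way: Mapping[tuple, float]
    residual_sd: float

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise ValidationError(f"residual_sd must be >= 0, got {self.residual_sd}")

    def implied_mean(self, cultivar: str, substrate: float, density: int) -> float:
        return (
            self.grand_mean
            + self.cultivar[cultivar]
            + self.substrate[substrate]
            + self.density[density]
            + self.cultivar_substrate[(cultivar, substrate)]
            + self.cultivar_density[(cultivar, density)]
            + self.substrate_density[(substrate, density)]
            + self.three_way[(cultivar, substrate, density)]
        )


@dataclass(frozen=True)
class EffectSpec:
    """Full generator specification for the factorial trial."""

    responses: Mapping[str, ResponseEffects]
    fruit_counts: Mapping[tuple, int]  # (cultivar, substrate, density) -> n
    irrigation_volume: Mapping[tuple, float]  # m3 / 10 a per treatment
    block_sd: float = 0.0
    round_net: bool = False

    def __post_init__(self) -> None:
        if self.block_sd < 0:
            raise ValidationError(f"block_sd must be >= 0, got {self.block_sd}")
        for key, n in self.fruit_counts.items():
            if n < 1:
                raise ValidationError(f"target fruit count must be >= 1, got {n} for {key}")
        missing = set(RESPONSES) - set(self.responses)
        if missing:
            raise ValidationError(f"missing response effects: {sorted(missing)}")

    @property
    def treatment_keys(self) -> list[tuple]:
        return list(self.fruit_counts)

    def implied_means(self) -> pd.DataFrame:
        """Treatment x response table of implied cell means."""
        rows = {}
        for key in self.treatment_keys:
            c, s, d = key
            rows[key] = {r: self.responses[r].implied_mean(c, s, d) for r in RESPONSES}
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.index = pd.MultiIndex.from_tuples(df.index, names=_FACTORS)
        return df


@dataclass(frozen=True)
class RandomPlan:
    """Seed and replicate structure of a simulated run."""

    seed: int = DEFAULT_SEED
    n_blocks: int = 3

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValidationError(f"n_blocks must be >= 1, got {self.n_blocks}")


def decompose_cell_means(cells: pd.Series, residual_sd: float) -> ResponseEffects:
    """Exact factorial decomposition of a balanced 3x2x2 cell-mean surface.

    ``cells`` is indexed by (cultivar, substrate_volume, plants_per_slab).
    Effects are deviations of marginal means from the grand mean, so they sum
    to zero within each factor and reconstruct every cell exactly.
    """
    cells = cells.astype(float)
    grand = cells.mean()
    lv = {f: sorted(set(cells.index.get_level_values(f))) for f in _FACTORS}
    main = {
        f: {v: cells.xs(v, level=f).mean() - grand for v in lv[f]} for f in _FACTORS
    }

    def two_way(f1: str, f2: str) -> dict:
        out = {}
        for v1, v2 in product(lv[f1], lv[f2]):
            m = cells.xs(v1, level=f1).xs(v2, level=f2).mean()
            out[(v1, v2)] = m - grand - main[f1][v1] - main[f2][v2]
        return out

    cs = two_way("cultivar", "substrate_volume")
    cd = two_way("cultivar", "plants_per_slab")
    sd_ = two_way("substrate_volume", "plants_per_slab")
    three = {}
    for (c, s, d), m in cells.items():
        three[(c, s, d)] = (
            m
            - grand
            - main["cultivar"][c]
            - main["substrate_volume"][s]
            - main["plants_per_slab"][d]
            - cs[(c, s)]
            - cd[(c, d)]
            - sd_[(s, d)]
        )
    return ResponseEffects(
        grand_mean=float(grand),
        cultivar=main["cultivar"],
        substrate=main["substrate_volume"],
        density=main["plants_per_slab"],
        cultivar_substrate=cs,
        cultivar_density=cd,
        substrate_density=sd_,
        three_way=three,
        residual_sd=residual_sd,
    )


def calibration_table() -> pd.DataFrame:
    """Per-treatment calibration targets assembled from the packaged fixtures.

    Columns: the six response means, plus total_yield, water_productivity,
    irrigation_volume (= yield / WP), plants_per_10a and n_fruits (503 fruits
    allocated as evenly as possible over the 12 treatments).
    """
    t1 = load_fixture("table1").set_index(list(_FACTORS))
    t2 = load_fixture("table2").set_index(list(_FACTORS))
    t4 = load_fixture("table4").set_index(["substrate_volume", "plants_per_slab"])
    brix = load_fixture("brix_calibration").set_index(list(_FACTORS))

    df = pd.DataFrame(index=t1.index)
    df["total_yield"] = t1["total_yield"].astype(float)
    df["water_productivity"] = t1["water_productivity"].astype(float)
    df["irrigation_volume"] = df["total_yield"] / df["water_productivity"]
    df["plants_per_10a"] = [
        int(t4.loc[(s, d), "plants_per_10a"]) for (_, s, d) in df.index
    ]
    df["weight"] = df["total_yield"] / df["plants_per_10a"]
    for col in ("length", "diameter", "flesh_thickness"):
        df[col] = t2[col].astype(float)
    df["net_score"] = t2["net_score"].astype(float)
    df["brix"] = brix["brix_mean"].astype(float)

    n_treat = len(df)
    base, extra = divmod(503, n_treat)
    df["n_fruits"] = [base + 1 if i < extra else base for i in range(n_treat)]
    return df


def default_effect_spec(
    residual_sd: Mapping[str, float] | None = None,
    block_sd: float = 0.0,
    round_net: bool = False,
) -> EffectSpec:
    """Effect spec whose implied cell means equal the calibration table."""
    sds = dict(DEFAULT_RESIDUAL_SD)
    if residual_sd:
        sds.update(residual_sd)
    cal = calibration_table()
    responses = {
        r: decompose_cell_means(cal[r], residual_sd=sds[r]) for r in RESPONSES
    }
    return EffectSpec(
        responses=responses,
        fruit_counts={key: int(n) for key, n in cal["n_fruits"].items()},
        irrigation_volume={key: float(v) for key, v in cal["irrigation_volume"].items()},
        block_sd=block_sd,
        round_net=round_net,
    )


def _allocate_blocks(n: int, n_blocks: int) -> list[int]:
    base, extra = divmod(n, n_blocks)
    return [base + 1 if b < extra else base for b in range(n_blocks)]


def simulate_trial(
    spec: EffectSpec | None = None, plan: RandomPlan | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Draw a synthetic trial; returns (fruit table, irrigation volumes).

    The fruit table uses the documented per-fruit schema. Identical
    ``(spec, plan)`` give bit-identical output. Fruits are allocated to blocks
    as evenly as possible within each treatment.
    """
    spec = spec or default_effect_spec()
    plan = plan or RandomPlan()
    rng = np.random.default_rng(plan.seed)

    # one block-effect draw per (response, block); zero when block_sd == 0
    block_fx = {
        r: (rng.normal(0.0, spec.block_sd, plan.n_blocks) if spec.block_sd > 0
            else np.zeros(plan.n_blocks))
        for r in RESPONSES
    }

    rows = []
    for key in spec.treatment_keys:
        c, s, d = key
        means = {r: spec.responses[r].implied_mean(c, s, d) for r in RESPONSES}
        sds = {r: spec.responses[r].residual_sd for r in RESPONSES}
        for block, n_b in enumerate(_allocate_blocks(spec.fruit_counts[key], plan.n_blocks), 1):
            draws = {
                r: means[r] + block_fx[r][block - 1] + rng.normal(0.0, sds[r], n_b)
                for r in RESPONSES
            }
            net = np.clip(draws["net_score"], 1.0, 5.0)
            if spec.round_net:
                net = np.round(net)
            for i in range(n_b):
                rows.append(
                    {
                        "cultivar": c,
                        "substrate_volume": float(s),
                        "plants_per_slab": int(d),
                        "block": block,
                        "weight": draws["weight"][i],
                        "length": draws["length"][i],
                        "diameter": draws["diameter"][i],
                        "flesh_thickness": draws["flesh_thickness"][i],
                        "brix": draws["brix"][i],
                        "net_score": net[i],
                    }
                )
    fruits = pd.DataFrame(rows)
    irrigation = pd.Series(spec.irrigation_volume, name="irrigation_volume")
    irrigation.index.names = _FACTORS
    return fruits, irrigation
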