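"""End-to-end analysis pipeline: simulate -> grade -> economics -> pareto -> report.

Each stage writes CSV tables (with JSON mirrors) into the output directory and
the run ends with a manifest listing every artifact and its SHA-256 checksum;
reruns with the same configuration and seed are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import economics as econ
from . import grading, stats
from .core_io import MARKET_CHANNELS, load_fixture, load_price_table
from .exceptions import ValidationError
from .pareto import ObjectiveMatrix, minmax_normalize, pareto_front
from .synthetic import DEFAULT_SEED, RandomPlan, default_effect_spec, simulate_trial

logger = logging.getLogger(__name__)

DEFAULT_OBJECTIVES = {"quality_score": "maximize", "total_yield": "maximize",
                      "water_productivity": "maximize"}

PERFORMANCE_METRICS = (
    "quality_score", "total_yield", "water_productivity", "roi",
    "mean_flesh_thickness", "mean_weight",
)


@dataclass
class RunConfig:
    """Pipeline configuration; flags override file values override defaults."""

    out_dir: str | Path = "melonopt_run"
    seed: int = DEFAULT_SEED
    n_blocks: int = 3
    channel: str = "premium"
    price_stat: str = "mean"
    brix_cuts: tuple[float, float, float] = (14.0, 12.0, 10.0)
    objectives: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_OBJECTIVES))
    letter_scope: str = "all"  # 'all' (across treatments) or 'cultivar'
    fruit_table: str | None = None  # optional measured input instead of simulation
    block_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.channel not in MARKET_CHANNELS:
            raise ValidationError(f"unknown market channel {self.channel!r}")
        if self.price_stat not in ("mean", "min", "max"):
            raise ValidationError(f"price_stat must be mean|min|max, got {self.price_stat!r}")
        if self.letter_scope not in ("all", "cultivar"):
            raise ValidationError(f"letter_scope must be 'all' or 'cultivar'")
        if self.fruit_table is not None and not Path(self.fruit_table).exists():
            raise ValidationError(f"fruit table not found: {self.fruit_table}")
        self.seed = int(self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def summarize_trial(
    fruits: pd.DataFrame,
    irrigation: pd.Series,
    channel: str = "premium",
    thresholds: grading.GradeThresholds = grading.DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Aggregate per-fruit data into per-treatment summaries.

    Total yield is reconstructed as mean fruit weight x projected plants per
    10 a (one fruit per plant); water productivity divides it by the supplied
    irrigation volume. The composite quality score uses the selected market
    channel's weights with bounds over the whole trial.
    """
    keys = ["cultivar", "substrate_volume", "plants_per_slab"]
    t4 = load_fixture("table4").set_index(["substrate_volume", "plants_per_slab"])
    g = fruits.groupby(keys, sort=False)
    out = g[["weight", "brix", "net_score", "flesh_thickness"]].mean()
    out.columns = ["mean_weight", "mean_brix", "mean_net_score", "mean_flesh_thickness"]
    out["n_fruits"] = g.size()
    out["plants_per_10a"] = [int(t4.loc[(s, d), "plants_per_10a"]) for (_, s, d) in out.index]
    out["total_yield"] = out["mean_weight"] * out["plants_per_10a"]
    out["irrigation_volume"] = irrigation.reindex(out.index)
    if out["irrigation_volume"].isna().any():
        raise ValidationError("irrigation volume missing for some treatments")
    out["water_productivity"] = out["total_yield"] / out["irrigation_volume"]
    means = out[["mean_brix", "mean_net_score"]].rename(
        columns={"mean_brix": "brix", "mean_net_score": "net_score"}
    )
    out["quality_score"] = grading.quality_scores_from_means(
        means, MARKET_CHANNELS[channel]
    )
    dist = grading.grade_distribution(fruits, by="brix", thresholds=thresholds)
    dist.index = out.index  # same grouping order
    for tier in dist.columns:
        out[f"pct_{tier.lower()}"] = dist[tier]
    out.index = [f"{c}/{s:g}L/{int(d)}p" for (c, s, d) in out.index]
    out.index.name = "treatment"
    # keep factor columns for downstream grouping
    out[keys] = pd.DataFrame(
        [(c, s, d) for (c, s, d) in g.size().index], index=out.index, columns=keys
    )
    return out


def economics_table(summaries: pd.DataFrame, price_stat: str = "mean") -> pd.DataFrame:
    """Per-treatment revenue/cost/profit/ROI from tier shares and prices."""
    prices = load_price_table()
    rows = {}
    for label, row in summaries.iterrows():
        production = {
            tier: row["total_yield"] * row[f"pct_{tier.lower()}"] / 100.0
            for tier in ("Premium", "Superior", "Medium", "Inferior")
        }
        rev = econ.revenue(production, prices, price_stat)
        cost = econ.default_cost_structure(
            row["substrate_volume"], int(row["plants_per_slab"])
        )
        result = econ.EconomicResult.from_revenue_cost(rev, cost.total)
        rows[label] = {
            "total_revenue": result.total_revenue,
            "total_cost": result.total_cost,
            "net_profit": result.net_profit,
            "roi": result.roi,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "treatment"
    return df


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> list[Path]:
    df.to_csv(path, index=index, float_format="%.10g")
    jpath = path.with_suffix(".json")
    df.reset_index().to_json(jpath, orient="records", indent=1, double_precision=10)
    return [path, jpath]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the artifact manifest (also written to disk)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    thresholds = grading.GradeThresholds(brix_cuts=tuple(config.brix_cuts))

    logger.info("stage: simulate")
    spec = default_effect_spec(block_sd=config.block_sd)
    if config.fruit_table is not None:
        fruits = pd.read_csv(config.fruit_table)
        _, irrigation = simulate_trial(spec, RandomPlan(seed=config.seed))
    else:
        fruits, irrigation = simulate_trial(
            spec, RandomPlan(seed=config.seed, n_blocks=config.n_blocks)
        )
    written += _write(fruits, out_dir / "fruits.csv", index=False)

    logger.info("stage: grade")
    summaries = summarize_trial(fruits, irrigation, config.channel, thresholds)
    written += _write(summaries, out_dir / "summaries.csv")
    for by in ("brix", "net"):
        dist = grading.grade_distribution(fruits, by=by, thresholds=thresholds)
        written += _write(dist, out_dir / f"grade_distribution_{by}.csv")

    logger.info("stage: economics")
    econ_df = economics_table(summaries, config.price_stat)
    written += _write(econ_df, out_dir / "economics.csv")

    logger.info("stage: pareto")
    obj_cols = list(config.objectives)
    missing = [c for c in obj_cols if c not in summaries.columns and c not in econ_df.columns]
    if missing:
        raise ValidationError(f"unknown objective column(s): {missing}")
    joined = summaries.join(econ_df)
    matrix = ObjectiveMatrix(values=joined[obj_cols], senses=dict(config.objectives))
    minmax_normalize(matrix)
    front = pareto_front(matrix)
    pareto_df = matrix.normalized.copy()
    pareto_df.columns = [f"{c}_norm" for c in pareto_df.columns]
    pareto_df = matrix.values.join(pareto_df)
    pareto_df["on_frontier"] = [
        lab in set(front.frontier_indices) for lab in matrix.values.index
    ]
    pareto_df["dominated_by_count"] = front.dominance_count
    written += _write(pareto_df, out_dir / "pareto.csv")

    logger.info("stage: report")
    perf = stats.performance_matrix(joined, PERFORMANCE_METRICS)
    written += _write(perf, out_dir / "performance_matrix.csv")
    corr = stats.pearson_matrix(joined, PERFORMANCE_METRICS)
    written += _write(corr, out_dir / "correlation_matrix.csv")
    replicates = stats.block_means(fruits)  # balanced: one row per treatment x block
    for response in ("brix", "weight", "net_score", "flesh_thickness"):
        anova = stats.three_way_anova(replicates, response)
        written += _write(anova.table, out_dir / f"anova_{response}.csv")
    letters = {}
    label = fruits["cultivar"].astype(str) + "/" + fruits["substrate_volume"].map(
        "{:g}".format) + "L/" + fruits["plants_per_slab"].astype(int).astype(str) + "p"
    for response in ("brix", "weight"):
        if config.letter_scope == "all":
            groups = {lab: grp[response].to_numpy() for lab, grp in fruits.groupby(label)}
            letters[response] = stats.tukey_hsd(groups).letters
        else:
            merged = {}
            for cv, sub in fruits.groupby("cultivar"):
                sub_lab = label[sub.index]
                groups = {lab: grp[response].to_numpy() for lab, grp in sub.groupby(sub_lab)}
                merged.update(stats.tukey_hsd(groups).letters)
            letters[response] = merged
    letters_df = pd.DataFrame(letters).sort_index()
    letters_df.index.name = "treatment"
    written += _write(letters_df, out_dir / "tukey_letters.csv")

    manifest = {
        "seed": config.seed,
        "channel": config.channel,
        "price_stat": config.price_stat,
        "artifacts": {str(p.name): _sha256(p) for p in written},
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.info("pipeline complete: %d artifacts in %s", len(written), out_dir)
    return manifest
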