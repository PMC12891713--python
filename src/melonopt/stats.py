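"""Supporting statistics: balanced three-way ANOVA, Tukey HSD with compact
letter display, Pearson correlation matrix, and the 0-100 normalized
performance matrix.

The trial design is a balanced complete 3x2x2 factorial; the ANOVA is the
classical orthogonal sum-of-squares decomposition (with balance, type I/II/III
coincide), fitted via ordinary least squares. Mean separation uses the
studentized-range (Tukey HSD) test; letter groups are assigned with the
insert-and-absorb algorithm so that two groups share no letter exactly when
they differ significantly. Normality (Shapiro-Wilk) and variance-homogeneity
(Levene) pre-checks are advisory log lines, not gates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.formula.api import ols

from .core_io import FruitRecord, records_to_frame
from .exceptions import DomainError, ValidationError
from .pareto import ObjectiveMatrix, minmax_normalize

logger = logging.getLogger(__name__)

ANOVA_TERMS = ("C", "S", "D", "C x S", "C x D", "S x D", "C x S x D", "Residual")

_TERM_MAP = {
    "C(cultivar)": "C",
    "C(substrate_volume)": "S",
    "C(plants_per_slab)": "D",
    "C(cultivar):C(substrate_volume)": "C x S",
    "C(cultivar):C(plants_per_slab)": "C x D",
    "C(substrate_volume):C(plants_per_slab)": "S x D",
    "C(cultivar):C(substrate_volume):C(plants_per_slab)": "C x S x D",
    "Residual": "Residual",
}


def significance_stars(p: float) -> str:
    """Table-footnote star convention: *, **, *** at 0.05/0.01/0.001."""
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


@dataclass(frozen=True)
class AnovaTable:
    """Term-wise SS/df/MS/F/p for the three-way factorial."""

    response: str
    table: pd.DataFrame  # index: ANOVA_TERMS; columns: sum_sq, df, mean_sq, F, p, sig

    @property
    def total_ss(self) -> float:
        return float(self.table["sum_sq"].sum())


def _as_frame(records: Iterable[FruitRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return records_to_frame(list(records))


def block_means(records: Iterable[FruitRecord] | pd.DataFrame) -> pd.DataFrame:
    """Per-(treatment, block) response means.

    The replicate unit of the design is the block, so aggregating fruits to
    block means yields a balanced table (one row per treatment x block) even
    when per-treatment fruit counts differ by a fruit or two.
    """
    df = _as_frame(records)
    keys = ["cultivar", "substrate_volume", "plants_per_slab", "block"]
    return df.groupby(keys, sort=False).mean(numeric_only=True).reset_index()


def three_way_anova(
    records: Iterable[FruitRecord] | pd.DataFrame, response: str
) -> AnovaTable:
    """Classical balanced three-way ANOVA of one response.

    Requires a complete, balanced factorial (equal fruit counts in every
    cultivar x substrate x density cell, at least 2 per cell); unbalanced
    input raises with a pointer to cell-mean preprocessing.
    """
    df = _as_frame(records)
    if response not in df.columns:
        raise ValidationError(f"unknown response {response!r}")
    cells = df.groupby(["cultivar", "substrate_volume", "plants_per_slab"]).size()
    n_cells = (
        df["cultivar"].nunique()
        * df["substrate_volume"].nunique()
        * df["plants_per_slab"].nunique()
    )
    if len(cells) != n_cells or cells.nunique() != 1:
        raise ValidationError(
            "three_way_anova requires a complete balanced factorial (equal cell "
            "counts); aggregate to cell means or rebalance before calling"
        )
    if cells.iloc[0] < 2:
        raise ValidationError("need at least 2 observations per cell")

    if df[response].nunique() > 1:
        sw = sps.shapiro(df[response].sample(min(len(df), 500), random_state=0))
        logger.info("Shapiro-Wilk on %s: W=%.4f p=%.3g (advisory)",
                    response, sw.statistic, sw.pvalue)
        groups = [g[response].to_numpy() for _, g in df.groupby(
            ["cultivar", "substrate_volume", "plants_per_slab"])]
        if any(np.ptp(g) > 0 for g in groups):
            lev = sps.levene(*groups)
            logger.info("Levene on %s: W=%.4f p=%.3g (advisory)",
                        response, lev.statistic, lev.pvalue)

    model = ols(
        f"Q('{response}') ~ C(cultivar) * C(substrate_volume) * C(plants_per_slab)",
        data=df,
    ).fit()
    raw = sm.stats.anova_lm(model, typ=1)
    table = raw.rename(index=_TERM_MAP).reindex(list(ANOVA_TERMS))
    table = table.rename(columns={"PR(>F)": "p"})
    table["mean_sq"] = table["sum_sq"] / table["df"]
    table["sig"] = table["p"].map(significance_stars)
    table = table[["sum_sq", "df", "mean_sq", "F", "p", "sig"]]
    return AnovaTable(response=response, table=table)


@dataclass(frozen=True)
class TukeyResult:
    """Pairwise studentized-range decisions plus compact letter display."""

    alpha: float
    means: pd.Series  # group -> mean, sorted descending
    pvalues: pd.DataFrame  # symmetric group x group
    significant: pd.DataFrame  # boolean, p < alpha
    letters: Mapping[str, str]  # group -> letter string, e.g. 'ab'


def _compact_letters(order: Sequence, significant: pd.DataFrame) -> dict:
    """Insert-and-absorb letter assignment over a significance relation."""
    sets: list[set] = [set(order)]
    for i, a in enumerate(order):
        for b in order[i + 1:]:
            if not significant.loc[a, b]:
                continue
            hit = [L for L in sets if a in L and b in L]
            for L in hit:
                sets.remove(L)
                for child in (L - {a}, L - {b}):
                    if child and not any(child <= other for other in sets):
                        sets.append(child)
            # absorb any set now contained in a newer one
            sets = [L for L in sets if not any(L < other for other in sets)]
    pos = {g: k for k, g in enumerate(order)}
    sets.sort(key=lambda L: min(pos[g] for g in L))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in order}
    for letter, L in zip(alphabet, sets):
        for g in L:
            out[g] += letter
    return out


def tukey_hsd(groups: Mapping[str, Sequence[float]], alpha: float = 0.05) -> TukeyResult:
    """Tukey HSD over named groups with a compact letter display.

    Groups sharing no letter differ at ``alpha``; every pair not significantly
    different shares at least one letter. Letters run from the highest group
    mean downward.
    """
    if len(groups) < 2:
        raise DomainError("need at least 2 groups")
    names = list(groups)
    samples = [np.asarray(groups[n], dtype=float) for n in names]
    if any(len(s) < 2 for s in samples):
        raise DomainError("every group needs at least 2 values")
    res = sps.tukey_hsd(*samples)
    pvals = pd.DataFrame(res.pvalue, index=names, columns=names)
    sig = (pvals < alpha) & ~np.eye(len(names), dtype=bool)
    means = pd.Series({n: float(np.mean(s)) for n, s in zip(names, samples)})
    order = list(means.sort_values(ascending=False).index)
    letters = _compact_letters(order, sig)
    return TukeyResult(
        alpha=alpha,
        means=means.loc[order],
        pvalues=pvals,
        significant=sig,
        letters=letters,
    )


def pearson_matrix(summaries: pd.DataFrame, metrics: Sequence[str]) -> pd.DataFrame:
    """Pearson correlation matrix over per-treatment metrics.

    With only a dozen treatments these correlations are descriptive; no
    p-values are attached. A constant metric yields NaN entries (flagged by a
    warning), never a silent zero.
    """
    missing = [m for m in metrics if m not in summaries.columns]
    if missing:
        raise ValidationError(f"missing metric column(s): {missing}")
    if len(summaries) < 3:
        raise DomainError("need at least 3 treatments for a correlation matrix")
    sub = summaries.loc[:, list(metrics)].astype(float)
    constant = [m for m in metrics if sub[m].nunique() == 1]
    if constant:
        logger.warning("constant metric(s) %s: correlations undefined (NaN)", constant)
    with np.errstate(invalid="ignore"):  # constant columns divide by zero sd
        corr = pd.DataFrame(
            np.corrcoef(sub.to_numpy(), rowvar=False), index=metrics, columns=metrics
        )
    np.fill_diagonal(corr.values, 1.0)
    for m in constant:
        corr.loc[m, :] = np.nan
        corr.loc[:, m] = np.nan
    return corr


def performance_matrix(summaries: pd.DataFrame, metrics: Sequence[str]) -> pd.DataFrame:
    """Treatments x metrics table normalized to 0-100 (all maximize-sense)."""
    missing = [m for m in metrics if m not in summaries.columns]
    if missing:
        raise ValidationError(f"missing metric column(s): {missing}")
    matrix = ObjectiveMatrix(values=summaries.loc[:, list(metrics)].astype(float))
    return minmax_normalize(matrix).normalized
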