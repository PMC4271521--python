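"""Outlier-window tests of the introgression-vs-ancestral-structure design.

The question under evaluation: can recent introgression between P2 and
P3 be told apart from shared ancestral variation by comparing absolute
divergence (d_XY) between candidate windows and the rest?  Candidates
are either the true Alternate windows of a simulated combined dataset
or the top 10% of windows ranked by D or an f estimator (D outliers are
restricted to D > 0, f outliers to windows with D >= 0).  P2-P3 d_XY of
the candidate set is compared against the remainder with a one-sided
Wilcoxon rank-sum test (lower in candidates), Bonferroni-corrected over
the models of a scenario at a 99% significance threshold.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .simulate import (
    CombinedDataset,
    model_grid_tables,
    simulate_combined,
    subsample_models,
    _split_seed,
)

__all__ = [
    "OutlierPartition",
    "ModelComparisonResult",
    "select_outliers",
    "wilcoxon_rank_sum",
    "bonferroni",
    "compare_dxy",
    "summarize_models",
    "estimator_accuracy",
    "evaluate_model_grid",
    "OUTLIER_STATISTICS",
]

OUTLIER_STATISTICS = ("D", "fG", "fhom", "fd")


@dataclass
class OutlierPartition:
    """Top-fraction windows of a statistic and the remainder.

    Eligibility: for D, candidates must have D > 0; for the f
    estimators, D >= 0 (an f value is only a meaningful introgression
    estimate when there is an ABBA excess).  Ineligible windows count
    toward the non-outlier side.
    """

    statistic: str
    outliers: np.ndarray
    nonoutliers: np.ndarray
    rule: str

    def __post_init__(self) -> None:
        if set(self.outliers) & set(self.nonoutliers):
            raise ValueError("outlier and nonoutlier sets overlap")


@dataclass
class ModelComparisonResult:
    """d_XY comparison between candidate and remaining windows."""

    model_id: str
    statistic: str
    mean_dxy_outliers: float | None
    mean_dxy_nonoutliers: float | None
    percent_of_nonoutlier: float | None
    raw_p: float | None
    adjusted_p: float | None
    significant: bool
    recall: float | None = None
    status: str = "ok"


def select_outliers(
    table: pd.DataFrame, statistic: str, top_fraction: float = 0.1
) -> OutlierPartition:
    """Partition windows into the top ``top_fraction`` of a statistic.

    The target count is ``round(top_fraction * n_windows)``, truncated
    to the number of eligible candidates; ties are broken by window
    order (stable sort), so the partition is deterministic and
    idempotent.  Rows are identified by DataFrame index.
    """
    if statistic not in OUTLIER_STATISTICS:
        raise ValueError(f"statistic must be one of {OUTLIER_STATISTICS}")
    if statistic not in table.columns:
        raise ValueError(f"statistic column {statistic!r} missing from table")
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must lie in (0, 1]")
    target = round(top_fraction * len(table))
    if statistic == "D":
        eligible = table["D"].notna() & (table["D"] > 0)
        rule = "top D among windows with D > 0"
    else:
        eligible = table["D"].notna() & (table["D"] >= 0) & table[statistic].notna()
        rule = f"top {statistic} among windows with D >= 0"
    candidates = table.loc[eligible, statistic]
    ranked = candidates.sort_values(ascending=False, kind="mergesort")
    outlier_idx = ranked.index[: min(target, len(ranked))].to_numpy()
    mask = table.index.isin(outlier_idx)
    return OutlierPartition(
        statistic=statistic,
        outliers=outlier_idx,
        nonoutliers=table.index[~mask].to_numpy(),
        rule=rule,
    )


def _exact_rank_sum_p(a: np.ndarray, b: np.ndarray, alternative: str) -> float:
    """One- or two-sided rank-sum p by exact enumeration of assignments.

    Midranks handle ties; every C(n, n_a) assignment of the pooled
    values to group A is enumerated, so this is only used for small
    total sizes.
    """
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n, na = len(pooled), len(a)
    observed = ranks[:na].sum()
    sums = np.array(
        [ranks[list(c)].sum() for c in itertools.combinations(range(n), na)]
    )
    eps = 1e-9
    p_less = np.mean(sums <= observed + eps)
    p_greater = np.mean(sums >= observed - eps)
    if alternative == "less":
        return float(p_less)
    if alternative == "greater":
        return float(p_greater)
    return float(min(1.0, 2.0 * min(p_less, p_greater)))


def wilcoxon_rank_sum(
    group_a, group_b, alternative: str = "less", exact_threshold: int = 20
) -> float | None:
    """Wilcoxon rank-sum (Mann-Whitney) p-value, one-sided by default.

    ``alternative='less'`` tests whether group A values are
    stochastically smaller than group B.  Small samples (total size at
    most ``exact_threshold``) are handled by exact enumeration of all
    group assignments with midranks for ties; larger samples use the
    tie-corrected normal approximation.  Returns ``None`` when either
    group is empty.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        return None
    if a.size + b.size <= exact_threshold:
        return _exact_rank_sum_p(a, b, alternative)
    _, p = sps.mannwhitneyu(a, b, alternative=alternative, method="asymptotic")
    return float(p)


def bonferroni(raw_p: float, m: int) -> float:
    """Bonferroni-adjusted p-value over ``m`` tests: min(1, p * m)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, raw_p * m)


def compare_dxy(
    dataset: CombinedDataset | pd.DataFrame,
    partition: OutlierPartition | str = "true",
    *,
    m: int = 1,
    alpha: float = 0.01,
    alternative: str = "less",
    model_id: str = "",
) -> ModelComparisonResult:
    """Compare P2-P3 d_XY between candidate windows and the remainder.

    ``partition`` is either an :class:`OutlierPartition` or the string
    ``"true"`` to use the simulated Background/Alternate labels.  The
    comparison is significant when the Bonferroni-adjusted one-sided
    Wilcoxon p-value falls below ``alpha`` *and* the candidate mean is
    lower.  ``recall`` (fraction of candidates that are true Alternate
    windows) is reported whenever labels are present and the partition
    is statistic-based.
    """
    table = dataset.table if isinstance(dataset, CombinedDataset) else dataset
    if "dxy_P2P3" not in table.columns:
        raise ValueError("table lacks the dxy_P2P3 column")
    recall = None
    if isinstance(partition, str):
        if partition != "true":
            raise ValueError("partition must be an OutlierPartition or 'true'")
        sel = table["label"] == "Alternate"
        statistic = "true"
    else:
        sel = table.index.isin(partition.outliers)
        statistic = partition.statistic
        if "label" in table.columns and sel.sum():
            recall = float((table.loc[sel, "label"] == "Alternate").mean())
    x = table.loc[sel, "dxy_P2P3"].dropna()
    y = table.loc[~sel, "dxy_P2P3"].dropna()
    if len(x) == 0 or len(y) == 0:
        return ModelComparisonResult(
            model_id=model_id,
            statistic=statistic,
            mean_dxy_outliers=None,
            mean_dxy_nonoutliers=None,
            percent_of_nonoutlier=None,
            raw_p=None,
            adjusted_p=None,
            significant=False,
            recall=recall,
            status="empty-partition-side",
        )
    mean_x, mean_y = float(x.mean()), float(y.mean())
    percent = 100.0 * mean_x / mean_y if mean_y > 0 else None
    raw_p = wilcoxon_rank_sum(x, y, alternative=alternative)
    adjusted = bonferroni(raw_p, m)
    significant = bool(adjusted < alpha and mean_x < mean_y)
    return ModelComparisonResult(
        model_id=model_id,
        statistic=statistic,
        mean_dxy_outliers=mean_x,
        mean_dxy_nonoutliers=mean_y,
        percent_of_nonoutlier=percent,
        raw_p=raw_p,
        adjusted_p=adjusted,
        significant=significant,
        recall=recall,
    )


def summarize_models(results: pd.DataFrame) -> pd.DataFrame:
    """Count significant models per scenario and partition statistic.

    ``results`` must carry ``scenario``, ``statistic`` and
    ``significant`` columns (one row per model x statistic); the output
    has one row per scenario with a ``n_models`` column and one count
    column per statistic.
    """
    counts = (
        results.pivot_table(
            index="scenario",
            columns="statistic",
            values="significant",
            aggfunc="sum",
            fill_value=0,
        )
        .astype(int)
        .reset_index()
    )
    n_models = results.groupby("scenario")["model_id"].nunique().rename("n_models")
    counts = counts.merge(n_models, on="scenario")
    order = ["scenario", "n_models"] + [
        c for c in ["true", "D", "fd", "fG", "fhom"] if c in counts.columns
    ]
    return counts[order]


def estimator_accuracy(grid_table: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard deviation of each statistic per grid setting.

    ``grid_table`` is the tidy output of
    :func:`fdscan.simulate.estimator_grid_statistics`.  Returns one row
    per (direction, t_gf, window_length, rho, f, statistic) with the
    mean, the sample standard deviation and the number of windows where
    the statistic was missing.
    """
    keys = ["direction", "t_gf", "window_length", "rho", "f"]
    records = []
    for setting, grp in grid_table.groupby(keys, sort=True):
        for stat in ("D", "fG", "fhom", "fd"):
            vals = grp[stat].astype(float)
            ok = vals.dropna()
            records.append(
                dict(zip(keys, setting))
                | {
                    "statistic": stat,
                    "mean": float(ok.mean()) if len(ok) else None,
                    "sd": float(ok.std(ddof=1)) if len(ok) >= 2 else None,
                    "n_windows": len(vals),
                    "n_missing": int(vals.isna().sum()),
                }
            )
    return pd.DataFrame(records)


def evaluate_model_grid(
    scenario: str,
    *,
    rho: float = 0.01,
    n_models: int | None = None,
    windows_per_model: int = 10000,
    alternate_fraction: float = 0.1,
    seed: int | None = None,
    statistics: Sequence[str] = ("true",) + OUTLIER_STATISTICS,
    top_fraction: float = 0.1,
    alpha: float = 0.01,
    window_length: int = 5000,
) -> pd.DataFrame:
    """Simulate and test a (possibly subsampled) scenario grid.

    For every model of the scenario grid (evenly subsampled to
    ``n_models`` when given), a combined dataset of
    ``windows_per_model`` windows is simulated (10% Alternate unless the
    scenario is null) and the P2-P3 d_XY comparison is run for the true
    labels and/or each statistic-based outlier partition.  The Bonferroni
    factor is the number of models actually run.  Returns one row per
    model x statistic.
    """
    pairs = model_grid_tables(scenario, rho=rho, window_length=window_length)
    if n_models is not None:
        pairs = subsample_models(pairs, n_models)
    m = len(pairs)
    n_alt = round(alternate_fraction * windows_per_model)
    seeds = _split_seed(seed, m)
    rows = []
    for pair, model_seed in zip(pairs, seeds):
        spec = pair.to_spec(
            n_background=windows_per_model - n_alt, n_alternate=n_alt, seed=int(model_seed)
        )
        dataset = simulate_combined(spec, minimal=True)
        for stat in statistics:
            if stat == "true":
                result = compare_dxy(dataset, "true", m=m, alpha=alpha, model_id=pair.model_id)
            else:
                part = select_outliers(dataset.table, stat, top_fraction)
                result = compare_dxy(dataset, part, m=m, alpha=alpha, model_id=pair.model_id)
            rows.append(
                {
                    "scenario": scenario,
                    "model_id": pair.model_id,
                    **pair.params,
                    "rho": rho,
                    "n_windows": dataset.n_windows,
                    "m": m,
                    "statistic": result.statistic,
                    "mean_dxy_outliers": result.mean_dxy_outliers,
                    "mean_dxy_nonoutliers": result.mean_dxy_nonoutliers,
                    "percent_of_nonoutlier": result.percent_of_nonoutlier,
                    "raw_p": result.raw_p,
                    "adjusted_p": result.adjusted_p,
                    "significant": result.significant,
                    "recall": result.recall,
                    "status": result.status,
                }
            )
    return pd.DataFrame(rows)
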