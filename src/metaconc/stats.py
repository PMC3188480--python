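"""Concentration-vs-descriptor statistics.

Each experimental condition is analysed independently.  For every
(condition, parameter) pair the pipeline computes the Pearson correlation R
between the parameter and log10 concentration, a Monte-Carlo permutation
p-value for R², and a significance flag from Benjamini-Hochberg FDR control
over the whole grid of tests.  Concentrations are additionally predicted per
metabolite by leave-one-out ordinary least squares on NPSA and NCA, scored
by the fraction of predictions within one order of magnitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError, TableJoinError

#: Default features of the concentration predictor.
DEFAULT_FEATURES = ("NPSA", "NCA")

#: Fold-deviation above which a LOO residual is flagged as an outlier.
DEFAULT_OUTLIER_FOLD = 30.0


# --------------------------------------------------------------------- types
@dataclass
class ConcentrationDataset:
    """Molar concentrations of one condition within one source study."""

    source: str
    condition: str
    entries: dict[str, float]  # metabolite id -> mol/L; missing ids = NA
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        bad = [k for k, v in self.entries.items() if not (v > 0) or not math.isfinite(v)]
        if bad:
            raise ValueError(
                f"non-positive or non-finite concentration for {bad[:5]} "
                f"in {self.condition!r}"
            )

    @property
    def label(self) -> str:
        return f"{self.source}:{self.condition}" if self.source else self.condition

    def to_series(self) -> pd.Series:
        return pd.Series(self.entries, name=self.label, dtype=float)


@dataclass(frozen=True)
class CorrelationResult:
    condition: str
    parameter: str
    n_used: int
    r: float
    r2: float
    p_perm: Optional[float] = None
    significant: Optional[bool] = None


@dataclass(frozen=True)
class RegressionModel:
    """OLS fit of log10 concentration on descriptor features."""

    features: tuple[str, ...]
    coefficients: np.ndarray  # slope per feature, log10-conc units
    intercept: float  # log10 mol/L

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        X = table.loc[:, list(self.features)].to_numpy(dtype=float)
        return X @ self.coefficients + self.intercept


@dataclass
class PredictionReport:
    """Leave-one-out prediction outcome for one condition."""

    condition: str
    rows: pd.DataFrame  # id, observed, predicted, residual, fold_deviation
    model: RegressionModel  # full-data fit, for coefficient inspection
    accuracy_1oom: float  # fraction of |residual| <= 1
    baseline_1oom: float  # fraction of observed within 1 log10 of the mean
    mean_fold_deviation: float  # 10**mean(|residual|)
    mean_of_folds: float  # mean(10**|residual|), the alternative averaging
    r2_fit: float  # squared correlation of predicted vs observed
    outliers: list[str]
    outlier_fold: float = DEFAULT_OUTLIER_FOLD


# ---------------------------------------------------------------- filtering
def filter_small(
    dataset: ConcentrationDataset,
    descriptors: pd.DataFrame,
    mw_max: float = 300.0,
    parameters: Optional[Sequence[str]] = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Join one condition's concentrations with the descriptor table.

    Returns the analysis table (descriptor columns plus ``log10_conc``) and
    a per-reason count of dropped rows.  Metabolites above *mw_max* Da, with
    missing concentration, or with NA in a requested parameter are dropped.
    Cofactors and bulky conjugates are what the mass cutoff removes; small
    metabolites are where the concentration trends are strongest.
    """
    conc = dataset.to_series()
    matched = conc.index.intersection(descriptors.index)
    if len(matched) == 0:
        unmatched = sorted(set(conc.index) ^ set(descriptors.index))
        raise TableJoinError(unmatched)

    dropped = {
        "unmatched_id": int(len(conc) - len(matched)),
        "na_concentration": 0,
        "mw_above_max": 0,
        "na_parameter": 0,
    }
    table = descriptors.loc[matched].copy()
    table["conc"] = conc.loc[matched]

    na_conc = table["conc"].isna()
    dropped["na_concentration"] = int(na_conc.sum())
    table = table[~na_conc]

    heavy = table["MW"] > mw_max
    dropped["mw_above_max"] = int(heavy.sum())
    table = table[~heavy]

    if parameters:
        missing = table[list(parameters)].isna().any(axis=1)
        dropped["na_parameter"] = int(missing.sum())
        table = table[~missing]

    table["log10_conc"] = np.log10(table["conc"].to_numpy(dtype=float))
    return table, dropped


# ------------------------------------------------------------- correlation
def _check_pair(x: np.ndarray, y: np.ndarray) -> None:
    if len(x) < 3:
        raise DegenerateInputError(f"degenerate input: only {len(x)} complete cases")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("degenerate input: zero variance")


def correlate(table: pd.DataFrame, parameter: str) -> tuple[float, float, int]:
    """Pearson R of *parameter* against log10 concentration.

    Uses the complete-case subset for this parameter.  Returns (r, r², n).
    """
    sub = table[[parameter, "log10_conc"]].dropna()
    x = sub[parameter].to_numpy(dtype=float)
    y = sub["log10_conc"].to_numpy(dtype=float)
    _check_pair(x, y)
    r = float(sps.pearsonr(x, y).statistic)
    return r, r * r, len(x)


def permutation_pvalue(
    table: pd.DataFrame,
    parameter: str,
    n_perm: int = 100_000,
    seed: int = 1,
) -> float:
    """Monte-Carlo permutation p-value for the R² of one correlation.

    The parameter column is shuffled ``n_perm`` times against the fixed
    concentrations; p is the fraction of shuffles whose R² strictly exceeds
    the observed R².  With strict inequality and no pseudo-count the minimum
    reportable p is 0, to be read as "< 1/n_perm".
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    sub = table[[parameter, "log10_conc"]].dropna()
    x = sub[parameter].to_numpy(dtype=float)
    y = sub["log10_conc"].to_numpy(dtype=float)
    _check_pair(x, y)

    xc = x - x.mean()
    yc = y - y.mean()
    denom_y = float(np.sqrt(yc @ yc))
    r_obs = float((xc @ yc) / (np.sqrt(xc @ xc) * denom_y))
    r2_obs = r_obs * r_obs

    rng = np.random.default_rng(seed)
    exceed = 0
    chunk = max(1, min(n_perm, 20_000))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perms = rng.permuted(np.broadcast_to(xc, (m, len(xc))).copy(), axis=1)
        num = perms @ yc
        norms = np.linalg.norm(perms, axis=1) * denom_y
        r2 = (num / norms) ** 2
        # strict inequality; the epsilon keeps permutations whose r² is
        # mathematically equal to the observed one (e.g. order reversals)
        # from being counted due to floating-point summation order
        exceed += int(np.count_nonzero(r2 > r2_obs + 1e-12))
        done += m
    return exceed / n_perm


def fdr_control(pvalues: Sequence[float], rate: float = 0.01) -> np.ndarray:
    """Benjamini-Hochberg step-up flags over one family of tests.

    The family is the flattened grid of all (condition, parameter) tests; at
    the default rate of 0.01 over 21 conditions x 8 parameters that is a
    single family of 168 p-values.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=rate, method="fdr_bh")
    return reject


def correlation_grid(
    tables: Mapping[str, pd.DataFrame],
    parameters: Sequence[str],
    n_perm: int = 100_000,
    fdr_rate: float = 0.01,
    seed: int = 1,
) -> list[CorrelationResult]:
    """Full condition x parameter grid with one shared FDR family.

    Conditions where a parameter is degenerate (all-NA, constant) are
    recorded with NaN statistics and excluded from the FDR family.
    """
    results: list[tuple[str, str, float, float, int, float]] = []
    rng = np.random.default_rng(seed)
    for cond, table in tables.items():
        for param in parameters:
            sub_seed = int(rng.integers(0, 2**31 - 1))
            try:
                r, r2, n = correlate(table, param)
                p = permutation_pvalue(table, param, n_perm=n_perm, seed=sub_seed)
            except DegenerateInputError:
                results.append((cond, param, np.nan, np.nan, 0, np.nan))
                continue
            results.append((cond, param, r, r2, n, p))

    valid = [i for i, rec in enumerate(results) if not math.isnan(rec[5])]
    flags = fdr_control([results[i][5] for i in valid], rate=fdr_rate)
    sig = {i: bool(f) for i, f in zip(valid, flags)}
    return [
        CorrelationResult(
            condition=cond, parameter=param, n_used=n, r=r, r2=r2,
            p_perm=(None if math.isnan(p) else p), significant=sig.get(i),
        )
        for i, (cond, param, r, r2, n, p) in enumerate(results)
    ]


def grid_to_frame(grid: Iterable[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "condition": g.condition,
                "parameter": g.parameter,
                "n": g.n_used,
                "R": g.r,
                "R2": g.r2,
                "p_perm": g.p_perm,
                "significant": g.significant,
            }
            for g in grid
        ]
    )


# ---------------------------------------------------------------- prediction
def _ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-squares coefficients for [X, 1] @ beta = y; raises if rank-deficient."""
    design = np.column_stack([X, np.ones(len(X))])
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        raise DegenerateInputError("rank-deficient design matrix")
    return beta


def loo_predict(
    table: pd.DataFrame,
    features: Sequence[str] = DEFAULT_FEATURES,
    condition: str = "",
    outlier_fold: float = DEFAULT_OUTLIER_FOLD,
) -> PredictionReport:
    """Leave-one-out linear prediction of log10 concentrations.

    Each metabolite's concentration is predicted from an OLS model trained
    on all the others, which guards against over-fitting at these sample
    sizes.  Accuracy is the fraction of predictions within one order of
    magnitude of the measurement; the baseline is how many measurements lie
    within one order of magnitude of the (log-scale) mean concentration.
    """
    feats = list(features)
    sub = table[feats + ["log10_conc"]].dropna()
    X = sub[feats].to_numpy(dtype=float)
    y = sub["log10_conc"].to_numpy(dtype=float)
    n = len(y)
    if n < len(feats) + 2:
        raise DegenerateInputError(
            f"need at least {len(feats) + 2} complete rows, got {n}"
        )

    predicted = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        beta = _ols(X[mask], y[mask])
        predicted[i] = X[i] @ beta[:-1] + beta[-1]
        mask[i] = True

    residual = y - predicted
    fold_dev = 10.0 ** np.abs(residual)
    full_beta = _ols(X, y)
    model = RegressionModel(
        features=tuple(feats), coefficients=full_beta[:-1], intercept=float(full_beta[-1])
    )

    rows = pd.DataFrame(
        {
            "id": sub.index,
            "observed_log10": y,
            "predicted_log10": predicted,
            "residual": residual,
            "fold_deviation": fold_dev,
        }
    ).set_index("id")

    r2_fit = float(np.corrcoef(predicted, y)[0, 1] ** 2) if np.ptp(predicted) > 0 else 0.0
    return PredictionReport(
        condition=condition,
        rows=rows,
        model=model,
        accuracy_1oom=float(np.mean(np.abs(residual) <= 1.0)),
        baseline_1oom=float(np.mean(np.abs(y - y.mean()) <= 1.0)),
        mean_fold_deviation=float(10.0 ** np.mean(np.abs(residual))),
        mean_of_folds=float(np.mean(fold_dev)),
        r2_fit=r2_fit,
        outliers=sorted(rows.index[fold_dev > outlier_fold]),
        outlier_fold=outlier_fold,
    )


# ----------------------------------------------------------------- subgroups
def subgroup_correlations(
    table: pd.DataFrame,
    group: Iterable[str],
    parameter: str,
    condition: str = "",
) -> CorrelationResult:
    """Correlation restricted to a metabolite subgroup (e.g. amino acids)."""
    members = table.index.intersection(list(group))
    if len(members) < 3:
        raise DegenerateInputError(
            f"subgroup has only {len(members)} members in the table"
        )
    r, r2, n = correlate(table.loc[members], parameter)
    return CorrelationResult(condition=condition, parameter=parameter, n_used=n, r=r, r2=r2)


def per_phosphate_fold(table: pd.DataFrame, series: Mapping[str, int]) -> float:
    """Concentration fold-change per additional phosphate group.

    Fits log10 concentration against the phosphate count across a series of
    related compounds (e.g. AMP/ADP/ATP) and returns 10**slope.
    """
    members = table.index.intersection(list(series))
    counts = np.array([series[m] for m in members], dtype=float)
    if len(set(counts.tolist())) < 2:
        raise DegenerateInputError("need at least two distinct phosphate counts")
    y = table.loc[members, "log10_conc"].to_numpy(dtype=float)
    slope = _ols(counts[:, None], y)[0]
    return float(10.0**slope)


def range_effect(table: pd.DataFrame, parameter: str) -> float:
    """Model-implied concentration fold-span across the parameter's range.

    |OLS slope| times the observed parameter range, exponentiated: how many
    fold concentrations change from one end of the parameter range to the
    other under the single-parameter linear model.
    """
    sub = table[[parameter, "log10_conc"]].dropna()
    x = sub[parameter].to_numpy(dtype=float)
    y = sub["log10_conc"].to_numpy(dtype=float)
    _check_pair(x, y)
    slope = _ols(x[:, None], y)[0]
    return float(10.0 ** (abs(slope) * np.ptp(x)))
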