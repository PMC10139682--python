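"""Descriptive and comparative statistics for the trial table.

Covers the baseline-balance layer of a two-arm trial report: pooled-variance
two-sample t tests from summary statistics, Pearson chi-square tests of
contingency tables, Cronbach's alpha, Little's MCAR test over missingness
patterns, subgroup filters (evaluative respondents; elevated baseline EPDS),
and the covariate-flagging rule (arm imbalance or completer/dropout
difference at p < .05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fiml import em_saturated, extract_patterns
from .schema import ARMS, COVARIATES, TrialDataset, score_columns

logger = logging.getLogger(__name__)


class DegenerateInputError(ValueError):
    """Raised when a test statistic is undefined for the given input."""


@dataclass(frozen=True)
class TwoSampleSummary:
    """Summary statistics of two independent samples."""

    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int

    def __post_init__(self):
        if self.sd1 <= 0 or self.sd2 <= 0:
            raise DegenerateInputError("standard deviations must be positive")
        if self.n1 < 2 or self.n2 < 2:
            raise DegenerateInputError("each group needs at least 2 observations")


@dataclass(frozen=True)
class ContingencyTable:
    """A labelled r x c table of non-negative counts."""

    counts: tuple  # tuple of row tuples
    row_labels: tuple = ()
    col_labels: tuple = ()

    def to_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)


def pooled_t_test(s: TwoSampleSummary) -> tuple[float, int, float]:
    """Pooled-variance two-sample t test from summaries.

    Returns (t, df, two-sided p) with df = n1 + n2 - 2.  Antisymmetric under
    swapping the groups.
    """
    df = s.n1 + s.n2 - 2
    sp2 = ((s.n1 - 1) * s.sd1**2 + (s.n2 - 1) * s.sd2**2) / df
    if sp2 <= 0:
        raise DegenerateInputError("zero pooled variance")
    t = (s.mean1 - s.mean2) / np.sqrt(sp2 * (1.0 / s.n1 + 1.0 / s.n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), int(df), float(p)


def two_sample_t_from_values(x1, x2) -> tuple[float, int, float]:
    """Pooled t test computed from raw values (ignoring NaN)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    x1, x2 = x1[~np.isnan(x1)], x2[~np.isnan(x2)]
    return pooled_t_test(
        TwoSampleSummary(
            x1.mean(), x1.std(ddof=1), len(x1), x2.mean(), x2.std(ddof=1), len(x2)
        )
    )


def chi_square_test(table, correction: bool = False) -> tuple[float, int, float]:
    """Pearson chi-square test of independence for an r x c count table.

    No continuity correction by default (the convention the reference
    report's 2x2 cells follow).  Invariant under row/column permutation.
    """
    if isinstance(table, ContingencyTable):
        table = table.to_array()
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or tab.shape[0] < 2 or tab.shape[1] < 2:
        raise DegenerateInputError("table must be at least 2x2")
    if np.any(tab < 0):
        raise DegenerateInputError("counts must be non-negative")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise DegenerateInputError("zero marginal row or column")
    res = stats.chi2_contingency(tab, correction=correction)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum item variances / total variance).

    Rows with any missing item are dropped (listwise).
    """
    x = np.asarray(item_matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise DegenerateInputError("need an n x k matrix with k >= 2 items")
    x = x[~np.isnan(x).any(axis=1)]
    if x.shape[0] < 2:
        raise DegenerateInputError("need at least 2 complete rows")
    k = x.shape[1]
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise DegenerateInputError("zero total-score variance")
    item_var = x.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def little_mcar_test(ds, variables: list | None = None) -> tuple[float, int, float]:
    """Little's pattern-mean homogeneity test of MCAR.

    ``ds`` may be a :class:`TrialDataset` (variables default to all ten
    score columns) or an (n, p) array with NaN.  EM gives the grand mean and
    covariance; the statistic sums, over missingness patterns j,
    n_j * (ybar_j - mu_j)' Sigma_j^{-1} (ybar_j - mu_j) restricted to the
    observed variables, with df = sum_j p_j - p.  Requires at least two
    distinct patterns.
    """
    if isinstance(ds, TrialDataset):
        cols = variables or score_columns(ds.instruments)
        y = ds.data[cols].to_numpy(dtype=float)
    else:
        y = np.asarray(ds, dtype=float)
        if variables is not None:
            y = y[:, variables]
    patterns, _ = extract_patterns(y)
    if len(patterns) < 2:
        raise DegenerateInputError(
            "Little's test needs at least 2 distinct missingness patterns"
        )
    mu, sigma, _, _, _ = em_saturated(y)
    stat = 0.0
    sum_pj = 0
    for pat in patterns:
        o = pat.observed
        sub = sigma[np.ix_(o, o)]
        d = pat.mean - mu[o]
        try:
            stat += pat.n * float(d @ np.linalg.solve(sub, d))
        except np.linalg.LinAlgError as exc:
            raise DegenerateInputError(
                f"singular EM covariance for pattern {o.tolist()}"
            ) from exc
        sum_pj += o.size
    df = sum_pj - y.shape[1]
    p = float(stats.chi2.sf(stat, df)) if df > 0 else float("nan")
    return float(stat), int(df), p


# ---------------------------------------------------------------------------
# Subgroups and covariate flagging
# ---------------------------------------------------------------------------


def completed_both(ds: TrialDataset, instruments=None) -> np.ndarray:
    """Boolean mask: all listed instruments present at both waves (default:
    listwise across all five)."""
    instruments = list(instruments or ds.instruments)
    cols = score_columns(instruments)
    return ds.data[cols].notna().all(axis=1).to_numpy()


def subgroup_filter(ds: TrialDataset, rule: str, instruments=None) -> TrialDataset:
    """Apply a named subgroup rule.

    ``evaluative`` keeps participants who completed both assessments — by
    default listwise across all five instruments; pass ``instruments`` for
    the per-model variant.  ``epds_gt9`` keeps baseline EPDS strictly above 9.
    """
    if rule == "evaluative":
        return ds.subset(completed_both(ds, instruments), note="evaluative")
    if rule == "epds_gt9":
        epds0 = ds.data["EPDS_T0"]
        return ds.subset((epds0.notna() & (epds0 > 9)).to_numpy(), note="epds_gt9")
    raise ValueError(f"unknown subgroup rule {rule!r}")


def _compare_groups(values: pd.Series, mask_a, mask_b, kind: str) -> float:
    """p-value of an arm or completer contrast for one covariate."""
    if min(int(np.sum(mask_a)), int(np.sum(mask_b))) < 2:
        return 1.0  # one side of the contrast is (near) empty: no evidence
    a, b = values[mask_a], values[mask_b]
    if kind == "numeric":
        _, _, p = two_sample_t_from_values(a.to_numpy(float), b.to_numpy(float))
        return p
    tab = pd.crosstab(values, pd.Series(np.where(mask_a, "a", "b"), index=values.index))
    tab = tab.loc[:, ["a", "b"]] if set(tab.columns) == {"a", "b"} else tab
    if tab.shape[0] < 2:
        return 1.0
    _, _, p = chi_square_test(tab.to_numpy())
    return p


def flag_covariates(ds: TrialDataset, alpha: float = 0.05) -> list[str]:
    """Covariates imbalanced between arms or between completers and dropouts.

    A covariate is flagged when either contrast has p below ``alpha``.
    Covariates absent from the table are skipped with a log entry.
    """
    flags = []
    arm_mask = (ds.data["arm"] == "intervention").to_numpy()
    comp_mask = completed_both(ds)
    for name, kind in COVARIATES.items():
        if name not in ds.data.columns:
            logger.warning("covariate %s absent from dataset; not flagged", name)
            continue
        values = ds.data[name]
        p_arm = _compare_groups(values, arm_mask, ~arm_mask, kind)
        p_comp = _compare_groups(values, comp_mask, ~comp_mask, kind)
        if p_arm < alpha or p_comp < alpha:
            flags.append(name)
    return flags


def describe(ds: TrialDataset) -> dict:
    """Arm-comparison report: counts, per-covariate summaries with test
    statistics, per-instrument descriptives, and wave-2 missingness."""
    out: dict = {"n": ds.arm_counts(), "covariates": {}, "instruments": {},
                 "missingness_t1": ds.missingness_rates("T1")}
    arm_mask = (ds.data["arm"] == "intervention").to_numpy()
    for name, kind in COVARIATES.items():
        if name not in ds.data.columns:
            continue
        entry: dict = {"kind": kind}
        if kind == "numeric":
            for arm in ARMS:
                vals = ds.data.loc[ds.data["arm"] == arm, name].dropna()
                entry[arm] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1)),
                              "n": int(len(vals))}
            t, df, p = two_sample_t_from_values(
                ds.data.loc[arm_mask, name], ds.data.loc[~arm_mask, name]
            )
            entry["test"] = {"t": t, "df": df, "p": p}
        else:
            tab = pd.crosstab(ds.data[name], ds.data["arm"])
            entry["counts"] = {
                str(level): {arm: int(tab.loc[level].get(arm, 0)) for arm in ARMS}
                for level in tab.index
            }
            if tab.shape[0] >= 2:
                chi2, df, p = chi_square_test(tab.to_numpy())
                entry["test"] = {"chi2": chi2, "df": df, "p": p}
        out["covariates"][name] = entry
    for inst in ds.instruments:
        entry = {}
        for arm in ARMS:
            sub = ds.data[ds.data["arm"] == arm]
            for wave in ("T0", "T1"):
                vals = sub[f"{inst}_{wave}"].dropna()
                entry[f"{arm}_{wave}"] = {
                    "mean": float(vals.mean()) if len(vals) else float("nan"),
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
                    "n": int(len(vals)),
                }
        out["instruments"][inst] = entry
    try:
        chi2, df, p = little_mcar_test(ds)
        out["little_mcar"] = {"chi2": chi2, "df": df, "p": p}
    except DegenerateInputError:
        out["little_mcar"] = None
    out["flagged_covariates"] = flag_covariates(ds)
    return out
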