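"""Fit indices, nested-model comparisons, and the orchestrated analysis
battery: per-instrument univariate constrained-vs-unconstrained multigroup
LCS comparisons, subgroup reruns, and the nested two-wave sequence A -> D.

Fit-index conventions
---------------------
chi2 of a structured model M is 2*(ll_saturated - ll_M) with df from
parameter counting.  CFI uses the per-group free-means/free-variances,
zero-covariance baseline.  RMSEA uses the sqrt(G) multigroup scaling with
N = total sample size,

    RMSEA = sqrt(G) * sqrt(max(chi2 - df, 0) / (df * N)),

the convention that reproduces the reference report's printed values from
its printed (chi2, df) pairs; its 90% CI inverts the noncentral chi-square
distribution in the noncentrality parameter and maps through the same
scaling, and the close-fit p-value tests RMSEA <= 0.05.  SRMR is the
group-size-weighted root mean square of standardized mean and covariance
residuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .descriptives import subgroup_filter
from .fiml import FitResult, fit_independence, fit_model, fit_saturated, standardize
from .lcs import ConstraintMap, count_df, two_wave_constraints, univariate_constraints
from .models import TwoWaveLcsModel, UnivariateLcsModel
from .schema import ARMS, TrialDataset

LCS_PARAM_BLOCKS = ("mu_delta", "var_delta", "cov0_delta")


@dataclass
class FitStats:
    """Global fit of one structured model."""

    chi2: float
    df: int
    p: float
    cfi: float
    rmsea: float
    rmsea_ci90: tuple
    rmsea_close_p: float
    srmr: float
    n_total: int
    n_groups: int
    saturated_flag: bool = False

    def to_dict(self) -> dict:
        return {
            "chi2": self.chi2, "df": self.df, "p": self.p, "cfi": self.cfi,
            "rmsea": self.rmsea, "rmsea_ci90": list(self.rmsea_ci90),
            "rmsea_close_p": self.rmsea_close_p, "srmr": self.srmr,
            "n_total": self.n_total, "n_groups": self.n_groups,
        }


@dataclass
class NestedComparison:
    """Likelihood-ratio comparison of a nested model against a general one."""

    nested: str
    general: str
    delta_chi2: float
    delta_df: int
    p: float
    preferred: str

    def to_dict(self) -> dict:
        return {"nested": self.nested, "general": self.general,
                "delta_chi2": self.delta_chi2, "delta_df": self.delta_df,
                "p": self.p, "preferred": self.preferred}


def rmsea_point(chi2: float, df: int, n_total: int, n_groups: int = 2) -> float:
    """Multigroup RMSEA from a (chi2, df) pair at total sample size N."""
    if df <= 0:
        return 0.0
    return float(
        np.sqrt(n_groups) * np.sqrt(max(chi2 - df, 0.0) / (df * n_total))
    )


def rmsea_ci(chi2: float, df: int, n_total: int, n_groups: int = 2,
             level: float = 0.90) -> tuple:
    """Invert the noncentral chi-square in its noncentrality to a CI, then
    map lambda -> sqrt(G) * sqrt(lambda / (df * N))."""
    if df <= 0:
        return (0.0, 0.0)
    lo_q, hi_q = (1.0 + level) / 2.0, (1.0 - level) / 2.0

    def bound(q: float) -> float:
        # lambda with P(ncx2(df, lam) <= chi2) = q; cdf decreases in lambda.
        if stats.ncx2.cdf(chi2, df, 1e-10) < q:
            return 0.0
        hi = max(chi2, 1.0)
        while stats.ncx2.cdf(chi2, df, hi) > q:
            hi *= 2.0
            if hi > 1e7:
                break
        lam = optimize.brentq(
            lambda l: stats.ncx2.cdf(chi2, df, l) - q, 1e-10, hi, xtol=1e-8
        )
        return float(np.sqrt(n_groups) * np.sqrt(lam / (df * n_total)))

    return (bound(lo_q), bound(hi_q))


def rmsea_close_fit_p(chi2: float, df: int, n_total: int, n_groups: int = 2,
                      rmsea0: float = 0.05) -> float:
    """P(chi2_df(lambda0) >= chi2) with lambda0 = N * df * rmsea0^2 / G."""
    if df <= 0:
        return float("nan")
    lam0 = n_total * df * rmsea0**2 / n_groups
    return float(stats.ncx2.sf(chi2, df, lam0))


def _srmr(fit: FitResult, saturated: FitResult) -> float:
    total_n = sum(fit.n_used)
    out = 0.0
    for n_g, (mu_m, cov_m), (mu_s, cov_s) in zip(
        fit.n_used, fit.group_moments, saturated.group_moments
    ):
        sd = np.sqrt(np.diag(cov_s))
        resid_sq = []
        p = len(mu_s)
        for i in range(p):
            resid_sq.append(((mu_s[i] - mu_m[i]) / sd[i]) ** 2)
            for j in range(i + 1):
                resid_sq.append(
                    ((cov_s[i, j] - cov_m[i, j]) / (sd[i] * sd[j])) ** 2
                )
        out += n_g / total_n * float(np.sqrt(np.mean(resid_sq)))
    return out


def fit_stats(fit: FitResult, saturated: FitResult, independence: FitResult,
              df: int | None = None, df_baseline: int | None = None) -> FitStats:
    """Assemble chi2/CFI/RMSEA/SRMR for a fitted structured model.

    All three fits must be on identical data and groups.  ``df`` defaults to
    moment count minus ``fit.n_params``; a model fitting exactly as many
    parameters as moments has df 0 and RMSEA is reported as 0 with the
    saturated flag set.
    """
    n_groups = len(fit.n_used)
    p = len(fit.group_moments[0][0])
    n_moments = n_groups * (p + p * (p + 1) // 2)
    if df is None:
        df = n_moments - fit.n_params
    if df_baseline is None:
        df_baseline = n_moments - independence.n_params
    n_total = sum(fit.n_used)
    chi2 = max(2.0 * (saturated.loglik - fit.loglik), 0.0)
    chi2_b = max(2.0 * (saturated.loglik - independence.loglik), 0.0)
    p_val = float(stats.chi2.sf(chi2, df)) if df > 0 else float("nan")
    denom = max(chi2_b - df_baseline, chi2 - df, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - max(chi2 - df, 0.0) / denom
    cfi = float(min(max(cfi, 0.0), 1.0))
    return FitStats(
        chi2=float(chi2),
        df=int(df),
        p=p_val,
        cfi=cfi,
        rmsea=rmsea_point(chi2, df, n_total, n_groups),
        rmsea_ci90=rmsea_ci(chi2, df, n_total, n_groups),
        rmsea_close_p=rmsea_close_fit_p(chi2, df, n_total, n_groups),
        srmr=_srmr(fit, saturated),
        n_total=n_total,
        n_groups=n_groups,
        saturated_flag=df <= 0,
    )


def lrt(nested_stats: FitStats, general_stats: FitStats,
        nested_label: str = "nested", general_label: str = "general",
        alpha: float = 0.05) -> NestedComparison:
    """Chi-square difference test of a nested pair fitted to the same data.

    Delta chi2 below -1e-6 signals a convergence failure and raises; small
    negative values are floored at zero.  The preferred model follows the
    conventional rule: the general model when the test is significant,
    otherwise the more parsimonious nested one.
    """
    d_chi2 = nested_stats.chi2 - general_stats.chi2
    if d_chi2 < -1e-6:
        raise RuntimeError(
            f"negative chi-square difference ({d_chi2:.3g}): nested model "
            "fits better than the general one — check convergence"
        )
    d_chi2 = max(d_chi2, 0.0)
    d_df = nested_stats.df - general_stats.df
    if d_df <= 0:
        raise ValueError("nested model must have larger df")
    p = float(stats.chi2.sf(d_chi2, d_df))
    return NestedComparison(
        nested=nested_label, general=general_label,
        delta_chi2=float(d_chi2), delta_df=int(d_df), p=p,
        preferred=general_label if p < alpha else nested_label,
    )


# ---------------------------------------------------------------------------
# Covariate adjustment
# ---------------------------------------------------------------------------


def residualize_on_covariates(ds: TrialDataset, covariates: list[str]) -> TrialDataset:
    """Partial the listed baseline covariates out of every score column.

    Categorical covariates are dummy-coded; each score column is replaced by
    its own mean plus the OLS residual on the covariates (fitted over rows
    where the score and all covariates are present).  This conditions the
    moment model on the covariates with effects pooled across arms.
    """
    data = ds.data.copy()
    X = pd.get_dummies(ds.data[covariates], drop_first=True, dtype=float)
    X.insert(0, "_const", 1.0)
    x_ok = X.notna().all(axis=1).to_numpy()
    xmat = X.to_numpy(dtype=float)
    from .schema import score_columns

    for col in score_columns(ds.instruments):
        y = data[col].to_numpy(dtype=float)
        rows = x_ok & ~np.isnan(y)
        if rows.sum() <= xmat.shape[1]:
            continue
        beta, *_ = np.linalg.lstsq(xmat[rows], y[rows], rcond=None)
        resid = y[rows] - xmat[rows] @ beta
        adj = np.full_like(y, np.nan)
        adj[rows] = y[rows][~np.isnan(y[rows])].mean() + resid
        data[col] = adj
    prov = dict(ds.provenance)
    prov["covariate_adjusted"] = list(covariates)
    return TrialDataset(data=data, schema=ds.schema, provenance=prov, continuous=True)


# ---------------------------------------------------------------------------
# Batteries
# ---------------------------------------------------------------------------


def _instrument_groups(ds: TrialDataset, instrument: str) -> list[np.ndarray]:
    groups = ds.arm_matrices([instrument])
    counts = ds.arm_counts()
    if min(counts.values()) == 0:
        raise ValueError(
            "multigroup battery needs records in both arms; "
            f"got {counts}"
        )
    return groups


def fit_univariate_pair(
    ds: TrialDataset, instrument: str, compute_se: bool = True
) -> dict:
    """Fit the constrained and unconstrained two-group LCS for one instrument.

    Returns fits, fit statistics and the Delta-chi2 comparison.
    """
    groups = _instrument_groups(ds, instrument)
    sat = fit_saturated(groups)
    ind = fit_independence(groups)
    out: dict = {"instrument": instrument, "saturated": sat, "independence": ind}
    for constrained in (True, False):
        cmap = univariate_constraints(constrained)
        model = UnivariateLcsModel(cmap, group_labels=list(ARMS),
                                   instrument=instrument)
        fit = fit_model(groups, model, compute_se=compute_se)
        _, _, df = count_df(cmap, n_variables=1, n_groups=2)
        stats_ = fit_stats(fit, sat, ind, df=df)
        key = "constrained" if constrained else "unconstrained"
        out[key] = {"model": model, "fit": fit, "stats": stats_}
    out["comparison"] = lrt(
        out["constrained"]["stats"], out["unconstrained"]["stats"],
        nested_label=f"{instrument}-constrained",
        general_label=f"{instrument}-unconstrained",
    )
    return out


def _univariate_entry(pair: dict) -> list[dict]:
    entries = []
    for key in ("constrained", "unconstrained"):
        model: UnivariateLcsModel = pair[key]["model"]
        fit: FitResult = pair[key]["fit"]
        params = []
        for g, arm in enumerate(ARMS):
            for block in LCS_PARAM_BLOCKS:
                est, se, p = model.extract(fit, block, g)
                params.append(
                    {"name": f"{block}[{arm}]", "estimate": est, "se": se, "p": p}
                )
        entries.append(
            {
                "model": f"{pair['instrument']}-{key}",
                "converged": bool(fit.converged),
                "loglik": fit.loglik,
                "fit_stats": pair[key]["stats"].to_dict(),
                "parameters": params,
            }
        )
    return entries


def run_univariate_battery(
    ds: TrialDataset,
    instruments=None,
    subgroup: str | None = None,
    covariates: list[str] | None = None,
    compute_se: bool = True,
) -> dict:
    """Per-instrument constrained/unconstrained multigroup LCS battery.

    ``subgroup`` of ``evaluative`` or ``epds_gt9`` reruns on the filtered
    table; ``covariates`` (list of column names) residualizes scores first.
    Instruments whose subgroup is too small for identification are skipped
    with a note.
    """
    if covariates:
        ds = residualize_on_covariates(ds, covariates)
    if subgroup:
        ds = subgroup_filter(ds, subgroup)
    if min(ds.arm_counts().values()) == 0:
        raise ValueError(
            f"multigroup battery needs records in both arms; got {ds.arm_counts()}"
        )
    report: dict = {"meta": {"subgroup": subgroup or "none",
                             "covariates": covariates or [],
                             "n": ds.arm_counts()},
                    "models": [], "comparisons": [], "skipped": []}
    for inst in instruments or ds.instruments:
        counts = ds.arm_counts()
        if min(counts.values()) < 10:
            report["skipped"].append({"instrument": inst, "reason": f"n={counts}"})
            continue
        pair = fit_univariate_pair(ds, inst, compute_se=compute_se)
        report["models"].extend(_univariate_entry(pair))
        report["comparisons"].append(pair["comparison"].to_dict())
    return report


def run_2wlcs_sequence(
    ds: TrialDataset,
    covariates: list[str] | None = None,
    compute_se: bool = True,
    labels: str = "ABCD",
) -> dict:
    """Fit the nested multigroup 2W-LCS sequence and sequential comparisons.

    Models run A (fully constrained) through D (unconstrained); each emits
    global fit statistics, and consecutive pairs a Delta-chi2 test.  The
    standardized per-group solution (baseline correlations, cross-lagged and
    change-to-change paths, change correlations) is attached for the last
    model when standard errors were computed.
    """
    if covariates:
        ds = residualize_on_covariates(ds, covariates)
    groups = ds.arm_matrices()
    sat = fit_saturated(groups)
    ind = fit_independence(groups)
    report: dict = {"meta": {"covariates": covariates or [], "n": ds.arm_counts()},
                    "models": [], "comparisons": []}
    fitted: list[tuple[str, TwoWaveLcsModel, FitResult, FitStats]] = []
    start = None
    for label in labels:
        cmap = two_wave_constraints(label)
        model = TwoWaveLcsModel(cmap, group_labels=list(ARMS))
        # Warm-start each model from the previous (nested) solution.
        init = None
        if start is not None:
            init = _carry_theta(fitted[-1][1], fitted[-1][2].estimates, model)
        fit = fit_model(groups, model, start=init,
                        compute_se=compute_se and label == labels[-1])
        _, _, df = count_df(cmap, n_variables=5, n_groups=2)
        st = fit_stats(fit, sat, ind, df=df)
        entry = {
            "model": f"2wlcs-{label}", "converged": bool(fit.converged),
            "loglik": fit.loglik, "fit_stats": st.to_dict(),
            "parameters": fit.to_dict()["parameters"],
        }
        report["models"].append(entry)
        fitted.append((label, model, fit, st))
        start = fit.estimates
    for (la, _, _, sa), (lb, mb, fb, sb) in zip(fitted[:-1], fitted[1:]):
        report["comparisons"].append(
            lrt(sa, sb, nested_label=f"2wlcs-{la}", general_label=f"2wlcs-{lb}").to_dict()
        )
    last_label, last_model, last_fit, _ = fitted[-1]
    if last_fit.param_cov is not None:
        vals, ses = standardize(last_fit, last_model.standardized_map())
        names = last_model.standardized_names()
        std = []
        for nm, v, s in zip(names, vals, ses if ses is not None else [None] * len(vals)):
            entry = {"name": nm, "estimate": float(v)}
            if s is not None and np.isfinite(s):
                entry["se"] = float(s)
                entry["p"] = float(2 * stats.norm.sf(abs(v / s))) if s > 0 else None
            std.append(entry)
        report["standardized"] = {"model": f"2wlcs-{last_label}", "parameters": std}
    return report


def _carry_theta(prev_model: TwoWaveLcsModel, prev_theta: np.ndarray,
                 new_model: TwoWaveLcsModel) -> np.ndarray:
    """Map a fitted nested solution onto a freer layout (duplicate shared
    blocks per group) as a warm start."""
    theta = np.empty(new_model.layout.size)
    for block, g, sl in new_model.layout.entries:
        theta[sl] = prev_model.layout.get(prev_theta, block, 0 if g is None else g)
    return theta
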